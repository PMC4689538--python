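"""Enumeration of stabilizable control sign patterns.

A two-compartment lineage is stable iff Delta = q_x*p_y - q_y*p_x > 0 and
B = 2*L**S**(p_x - p_y) - q_y > 0.  A *sign pattern* fixes only the signs of
the four controls; it is called stabilizable when strictly positive magnitudes
for its nonzero controls, some L* > 0 and some S* in (0, 1] exist that satisfy
both conditions.  Because the magnitudes, L* and S* can be scaled freely and
independently, feasibility reduces to an exact calculus on signs (derivation
in docs/methods.md), which a seeded random-magnitude sampler cross-checks.

Minimal systems are the stabilizable patterns with exactly two nonzero
controls; irreducible three-control systems are stabilizable patterns that
stop being stabilizable whenever any single control is zeroed.  There are
exactly two of the former and three of the latter.
"""

from __future__ import annotations

import itertools
from typing import Iterator

import numpy as np

from .control import SignPattern
from .errors import InvalidParameterError

__all__ = [
    "is_stabilizable",
    "is_stabilizable_sampled",
    "enumerate_minimal",
    "all_sign_patterns",
]


def all_sign_patterns() -> Iterator[SignPattern]:
    """All 81 sign patterns over the three-valued alphabet."""
    for signs in itertools.product((-1, 0, 1), repeat=4):
        yield SignPattern(*signs)


def is_stabilizable(pattern: SignPattern) -> bool:
    """Exact decision: does the pattern admit Delta > 0 and B > 0?

    Case analysis on sign(q_y); writes sa = sign(q_x*p_y) for the sign of the
    first term of Delta.  See docs/methods.md for the derivation.
    """
    sqx, sqy, spx, spy = pattern.signs
    sa = sqx * spy
    if sqy == -1:
        # -q_y > 0 stabilizes B at small 2L*S*; Delta > 0 needs its positive
        # term: q_x*p_y > 0 achievable, or -q_y*p_x > 0 i.e. p_x > 0.
        return sa == 1 or spx == 1
    if sqy == 0:
        # B = 2L*S*(p_x - p_y): need p_x - p_y > 0 achievable; Delta = q_x*p_y.
        return sa == 1 and (spx == 1 or spy == -1)
    # q_y > 0: B > 0 forces p_x - p_y > 0 dominating q_y.
    p_plus = (spx == 1) or (spy == -1)
    if not p_plus:
        return False
    if spx == 1:
        # -q_y*p_x < 0 is forced in Delta, so the q_x*p_y term must win.
        return sa == 1
    # p_x <= 0: the -q_y*p_x term of Delta is >= 0; feasible if it is strictly
    # positive (p_x < 0) or if q_x*p_y can be made positive.
    return sa == 1 or spx == -1


def is_stabilizable_sampled(
    pattern: SignPattern, n_draws: int = 1000, seed: int = 0
) -> bool:
    """Monte-Carlo cross-check of :func:`is_stabilizable`.

    Draws control magnitudes and L* log-uniformly on [1e-2, 1e2] and S*
    uniformly on (0, 1]; returns True if any draw satisfies both stability
    conditions.  Seeded for reproducibility.
    """
    rng = np.random.default_rng(seed)
    sqx, sqy, spx, spy = pattern.signs
    for _ in range(n_draws):
        mags = 10.0 ** rng.uniform(-2, 2, size=4)
        q_x, q_y, p_x, p_y = (s * m for s, m in zip((sqx, sqy, spx, spy), mags))
        L_star = 10.0 ** rng.uniform(-2, 2)
        S_star = 1.0 - rng.uniform(0.0, 1.0)  # in (0, 1]
        delta = q_x * p_y - q_y * p_x
        b = 2.0 * L_star * S_star * (p_x - p_y) - q_y
        if delta > 0.0 and b > 0.0:
            return True
    return False


def _is_irreducible(pattern: SignPattern) -> bool:
    """No single-control zeroing leaves a stabilizable pattern."""
    return not any(
        is_stabilizable(pattern.zeroed(name)) for name in pattern.support
    )


def _label(pattern: SignPattern) -> SignPattern:
    from .lna import MINIMAL_PATTERNS

    for name, signs in MINIMAL_PATTERNS.items():
        if pattern.signs == signs:
            return SignPattern(*pattern.signs, label=name)
    return pattern


def enumerate_minimal(k: int, allow_full: bool = False) -> list[SignPattern]:
    """Stabilizable sign patterns with exactly ``k`` nonzero controls.

    For k = 2 these are the minimal systems (exactly two exist); for k = 3
    only irreducible patterns are returned -- those that cannot be reduced to a
    stabilizable two-control system by zeroing one control (exactly three
    exist).  ``allow_full=True`` additionally permits k = 4 (all stabilizable
    four-control patterns, no irreducibility filter, no labels).
    """
    valid = {2, 3} | ({4} if allow_full else set())
    if k not in valid:
        raise InvalidParameterError(f"k must be in {sorted(valid)}, got {k}")
    out = []
    for pattern in all_sign_patterns():
        if pattern.n_controls != k or not is_stabilizable(pattern):
            continue
        if k == 3 and not _is_irreducible(pattern):
            continue
        out.append(_label(pattern) if k in (2, 3) else pattern)
    return out
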