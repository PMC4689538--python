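"""Linear-noise analysis of the mixed-divisions steady state.

Expanding the master equation of the update process to leading order around
the mixed equilibrium (van Kampen-style weak-feedback expansion, feedback
strength epsilon << 1) gives Gaussian fluctuations with

    Var[I] = K_x / (4*B*Delta),      Var[J] = K_y / (4*B*Delta),

where, writing L* and S* for the equilibrium division rate and symmetric
fraction and (q_x, q_y, p_x, p_y) for the controls,

    Delta = q_x*p_y - q_y*p_x,
    B     = 2*L**S**(p_x - p_y) - q_y,
    K_x   = 2*L**S**Delta + q_y^2 + 8*L*^2*S**p_y^2,
    K_y   = 2*L**(2 + S*)*Delta + q_x^2 + 8*L*^2*S**p_x^2.

The state is stable iff Delta > 0 and B > 0.  Since S* enters only through B,
the stability boundary is the critical symmetric fraction

    S_c = q_y / (2*L**(p_x - p_y)),

with B > 0 iff S* > S_c when p_x > p_y (and S* < S_c when p_x < p_y).  The
derivatives of the variances in S* are available in closed form and are
monotone in S* for fixed controls:

    dVar[I]/dS* = (L*/2)/(B^2*Delta) * p_y*q_y*(q_y - q_x - 4*L**p_y),
    dVar[J]/dS* = (L*/2)/(B^2*Delta) * (p_x*q_x - Delta)*(q_y - q_x - 4*L**p_y).

(The prefactor is L*/2, the exact derivative of Var = K/(4*B*Delta); it is
often quoted as L*^2, which coincides with L*/2 exactly when L* = 1/2 -- the
value every network with complementary death D = 1 - L takes at equilibrium.)

``solve_moment_system`` provides an independent route to the same variances by
solving the full linear system of first and second moment equations (including
the first-derivative terms of L, D and S, which cancel), and is used as a
cross-check oracle in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Literal, Optional

import numpy as np

from .control import ControlNetwork, Controls, SignPattern
from .equilibrium import Equilibrium
from .errors import InvalidParameterError, NonHyperbolicError

__all__ = [
    "LNAResult",
    "SensitivityResult",
    "ClassificationRecord",
    "lna_moments",
    "stability",
    "critical_symmetry",
    "variance_sensitivity",
    "classify_network",
    "solve_moment_system",
    "sensitivity_symbolic",
]


@dataclass(frozen=True)
class LNAResult:
    """Leading-order moments and stability diagnostics at a mixed equilibrium."""

    mean_I: float
    mean_J: float
    Delta: float
    B: float
    K_x: float
    K_y: float
    var_I: float
    var_J: float
    stable: bool
    S_c: float

    def report(self) -> dict:
        return {
            "mean_I": self.mean_I,
            "mean_J": self.mean_J,
            "Delta": self.Delta,
            "B": self.B,
            "Kx": self.K_x,
            "Ky": self.K_y,
            "varI": self.var_I,
            "varJ": self.var_J,
            "stable": self.stable,
            "Sc": self.S_c,
        }


@dataclass(frozen=True)
class SensitivityResult:
    """Derivatives of the two population variances with respect to S*."""

    dvarI_dS: float
    dvarJ_dS: float


def _delta(c: Controls) -> float:
    return c.q_x * c.p_y - c.q_y * c.p_x


def _B(c: Controls, L_star: float, S_star: float) -> float:
    return 2.0 * L_star * S_star * (c.p_x - c.p_y) - c.q_y


def critical_symmetry(controls: Controls, L_star: float) -> float:
    """S_c = q_y / (2 L* (p_x - p_y)), the symmetry at which B changes sign.

    When p_x = p_y, B does not depend on S*; the convention is signed infinity
    (-inf for q_y < 0, +inf for q_y > 0, nan only if additionally q_y = 0, in
    which case B is identically zero and the system is non-hyperbolic).
    """
    diff = controls.p_x - controls.p_y
    if diff == 0.0:
        if controls.q_y < 0:
            return -math.inf
        if controls.q_y > 0:
            return math.inf
        return math.nan
    return controls.q_y / (2.0 * L_star * diff)


def stability(
    controls: Controls, L_star: float, S_star: float
) -> tuple[bool, float]:
    """Stability verdict (Delta > 0 and B > 0) and the critical symmetry S_c.

    The stable window in S* is S* > S_c when p_x > p_y and S* < S_c when
    p_x < p_y; when p_x = p_y the verdict is independent of S*.
    """
    if not (L_star > 0):
        raise InvalidParameterError(f"L_star must be positive, got {L_star}")
    delta = _delta(controls)
    b = _B(controls, L_star, S_star)
    return (delta > 0.0 and b > 0.0), critical_symmetry(controls, L_star)


def lna_moments(eq: Equilibrium, controls: Controls, S_star: float) -> LNAResult:
    """Leading-order means, variances and stability at a mixed equilibrium.

    Means equal the deterministic populations (i0, j0); variances follow the
    closed forms above.  Raises :class:`NonHyperbolicError` when Delta = 0 or
    B = 0 (the linearization is degenerate and the variances are undefined).
    """
    if eq.kind != "mixed":
        raise InvalidParameterError(
            "linear-noise variances are available only at the mixed steady state; "
            "the purely asymmetric branch is simulation-only"
        )
    if not (0 < S_star <= 1):
        raise InvalidParameterError(f"S_star must lie in (0, 1], got {S_star}")
    L_star = eq.L_star
    delta = _delta(controls)
    b = _B(controls, L_star, S_star)
    if delta == 0.0 or b == 0.0:
        raise NonHyperbolicError(
            f"degenerate linearization (Delta={delta:g}, B={b:g}): variances undefined"
        )
    k_x = 2.0 * L_star * S_star * delta + controls.q_y**2 \
        + 8.0 * L_star**2 * S_star * controls.p_y**2
    k_y = 2.0 * L_star * (2.0 + S_star) * delta + controls.q_x**2 \
        + 8.0 * L_star**2 * S_star * controls.p_x**2
    denom = 4.0 * b * delta
    return LNAResult(
        mean_I=eq.i0,
        mean_J=eq.j0,
        Delta=delta,
        B=b,
        K_x=k_x,
        K_y=k_y,
        var_I=k_x / denom,
        var_J=k_y / denom,
        stable=(delta > 0.0 and b > 0.0),
        S_c=critical_symmetry(controls, L_star),
    )


def variance_sensitivity(
    controls: Controls, L_star: float, S_star: float
) -> SensitivityResult:
    """Closed-form derivatives of Var[I] and Var[J] with respect to S*."""
    delta = _delta(controls)
    b = _B(controls, L_star, S_star)
    if delta == 0.0 or b == 0.0:
        raise NonHyperbolicError(
            f"degenerate linearization (Delta={delta:g}, B={b:g})"
        )
    common = 0.5 * L_star / (b**2 * delta) * (controls.q_y - controls.q_x - 4.0 * L_star * controls.p_y)
    return SensitivityResult(
        dvarI_dS=common * controls.p_y * controls.q_y + 0.0,  # +0.0 avoids -0.0
        dvarJ_dS=common * (controls.p_x * controls.q_x - delta) + 0.0,
    )


def solve_moment_system(
    controls: Controls,
    L_star: float,
    S_star: float,
    l_x: float = 0.0,
    l_y: float = 0.0,
    d_x: float = 0.0,
    d_y: float = 0.0,
    s_x: float = 0.0,
    s_y: float = 0.0,
) -> dict:
    """Solve the full linear first/second-moment system directly.

    Unknowns are the centred moments (X10, X01, X20, X02, X11); the first-moment
    equations are homogeneous with determinant -Delta != 0, forcing X10 = X01 = 0,
    so the first-derivative terms of L, D and S (l_x, ..., s_y) drop out of the
    result -- they are accepted here so that the cancellation can be verified.
    Returns a dict with the raw moments and var_I = X20, var_J = X02.

    This is an independent brute-force route to the closed-form variances and
    agrees with :func:`lna_moments` to machine precision.
    """
    q_x, q_y, p_x, p_y = controls.q_x, controls.q_y, controls.p_x, controls.p_y
    L, S = L_star, S_star
    delta = _delta(controls)
    if delta == 0.0:
        raise NonHyperbolicError("Delta = 0: first-moment system is singular")
    a = np.zeros((5, 5))
    rhs = np.zeros(5)
    # unknown order: X10, X01, X20, X02, X11
    # d<i>/dt = 0
    a[0, 0] = -2.0 * L * S * p_x
    a[0, 1] = -2.0 * L * S * p_y
    # d<j>/dt = 0
    a[1, 0] = 2.0 * L * S * p_x + q_x
    a[1, 1] = 2.0 * L * S * p_y + q_y
    # d<i^2>/dt = 0
    a[2, 0] = S * l_x + L * s_x
    a[2, 1] = S * l_y + L * s_y
    a[2, 2] = -4.0 * L * S * p_x
    a[2, 4] = -4.0 * L * S * p_y
    rhs[2] = -L * S
    # d<ij>/dt = 0
    a[3, 0] = -(S * l_x + L * s_x + 2.0 * L * S * p_x)
    a[3, 1] = -(S * l_y + L * s_y + 2.0 * L * S * p_y)
    a[3, 2] = 2.0 * L * S * p_x + q_x
    a[3, 3] = -2.0 * L * S * p_y
    a[3, 4] = 2.0 * L * S * (p_y - p_x) + q_y
    rhs[3] = L * S
    # d<j^2>/dt = 0
    a[4, 0] = S * (4.0 * L * p_x + l_x) + l_x + d_x + L * s_x
    a[4, 1] = S * (4.0 * L * p_y + l_y) + l_y + d_y + L * s_y
    a[4, 4] = 4.0 * L * S * p_x + 2.0 * q_x
    a[4, 3] = 4.0 * L * S * p_y + 2.0 * q_y
    rhs[4] = -L * (2.0 + S)
    sol = np.linalg.solve(a, rhs)
    x10, x01, x20, x02, x11 = sol
    return {
        "X10": x10,
        "X01": x01,
        "X20": x20,
        "X02": x02,
        "X11": x11,
        "var_I": x20 - x10**2,
        "var_J": x02 - x01**2,
    }


@lru_cache(maxsize=8)
def _sympy_sensitivities():
    import sympy as sp

    L, S, px, py, qx, qy = sp.symbols("L S p_x p_y q_x q_y", real=True)
    delta = qx * py - qy * px
    b = 2 * L * S * (px - py) - qy
    kx = 2 * L * S * delta + qy**2 + 8 * L**2 * S * py**2
    ky = 2 * L * (2 + S) * delta + qx**2 + 8 * L**2 * S * px**2
    var_i = kx / (4 * b * delta)
    var_j = ky / (4 * b * delta)
    return (L, S, px, py, qx, qy), (sp.diff(var_i, S), sp.diff(var_j, S))


def sensitivity_symbolic(pattern: SignPattern, which: Literal["I", "J"] = "I"):
    """Symbolic dVar/dS* with the pattern's zero controls substituted.

    Differentiates the closed-form variance symbolically, sets the controls
    that are zero in ``pattern`` to zero, and simplifies.  Returns a sympy
    expression (the integer 0 when the derivative vanishes identically, as in
    the two-control system with only q_x, p_y and in the q_y = 0 three-control
    family).
    """
    import sympy as sp

    syms, (d_i, d_j) = _sympy_sensitivities()
    _, _, px, py, qx, qy = syms
    expr = d_i if which == "I" else d_j
    subs = {}
    for sym, sign in zip((qx, qy, px, py), pattern.signs):
        if sign == 0:
            subs[sym] = 0
    return sp.simplify(expr.subs(subs))


# -- classification of sign patterns ----------------------------------------

#: Canonical minimal (two-control) and irreducible (three-control) systems.
#: Signs are in the order (q_x, q_y, p_x, p_y).
MINIMAL_PATTERNS: dict[str, tuple[int, int, int, int]] = {
    "#1": (-1, 0, 0, -1),
    "#2": (0, -1, 1, 0),
    "#3": (1, -1, 0, 1),
    "#4": (0, 1, -1, -1),
    "#5": (1, 0, 1, 1),
}

Trend = Literal["increasing", "decreasing", "constant", "indeterminate"]


@dataclass(frozen=True)
class ClassificationRecord:
    """Label and variance-vs-symmetry trends of a control sign pattern."""

    label: str
    var_I_trend: Trend
    var_J_trend: Trend
    optimal_symmetry: Literal["symmetric", "asymmetric", "indifferent", "depends", "n/a"]


def _sample_trend_signs(
    pattern: SignPattern, n_draws: int = 400, seed: int = 0
) -> tuple[set[int], set[int]]:
    """Signs of the two sensitivities over random stable magnitude draws."""
    rng = np.random.default_rng(seed)
    signs_i: set[int] = set()
    signs_j: set[int] = set()
    found = 0
    for _ in range(n_draws):
        mags = 10.0 ** rng.uniform(-2, 2, size=4)
        c = Controls(*(s * m for s, m in zip(pattern.signs, mags)))
        L_star = 10.0 ** rng.uniform(-2, 2)
        S_star = rng.uniform(1e-6, 1.0)
        stable, _ = stability(c, L_star, S_star)
        if not stable:
            continue
        found += 1
        sens = variance_sensitivity(c, L_star, S_star)
        signs_i.add(0 if sens.dvarI_dS == 0 else (1 if sens.dvarI_dS > 0 else -1))
        signs_j.add(0 if sens.dvarJ_dS == 0 else (1 if sens.dvarJ_dS > 0 else -1))
    if found == 0:
        raise NonHyperbolicError("no stable magnitudes found for pattern")
    return signs_i, signs_j


def _trend(signs: set[int]) -> Trend:
    if signs == {0}:
        return "constant"
    if signs == {1}:
        return "increasing"
    if signs == {-1}:
        return "decreasing"
    return "indeterminate"


def symmetry_window(pattern: SignPattern, n_draws: int = 400, seed: int = 0) -> str:
    """Describe the stable window in S* for a sign pattern.

    B = 2*L**S**(p_x - p_y) - q_y is monotone in S*, so the stable region is
    S* > S_c when p_x > p_y and S* < S_c when p_x < p_y.  The sign of
    p_x - p_y over stable magnitude draws determines the branch; when q_y = 0
    (so S_c = 0) or q_y < 0 with p_x > p_y (S_c < 0), the whole interval
    (0, 1] is stable.
    """
    rng = np.random.default_rng(seed)
    diff_signs: set[int] = set()
    for _ in range(n_draws):
        mags = 10.0 ** rng.uniform(-2, 2, size=4)
        c = Controls(*(s * m for s, m in zip(pattern.signs, mags)))
        L_star = 10.0 ** rng.uniform(-2, 2)
        S_star = rng.uniform(1e-6, 1.0)
        if stability(c, L_star, S_star)[0]:
            d = c.p_x - c.p_y
            diff_signs.add(0 if d == 0 else (1 if d > 0 else -1))
    if not diff_signs:
        return "empty (unstabilizable)"
    if diff_signs == {1}:
        if pattern.q_y == 0:
            return "S* > S_c = 0 (all of (0, 1])"
        if pattern.q_y < 0:
            return "all of (0, 1] (S_c < 0)"
        return "S* > S_c"
    if diff_signs == {-1}:
        return "S* < S_c"
    if diff_signs == {0}:
        return "independent of S*"
    return "depends on magnitudes"


def classify_network(pattern: SignPattern) -> ClassificationRecord:
    """Classify a control sign pattern.

    Matches against the five minimal/irreducible systems (#1-#5); any other
    stabilizable pattern is labelled "non-minimal" and a pattern with no stable
    regime "unstabilizable".  Trends of Var[I] and Var[J] versus S* are
    determined from the signs of the closed-form sensitivities sampled over
    stable magnitudes (they are exact zeros when p_y*q_y = 0 for Var[I]).
    """
    from .enumeration import is_stabilizable  # local import: avoid cycle

    if not is_stabilizable(pattern):
        return ClassificationRecord(
            label="unstabilizable",
            var_I_trend="indeterminate",
            var_J_trend="indeterminate",
            optimal_symmetry="n/a",
        )
    label = "non-minimal"
    for name, signs in MINIMAL_PATTERNS.items():
        if pattern.signs == signs:
            label = name
            break
    signs_i, signs_j = _sample_trend_signs(pattern)
    trend_i, trend_j = _trend(signs_i), _trend(signs_j)
    if trend_j == "decreasing" and trend_i in ("decreasing", "constant"):
        optimal = "symmetric"
    elif trend_j == "increasing" and trend_i in ("increasing", "constant"):
        optimal = "asymmetric"
    elif trend_i == "constant" and trend_j == "constant":
        optimal = "indifferent"
    else:
        optimal = "depends"
    return ClassificationRecord(
        label=label,
        var_I_trend=trend_i,
        var_J_trend=trend_j,
        optimal_symmetry=optimal,
    )
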