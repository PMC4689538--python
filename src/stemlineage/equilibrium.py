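"""Steady states and mean-field dynamics of the two-compartment lineage.

The deterministic (mean-field) limit of the stochastic update process is

    dI/dt = L*S*(1 - 2P) + E,
    dJ/dt = 2*L*S*P + L*(1 - S) - D,

with all rates evaluated at the scaled state (x, y) = (eps*I, eps*J); one event
changes a count by +-1, so population-level rates are also count derivatives
per update.  Two families of steady states exist:

* mixed divisions: L = D and P = 1/2 (symmetric differentiations balance
  symmetric proliferations), requiring no influx;
* purely asymmetric: S = 0 and L = D, with P unconstrained -- generically a
  one-parameter curve rather than an isolated point, which the solver detects
  and reports.

The equilibrium populations do not depend on the symmetric fraction S; only
stability and fluctuation size do.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from scipy.integrate import solve_ivp

from .control import ControlNetwork
from .errors import DivergenceError, InvalidParameterError, NoEquilibriumError

__all__ = [
    "Equilibrium",
    "MeanFieldTrajectory",
    "solve_mixed",
    "solve_asymmetric",
    "integrate_mean_field",
]

_RESIDUAL_TOL = 1e-12


@dataclass(frozen=True)
class Equilibrium:
    """A steady state of the lineage, in raw cell counts."""

    i0: float
    j0: float
    L_star: float
    S_star: float
    P_star: float
    kind: Literal["mixed", "purely_asymmetric"]
    residuals: tuple[float, ...] = field(default=())
    underdetermined: bool = False

    def summary(self) -> dict:
        return {
            "kind": self.kind,
            "i0": self.i0,
            "j0": self.j0,
            "L_star": self.L_star,
            "S_star": self.S_star,
            "P_star": self.P_star,
            "residuals": list(self.residuals),
            "underdetermined": self.underdetermined,
        }


def _safe_eval(fun, z: np.ndarray) -> np.ndarray:
    """Evaluate a residual, mapping math-domain failures to +inf components."""
    try:
        return np.asarray(fun(z), dtype=float)
    except (OverflowError, ValueError, ZeroDivisionError):
        return np.array([np.inf, np.inf])


def _fd_jacobian(fun, z: np.ndarray) -> np.ndarray:
    f0 = _safe_eval(fun, z)
    jac = np.empty((f0.size, z.size))
    for k in range(z.size):
        step = 1e-7 * max(1.0, abs(z[k]))
        zp = z.copy(); zp[k] += step
        zm = z.copy(); zm[k] -= step
        jac[:, k] = (_safe_eval(fun, zp) - _safe_eval(fun, zm)) / (2.0 * step)
    return jac


def _damped_newton(fun, z0: np.ndarray, maxiter: int = 100) -> Optional[np.ndarray]:
    """Newton iteration with step halving; pseudo-inverse handles rank-deficient
    Jacobians (minimum-norm step).  Returns None on failure."""
    z = np.asarray(z0, dtype=float)
    f = _safe_eval(fun, z)
    if not np.all(np.isfinite(f)):
        return None
    for _ in range(maxiter):
        norm = np.max(np.abs(f))
        if norm < _RESIDUAL_TOL:
            return z
        jac = _fd_jacobian(fun, z)
        if not np.all(np.isfinite(jac)):
            return None
        try:
            step = np.linalg.lstsq(jac, -f, rcond=None)[0]
        except np.linalg.LinAlgError:
            return None
        lam = 1.0
        for _ in range(40):
            z_new = z + lam * step
            f_new = _safe_eval(fun, z_new)
            if np.all(np.isfinite(f_new)) and np.max(np.abs(f_new)) < norm:
                z, f = z_new, f_new
                break
            lam *= 0.5
        else:
            return None
    return z if np.max(np.abs(f)) < _RESIDUAL_TOL else None


_GRID = np.geomspace(1e-3, 10.0, 6)


def _solve_with_multistart(fun) -> tuple[np.ndarray, list[np.ndarray]]:
    """Damped Newton from (1, 1) with a log-grid multi-start fallback.

    Returns the root from the default guess (or the first grid root) and the
    list of all distinct roots found on the grid (used to warn on multiplicity).
    """
    default = _damped_newton(fun, np.array([1.0, 1.0]))
    roots: list[np.ndarray] = []

    def record(r: Optional[np.ndarray]) -> None:
        if r is None:
            return
        for other in roots:
            scale = np.maximum(1e-9, np.abs(other))
            if np.max(np.abs(r - other) / scale) < 1e-6:
                return
        roots.append(r)

    record(default)
    for gx, gy in itertools.product(_GRID, _GRID):
        record(_damped_newton(fun, np.array([gx, gy])))
    if default is None and not roots:
        raise NoEquilibriumError("no steady state found in the search domain [1e-3, 10]^2")
    primary = default if default is not None else roots[0]
    return primary, roots


def solve_mixed(network: ControlNetwork) -> Equilibrium:
    """Solve the mixed-divisions steady state: P = 1/2 and L = D.

    Requires a closed system (no exogenous influx): with E > 0 stationarity of
    the stem-cell count forces P > 1/2 and the mixed state does not exist.
    """
    if network.has_influx:
        raise InvalidParameterError(
            "mixed steady state requires no influx (E absent or zero)"
        )

    def residual(z: np.ndarray):
        x, y = z
        return np.array([
            network.P(x, y) - 0.5,
            network.L(x, y) - network.D(x, y),
        ])

    root, roots = _solve_with_multistart(residual)
    if len(roots) > 1:
        warnings.warn(
            f"multiple mixed steady states found ({len(roots)}); "
            "returning the one reached from the default initial guess",
            stacklevel=2,
        )
    x0, y0 = float(root[0]), float(root[1])
    res = residual(root)
    eps = network.epsilon
    return Equilibrium(
        i0=x0 / eps,
        j0=y0 / eps,
        L_star=float(network.L(x0, y0)),
        S_star=float(network.S(x0, y0)),
        P_star=float(network.P(x0, y0)),
        kind="mixed",
        residuals=(float(res[0]), float(res[1])),
    )


def solve_asymmetric(network: ControlNetwork) -> Equilibrium:
    """Solve the purely asymmetric steady state: S forced to 0, L = D.

    The division/death balance is a single scalar condition in two unknowns,
    so the state is generically a one-parameter curve; the returned point is
    the one reached from the default initial guess and ``underdetermined`` is
    set when the residual Jacobian has rank < 2.  With an influx the stem-cell
    balance adds the condition E = 0.
    """

    def residual(z: np.ndarray):
        x, y = z
        parts = [network.L(x, y) - network.D(x, y)]
        if network.has_influx:
            parts.append(network.E(x))
        return np.array(parts)

    root, _ = _solve_with_multistart(residual)
    x0, y0 = float(root[0]), float(root[1])
    res = residual(root)
    jac = _fd_jacobian(residual, root)
    sv = np.linalg.svd(jac, compute_uv=False)
    rank = int(np.sum(sv > max(1e-10, 1e-8 * sv[0]))) if sv.size else 0
    underdetermined = rank < 2
    if underdetermined:
        warnings.warn(
            "purely asymmetric steady state is under-determined "
            f"(residual Jacobian rank {rank} < 2): returned point is one of a solution curve",
            stacklevel=2,
        )
    eps = network.epsilon
    return Equilibrium(
        i0=x0 / eps,
        j0=y0 / eps,
        L_star=float(network.L(x0, y0)),
        S_star=0.0,
        P_star=float(network.P(x0, y0)),
        kind="purely_asymmetric",
        residuals=tuple(float(r) for r in res),
        underdetermined=underdetermined,
    )


@dataclass(frozen=True)
class MeanFieldTrajectory:
    """Sampled deterministic trajectory in raw counts."""

    t: np.ndarray
    I: np.ndarray
    J: np.ndarray

    @property
    def final(self) -> tuple[float, float]:
        return float(self.I[-1]), float(self.J[-1])


def integrate_mean_field(
    network: ControlNetwork,
    init: tuple[float, float],
    horizon: float,
    n_samples: int = 500,
    bound: float = 1e9,
) -> MeanFieldTrajectory:
    """Integrate the mean-field ODE from ``init = (I, J)`` up to ``horizon``.

    Time is measured in updates of the stochastic process.  Uses an adaptive
    stiff-capable integrator at rtol 1e-9.  States exceeding ``bound`` raise
    :class:`DivergenceError`.
    """
    if not (horizon > 0):
        raise InvalidParameterError(f"horizon must be positive, got {horizon}")
    I0, J0 = float(init[0]), float(init[1])
    if I0 < 0 or J0 < 0:
        raise InvalidParameterError(f"initial state must be nonnegative, got {init}")
    eps = network.epsilon

    def rhs(_t, z):
        x, y = eps * z[0], eps * z[1]
        l = network.L(x, y)
        s = network.S(x, y)
        p = network.P(x, y)
        d = network.D(x, y)
        dI = l * s * (1.0 - 2.0 * p)
        if network.has_influx:
            dI += network.E(x)
        dJ = 2.0 * l * s * p + l * (1.0 - s) - d
        return (dI, dJ)

    def blow_up(_t, z):
        return bound - max(abs(z[0]), abs(z[1]))

    blow_up.terminal = True

    sol = solve_ivp(
        rhs,
        (0.0, float(horizon)),
        (I0, J0),
        method="LSODA",
        rtol=1e-9,
        atol=1e-12,
        t_eval=np.linspace(0.0, float(horizon), n_samples),
        events=blow_up,
    )
    if sol.status == 1:  # terminated by the blow-up event
        raise DivergenceError(f"mean-field state exceeded bound {bound:g}")
    if not sol.success:
        raise NoEquilibriumError(f"mean-field integration failed: {sol.message}")
    return MeanFieldTrajectory(t=sol.t, I=sol.y[0], J=sol.y[1])
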