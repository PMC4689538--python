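"""Control networks for a two-compartment stem-cell lineage.

A lineage of stem cells (count ``I``) and differentiated cells (count ``J``)
is governed by four rate/probability functions of the scaled populations
``x = epsilon * I`` and ``y = epsilon * J``:

* ``L(x, y)`` -- stem-cell division rate (probability of a division per update),
* ``S(x, y)`` -- probability that a division is symmetric,
* ``P(x, y)`` -- probability that a symmetric division differentiates (two
  differentiated daughters rather than two stem cells),
* ``D(x, y)`` -- death rate of differentiated cells,

optionally augmented by an exogenous stem-cell influx ``E(x)`` (e.g. hair
follicles feeding an epidermal lineage).  The parameter ``epsilon`` sets the
strength of the feedback of cell numbers on rates, and thereby the equilibrium
population size (which scales as ``1/epsilon``).

The *controls* of a network are the four partial derivatives, evaluated at the
homeostatic equilibrium, of the net growth rate ``L - D`` and the
differentiation probability ``P`` with respect to the stem (``x``) and
differentiated (``y``) populations.  Following the convention that rates depend
on cell numbers through ``epsilon * count``, the controls carry one factor of
``epsilon``: ``q_x = epsilon * d(L - D)/dx`` and so on.  Their signs define the
feedback wiring (the "control network") and fully determine stability and the
qualitative dependence of population variances on the symmetric-division
fraction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

from .errors import InvalidParameterError, NumericalFailureError

__all__ = [
    "ControlNetwork",
    "Controls",
    "SignPattern",
    "make_model3",
    "make_model5",
    "make_follicle_model",
    "evaluate_controls",
]


@dataclass(frozen=True)
class ControlNetwork:
    """Rate/probability functions of the scaled populations (x, y) = (eps*I, eps*J).

    ``L``, ``P``, ``D``, ``S`` take ``(x, y)``; the optional influx ``E`` takes
    ``x`` only.  ``params`` records how the network was constructed so it can be
    serialized back to a configuration mapping.
    """

    L: Callable[[float, float], float]
    P: Callable[[float, float], float]
    D: Callable[[float, float], float]
    S: Callable[[float, float], float]
    epsilon: float
    E: Optional[Callable[[float], float]] = None
    name: str = "custom"
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.epsilon > 0):
            raise InvalidParameterError(f"epsilon must be positive, got {self.epsilon}")

    @property
    def has_influx(self) -> bool:
        return self.E is not None

    def scaled(self, I: float, J: float) -> tuple[float, float]:
        """Map raw counts to scaled coordinates."""
        return self.epsilon * I, self.epsilon * J


@dataclass(frozen=True)
class Controls:
    """The four feedback controls q_x, q_y, p_x, p_y at an equilibrium.

    q_* are derivatives of L - D, p_* of P; subscript x means with respect to
    the stem-cell population, y the differentiated population.  All four carry
    a factor epsilon (derivative with respect to the raw count).
    """

    q_x: float
    q_y: float
    p_x: float
    p_y: float

    def __post_init__(self) -> None:
        for name in ("q_x", "q_y", "p_x", "p_y"):
            if not math.isfinite(getattr(self, name)):
                raise NumericalFailureError(f"non-finite control {name}")

    def sign_pattern(self, atol: float = 0.0) -> "SignPattern":
        """Three-valued signs of the controls; |value| <= atol counts as zero."""

        def sgn(v: float) -> int:
            if abs(v) <= atol:
                return 0
            return 1 if v > 0 else -1

        return SignPattern(sgn(self.q_x), sgn(self.q_y), sgn(self.p_x), sgn(self.p_y))


_SIGNS = (-1, 0, 1)


@dataclass(frozen=True)
class SignPattern:
    """Signs (-1, 0, +1) of the four controls, in the order q_x, q_y, p_x, p_y."""

    q_x: int
    q_y: int
    p_x: int
    p_y: int
    label: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("q_x", "q_y", "p_x", "p_y"):
            if getattr(self, name) not in _SIGNS:
                raise InvalidParameterError(
                    f"sign entry {name} must be -1, 0 or +1, got {getattr(self, name)}"
                )

    @property
    def signs(self) -> tuple[int, int, int, int]:
        return (self.q_x, self.q_y, self.p_x, self.p_y)

    @property
    def support(self) -> tuple[str, ...]:
        names = ("q_x", "q_y", "p_x", "p_y")
        return tuple(n for n, s in zip(names, self.signs) if s != 0)

    @property
    def n_controls(self) -> int:
        return sum(1 for s in self.signs if s != 0)

    def zeroed(self, name: str) -> "SignPattern":
        """Copy of the pattern with one control set to zero."""
        kw = {"q_x": self.q_x, "q_y": self.q_y, "p_x": self.p_x, "p_y": self.p_y}
        if name not in kw:
            raise InvalidParameterError(f"unknown control {name!r}")
        kw[name] = 0
        return SignPattern(**kw)


def _check_preset_args(epsilon: float, symmetry: float) -> None:
    if not (epsilon > 0):
        raise InvalidParameterError(f"epsilon must be positive, got {epsilon}")
    if not (0 < symmetry <= 1):
        raise InvalidParameterError(f"symmetry must lie in (0, 1], got {symmetry}")


def make_model3(epsilon: float, symmetry: float) -> ControlNetwork:
    """Three-control network: division promoted by stem cells, inhibited by
    differentiated cells; differentiation promoted by differentiated cells.

    L = (1 - e^-x) / (1 - e^-x + y),  P = 1 - e^-3y,  D = 1 - L,  S = symmetry.
    Controls at the mixed equilibrium: q_x > 0, q_y < 0, p_x = 0, p_y > 0.
    """
    _check_preset_args(epsilon, symmetry)

    def L(x: float, y: float) -> float:
        u = 1.0 - math.exp(-x)
        denom = u + y
        if denom == 0.0:
            return 0.0  # limit at the origin
        return u / denom

    def P(x: float, y: float) -> float:
        return 1.0 - math.exp(-3.0 * y)

    def D(x: float, y: float) -> float:
        return 1.0 - L(x, y)

    c = float(symmetry)

    def S(x: float, y: float) -> float:
        return c

    return ControlNetwork(
        L=L, P=P, D=D, S=S, epsilon=float(epsilon),
        name="model3", params={"epsilon": float(epsilon), "symmetry": c},
    )


def make_model5(epsilon: float, symmetry: float) -> ControlNetwork:
    """Three-control network: both division and differentiation promoted by
    stem cells, differentiation also promoted by differentiated cells.

    L = 2 tanh(x) / (2 tanh(x) + 0.4),  P = tanh(x + 0.1 y),  D = 1 - L.
    Controls at the mixed equilibrium: q_x > 0, q_y = 0, p_x > p_y > 0.
    """
    _check_preset_args(epsilon, symmetry)

    def L(x: float, y: float) -> float:
        t = math.tanh(x)
        return 2.0 * t / (2.0 * t + 0.4)

    def P(x: float, y: float) -> float:
        return math.tanh(x + 0.1 * y)

    def D(x: float, y: float) -> float:
        return 1.0 - L(x, y)

    c = float(symmetry)

    def S(x: float, y: float) -> float:
        return c

    return ControlNetwork(
        L=L, P=P, D=D, S=S, epsilon=float(epsilon),
        name="model5", params={"epsilon": float(epsilon), "symmetry": c},
    )


def make_follicle_model(
    epsilon: float, symmetry: float, h: float, influx: bool = True
) -> ControlNetwork:
    """Epidermal-lineage variant with linear death and an optional exogenous
    stem-cell source modelling hair-follicle contribution.

    L = 0.9 tanh(x) / (2 tanh(x) + 0.4),  P = tanh(x + 0.1 y),
    D = h + 0.01 y,  S = symmetry,  E = 0.02 / (1 + x).

    ``influx=False`` drops E (hairless skin, e.g. footpad epidermis).
    """
    _check_preset_args(epsilon, symmetry)
    if h < 0:
        raise InvalidParameterError(f"baseline death rate h must be >= 0, got {h}")

    def L(x: float, y: float) -> float:
        t = math.tanh(x)
        return 0.9 * t / (2.0 * t + 0.4)

    def P(x: float, y: float) -> float:
        return math.tanh(x + 0.1 * y)

    hh = float(h)

    def D(x: float, y: float) -> float:
        return hh + 0.01 * y

    c = float(symmetry)

    def S(x: float, y: float) -> float:
        return c

    E = (lambda x: 0.02 / (1.0 + x)) if influx else None

    return ControlNetwork(
        L=L, P=P, D=D, S=S, epsilon=float(epsilon), E=E,
        name="follicle",
        params={
            "epsilon": float(epsilon), "symmetry": c, "h": hh, "influx": bool(influx),
        },
    )


def _central_diff(f: Callable[[float], float], t: float) -> float:
    # Step scaled to the coordinate: controls are O(eps) and coordinates O(1),
    # so an absolute step must not swamp the derivative.
    step = 1e-6 * max(1.0, abs(t))
    return (f(t + step) - f(t - step)) / (2.0 * step)


def evaluate_controls(network: ControlNetwork, point: tuple[float, float]) -> Controls:
    """Evaluate the four controls at a point in scaled coordinates.

    Returns derivatives of ``L - D`` (q) and ``P`` (p) with respect to raw cell
    counts, i.e. epsilon times the derivative in the scaled coordinate,
    computed by central finite differences.
    """
    x, y = float(point[0]), float(point[1])
    if x < 0 or y < 0:
        raise InvalidParameterError(f"point must have nonnegative coordinates, got {point}")
    eps = network.epsilon

    def q(u: float, v: float) -> float:
        return network.L(u, v) - network.D(u, v)

    q_x = eps * _central_diff(lambda t: q(t, y), x)
    q_y = eps * _central_diff(lambda t: q(x, t), y)
    p_x = eps * _central_diff(lambda t: network.P(t, y), x)
    p_y = eps * _central_diff(lambda t: network.P(x, t), y)
    return Controls(q_x=q_x, q_y=q_y, p_x=p_x, p_y=p_y)
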