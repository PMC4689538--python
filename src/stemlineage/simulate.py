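"""Discrete stochastic simulation of the two-compartment lineage.

At each update one of five events occurs, with weights evaluated at the current
scaled state (x, y) = (eps*I, eps*J):

====================  =================  =======================
event                 weight             state change
====================  =================  =======================
symmetric diff.       L*S*P              (I, J) -> (I-1, J+2)
symmetric prolif.     L*S*(1-P)          (I, J) -> (I+1, J)
asymmetric division   L*(1-S)            (I, J) -> (I,   J+1)
death                 D                  (I, J) -> (I,   J-1)
influx (optional)     E                  (I, J) -> (I+1, J)
====================  =================  =======================

Rates are population-level (L is the probability that *some* stem cell divides
in an update), so for closed networks with D = 1 - L the weights sum to one
and every update is an event.  Otherwise the default per-step scheme treats
the weights as literal Bernoulli probabilities when they sum to <= 1 (a "none"
event absorbs the remainder) and normalizes by the sum when it exceeds 1.  The
exact event-time scheme draws exponential waiting times with the weight sum as
total rate.

Micro-injuries -- random removal of a fraction of cells at a small fraction of
updates, modelling e.g. abrasion of paw epidermis -- and variants (transient
death-rate multiplier, stem-cell removal) are supported via
:class:`InjuryConfig`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .control import ControlNetwork
from .equilibrium import solve_mixed
from .errors import InvalidParameterError

__all__ = [
    "InjuryConfig",
    "SimulationConfig",
    "Trajectory",
    "MomentEstimate",
    "simulate",
    "estimate_moments",
    "sweep_symmetry",
    "EVENT_NAMES",
]

EVENT_NAMES: tuple[str, ...] = (
    "none", "diff", "prolif", "asym", "death", "influx", "injury",
)
_NONE, _DIFF, _PROLIF, _ASYM, _DEATH, _INFLUX, _INJURY = range(7)


@dataclass(frozen=True)
class InjuryConfig:
    """Random micro-injury perturbation.

    Each update is independently an injury event with probability
    ``update_fraction``.  In ``removal`` mode, the nearest integer to
    ``removal_fraction`` times the target population is removed (floor 0);
    in ``death-rate-multiplier`` mode the death weight is multiplied by
    ``death_multiplier`` for that update and an ordinary event is drawn.
    """

    update_fraction: float
    removal_fraction: float = 0.0
    target: Literal["differentiated", "stem", "both"] = "differentiated"
    mode: Literal["removal", "death-rate-multiplier"] = "removal"
    death_multiplier: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.update_fraction <= 1.0):
            raise InvalidParameterError("update_fraction must be in [0, 1]")
        if not (0.0 <= self.removal_fraction <= 1.0):
            raise InvalidParameterError("removal_fraction must be in [0, 1]")
        if self.death_multiplier < 0:
            raise InvalidParameterError("death_multiplier must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to reproduce one stochastic run."""

    network: ControlNetwork
    steps: int
    seed: Union[int, Sequence[int]]
    init: Union[tuple[int, int], Literal["equilibrium"]] = "equilibrium"
    scheme: Literal["per-step", "exact"] = "per-step"
    stop_on_extinction: bool = True
    injury: Optional[InjuryConfig] = None

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise InvalidParameterError(f"steps must be >= 1, got {self.steps}")

    def resolve_init(self) -> tuple[int, int]:
        """Initial counts; "equilibrium" means the rounded-up mixed steady state
        (or, for networks with an influx, the rounded-up mean-field attractor,
        since the stem-cell balance then requires P > 1/2)."""
        if self.init == "equilibrium":
            if self.network.has_influx:
                from .equilibrium import integrate_mean_field

                start = 1.0 / self.network.epsilon
                att = integrate_mean_field(
                    self.network, (start, start), 2e5, n_samples=2
                ).final
                return (max(1, math.ceil(att[0])), math.ceil(att[1]))
            eq = solve_mixed(self.network)
            return (math.ceil(eq.i0), math.ceil(eq.j0))
        I0, J0 = int(self.init[0]), int(self.init[1])
        if I0 < 1 or J0 < 0:
            raise InvalidParameterError(
                f"initial state needs I >= 1 and J >= 0, got {(I0, J0)}"
            )
        return (I0, J0)

    def echo(self) -> dict:
        d = {
            "network": {"name": self.network.name, **self.network.params},
            "steps": self.steps,
            "seed": list(self.seed) if isinstance(self.seed, (list, tuple)) else self.seed,
            "init": self.init if self.init == "equilibrium" else list(self.init),
            "scheme": self.scheme,
            "stop_on_extinction": self.stop_on_extinction,
        }
        if self.injury is not None:
            d["injury"] = {
                "update_fraction": self.injury.update_fraction,
                "removal_fraction": self.injury.removal_fraction,
                "target": self.injury.target,
                "mode": self.injury.mode,
                "death_multiplier": self.injury.death_multiplier,
            }
        return d


@dataclass(frozen=True)
class Trajectory:
    """A realized run: states ``I[k], J[k]`` for k = 0..n and the event taking
    state k to k+1 (integer codes into :data:`EVENT_NAMES`)."""

    I: np.ndarray
    J: np.ndarray
    events: np.ndarray
    extinct: bool = False
    frozen: bool = False
    times: Optional[np.ndarray] = None  # event times under the exact scheme
    weight_sums: Optional[np.ndarray] = None  # recorded when influx present

    def __len__(self) -> int:
        return len(self.I)

    @property
    def n_steps(self) -> int:
        return len(self.events)

    def event_counts(self) -> dict[str, int]:
        counts = np.bincount(self.events, minlength=len(EVENT_NAMES))
        return {name: int(c) for name, c in zip(EVENT_NAMES, counts)}

    def to_dataframe(self) -> pd.DataFrame:
        events = np.concatenate(([_NONE], self.events))  # state 0 has no incoming event
        return pd.DataFrame(
            {
                "step": np.arange(len(self.I)),
                "I": self.I,
                "J": self.J,
                "event": [EVENT_NAMES[e] for e in events],
            }
        )


@dataclass(frozen=True)
class MomentEstimate:
    """Empirical per-step moments of a trajectory window.

    ``rel_sd_J`` follows the variance-to-mean convention Var(J)/E(J) used for
    the robustness comparisons; ``cv_J`` is the conventional relative standard
    deviation sd(J)/E(J), the size-normalized fluctuation measure (the two
    differ in trend whenever the mean itself shifts, as it does under an
    exogenous influx).
    """

    mean_I: float
    mean_J: float
    var_I: float
    var_J: float
    rel_sd_J: float
    cv_J: float
    n_samples: int

    def report(self) -> dict:
        return {
            "mean_I": self.mean_I,
            "mean_J": self.mean_J,
            "var_I": self.var_I,
            "var_J": self.var_J,
            "rel_sd_J": self.rel_sd_J,
            "cv_J": self.cv_J,
            "n_samples": self.n_samples,
        }


# state-change table indexed by event code: (dI, dJ)
_MOVES = ((0, 0), (-1, 2), (1, 0), (0, 1), (0, -1), (1, 0), (0, 0))


def simulate(config: SimulationConfig) -> Trajectory:
    """Run one stochastic realization of the lineage process.

    Deterministic given the config: the same seed yields a bit-identical
    trajectory.  Terminates at the step budget, on extinction of either
    population (when ``stop_on_extinction``), or on a frozen state (zero total
    weight with no influx).
    """
    net = config.network
    Lf, Pf, Df, Sf, Ef = net.L, net.P, net.D, net.S, net.E
    eps = net.epsilon
    steps = config.steps
    exact = config.scheme == "exact"
    injury = config.injury

    I, J = config.resolve_init()
    rng = np.random.default_rng(config.seed)
    draws = rng.random(steps)
    inj_draws = rng.random(steps) if injury is not None else None
    exp_draws = rng.exponential(size=steps) if exact else None

    I_hist = np.empty(steps + 1, dtype=np.int64)
    J_hist = np.empty(steps + 1, dtype=np.int64)
    events = np.empty(steps, dtype=np.int8)
    times = np.empty(steps, dtype=np.float64) if exact else None
    wsums = np.empty(steps, dtype=np.float64) if net.has_influx else None
    I_hist[0], J_hist[0] = I, J

    extinct = False
    frozen = False
    t = 0.0
    k = 0
    inj_removal = injury.removal_fraction if injury is not None else 0.0
    inj_thresh = injury.update_fraction if injury is not None else -1.0
    while k < steps:
        if injury is not None and inj_draws[k] < inj_thresh and injury.mode == "removal":
            tgt = injury.target
            if tgt in ("differentiated", "both"):
                J -= min(J, int(round(inj_removal * J)))
            if tgt in ("stem", "both"):
                I -= min(I, int(round(inj_removal * I)))
            ev = _INJURY
            if exact:
                times[k] = t
        else:
            x = eps * I
            y = eps * J
            l = Lf(x, y)
            s = Sf(x, y)
            p = Pf(x, y)
            d = Df(x, y)
            if injury is not None and injury.mode == "death-rate-multiplier" \
                    and inj_draws[k] < inj_thresh:
                d *= injury.death_multiplier
            ls = l * s
            w_diff = ls * p
            w_prolif = ls - w_diff
            w_asym = l - ls
            if I == 0:
                w_diff = w_prolif = w_asym = 0.0
            w_death = d if J > 0 else 0.0
            w_influx = Ef(x) if Ef is not None else 0.0
            total = w_diff + w_prolif + w_asym + w_death + w_influx
            if wsums is not None:
                wsums[k] = total
            if total <= 0.0:
                if Ef is None:
                    frozen = True
                    break
                ev = _NONE
            else:
                u = draws[k]
                if total > 1.0:
                    u *= total
                if u < w_diff:
                    ev = _DIFF
                    I -= 1
                    J += 2
                elif u < w_diff + w_prolif:
                    ev = _PROLIF
                    I += 1
                elif u < w_diff + w_prolif + w_asym:
                    ev = _ASYM
                    J += 1
                elif u < w_diff + w_prolif + w_asym + w_death:
                    ev = _DEATH
                    J -= 1
                elif u < total:
                    ev = _INFLUX
                    I += 1
                else:
                    ev = _NONE
            if exact:
                t += exp_draws[k] / total if total > 0.0 else 0.0
                times[k] = t
        events[k] = ev
        k += 1
        I_hist[k] = I
        J_hist[k] = J
        if config.stop_on_extinction and (I == 0 or J == 0):
            extinct = True
            break

    n = k  # realized number of updates
    return Trajectory(
        I=I_hist[: n + 1],
        J=J_hist[: n + 1],
        events=events[:n],
        extinct=extinct,
        frozen=frozen,
        times=times[:n] if exact else None,
        weight_sums=wsums[:n] if wsums is not None else None,
    )


def estimate_moments(traj: Trajectory, burn_in: int = 0) -> MomentEstimate:
    """Per-step means and variances of the populations after ``burn_in``.

    Moments are computed over the time-course of the run (each retained step
    weighted equally, population variance).
    """
    if burn_in < 0 or burn_in >= len(traj.I):
        raise InvalidParameterError(
            f"burn_in {burn_in} leaves no samples in a trajectory of {len(traj.I)} states"
        )
    I = traj.I[burn_in:]
    J = traj.J[burn_in:]
    mean_I = float(np.mean(I))
    mean_J = float(np.mean(J))
    var_I = float(np.var(I))
    var_J = float(np.var(J))
    return MomentEstimate(
        mean_I=mean_I,
        mean_J=mean_J,
        var_I=var_I,
        var_J=var_J,
        rel_sd_J=var_J / mean_J if mean_J > 0 else math.nan,
        cv_J=math.sqrt(var_J) / mean_J if mean_J > 0 else math.nan,
        n_samples=len(I),
    )


def _replicate_seed(base_seed: Union[int, Sequence[int]], s_index: int, rep: int) -> list:
    base = list(base_seed) if isinstance(base_seed, (list, tuple)) else [base_seed]
    return base + [s_index, rep]


def sweep_symmetry(
    config: SimulationConfig,
    s_values: Sequence[float],
    replicates: int,
    burn_in: int = 0,
    network_factory=None,
) -> pd.DataFrame:
    """Replicated moment estimates over a grid of symmetric fractions S.

    ``config`` is the template; for each S the network is rebuilt via
    ``network_factory(S)`` (defaults to the preset constructor recorded in
    ``config.network.params``).  Replicate seeds derive from the template seed
    and the (S index, replicate) counters, so every cell is independent yet
    reproducible.  Failed cells are kept as rows with an ``error`` marker.
    """
    from . import io as _io  # default factory uses the config machinery

    if network_factory is None:
        base_cfg = dict(config.network.params)
        base_cfg["preset"] = config.network.name

        def network_factory(s: float) -> ControlNetwork:
            cfg = dict(base_cfg)
            cfg["symmetry"] = float(s)
            return _io.network_from_config(cfg)

    rows = []
    for s_index, s in enumerate(s_values):
        if not (0 < s <= 1):
            raise InvalidParameterError(f"S values must lie in (0, 1], got {s}")
        net = network_factory(float(s))
        for rep in range(replicates):
            cell = replace(
                config, network=net, seed=_replicate_seed(config.seed, s_index, rep)
            )
            row = {"S": float(s), "replicate": rep}
            try:
                traj = simulate(cell)
                est = estimate_moments(traj, burn_in=burn_in)
                row.update(est.report())
                row["extinct"] = traj.extinct
                row["error"] = ""
            except Exception as exc:  # partial tables allowed
                row.update(
                    {k: math.nan for k in
                     ("mean_I", "mean_J", "var_I", "var_J", "rel_sd_J", "cv_J")}
                )
                row["n_samples"] = 0
                row["extinct"] = False
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    return pd.DataFrame(rows)
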