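"""Deterministic short-run fixtures for regression testing.

Each fixture is a seeded 5,000-step simulation plus its expected moment
summary; regenerating with the same name and seed is bit-exact, so the pair
serves as a regression anchor without shipping any data files.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Union

from .errors import InvalidParameterError
from .io import dump_json, network_from_config, write_trajectory_csv
from .simulate import (
    InjuryConfig,
    SimulationConfig,
    Trajectory,
    estimate_moments,
    simulate,
)

__all__ = ["FIXTURE_NAMES", "fixture_config", "make_fixture"]

_STEPS = 5_000

_FIXTURES: dict[str, dict] = {
    "model3-short": {
        "network": {"preset": "model3", "epsilon": 0.005, "symmetry": 0.5},
    },
    "model5-short": {
        "network": {"preset": "model5", "epsilon": 0.005, "symmetry": 0.8},
    },
    "injury-short": {
        "network": {"preset": "model5", "epsilon": 0.002, "symmetry": 0.5},
        "injury": {"update_fraction": 0.01, "removal_fraction": 0.10},
    },
    # small populations here make transient J = 0 states routine, so the run
    # continues through them rather than stopping
    "follicle-short": {
        "network": {"preset": "follicle", "epsilon": 0.05, "symmetry": 0.5,
                    "h": 0.3, "influx": True},
        "stop_on_extinction": False,
    },
}

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def fixture_config(name: str, seed: int) -> SimulationConfig:
    if name not in _FIXTURES:
        raise InvalidParameterError(
            f"unknown fixture {name!r}; choose from {list(FIXTURE_NAMES)}"
        )
    entry = _FIXTURES[name]
    injury = InjuryConfig(**entry["injury"]) if "injury" in entry else None
    return SimulationConfig(
        network=network_from_config(entry["network"]),
        steps=_STEPS,
        seed=seed,
        injury=injury,
        stop_on_extinction=entry.get("stop_on_extinction", True),
    )


def make_fixture(
    name: str, seed: int, out_dir: Optional[Union[str, Path]] = None
) -> tuple[Trajectory, dict]:
    """Generate a named fixture: (trajectory, expected-summary dict).

    The summary includes the empirical moments, event counts and the config
    echo.  If ``out_dir`` is given, writes ``<name>.csv`` and ``<name>.json``
    there and records the paths in the summary.
    """
    config = fixture_config(name, seed)
    traj = simulate(config)
    est = estimate_moments(traj)
    summary = {
        "fixture": name,
        "seed": seed,
        "config": config.echo(),
        "moments": est.report(),
        "event_counts": traj.event_counts(),
        "extinct": traj.extinct,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        csv_path = out / f"{name}.csv"
        json_path = out / f"{name}.json"
        write_trajectory_csv(traj, csv_path)
        json_path.write_text(dump_json(summary), encoding="utf-8", newline="\n")
        summary["outputs"] = [str(csv_path), str(json_path)]
    return traj, summary
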