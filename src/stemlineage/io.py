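"""Configuration handling, run manifests, and tabular/JSON writers.

Network configurations are plain mappings: either a preset,

    {"preset": "model3", "epsilon": 0.005, "symmetry": 0.5}

(presets: ``model3``, ``model5``, ``follicle`` -- the latter also takes ``h``
and ``influx``), or a custom network given as expression strings in the scaled
coordinates ``x`` and ``y`` (``E`` in ``x`` only), parsed with sympy:

    {"custom": {"L": "x/(1+x+y)", "P": "y/(1+y)", "D": "1 - x/(1+x+y)",
                "S": "0.5", "E": "0.01/(1+x)"}, "epsilon": 0.01}

All floating-point JSON output is serialized to 12 significant digits.
Trajectory CSVs use a comma-separated header row ``step,I,J,event`` with LF
line endings.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd
import yaml

from . import __version__
from .control import ControlNetwork, make_follicle_model, make_model3, make_model5
from .errors import InvalidParameterError
from .simulate import EVENT_NAMES, Trajectory

__all__ = [
    "RunManifest",
    "network_from_config",
    "network_to_config",
    "load_config",
    "write_json",
    "dump_json",
    "write_trajectory_csv",
    "read_trajectory_csv",
]

_PRESETS = {"model3", "model5", "follicle"}


def network_from_config(config: dict) -> ControlNetwork:
    """Build a :class:`ControlNetwork` from a configuration mapping."""
    cfg = dict(config)
    preset = cfg.pop("preset", cfg.pop("name", None))
    custom = cfg.pop("custom", None)
    if (preset is None) == (custom is None):
        raise InvalidParameterError(
            "config must contain exactly one of 'preset' or 'custom'"
        )
    if preset is not None:
        if preset == "model3":
            return make_model3(cfg["epsilon"], cfg["symmetry"])
        if preset == "model5":
            return make_model5(cfg["epsilon"], cfg["symmetry"])
        if preset == "follicle":
            return make_follicle_model(
                cfg["epsilon"], cfg["symmetry"], cfg.get("h", 0.3),
                influx=cfg.get("influx", True),
            )
        raise InvalidParameterError(
            f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}"
        )
    return _custom_network(custom, epsilon=cfg["epsilon"])


def _custom_network(exprs: dict, epsilon: float) -> ControlNetwork:
    import sympy as sp

    x, y = sp.symbols("x y")
    funcs = {}
    for key in ("L", "P", "D", "S"):
        if key not in exprs:
            raise InvalidParameterError(f"custom network missing expression for {key!r}")
        expr = sp.sympify(exprs[key], locals={"x": x, "y": y})
        funcs[key] = sp.lambdify((x, y), expr, modules="math")
    E = None
    if exprs.get("E") is not None:
        E = sp.lambdify((x,), sp.sympify(exprs["E"], locals={"x": x}), modules="math")
    return ControlNetwork(
        L=funcs["L"], P=funcs["P"], D=funcs["D"], S=funcs["S"],
        epsilon=float(epsilon), E=E, name="custom",
        params={"epsilon": float(epsilon), "custom": dict(exprs)},
    )


def network_to_config(network: ControlNetwork) -> dict:
    """Serializable configuration mapping for a network built by this package."""
    if network.name in _PRESETS:
        return {"preset": network.name, **network.params}
    if "custom" in network.params:
        return {"custom": dict(network.params["custom"]),
                "epsilon": network.epsilon}
    raise InvalidParameterError(
        "network was not built from a preset or expression config; cannot serialize"
    )


def load_config(path: Union[str, Path]) -> dict:
    """Read a structured-text (YAML/JSON) configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh)


@dataclass(frozen=True)
class RunManifest:
    """Provenance record for one CLI run: what was executed, with what inputs."""

    subcommand: str
    config: dict
    seed: Optional[int]
    version: str = field(default=__version__)
    outputs: tuple[str, ...] = ()

    def to_json(self) -> str:
        return dump_json(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        d = json.loads(text)
        d["outputs"] = tuple(d.get("outputs", ()))
        return cls(**d)


def _round_floats(obj):
    # 12 significant digits keeps JSON reports reproducible across platforms
    if isinstance(obj, float):
        return float(f"{obj:.12g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    if isinstance(obj, bool) or obj is None or isinstance(obj, (int, str)):
        return obj
    if hasattr(obj, "item"):  # numpy scalar
        return _round_floats(obj.item())
    return obj


def dump_json(payload: dict) -> str:
    return json.dumps(_round_floats(payload), indent=2, allow_nan=True) + "\n"


def write_json(payload: dict, path: Union[str, Path]) -> None:
    Path(path).write_text(dump_json(payload), encoding="utf-8", newline="\n")


def write_trajectory_csv(traj: Trajectory, path: Union[str, Path]) -> None:
    traj.to_dataframe().to_csv(path, index=False, lineterminator="\n")


def read_trajectory_csv(path: Union[str, Path]) -> Trajectory:
    """Inverse of :func:`write_trajectory_csv` (state series and event codes)."""
    df = pd.read_csv(path)
    codes = {name: i for i, name in enumerate(EVENT_NAMES)}
    import numpy as np

    events = np.array([codes[e] for e in df["event"].tolist()[1:]], dtype=np.int8)
    return Trajectory(
        I=df["I"].to_numpy(dtype=np.int64),
        J=df["J"].to_numpy(dtype=np.int64),
        events=events,
    )
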