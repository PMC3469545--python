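"""Experiment configuration and result serialization.

Configs are flat YAML/JSON files with four blocks (``model``,
``control``, ``scheme``, ``numerics``); every key is optional and
defaults to the standard calibration, so an empty file is a complete,
valid configuration.  Unknown keys and constraint violations raise
with the offending key named.

All times inside the package are hours on the 16-hour-day clock;
day-denominated user inputs (therapy lengths) are converted at the
boundary.  Tabular results are written as CSV with a JSON metadata
sidecar carrying the parameters and the base seed, so any output can
be reproduced from its sidecar alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .cessation import SuccessCurve, TherapyScheme
from .model import BifurcationDiagram, ModelParams
from .stochastic import ControlParams, Trajectory

__all__ = [
    "Numerics",
    "ExperimentConfig",
    "load_config",
    "save_config",
    "write_results",
]


@dataclass(frozen=True)
class Numerics:
    """Integration and Monte Carlo settings."""

    dt: float = 0.1  # Euler step [h]
    duration_days: float = 1000.0  # free-trajectory length
    n_runs: int = 100
    base_seed: int = 0

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError(f"numerics.dt must be positive, got {self.dt!r}")
        if self.n_runs < 1:
            raise ValueError(f"numerics.n_runs must be >= 1, got {self.n_runs!r}")


@dataclass(frozen=True)
class ExperimentConfig:
    """Complete, serialisable description of an experiment."""

    model: ModelParams = field(default_factory=ModelParams)
    control: ControlParams = field(default_factory=ControlParams)
    scheme: TherapyScheme | None = None
    numerics: Numerics = field(default_factory=Numerics)

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {
            "model": dataclasses.asdict(self.model),
            "control": dataclasses.asdict(self.control),
            "numerics": dataclasses.asdict(self.numerics),
        }
        if self.scheme is not None:
            out["scheme"] = dataclasses.asdict(self.scheme)
        return out


_BLOCKS = {
    "model": ModelParams,
    "control": ControlParams,
    "scheme": TherapyScheme,
    "numerics": Numerics,
}


def _build_block(name: str, cls, data: dict) -> Any:
    if not isinstance(data, dict):
        raise ValueError(f"config block {name!r} must be a mapping")
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config block {name!r}; "
            f"allowed: {sorted(known)}"
        )
    for key, value in data.items():
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ValueError(
                f"config key {name}.{key} must be a number, got {value!r}"
            )
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config block {name!r}: {exc}") from exc


def load_config(path: str | Path) -> ExperimentConfig:
    """Read a YAML/JSON config, filling defaults for absent keys."""
    path = Path(path)
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config root of {path} must be a mapping")
    unknown = set(raw) - set(_BLOCKS)
    if unknown:
        raise ValueError(
            f"unknown config block(s) {sorted(unknown)}; "
            f"allowed: {sorted(_BLOCKS)}"
        )
    blocks: dict[str, Any] = {}
    for name, cls in _BLOCKS.items():
        if name in raw:
            blocks[name] = _build_block(name, cls, raw[name])
    return ExperimentConfig(**blocks)


def save_config(config: ExperimentConfig, path: str | Path) -> Path:
    """Write a config so that load(save(x)) == x."""
    path = Path(path)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return path


def _sidecar_meta(obj: Any) -> dict[str, Any]:
    meta: dict[str, Any] = {"type": type(obj).__name__}
    if isinstance(obj, Trajectory):
        m = dict(obj.metadata)
        for key in ("model", "control"):
            if key in m and dataclasses.is_dataclass(m[key]):
                m[key] = dataclasses.asdict(m[key])
        meta.update(m)
    elif isinstance(obj, SuccessCurve):
        meta.update(
            scheme=obj.scheme, n_runs=obj.n_runs, base_seed=obj.base_seed
        )
    elif isinstance(obj, BifurcationDiagram):
        meta.update(
            params=dataclasses.asdict(obj.params),
            S_fold_low=obj.S_fold_low,
            S_fold_high=obj.S_fold_high,
        )
    return meta


def write_results(obj, path: str | Path) -> tuple[Path, Path]:
    """Write a result object as CSV plus a JSON metadata sidecar.

    Accepts a Trajectory, SuccessCurve or BifurcationDiagram (anything
    with ``to_frame``).  Column order is fixed by the object type.
    Returns (csv_path, sidecar_path).
    """
    path = Path(path)
    if not hasattr(obj, "to_frame"):
        raise TypeError(f"cannot serialise object of type {type(obj).__name__}")
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
        obj.to_frame().to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"failed to write results to {path}: {exc}") from exc
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(_sidecar_meta(obj), indent=2, default=str))
    return path, sidecar
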