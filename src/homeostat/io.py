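"""Declarative run descriptions (YAML/JSON) and trajectory export."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from .errors import ConfigError
from .models import get_model
from .simulate import PerturbationSchedule, SimulationConfig, Trajectory, integrate

__all__ = ["RunDescription", "load_run_description", "run_from_description",
           "export_trajectory"]


@dataclass(frozen=True)
class RunDescription:
    """One simulation run: model, parameters, initial state, schedules, solver."""

    model: str
    params: Mapping[str, float]
    initial_state: Mapping[str, float] | Sequence[float]
    schedules: tuple[dict, ...] = ()
    config: Mapping[str, float] = field(default_factory=dict)


def _parse_schedule(d: Mapping) -> PerturbationSchedule:
    if "parameter" not in d:
        raise ConfigError(f"schedule needs a 'parameter' key: {d}")
    kind = d.get("type", "breakpoints")
    if kind == "step":
        return PerturbationSchedule.step(
            d["parameter"], float(d["t_step"]),
            float(d["phase1"]), float(d["phase2"]))
    if kind == "constant":
        return PerturbationSchedule.constant(d["parameter"], float(d["value"]))
    if kind == "breakpoints":
        return PerturbationSchedule(
            d["parameter"],
            tuple((float(t), float(v)) for t, v in d["breakpoints"]))
    raise ConfigError(f"unknown schedule type {kind!r}")


def load_run_description(path) -> RunDescription:
    """Read a YAML (or JSON — a YAML subset) run description."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping at top level")
    missing = {"model", "params", "initial_state"} - set(data)
    if missing:
        raise ConfigError(f"{path}: missing required keys {sorted(missing)}")
    return RunDescription(
        model=data["model"],
        params=data["params"],
        initial_state=data["initial_state"],
        schedules=tuple(data.get("schedules", ())),
        config=data.get("config", {}),
    )


def run_from_description(desc: RunDescription) -> Trajectory:
    """Execute one declarative run."""
    model = get_model(desc.model)
    if isinstance(desc.initial_state, Mapping):
        try:
            state = [desc.initial_state[s] for s in model.species]
        except KeyError as exc:
            raise ConfigError(
                f"initial_state missing species {exc}; need {model.species}"
            ) from None
    else:
        state = list(desc.initial_state)
    schedules = [_parse_schedule(d) for d in desc.schedules]
    config = SimulationConfig(**desc.config)
    return integrate(model, dict(desc.params), state, schedules, config)


def export_trajectory(traj: Trajectory, basename, outdir=".") -> tuple[Path, Path]:
    """Write tidy CSV plus a JSON metadata sidecar; returns both paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / f"{basename}.csv"
    json_path = outdir / f"{basename}.json"
    traj.to_csv(csv_path)
    json_path.write_text(json.dumps(traj.metadata(), indent=2, default=str))
    return csv_path, json_path
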