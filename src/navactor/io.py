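"""Run configuration, output serialization and reproducibility bookkeeping.

A run is fully described by a declarative config (YAML or JSON): environment,
per-condition protocols, noise parameters, cost weights, planner settings,
ablation and seeds. The config snapshot written next to a run's outputs,
together with the seed manifest, regenerates the endpoint CSV bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .env_model import FieldOfView, MotorNoise, ObservationNoise
from .belief_filter import RepresentationNoise
from .params import DEFAULT_NOISE, NoiseParams
from .planner import CostWeights, PlannerConfig
from .task_protocols import (
    AblationSpec,
    CONDITIONS,
    Disorientation,
    EnvironmentLayout,
    TrialProtocol,
    make_environment,
)

__all__ = ["RunConfig", "load_config", "dump_config", "write_outputs"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce a simulation run."""

    environment: object = "nardini_like"
    protocols: dict = field(
        default_factory=lambda: {c: TrialProtocol(condition=c) for c in CONDITIONS}
    )
    noise: NoiseParams = DEFAULT_NOISE
    weights: CostWeights = field(default_factory=CostWeights)
    planner: PlannerConfig = field(default_factory=PlannerConfig)
    ablation: AblationSpec = field(default_factory=AblationSpec)
    base_seed: int = 0
    n_participants: int = 2
    trials_per_condition: int = 2
    out_dir: str = "navactor_out"


def _build_strict(cls, data: dict, path: str):
    """Instantiate a (frozen) dataclass from a mapping, rejecting unknown keys."""
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} under '{path}'")
    return cls(**data)


def _protocol_from_dict(cond: str, data: dict) -> TrialProtocol:
    data = dict(data)
    data.setdefault("condition", cond)
    if "conflict_angle_deg" in data:
        data["conflict_angle"] = float(np.deg2rad(data.pop("conflict_angle_deg")))
    if "disorientation" in data:
        data["disorientation"] = _build_strict(
            Disorientation, data["disorientation"], f"protocols.{cond}.disorientation"
        )
    if "goal_sequence" in data:
        data["goal_sequence"] = tuple(data["goal_sequence"])
    return _build_strict(TrialProtocol, data, f"protocols.{cond}")


def _noise_from_dict(data: dict) -> NoiseParams:
    known = {"motor", "observation", "representation"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} under 'noise'")
    return NoiseParams(
        motor=_build_strict(MotorNoise, data.get("motor", {}), "noise.motor"),
        observation=_build_strict(
            ObservationNoise, data.get("observation", {}), "noise.observation"
        ),
        representation=_build_strict(
            RepresentationNoise, data.get("representation", {}), "noise.representation"
        ),
    )


def _weights_from_dict(data: dict) -> CostWeights:
    data = dict(data)
    for key in ("cq", "cr"):
        if key in data:
            data[key] = np.asarray(data[key], float)
    return _build_strict(CostWeights, data, "weights")


def _planner_from_dict(data: dict) -> PlannerConfig:
    data = dict(data)
    for key in ("v_bounds", "w_bounds", "visibility_schedule"):
        if key in data:
            data[key] = tuple(data[key])
    return _build_strict(PlannerConfig, data, "planner")


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run config, filling explicit defaults.

    Unknown keys anywhere in the document are hard errors naming the key.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown top-level key(s) {sorted(unknown)}")
    kwargs = {}
    if "environment" in raw:
        kwargs["environment"] = raw["environment"]
    if "protocols" in raw:
        kwargs["protocols"] = {
            cond: _protocol_from_dict(cond, spec or {})
            for cond, spec in raw["protocols"].items()
        }
    if "noise" in raw:
        kwargs["noise"] = _noise_from_dict(raw["noise"])
    if "weights" in raw:
        kwargs["weights"] = _weights_from_dict(raw["weights"] or {})
    if "planner" in raw:
        kwargs["planner"] = _planner_from_dict(raw["planner"] or {})
    if "ablation" in raw:
        kwargs["ablation"] = _build_strict(AblationSpec, raw["ablation"] or {}, "ablation")
    for key in ("base_seed", "n_participants", "trials_per_condition", "out_dir"):
        if key in raw:
            kwargs[key] = raw[key]
    return RunConfig(**kwargs)


def _to_plain(obj):
    """Recursively convert dataclasses/arrays to YAML-serializable values."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {
            f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)
        }
    if isinstance(obj, EnvironmentLayout):
        return {
            "landmarks": obj.landmarks.tolist(),
            "goals": obj.goals.tolist(),
            "start_pose": obj.start_pose.tolist(),
            "fov_half_angle": obj.fov.half_angle,
            "fov_max_range": obj.fov.max_range,
            "name": obj.name,
        }
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, float) and np.isinf(obj):
        return ".inf" if obj > 0 else "-.inf"
    return obj


def dump_config(config: RunConfig, path) -> None:
    """Write a config (with all defaults materialized) as YAML."""
    plain = _to_plain(config)
    plain["protocols"] = {
        cond: _to_plain(proto) for cond, proto in config.protocols.items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(plain, fh, sort_keys=True)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_outputs(dataset: pd.DataFrame, logs: dict, config: RunConfig, out_dir) -> dict:
    """Write endpoint CSV, per-trial logs, config snapshot and a manifest.

    ``logs`` maps a trial key (any string) to a TrajectoryLog or DataFrame.
    The manifest lists every written file with its sha256 checksum; re-running
    with the same config and seeds reproduces identical endpoint checksums.
    Returns the manifest dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []

    endpoints = out / "endpoints.csv"
    dataset.to_csv(endpoints, index=False)
    files.append(endpoints)

    log_dir = out / "logs"
    if logs:
        log_dir.mkdir(exist_ok=True)
    for key, log in logs.items():
        df = log.to_dataframe() if hasattr(log, "to_dataframe") else log
        path = log_dir / f"trial_{key}.csv"
        df.to_csv(path, index=False)
        files.append(path)

    snapshot = out / "config_snapshot.yaml"
    dump_config(config, snapshot)
    files.append(snapshot)

    seeds = out / "seed_manifest.json"
    seed_info = {"base_seed": config.base_seed}
    if "seed" in dataset.columns:
        seed_info["trial_seeds"] = [int(s) for s in dataset["seed"]]
    with open(seeds, "w") as fh:
        json.dump(seed_info, fh, indent=1)
    files.append(seeds)

    manifest = {
        "files": [
            {"path": str(p.relative_to(out)), "sha256": _sha256(p)} for p in files
        ]
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
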