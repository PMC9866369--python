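"""YAML run configuration binding scene, kernel, architecture and training.

A run config is a YAML file with up to five sections, each mapping
directly onto the corresponding dataclass (missing keys fall back to the
dataclass defaults)::

    scene:        {image_height: 64, image_width: 64, count_range: [5, 15], ...}
    kernel:       {sigma: 2.0, truncation_radius: 8, normalization: unit_integral}
    architecture: {family: unet, base_channels: 32, ...}
    training:     {learning_rate: 0.01, epochs: 200, batch_size: 1, ...}
    paths:        {data_dir: ..., out_dir: ..., checkpoint: ...}

Lists in YAML are coerced to the tuples the dataclasses expect.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .density import KernelSpec
from .models import ArchitectureSpec
from .synthetic import SceneConfig
from .training import TrainConfig


@dataclass(frozen=True)
class Paths:
    data_dir: str = "data"
    out_dir: str = "out"
    checkpoint: str | None = None


@dataclass(frozen=True)
class RunConfig:
    scene: SceneConfig
    kernel: KernelSpec
    architecture: ArchitectureSpec
    training: TrainConfig
    paths: Paths


def _build(cls, section: dict, name: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(section) - set(fields)
    if unknown:
        raise ValueError(f"{name}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for key, value in section.items():
        if isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{name}: {exc}") from exc


def load_run_config(path) -> RunConfig:
    """Parse and validate a YAML run config; raises ValueError naming the
    offending section/field on invalid input."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    known = {"scene", "kernel", "architecture", "training", "paths"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown sections {sorted(unknown)}")
    return RunConfig(
        scene=_build(SceneConfig, raw.get("scene") or {}, "scene"),
        kernel=_build(KernelSpec, raw.get("kernel") or {}, "kernel"),
        architecture=_build(ArchitectureSpec, raw.get("architecture") or {}, "architecture"),
        training=_build(TrainConfig, raw.get("training") or {}, "training"),
        paths=_build(Paths, raw.get("paths") or {}, "paths"),
    )


def dump_run_config(config: RunConfig, path) -> None:
    """Echo a run config back to YAML (used for output-directory provenance)."""
    payload = {
        "scene": dataclasses.asdict(config.scene),
        "kernel": dataclasses.asdict(config.kernel),
        "architecture": dataclasses.asdict(config.architecture),
        "training": dataclasses.asdict(config.training),
        "paths": dataclasses.asdict(config.paths),
    }

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, tuple):
            return [_clean(v) for v in obj]
        return obj

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(_clean(payload), fh, sort_keys=False)
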