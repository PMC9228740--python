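"""Run configuration: nested sections, YAML round-trip, strict key checking.

A :class:`RunConfig` mirrors the pipeline stages (preprocess / index / model /
train / affinity / grading / simulate) plus a global seed.  Unknown keys are
rejected on load rather than silently ignored, and every CLI output directory
receives an ``effective_config.yaml`` echo of the fully-merged configuration
so any artifact can be replayed.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .affinity import RegionCorrectionConfig
from .preprocess import PreprocessConfig

__all__ = [
    "IndexConfig",
    "ModelSection",
    "TrainSection",
    "GradingSection",
    "SimulateSection",
    "RunConfig",
    "load_config",
    "save_config",
    "write_effective_config",
]


@dataclasses.dataclass(frozen=True)
class IndexConfig:
    """Which band pair feeds the model and whether the signed root is applied."""

    band_a: str = "B5"
    band_b: str = "B1"
    sqrt: bool = True


@dataclasses.dataclass(frozen=True)
class ModelSection:
    input_size: int = 96
    n_layers: int = 2
    n_heads: int = 4
    embed_dim: int = 64
    patch_size: int = 4
    mlp_ratio: int = 2
    detail_skip: bool = True


@dataclasses.dataclass(frozen=True)
class TrainSection:
    epochs: int = 60
    learning_rate: float = 1e-3
    batch_size: int = 8


@dataclasses.dataclass(frozen=True)
class GradingSection:
    water_only: bool = False


@dataclasses.dataclass(frozen=True)
class SimulateSection:
    preset: str = "regular"
    n: int = 8
    height: int = 96
    width: int = 96
    bloom_fraction: float = 0.3


@dataclasses.dataclass(frozen=True)
class RunConfig:
    preprocess: PreprocessConfig = dataclasses.field(default_factory=PreprocessConfig)
    index: IndexConfig = dataclasses.field(default_factory=IndexConfig)
    model: ModelSection = dataclasses.field(default_factory=ModelSection)
    train: TrainSection = dataclasses.field(default_factory=TrainSection)
    affinity: RegionCorrectionConfig = dataclasses.field(
        default_factory=RegionCorrectionConfig
    )
    grading: GradingSection = dataclasses.field(default_factory=GradingSection)
    simulate: SimulateSection = dataclasses.field(default_factory=SimulateSection)
    seed: int = 0
    verbosity: str = "info"


_SECTIONS = {
    "preprocess": PreprocessConfig,
    "index": IndexConfig,
    "model": ModelSection,
    "train": TrainSection,
    "affinity": RegionCorrectionConfig,
    "grading": GradingSection,
    "simulate": SimulateSection,
}


def _build(cls, data: dict, path: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValueError(f"unknown config key(s) under {path}: {sorted(unknown)}")
    return cls(**data)


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run config, rejecting unknown keys at any level."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError("run config must be a YAML mapping")
    top_known = set(_SECTIONS) | {"seed", "verbosity"}
    unknown = set(raw) - top_known
    if unknown:
        raise ValueError(f"unknown top-level config key(s): {sorted(unknown)}")
    kwargs = {}
    for name, cls in _SECTIONS.items():
        section = raw.get(name, {}) or {}
        if not isinstance(section, dict):
            raise ValueError(f"config section {name!r} must be a mapping")
        kwargs[name] = _build(cls, section, name)
    if "seed" in raw:
        kwargs["seed"] = int(raw["seed"])
    if "verbosity" in raw:
        kwargs["verbosity"] = str(raw["verbosity"])
    return RunConfig(**kwargs)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(dataclasses.asdict(config), sort_keys=True)
    )


def write_effective_config(config: RunConfig, out_dir: str | Path) -> Path:
    """Echo the merged configuration into an artifact directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    target = out / "effective_config.yaml"
    save_config(config, target)
    return target
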