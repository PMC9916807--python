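"""Run configuration: a validated YAML schema wiring all pipeline stages."""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .losses import LossConfig
from .train import TrainConfig

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass
class SimulateSection:
    n_slides: int = 20
    prevalence: float = 0.5
    width: int = 1024
    height: int = 1024


@dataclass
class SlidePipelineSection:
    patch_size: int = 256
    min_foreground_fraction: float = 0.5


@dataclass
class EncoderSection:
    name: str = "desk"
    seed: int = 0
    output_dim: int = 1024


@dataclass
class ModelSection:
    profile: str = "paper"
    n_classes: int = 2
    seed: int = 0
    dropout_p: float = 0.25


@dataclass
class SplitSection:
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)


@dataclass
class HeatmapSection:
    class_index: int = 1
    colormap: str = "coolwarm"
    alpha_blend: float = 0.5
    downsample: int = 4


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "wsimil_run"
    simulate: SimulateSection = field(default_factory=SimulateSection)
    slide_pipeline: SlidePipelineSection = field(default_factory=SlidePipelineSection)
    encoder: EncoderSection = field(default_factory=EncoderSection)
    model: ModelSection = field(default_factory=ModelSection)
    loss: LossConfig = field(default_factory=LossConfig)
    training: TrainConfig = field(default_factory=TrainConfig)
    split: SplitSection = field(default_factory=SplitSection)
    heatmap: HeatmapSection = field(default_factory=HeatmapSection)

    def validate(self) -> None:
        self.loss.validate()
        self.training.validate()
        if not 0 <= self.simulate.prevalence <= 1:
            raise ValueError("simulate.prevalence must lie in [0, 1]")
        fr = self.split.fractions
        if len(fr) != 3 or abs(sum(fr) - 1.0) > 1e-9 or min(fr) < 0:
            raise ValueError("split.fractions must be three non-negative values summing to 1")


_SECTION_TYPES = {
    "simulate": SimulateSection,
    "slide_pipeline": SlidePipelineSection,
    "encoder": EncoderSection,
    "model": ModelSection,
    "loss": LossConfig,
    "training": TrainConfig,
    "split": SplitSection,
    "heatmap": HeatmapSection,
}


def _build_section(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} in section '{path}'")
    kwargs = {k: tuple(v) if isinstance(v, list) else v for k, v in data.items()}
    return cls(**kwargs)


def load_config(path: str | Path | None = None, data: dict | None = None) -> RunConfig:
    """Parse and validate a run config from YAML (or an explicit mapping)."""
    if data is None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    names = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} at top level")
    kwargs = {}
    for key, value in data.items():
        if key in _SECTION_TYPES:
            if not isinstance(value, dict):
                raise ValueError(f"config section '{key}' must be a mapping")
            kwargs[key] = _build_section(_SECTION_TYPES[key], value, key)
        else:
            kwargs[key] = value
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg


def config_hash(cfg: RunConfig) -> str:
    """Stable short hash of the full resolved configuration."""
    canonical = yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
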