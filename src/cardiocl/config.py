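"""Layered run configuration.

A single YAML document overrides defaults section by section; every field
not mentioned keeps its default, and unknown keys are rejected.  The
resolved configuration (plus the seed) fully determines a run.

Sections and their dataclasses::

    synthetic:      SynthConfig
    preprocessing:  target_s, target_len, min_length_s, max_missing_leads
    augmentation:   AugmentationConfig
    model:          ModelConfig
    loss:           LossConfig
    pretrain:       epochs, batch_size, learning_rate, checkpoint_every
    probe:          ProbeConfig
    finetune:       FinetuneConfig
    split:          SplitSpec
    seed:           int
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .augment import AugmentationConfig
from .evaluate import FinetuneConfig, ProbeConfig, SplitSpec
from .losses import LossConfig
from .model import ModelConfig
from .pretrain import PretrainConfig
from .synthetic import SynthConfig

__all__ = ["PreprocessingConfig", "RunConfig", "load_run_config"]


@dataclass(frozen=True)
class PreprocessingConfig:
    target_s: float = 10.0
    target_len: int = 2048
    #: quality-control thresholds (the source pipelines drop records with
    #: insufficient length or missing leads; exact thresholds are a choice)
    min_length_s: float = 10.0
    max_missing_leads: int = 0


@dataclass(frozen=True)
class RunConfig:
    synthetic: SynthConfig = field(default_factory=SynthConfig)
    preprocessing: PreprocessingConfig = field(
        default_factory=PreprocessingConfig)
    augmentation: AugmentationConfig = field(
        default_factory=AugmentationConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    probe: ProbeConfig = field(default_factory=ProbeConfig)
    finetune: FinetuneConfig = field(default_factory=FinetuneConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    epochs: int = 200
    batch_size: int = 64
    learning_rate: float = 1e-3
    checkpoint_every: int = 0
    seed: int = 0

    def pretrain_config(self) -> PretrainConfig:
        return PretrainConfig(epochs=self.epochs, batch_size=self.batch_size,
                              learning_rate=self.learning_rate,
                              model=self.model,
                              augmentation=self.augmentation, loss=self.loss,
                              seed=self.seed,
                              checkpoint_every=self.checkpoint_every)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _build(cls, overrides: dict, label: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(overrides) - names
    if unknown:
        raise ValueError(f"unknown keys in section {label!r}: "
                         f"{sorted(unknown)}")
    coerced = {}
    for k, v in overrides.items():
        coerced[k] = tuple(v) if isinstance(v, list) else v
    return cls(**coerced)


def load_run_config(path: str | Path | None = None,
                    overrides: dict | None = None) -> RunConfig:
    """Load a RunConfig from YAML (or an override dict), layered over
    defaults."""
    doc = dict(overrides or {})
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError("config document must be a mapping")
        loaded.update(doc)
        doc = loaded
    sections = {
        "synthetic": SynthConfig, "preprocessing": PreprocessingConfig,
        "augmentation": AugmentationConfig, "model": ModelConfig,
        "loss": LossConfig, "probe": ProbeConfig,
        "finetune": FinetuneConfig, "split": SplitSpec,
    }
    kwargs = {}
    scalars = {"epochs", "batch_size", "learning_rate",
               "checkpoint_every", "seed"}
    for key, val in doc.items():
        if key in sections:
            kwargs[key] = _build(sections[key], dict(val or {}), key)
        elif key in scalars:
            kwargs[key] = val
        else:
            raise ValueError(f"unknown config section {key!r}")
    # seed propagates into sub-configs that carry their own seed unless set
    cfg = RunConfig(**kwargs)
    return cfg
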