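"""Run configuration: schema-validated sections mirroring each module's
config type, YAML loading, dot-path overrides and content hashing."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .phantom import PhantomConfig
from .preprocess import AugmentConfig
from .backbone import BackboneConfig
from .rl import PPOConfig
from .training import TrainConfig


class _Section(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomSection(_Section):
    n_patients_per_class: int = 20
    slices_per_patient: int | tuple[int, int] = 4
    image_size: int = 128
    roi_radius_range: tuple[float, float] = (12.0, 28.0)
    roi_contrast: float = 0.15
    roi_texture_freq: tuple[float, float] = (4.0, 10.0)
    texture_amplitude: float = 0.06
    background_distractor_count: int = 6
    distractor_contrast: float = 0.45
    background_level: float = 0.35
    center_jitter: float = 0.12
    noise_sigma: float = 0.05

    def build(self, seed: int) -> PhantomConfig:
        return PhantomConfig(seed=seed, **self.model_dump())


class AugmentSection(_Section):
    rotation_degrees: tuple[float, float] = (-10.0, 10.0)
    crop_fraction: float = 0.1
    flip_horizontal: float = 0.5
    flip_vertical: float = 0.5
    jitter_brightness: float = 0.1
    jitter_contrast: float = 0.1

    def build(self, seed: int) -> AugmentConfig:
        return AugmentConfig(seed=seed, **self.model_dump())


class PreprocessSection(_Section):
    window: int = 128
    n_val_per_class: int = 10
    balance: bool = True
    augment_train: bool = False
    augment: AugmentSection = Field(default_factory=AugmentSection)


class BackboneSection(_Section):
    stem_channels: int = 16
    stage_channels: tuple[int, int, int] = (64, 128, 256)
    blocks_per_stage: int = 9
    attention_enabled: bool = True

    def build(self, input_size: int) -> BackboneConfig:
        return BackboneConfig(input_size=input_size, **self.model_dump())


class RLSection(_Section):
    enabled: bool = True
    epsilon: float = 0.2
    benchmark_accuracy: float = 0.9
    epochs_per_update: int = 4
    learning_rate: float = 0.01
    critic_lr: float = 1e-3
    exploration_std: float = 0.1
    action_mode: Literal["spatial", "channel"] = "spatial"
    advantage_standardize: bool = False

    def build(self) -> PPOConfig:
        d = self.model_dump()
        d.pop("enabled")
        return PPOConfig(**d)


class TrainSection(_Section):
    epochs: int = 600
    batch_size: int = 32
    classifier_lr: float = 0.1
    lr_decay_factor: float = 0.1
    lr_decay_every: int = 100
    weight_decay: float = 5e-4
    momentum: float = 0.9

    def build(self, seed: int, generator_lr: float, rl_enabled: bool) -> TrainConfig:
        return TrainConfig(seed=seed, generator_lr=generator_lr,
                           rl_enabled=rl_enabled, **self.model_dump())


class EvalSection(_Section):
    threshold: float = 0.5
    ci_level: float = 0.95


class RunConfig(_Section):
    seed: int = 0
    phantom: PhantomSection = Field(default_factory=PhantomSection)
    preprocess: PreprocessSection = Field(default_factory=PreprocessSection)
    backbone: BackboneSection = Field(default_factory=BackboneSection)
    rl: RLSection = Field(default_factory=RLSection)
    train: TrainSection = Field(default_factory=TrainSection)
    eval: EvalSection = Field(default_factory=EvalSection)


class ConfigError(ValueError):
    """Invalid run configuration, with a field-level message."""


def _parse_override(item: str) -> tuple[list[str], object]:
    if "=" not in item:
        raise ConfigError(f"override {item!r} must look like section.key=value")
    path, raw = item.split("=", 1)
    value = yaml.safe_load(raw)
    return path.split("."), value


def load_run_config(path: str | Path | None = None,
                    overrides: list[str] | None = None) -> RunConfig:
    """Load and validate a YAML run config, applying dot-path overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("run config must be a YAML mapping")
    for item in overrides or []:
        keys, value = _parse_override(item)
        node = data
        for key in keys[:-1]:
            node = node.setdefault(key, {})
            if not isinstance(node, dict):
                raise ConfigError(f"cannot override through scalar at {key!r}")
        node[keys[-1]] = value
    try:
        return RunConfig.model_validate(data)
    except ValidationError as exc:
        details = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}"
            for err in exc.errors())
        raise ConfigError(f"invalid run config: {details}") from exc


def config_hash(config: RunConfig) -> str:
    canonical = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(canonical.encode("utf-8")).hexdigest()[:16]


def dump_resolved(config: RunConfig, path: str | Path) -> None:
    payload = config.model_dump(mode="json")
    payload["_config_hash"] = config_hash(config)
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
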