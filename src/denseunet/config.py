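"""Nested pipeline configuration with YAML round-tripping.

A :class:`PipelineConfig` mirrors the module configs (phantom / preprocess /
model / loss / train); every field has a default, unknown keys are rejected
by name, and ``load(dump(cfg)) == cfg`` holds exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

from .containers import ValidationError
from .io import dump_yaml, load_yaml
from .losses import LossConfig
from .model import DenseUnetConfig
from .phantom import PhantomConfig
from .train import TrainConfig


@dataclass(frozen=True)
class PreprocessConfig:
    crop: tuple[int, int] = (160, 160)
    norm_support: str = "volume"
    keep_empty: bool = False


@dataclass(frozen=True)
class PipelineConfig:
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    train: TrainConfig = field(default_factory=TrainConfig)


def _build(cls, data: dict, path: str):
    """Recursively build a dataclass from a mapping, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ValidationError(f"config section {path!r} must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValidationError(
            f"unknown config key(s) {sorted(unknown)} in section {path!r}"
        )
    defaults = cls()
    kwargs = {}
    for name, value in data.items():
        current = getattr(defaults, name)
        if dataclasses.is_dataclass(current):
            kwargs[name] = _build(type(current), value, f"{path}.{name}")
        elif isinstance(current, tuple) and isinstance(value, (list, tuple)):
            kwargs[name] = tuple(value)
        elif isinstance(current, dict) and isinstance(value, dict):
            kwargs[name] = {
                k: tuple(v) if isinstance(v, list) else v for k, v in value.items()
            }
        else:
            kwargs[name] = value
    return cls(**kwargs)


def _plain(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    return obj


def config_to_dict(config: PipelineConfig) -> dict:
    return _plain(config)


def config_from_dict(data: dict) -> PipelineConfig:
    return _build(PipelineConfig, data or {}, "pipeline")


def load_config(path: str | Path) -> PipelineConfig:
    return config_from_dict(load_yaml(path))


def save_config(config: PipelineConfig, path: str | Path) -> None:
    dump_yaml(config_to_dict(config), path)


__all__ = [
    "PipelineConfig",
    "PreprocessConfig",
    "PhantomConfig",
    "TrainConfig",
    "LossConfig",
    "DenseUnetConfig",
    "load_config",
    "save_config",
    "config_to_dict",
    "config_from_dict",
]
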