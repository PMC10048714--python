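"""Run configuration: one human-readable YAML file, lossless round-trip."""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import yaml

from .fusion import HeadConfig
from .image_branch import ImageTrainConfig
from .pipeline import ExperimentConfig
from .spectral_branch import MLPConfig
from .synthetic_data import SyntheticConfig

__all__ = ["to_yaml", "from_yaml", "load_config", "save_config", "config_hash"]

_SECTIONS = {
    "synthetic": SyntheticConfig,
    "mlp": MLPConfig,
    "image_train": ImageTrainConfig,
    "head": HeadConfig,
}


def _plain(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _plain(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, tuple):
        return [_plain(v) for v in obj]
    if isinstance(obj, list):
        return [_plain(v) for v in obj]
    return obj


def _tuples(value):
    if isinstance(value, list):
        return tuple(_tuples(v) for v in value)
    return value


def to_yaml(config: ExperimentConfig) -> str:
    return yaml.safe_dump(_plain(config), sort_keys=True)


def from_yaml(text: str) -> ExperimentConfig:
    raw = yaml.safe_load(text) or {}
    kwargs = {}
    for key, value in raw.items():
        if key in _SECTIONS:
            sub = {k: _tuples(v) for k, v in value.items()}
            kwargs[key] = _SECTIONS[key](**sub)
        else:
            kwargs[key] = _tuples(value)
    return ExperimentConfig(**kwargs)


def save_config(config: ExperimentConfig, path) -> Path:
    path = Path(path)
    path.write_text(to_yaml(config))
    return path


def load_config(path) -> ExperimentConfig:
    return from_yaml(Path(path).read_text())


def config_hash(config: ExperimentConfig) -> str:
    """Short stable identifier of a run configuration."""
    return hashlib.sha256(to_yaml(config).encode()).hexdigest()[:8]
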