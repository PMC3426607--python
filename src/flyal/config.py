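"""Structured-text (YAML) serialization of configurations and manifests."""

from __future__ import annotations

import hashlib
from dataclasses import fields
from pathlib import Path

import numpy as np
import yaml

from .network import ArchitectureConfig
from .odors import OdorSpec

__all__ = [
    "architecture_to_dict",
    "architecture_from_dict",
    "save_architecture",
    "load_architecture",
    "save_panel",
    "load_panel",
    "config_hash",
]


def _plain(value):
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    return value


def architecture_to_dict(cfg: ArchitectureConfig) -> dict:
    return {f.name: _plain(getattr(cfg, f.name)) for f in fields(cfg)}


def architecture_from_dict(data: dict) -> ArchitectureConfig:
    return ArchitectureConfig(**data)


def save_architecture(cfg: ArchitectureConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(architecture_to_dict(cfg), sort_keys=True))


def load_architecture(path) -> ArchitectureConfig:
    return architecture_from_dict(yaml.safe_load(Path(path).read_text()))


def save_panel(panel, path) -> None:
    data = [
        {f.name: _plain(getattr(odor, f.name)) for f in fields(odor)} for odor in panel
    ]
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def load_panel(path) -> list[OdorSpec]:
    return [OdorSpec(**d) for d in yaml.safe_load(Path(path).read_text())]


def config_hash(cfg: ArchitectureConfig) -> str:
    """Stable short hash of a configuration, for run manifests."""
    text = yaml.safe_dump(architecture_to_dict(cfg), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]
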