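"""Pipeline configuration: defaults, YAML loading, strict key checking.

The default configuration reproduces the field-tested parameter set exactly:
30 px size threshold, 0.4 minimum confidence, 0.15 maximum cosine distance,
30-frame maximum age, 3 hits to confirm, 0.3 IoU fallback threshold, one GPS
fix every 3 s at 30 fps, 300-apple containers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .detection_io import DetectionFilterConfig
from .tracking import TrackerConfig
from .geospatial import SyncConfig
from .container_opt import ContainerConfig
from .synthetic import SceneConfig


@dataclass(frozen=True)
class PipelineConfig:
    filter: DetectionFilterConfig = field(default_factory=DetectionFilterConfig)
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    sync: SyncConfig = field(default_factory=SyncConfig)
    container: ContainerConfig = field(default_factory=ContainerConfig)
    scene: SceneConfig = field(default_factory=SceneConfig)


_SECTIONS = {
    "filter": DetectionFilterConfig,
    "tracker": TrackerConfig,
    "sync": SyncConfig,
    "container": ContainerConfig,
    "scene": SceneConfig,
}


def _build_section(cls: type, data: dict[str, Any], section: str) -> Any:
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown key(s) in section '{section}': {sorted(unknown)}")
    # YAML reads tuples back as lists; coerce for tuple-typed fields
    coerced = {k: tuple(v) if isinstance(v, list) else v for k, v in data.items()}
    return cls(**coerced)


def config_from_dict(data: dict[str, Any]) -> PipelineConfig:
    unknown = set(data) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown configuration section(s): {sorted(unknown)}")
    kwargs = {
        name: _build_section(cls, data.get(name, {}) or {}, name)
        for name, cls in _SECTIONS.items()
    }
    return PipelineConfig(**kwargs)


def config_to_dict(cfg: PipelineConfig) -> dict[str, Any]:
    out: dict[str, Any] = {}
    for name in _SECTIONS:
        section = dataclasses.asdict(getattr(cfg, name))
        out[name] = {k: list(v) if isinstance(v, tuple) else v for k, v in section.items()}
    return out


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML config; unknown sections or keys are rejected."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: top level must be a mapping of sections")
    return config_from_dict(data)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)
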