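"""Nested pipeline configuration with lossless YAML/JSON round-tripping."""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .detection import (DEFAULT_DR_THRESHOLD, DEFAULT_MIN_BLOB_AREA,
                        DEFAULT_PATCH_SIZE)
from .filters import DEFAULT_ASPECT_RATIO, DEFAULT_SIGMA_FRACTION
from .metrics import DEFAULT_MATCH_RADIUS
from .postprocess import (DEFAULT_MIN_SEPARATION_DEG, DEFAULT_MIN_SIZE,
                          DEFAULT_PROMINENCE_FRAC)
from .preprocess import PreprocessConfig
from .segmentation import GESUNetSpec
from .synthgen import SceneConfig

__all__ = ["FilterBankConfig", "DetectionConfig", "PostprocessConfig",
           "MetricsConfig", "PipelineConfig"]


@dataclass
class FilterBankConfig:
    n_scales: int = 3
    n_orientations: int = 20
    base_kernel_size: int = 15
    aspect_ratio: float = DEFAULT_ASPECT_RATIO
    sigma_fraction: float = DEFAULT_SIGMA_FRACTION


@dataclass
class DetectionConfig:
    dr_threshold: float = DEFAULT_DR_THRESHOLD
    min_blob_area: int = DEFAULT_MIN_BLOB_AREA
    patch_size: int = DEFAULT_PATCH_SIZE


@dataclass
class PostprocessConfig:
    min_size: int = DEFAULT_MIN_SIZE
    prominence_frac: float = DEFAULT_PROMINENCE_FRAC
    min_separation_deg: float = DEFAULT_MIN_SEPARATION_DEG
    #: classify the segmented mask ("mask") or the raw patch ("patch")
    classify_on: str = "mask"


@dataclass
class MetricsConfig:
    match_radius: float = DEFAULT_MATCH_RADIUS


def _as_tuples(obj):
    """Recursively convert lists to tuples (YAML loses tuple-ness)."""
    if isinstance(obj, list):
        return tuple(_as_tuples(v) for v in obj)
    return obj


@dataclass
class PipelineConfig:
    filters: FilterBankConfig = field(default_factory=FilterBankConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    segmentation: GESUNetSpec = field(default_factory=GESUNetSpec)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    metrics: MetricsConfig = field(default_factory=MetricsConfig)
    synthgen: SceneConfig = field(default_factory=SceneConfig)
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = {}
        sections = {
            "filters": FilterBankConfig,
            "preprocess": PreprocessConfig,
            "detection": DetectionConfig,
            "segmentation": GESUNetSpec,
            "postprocess": PostprocessConfig,
            "metrics": MetricsConfig,
            "synthgen": SceneConfig,
        }
        for key, klass in sections.items():
            if key in data:
                section = {k: _as_tuples(v) for k, v in data[key].items()}
                kwargs[key] = klass(**section)
        for key in ("seed", "log_level"):
            if key in data:
                kwargs[key] = data[key]
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        data = self.to_dict()
        with open(path, "w") as fh:
            if path.suffix == ".json":
                json.dump(data, fh, indent=2)
            else:
                yaml.safe_dump(data, fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            if path.suffix == ".json":
                data = json.load(fh)
            else:
                data = yaml.safe_load(fh)
        return cls.from_dict(data)
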