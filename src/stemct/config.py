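"""Pipeline configuration: YAML parsing, validation, defaults, manifests.

One config file drives every subcommand.  All segmentation defaults are the
platform's standard operating point: closing radius 3 px, minimum-area
factor 0.00005 of the image, high-intensity (rind) threshold 175, dark
(pithy) threshold 20, eccentricity cutoff 0.08, pixel spacing 1/1.024 mm/px
and 0.6 mm slice thickness.  Unknown keys are rejected so that typos never
silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .imaging import SegmentationConfig
from .stack import GridSpec

__all__ = ["PipelineConfig", "ConfigError", "validate_config", "run_manifest"]


class ConfigError(ValueError):
    """Malformed pipeline configuration."""


@dataclass
class PipelineConfig:
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    grid: GridSpec = field(default_factory=GridSpec)
    pixel_spacing_mm: float = 1.0 / 1.024
    slice_thickness_mm: float = 0.6
    node_annotations: str | None = None
    node_half_width: int = 1
    outlier_k: float = 3.5
    output_dir: str = "stemct_out"
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


_TOP_KEYS = {
    "segmentation",
    "grid",
    "pixel_spacing_mm",
    "slice_thickness_mm",
    "node_annotations",
    "node_half_width",
    "outlier_k",
    "output_dir",
    "seed",
    "log_level",
}


def _build(cls, data: dict, path: str) -> object:
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} under '{path}'")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid values under '{path}': {exc}") from exc


def validate_config(path: str | Path | None = None, data: dict | None = None) -> PipelineConfig:
    """Load, validate and normalise a pipeline config.

    An empty or missing mapping yields the all-defaults config.  Unknown
    keys raise :class:`ConfigError` with the offending key path, as do
    out-of-range values (reported by the underlying dataclass).
    """
    if data is None:
        if path is None:
            data = {}
        else:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError("config root must be a mapping")
    unknown = set(data) - _TOP_KEYS
    if unknown:
        raise ConfigError(f"unknown top-level key(s) {sorted(unknown)}")
    seg = _build(SegmentationConfig, dict(data.get("segmentation") or {}), "segmentation")
    grid_data = dict(data.get("grid") or {})
    if "image_shape" in grid_data:
        grid_data["image_shape"] = tuple(grid_data["image_shape"])
    grid = _build(GridSpec, grid_data, "grid")
    rest = {k: v for k, v in data.items() if k not in ("segmentation", "grid")}
    cfg = PipelineConfig(segmentation=seg, grid=grid, **rest)
    if not isinstance(cfg.seed, int):
        raise ConfigError("seed must be an integer")
    if cfg.pixel_spacing_mm <= 0 or cfg.slice_thickness_mm <= 0:
        raise ConfigError("calibration values must be positive")
    if cfg.node_half_width < 0:
        raise ConfigError("node_half_width must be >= 0")
    return cfg


def run_manifest(config: PipelineConfig, extra: dict | None = None) -> dict:
    """Reproducibility manifest: config hash, seed, package versions.

    Deliberately excludes wall-clock time so that identical runs produce
    byte-identical manifests.
    """
    import numpy
    import pandas
    import scipy
    import skimage

    from . import __version__

    cfg = config.to_dict()
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": config.seed,
        "versions": {
            "stemct": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "scikit-image": skimage.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    return manifest
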