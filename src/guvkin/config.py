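"""Pipeline configuration.

A single structured config object holds every tunable of the analysis:
acquisition fallbacks (pixel size, frame interval), segmentation
parameters, linear-window search parameters, and background-ROI /
curvature settings.  All lengths are in micrometres, all times in
minutes, pixel coordinates are 0-based (row, col).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple, Union

import yaml

log = logging.getLogger("guvkin")


@dataclass
class SegmentationConfig:
    """Parameters of the ring-detection stage.

    ``sigma_small_px`` defaults to half the expected membrane thickness
    in pixels when left as ``None``; the large scale is
    ``sigma_large_ratio`` times the small one.
    """

    sigma_small_px: Optional[float] = None
    sigma_large_ratio: float = 3.0
    #: "otsu" or a fixed numeric threshold on the band-pass response.
    threshold: Union[str, float] = "otsu"
    #: Otsu floor in robust SDs of the response (guards empty frames).
    noise_floor_sigmas: float = 3.0
    smooth_radius_px: int = 1
    #: "close" (default; preserves thin rings), "open" or "none".
    smooth_operator: str = "close"
    #: drop mask components smaller than this before hole-filling.
    despeckle_min_px: int = 5
    thickness_um: float = 0.5
    min_radius_um: float = 1.0
    min_circularity: float = 0.7
    #: segment every frame (True) or reuse the reference frame's mask.
    per_frame: bool = True
    #: frame used to define frame-fixed GUV regions.
    reference_frame: int = 0
    #: membrane pixels are collected within this multiple of the radius
    #: around each region's centroid.
    neighborhood_factor: float = 1.5


@dataclass
class WindowConfig:
    """Automatic linear-window search for initial rates.

    The classical manual procedure picks the linear region of the
    progress curve by eye; the automatic search scans contiguous windows of at
    least ``min_points`` samples, keeps those with r^2 >= ``r2_min`` and
    returns the one with the largest slope (ties: longer window, then
    earlier start).  A manual window overrides the search.
    """

    min_points: int = 14
    r2_min: float = 0.95
    manual: Optional[Tuple[int, int]] = None


@dataclass
class BackgroundConfig:
    """GUV-free regions used for the temporal baseline."""

    n_rois: int = 10
    roi_radius_um: float = 1.5
    margin_um: float = 1.0


@dataclass
class PipelineConfig:
    #: fallbacks used when the image file carries no metadata.
    pixel_size_um: float = 0.25
    frame_interval_min: float = 2.5
    channel_names: Tuple[str, str] = ("membrane", "reporter")
    #: channel quantified against the baseline (the PI(3)P reporter).
    reporter_channel: str = "reporter"
    membrane_channel: str = "membrane"
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    window: WindowConfig = field(default_factory=WindowConfig)
    background: BackgroundConfig = field(default_factory=BackgroundConfig)
    #: end-point time for the curvature-intensity analysis.
    t_end_min: float = 60.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        for key, sub in (
            ("segmentation", SegmentationConfig),
            ("window", WindowConfig),
            ("background", BackgroundConfig),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        if "channel_names" in d:
            d["channel_names"] = tuple(d["channel_names"])
        cfg = cls(**d)
        if cfg.window.manual is not None:
            cfg.window.manual = tuple(cfg.window.manual)
        return cfg


def load_config(path: Union[str, Path]) -> PipelineConfig:
    """Load a YAML config file; missing keys take their defaults."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    cfg = PipelineConfig.from_dict(data)
    log.info("loaded config from %s", path)
    return cfg


def save_config(cfg: PipelineConfig, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=False)
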