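"""Per-GUV intensity traces and temporal baseline correction.

The mean membrane intensity of each GUV is recorded per channel and
frame; the diffuse haze of the reporter channel is estimated from
GUV-free background regions (mean per ROI per frame, then unweighted
mean across ROIs) and subtracted per time point.  Negative corrected
values in the lag phase are expected and preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .io import ImageStack, RoiSet
from .segment import GUVRegion

log = logging.getLogger("guvkin")


@dataclass
class IntensityTrace:
    """Mean intensity of one ROI in one channel versus time.

    Frames where the ROI had no membrane pixels are NaN (missing),
    never silently zero.  ``corrected`` is ``raw - baseline``.
    """

    roi_id: str
    channel: str
    time_min: np.ndarray
    raw: np.ndarray
    corrected: Optional[np.ndarray] = None
    baseline: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, float)
        self.raw = np.asarray(self.raw, float)
        if self.time_min.shape != self.raw.shape:
            raise ValueError("time and raw lengths differ")

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.raw).sum())

    @property
    def values(self) -> np.ndarray:
        """Corrected values when available, else raw."""
        return self.raw if self.corrected is None else self.corrected


@dataclass
class BaselineProfile:
    """Temporal haze profile averaged over GUV-free regions."""

    time_min: np.ndarray
    values: np.ndarray
    n_regions: int

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, float)
        self.values = np.asarray(self.values, float)
        if self.time_min.shape != self.values.shape:
            raise ValueError("time and value lengths differ")
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("baseline values must be finite")


def measure_traces(
    stack: ImageStack,
    regions: Sequence[GUVRegion],
    channels: Optional[Sequence[str]] = None,
) -> List[IntensityTrace]:
    """Mean membrane intensity per region, channel and frame.

    A region's pixel set for a frame is ``membrane_pixels[frame]`` when
    per-frame sets were recorded, else the single frame-fixed set.  An
    empty pixel set yields NaN for that frame, with a logged count.
    """
    channels = list(channels or stack.channel_names)
    h, w = stack.frame_shape
    traces: List[IntensityTrace] = []
    for region in regions:
        fixed = region.membrane_pixels.get(0)
        for rows, cols in region.membrane_pixels.values():
            if len(rows) and (rows.max() >= h or cols.max() >= w):
                raise ValueError(f"region {region.label} references out-of-bounds pixels")
        for channel in channels:
            c = stack.channel_index(channel)
            vals = np.full(stack.n_frames, np.nan)
            n_empty = 0
            for t in range(stack.n_frames):
                rows, cols = region.membrane_pixels.get(t, fixed if fixed is not None else ((), ()))
                if len(rows) == 0:
                    n_empty += 1
                    continue
                vals[t] = float(np.mean(stack.pixels[t, c, rows, cols]))
            if n_empty:
                log.info(
                    "region %d channel %s: %d frames with empty membrane mask",
                    region.label, channel, n_empty,
                )
            traces.append(
                IntensityTrace(
                    roi_id=str(region.label),
                    channel=channel,
                    time_min=np.asarray(stack.time_stamps_min),
                    raw=vals,
                )
            )
    return traces


def estimate_baseline(
    stack: ImageStack, background_rois: RoiSet, channel: str
) -> BaselineProfile:
    """Average the temporal profiles of GUV-free regions.

    Each background ROI contributes one per-frame mean profile; the
    profiles are averaged unweighted by ROI area.
    """
    rois = background_rois.of_kind("background")
    if not rois:
        raise ValueError("baseline required: no background ROIs given")
    c = stack.channel_index(channel)
    profiles = []
    for roi in rois:
        rows, cols = roi.pixel_coords(stack.frame_shape)
        if len(rows) == 0:
            raise ValueError(f"background ROI {roi.roi_id!r} contains no pixels")
        profiles.append(stack.pixels[:, c, rows, cols].mean(axis=1))
    values = np.mean(profiles, axis=0)
    log.info("baseline from %d background regions, channel %s", len(rois), channel)
    return BaselineProfile(
        time_min=np.asarray(stack.time_stamps_min),
        values=values,
        n_regions=len(rois),
    )


def subtract_baseline(
    trace: IntensityTrace, baseline: BaselineProfile
) -> IntensityTrace:
    """Per-time-point baseline subtraction; negatives are preserved."""
    if trace.time_min.shape != baseline.time_min.shape or not np.allclose(
        trace.time_min, baseline.time_min
    ):
        raise ValueError("trace and baseline time grids differ")
    return IntensityTrace(
        roi_id=trace.roi_id,
        channel=trace.channel,
        time_min=trace.time_min,
        raw=trace.raw,
        corrected=trace.raw - baseline.values,
        baseline=baseline.values.copy(),
    )
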