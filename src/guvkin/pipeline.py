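"""End-to-end movie analysis: segment -> quantify -> rates.

Ties the stage modules together the way the CLI and the parameter
recovery studies use them: per-frame segmentation of both channels,
GUV labelling on a reference frame (vesicles are immobilized, so
regions are frame-fixed), deterministic placement of GUV-free
background regions, baseline-corrected reporter traces and per-GUV
initial rates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.ndimage import binary_dilation, distance_transform_edt

from .config import PipelineConfig
from .io import (
    GUVS_COLUMNS,
    ImageStack,
    RATES_COLUMNS,
    Roi,
    RoiSet,
    TRACES_COLUMNS,
    validate_traces_table,
)
from .kinetics import InitialRate, initial_rate
from .quantify import (
    BaselineProfile,
    IntensityTrace,
    estimate_baseline,
    measure_traces,
    subtract_baseline,
)
from .segment import (
    GUVRegion,
    default_sigmas,
    extract_membrane,
    label_guvs,
    membrane_pixels_near,
    segment_channel,
    union_masks,
)

log = logging.getLogger("guvkin")


@dataclass
class MovieAnalysis:
    regions: List[GUVRegion]
    traces: List[IntensityTrace]
    baseline: BaselineProfile
    rates: List[InitialRate]
    background_rois: RoiSet

    def traces_frame(self) -> pd.DataFrame:
        rows = []
        for tr in self.traces:
            base = tr.baseline if tr.baseline is not None else np.zeros_like(tr.raw)
            corr = tr.corrected if tr.corrected is not None else tr.raw - base
            for i, t in enumerate(tr.time_min):
                rows.append(
                    {
                        "roi_id": tr.roi_id, "channel": tr.channel,
                        "time_min": t, "raw": tr.raw[i],
                        "baseline": base[i], "corrected": corr[i],
                    }
                )
        return validate_traces_table(pd.DataFrame(rows, columns=TRACES_COLUMNS))

    def guvs_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "roi_id": str(r.label),
                    "centroid_y": r.centroid[0], "centroid_x": r.centroid[1],
                    "radius_um": r.radius_um, "circularity": r.circularity,
                }
                for r in self.regions
            ],
            columns=GUVS_COLUMNS,
        )

    def rates_frame(self) -> pd.DataFrame:
        rows = []
        time = self.baseline.time_min
        for r in self.rates:
            rows.append(
                {
                    "roi_id": r.roi_id,
                    "window_start_min": time[r.window[0]],
                    "window_end_min": time[r.window[1]],
                    "slope_au_per_min": r.slope,
                    "intercept": r.intercept,
                    "r2": r.r_squared,
                    "se": r.slope_se,
                    "low_confidence": r.low_confidence,
                }
            )
        return pd.DataFrame(rows, columns=RATES_COLUMNS)


def segment_movie(
    stack: ImageStack, config: Optional[PipelineConfig] = None
) -> Tuple[List[GUVRegion], np.ndarray, np.ndarray]:
    """Segment every frame and label GUVs on the reference frame.

    Returns ``(regions, membrane_masks, filled_masks)`` where the mask
    arrays have shape (T, Y, X).  Regions carry per-frame membrane
    pixel sets restricted to a neighbourhood of their frame-fixed
    centroid.
    """
    cfg = config or PipelineConfig()
    seg = cfg.segmentation
    ss, sl = default_sigmas(
        seg.thickness_um, stack.pixel_size_um, seg.sigma_small_px, seg.sigma_large_ratio
    )
    log.info("segmenting %d frames (DoG sigmas %.2f/%.2f px, threshold %s)",
             stack.n_frames, ss, sl, seg.threshold)
    ref = seg.reference_frame
    if not 0 <= ref < stack.n_frames:
        raise ValueError(f"reference frame {ref} outside movie of {stack.n_frames} frames")

    membrane_masks = np.zeros((stack.n_frames,) + tuple(stack.frame_shape), bool)
    filled_masks = np.zeros_like(membrane_masks)
    frames = range(stack.n_frames) if seg.per_frame else [ref]
    for t in frames:
        channel_masks = [
            segment_channel(
                stack.pixels[t, c], ss, sl, seg.threshold,
                noise_floor_sigmas=seg.noise_floor_sigmas,
            )
            for c in range(stack.n_channels)
        ]
        union = channel_masks[0]
        for m in channel_masks[1:]:
            union = union_masks(union, m)
        membrane_masks[t], filled_masks[t] = extract_membrane(
            union, seg.thickness_um, stack.pixel_size_um,
            smooth_radius_px=seg.smooth_radius_px,
            smooth_operator=seg.smooth_operator,
            despeckle_min_px=seg.despeckle_min_px,
        )
    if not seg.per_frame:
        membrane_masks[:] = membrane_masks[ref]
        filled_masks[:] = filled_masks[ref]

    regions = label_guvs(
        filled_masks[ref],
        membrane_masks[ref],
        stack.pixel_size_um,
        min_radius_um=seg.min_radius_um,
        min_circularity=seg.min_circularity,
        neighborhood_factor=seg.neighborhood_factor,
        frame=ref,
    )
    for region in regions:
        for t in range(stack.n_frames):
            region.membrane_pixels[t] = membrane_pixels_near(
                membrane_masks[t],
                region.centroid,
                region.radius_px * seg.neighborhood_factor,
            )
    log.info("labelled %d GUVs on frame %d", len(regions), ref)
    return regions, membrane_masks, filled_masks


def auto_background_rois(
    filled_masks: np.ndarray,
    pixel_size_um: float,
    n_rois: int = 10,
    roi_radius_um: float = 1.5,
    margin_um: float = 1.0,
) -> RoiSet:
    """Place GUV-free disc ROIs deterministically (no RNG).

    Candidate centers on a regular grid are ranked by their distance to
    the nearest segmented GUV (union over frames, dilated by a safety
    margin) and greedily accepted farthest-first subject to mutual
    separation.  Raises if fewer than ``n_rois`` clear positions exist.
    """
    occupied = filled_masks.any(axis=0) if filled_masks.ndim == 3 else filled_masks
    r_px = roi_radius_um / pixel_size_um
    margin_px = max(1, round(margin_um / pixel_size_um))
    forbidden = binary_dilation(occupied, iterations=margin_px)
    dist = distance_transform_edt(~forbidden)
    h, w = occupied.shape
    step = max(2, int(round(r_px)))
    candidates = [
        (float(dist[y, x]), y, x)
        for y in range(int(np.ceil(r_px)), h - int(np.ceil(r_px)), step)
        for x in range(int(np.ceil(r_px)), w - int(np.ceil(r_px)), step)
        if dist[y, x] > r_px
    ]
    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    chosen: List[Tuple[int, int]] = []
    min_sep2 = (2 * r_px + 2) ** 2
    for _, y, x in candidates:
        if all((y - cy) ** 2 + (x - cx) ** 2 >= min_sep2 for cy, cx in chosen):
            chosen.append((y, x))
            if len(chosen) == n_rois:
                break
    if len(chosen) < n_rois:
        raise RuntimeError(
            f"only {len(chosen)} GUV-free background positions found, need {n_rois}"
        )
    return RoiSet(
        [
            Roi(f"bg{i:02d}", "background", "disc", (float(y), float(x), r_px))
            for i, (y, x) in enumerate(chosen)
        ]
    )


def analyze_movie(
    stack: ImageStack,
    config: Optional[PipelineConfig] = None,
    background_rois: Optional[RoiSet] = None,
    regions: Optional[Sequence[GUVRegion]] = None,
) -> MovieAnalysis:
    """Full pipeline: segmentation, traces, baseline, initial rates.

    ``background_rois`` and ``regions`` may be supplied (e.g. manual
    ROIs or simulator ground truth); otherwise they are derived from
    the segmentation.  Only the reporter channel is baseline-corrected;
    the membrane-dye channel is reported raw.
    """
    cfg = config or PipelineConfig()
    filled_masks = None
    if regions is None:
        regions, _, filled_masks = segment_movie(stack, cfg)
    regions = list(regions)
    if background_rois is None:
        if filled_masks is None:
            _, _, filled_masks = segment_movie(stack, cfg)
        background_rois = auto_background_rois(
            filled_masks,
            stack.pixel_size_um,
            n_rois=cfg.background.n_rois,
            roi_radius_um=cfg.background.roi_radius_um,
            margin_um=cfg.background.margin_um,
        )
    traces = measure_traces(stack, regions)
    baseline = estimate_baseline(stack, background_rois, cfg.reporter_channel)
    out_traces: List[IntensityTrace] = []
    corrected: Dict[str, IntensityTrace] = {}
    for tr in traces:
        if tr.channel == cfg.reporter_channel:
            tr = subtract_baseline(tr, baseline)
            corrected[tr.roi_id] = tr
        out_traces.append(tr)
    rates = []
    for region in regions:
        tr = corrected.get(str(region.label))
        if tr is None:
            continue
        rates.append(
            initial_rate(
                tr,
                window=cfg.window.manual,
                min_points=cfg.window.min_points,
                r2_min=cfg.window.r2_min,
            )
        )
    return MovieAnalysis(
        regions=regions,
        traces=out_traces,
        baseline=baseline,
        rates=rates,
        background_rois=background_rois,
    )


def recover_condition_rates(
    scenes: Dict[str, "SimulationScene"],  # noqa: F821 - forward ref
    config: Optional[PipelineConfig] = None,
) -> Dict[str, List[float]]:
    """Simulate each condition's movie and recover per-GUV rates."""
    from .simulate import simulate_timelapse

    out: Dict[str, List[float]] = {}
    for cond, scene in scenes.items():
        stack, _ = simulate_timelapse(scene)
        analysis = analyze_movie(stack, config)
        out[cond] = [r.slope for r in analysis.rates]
    return out


def pooled_fixture_rates(
    fixture_name: str,
    seeds: Sequence[int],
    config: Optional[PipelineConfig] = None,
    low_noise: bool = False,
    conditions: Optional[Sequence[str]] = None,
) -> Dict[str, List[float]]:
    """Pool recovered per-GUV rates over replicate simulation seeds."""
    from .simulate import fixture

    pooled: Dict[str, List[float]] = {}
    for seed in seeds:
        scenes = fixture(fixture_name, seed=seed, low_noise=low_noise)
        if conditions is not None:
            scenes = {c: scenes[c] for c in conditions}
        for cond, rates in recover_condition_rates(scenes, config).items():
            pooled.setdefault(cond, []).extend(rates)
    return pooled
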