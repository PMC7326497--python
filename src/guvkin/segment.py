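"""Membrane segmentation of GUV ring cross-sections.

Pipeline per frame and channel: band-pass the image with a difference
of Gaussians, threshold the response (Otsu by default), take the union
of the per-channel masks, smooth by morphological opening, fill the
ring interiors, and carve a contour band of calibrated thickness with
an internal morphological gradient (mask minus its erosion).  The
membrane is the intersection of that band with the original
segmentation, which discards spurious signal inside the GUVs.

This module is deterministic: no randomness anywhere.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
from scipy.ndimage import (
    binary_closing,
    binary_erosion,
    binary_fill_holes,
    binary_opening,
    gaussian_filter,
)
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import disk, remove_small_objects

log = logging.getLogger("guvkin")


def dog_response(
    frame: np.ndarray, sigma_small_px: float, sigma_large_px: float
) -> np.ndarray:
    """Difference-of-Gaussians band-pass response (mirror boundaries).

    Zero-mean on constant inputs; enhances ring-like structures whose
    width is near ``sigma_small_px``.
    """
    if not 0 < sigma_small_px < sigma_large_px:
        raise ValueError(
            f"need 0 < sigma_small < sigma_large, got {sigma_small_px}, {sigma_large_px}"
        )
    frame = np.asarray(frame, float)
    return gaussian_filter(frame, sigma_small_px, mode="mirror") - gaussian_filter(
        frame, sigma_large_px, mode="mirror"
    )


def segment_channel(
    frame: np.ndarray,
    sigma_small_px: float,
    sigma_large_px: float,
    threshold: Union[str, float] = "otsu",
    noise_floor_sigmas: float = 3.0,
) -> np.ndarray:
    """Threshold the DoG response of one channel into a binary mask.

    ``threshold="otsu"`` picks the threshold from the response
    histogram; a float is used as a fixed threshold.  The Otsu
    threshold is floored at ``noise_floor_sigmas`` robust standard
    deviations (1.4826 MAD) of the response, so a frame without ring
    structure — e.g. the reporter channel during the lag phase, where
    the response is pure detection noise that Otsu would happily split
    in half — yields a (near-)empty mask instead of flooding the
    segmentation.  A constant response yields an empty mask with a
    logged warning.
    """
    resp = dog_response(frame, sigma_small_px, sigma_large_px)
    if np.ptp(resp) < 1e-12:
        log.warning("constant DoG response; returning empty mask")
        return np.zeros(frame.shape, bool)
    if threshold == "otsu":
        noise_sd = 1.4826 * float(np.median(np.abs(resp - np.median(resp))))
        theta = max(threshold_otsu(resp), noise_floor_sigmas * noise_sd)
    else:
        theta = float(threshold)
    return resp > theta


def union_masks(mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Elementwise OR of the two channel masks."""
    if mask_a.shape != mask_b.shape:
        raise ValueError(f"mask shapes differ: {mask_a.shape} vs {mask_b.shape}")
    return mask_a | mask_b


def extract_membrane(
    union_mask: np.ndarray,
    thickness_um: float,
    pixel_size_um: float,
    smooth_radius_px: int = 1,
    smooth_operator: str = "close",
    despeckle_min_px: int = 0,
) -> Tuple[np.ndarray, np.ndarray]:
    """Carve the calibrated-thickness membrane band from a ring mask.

    Steps: S = smooth(union_mask, disc(smooth_radius)), optionally
    dropping connected components below ``despeckle_min_px`` pixels;
    F = fill(S); G = F minus erosion(F, disc(k)) with
    k = round(thickness/pixel) clamped to >= 1 — the internal
    morphological gradient, a contour band of calibrated thickness;
    membrane = G AND union_mask, which discards spurious signal inside
    the GUVs.  Returns ``(membrane_mask, filled_mask)``.

    The smoothing operator is a binary closing by default: at typical
    pixel sizes the thresholded rings are only ~2 px wide, and an
    opening severs them (so their interiors never fill), whereas a
    closing repairs small gaps and preserves ring topology.
    ``smooth_operator`` accepts "close", "open" or "none".
    """
    if not thickness_um > 0:
        raise ValueError("thickness_um must be > 0")
    union_mask = np.asarray(union_mask, bool)
    k = round(thickness_um / pixel_size_um)
    if k < 1:
        log.warning("membrane thickness below one pixel; clamping erosion radius to 1")
        k = 1
    if smooth_radius_px > 0 and smooth_operator != "none":
        if smooth_operator == "close":
            smoothed = binary_closing(union_mask, structure=disk(smooth_radius_px))
        elif smooth_operator == "open":
            smoothed = binary_opening(union_mask, structure=disk(smooth_radius_px))
        else:
            raise ValueError(f"unknown smooth_operator {smooth_operator!r}")
    else:
        smoothed = union_mask
    if despeckle_min_px > 0:
        smoothed = remove_small_objects(smoothed, max_size=despeckle_min_px - 1)
    filled = binary_fill_holes(smoothed)
    gradient = filled & ~binary_erosion(filled, structure=disk(k))
    membrane = gradient & union_mask
    return membrane, filled


@dataclass
class GUVRegion:
    """One labelled vesicle cross-section.

    ``radius_px`` is the equivalent radius sqrt(area/pi) of the filled
    component; ``membrane_pixels`` maps frame index -> (rows, cols) of
    the membrane band near this GUV at that frame.
    """

    label: int
    centroid: Tuple[float, float]  # (row, col) px
    radius_px: float
    radius_um: float
    circularity: float
    membrane_pixels: Dict[int, Tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict, repr=False
    )

    @property
    def curvature_per_um(self) -> float:
        return 1.0 / self.radius_um


def label_guvs(
    filled_mask: np.ndarray,
    membrane_mask: np.ndarray,
    pixel_size_um: float,
    min_radius_um: float = 1.0,
    min_circularity: float = 0.7,
    neighborhood_factor: float = 1.5,
    frame: int = 0,
) -> List[GUVRegion]:
    """Label 8-connected filled components as candidate GUVs.

    Components smaller than ``min_radius_um`` or less circular than
    ``min_circularity`` (circularity = 4 pi area / perimeter^2) are
    discarded and logged — the automated analogue of manual ROI
    curation for touching or misshapen vesicles.  Each kept region's
    membrane pixels are the membrane mask within
    ``neighborhood_factor * radius`` of its centroid.
    """
    if filled_mask.shape != membrane_mask.shape:
        raise ValueError("filled and membrane masks must share a shape")
    labels = cc_label(filled_mask, connectivity=2)
    regions: List[GUVRegion] = []
    n_discarded = 0
    for prop in regionprops(labels):
        radius_px = math.sqrt(prop.area / math.pi)
        radius_um = radius_px * pixel_size_um
        perimeter = prop.perimeter
        circularity = (
            4.0 * math.pi * prop.area / perimeter**2 if perimeter > 0 else 0.0
        )
        if radius_um < min_radius_um or circularity < min_circularity:
            n_discarded += 1
            continue
        region = GUVRegion(
            label=prop.label,
            centroid=tuple(prop.centroid),
            radius_px=radius_px,
            radius_um=radius_um,
            circularity=circularity,
        )
        region.membrane_pixels[frame] = membrane_pixels_near(
            membrane_mask, region.centroid, radius_px * neighborhood_factor
        )
        regions.append(region)
    if n_discarded:
        log.info("discarded %d components (size/circularity filters)", n_discarded)
    return regions


def membrane_pixels_near(
    membrane_mask: np.ndarray, centroid: Tuple[float, float], radius_px: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Membrane-mask pixels within ``radius_px`` of ``centroid``."""
    rows, cols = np.nonzero(membrane_mask)
    keep = (rows - centroid[0]) ** 2 + (cols - centroid[1]) ** 2 <= radius_px**2
    return rows[keep], cols[keep]


def fit_circle(points: np.ndarray) -> Tuple[Tuple[float, float], float]:
    """Algebraic (Kasa) least-squares circle through (row, col) points.

    Exact for points lying on a circle.  Raises on fewer than three
    points or collinear input.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (row, col) points")
    y, x = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * y, 2 * x, np.ones(len(pts))])
    b = y**2 + x**2
    # rank-deficient normal system <=> collinear points
    if np.linalg.matrix_rank(A) < 3:
        raise ValueError("points are collinear; no unique circle")
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cy, cx, c = sol
    r2 = c + cy**2 + cx**2
    if r2 <= 0:
        raise ValueError("degenerate circle fit")
    return (float(cy), float(cx)), float(math.sqrt(r2))


def max_project(zstack: Union[np.ndarray, List[np.ndarray]]) -> np.ndarray:
    """Maximum-intensity projection of a list of equally shaped slices."""
    slices = [np.asarray(s) for s in zstack]
    if len(slices) == 0:
        raise ValueError("need at least one slice")
    shape = slices[0].shape
    if any(s.shape != shape for s in slices):
        raise ValueError("slices must share a shape")
    return np.max(np.stack(slices), axis=0)


def default_sigmas(
    thickness_um: float, pixel_size_um: float, sigma_small_px: Optional[float] = None,
    sigma_large_ratio: float = 3.0,
) -> Tuple[float, float]:
    """Default DoG scales: half the membrane thickness, and 3x that."""
    if sigma_small_px is None:
        sigma_small_px = 0.5 * thickness_um / pixel_size_um
    return sigma_small_px, sigma_small_px * sigma_large_ratio
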