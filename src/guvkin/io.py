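"""Image stacks, ROI definitions and results tables.

Images are TIFF / OME-TIFF with axes normalized to (T, C, Y, X).
ROIs are a minimal structured text format (one ROI per line, see
:func:`read_rois`).  Tables are plain CSV with documented headers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import tifffile

from .config import PipelineConfig

log = logging.getLogger("guvkin")

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Unreadable or ambiguous image / ROI file."""


# ---------------------------------------------------------------------------
# ImageStack


@dataclass
class ImageStack:
    """A (T, C, Y, X) intensity array with acquisition metadata.

    ``pixels`` are arbitrary units, non-negative on input;
    ``time_stamps_min`` are minutes since enzyme addition, strictly
    increasing; ``pixel_size_um`` is micrometres per pixel.
    """

    pixels: np.ndarray
    time_stamps_min: List[float]
    channel_names: List[str]
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 4:
            raise ValueError(f"pixels must be 4-D (T,C,Y,X), got {self.pixels.ndim}-D")
        t, c = self.pixels.shape[:2]
        self.time_stamps_min = [float(x) for x in self.time_stamps_min]
        self.channel_names = [str(x) for x in self.channel_names]
        if len(self.time_stamps_min) != t:
            raise ValueError(
                f"{len(self.time_stamps_min)} time stamps for {t} frames"
            )
        if len(self.channel_names) != c:
            raise ValueError(
                f"{len(self.channel_names)} channel names for {c} channels"
            )
        if np.any(np.diff(self.time_stamps_min) <= 0):
            raise ValueError("time stamps must be strictly increasing")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")

    @property
    def n_frames(self) -> int:
        return self.pixels.shape[0]

    @property
    def n_channels(self) -> int:
        return self.pixels.shape[1]

    @property
    def frame_shape(self) -> Tuple[int, int]:
        return self.pixels.shape[2:]

    def channel_index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(
                f"channel {name!r} not in {self.channel_names}"
            ) from None


def read_stack(
    path: PathLike,
    channel_names: Optional[Sequence[str]] = None,
    config: Optional[PipelineConfig] = None,
) -> ImageStack:
    """Read a TIFF/OME-TIFF stack, normalizing axes to (T, C, Y, X).

    Metadata missing from the file (time stamps, pixel size, channel
    names) is resolved from ``config`` (defaults if None) with a logged
    warning; axis orders that cannot be resolved raise
    :class:`FormatError` rather than being guessed silently.
    """
    cfg = config or PipelineConfig()
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        tf = tifffile.TiffFile(str(path))
    except Exception as exc:  # pragma: no cover - tifffile message varies
        raise FormatError(f"unreadable TIFF {path}: {exc}") from exc
    with tf:
        series = tf.series[0]
        axes = series.axes.upper().replace("S", "C").replace("Q", "T")
        data = series.asarray()
        if any(a not in "TCZYX" for a in axes):
            raise FormatError(f"cannot interpret axes {series.axes!r} in {path}")
        # insert missing singleton axes, drop Z by treating it as an error
        if "Z" in axes:
            if data.shape[axes.index("Z")] != 1:
                raise FormatError(
                    f"{path} has a Z dimension; max-project before analysis"
                )
            data = np.squeeze(data, axis=axes.index("Z"))
            axes = axes.replace("Z", "")
        for missing in set("TC") - set(axes):
            data = data[np.newaxis]
            axes = missing + axes
        if sorted(axes) != ["C", "T", "X", "Y"]:
            raise FormatError(f"cannot normalize axes {series.axes!r} in {path}")
        data = np.moveaxis(
            data, [axes.index(a) for a in "TCYX"], [0, 1, 2, 3]
        )

        names: Optional[List[str]] = None
        times: Optional[List[float]] = None
        px_um: Optional[float] = None
        if tf.is_ome and tf.ome_metadata:
            meta = tifffile.xml2dict(tf.ome_metadata)
            image = meta.get("OME", {}).get("Image", {})
            if isinstance(image, list):
                image = image[0]
            pixels_md = image.get("Pixels", {})
            px_um = pixels_md.get("PhysicalSizeX") or None
            chans = pixels_md.get("Channel", [])
            if isinstance(chans, dict):
                chans = [chans]
            got = [c.get("Name") for c in chans]
            if len(got) == data.shape[1] and all(got):
                names = [str(n) for n in got]
            planes = pixels_md.get("Plane", [])
            if isinstance(planes, dict):
                planes = [planes]
            by_t = {}
            for p in planes:
                if "DeltaT" in p and "TheT" in p:
                    by_t.setdefault(int(p["TheT"]), float(p["DeltaT"]))
            if len(by_t) == data.shape[0]:
                times = [by_t[t] / 60.0 for t in range(data.shape[0])]

    if channel_names is not None:
        if len(channel_names) != data.shape[1]:
            raise FormatError(
                f"{len(channel_names)} channel names for {data.shape[1]} channels"
            )
        names = [str(n) for n in channel_names]
    if names is None:
        names = list(cfg.channel_names)[: data.shape[1]]
        if len(names) < data.shape[1]:
            names += [f"ch{i}" for i in range(len(names), data.shape[1])]
        log.warning("%s: channel names missing, using %s from config", path, names)
    if times is None:
        times = [i * cfg.frame_interval_min for i in range(data.shape[0])]
        log.warning(
            "%s: time stamps missing, using %.3g min frame interval from config",
            path,
            cfg.frame_interval_min,
        )
    if px_um is None:
        px_um = cfg.pixel_size_um
        log.warning("%s: pixel size missing, using %.3g um from config", path, px_um)

    stack = ImageStack(data, times, names, float(px_um))
    log.info(
        "read %s: T=%d C=%d YX=%s dtype=%s",
        path, stack.n_frames, stack.n_channels, stack.frame_shape, data.dtype,
    )
    return stack


def write_stack(stack: ImageStack, path: PathLike) -> Path:
    """Write an OME-TIFF with axes TCYX and embedded metadata.

    Integer data round-trips bit-exactly through :func:`read_stack`;
    float data is stored as float32.
    """
    path = Path(path)
    data = stack.pixels
    if data.dtype.kind == "f" and data.dtype != np.float32:
        data = data.astype(np.float32)
    seconds = [t * 60.0 for t in stack.time_stamps_min]
    # one plane record per (T, C) page, in page order
    delta_t = [s for s in seconds for _ in range(stack.n_channels)]
    tifffile.imwrite(
        str(path),
        data,
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "TCYX",
            "Channel": {"Name": list(stack.channel_names)},
            "PhysicalSizeX": stack.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeY": stack.pixel_size_um,
            "PhysicalSizeYUnit": "µm",
            "Plane": {"DeltaT": delta_t},
        },
    )
    log.info("wrote %s: T=%d C=%d", path, stack.n_frames, stack.n_channels)
    return path


# ---------------------------------------------------------------------------
# ROIs


@dataclass
class Roi:
    """One frame-fixed region: a disc or polygon in pixel coordinates."""

    roi_id: str
    kind: str  # "membrane" or "background"
    shape: str  # "disc" or "polygon"
    #: disc: (cy, cx, radius); polygon: [(y0, x0), (y1, x1), ...]
    params: tuple

    def pixel_coords(self, image_shape: Tuple[int, int]) -> Tuple[np.ndarray, np.ndarray]:
        """(rows, cols) of the pixels inside the ROI."""
        h, w = image_shape
        if self.shape == "disc":
            cy, cx, r = self.params
            yy, xx = np.ogrid[:h, :w]
            mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        else:
            from skimage.draw import polygon as _polygon

            ys = [p[0] for p in self.params]
            xs = [p[1] for p in self.params]
            rr, cc = _polygon(ys, xs, shape=(h, w))
            mask = np.zeros((h, w), bool)
            mask[rr, cc] = True
        return np.nonzero(mask)


@dataclass
class RoiSet:
    rois: List[Roi] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.roi_id for r in self.rois]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate ROI ids: {sorted(dupes)}")

    def of_kind(self, kind: str) -> List[Roi]:
        return [r for r in self.rois if r.kind == kind]

    def __len__(self) -> int:
        return len(self.rois)


def read_rois(path: PathLike, image_shape: Tuple[int, int]) -> RoiSet:
    """Parse the structured-text ROI dialect and validate geometry.

    Format, one ROI per line (blank lines and ``#`` comments ignored)::

        <id> <membrane|background> disc <cy> <cx> <radius>
        <id> <membrane|background> polygon <y0> <x0> <y1> <x1> ...

    Coordinates are 0-based pixels.  Vertices or disc extents outside
    ``image_shape`` raise a validation error naming the ROI id.
    """
    h, w = image_shape
    rois: List[Roi] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 4:
                raise FormatError(f"{path}:{lineno}: malformed ROI line {line!r}")
            roi_id, kind, shape = parts[0], parts[1], parts[2]
            if kind not in ("membrane", "background"):
                raise FormatError(f"{path}:{lineno}: unknown ROI kind {kind!r}")
            nums = [float(x) for x in parts[3:]]
            if shape == "disc":
                if len(nums) != 3:
                    raise FormatError(f"{path}:{lineno}: disc needs cy cx r")
                cy, cx, r = nums
                if r <= 0:
                    raise FormatError(f"ROI {roi_id!r}: radius must be > 0")
                if not (0 <= cy - r and cy + r <= h - 1 and 0 <= cx - r and cx + r <= w - 1):
                    raise FormatError(f"ROI {roi_id!r}: disc outside image bounds")
                rois.append(Roi(roi_id, kind, "disc", (cy, cx, r)))
            elif shape == "polygon":
                if len(nums) < 6 or len(nums) % 2:
                    raise FormatError(f"{path}:{lineno}: polygon needs >=3 (y, x) pairs")
                pts = list(zip(nums[0::2], nums[1::2]))
                for y, x in pts:
                    if not (0 <= y <= h - 1 and 0 <= x <= w - 1):
                        raise FormatError(f"ROI {roi_id!r}: vertex ({y}, {x}) outside image bounds")
                rois.append(Roi(roi_id, kind, "polygon", tuple(pts)))
            else:
                raise FormatError(f"{path}:{lineno}: unknown ROI shape {shape!r}")
    rs = RoiSet(rois)
    log.info("read %d ROIs from %s (%d membrane, %d background)",
             len(rs), path, len(rs.of_kind("membrane")), len(rs.of_kind("background")))
    return rs


def write_rois(rois: RoiSet, path: PathLike) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for r in rois.rois:
            if r.shape == "disc":
                cy, cx, rad = r.params
                fh.write(f"{r.roi_id} {r.kind} disc {cy:g} {cx:g} {rad:g}\n")
            else:
                coords = " ".join(f"{y:g} {x:g}" for y, x in r.params)
                fh.write(f"{r.roi_id} {r.kind} polygon {coords}\n")
    return path


# ---------------------------------------------------------------------------
# Results tables

TRACES_COLUMNS = ["roi_id", "channel", "time_min", "raw", "baseline", "corrected"]
GUVS_COLUMNS = ["roi_id", "centroid_y", "centroid_x", "radius_um", "circularity"]
RATES_COLUMNS = [
    "roi_id", "window_start_min", "window_end_min",
    "slope_au_per_min", "intercept", "r2", "se", "low_confidence",
]
CURVATURE_COLUMNS = ["condition", "slope", "intercept", "se", "p", "n"]


def validate_traces_table(df: pd.DataFrame, rtol: float = 1e-9) -> pd.DataFrame:
    """Check corrected == raw - baseline (conservation) on finite rows."""
    missing = [c for c in TRACES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"traces table missing columns {missing}")
    ok = df[["raw", "baseline", "corrected"]].notna().all(axis=1)
    resid = df.loc[ok, "raw"] - df.loc[ok, "baseline"] - df.loc[ok, "corrected"]
    scale = np.maximum(1.0, df.loc[ok, "raw"].abs())
    if not np.all(np.abs(resid) <= rtol * scale):
        raise ValueError("traces table violates corrected = raw - baseline")
    return df


def write_table(df: pd.DataFrame, path: PathLike) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    log.info("wrote %s (%d rows)", path, len(df))
    return path


def read_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path)
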