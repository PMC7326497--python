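"""Membrane curvature versus activity.

For each GUV the curvature of its equatorial section is 1/R (per um);
plotting end-point reporter intensity against curvature and fitting a
line tests whether smaller (more highly curved) vesicles accumulate
more product — a positive slope indicates curvature-activated kinase
activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .kinetics import fit_line
from .quantify import IntensityTrace
from .segment import GUVRegion

log = logging.getLogger("guvkin")


def curvature_table(
    regions: Sequence[GUVRegion],
    traces: Sequence[IntensityTrace],
    t_end: float = 60.0,
    channel: str = "reporter",
) -> List[Tuple[float, float]]:
    """(1/radius_um, intensity at the frame nearest ``t_end``) pairs.

    Regions whose trace is missing at the end point are excluded and
    logged.  ``t_end`` outside the acquisition range is an error.
    """
    by_id = {tr.roi_id: tr for tr in traces if tr.channel == channel}
    pairs: List[Tuple[float, float]] = []
    n_excluded = 0
    for region in regions:
        tr = by_id.get(str(region.label))
        if tr is None:
            n_excluded += 1
            continue
        t = tr.time_min
        if not (t.min() <= t_end <= t.max()):
            raise ValueError(
                f"t_end {t_end} min outside acquisition range [{t.min()}, {t.max()}]"
            )
        i = int(np.argmin(np.abs(t - t_end)))
        v = tr.values[i]
        if np.isnan(v):
            n_excluded += 1
            continue
        pairs.append((region.curvature_per_um, float(v)))
    if n_excluded:
        log.info("curvature table: excluded %d regions without end-point data", n_excluded)
    return pairs


@dataclass
class CurvatureFit:
    condition: str
    n: int
    slope: float  # AU*um
    intercept: float
    slope_se: float
    p_value: float  # two-sided, slope != 0


def fit_curvature(
    table: Sequence[Tuple[float, float]], condition: str = ""
) -> CurvatureFit:
    """OLS of intensity on curvature with a t-test on the slope."""
    if len(table) < 3:
        raise ValueError("need at least 3 GUVs for a curvature fit")
    x = np.asarray([p[0] for p in table], float)
    y = np.asarray([p[1] for p in table], float)
    if np.unique(x).size < 2:
        raise ValueError("need at least 2 distinct curvatures")
    slope, intercept, r2, se = fit_line(x, y)
    n = len(x)
    if se > 0:
        tstat = slope / se
        p = float(2 * stats.t.sf(abs(tstat), df=n - 2))
    else:
        p = 0.0 if slope != 0 else 1.0
    return CurvatureFit(
        condition=condition, n=n, slope=slope, intercept=intercept,
        slope_se=se, p_value=p,
    )
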