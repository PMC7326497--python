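"""Initial rates, fold-changes and group comparisons.

The initial rate of reporter recruitment is the slope (AU/min) of an
ordinary least-squares line fitted to the linear region of the
baseline-corrected progress curve — after the lag phase, before the
plateau.  The linear region can be given manually (the procedure used
for the original measurements) or located automatically: among all
contiguous windows of at least ``min_points`` samples with
r^2 >= ``r2_min``, take the one with the largest slope (ties broken by
longer window, then earlier start).  If no window qualifies, the
steepest minimum-length window is returned flagged ``low_confidence``.

Conditions are compared as mean per-GUV rates (GUVs as replicates):
fold-change of group means, and a two-sided Welch t-test.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .quantify import IntensityTrace

log = logging.getLogger("guvkin")


def fit_line(
    times: Sequence[float], values: Sequence[float]
) -> Tuple[float, float, float, float]:
    """Ordinary least squares of values on times.

    Returns ``(slope, intercept, r_squared, slope_se)``.  r^2 is
    defined as 1 when both SS_tot and SS_res vanish (an exact constant
    fit); ``slope_se`` is NaN for n = 2 (no residual degrees of
    freedom).
    """
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    if t.shape != y.shape:
        raise ValueError("times and values lengths differ")
    if t.size < 2:
        raise ValueError("need at least 2 points")
    if np.ptp(t) == 0:
        raise ValueError("all time points are equal")
    tm, ym = t.mean(), y.mean()
    sxx = float(np.sum((t - tm) ** 2))
    sxy = float(np.sum((t - tm) * (y - ym)))
    slope = sxy / sxx
    intercept = ym - slope * tm
    resid = y - (intercept + slope * t)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - ym) ** 2))
    if ss_tot > 0:
        r_squared = 1.0 - ss_res / ss_tot
    else:
        r_squared = 1.0 if ss_res <= 1e-24 else 0.0
    r_squared = min(max(r_squared, 0.0), 1.0)
    n = t.size
    slope_se = math.sqrt(ss_res / (n - 2) / sxx) if n > 2 else float("nan")
    return slope, intercept, r_squared, slope_se


@dataclass
class Window:
    """An inclusive index window into a trace."""

    start: int
    end: int
    slope: float
    r_squared: float
    slope_se: float = 0.0
    low_confidence: bool = False

    @property
    def n_points(self) -> int:
        return self.end - self.start + 1


def find_linear_window(
    trace: IntensityTrace,
    min_points: int = 14,
    r2_min: float = 0.95,
) -> Window:
    """Locate the linear region of a corrected progress curve.

    Scans every contiguous window of at least ``min_points`` non-missing
    samples.  Among windows with r^2 >= ``r2_min`` the steepest wins;
    slopes within one standard error of the steepest count as tied, and
    ties go to the longer window, then the earlier start.  With no
    qualifying window the globally steepest minimum-length window is
    returned with ``low_confidence=True``.

    The one-SE tie band matters on noisy traces: picking the literal
    argmax slope over many overlapping windows is upward-biased by
    roughly the slope SE of the shortest window, which would inflate
    the rates of weakly active conditions (and hence deflate
    fold-changes against them).  On noiseless traces the SE of an
    exactly linear window is 0 and the rule reduces to exact ties.
    """
    t = trace.time_min
    y = trace.values
    keep = ~np.isnan(y)
    if keep.sum() < len(y):
        log.info("trace %s: %d missing points excluded from window search",
                 trace.roi_id, int((~keep).sum()))
    idx = np.nonzero(keep)[0]
    t, y = t[keep], y[keep]
    n = len(t)
    if n < min_points:
        raise ValueError(f"trace has {n} usable points, need >= {min_points}")

    qualifying: List[Window] = []
    fallback: Optional[Window] = None
    for start in range(n - min_points + 1):
        for end in range(start + min_points - 1, n):
            slope, _, r2, se = fit_line(t[start : end + 1], y[start : end + 1])
            if math.isnan(se):
                se = 0.0
            w = Window(int(idx[start]), int(idx[end]), slope, r2, se)
            if end - start + 1 == min_points:
                if fallback is None or slope > fallback.slope:
                    fallback = w
            if r2 >= r2_min:
                qualifying.append(w)
    if qualifying:
        steepest = max(qualifying, key=lambda w: w.slope)
        tied = [w for w in qualifying if w.slope >= steepest.slope - steepest.slope_se]
        return max(tied, key=lambda w: (w.n_points, -w.start, w.slope))
    assert fallback is not None
    fallback.low_confidence = True
    return fallback


@dataclass
class InitialRate:
    roi_id: str
    window: Tuple[int, int]  # inclusive indices into the trace
    slope: float  # AU/min
    intercept: float
    r_squared: float
    slope_se: float
    n_points: int
    low_confidence: bool = False


def initial_rate(
    trace: IntensityTrace,
    window: Optional[Tuple[int, int]] = None,
    min_points: int = 14,
    r2_min: float = 0.95,
) -> InitialRate:
    """Initial rate of one trace, over a manual or automatic window."""
    low_confidence = False
    if window is None:
        w = find_linear_window(trace, min_points=min_points, r2_min=r2_min)
        window = (w.start, w.end)
        low_confidence = w.low_confidence
    start, end = window
    if not (0 <= start < end < len(trace.time_min)):
        raise ValueError(f"window {window} outside trace of length {len(trace.time_min)}")
    t = trace.time_min[start : end + 1]
    y = trace.values[start : end + 1]
    keep = ~np.isnan(y)
    slope, intercept, r2, se = fit_line(t[keep], y[keep])
    return InitialRate(
        roi_id=trace.roi_id,
        window=(start, end),
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        slope_se=se,
        n_points=int(keep.sum()),
        low_confidence=low_confidence,
    )


def fold_change(rates_a: Sequence[float], rates_b: Sequence[float]) -> float:
    """Ratio of group mean rates, mean(a) / mean(b)."""
    a = np.asarray(rates_a, float)
    b = np.asarray(rates_b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both rate lists must be non-empty")
    mb = b.mean()
    if mb <= 0:
        raise ZeroDivisionError(
            "no detectable activity in denominator (mean rate <= 0)"
        )
    return float(a.mean() / mb)


@dataclass
class RateComparison:
    label_a: str
    label_b: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int
    fold_change: Optional[float]
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    degenerate: bool = False


def compare_rates(
    rates_a: Sequence[float],
    rates_b: Sequence[float],
    label_a: str = "A",
    label_b: str = "B",
) -> RateComparison:
    """Two-sided Welch t-test between per-GUV rate groups.

    Reports group means, SD and SEM (both dispersion conventions are
    emitted), the fold-change of means when defined, and the Welch
    statistic with Welch-Satterthwaite degrees of freedom.  Two
    zero-variance groups with equal means give p = 1, flagged
    degenerate.
    """
    a = np.asarray(rates_a, float)
    b = np.asarray(rates_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need n >= 2 per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    fc = float(a.mean() / b.mean()) if b.mean() > 0 else None
    common = dict(
        label_a=label_a, label_b=label_b,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sd_a=float(math.sqrt(va)), sd_b=float(math.sqrt(vb)),
        sem_a=float(math.sqrt(va / a.size)), sem_b=float(math.sqrt(vb / b.size)),
        n_a=int(a.size), n_b=int(b.size), fold_change=fc,
    )
    if va == 0 and vb == 0:
        equal = a.mean() == b.mean()
        return RateComparison(
            **common,
            t_statistic=0.0 if equal else math.inf,
            degrees_of_freedom=float(a.size + b.size - 2),
            p_value=1.0 if equal else 0.0,
            degenerate=True,
        )
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / a.size, vb / b.size
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    return RateComparison(
        **common,
        t_statistic=float(res.statistic),
        degrees_of_freedom=float(df),
        p_value=float(res.pvalue),
    )
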