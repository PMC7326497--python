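"""Rate extraction: OLS, window search, fold-changes, Welch test."""

import math

import numpy as np
import pytest

from guvkin import compare_rates, find_linear_window, fit_line, fold_change, initial_rate
from guvkin.quantify import IntensityTrace

from conftest import regions_from_truth


def _trace(values, times=None):
    values = np.asarray(values, float)
    if times is None:
        times = np.arange(len(values), dtype=float)
    return IntensityTrace("1", "reporter", times, values)


class TestFitLine:
    def test_exact_line(self):
        slope, intercept, r2, se = fit_line([0, 1, 2, 3], [1, 3, 5, 7])
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert r2 == pytest.approx(1.0)
        assert se == pytest.approx(0.0, abs=1e-12)

    def test_constant_values(self):
        slope, _, r2, _ = fit_line([0, 1, 2], [4, 4, 4])
        assert slope == 0.0
        assert r2 == 1.0  # zero residual on zero variance

    def test_matches_normal_equations_oracle(self, rng):
        t = np.linspace(0, 10, 20)
        y = 3.2 * t - 1.7 + rng.normal(0, 0.5, 20)
        slope, intercept, r2, se = fit_line(t, y)
        # independent route: solve the normal equations directly
        X = np.column_stack([t, np.ones_like(t)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        exp_r2 = 1 - resid @ resid / np.sum((y - y.mean()) ** 2)
        exp_se = math.sqrt(
            (resid @ resid / 18) * np.linalg.inv(X.T @ X)[0, 0]
        )
        assert slope == pytest.approx(beta[0], abs=1e-9)
        assert intercept == pytest.approx(beta[1], abs=1e-9)
        assert r2 == pytest.approx(exp_r2, abs=1e-9)
        assert se == pytest.approx(exp_se, abs=1e-9)

    def test_slope_shift_and_scale_invariance(self, rng):
        t = np.arange(10.0)
        y = rng.normal(0, 1, 10)
        s0 = fit_line(t, y)[0]
        assert fit_line(t, y + 100)[0] == pytest.approx(s0, abs=1e-9)
        assert fit_line(t, 3 * y)[0] == pytest.approx(3 * s0, abs=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_line([1], [2])
        with pytest.raises(ValueError):
            fit_line([2, 2, 2], [1, 2, 3])


def enumerate_windows_oracle(times, values, min_points, r2_min):
    """Independent re-implementation of the window-selection rule."""
    n = len(values)
    wins = []
    for a in range(n):
        for b in range(a + min_points - 1, n):
            s, _, r2, se = fit_line(times[a : b + 1], values[a : b + 1])
            wins.append((a, b, s, r2, 0.0 if math.isnan(se) else se))
    qual = [w for w in wins if w[3] >= r2_min]
    if not qual:
        short = [w for w in wins if w[1] - w[0] + 1 == min_points]
        return max(short, key=lambda w: w[2])[:2] + (True,)
    top = max(qual, key=lambda w: w[2])
    tied = [w for w in qual if w[2] >= top[2] - top[4]]
    best = max(tied, key=lambda w: (w[1] - w[0], -w[0], w[2]))
    return best[:2] + (False,)


class TestFindLinearWindow:
    def test_lag_linear_plateau_example(self):
        # brute-force enumeration picks the exact linear segment
        tr = _trace([0, 0, 0, 2, 4, 6, 8, 10, 10, 10])
        w = find_linear_window(tr, min_points=4, r2_min=0.95)
        assert (w.start, w.end) == (2, 7)
        assert w.slope == pytest.approx(2.0)
        assert not w.low_confidence

    def test_pure_line_full_range(self):
        tr = _trace(2.0 * np.arange(12))
        w = find_linear_window(tr, min_points=4)
        assert (w.start, w.end) == (0, 11)

    def test_all_zero_low_confidence(self):
        tr = _trace(np.zeros(10))
        w = find_linear_window(tr, min_points=4)
        assert w.slope == 0.0
        assert w.low_confidence or w.r_squared == 1.0

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="points"):
            find_linear_window(_trace([1.0, 2.0]), min_points=4)

    def test_matches_independent_enumerator(self, rng):
        for _ in range(100):
            n = rng.integers(8, 26)
            lag = rng.integers(0, n // 2)
            rate = rng.uniform(0, 3)
            plateau = rng.uniform(1, 40)
            t = np.arange(n, dtype=float)
            y = np.clip(rate * (t - lag), 0, plateau) + rng.normal(0, 0.3, n)
            tr = _trace(y, t)
            mp = int(rng.integers(4, 8))
            w = find_linear_window(tr, min_points=mp, r2_min=0.95)
            a, b, low = enumerate_windows_oracle(t, y, mp, 0.95)
            assert (w.start, w.end, w.low_confidence) == (a, b, low)


class TestInitialRate:
    def test_manual_window_on_exact_line(self):
        tr = _trace([0, 0, 2, 4, 6, 8, 8])
        r = initial_rate(tr, window=(1, 5))
        assert r.slope == pytest.approx(2.0)
        assert r.n_points == 5

    def test_two_point_window_is_difference_quotient(self):
        tr = _trace([1.0, 2.0, 8.0], [0.0, 2.0, 4.0])
        r = initial_rate(tr, window=(1, 2))
        assert r.slope == pytest.approx((8.0 - 2.0) / 2.0)

    def test_noiseless_auto_rate_matches_truth(self, noiseless_movie):
        """End-to-end on a blur- and noise-free movie: automatic window
        on the exactly linear corrected trace recovers the rate to 2%."""
        from guvkin import analyze_movie

        stack, gt = noiseless_movie
        analysis = analyze_movie(stack)
        assert len(analysis.rates) == len(gt.true_rates)
        for r in analysis.rates:
            assert r.slope == pytest.approx(1.0, rel=0.02)

    def test_rate_recovery_with_truth_masks(self):
        """With ground-truth membrane masks and no optical blur the rate
        estimator is accurate to ~10% median relative error at default
        detection noise.  (With blur every measured rate additionally
        carries the fixed optical attenuation of the band-pass ring
        profile, which cancels in the fold-change comparisons.)"""
        import dataclasses

        from guvkin import analyze_movie, fixture, simulate_timelapse

        scene = dataclasses.replace(fixture("FIG1C", seed=2)["CI"], psf_sigma_um=0.0)
        stack, gt = simulate_timelapse(scene)
        regions = regions_from_truth(gt, stack.n_frames)
        analysis = analyze_movie(stack, regions=regions)
        assert len(analysis.rates) == len(gt.true_rates)
        rel_err = [
            abs(r.slope - gt.true_rates[int(r.roi_id) - 1]) / gt.true_rates[int(r.roi_id) - 1]
            for r in analysis.rates
        ]
        assert np.median(rel_err) <= 0.10


class TestFoldChange:
    def test_simple_ratio(self):
        assert fold_change([2.0], [0.5]) == pytest.approx(4.0)

    def test_identical_groups_unity(self):
        assert fold_change([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_dead_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError, match="denominator"):
            fold_change([1.0], [0.0, 0.0])


class TestCompareRates:
    def test_equal_groups_t_zero(self):
        cmp = compare_rates([1, 2, 3], [1, 2, 3])
        assert cmp.t_statistic == pytest.approx(0.0)
        assert cmp.p_value == pytest.approx(1.0)

    def test_welch_hand_example(self):
        # A=[2,4,6], B=[1,2,3]: means 4,2; var 4,1
        # t = 2 / sqrt(4/3 + 1/3) = 1.549; WS df = 2.94
        cmp = compare_rates([2, 4, 6], [1, 2, 3])
        assert cmp.t_statistic == pytest.approx(2 / math.sqrt(5 / 3), abs=1e-3)
        va, vb = 4 / 3, 1 / 3
        df = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        assert cmp.degrees_of_freedom == pytest.approx(df, abs=1e-2)

    def test_separated_groups_significant(self, rng):
        a = rng.normal(100, 1, 10)
        b = rng.normal(0, 1, 10)
        assert compare_rates(a, b).p_value < 1e-3

    def test_degenerate_zero_variance(self):
        cmp = compare_rates([2.0, 2.0], [2.0, 2.0])
        assert cmp.p_value == 1.0
        assert cmp.degenerate

    def test_reports_both_dispersion_conventions(self):
        cmp = compare_rates([1.0, 3.0], [2.0, 4.0])
        assert cmp.sd_a == pytest.approx(math.sqrt(2))
        assert cmp.sem_a == pytest.approx(1.0)
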