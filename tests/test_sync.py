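"""Windowed Spearman matrices, Fisher-z averaging, the wave-vs-background
rank test, trace integrals, distance binning and the extension regression."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ohcsync.sync import (AnalysisWindow, activity_increase_by_distance,
                          compare_wave_size_classes, distance_to_mask_um,
                          fisher_average, make_wave_window,
                          pick_background_window, regress_sync_vs_extension,
                          spearman_matrix, trace_integral, wave_size_class)
from ohcsync.sync import test_sync_increase as sync_increase_test

FR = 30.3
WIN = AnalysisWindow(0, 400)


class TestWindows:
    def test_centred_window(self):
        w = make_wave_window(2000, 4000)
        assert (w.start_frame, w.end_frame) == (1800, 2200)

    def test_peak_too_early_rejected(self):
        assert make_wave_window(100, 4000) is None

    def test_window_duration_13_2_s(self):
        w = make_wave_window(2000, 4000)
        assert w.duration_s(30.3) == pytest.approx(13.2, abs=0.005)

    def test_background_no_waves_starts_at_zero(self):
        w = pick_background_window([], 4000)
        assert (w.start_frame, w.end_frame) == (0, 400)

    def test_background_earliest_after_wave(self):
        w = pick_background_window([(0, 500)], 4000)
        assert (w.start_frame, w.end_frame) == (500, 900)

    def test_background_none_when_fully_occupied(self):
        assert pick_background_window([(0, 4000)], 4000) is None


class TestSpearman:
    def test_identical_monotone_traces_correlate_perfectly(self):
        x = np.linspace(0, 1, 400)
        res = spearman_matrix(np.vstack([x, x]), WIN)
        assert res.r_matrix[0, 1] == pytest.approx(1.0)

    def test_worked_rank_example(self):
        # x=[1..5], y=[1,3,2,5,4]: sum d^2 = 4, r_s = 1 - 24/120 = 0.8
        x = np.array([1, 2, 3, 4, 5.0])
        y = np.array([1, 3, 2, 5, 4.0])
        win = AnalysisWindow(0, 400)
        vals = np.vstack([np.resize(x, 400), np.resize(y, 400)])
        # direct check on the 5-sample window via the brute-force oracle
        r = np.corrcoef(stats.rankdata(x), stats.rankdata(y))[0, 1]
        assert r == pytest.approx(0.8)
        res = spearman_matrix(np.vstack([np.tile(x, 80), np.tile(y, 80)]), win)
        assert res.r_matrix[0, 1] == pytest.approx(0.8, abs=1e-12)

    def test_constant_trace_pair_undefined(self):
        rng = np.random.default_rng(0)
        vals = np.vstack([rng.random(400), np.full(400, 3.0), rng.random(400)])
        res = spearman_matrix(vals, WIN)
        assert res.excluded_pairs == 2
        assert res.n_pairs_valid == 1
        assert np.isnan(res.r_matrix[0, 1])

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(42)
        win = AnalysisWindow(0, 400)
        for _ in range(20):
            vals = rng.random((10, 400))
            res = spearman_matrix(vals, win)
            ranks = np.array([stats.rankdata(v) for v in vals])
            oracle = np.corrcoef(ranks)
            assert np.abs(res.r_matrix - oracle).max() < 1e-10

    def test_fewer_than_two_cells_raises(self):
        with pytest.raises(ValueError):
            spearman_matrix(np.zeros((1, 400)), WIN)


class TestFisherAverage:
    def test_all_zero(self):
        m = np.zeros((4, 4))
        np.fill_diagonal(m, 1.0)
        assert fisher_average(m) == 0.0

    def test_equal_pairs_fixed_point(self):
        m = np.full((3, 3), 0.5)
        np.fill_diagonal(m, 1.0)
        assert fisher_average(m) == pytest.approx(0.5, abs=1e-12)

    def test_worked_mixed_pair(self):
        m = np.eye(3)
        m[0, 1] = m[1, 0] = 0.0
        m[0, 2] = m[2, 0] = 0.9
        m[1, 2] = m[2, 1] = np.nan
        expected = np.tanh((np.arctanh(0.0) + np.arctanh(0.9)) / 2)
        assert fisher_average(m) == pytest.approx(expected, abs=1e-12)
        assert fisher_average(m) == pytest.approx(0.627, abs=5e-4)

    def test_off_diagonal_constant_returns_that_value(self):
        for r in (-0.6, 0.0, 0.3, 0.95):
            m = np.full((6, 6), r)
            np.fill_diagonal(m, 1.0)
            assert fisher_average(m) == pytest.approx(r, abs=1e-6)

    def test_no_valid_pairs_raises(self):
        m = np.full((3, 3), np.nan)
        np.fill_diagonal(m, 1.0)
        with pytest.raises(ValueError):
            fisher_average(m)

    def test_perfect_correlation_is_clipped_not_infinite(self):
        m = np.ones((3, 3))
        assert np.isfinite(fisher_average(m))
        assert fisher_average(m) < 1.0

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_rank_invariance_under_monotone_transforms(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.standard_normal((5, 400))
        transformed = np.exp(vals * 2.0) + 1.0      # strictly monotone
        a = spearman_matrix(vals, WIN)
        b = spearman_matrix(transformed, WIN)
        assert fisher_average(a.r_matrix) == pytest.approx(
            fisher_average(b.r_matrix), abs=1e-9)


class TestSyncIncrease:
    def test_extreme_separation_significant(self):
        # 45 pairwise coefficients at 0.9 vs 45 at 0.0
        wave = _as_result(_const_matrix(0.9, 10))
        bg = _as_result(_const_matrix(0.0, 10))
        p, sig = sync_increase_test(wave, bg)
        assert p < 0.001 and sig

    def test_identical_samples_not_significant(self):
        rng = np.random.default_rng(0)
        m = _const_matrix(0.0, 10)
        iu = np.triu_indices(10, 1)
        m[iu] = rng.uniform(-0.2, 0.6, iu[0].size)
        m[(iu[1], iu[0])] = m[iu]
        a = _as_result(m)
        p, sig = sync_increase_test(a, a)
        assert not sig
        assert 0.4 < p < 0.6


def _const_matrix(r, n):
    m = np.full((n, n), float(r))
    np.fill_diagonal(m, 1.0)
    return m


def _as_result(m):
    from ohcsync.sync import CorrelationResult
    iu = np.triu_indices_from(m, 1)
    nan = np.isnan(m[iu]).sum()
    return CorrelationResult(r_matrix=m, n_pairs_valid=iu[0].size - nan,
                             excluded_pairs=int(nan))


class TestTraceIntegral:
    def test_constant_trace(self):
        trace = np.full(800, 0.2)
        assert trace_integral(trace, WIN, FR) == pytest.approx(0.2 * 400 / FR,
                                                               rel=1e-9)
        assert trace_integral(trace, WIN, FR) == pytest.approx(2.64, abs=0.01)

    def test_zero_trace(self):
        assert trace_integral(np.zeros(500), WIN, FR) == 0.0

    def test_linear_ramp_unchanged_by_order1_smoothing(self):
        ramp = np.linspace(0, 1, 600)
        assert trace_integral(ramp, WIN, FR) == pytest.approx(
            ramp[:400].sum() / FR, rel=1e-9)

    def test_window_beyond_trace_raises(self):
        with pytest.raises(ValueError):
            trace_integral(np.zeros(300), WIN, FR)


class TestActivityIncrease:
    def test_distance_zero_inside_mask(self):
        mask = np.zeros((10, 10), bool)
        mask[4:7, 4:7] = True
        assert distance_to_mask_um((5.5, 5.5), mask, 1.0) == 0.0
        assert distance_to_mask_um((0.0, 5.0), mask, 1.0) > 3.0

    def test_equal_integrals_zero_fraction(self):
        dff = np.tile(np.linspace(0, 1, 800), (2, 1))
        wave = AnalysisWindow(0, 400)
        bg = AnalysisWindow(0, 400, kind="background")
        inc, table = activity_increase_by_distance(
            dff, ["a", "b"], np.array([0.0, 120.0]), wave, bg, FR)
        assert all(a.fractional_increase == pytest.approx(0.0) for a in inc)

    def test_zero_background_integral_excluded(self):
        dff = np.zeros((1, 800))
        dff[0, 450:500] = 1.0
        wave = AnalysisWindow(400, 800)
        bg = AnalysisWindow(0, 400, kind="background")
        inc, table = activity_increase_by_distance(
            dff, ["a"], np.array([10.0]), wave, bg, FR)
        assert inc[0].fractional_increase is None
        assert table["n"].sum() == 0


class TestRegression:
    def test_exact_line_recovered(self):
        ext = np.array([20.0, 60.0, 100.0, 140.0, 180.0])
        rsavg = 0.002 * ext + 0.1
        res = regress_sync_vs_extension(ext, rsavg)
        assert res.slope == pytest.approx(0.002, rel=1e-9)
        assert res.intercept == pytest.approx(0.1, rel=1e-6)
        assert res.p_slope < 1e-10
        assert res.pearson_r == pytest.approx(1.0)

    def test_equal_extensions_undefined(self):
        with pytest.raises(ValueError):
            regress_sync_vs_extension(np.full(5, 80.0), np.linspace(0, 1, 5))

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            regress_sync_vs_extension(np.array([1.0, 2.0]), np.array([0.1, 0.2]))


class TestWaveSizeClasses:
    def test_boundary_membership_is_strict(self):
        assert wave_size_class(74.9) == "small"
        assert wave_size_class(75.0) is None
        assert wave_size_class(150.0) is None
        assert wave_size_class(150.1) == "large"

    def test_identical_groups_not_different(self):
        res = compare_wave_size_classes([1.0, 1.1, 0.9], [1.0, 1.1, 0.9])
        assert res["p"] > 0.9
        assert res["mean_small"] == pytest.approx(res["mean_large"])

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            compare_wave_size_classes([], [1.0])
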