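import itertools

import numpy as np
import pytest
from scipy import signal, stats

from laminar_ifc.ifc import (
    DELTA_BIN_EDGES,
    bandpass,
    bin_curve,
    block_basis,
    fit_selectivity,
    pages_trend_test,
    pairwise_ifc,
    regress_out,
    stimulus_design,
)

TR = 2.5
F_P = 1.0 / 30.0


class TestRegressOut:
    def test_exact_model_zero_residual(self):
        X = stimulus_design(180, TR, F_P)
        ts = (0.7 * X[:, 1] - 0.2 * X[:, 2] + 3.0)[None, :]
        res = regress_out(ts, X)
        np.testing.assert_allclose(res, 0.0, atol=1e-10)

    def test_ols_orthogonality(self, rng):
        X = stimulus_design(180, TR, F_P, n_harmonics=2)
        ts = rng.standard_normal((8, 180))
        res = regress_out(ts, X)
        cross = res @ X
        assert np.max(np.abs(cross)) < 1e-8

    def test_wm_confound_removed(self, rng):
        # ts = model + 0.5 * WM + noise; with the WM regressor the residual
        # is uncorrelated with WM
        wm = rng.standard_normal(180)
        corrs = []
        for _ in range(50):
            ts = (np.cos(2 * np.pi * F_P * np.arange(180) * TR)
                  + 0.5 * wm + rng.standard_normal(180))[None, :]
            X = np.column_stack([stimulus_design(180, TR, F_P), wm])
            res = regress_out(ts, X)[0]
            corrs.append(np.corrcoef(res, wm)[0, 1])
        assert abs(np.mean(corrs)) < 0.01

    def test_rank_deficient_raises(self):
        X = stimulus_design(180, TR, F_P)
        X = np.column_stack([X, X[:, 1]])
        with pytest.raises(ValueError, match="collinear"):
            regress_out(np.zeros((1, 180)), X)

    def test_intercept_required(self):
        X = stimulus_design(180, TR, F_P)[:, 1:]  # drop the intercept
        with pytest.raises(ValueError, match="intercept"):
            regress_out(np.zeros((1, 180)), X)

    def test_block_basis_removes_any_periodic_signal(self, rng):
        X = block_basis(180, 12)
        block = rng.standard_normal(12)
        ts = np.tile(block, 15)[None, :]
        res = regress_out(ts, X)
        np.testing.assert_allclose(res, 0.0, atol=1e-10)


class TestBandpass:
    def test_inband_gain_near_unity(self):
        t = np.arange(720) * TR
        ts = np.cos(2 * np.pi * F_P * t)
        out = bandpass(ts, tr=TR)
        mid = slice(100, 620)  # avoid edge transients
        gain = out[mid].std() / ts[mid].std()
        assert abs(gain - 1.0) < 0.05

    def test_drift_attenuated(self):
        t = np.arange(720) * TR
        drift = np.cos(2 * np.pi * 0.001 * t)
        out = bandpass(drift, tr=TR)
        assert out.std() < 0.1 * drift.std()

    def test_white_noise_band_fraction(self, rng):
        # oracle: filtfilt variance ratio = mean(|H|^4) over the spectrum
        sos = signal.butter(6, [0.01, 0.1], btype="bandpass", fs=1 / TR,
                            output="sos")
        w, h = signal.sosfreqz(sos, worN=4096, fs=1 / TR)
        expected = np.mean(np.abs(h) ** 4)
        ratios = [np.var(bandpass(rng.standard_normal(2000), tr=TR))
                  for _ in range(40)]
        assert np.mean(ratios) == pytest.approx(expected, rel=0.1)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(100), low=0.01, high=0.3, tr=TR)
        with pytest.raises(ValueError):
            bandpass(np.zeros(100), low=0.0, high=0.1, tr=TR)


class TestPairwiseIFC:
    def test_delta_in_octaves(self, rng):
        res = rng.standard_normal((2, 100))
        feature = np.log2([500.0, 2000.0])
        delta, r = pairwise_ifc(res, np.ones(2, bool), feature)
        assert delta[0] == pytest.approx(2.0)

    def test_pair_count(self, rng):
        n = 9
        res = rng.standard_normal((n, 50))
        feature = np.linspace(0, 2.5, n)
        delta, r = pairwise_ifc(res, np.ones(n, bool), feature)
        assert delta.size == n * (n - 1) // 2

    def test_identical_series_r_one(self, rng):
        x = rng.standard_normal(80)
        res = np.stack([x, x])
        delta, r = pairwise_ifc(res, np.ones(2, bool), np.array([0.0, 0.5]))
        assert r[0] == pytest.approx(1.0)

    def test_large_delta_dropped(self, rng):
        res = rng.standard_normal((2, 50))
        delta, r = pairwise_ifc(res, np.ones(2, bool), np.array([0.0, 3.5]))
        assert delta.size == 0

    def test_empty_region_error(self, rng):
        res = rng.standard_normal((3, 50))
        with pytest.raises(ValueError):
            pairwise_ifc(res, np.zeros(3, bool), np.zeros(3))

    def test_nan_feature_excluded(self, rng):
        res = rng.standard_normal((3, 50))
        feature = np.array([0.0, np.nan, 1.0])
        delta, r = pairwise_ifc(res, np.ones(3, bool), feature)
        assert delta.size == 1


class TestBinCurve:
    def test_single_pair_lands_in_bin(self):
        curve = bin_curve(np.array([0.2]), np.array([0.5]))
        assert curve.r_mean[1] == pytest.approx(0.5)
        assert curve.n_pairs[1] == 1

    def test_fisher_mean_exact(self):
        # tanh((atanh 0 + atanh 0.8) / 2) = tanh(ln(3)/2) = 0.5 exactly
        curve = bin_curve(np.array([0.01, 0.02]), np.array([0.0, 0.8]))
        assert curve.r_mean[0] == pytest.approx(0.5, abs=1e-12)

    def test_round_trip_identical_r(self, rng):
        r = 0.37
        curve = bin_curve(rng.uniform(0, 0.18, 50), np.full(50, r))
        assert curve.r_mean[0] == pytest.approx(r, abs=1e-12)

    def test_empty_bins_flagged(self):
        curve = bin_curve(np.array([0.1]), np.array([0.2]))
        assert np.isnan(curve.r_mean[3])
        assert curve.n_pairs[3] == 0

    def test_half_open_edges(self):
        curve = bin_curve(np.array([0.1875]), np.array([0.4]))
        assert curve.n_pairs[1] == 1 and curve.n_pairs[0] == 0

    def test_binned_decay_matches_prediction(self, rng):
        # uniform deltas with exact exponential r: per-bin Fisher mean should
        # track the decay evaluated at the per-bin mean delta
        lam, r0 = 1.3, 0.6
        delta = rng.uniform(0, 3, 40_000)
        r = r0 * np.exp(-lam * delta)
        curve = bin_curve(delta, r)
        pred = r0 * np.exp(-lam * curve.x_mean)
        # Fisher averaging of a convex decay slightly exceeds the value at
        # the mean delta for wide bins; allow a small absolute slack
        np.testing.assert_allclose(curve.r_mean, pred, atol=0.01)

    def test_no_pairs_error(self):
        with pytest.raises(ValueError):
            bin_curve(np.array([]), np.array([]))


class TestFitSelectivity:
    def test_exact_generating_values(self):
        x = np.array([0.0, 1.0, 2.0])
        y = 0.8 * np.exp(-1.5 * x)
        curve = bin_curve(np.array([0.1, 1.0, 2.0]), np.array([0.5, 0.5, 0.5]))
        curve.r_mean = np.array([y[0], y[1], y[2], np.nan, np.nan])
        curve.n_pairs = np.array([1, 1, 1, 0, 0])
        curve.x_mid = np.array([0.0, 1.0, 2.0, np.nan, np.nan])
        r0, lam = fit_selectivity(curve, x_mode="midpoint")
        assert r0 == pytest.approx(0.8, abs=1e-8)
        assert lam == pytest.approx(1.5, abs=1e-8)

    def test_flat_curve_lambda_zero(self):
        curve = bin_curve(np.array([0.1, 0.5, 1.0, 2.0]), np.full(4, 0.3))
        r0, lam = fit_selectivity(curve)
        assert lam == pytest.approx(0.0, abs=1e-8)
        assert r0 == pytest.approx(0.3, abs=1e-8)

    def test_needs_three_bins(self):
        curve = bin_curve(np.array([0.1, 0.3]), np.array([0.5, 0.4]))
        with pytest.raises(ValueError):
            fit_selectivity(curve)

    def test_negative_bins_allowed(self):
        curve = bin_curve(np.array([0.1, 0.5, 1.0, 2.0]),
                          np.array([0.5, 0.2, -0.05, -0.1]))
        r0, lam = fit_selectivity(curve)
        assert np.isfinite(lam) and lam >= 0


def page_bruteforce_p(table, coef):
    """Exact one-sided p by enumerating all within-row rank permutations."""
    n, k = table.shape
    ranks = np.stack([stats.rankdata(row) for row in table])
    l_obs = float(np.sum(ranks * coef))
    base = list(itertools.permutations(range(1, k + 1)))
    count = total = 0
    for combo in itertools.product(base, repeat=n):
        l_val = float(np.sum(np.asarray(combo) * coef))
        total += 1
        if l_val >= l_obs:
            count += 1
    return count / total


class TestPagesTrendTest:
    def test_perfectly_decreasing_maximum_L(self):
        table = np.tile(np.arange(5, 0, -1, dtype=float), (20, 1))
        res = pages_trend_test(table, order="decreasing")
        assert res.L == 20 * sum(j * j for j in range(1, 6))  # 1100
        assert res.p < 1e-10

    def test_constant_rows_average_ranks(self):
        table = np.ones((20, 5))
        res = pages_trend_test(table, order="decreasing")
        assert res.L == pytest.approx(45 * 20)
        assert res.p == pytest.approx(0.5, abs=0.01)

    def test_exact_matches_bruteforce(self, rng):
        table = rng.standard_normal((3, 3))
        coef = np.array([3.0, 2.0, 1.0])
        expected = page_bruteforce_p(table, coef)
        res = pages_trend_test(table, order="decreasing", method="exact")
        assert res.p == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy(self, rng):
        table = rng.standard_normal((6, 4))
        ours = pages_trend_test(table, order="increasing", method="exact")
        ref = stats.page_trend_test(table, method="exact")
        assert ours.L == pytest.approx(ref.statistic)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_asymptotic_matches_scipy(self, rng):
        table = rng.standard_normal((15, 5))
        ours = pages_trend_test(table, order="increasing", method="asymptotic")
        ref = stats.page_trend_test(table, method="asymptotic")
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_permutation_close_to_exact(self, rng):
        table = rng.standard_normal((4, 4))
        exact = pages_trend_test(table, method="exact")
        perm = pages_trend_test(table, method="permutation", n_perm=4000, seed=3)
        assert perm.p == pytest.approx(exact.p, abs=0.03)

    def test_missing_cells_rejected(self):
        table = np.ones((4, 4))
        table[1, 2] = np.nan
        with pytest.raises(ValueError):
            pages_trend_test(table)

    def test_type_one_error_quick(self, rng):
        # exchangeable null: rejection rate at alpha=0.05 near nominal
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            table = rng.standard_normal((20, 5))
            if pages_trend_test(table).p < 0.05:
                rejections += 1
        assert 0.02 < rejections / n_rep < 0.09

    def test_input_validation(self):
        with pytest.raises(ValueError):
            pages_trend_test(np.ones((3, 2)))
        with pytest.raises(ValueError):
            pages_trend_test(np.ones((3, 4)), order="sideways")
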