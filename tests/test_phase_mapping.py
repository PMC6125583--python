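import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from laminar_ifc.phase_mapping import (
    FISHER_Z_CAP,
    activation_zscore,
    average_phase,
    calibrated_zscore,
    fourier_component,
    map_subject,
    phase_to_latency,
)
from laminar_ifc.synthetic_data import DepthRunSeries, make_ground_truth, simulate_subject
from laminar_ifc.stimulus_surface import ChirpStimulus

from conftest import tiny_synth

F_P = 1.0 / 30.0
TR = 2.5
T = np.arange(180) * TR


class TestFourierComponent:
    def test_pure_cosine(self):
        comp = fourier_component(np.cos(2 * np.pi * F_P * T), F_P, TR)
        assert comp.amplitude == pytest.approx(1.0)
        assert comp.phase == pytest.approx(0.0, abs=1e-9)

    def test_pure_sine_cos_convention(self):
        comp = fourier_component(np.sin(2 * np.pi * F_P * T), F_P, TR)
        assert comp.phase == pytest.approx(3 * np.pi / 2)

    def test_amplitude_and_phase_recovered(self):
        ts = 2.5 * np.cos(2 * np.pi * F_P * T + 1.2)
        comp = fourier_component(ts, F_P, TR)
        assert comp.amplitude == pytest.approx(2.5)
        assert comp.phase == pytest.approx(1.2)

    def test_white_noise_rayleigh_mean(self, rng):
        # oracle: |X| is Rayleigh with per-quadrature SD sqrt(2/N) * sigma,
        # so E|X| = sigma * sqrt(pi / N)
        amps = [fourier_component(rng.standard_normal(180), F_P, TR).amplitude
                for _ in range(3000)]
        assert np.mean(amps) == pytest.approx(np.sqrt(np.pi / 180), rel=0.05)

    def test_too_short_series(self):
        with pytest.raises(ValueError):
            fourier_component(np.zeros(8), F_P, TR)

    def test_non_harmonic_frequency(self):
        with pytest.raises(ValueError):
            fourier_component(np.zeros(180), 0.017, TR)

    def test_vectorized_matches_loop(self, rng):
        ts = rng.standard_normal((5, 180))
        comp = fourier_component(ts, F_P, TR)
        for v in range(5):
            single = fourier_component(ts[v], F_P, TR)
            assert comp.amplitude[v] == pytest.approx(single.amplitude)
            assert comp.phase[v] == pytest.approx(single.phase)


class TestActivationZscore:
    def test_self_model_capped(self):
        ts = np.cos(2 * np.pi * F_P * T + 0.3)
        comp = fourier_component(ts, F_P, TR)
        z = activation_zscore(ts, comp, F_P, TR)
        assert z == pytest.approx(FISHER_Z_CAP)

    def test_orthogonal_harmonic(self):
        ts = np.cos(2 * np.pi * 2 * F_P * T)
        comp = fourier_component(ts, F_P, TR)
        comp.amplitude = np.asarray(1.0)  # force a nonzero model
        z = activation_zscore(ts, comp, F_P, TR)
        assert abs(z) < 1e-8

    def test_model_plus_noise_simulation(self, rng):
        # model SD 1 + unit noise -> E[r] ~ 1/sqrt(2), z ~ atanh(0.707) ~ 0.881
        zs = []
        for _ in range(600):
            model = np.sqrt(2) * np.cos(2 * np.pi * F_P * T + 0.8)
            ts = model + rng.standard_normal(180)
            comp = fourier_component(ts, F_P, TR)
            zs.append(activation_zscore(ts, comp, F_P, TR))
        assert np.mean(zs) == pytest.approx(np.arctanh(1 / np.sqrt(2)), abs=0.05)

    def test_zero_variance_invalid(self):
        comp = fourier_component(np.cos(2 * np.pi * F_P * T), F_P, TR)
        assert np.isnan(activation_zscore(np.zeros(180), comp, F_P, TR))


class TestCalibratedZscore:
    def test_null_calibration(self, rng):
        # fitted-sinusoid null: fraction of z > 1.65 should be ~5%
        n_rep = 4000
        ts = rng.standard_normal((n_rep, 180))
        comp = fourier_component(ts, F_P, TR)
        t = np.arange(180) * TR
        model = comp.amplitude[:, None] * np.cos(2 * np.pi * F_P * t + comp.phase[:, None])
        tc = ts - ts.mean(1, keepdims=True)
        mc = model - model.mean(1, keepdims=True)
        r = (tc * mc).sum(1) / np.sqrt((tc**2).sum(1) * (mc**2).sum(1))
        z = calibrated_zscore(r, 180)
        frac = np.mean(z > 1.65)
        assert 0.03 < frac < 0.07


class TestAveragePhase:
    def test_substitution_example(self):
        assert average_phase(1.0, 2.0) == pytest.approx((1 + 2 * np.pi - 2) / 2)

    def test_equal_phases_give_pi(self):
        assert average_phase(0.7, 0.7) == pytest.approx(np.pi)

    @settings(deadline=None, max_examples=100)
    @given(st.floats(0, 2 * np.pi - 1e-9), st.floats(0, 2 * np.pi - 1e-9))
    def test_wrapped_output(self, a, b):
        out = average_phase(a, b)
        assert 0 <= out < 2 * np.pi

    def test_phase_to_latency(self):
        assert phase_to_latency(0.0, F_P) == 0.0
        assert phase_to_latency(np.pi, F_P) == pytest.approx(15.0)
        assert phase_to_latency(2 * np.pi - 1e-9, F_P) == pytest.approx(30.0)


def _noiseless_cohort(delay):
    cfg = tiny_synth(noise_sd=0.0, delay_range=(delay, delay),
                     tw_core_oct=0.8, tw_noncore_oct=0.9)
    stim = ChirpStimulus()
    gt = make_ground_truth(cfg.sheet(), cfg, seed=0)
    runs = simulate_subject(gt, stim, cfg, 0, seed=1)
    return stim, gt, runs


class TestMapSubject:
    def test_noiseless_recovery_within_quantization(self):
        stim, gt, runs = _noiseless_cohort(delay=4.0)
        maps = map_subject(runs, stim, z_threshold=-np.inf)
        err = np.abs(maps[0.1].logf - gt.logf)
        # tolerance: TR/2 * 0.2 oct/s * ln 2 per the latency quantization bound
        assert np.nanmax(err) <= stim.tr / 2 * 0.2 * np.log(2)

    def test_delay_cancellation(self):
        # Eq. 2 invariance: recovered phase identical for any delay
        results = {}
        for d in (3.0, 5.0, 8.0):
            stim, gt, runs = _noiseless_cohort(delay=d)
            maps = map_subject(runs, stim, z_threshold=-np.inf)
            results[d] = maps[0.1].phi_avg
        spread = np.ptp(np.stack(list(results.values())), axis=0)
        assert np.max(spread) < 2 * np.pi * F_P * stim.tr / 2

    def test_direction_symmetry(self):
        stim, gt, runs = _noiseless_cohort(delay=0.0)
        maps = map_subject(runs, stim, z_threshold=-np.inf)
        # swap which runs carry which label while also swapping the labels:
        # the rising/falling sets are interchanged twice, a no-op
        import dataclasses
        flip = {"rising": "falling", "falling": "rising"}
        swapped = [dataclasses.replace(r, direction=flip[r.direction]) for r in runs]
        swapped = [dataclasses.replace(r, direction=flip[r.direction]) for r in swapped]
        maps2 = map_subject(swapped, stim, z_threshold=-np.inf)
        np.testing.assert_allclose(maps[0.1].phi_avg, maps2[0.1].phi_avg)

    def test_monotone_map(self):
        # within the uniform-tuning-width region, noiseless recovered
        # preference orders vertices exactly as the truth does
        from scipy.stats import spearmanr
        stim, gt, runs = _noiseless_cohort(delay=2.0)
        maps = map_subject(runs, stim, z_threshold=-np.inf)
        amap = maps[0.1]
        ok = np.isfinite(amap.logf) & ~gt.core_mask
        rho = spearmanr(gt.logf[ok], amap.logf[ok]).statistic
        assert rho == pytest.approx(1.0)

    def test_all_noise_subject_mostly_invalid(self, rng):
        # nominal one-tailed 5% at z > 1.65 (binomial tolerance)
        stim = ChirpStimulus()
        n_v = 1500
        runs = []
        for i, direction in enumerate(("rising", "rising", "falling", "falling")):
            runs.append(DepthRunSeries(
                subject=0, depth=0.1, run_id=f"run-{i}", direction=direction,
                data=rng.standard_normal((n_v, 180)), tr=TR,
                nuisance=np.zeros((7, 180))))
        maps = map_subject(runs, stim, z_threshold=1.65)
        assert np.mean(~maps[0.1].valid) >= 0.93

    def test_threshold_minus_inf_all_latency_valid(self):
        stim, gt, runs = _noiseless_cohort(delay=0.0)
        maps = map_subject(runs, stim, z_threshold=-np.inf)
        # every vertex prefers a frequency inside the chirp -> all valid
        assert maps[0.1].valid.all()

    def test_missing_direction_error(self):
        stim, gt, runs = _noiseless_cohort(delay=0.0)
        rising_only = [r for r in runs if r.direction == "rising"]
        with pytest.raises(ValueError):
            map_subject(rising_only, stim)
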