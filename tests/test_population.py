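import numpy as np
import pytest
from scipy.stats import pearsonr

from psiacx.population import (
    group_average_ftc,
    noise_correlations,
    off_bf_ratio,
    peak_normalize,
    tuning_curve,
)

FREQS10 = 2.0 * 2.0 ** (np.arange(10) / 2.0)


def curve_from(mat, freqs=None):
    mat = np.atleast_2d(np.asarray(mat, float))
    freqs = FREQS10[: mat.shape[1]] if freqs is None else np.asarray(freqs, float)
    n_trials = mat.shape[1]
    return tuning_curve(mat, np.arange(n_trials) % freqs.size, freqs)


class TestTuningCurve:
    def test_single_peak(self):
        amps = np.zeros((1, 10))
        amps[0, FREQS10.tolist().index(8.0)] = 1.0
        c = curve_from(amps)
        assert c.bf_khz[0] == 8.0

    def test_tie_breaks_to_lowest_frequency(self):
        amps = np.zeros((1, 10))
        amps[0, 4] = 1.0   # 8 kHz
        amps[0, 5] = 1.0   # 11.31 kHz
        assert curve_from(amps).bf_khz[0] == 8.0

    def test_missing_frequency_raises(self):
        with pytest.raises(ValueError):
            tuning_curve(np.ones((1, 5)), np.zeros(5, dtype=int), FREQS10[:2])

    def test_noiseless_generator_bf_recovery(self, protocol10):
        from psiacx.synthetic import SynthNeuralConfig, simulate_experiment

        cfg = SynthNeuralConfig(
            n_neurons=20, trial_noise_sd=0.0, condition_gain={"Pre": 1.0}, seed=4
        )
        exp = simulate_experiment(cfg, protocol10)
        c = tuning_curve(
            exp.sessions["Pre"].evoked_amplitudes,
            protocol10.trial_freq_idx,
            protocol10.frequencies_khz,
        )
        np.testing.assert_array_equal(c.bf_khz, exp.bf_khz)


class TestPeakNormalize:
    def test_scales_to_unit_peak(self):
        c = peak_normalize(curve_from([[0.2, 0.4]], freqs=FREQS10[:2]))
        np.testing.assert_allclose(c.mean_response[0], [0.5, 1.0])

    def test_idempotent(self):
        c1 = peak_normalize(curve_from([[0.2, 0.4, 0.1]], freqs=FREQS10[:3]))
        c2 = peak_normalize(c1)
        np.testing.assert_allclose(c1.mean_response, c2.mean_response)

    def test_nonpositive_peak_excluded(self):
        with pytest.warns(RuntimeWarning, match="nonpositive FTC peak"):
            c = peak_normalize(curve_from([[-1.0, -2.0], [1.0, 2.0]], freqs=FREQS10[:2]))
        assert c.n_neurons == 1


class TestGroupAverage:
    def test_single_member_group_is_identity(self):
        c = peak_normalize(curve_from([[0.1, 0.5, 0.2]], freqs=FREQS10[:3]))
        g = group_average_ftc(c)
        np.testing.assert_allclose(g.curves[0], c.mean_response[0])
        np.testing.assert_array_equal(g.sems[0], 0.0)

    def test_identical_members_give_zero_sem(self):
        c = peak_normalize(
            curve_from([[0.1, 0.5, 0.2], [0.1, 0.5, 0.2]], freqs=FREQS10[:3])
        )
        g = group_average_ftc(c)
        assert g.counts.tolist() == [2]
        np.testing.assert_allclose(g.sems, 0.0, atol=1e-15)

    def test_synthetic_cohort_matches_gaussian_shape(self, protocol10):
        from psiacx.fluorescence import compute_dff, response_amplitude, sigma_normalize
        from psiacx.synthetic import SynthNeuralConfig, simulate_experiment
        from tests.conftest import corrected_traces

        w = 0.8
        cfg = SynthNeuralConfig(
            n_neurons=40, tuning_width_oct=w, trial_noise_sd=0.05,
            condition_gain={"Pre": 1.0}, seed=6,
        )
        exp = simulate_experiment(cfg, protocol10)
        tr = corrected_traces(exp.sessions["Pre"])
        t = sigma_normalize(compute_dff(tr, protocol10))
        amps = response_amplitude(t)
        c = peak_normalize(
            tuning_curve(amps, protocol10.trial_freq_idx, protocol10.frequencies_khz)
        )
        g = group_average_ftc(c)
        logf = np.log2(protocol10.frequencies_khz)
        for bf, curve in zip(g.bf_khz, g.curves):
            expected = np.exp(-((logf - np.log2(bf)) ** 2) / (2 * w**2))
            assert np.abs(curve - expected).max() < 0.12
            # peak of the averaged group curve stays at the group BF
            assert protocol10.frequencies_khz[np.argmax(curve)] == bf


class TestOffBfRatio:
    def test_flat_ftc_is_100_percent(self):
        assert off_bf_ratio(curve_from([np.ones(10)]))[0] == pytest.approx(100.0)

    def test_delta_ftc_is_0_percent(self):
        amps = np.zeros((1, 10))
        amps[0, 3] = 2.0
        assert off_bf_ratio(curve_from([amps[0]]))[0] == pytest.approx(0.0)

    def test_gaussian_closed_form(self):
        w = 0.8
        logf = np.log2(FREQS10)
        d = logf - np.log2(8.0)
        ftc = np.exp(-(d**2) / (2 * w**2))
        expected = 100.0 * ftc[d != 0].mean() / 1.0
        got = off_bf_ratio(curve_from([ftc]))[0]
        assert got == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_bf_response_excluded(self):
        with pytest.warns(RuntimeWarning, match="nonpositive BF response"):
            r = off_bf_ratio(curve_from([[-1.0, -0.5]], freqs=FREQS10[:2]))
        assert np.isnan(r[0])


class TestNoiseCorrelations:
    def test_duplicate_neuron_correlates_perfectly(self, rng):
        x = rng.normal(0, 1, 40)
        res = noise_correlations(np.vstack([x, x]), np.arange(40) % 4)
        assert res.pair_matrix[0, 1] == pytest.approx(1.0)

    def test_matrix_invariants(self, rng):
        amps = rng.normal(0, 1, (6, 60))
        res = noise_correlations(amps, np.arange(60) % 5)
        m = res.pair_matrix
        np.testing.assert_allclose(m, m.T)
        np.testing.assert_allclose(np.diag(m), 1.0)
        assert (np.abs(m) <= 1 + 1e-12).all()

    def test_affine_rescaling_invariance(self, rng):
        amps = rng.normal(0, 1, (5, 40))
        idx = np.arange(40) % 4
        r1 = noise_correlations(amps, idx)
        scale = rng.uniform(0.5, 3.0, (5, 1))
        shift = rng.normal(0, 2, (5, 1))
        r2 = noise_correlations(amps * scale + shift, idx)
        np.testing.assert_allclose(r1.pair_matrix, r2.pair_matrix, atol=1e-10)

    def test_matches_brute_force_oracle(self, rng):
        amps = rng.normal(0, 1, (4, 24))
        idx = np.arange(24) % 3
        res = noise_correlations(amps, idx)
        # independent double-loop oracle
        resid = amps.copy()
        for j in range(3):
            resid[:, idx == j] -= amps[:, idx == j].mean(axis=1, keepdims=True)
        for i in range(4):
            for k in range(i + 1, 4):
                r, _ = pearsonr(resid[i], resid[k])
                assert res.pair_matrix[i, k] == pytest.approx(r, abs=1e-12)

    def test_independent_neurons_near_zero(self, rng):
        amps = rng.normal(0, 1, (10, 2000))
        res = noise_correlations(amps, np.arange(2000) % 10)
        assert abs(res.experiment_mean) < 0.02

    def test_mean_monotone_in_generated_rho(self, protocol10):
        from psiacx.synthetic import SynthNeuralConfig, simulate_experiment

        means = []
        for rho in (0.0, 0.1, 0.3, 0.5):
            cfg = SynthNeuralConfig(
                n_neurons=30, shared_noise_rho=rho, condition_gain={"Pre": 1.0}, seed=9
            )
            amps = simulate_experiment(cfg, protocol10).sessions["Pre"].evoked_amplitudes
            means.append(
                noise_correlations(amps, protocol10.trial_freq_idx).experiment_mean
            )
        assert means == sorted(means)

    def test_zero_variance_neuron_flagged(self):
        amps = np.vstack([np.zeros(12), np.random.default_rng(0).normal(0, 1, (2, 12))])
        with pytest.warns(RuntimeWarning, match="zero residual variance"):
            res = noise_correlations(amps, np.arange(12) % 3)
        assert np.isnan(res.pair_matrix[0, 1])
        assert np.isfinite(res.experiment_mean)

    def test_too_few_neurons_or_trials_raise(self):
        with pytest.raises(ValueError):
            noise_correlations(np.ones((1, 10)), np.arange(10) % 2)
        with pytest.raises(ValueError):
            noise_correlations(np.ones((3, 3)), np.arange(3))
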