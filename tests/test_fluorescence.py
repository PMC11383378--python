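import numpy as np
import pytest

from psiacx import make_tone_protocol
from psiacx.fluorescence import (
    CellTraces,
    build_roi_masks,
    compute_dff,
    extract_traces,
    neuropil_correct,
    qc_filter_cells,
    response_amplitude,
    sigma_normalize,
)
from psiacx.synthetic import render_session_movie
from tests.conftest import corrected_traces


def as_set(rows, cols):
    return set(zip(rows.tolist(), cols.tolist()))


class TestRoiMasks:
    def test_distant_cells_have_disjoint_full_masks(self):
        masks = build_roi_masks([(60, 60), (60, 160)], (220, 220))
        s0 = as_set(*masks.somatic[0])
        s1 = as_set(*masks.somatic[1])
        assert not s0 & s1
        assert not as_set(*masks.neuropil[0]) & s0
        assert not as_set(*masks.neuropil[1]) & s1

    def test_close_cells_shed_shared_annulus_pixels(self):
        centers = [(50.0, 50.0), (50.0, 54.0)]
        masks = build_roi_masks(centers, (100, 100))
        # brute-force oracle: pixels within both somatic annuli
        yy, xx = np.mgrid[0:100, 0:100]
        in_ann = []
        for cy, cx in centers:
            d = np.hypot(yy - cy, xx - cx)
            in_ann.append((d >= 2.0) & (d <= 6.0))
        shared = as_set(*np.nonzero(in_ann[0] & in_ann[1]))
        assert shared  # the construction must actually overlap
        for i in range(2):
            assert not as_set(*masks.somatic[i]) & shared
            expected = as_set(*np.nonzero(in_ann[i])) - shared
            assert as_set(*masks.somatic[i]) == expected

    def test_neuropil_ring_starts_at_gap_distance(self):
        masks = build_roi_masks([(40, 40)], (80, 80), neuropil_gap_px=3.0)
        srows, scols = masks.somatic[0]
        nrows, ncols = masks.neuropil[0]
        d = np.hypot(
            nrows[:, None] - srows[None, :], ncols[:, None] - scols[None, :]
        ).min()
        assert d >= 3.0

    def test_border_truncation_warns(self):
        with pytest.warns(RuntimeWarning, match="truncated"):
            build_roi_masks([(3, 3)], (64, 64))

    def test_center_outside_image_raises(self):
        with pytest.raises(ValueError):
            build_roi_masks([(100, 10)], (64, 64))


class TestExtractTraces:
    def test_uniform_movie(self):
        masks = build_roi_masks([(30, 30)], (64, 64))
        movie = np.full((8, 64, 64), 3.5)
        tr = extract_traces(movie, masks)
        np.testing.assert_allclose(tr.C_raw, 3.5)
        np.testing.assert_allclose(tr.N, 3.5)

    def test_painted_roi_exact_recovery(self):
        masks = build_roi_masks([(20, 20), (20, 44)], (64, 64))
        movie = np.zeros((5, 64, 64))
        vals = np.array([[1.0, 2.0, 3.0, 4.0, 5.0], [10.0, 9.0, 8.0, 7.0, 6.0]])
        for i in range(2):
            r, c = masks.somatic[i]
            movie[:, r, c] = vals[i][:, None]
        tr = extract_traces(movie, masks)
        np.testing.assert_allclose(tr.C_raw, vals)

    def test_checkerboard_mean(self):
        masks = build_roi_masks([(30, 30)], (64, 64))
        movie = np.zeros((1, 64, 64))
        r, c = masks.somatic[0]
        paint = np.where(np.arange(r.size) % 2 == 0, 1.0, 3.0)
        movie[0, r, c] = paint
        tr = extract_traces(movie, masks)
        assert tr.C_raw[0, 0] == pytest.approx(paint.mean())

    def test_shape_mismatch_raises(self):
        masks = build_roi_masks([(30, 30)], (64, 64))
        with pytest.raises(ValueError):
            extract_traces(np.zeros((3, 32, 32)), masks)


class TestNeuropilCorrection:
    def test_printed_arithmetic(self):
        assert neuropil_correct(np.array([10.0]), np.array([10.0]), 0.7)[0] == pytest.approx(3.0)

    def test_zero_neuropil_is_identity(self):
        c = np.arange(5.0)
        np.testing.assert_array_equal(neuropil_correct(c, np.zeros(5)), c)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            neuropil_correct(np.zeros(4), np.zeros(5))

    def test_generator_truth_recovered_exactly(self, noiseless_experiment):
        s = noiseless_experiment.sessions["Pre"]
        corrected = neuropil_correct(s.raw_somatic, s.neuropil, 0.7)
        np.testing.assert_allclose(corrected, s.true_somatic, rtol=0, atol=1e-12)


class TestQc:
    @pytest.mark.parametrize("value,kept", [(1.0, True), (-0.1, False), (0.0, False)])
    def test_positivity_rule(self, value, kept):
        tr = CellTraces(
            C_raw=np.zeros((1, 10)), N=np.zeros((1, 10)), frame_rate_hz=30.0,
            C=np.full((1, 10), value),
        )
        assert (0 in qc_filter_cells(tr)) is kept


class TestDff:
    def test_constant_trace_gives_zero(self, small_protocol):
        n_frames = int(small_protocol.duration_s * 30)
        tr = CellTraces(
            C_raw=np.ones((2, n_frames)), N=np.zeros((2, n_frames)),
            frame_rate_hz=30.0, C=np.full((2, n_frames), 4.2),
        )
        t = compute_dff(tr, small_protocol)
        assert t.valid.all()
        np.testing.assert_allclose(t.dff, 0.0, atol=1e-14)

    def test_step_response_ratio(self, small_protocol):
        # baseline 1.0, post-stimulus 1.5  ->  dff = 0.5
        n_frames = int(small_protocol.duration_s * 30)
        C = np.ones((1, n_frames))
        onset = int(round(small_protocol.trial_onset_s[0] * 30))
        C[0, onset + 1 : onset + 31] = 1.5
        tr = CellTraces(C_raw=C, N=np.zeros_like(C), frame_rate_hz=30.0, C=C)
        t = compute_dff(tr, small_protocol)
        amp = response_amplitude(t)
        assert amp[0, 0] == pytest.approx(0.5)

    def test_baseline_window_mean_is_zero(self, noiseless_experiment, small_protocol):
        tr = corrected_traces(noiseless_experiment.sessions["Pre"])
        t = compute_dff(tr, small_protocol)
        nb = int(round(t.baseline_window_s * t.frame_rate_hz))
        base_means = np.nanmean(t.dff[:, :, :nb], axis=2)
        np.testing.assert_allclose(base_means[t.valid], 0.0, atol=1e-12)

    def test_nonpositive_baseline_excluded_with_warning(self, small_protocol):
        n_frames = int(small_protocol.duration_s * 30)
        C = np.full((1, n_frames), -1.0)
        tr = CellTraces(C_raw=C, N=np.zeros_like(C), frame_rate_hz=30.0, C=C)
        with pytest.warns(RuntimeWarning, match="nonpositive baseline"):
            t = compute_dff(tr, small_protocol)
        assert not t.valid.any()

    def test_peak_dff_equals_amplitude_over_baseline(self):
        from psiacx.synthetic import SynthNeuralConfig, simulate_experiment

        # long ISI so adjacent-trial kernel tails are negligible
        protocol = make_tone_protocol(4, 32, 1, repeats=3, isi_choices_s=(12.0,), seed=2)
        cfg = SynthNeuralConfig(
            n_neurons=1, bf_khz=np.array([8.0]), base_amplitude=0.6,
            trial_noise_sd=0.0, condition_gain={"Pre": 1.0},
            baseline_fluorescence=2.0, seed=0,
        )
        exp = simulate_experiment(cfg, protocol)
        tr = corrected_traces(exp.sessions["Pre"])
        t = compute_dff(tr, protocol)
        at_bf = protocol.trial_frequencies_khz == 8.0
        peaks = np.nanmax(t.dff[0, at_bf], axis=1)
        # kernel is peak-normalized: peak dff = amplitude / baseline
        np.testing.assert_allclose(peaks, 0.6 / 2.0, rtol=2e-3)


class TestAmplitude:
    def test_unit_window(self, small_protocol):
        n_frames = int(small_protocol.duration_s * 30)
        C = np.ones((1, n_frames))
        tr = CellTraces(C_raw=C, N=np.zeros_like(C), frame_rate_hz=30.0, C=C)
        t = compute_dff(tr, small_protocol)
        t.dff[:] = 1.0
        np.testing.assert_allclose(response_amplitude(t), 1.0)

    def test_linear_ramp_gives_half(self, small_protocol):
        n_frames = int(small_protocol.duration_s * 30)
        C = np.ones((1, n_frames))
        tr = CellTraces(C_raw=C, N=np.zeros_like(C), frame_rate_hz=30.0, C=C)
        t = compute_dff(tr, small_protocol)
        nb = int(round(2.0 * 30))
        ramp = np.linspace(0, 1, 30)
        t.dff[:, :, nb + 1 : nb + 31] = ramp
        assert response_amplitude(t)[0, 0] == pytest.approx(0.5, abs=1.0 / 30)

    def test_window_beyond_raster_raises(self, small_protocol):
        n_frames = int(small_protocol.duration_s * 30)
        C = np.ones((1, n_frames))
        tr = CellTraces(C_raw=C, N=np.zeros_like(C), frame_rate_hz=30.0, C=C)
        t = compute_dff(tr, small_protocol)
        with pytest.raises(ValueError):
            response_amplitude(t, window_s=10.0)


class TestSigmaNormalize:
    def test_two_point_sd(self):
        # two trials with amplitudes {0, 2} -> sample SD (ddof 1) = sqrt(2)
        protocol = make_tone_protocol(4, 8, 1, repeats=1, isi_choices_s=(6.0,), seed=0)
        n_frames = int(protocol.duration_s * 30)
        C = np.ones((1, n_frames))
        onsets = np.floor(protocol.trial_onset_s * 30 + 0.5).astype(int)
        for k, o in enumerate(onsets):
            C[0, o + 1 : o + 31] += 2.0 * (k % 2)
        tr = CellTraces(C_raw=C, N=np.zeros_like(C), frame_rate_hz=30.0, C=C)
        t = sigma_normalize(compute_dff(tr, protocol))
        assert t.sigma[0] == pytest.approx(np.sqrt(2), rel=1e-6)

    def test_normalized_amplitude_sd_is_one(self, protocol10):
        from psiacx.synthetic import SynthNeuralConfig, simulate_experiment

        cfg = SynthNeuralConfig(n_neurons=8, condition_gain={"Pre": 1.0}, seed=3)
        exp = simulate_experiment(cfg, protocol10)
        tr = corrected_traces(exp.sessions["Pre"])
        t = sigma_normalize(compute_dff(tr, protocol10))
        amps = response_amplitude(t)
        np.testing.assert_allclose(np.nanstd(amps, axis=1, ddof=1), 1.0, rtol=1e-10)

    def test_zero_sigma_neuron_excluded(self, small_protocol):
        n_frames = int(small_protocol.duration_s * 30)
        C = np.ones((2, n_frames))
        onsets = np.floor(small_protocol.trial_onset_s * 30 + 0.5).astype(int)
        for k, o in enumerate(onsets):  # neuron 1 varies, neuron 0 constant
            C[1, o + 1 : o + 31] += 1.0 + (k % 2)
        tr = CellTraces(C_raw=C, N=np.zeros_like(C), frame_rate_hz=30.0, C=C)
        with pytest.warns(RuntimeWarning, match="zero/undefined amplitude SD"):
            t = sigma_normalize(compute_dff(tr, small_protocol))
        assert t.n_neurons == 1
        assert t.neuron_ids.tolist() == [1]


def test_end_to_end_movie_recovery_and_scale_invariance(noiseless_experiment, small_protocol):
    """Movie -> masks -> traces -> correction reproduces generator truth, and
    the ΔF/F chain is invariant to a global multiplicative rescaling."""
    # centers spaced so neuropil rings cannot overlap (ring outer radius 19)
    centers = [(24, 24), (24, 104), (104, 24), (104, 104)]
    masks = build_roi_masks(centers, (128, 128))
    session = noiseless_experiment.sessions["Pre"]
    movie = render_session_movie(session, masks)
    tr = extract_traces(movie, masks).corrected(0.7)
    np.testing.assert_allclose(tr.C, session.true_somatic[:4], rtol=0, atol=1e-10)

    t1 = sigma_normalize(compute_dff(tr, small_protocol))
    tr2 = extract_traces(movie * 7.5, masks).corrected(0.7)
    t2 = sigma_normalize(compute_dff(tr2, small_protocol))
    np.testing.assert_allclose(t1.dff, t2.dff, rtol=1e-9, atol=1e-10)
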