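"""EMG-only onset detector: rest-noise estimate, threshold semantics,
streaming/batch equivalence, and the delay-constrained grid search."""

import numpy as np
import pytest

from swallowdetect import EmgOnsetParams, detect_emg_onsets, estimate_rest_sigma, optimize_emg_params
from swallowdetect.emg import StreamingEmgDetector


class TestRestSigma:
    def test_tracks_quietest_segment(self, rng):
        x = np.concatenate([rng.normal(0, 1.0, 5000), rng.normal(0, 0.2, 5000)])
        sigma0 = estimate_rest_sigma(x, n_sigma=250)
        assert sigma0[-1] == pytest.approx(0.2, rel=0.15)

    def test_constant_signal_hits_floor(self):
        sigma0 = estimate_rest_sigma(np.full(1000, 3.0), n_sigma=250, sigma0_floor=1e-12)
        assert np.all(sigma0 == 1e-12)

    def test_non_increasing(self, rng):
        sigma0 = estimate_rest_sigma(rng.standard_normal(3000), n_sigma=250)
        assert np.all(np.diff(sigma0) <= 0)

    def test_too_short_input_rejected(self):
        with pytest.raises(ValueError, match="insufficient samples"):
            estimate_rest_sigma(np.zeros(100), n_sigma=250)


class TestDetect:
    def test_hand_traced_single_onset(self):
        # theta0=2, sigma0=0.5 (threshold 1.0), envelope steps 0.1 -> 1.5 at
        # sample 400, w=50: the 50th consecutive suprathreshold sample is 449
        eemg = np.where(np.arange(2000) < 400, 0.1, 1.5)
        sigma0 = np.full(2000, 0.5)
        onsets = detect_emg_onsets(eemg, sigma0, EmgOnsetParams(theta0=2.0, w=50, n_sigma=250))
        assert onsets.indices.tolist() == [449]

    def test_subthreshold_envelope_yields_nothing(self):
        eemg = np.full(3000, 0.4)
        onsets = detect_emg_onsets(eemg, np.full(3000, 0.5), EmgOnsetParams(theta0=1.0, w=50))
        assert len(onsets) == 0

    def test_second_burst_inside_refractory_suppressed(self):
        # bursts at 0.5 s spacing with a dip between them: the dip satisfies
        # the below-threshold re-arm but the 1.0 s refractory does not
        eemg = np.full(4000, 0.1)
        eemg[500:900] = 1.5
        eemg[1000:1400] = 1.5
        sigma0 = np.full(4000, 0.5)
        onsets = detect_emg_onsets(eemg, sigma0, EmgOnsetParams(theta0=2.0, w=50, n_sigma=250))
        assert len(onsets) == 1

    def test_burst_after_refractory_detected(self):
        eemg = np.full(6000, 0.1)
        eemg[500:900] = 1.5
        eemg[2500:2900] = 1.5
        sigma0 = np.full(6000, 0.5)
        onsets = detect_emg_onsets(eemg, sigma0, EmgOnsetParams(theta0=2.0, w=50, n_sigma=250))
        assert onsets.indices.tolist() == [549, 2549]

    def test_no_onset_inside_warmup(self):
        eemg = np.full(3000, 1.5)
        sigma0 = np.full(3000, 0.5)
        params = EmgOnsetParams(theta0=2.0, w=50, n_sigma=250)
        onsets = detect_emg_onsets(eemg, sigma0, params)
        assert all(i >= params.n_start for i in onsets.indices)

    def test_streaming_batch_equivalence(self, rng):
        eemg = np.abs(rng.standard_normal(8000)) + 0.2 * (
            np.sin(2 * np.pi * np.arange(8000) / 1500.0) > 0.6)
        sigma0 = estimate_rest_sigma(eemg, n_sigma=250)
        params = EmgOnsetParams(theta0=1.2, w=60, n_sigma=250)
        det = StreamingEmgDetector(params)
        stream_onsets = [n for n, (e, s0) in enumerate(zip(eemg, sigma0)) if det.step(e, s0)]
        batch = detect_emg_onsets(eemg, sigma0, params)
        assert batch.indices.tolist() == stream_onsets
        assert batch.n_skip == det.n_skip

    def test_onset_count_non_increasing_in_theta0(self, rng):
        eemg = np.abs(rng.standard_normal(10_000))
        sigma0 = estimate_rest_sigma(eemg, n_sigma=250)
        counts = [len(detect_emg_onsets(eemg, sigma0, EmgOnsetParams(theta0=th, w=50)))
                  for th in (1.0, 1.5, 2.0, 2.5, 3.0)]
        assert counts == sorted(counts, reverse=True)


class TestGridSearch:
    @staticmethod
    def _triple(onset_sample=1000, level=2.0):
        eemg = np.full(5000, 0.1)
        eemg[onset_sample:onset_sample + 600] = level
        sigma0 = np.full(5000, 0.5)
        refs = np.asarray([onset_sample / 1000.0])
        return eemg, sigma0, refs

    def test_perfect_cell_wins(self):
        triple = self._triple()
        res = optimize_emg_params([triple], theta0_grid=np.asarray([2.0, 100.0]),
                                  w_grid=np.asarray([50]), theta_mu_d=0.5)
        assert (res.theta0, res.w) == (2.0, 50)
        assert res.delay_constraint_met
        assert res.f_matrix[0, 0] == 1.0 and res.f_matrix[1, 0] == 0.0

    def test_impossible_delay_bound_flags_fallback(self):
        res = optimize_emg_params([self._triple()], theta0_grid=np.asarray([2.0]),
                                  w_grid=np.asarray([50]), theta_mu_d=-1.0)
        assert not res.delay_constraint_met

    def test_matrices_match_hand_evaluation(self):
        # 2x2 grid on a single recording: larger w shifts the onset later,
        # theta0 above the burst level kills detection entirely
        triple = self._triple(onset_sample=1000, level=2.0)
        res = optimize_emg_params([triple], theta0_grid=np.asarray([2.0, 50.0]),
                                  w_grid=np.asarray([50, 300]), theta_mu_d=0.5)
        # onset indices 1049 and 1299 -> delays 0.049 s and 0.299 s
        np.testing.assert_allclose(res.f_matrix, [[1.0, 1.0], [0.0, 0.0]])
        np.testing.assert_allclose(res.mu_matrix[0], [0.049, 0.299])
        assert np.all(np.isnan(res.mu_matrix[1]))
        assert (res.theta0, res.w) == (2.0, 50)

    def test_default_grids_match_published_design(self):
        from swallowdetect.emg import DEFAULT_THETA0_GRID, DEFAULT_W_GRID
        assert DEFAULT_THETA0_GRID.size == 13 and DEFAULT_W_GRID.size == 11
        assert DEFAULT_THETA0_GRID[0] == 1.0 and DEFAULT_THETA0_GRID[-1] == 7.0
        assert DEFAULT_W_GRID[0] == 50 and DEFAULT_W_GRID[-1] == 300
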