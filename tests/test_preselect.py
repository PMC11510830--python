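"""Streaming BI drop-detector: hand traces, properties, and an independently
coded offline oracle on seeded random walks."""

import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from swallowdetect import PreselectParams, preselect_init, preselect_signal, preselect_step
from swallowdetect.preselect import preselect_indices


def offline_oracle(bi, theta):
    """Second-path re-derivation of the drop detector, written offline-first.

    Peaks are found up front (strict three-point maxima); the trace is then
    scanned once, re-arming at each peak and firing at the first sample whose
    drop below the latest peak exceeds ``theta``. A peak at index p becomes
    visible one sample later (when the sample after the peak arrives).
    """
    bi = np.asarray(bi, float)
    peaks = [p for p in range(1, bi.size - 1)
             if bi[p - 1] < bi[p] and bi[p] > bi[p + 1]]
    peak_set = set(peaks)
    armed = False
    peak_val = bi[0] if bi.size else 0.0
    fires = []
    for m in range(1, bi.size):
        if m - 1 in peak_set:
            peak_val = bi[m - 1]
            armed = True
        if armed and peak_val - bi[m] > theta:
            fires.append(m)
            armed = False
    return fires


class TestStepSemantics:
    def test_init_state(self):
        st_ = preselect_init(5.0)
        assert (st_.bi_max, st_.prev, st_.prev2, st_.max_flag) == (5.0, 5.0, 5.0, False)

    def test_init_rejects_nan(self):
        with pytest.raises(ValueError):
            preselect_init(float("nan"))

    def test_fires_on_drop_past_threshold(self):
        params = PreselectParams(theta_ps=0.18)
        state = preselect_init(5.0)
        fired = [preselect_step(state, s, params)[0] for s in (6.0, 5.9, 5.8)]
        assert fired == [False, False, True]  # bi_max=6.0, drop 0.2 > 0.18

    def test_strictly_decreasing_stream_never_fires(self):
        params = PreselectParams()
        state = preselect_init(10.0)
        assert not any(preselect_step(state, 10.0 - 0.1 * k, params)[0]
                       for k in range(1, 50))

    def test_no_second_fire_without_new_maximum(self):
        params = PreselectParams(theta_ps=0.18)
        stream = [5.0, 6.0] + [6.0 - 0.1 * k for k in range(1, 20)]
        state = preselect_init(stream[0])
        fires = [k for k, s in enumerate(stream[1:], 1)
                 if preselect_step(state, s, params)[0]]
        assert len(fires) == 1


class TestSignalLevel:
    def test_linear_descent_fire_delay_matches_ramp_arithmetic(self):
        # 1.0 ohm drop over 0.39 s: the 0.18 ohm threshold crossing sits
        # 0.18 / (1.0/0.39) ~ 0.070 s after the descent start
        fs = 100.0
        t = np.arange(int(1.5 * fs)) / fs
        bi = np.full(t.size, 500.0)
        bi[:20] += np.linspace(0, 0.05, 20)  # small rise to create the peak
        start = 20
        n_drop = int(0.39 * fs)
        bi[start:start + n_drop] -= 1.0 * np.arange(n_drop) / n_drop
        bi[start + n_drop:] = bi[start + n_drop - 1]
        toi = preselect_signal(bi)
        assert toi.size == 1
        delay = toi[0] - start / fs
        assert delay == pytest.approx(0.18 * 0.39, abs=1.5 / fs)

    def test_subthreshold_noise_yields_nothing(self):
        rng = np.random.default_rng(11)
        bi = 500.0 + 0.05 * rng.random(2000)  # peak-to-peak < 0.18
        assert preselect_signal(bi).size == 0

    def test_recovery_above_old_maximum_rearms(self):
        # strict monotone segments (no plateau samples) so each apex registers
        valley = np.concatenate([np.linspace(0, 0.3, 10),
                                 np.linspace(0.3, -0.4, 20)[1:]])
        bi = 500.0 + np.concatenate([valley, np.linspace(-0.4, 0.0, 10)[1:-1], valley])
        assert preselect_signal(bi).size == 2

    def test_empty_input(self):
        assert preselect_signal(np.empty(0)).size == 0


class TestOracleEquivalence:
    def test_matches_offline_oracle_on_100_random_walks(self):
        params = PreselectParams(theta_ps=0.18)
        rng = np.random.default_rng(2024)
        for _ in range(100):
            bi = 500.0 + np.cumsum(0.05 * rng.standard_normal(10_000))
            got = preselect_indices(bi, params).tolist()
            assert got == offline_oracle(bi, params.theta_ps)

    @given(st.lists(st.floats(-1, 1, allow_nan=False), min_size=2, max_size=60),
           st.floats(0.05, 0.5))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_oracle_on_arbitrary_streams(self, samples, theta):
        bi = np.asarray(samples)
        params = PreselectParams(theta_ps=theta)
        assert preselect_indices(bi, params).tolist() == offline_oracle(bi, theta)

    @given(st.floats(0.05, 2.0), st.floats(0.01, 3.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_descent_fires_iff_depth_exceeds_threshold(self, theta, depth):
        # exact depth == theta ties are out of contract (strict comparison on
        # rounded floats); everything else must agree with the definition
        assume(abs(depth - theta) > 1e-6)
        bi = np.concatenate([[0.0, 0.5], np.linspace(0.5, 0.5 - depth, 41)[1:]])
        fires = preselect_indices(bi, PreselectParams(theta_ps=theta))
        assert (fires.size == 1) == (depth > theta)

    def test_fire_count_bounded_by_local_maxima(self):
        rng = np.random.default_rng(5)
        bi = np.cumsum(rng.standard_normal(5000))
        n_peaks = int(np.sum((bi[1:-1] > bi[:-2]) & (bi[1:-1] > bi[2:])))
        assert preselect_indices(bi, PreselectParams(1.0)).size <= n_peaks
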