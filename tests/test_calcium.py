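"""Per-trace calcium formulas against hand arithmetic and brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal

import rewardmap as rm
from rewardmap.calcium import butter_lowpass, detect_peaks_trace
from rewardmap.errors import InvalidInputError


def session_from(F, frame_rate=4.82, baseline_window=(0.0, None), **kw):
    F = np.atleast_2d(np.asarray(F, dtype=float))
    t1 = baseline_window[1]
    if t1 is None:
        t1 = F.shape[1] / frame_rate
    return rm.CalciumSession(F=F, frame_rate=frame_rate,
                             baseline_window=(baseline_window[0], t1), **kw)


class TestZscoreBaseline:
    def test_hand_trace(self):
        # baseline = first 3 frames: mu=2, sd=1 (ddof=1) -> z = (-1, 1, 0, 6)
        sess = session_from([1.0, 3.0, 2.0, 8.0], frame_rate=1.0,
                            baseline_window=(0.0, 3.0))
        z, excluded = rm.zscore_baseline(sess)
        np.testing.assert_allclose(z[0], [-1.0, 1.0, 0.0, 6.0])
        assert not excluded.any()

    def test_baseline_moments_by_construction(self, rng):
        sess = session_from(rng.random((8, 200)) + 1.0,
                            baseline_window=(0.0, 20.0))
        z, _ = rm.zscore_baseline(sess)
        frames = sess.baseline_frames()
        assert np.abs(z[:, frames].mean(axis=1)).max() < 1e-12
        np.testing.assert_allclose(z[:, frames].std(axis=1, ddof=1), 1.0,
                                   rtol=1e-9)

    def test_constant_trace_flagged(self):
        sess = session_from(np.vstack([np.ones(50), np.arange(50.0)]),
                            baseline_window=(0.0, 5.0))
        z, excluded = rm.zscore_baseline(sess)
        assert excluded[0] and not excluded[1]
        np.testing.assert_array_equal(z[0], 0.0)


class TestConsumptionPreprocess:
    def test_dc_gain_and_below_median_rule(self):
        # 4 constant traces with baseline means 1,2,3,4: subset = {1,2}
        F = np.outer([1.0, 2.0, 3.0, 4.0], np.ones(120))
        sess = session_from(F, baseline_window=(0.0, 10.0))
        filtered = butter_lowpass(F)
        np.testing.assert_allclose(filtered, F, atol=1e-6)  # unit DC gain
        # pooled below-median baseline: samples of traces 1 and 2
        frames = sess.baseline_frames()
        pooled = filtered[:2, frames].ravel()
        mu, sd = pooled.mean(), pooled.std(ddof=1)
        z = rm.consumption_preprocess(sess)
        np.testing.assert_allclose(z, (filtered - mu) / sd, atol=1e-9)

    def test_matches_two_step_oracle(self, rng):
        F = rng.random((12, 300)) + 5.0
        sess = session_from(F, baseline_window=(0.0, 20.0))
        z = rm.consumption_preprocess(sess)
        # independent oracle: explicit filter then explicit subset statistics
        b, a = signal.butter(2, 0.266)
        Ff = np.vstack([signal.filtfilt(b, a, F[i]) for i in range(12)])
        frames = sess.baseline_frames()
        means = Ff[:, frames].mean(axis=1)
        subset = np.flatnonzero(means < np.median(means))
        pooled = Ff[np.ix_(subset, frames)].ravel()
        oracle = (Ff - pooled.mean()) / pooled.std(ddof=1)
        np.testing.assert_allclose(z, oracle, atol=1e-9)

    def test_too_few_traces_rejected(self, rng):
        sess = session_from(rng.random((3, 100)))
        with pytest.raises(InvalidInputError):
            rm.consumption_preprocess(sess)


class TestDrugNormalize:
    def test_constant_trace_zero(self):
        F = np.full((1, 289), 7.0)
        out = rm.drug_normalize(F)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_quintile_rule_ten_samples(self):
        # one 10-frame segment: lowest quintile of 1..10 is {1,2}, mu=1.5
        F = np.arange(1.0, 11.0)[None, :]
        out = rm.drug_normalize(F, frame_rate=1.0, segment_len_s=10.0)
        np.testing.assert_allclose(out[0], (F[0] - 1.5) / 1.5)

    def test_gain_invariance(self, rng):
        F = rng.random((5, 600)) + 2.0
        out1 = rm.drug_normalize(F)
        out2 = rm.drug_normalize(3.7 * F)
        np.testing.assert_allclose(out1, out2, atol=1e-12)

    def test_segments_independent_of_order(self, rng):
        """Per-segment normalization: shuffling segments then re-sorting
        reproduces the original output."""
        fr, seg_s = 1.0, 50.0
        F = rng.random((4, 200)) + 1.0
        out = rm.drug_normalize(F, frame_rate=fr, segment_len_s=seg_s)
        segs = [slice(i * 50, (i + 1) * 50) for i in range(4)]
        perm = [2, 0, 3, 1]
        F_shuf = np.concatenate([F[:, segs[p]] for p in perm], axis=1)
        out_shuf = rm.drug_normalize(F_shuf, frame_rate=fr, segment_len_s=seg_s)
        for dst, src in enumerate(perm):
            np.testing.assert_allclose(out[:, segs[src]],
                                       out_shuf[:, segs[dst]], atol=1e-12)

    def test_nonpositive_quintile_rejected(self):
        with pytest.raises(InvalidInputError):
            rm.drug_normalize(np.zeros((1, 289)))


class TestDetectPeaks:
    @staticmethod
    def oracle(trace, sigma, min_distance_s, frame_rate, mult=3.0):
        """Enumerate all strict local maxima above threshold and prune
        exhaustively, highest first (ties: earlier frame)."""
        n = len(trace)
        cand = [i for i in range(1, n - 1)
                if trace[i] > trace[i - 1] and trace[i] > trace[i + 1]
                and trace[i] > mult * sigma]
        d = round(min_distance_s * frame_rate)
        kept = []
        for i in sorted(cand, key=lambda i: (-trace[i], i)):
            if all(abs(i - j) >= d for j in kept):
                kept.append(i)
        return sorted(kept)

    def test_flat_trace_no_peaks(self):
        frames, amps = detect_peaks_trace(np.zeros(100), sigma=1.0)
        assert frames.size == 0

    def test_single_impulse(self):
        trace = np.zeros(100)
        trace[40] = 5.0
        frames, amps = detect_peaks_trace(trace, sigma=1.0)
        np.testing.assert_array_equal(frames, [40])
        np.testing.assert_allclose(amps, [5.0])

    def test_matches_bruteforce_on_random_traces(self, rng):
        for _ in range(200):
            trace = rng.standard_normal(rng.integers(20, 300)) * 2.0
            frames, _ = detect_peaks_trace(trace, sigma=1.0)
            assert list(frames) == self.oracle(trace, 1.0, 1.3, 4.82)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-5, 10, allow_nan=False), min_size=5,
                    max_size=80),
           st.floats(0.2, 3.0))
    def test_spacing_and_threshold_invariants(self, values, min_dist_s):
        trace = np.asarray(values)
        frames, amps = detect_peaks_trace(trace, sigma=1.0,
                                          min_distance_s=min_dist_s,
                                          frame_rate=4.82)
        assert np.all(amps > 3.0)
        if frames.size > 1:
            assert np.diff(frames).min() >= round(min_dist_s * 4.82)


class TestCallActivation:
    def test_consumption_recovery(self, consumption_session):
        session, truth = consumption_session
        call = rm.call_activation(session, "food")
        reward = truth.neuron_populations == "reward"
        silent = truth.neuron_populations == "silent"
        assert call.activated[reward].mean() >= 0.9
        assert call.activated[silent].mean() <= 0.1

    def test_drug_recovery_and_false_positive_rate(self, drug_session):
        session, truth = drug_session
        call = rm.call_activation(session, "cocaine")
        reward = truth.neuron_populations == "reward"
        assert call.activated[reward].mean() >= 0.9
        # oracle false-positive rate: all-silent sessions, several seeds
        fps = []
        for seed in range(5):
            spec = rm.CalciumSimSpec(
                seed=300 + seed, duration=3720.0, n_neurons=30,
                event_times={"injection": 60.0},
                record_windows=rm.drug_record_windows(),
                populations={"silent": (30, 0.0)},
            )
            sess, _ = rm.gen_calcium_session(spec)
            fps.append(rm.call_activation(sess, "cocaine").activated.mean())
        oracle_rate = np.mean(fps)
        silent = truth.neuron_populations == "silent"
        assert call.activated[silent].mean() <= oracle_rate + 0.1

    def test_window_boundary_is_half_open(self):
        """A peak at exactly +40.0 min post injection is not cocaine-counted."""
        fr = 1.0
        n = 3300
        F = np.full((4, n), 50.0)
        F[:, :60] += np.sin(np.arange(60))  # baseline variability
        t_inj = 60.0
        edge = int(t_inj + 40 * 60)      # exactly 40 min post injection
        inside = int(t_inj + 30 * 60)
        F[0, edge] = 500.0
        F[1, inside] = 500.0
        sess = rm.CalciumSession(F=F, frame_rate=fr,
                                 events={"injection": t_inj},
                                 baseline_window=(0.0, 60.0))
        call = rm.call_activation(sess, "cocaine")
        assert not call.activated[0]
        assert call.activated[1]

    def test_missing_event_named(self, consumption_session):
        session, _ = consumption_session
        sess = rm.CalciumSession(F=session.F, frame_rate=session.frame_rate,
                                 baseline_window=session.baseline_window)
        with pytest.raises(InvalidInputError, match="injection"):
            rm.call_activation(sess, "cocaine")


class TestVennCounts:
    def test_exclusive_membership(self):
        def call(stim, flags):
            flags = np.asarray(flags, bool)
            return rm.ActivationCall(stim, flags, np.zeros(flags.size),
                                     np.zeros(flags.size, bool))
        calls = {
            "food": call("food", [1, 1, 0, 0]),
            "cocaine": call("cocaine", [1, 0, 1, 0]),
        }
        counts = rm.venn_counts(calls)
        assert counts[frozenset({"food", "cocaine"})] == 1
        assert counts[frozenset({"food"})] == 1
        assert counts[frozenset({"cocaine"})] == 1
        assert counts[frozenset()] == 1


class TestPreferenceStrength:
    @pytest.mark.parametrize("a,b,expected", [
        (2.0, 2.0, 0.0),
        (3.0, 0.0, 1.0),
        (3.0, 1.0, 0.5),
    ])
    def test_known_values(self, a, b, expected):
        assert rm.preference_strength(a, b) == pytest.approx(expected)

    def test_both_zero_is_nan(self):
        assert math.isnan(rm.preference_strength(0.0, 0.0))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.floats(0, 100), st.floats(0, 100))
    def test_antisymmetric_and_bounded(self, a, b):
        s = rm.preference_strength(a, b)
        if a + b == 0:
            assert math.isnan(s)
        else:
            assert -1.0 <= s <= 1.0
            assert s == pytest.approx(-rm.preference_strength(b, a))


class TestSessionIO:
    def test_hdf5_roundtrip(self, tmp_path, drug_session):
        session, _ = drug_session
        p = tmp_path / "s.h5"
        session.to_hdf5(p)
        back = rm.CalciumSession.from_hdf5(p)
        np.testing.assert_array_equal(back.F, session.F)
        np.testing.assert_array_equal(back.velocity, session.velocity)
        np.testing.assert_array_equal(back.frame_times, session.frame_times)
        assert back.events.keys() == session.events.keys()
        assert back.frame_rate == session.frame_rate
        assert back.cell_type == session.cell_type
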