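"""Slice extraction, kNN classification, voting and de-duplication."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pulsecap import (
    IntervalPulseDecoder,
    PulseSequence,
    SliceKNNClassifier,
    TranslocationTrajectory,
    assign_tap,
    dedup_detections,
    make_slices,
)
from pulsecap.reconstruct import _count_interval_votes


class TestAssignTap:
    @pytest.mark.parametrize(
        "pulses,end,expected",
        [
            ((100,), 105, 5),
            ((100, 103), 104, 4),  # 104-103 = 1 < 3 -> fall back to 100
            ((100, 103), 106, 3),  # exactly 3: no fallback
            ((100,), 50, None),  # no pulse before the slice
            ((100, 103), 103, 3),  # 0 < 3 -> fallback
        ],
    )
    def test_examples(self, pulses, end, expected):
        assert assign_tap(np.array(pulses), end) == expected

    @settings(derandomize=True, max_examples=60)
    @given(
        data=st.lists(st.integers(3, 40), min_size=1, max_size=8),
        extra=st.integers(0, 50),
    )
    def test_label_points_at_a_real_pulse_and_respects_threshold(self, data, extra):
        pulses = np.cumsum(np.asarray(data))
        end = int(pulses[-1]) + extra
        tap = assign_tap(pulses, end)
        if tap is not None:
            assert end - tap in set(pulses.tolist())
            # below-threshold TAPs only occur when there is no earlier pulse
            if tap < 3:
                assert end - tap == pulses[0]


class TestMakeSlices:
    def _traj(self, x):
        return TranslocationTrajectory(0, np.arange(len(x)), np.asarray(x, float))

    def test_count_and_coverage(self):
        slices = make_slices(self._traj(np.zeros(40)), ell=6)
        assert len(slices) == 35  # T - 5
        # an interior time point belongs to exactly ell slices
        t = 20
        covering = [
            s for s in slices if s.end_time - 5 <= t <= s.end_time
        ]
        assert len(covering) == 6

    def test_linear_ramp_gives_constant_features(self):
        slices = make_slices(self._traj(0.3 * np.arange(30)), ell=6)
        for s in slices:
            np.testing.assert_allclose(s.features, 0.3)

    def test_interval_labels(self):
        pulses = PulseSequence(duration=40, pulse_times=(10, 25))
        slices = make_slices(self._traj(np.zeros(40)), ell=6, pulses=pulses)
        by_end = {s.end_time: s.label for s in slices}
        assert by_end[15] == 5
        assert by_end[26] == 16  # 26-25 = 1 < 3 -> previous pulse
        assert by_end[9] is None

    def test_too_short_trajectory(self):
        with pytest.raises(ValueError):
            make_slices(self._traj(np.zeros(4)), ell=6)


class TestSliceKNN:
    def test_single_neighbor_toy(self):
        X = np.array([[0.0, 0.0], [10.0, 10.0], [10.0, 11.0]])
        y = np.array(["A", "B", "B"])
        clf = SliceKNNClassifier(k=1).fit(X, y)
        assert clf.predict([[9.0, 9.0]])[0] == "B"

    def test_unanimous_neighbors(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (25, 3)), rng.normal(5, 0.1, (25, 3))])
        y = np.array([0] * 25 + [1] * 25)
        clf = SliceKNNClassifier(k=20).fit(X, y)
        assert clf.predict([[0.0, 0.0, 0.0]])[0] == 0
        assert clf.predict([[5.0, 5.0, 5.0]])[0] == 1

    def test_matches_bruteforce_oracle(self):
        """Predictions equal an all-pairs-distance oracle on random slices."""
        rng = np.random.default_rng(42)
        X = rng.normal(size=(600, 5))
        y = rng.integers(0, 6, size=600)
        queries = rng.normal(size=(200, 5))
        k = 20
        clf = SliceKNNClassifier(k=k).fit(X, y)
        pred = clf.predict(queries)
        for q, p in zip(queries, pred):
            d = np.sqrt(((X - q) ** 2).sum(axis=1))
            order = np.argsort(d, kind="stable")[:k]
            labels, counts = np.unique(y[order], return_counts=True)
            tied = labels[counts == counts.max()]
            if len(tied) == 1:
                expected = tied[0]
            else:
                means = [d[order][y[order] == lab].mean() for lab in tied]
                expected = tied[int(np.argmin(means))]
            assert p == expected

    def test_requires_enough_training_slices(self):
        with pytest.raises(ValueError):
            SliceKNNClassifier(k=20).fit(np.zeros((5, 3)), np.zeros(5))


class TestVotingAndDedup:
    def test_three_votes_agree(self):
        ends = np.array([13, 14, 15])
        taps = np.array([3, 4, 5])  # all vote for minute 10
        det = _count_interval_votes(ends, taps, t_d=5, vote_min=2, t_lo=0, t_hi=30)
        assert det.tolist() == [10]

    def test_single_vote_insufficient(self):
        det = _count_interval_votes(
            np.array([13]), np.array([3]), t_d=5, vote_min=2, t_lo=0, t_hi=30
        )
        assert det.size == 0

    def test_unreliable_taps_ignored(self):
        ends = np.arange(10, 20)
        taps = np.full(10, 9)  # outside {3,4,5}: no votes at all
        det = _count_interval_votes(ends, taps, t_d=5, vote_min=2, t_lo=0, t_hi=40)
        assert det.size == 0

    @pytest.mark.parametrize(
        "times,expected",
        [([10, 12], [10]), ([10, 13], [10, 13]), ([], []), ([5, 6, 7, 11], [5, 11])],
    )
    def test_dedup_examples(self, times, expected):
        assert dedup_detections(times).tolist() == expected

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.integers(0, 80), max_size=25))
    def test_dedup_spacing_subset_idempotent(self, times):
        out = dedup_detections(times)
        assert set(out.tolist()) <= set(times)
        if out.size > 1:
            assert np.diff(out).min() >= 3
        assert dedup_detections(out).tolist() == out.tolist()


class TestIntervalDecoder:
    def test_exact_recovery_on_noiseless_data(self, gap_pulses, noiseless_ensemble):
        _, _, xs = noiseless_ensemble
        decoder = IntervalPulseDecoder().fit(xs[:15], gap_pulses)
        detections = decoder.predict(xs[15:])
        t_max = xs[0].times[-1] - decoder.t_D
        expected = gap_pulses.times_array
        expected = expected[expected <= t_max]
        for det in detections.values():
            np.testing.assert_array_equal(det, expected)

    def test_no_lookahead_beyond_decision_window(self, gap_pulses, noisy_ensemble):
        """Masking values after t0 + t_D never changes the decision at t0."""
        _, _, xs = noisy_ensemble
        decoder = IntervalPulseDecoder().fit(xs[:30], gap_pulses)
        traj = xs[40]
        cut = 500
        truncated = TranslocationTrajectory(
            traj.track_id, traj.times[: cut + 1 - traj.times[0]],
            traj.x[: cut + 1 - traj.times[0]],
        )
        full = decoder.predict([traj])[traj.track_id]
        part = decoder.predict([truncated])[traj.track_id]
        horizon = cut - decoder.t_D
        np.testing.assert_array_equal(full[full <= horizon], part[part <= horizon])

    def test_sklearn_param_interface(self):
        decoder = IntervalPulseDecoder(k=7, t_D=4)
        assert decoder.get_params() == {"k": 7, "t_D": 4, "vote_min": 2}
        decoder.set_params(k=20)
        assert decoder.k == 20


class TestBinaryDecoder:
    class _Stub:
        def __init__(self, label):
            self.label = label

        def predict(self, X):
            return np.full(len(X), self.label, dtype=int)

    @pytest.mark.parametrize(
        "preds,expected", [((1, 1, 1), 1), ((1, 0, 0), 0), ((1, 1, 0), 1), ((0, 0, 0), 0)]
    )
    def test_hard_voting_truth_table(self, preds, expected):
        from pulsecap import BinaryPulseDecoder

        decoder = BinaryPulseDecoder()
        decoder.classifiers_ = [self._Stub(p) for p in preds]
        decoder.slots_ = np.array([10])
        traj = TranslocationTrajectory(0, np.arange(0, 20), np.zeros(20))
        out = decoder.predict([traj])
        assert out[0][10] == expected

    def test_noiseless_binary_recovery(self):
        from pulsecap import (
            BinaryPulseDecoder,
            SimulationParams,
            make_binary_sequence,
            normalize_trajectory,
            simulate_experiment,
        )

        seq = make_binary_sequence(10)
        params = SimulationParams.noiseless()
        raws, _ = simulate_experiment(seq, 30, params, seed=12)
        xs = [normalize_trajectory(r) for r in raws]
        decoder = BinaryPulseDecoder().fit(xs[:15], seq)
        out = decoder.predict(xs[15:])
        digit = {int(s): int(s in set(seq.pulse_times)) for s in decoder.slots_}
        for track_slots in out.values():
            assert track_slots  # at least one scored slot
            for slot, det in track_slots.items():
                assert det == digit[slot]
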