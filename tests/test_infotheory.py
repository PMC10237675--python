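"""Entropy tables, bitrate, loss decomposition, kNN neighborhood estimator."""

import numpy as np
import pytest

from pulsecap import (
    ConfusionMatrix,
    IntervalPulseDecoder,
    bitrate,
    build_confusion,
    build_contingency,
    classify_errors,
    cond_entropy_confusion,
    cond_entropy_contingency,
    decompose_losses,
    neighborhood_entropy,
    per_cell_bitrates,
    recfree_bitrate,
    recfree_cond_entropy,
    resample_estimate,
)
from pulsecap.infotheory import digit_span, digits_from_times


class TestConfusion:
    def test_perfect_reconstruction_has_no_fp_fn(self):
        s = [np.array([1, 0, 0, 1, 0])]
        m = build_confusion(s, s)
        assert m.fp == 0.0 and m.fn == 0.0
        assert cond_entropy_confusion(m) == 0.0

    def test_hand_counted_joint(self):
        m = build_confusion([np.array([1, 0, 1, 0])], [np.array([1, 0, 0, 0])])
        assert (m.tp, m.tn, m.fn, m.fp) == (0.25, 0.5, 0.25, 0.0)

    def test_independent_uniform_gives_one_bit(self):
        m = ConfusionMatrix(0.25, 0.25, 0.25, 0.25)
        assert cond_entropy_confusion(m) == pytest.approx(1.0)

    def test_averaged_confidence_worked_example(self):
        """p_a = 3/4 average confidence transmits ~3.8 of 20 bits, while a
        receiver who knows which half of the digits is perfect gets 10."""
        m = ConfusionMatrix(tp=3 / 8, fn=1 / 8, fp=1 / 8, tn=3 / 8)
        h = cond_entropy_confusion(m)
        assert h == pytest.approx(0.8112781, abs=1e-6)
        assert 20 * (1 - h) == pytest.approx(3.774, abs=1e-3)
        perfect = cond_entropy_confusion(ConfusionMatrix(0.5, 0.0, 0.0, 0.5))
        useless = cond_entropy_confusion(ConfusionMatrix(0.25, 0.25, 0.25, 0.25))
        assert 10 * (1 - perfect) + 10 * (1 - useless) == pytest.approx(10.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(0.5, 0.5, 0.5, 0.5)
        with pytest.raises(ValueError):
            build_confusion([np.zeros(3)], [np.zeros(4)])


class TestContingency:
    def test_on_time_reconstruction_is_lossless(self):
        s = digits_from_times([10, 20, 30], (5, 35))
        t = build_contingency([s], [s])
        assert cond_entropy_contingency(t) == pytest.approx(0.0, abs=1e-12)
        assert t.spurious_mass == 0.0

    def test_consistent_one_minute_delay_is_lossless(self):
        """A deterministic 1-min shift maps pulses to pattern (0,0,1),
        which still identifies them uniquely."""
        s = digits_from_times([10, 20, 30], (5, 35))
        r = digits_from_times([11, 21, 31], (5, 35))
        t = build_contingency([s], [r])
        assert t.pattern_prob((0, 0, 1), 1) > 0
        assert t.pattern_prob((0, 1, 0), 1) == 0.0
        assert cond_entropy_contingency(t) == pytest.approx(0.0, abs=1e-12)

    def test_no_detections_only_empty_pattern(self):
        s = digits_from_times([10, 20], (5, 25))
        r = np.zeros_like(s)
        t = build_contingency([s], [r])
        assert t.probs[[i for i in range(8) if i != 0]].sum() == 0.0

    def test_independent_reconstruction_gives_marginal_entropy(self):
        """Weighted enumeration: R independent of S leaves H(S_d) bits."""
        atoms = [np.array(v) for v in ([0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1])]
        S_list, R_list, w = [], [], []
        for s in atoms:
            for r in atoms:
                S_list.append(s)
                R_list.append(r)
                w.append(1 / 16)
        t = build_contingency(S_list, R_list, weights=w)
        assert cond_entropy_contingency(t) == pytest.approx(
            -(0.25 * np.log2(0.25) + 0.75 * np.log2(0.75))
        )

    def test_spacing_violation_rejected_in_strict_mode(self):
        s = digits_from_times([10], (5, 15))
        r = digits_from_times([9, 11], (5, 15))
        with pytest.raises(ValueError):
            build_contingency([s], [r])
        build_contingency([s], [r], strict=False)  # tolerated when pooling


class TestBitrate:
    def test_perfect_binary_channel(self):
        est = bitrate(h_S=0.1, H_cond_per_digit=0.0, digits_per_min=0.1)
        assert est.bitrate == pytest.approx(6.0)  # 19 bits / 190 min

    def test_zero_when_loss_equals_input(self):
        assert bitrate(0.2, 1.0, 0.2).bitrate == pytest.approx(0.0)

    def test_rate_identity(self):
        est = bitrate(0.156, 0.03)
        assert est.bitrate == pytest.approx(
            60 * (est.input_entropy_rate - est.cond_entropy_rate), abs=1e-9
        )


class TestClassifyErrors:
    def test_deferred_not_decomposed_into_miss_plus_false(self):
        s = digits_from_times([50], (40, 60))
        r = digits_from_times([51], (40, 60))
        errors = classify_errors(s, r)
        assert errors["deferred"] == [(10, 11)]
        assert errors["missed"] == [] and errors["false"] == []

    def test_missed_and_false(self):
        s = digits_from_times([50], (40, 80))
        errors = classify_errors(s, np.zeros_like(s))
        assert errors["missed"] == [10]
        r = digits_from_times([70], (40, 80))
        errors = classify_errors(np.zeros_like(r), r)
        assert errors["false"] == [30]

    def test_precondition_on_input_spacing(self):
        with pytest.raises(ValueError):
            classify_errors(np.array([0, 1, 1, 0]), np.zeros(4))


class TestDecomposeLosses:
    def _toy(self):
        span = (0, 60)
        s = digits_from_times([10, 25, 40], span)
        r = digits_from_times([11, 40, 52], span)  # deferred, missed, false
        return s, r

    def test_contributions_sum_to_total(self):
        s, r = self._toy()
        h_S = 0.15
        out = decompose_losses([s], [r], h_S)
        total = out["false"] + out["missed"] + out["inaccurate"]
        assert total == pytest.approx(out["total"], abs=1e-9)
        assert out["total"] == pytest.approx(
            h_S * 60
            - bitrate(h_S, cond_entropy_contingency(build_contingency([s], [r]))).bitrate,
            abs=1e-9,
        )

    def test_pure_false_detections_attributed_fully(self):
        span = (0, 60)
        s = digits_from_times([10, 30], span)
        r = digits_from_times([10, 30, 50], span)
        out = decompose_losses([s], [r], 0.15)
        assert out["false"] == pytest.approx(out["total"], abs=1e-9)
        assert out["missed"] == pytest.approx(0.0, abs=1e-9)

    def test_binary_two_order_average_matches_hand_enumeration(self):
        """One miss + one false: the average over both correction orders
        equals the mean of the two orderings enumerated by hand."""
        s = [np.array([1, 0, 1, 0, 0, 1, 0, 0])]
        r = [np.array([0, 0, 1, 0, 1, 1, 0, 0])]  # missed d0, false d4
        h_S, dpm = 0.1, 0.1

        def bits(rr):
            return bitrate(
                h_S, cond_entropy_confusion(build_confusion(s, [rr])), dpm
            ).bitrate

        r0 = r[0]
        fix_false = r0.copy(); fix_false[4] = 0
        fix_miss = r0.copy(); fix_miss[0] = 1
        both = r0.copy(); both[4] = 0; both[0] = 1
        # order false-then-missed and missed-then-false
        false_first = (bits(fix_false) - bits(r0), bits(both) - bits(fix_false))
        miss_first = (bits(both) - bits(fix_miss), bits(fix_miss) - bits(r0))
        expected_false = (false_first[0] + miss_first[0]) / 2
        expected_miss = (false_first[1] + miss_first[1]) / 2
        out = decompose_losses(s, r, h_S, digits_per_min=dpm, mode="binary")
        assert out["false"] == pytest.approx(expected_false, abs=1e-12)
        assert out["missed"] == pytest.approx(expected_miss, abs=1e-12)
        assert out["false"] + out["missed"] == pytest.approx(out["total"], abs=1e-12)


class TestRecfree:
    def test_neighborhood_entropy_values(self):
        assert neighborhood_entropy(20, 0) == 0.0
        assert neighborhood_entropy(10, 10) == pytest.approx(
            1.0 + 1.0 / (40 * np.log(2)), abs=1e-9
        )
        with pytest.raises(ValueError):
            neighborhood_entropy(5, 5, k=20)

    def test_pure_neighborhoods_give_zero_conditional_entropy(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.01, (30, 7)), rng.normal(10, 0.01, (30, 7))])
        labels = np.array([0] * 30 + [1] * 30)
        assert recfree_cond_entropy(X, labels, k=20) == 0.0

    def test_noiseless_ensemble_recovers_input_entropy(
        self, gap_pulses, noiseless_ensemble
    ):
        _, _, xs = noiseless_ensemble
        est = recfree_bitrate(xs, gap_pulses)
        h = gap_pulses.protocol.entropy_rate * 60
        assert est.bitrate == pytest.approx(h, rel=0.01)


class TestResampleEstimate:
    def test_zero_noise_gives_zero_dispersion(self, gap_pulses, noiseless_ensemble):
        _, _, xs = noiseless_ensemble
        est = resample_estimate(xs, gap_pulses, n_rep=3, seed=1, with_losses=False)
        assert est.resamples["sd"] == pytest.approx(0.0, abs=1e-9)

    def test_same_master_seed_reproduces(self, gap_pulses, noisy_ensemble):
        _, _, xs = noisy_ensemble
        a = resample_estimate(xs, gap_pulses, n_rep=2, seed=5, with_losses=False)
        b = resample_estimate(xs, gap_pulses, n_rep=2, seed=5, with_losses=False)
        assert a.bitrate == b.bitrate
        assert a.resamples["values"] == b.resamples["values"]

    def test_recfree_dispersion_reported(self, gap_pulses, noisy_ensemble):
        _, _, xs = noisy_ensemble
        est = resample_estimate(xs, gap_pulses, method="recfree", n_rep=3, seed=2)
        assert est.resamples["n"] == 3
        assert est.resamples["sd"] >= 0.0
        assert est.bitrate == pytest.approx(est.resamples["mean"])


class TestPerCellBitrates:
    def test_negative_values_occur_for_uninformative_cells(
        self, gap_pulses, noisy_ensemble
    ):
        """Cells carrying no information get a per-digit bound equal to the
        marginal digit entropy, which exceeds the input entropy rate here,
        so their bitrate estimate is negative."""
        _, _, xs = noisy_ensemble
        decoder = IntervalPulseDecoder().fit(xs[: len(xs) // 2], gap_pulses)
        flat = [
            x.__class__(track_id=9000 + i, times=x.times, x=np.zeros_like(x.x))
            for i, x in enumerate(xs[:3])
        ]
        values = per_cell_bitrates(decoder, list(xs[len(xs) // 2 :]) + flat, gap_pulses)
        assert np.isfinite(values).all()
        assert values.min() < 0


class TestDispersionScaling:
    def test_resample_sd_shrinks_with_ensemble_size(self):
        """Dispersion over subsamples shrinks roughly as 1/sqrt(n_cells)
        (checked as a strict ordering between 60- and 240-cell ensembles)."""
        from pulsecap import (
            SimulationParams,
            draw_interval_sequence,
            normalize_trajectory,
            select_tracks,
            simulate_experiment,
        )

        seq = draw_interval_sequence(10, 20, 480, seed=61)
        params = SimulationParams()
        sds = {}
        for n in (60, 240):
            trajs, _ = simulate_experiment(seq, n, params, seed=62)
            xs = [normalize_trajectory(t) for t in select_tracks(trajs, f=0.2)]
            est = resample_estimate(xs, seq, method="recfree", n_rep=8, seed=63)
            sds[n] = est.resamples["sd"]
        assert sds[240] < sds[60] / 1.4
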