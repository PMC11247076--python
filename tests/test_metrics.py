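import numpy as np
import pytest

from arousalkit.io_psg import EventList, Hypnogram
from arousalkit.metrics import (
    ConfusionCounts,
    UndefinedMetricError,
    arousal_index,
    evaluate_record,
    evaluate_set,
    match_events,
    micro_f1,
    sample_auprc,
)
from conftest import brute_force_auprc


def _ev(*pairs):
    return EventList([(float(o), float(d), "Arousal") for o, d in pairs])


class TestSampleAuprc:
    def test_perfect_ranking(self):
        y = np.array([0, 0, 1, 1, 0, 1])
        p = np.array([0.1, 0.2, 0.8, 0.9, 0.3, 0.7])
        assert sample_auprc(p, y) == 1.0

    def test_constant_scores_give_prevalence(self):
        y = np.array([0] * 70 + [1] * 30)
        p = np.full(100, 0.42)
        assert sample_auprc(p, y) == pytest.approx(0.3)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            sample_auprc(np.array([0.1, 0.9]), np.array([1, 1]))

    @pytest.mark.parametrize("n", [10, 50, 200])
    def test_matches_exhaustive_threshold_oracle(self, n, rng):
        for _ in range(10):
            y = (rng.random(n) < 0.3).astype(int)
            if y.min() == y.max():
                continue
            p = rng.random(n)
            assert sample_auprc(p, y) == pytest.approx(brute_force_auprc(p, y), abs=1e-12)

    def test_anti_ranked_matches_oracle(self):
        y = np.array([1, 1, 0, 0])
        p = np.array([0.1, 0.2, 0.8, 0.9])
        assert sample_auprc(p, y) == pytest.approx(brute_force_auprc(p, y), abs=1e-12)


class TestMatchEvents:
    def test_two_predictions_on_one_truth(self):
        c = match_events(_ev((10, 10)), _ev((12, 3), (18, 4)))
        assert (c.tp, c.fn, c.fp) == (1, 1, 0)

    def test_one_prediction_over_two_truths(self):
        c = match_events(_ev((10, 5), (20, 5)), _ev((12, 14)))
        assert (c.tp, c.fp, c.fn) == (2, 1, 0)

    def test_plain_miss(self):
        c = match_events(_ev((10, 5)), _ev())
        assert (c.tp, c.fp, c.fn) == (0, 0, 1)

    def test_plain_false_alarm(self):
        c = match_events(_ev(), _ev((10, 5)))
        assert (c.tp, c.fp, c.fn) == (0, 1, 0)

    def test_touching_intervals_do_not_overlap(self):
        # half-open: [10,15) and [15,20) share no sample
        c = match_events(_ev((10, 5)), _ev((15, 5)))
        assert (c.tp, c.fp, c.fn) == (0, 1, 1)

    def test_overlap_within_one_list_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            match_events(_ev((10, 10), (15, 10)), _ev())

    def test_role_swap_exchanges_fp_and_fn_in_simple_cases(self):
        # one-to-one overlaps plus misses: swapping roles swaps FP <-> FN
        truth, pred = _ev((10, 5), (30, 5), (60, 5)), _ev((12, 5), (45, 5))
        a = match_events(truth, pred)
        b = match_events(pred, truth)
        assert (a.tp, a.fp, a.fn) == (b.tp, b.fn, b.fp)

    def test_count_conservation_random_pairs(self, rng):
        # tp <= |truth|; tp + fn exceeds |truth| exactly by the number of
        # extra predictions absorbed by multi-covered truths
        for _ in range(200):
            def rand_events():
                n = int(rng.integers(0, 8))
                starts = np.sort(rng.uniform(0, 500, n))
                evs, last = [], 0.0
                for s in starts:
                    s = max(s, last)
                    d = float(rng.uniform(3, 20))
                    if s + d > 600:
                        break
                    evs.append((s, d))
                    last = s + d + 0.5
                return _ev(*evs)

            truth, pred = rand_events(), rand_events()
            c = match_events(truth, pred)
            k = np.zeros(len(truth), dtype=int)
            for i, (tlo, thi) in enumerate(truth.intervals()):
                for plo, phi in pred.intervals():
                    if plo < thi and tlo < phi:
                        k[i] += 1
            assert c.tp <= len(truth)
            assert c.tp + c.fn == len(truth) + np.maximum(k - 1, 0).sum()


class TestMicroF1:
    def test_formula(self):
        assert micro_f1([ConfusionCounts(8, 2, 2)]) == pytest.approx(0.8)

    def test_pooling_equals_merged_record(self):
        split = [ConfusionCounts(4, 1, 1), ConfusionCounts(4, 1, 1)]
        pooled = [ConfusionCounts(8, 2, 2)]
        assert micro_f1(split) == micro_f1(pooled) == pytest.approx(0.8)

    def test_perfect(self):
        assert micro_f1([ConfusionCounts(5, 0, 0)]) == 1.0

    def test_undefined_on_empty_counts(self):
        with pytest.raises(UndefinedMetricError):
            micro_f1([ConfusionCounts(0, 0, 0)])

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0)


class TestArousalIndex:
    def test_definition(self):
        h = Hypnogram(["N2"] * 240)  # 2 h of sleep
        assert arousal_index(_ev(*[(i * 100, 5) for i in range(60)]), h) == 30.0

    def test_zero_events(self):
        assert arousal_index(_ev(), Hypnogram(["N2"] * 120)) == 0.0

    def test_clinical_scale_night(self):
        # 160 events over 360 min of sleep: ArI ~ 26.7/h, a plausible
        # clinical average
        h = Hypnogram(["N2"] * 720)
        e = _ev(*[(i * 130, 5) for i in range(160)])
        assert arousal_index(e, h) == pytest.approx(26.6667, abs=1e-3)

    def test_zero_sleep_undefined(self):
        with pytest.raises(UndefinedMetricError):
            arousal_index(_ev((10, 5)), Hypnogram(["W"] * 100))


class TestEvaluate:
    H = Hypnogram(["N2"] * 120)  # 1 h sleep

    def test_perfect_prediction(self):
        truth = _ev((10, 5), (100, 5))
        rows = [
            evaluate_record(f"r{i}", truth, truth, self.H) for i in range(2)
        ]
        rep = evaluate_set(rows)
        assert rep.f1 == 1.0
        assert rep.ari_error_mean == 0.0
        assert rep.ari_pearson_r is None  # zero variance across records

    def test_affine_ari_shift(self):
        rows = []
        for i, n_extra in enumerate((0, 1, 2, 3)):
            truth = _ev(*[(100 * k + 10, 5) for k in range(3 + i)])
            pred = _ev(*[(100 * k + 12, 5) for k in range(3 + i)],
                       *[(2000 + 50 * j, 5) for j in range(n_extra + 2)])
            rows.append(evaluate_record(f"r{i}", truth, pred, self.H))
        rep = evaluate_set(rows)
        diffs = [r.ari_diff for r in rep.rows]
        errs = [r.ari_error for r in rep.rows]
        assert np.all(np.array(errs) == np.abs(diffs))
        assert rep.ari_pearson_r == pytest.approx(1.0)

    def test_median_iqr_match_order_statistics(self, rng):
        rows = []
        for i in range(11):
            n_t = int(rng.integers(3, 20))
            n_p = int(rng.integers(3, 20))
            truth = _ev(*[(150 * k, 5) for k in range(n_t)])
            pred = _ev(*[(150 * k + 50, 5) for k in range(n_p)])
            rows.append(evaluate_record(f"r{i}", truth, pred, Hypnogram(["N2"] * 600)))
        rep = evaluate_set(rows)
        errs = np.array([r.ari_error for r in rows])
        assert rep.ari_error_median == pytest.approx(np.percentile(errs, 50))
        assert rep.ari_error_iqr[0] == pytest.approx(np.percentile(errs, 25))
        assert rep.ari_error_iqr[1] == pytest.approx(np.percentile(errs, 75))

    def test_single_record_set_rejected(self):
        truth = _ev((10, 5))
        row = evaluate_record("r", truth, truth, self.H)
        with pytest.raises(UndefinedMetricError):
            evaluate_set([row])
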