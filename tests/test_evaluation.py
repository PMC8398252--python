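import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ecgbeats as eb
from ecgbeats.evaluation import ConfusionMatrix, confusion, metrics


def _brute_force_counts(truth, pred, cls):
    tp = sum(1 for t, p in zip(truth, pred) if t == cls and p == cls)
    fn = sum(1 for t, p in zip(truth, pred) if t == cls and p != cls)
    fp = sum(1 for t, p in zip(truth, pred) if t != cls and p == cls)
    tn = sum(1 for t, p in zip(truth, pred) if t != cls and p != cls)
    return tp, fn, fp, tn


class TestConfusion:
    def test_perfect_predictions_diagonal(self):
        labels = ["N", "S", "V", "F", "Q", "N", "V"]
        cm = confusion(labels, labels)
        assert np.trace(cm.counts) == 7
        assert cm.counts.sum() == 7

    def test_empty_inputs_all_zero(self):
        cm = confusion([], [])
        assert cm.counts.sum() == 0

    def test_three_beat_hand_enumeration(self):
        cm = confusion(["N", "N", "S"], ["N", "V", "S"])
        assert cm.counts[0, 0] == 1  # N -> N
        assert cm.counts[0, 2] == 1  # N -> V
        assert cm.counts[1, 1] == 1  # S -> S
        assert cm.counts.sum() == 3

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            confusion(["N"], ["N", "S"])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="X"):
            confusion(["N", "X"], ["N", "N"])


class TestMetrics:
    def test_diagonal_matrix_all_metrics_100(self):
        cm = ConfusionMatrix(np.diag([10, 5, 3, 2, 1]))
        rep = metrics(cm)
        assert rep.acc == 100.0
        for c in eb.CLASS_ORDER:
            assert rep.se[c] == 100.0
            assert rep.plus_p[c] == 100.0
            assert rep.f1[c] == 100.0

    def test_three_beat_worked_example(self):
        rep = eb.evaluate(["N", "N", "S"], ["N", "V", "S"])
        assert rep.se["N"] == pytest.approx(50.0)
        assert rep.plus_p["N"] == pytest.approx(100.0)
        assert rep.f1["N"] == pytest.approx(66.667, abs=1e-3)
        assert rep.acc == pytest.approx(66.667, abs=1e-3)

    def test_zero_support_class_reported_as_nan_and_flagged(self):
        rep = eb.evaluate(["N", "N", "V"], ["N", "N", "V"])
        assert math.isnan(rep.se["F"])
        assert "F" in rep.undefined
        # macro means exclude the undefined classes
        assert rep.macro_se == pytest.approx(100.0)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            metrics(ConfusionMatrix(np.zeros((5, 5), dtype=int)))

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 21))
        truth = [eb.CLASS_ORDER[i] for i in rng.integers(0, 5, n)]
        pred = [eb.CLASS_ORDER[i] for i in rng.integers(0, 5, n)]
        rep = eb.evaluate(truth, pred)
        for cls in eb.CLASS_ORDER:
            tp, fn, fp, tn = _brute_force_counts(truth, pred, cls)
            if tp + fn:
                assert rep.se[cls] == pytest.approx(tp / (tp + fn) * 100)
            else:
                assert math.isnan(rep.se[cls])
            if tp + fp:
                assert rep.plus_p[cls] == pytest.approx(tp / (tp + fp) * 100)
            if 2 * tp + fp + fn:
                assert rep.f1[cls] == pytest.approx(
                    2 * tp / (2 * tp + fp + fn) * 100
                )
            assert rep.acc_ovr[cls] == pytest.approx((tp + tn) / n * 100)
        correct = sum(1 for t, p in zip(truth, pred) if t == p)
        assert rep.acc == pytest.approx(correct / n * 100)

    def test_tp_sums_and_support_partition(self):
        rng = np.random.default_rng(10)
        truth = [eb.CLASS_ORDER[i] for i in rng.integers(0, 5, 50)]
        pred = [eb.CLASS_ORDER[i] for i in rng.integers(0, 5, 50)]
        cm = confusion(truth, pred)
        rep = metrics(cm)
        assert sum(rep.support.values()) == 50
        assert sum(cm.counts[i, i] for i in range(5)) == np.trace(cm.counts)

    def test_accuracy_invariant_to_class_permutation(self):
        rng = np.random.default_rng(11)
        truth = [eb.CLASS_ORDER[i] for i in rng.integers(0, 5, 40)]
        pred = [eb.CLASS_ORDER[i] for i in rng.integers(0, 5, 40)]
        rep1 = eb.evaluate(truth, pred)
        relabel = dict(zip("NSVFQ", "QVFSN"))
        rep2 = eb.evaluate(
            [relabel[t] for t in truth], [relabel[p] for p in pred]
        )
        assert rep1.acc == pytest.approx(rep2.acc)

    def test_f1_identity_where_defined(self):
        rng = np.random.default_rng(12)
        truth = [eb.CLASS_ORDER[i] for i in rng.integers(0, 5, 60)]
        pred = [eb.CLASS_ORDER[i] for i in rng.integers(0, 5, 60)]
        rep = eb.evaluate(truth, pred)
        for c in eb.CLASS_ORDER:
            se, pp = rep.se[c], rep.plus_p[c]
            if not (math.isnan(se) or math.isnan(pp)) and se + pp > 0:
                assert rep.f1[c] == pytest.approx(2 * se * pp / (se + pp))

    def test_report_serializes_nan_as_null(self):
        rep = eb.evaluate(["N", "N"], ["N", "N"])
        d = rep.to_dict()
        assert d["se"]["S"] is None
        import json

        json.dumps(d)  # must be valid JSON

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(np.full((5, 5), -1))


_labels = st.lists(st.sampled_from(eb.CLASS_ORDER), min_size=1, max_size=20)


class TestMetricProperties:
    @settings(max_examples=50, derandomize=True)
    @given(truth=_labels, pred=_labels)
    def test_sensitivity_matches_pair_counting_for_any_labels(self, truth, pred):
        n = min(len(truth), len(pred))
        truth, pred = truth[:n], pred[:n]
        rep = eb.evaluate(truth, pred)
        for cls in eb.CLASS_ORDER:
            tp, fn, fp, tn = _brute_force_counts(truth, pred, cls)
            if tp + fn:
                assert rep.se[cls] == pytest.approx(tp / (tp + fn) * 100)
            else:
                assert math.isnan(rep.se[cls])
            assert rep.support[cls] == tp + fn
        correct = sum(1 for t, p in zip(truth, pred) if t == p)
        assert rep.acc == pytest.approx(correct / n * 100)

    @settings(max_examples=50, derandomize=True)
    @given(truth=_labels)
    def test_self_prediction_is_perfect(self, truth):
        rep = eb.evaluate(truth, truth)
        assert rep.acc == 100.0
        for cls in set(truth):
            assert rep.se[cls] == 100.0 and rep.plus_p[cls] == 100.0
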