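"""Metric formalism: one-vs-rest confusion counts, the three F1 averaging
schemes, balanced accuracy, and threshold-sweep ROC/PR curves — checked
against hand arithmetic, a brute-force pair-ordering oracle, and
scikit-learn as an independent implementation."""

import numpy as np
import pytest
import sklearn.metrics as skm
from hypothesis import given, settings
from hypothesis import strategies as st

from deepcytometry import metrics as m

TRUE = np.array([0, 0, 1, 2])
PRED = np.array([0, 1, 1, 2])


class TestConfusionCounts:
    def test_hand_tally(self):
        c = m.confusion_counts(TRUE, PRED)
        assert (c.tp[0], c.fn[0], c.fp[0]) == (1, 1, 0)
        assert (c.tp[1], c.fp[1], c.fn[1]) == (1, 1, 0)
        assert (c.tp[2], c.fp[2], c.fn[2]) == (1, 0, 0)

    def test_perfect_predictions(self):
        c = m.confusion_counts(TRUE, TRUE)
        assert not c.fp.any() and not c.fn.any()

    def test_tp_sum_equals_correct_count(self, rng):
        yt = rng.integers(0, 3, 100)
        yp = rng.integers(0, 3, 100)
        c = m.confusion_counts(yt, yp)
        assert c.tp.sum() == np.sum(yt == yp)

    def test_counts_partition_n(self, rng):
        yt = rng.integers(0, 3, 57)
        yp = rng.integers(0, 3, 57)
        c = m.confusion_counts(yt, yp)
        assert np.all(c.tp + c.fp + c.fn + c.tn == 57)
        assert c.condition_positive.sum() == 57

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            m.confusion_counts([0, 3], [0, 1])


class TestClasswiseMetrics:
    def test_hand_arithmetic(self):
        c = m.ConfusionCounts(tp=np.array([8]), fp=np.array([2]),
                              fn=np.array([2]), tn=np.array([88]), n=100)
        precision, recall, f1, flags = m.classwise_metrics(c)
        assert (precision[0], recall[0], f1[0]) == pytest.approx((0.8,) * 3)
        assert not flags[0]

    def test_degenerate_class_convention(self):
        c = m.ConfusionCounts(tp=np.array([0]), fp=np.array([0]),
                              fn=np.array([5]), tn=np.array([5]), n=10)
        precision, recall, f1, flags = m.classwise_metrics(c)
        assert (precision[0], recall[0], f1[0]) == (0.0, 0.0, 0.0)
        assert flags[0]

    def test_single_class_all_correct(self):
        c = m.ConfusionCounts(tp=np.array([10]), fp=np.array([0]),
                              fn=np.array([0]), tn=np.array([0]), n=10)
        precision, recall, f1, _ = m.classwise_metrics(c)
        assert (precision[0], recall[0], f1[0]) == (1.0, 1.0, 1.0)


class TestAveragedF1:
    def test_micro_f1_equals_accuracy_on_worked_example(self):
        c = m.confusion_counts(TRUE, PRED)
        _, _, micro_f1 = m.averaged_f1(c, "micro")
        assert micro_f1 == pytest.approx(0.75)
        acc, _ = m.accuracy_and_bacc(TRUE, PRED)
        assert micro_f1 == pytest.approx(acc)

    def test_prevalence_weights(self):
        yt = np.array([0] * 5 + [1] * 3 + [2] * 2)
        c = m.confusion_counts(yt, yt)
        assert np.allclose(c.weights, [0.5, 0.3, 0.2])

    def test_equal_counts_make_macro_equal_weighted(self, rng):
        yt = np.repeat([0, 1, 2], 20)
        yp = rng.integers(0, 3, 60)
        c = m.confusion_counts(yt, yp)
        assert m.averaged_f1(c, "macro") == pytest.approx(
            m.averaged_f1(c, "weighted"))

    @pytest.mark.parametrize("scheme,sk_avg", [
        ("micro", "micro"), ("macro", "macro"), ("weighted", "weighted")])
    def test_matches_sklearn(self, rng, scheme, sk_avg):
        yt = rng.integers(0, 3, 200)
        yp = rng.integers(0, 3, 200)
        c = m.confusion_counts(yt, yp)
        p, r, f1 = m.averaged_f1(c, scheme)
        assert p == pytest.approx(
            skm.precision_score(yt, yp, average=sk_avg, zero_division=0))
        assert r == pytest.approx(
            skm.recall_score(yt, yp, average=sk_avg, zero_division=0))
        assert f1 == pytest.approx(
            skm.f1_score(yt, yp, average=sk_avg, zero_division=0))

    @given(st.integers(0, 10_000))
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_micro_f1_is_accuracy_and_weights_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 60))
        yt = rng.integers(0, 3, n)
        yp = rng.integers(0, 3, n)
        c = m.confusion_counts(yt, yp)
        _, _, micro_f1 = m.averaged_f1(c, "micro")
        assert micro_f1 == pytest.approx(np.mean(yt == yp))
        assert c.weights.sum() == pytest.approx(1.0)


class TestAccuracyAndBacc:
    def test_worked_example(self):
        acc, bacc = m.accuracy_and_bacc(TRUE, PRED)
        assert acc == pytest.approx(0.75)
        # per-class recalls (0.5, 1, 1) -> mean 0.8333...
        assert bacc == pytest.approx(5.0 / 6.0)

    def test_perfect(self):
        acc, bacc = m.accuracy_and_bacc(TRUE, TRUE)
        assert (acc, bacc) == (1.0, 1.0)

    def test_matches_sklearn_balanced_accuracy(self, rng):
        yt = rng.integers(0, 3, 150)
        yp = rng.integers(0, 3, 150)
        _, bacc = m.accuracy_and_bacc(yt, yp)
        assert bacc == pytest.approx(skm.balanced_accuracy_score(yt, yp))

    def test_binary_form(self):
        assert m.binary_bacc(0.9, 0.7) == pytest.approx(0.8)


def brute_force_auc(scores, labels):
    """Fraction of (positive, negative) pairs ranked correctly; ties 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestCurves:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert m.curve(scores, labels, "roc").area == pytest.approx(1.0)
        assert m.curve(scores, labels, "pr").area == pytest.approx(1.0)

    def test_hand_counted_auc(self):
        scores = np.array([0.9, 0.8, 0.4, 0.3])
        labels = np.array([1, 0, 1, 0])
        # 3 of the 4 positive-negative pairs are ordered correctly
        assert m.curve(scores, labels, "roc").area == pytest.approx(0.75)

    def test_label_inversion_symmetry(self, rng):
        scores = rng.normal(size=30)
        labels = rng.integers(0, 2, 30)
        labels[:2] = [0, 1]
        a = m.curve(scores, labels, "roc").area
        b = m.curve(scores, 1 - labels, "roc").area
        assert a + b == pytest.approx(1.0)

    def test_trapezoid_auc_equals_pair_ordering_oracle(self):
        """On every instance (with heavy ties) the trapezoidal area equals
        the brute-force probability of correct pair ordering."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(4, 51))
            scores = np.round(rng.random(n), 1)  # force ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                labels[0] = 1 - labels[0]
            auc = m.curve(scores, labels, "roc").area
            assert auc == pytest.approx(brute_force_auc(scores, labels))

    def test_matches_sklearn_on_continuous_scores(self, rng):
        scores = rng.normal(size=80)
        labels = rng.integers(0, 2, 80)
        labels[:2] = [0, 1]
        assert m.curve(scores, labels, "roc").area == pytest.approx(
            skm.roc_auc_score(labels, scores))
        assert m.curve(scores, labels, "pr").area == pytest.approx(
            skm.average_precision_score(labels, scores))

    def test_single_class_roc_undefined(self):
        with pytest.raises(m.UndefinedCurveError):
            m.curve(np.array([0.2, 0.4]), np.array([1, 1]), "roc")


class TestAveragedCurves:
    @staticmethod
    def _problem(rng, n=60):
        y = rng.integers(0, 3, n)
        scores = rng.random((n, 3))
        scores[np.arange(n), y] += 0.5  # informative but imperfect
        scores /= scores.sum(axis=1, keepdims=True)
        return scores, y

    def test_perfectly_separated_gives_unit_area(self):
        y = np.array([0, 1, 2, 0, 1, 2])
        scores = np.zeros((6, 3))
        scores[np.arange(6), y] = 1.0
        for scope in ("micro", "macro"):
            assert m.averaged_curve(scores, y, scope, "roc").area \
                == pytest.approx(1.0)

    def test_micro_equals_pooled_pairs(self, rng):
        scores, y = self._problem(rng)
        onehot = np.zeros_like(scores, dtype=int)
        onehot[np.arange(len(y)), y] = 1
        micro = m.averaged_curve(scores, y, "micro", "roc")
        assert micro.area == pytest.approx(
            brute_force_auc(scores.ravel(), onehot.ravel()))

    def test_macro_roc_matches_sklearn_ovr(self, rng):
        scores, y = self._problem(rng)
        macro = m.averaged_curve(scores, y, "macro", "roc")
        expected = skm.roc_auc_score(y, scores, multi_class="ovr",
                                     average="macro")
        assert macro.area == pytest.approx(expected)

    def test_degenerate_class_skipped_with_warning(self, rng):
        y = rng.integers(0, 2, 40)  # class 2 never appears
        y[:2] = [0, 1]
        scores = rng.random((40, 3))
        with pytest.warns(RuntimeWarning):
            result = m.averaged_curve(scores, y, "macro", "roc")
        assert 0.0 <= result.area <= 1.0


class TestIsoContours:
    @pytest.mark.parametrize("level", [0.5, 0.7, 0.9])
    def test_iso_bacc_points_have_constant_bacc(self, level):
        fpr, tpr = m.iso_bacc_contour(level)
        assert np.allclose(m.binary_bacc(tpr, 1.0 - fpr), level)

    @pytest.mark.parametrize("level", [0.5, 0.7, 0.9])
    def test_iso_f1_points_have_constant_f1(self, level):
        recall, precision = m.iso_f1_contour(level)
        f1 = 2 * precision * recall / (precision + recall)
        assert np.allclose(f1, level, atol=1e-6)
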