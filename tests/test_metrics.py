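"""Confusion-matrix metrics against brute-force and sklearn cross-checks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import precision_recall_fscore_support

from fundusnet import (
    ArchitectureSpec,
    ConfusionMatrix,
    build_model,
    classification_metrics,
    confusion_matrix,
    evaluate,
)


def brute_force_metrics(counts):
    n = counts.shape[0]
    precision, recall, f1 = [], [], []
    for c in range(n):
        tp = counts[c][c]
        fp = sum(counts[r][c] for r in range(n)) - tp
        fn = sum(counts[c][r] for r in range(n)) - tp
        p = tp / (tp + fp) if tp + fp > 0 else 0.0
        r = tp / (tp + fn) if tp + fn > 0 else 0.0
        f = 2 * p * r / (p + r) if p + r > 0 else 0.0
        precision.append(p), recall.append(r), f1.append(f)
    acc = sum(counts[c][c] for c in range(n)) / counts.sum()
    return precision, recall, f1, acc


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        y = np.array([0, 0, 1, 2, 2, 2])
        cm = confusion_matrix(y, y, 3)
        np.testing.assert_array_equal(cm.counts, np.diag([2, 1, 3]))

    def test_total_is_conserved(self, rng):
        y = rng.integers(0, 4, 50)
        p = rng.integers(0, 4, 50)
        assert confusion_matrix(y, p, 4).total == 50

    def test_three_class_toy_grid(self):
        y = [0, 0, 0, 1, 1, 1, 2, 2, 2]
        p = [0, 1, 0, 1, 1, 2, 2, 2, 0]
        cm = confusion_matrix(y, p, 3)
        np.testing.assert_array_equal(
            cm.counts, [[2, 1, 0], [0, 2, 1], [1, 0, 2]]
        )

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            confusion_matrix([0, 3], [0, 1], 3)


class TestClassificationMetrics:
    def test_perfect_predictions_score_one(self):
        report = classification_metrics(ConfusionMatrix(np.diag([5, 7, 3])))
        assert report.accuracy == 1.0
        np.testing.assert_array_equal(report.f1, 1.0)
        assert report.macro_f1 == 1.0

    def test_binary_hand_computation(self):
        report = classification_metrics(ConfusionMatrix([[8, 2], [3, 7]]))
        assert report.precision[0] == pytest.approx(8 / 11, abs=1e-12)
        assert report.recall[0] == pytest.approx(0.8, abs=1e-12)
        assert report.f1[0] == pytest.approx(2 * (8 / 11) * 0.8 / (8 / 11 + 0.8), abs=1e-12)
        assert report.accuracy == pytest.approx(0.75)

    def test_never_predicted_class_reported_zero_and_flagged(self):
        cm = ConfusionMatrix([[0, 5], [0, 5]])
        report = classification_metrics(cm)
        assert report.precision[0] == 0.0 and report.f1[0] == 0.0
        assert 0 in report.undefined_classes

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_and_sklearn(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        counts = rng.integers(0, 30, size=(n, n))
        counts[0, 0] += 1  # non-empty
        report = classification_metrics(ConfusionMatrix(counts))
        bp, br, bf, bacc = brute_force_metrics(counts)
        np.testing.assert_allclose(report.precision, bp, atol=1e-12)
        np.testing.assert_allclose(report.recall, br, atol=1e-12)
        np.testing.assert_allclose(report.f1, bf, atol=1e-12)
        assert report.accuracy == pytest.approx(bacc, abs=1e-12)
        # independent library cross-check on the expanded label lists
        y_true = np.repeat(np.arange(n), counts.sum(axis=1))
        y_pred = np.concatenate(
            [np.repeat(np.arange(n), counts[r]) for r in range(n)]
        )
        sp, sr, sf, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=np.arange(n), zero_division=0
        )
        np.testing.assert_allclose(report.precision, sp, atol=1e-12)
        np.testing.assert_allclose(report.recall, sr, atol=1e-12)
        np.testing.assert_allclose(report.f1, sf, atol=1e-12)

    def test_macro_f1_invariant_under_relabeling(self, rng):
        counts = rng.integers(0, 20, size=(4, 4)) + 1
        report = classification_metrics(ConfusionMatrix(counts))
        perm = rng.permutation(4)
        permuted = counts[np.ix_(perm, perm)]
        report_p = classification_metrics(ConfusionMatrix(permuted))
        assert report.macro_f1 == pytest.approx(report_p.macro_f1, abs=1e-12)
        assert report.accuracy == pytest.approx(report_p.accuracy, abs=1e-12)

    def test_f1_between_precision_and_recall(self, rng):
        counts = rng.integers(0, 25, size=(5, 5)) + 1
        report = classification_metrics(ConfusionMatrix(counts))
        lo = np.minimum(report.precision, report.recall)
        hi = np.maximum(report.precision, report.recall)
        assert np.all(report.f1 >= lo - 1e-12) and np.all(report.f1 <= hi + 1e-12)

    def test_degenerate_single_class_predictor(self):
        # always predicts class 0 on balanced 10-class data
        counts = np.zeros((10, 10), dtype=int)
        counts[:, 0] = 10
        report = classification_metrics(ConfusionMatrix(counts))
        assert report.accuracy == pytest.approx(0.1, abs=1e-12)
        assert report.macro_f1 == pytest.approx(2 * 0.1 * 1.0 / 1.1 / 10, abs=1e-12)


class TestEvaluate:
    @pytest.fixture(scope="class")
    def random_model_and_data(self):
        spec = ArchitectureSpec(
            input_height=32, input_width=32, stem_filters=4,
            block_channels=(8, 8, 8, 8), se_reduction=2, dense_units=(8, 8),
            num_classes=10, dropout_rate=0.0,
        )
        rng = np.random.default_rng(1)
        return build_model(spec, seed=1), rng.random((16, 32, 32, 3)), rng.integers(0, 10, 16)

    def test_report_consistent_with_own_confusion_matrix(self, random_model_and_data):
        model, x, y = random_model_and_data
        report, cm = evaluate(model, x, y)
        recomputed = classification_metrics(cm)
        assert report.accuracy == recomputed.accuracy
        np.testing.assert_array_equal(report.f1, recomputed.f1)

    def test_empty_split_rejected(self, random_model_and_data):
        model, x, y = random_model_and_data
        with pytest.raises(ValueError, match="empty"):
            evaluate(model, x, y, indices=np.array([], dtype=int))
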