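"""Tests for fold construction, confusion matrices and metric arithmetic."""

import numpy as np
import pytest

from eegentropy.evaluation import (
    binary_metrics,
    confusion,
    cross_validate,
    metrics,
    multiclass_metrics,
    stratified_sequential_folds,
)


class TestFolds:
    def test_sequential_protocol_first_fold(self):
        """200 balanced samples, 10 folds: fold 1 takes the first ten of
        each class, fold 2 the next ten, and so on."""
        labels = np.r_[np.ones(100, int), np.zeros(100, int)]
        folds = stratified_sequential_folds(labels, 10)
        np.testing.assert_array_equal(
            folds[0].test_idx, np.r_[np.arange(0, 10), np.arange(100, 110)]
        )
        np.testing.assert_array_equal(
            folds[1].test_idx, np.r_[np.arange(10, 20), np.arange(110, 120)]
        )
        assert all(len(f.test_idx) == 20 for f in folds)

    @pytest.mark.parametrize(
        "sizes, n_folds",
        [((30, 30), 10), ((95, 40), 10), ((25, 25, 13), 5), ((100, 100, 100), 20)],
    )
    def test_partition_properties(self, sizes, n_folds, rng):
        labels = np.concatenate([np.full(s, c) for c, s in enumerate(sizes)])
        labels = rng.permutation(labels)
        folds = stratified_sequential_folds(labels, n_folds)
        all_test = np.concatenate([f.test_idx for f in folds])
        assert np.array_equal(np.sort(all_test), np.arange(labels.size))  # partition
        for f in folds:
            assert len(np.intersect1d(f.test_idx, f.train_idx)) == 0
            for c, s in enumerate(sizes):
                in_fold = np.sum(labels[f.test_idx] == c)
                assert abs(in_fold - s / n_folds) < 1  # block sizes differ by <= 1

    def test_class_smaller_than_folds_rejected(self):
        with pytest.raises(ValueError, match="fewer than"):
            stratified_sequential_folds([0] * 5 + [1] * 50, 10)

    def test_shuffled_mode_is_seeded_and_stratified(self):
        labels = np.r_[np.zeros(40, int), np.ones(40, int)]
        f1 = stratified_sequential_folds(labels, 4, shuffle=True, seed=7)
        f2 = stratified_sequential_folds(labels, 4, shuffle=True, seed=7)
        f3 = stratified_sequential_folds(labels, 4, shuffle=True, seed=8)
        np.testing.assert_array_equal(f1[0].test_idx, f2[0].test_idx)
        assert not np.array_equal(f1[0].test_idx, f3[0].test_idx)
        assert np.sum(labels[f1[0].test_idx]) == 10  # stratification preserved


class TestConfusion:
    def test_all_correct_is_diagonal(self):
        cm = confusion([0, 1, 2, 1], [0, 1, 2, 1], 3)
        assert np.trace(cm) == 4 and cm.sum() == 4

    def test_total_conservation_and_additivity(self, rng):
        y1, p1 = rng.integers(0, 3, 50), rng.integers(0, 3, 50)
        y2, p2 = rng.integers(0, 3, 30), rng.integers(0, 3, 30)
        pooled = confusion(np.r_[y1, y2], np.r_[p1, p2], 3)
        np.testing.assert_array_equal(pooled, confusion(y1, p1, 3) + confusion(y2, p2, 3))
        assert pooled.sum() == 80

    def test_label_range_checked(self):
        with pytest.raises(ValueError, match="labels"):
            confusion([0, 3], [0, 1], 2)


class TestMetrics:
    def test_binary_printed_example(self):
        """Cumulative two-class matrix with cells 1288/8/16/829: the
        seizure class must score 98.1% recall and 99.0% precision."""
        cm = np.array([[1288, 8], [16, 829]])
        out = binary_metrics(cm, positive=1)
        assert round(out["recall"], 1) == 98.1
        assert round(out["precision"], 1) == 99.0

    def test_three_class_printed_recalls(self):
        """Diagonal 191/189/89 with class sizes 200/200/100 gives
        per-class recalls 95.5 / 94.5 / 89.0 percent."""
        cm = np.array([[191, 6, 3], [7, 189, 4], [6, 5, 89]])
        assert cm.sum(axis=1).tolist() == [200, 200, 100]
        out = multiclass_metrics(cm)
        recalls = [round(out["per_class"][c]["recall"], 1) for c in range(3)]
        assert recalls == [95.5, 94.5, 89.0]

    def test_perfect_matrix_all_hundred(self):
        out = binary_metrics(np.diag([40, 60]), positive=1)
        assert all(out[k] == 100.0 for k in ("accuracy", "precision", "recall", "specificity", "f1"))

    def test_metric_identities(self, rng):
        y = rng.integers(0, 2, 200)
        p = rng.integers(0, 2, 200)
        cm = confusion(y, p, 2)
        out = binary_metrics(cm, positive=1)
        assert out["accuracy"] == pytest.approx(100 * np.trace(cm) / cm.sum())
        pr, rc = out["precision"], out["recall"]
        assert out["f1"] == pytest.approx(2 * pr * rc / (pr + rc), abs=1e-12)
        flipped = binary_metrics(cm, positive=0)
        assert out["specificity"] == pytest.approx(flipped["recall"])

    def test_agreement_with_sklearn(self, rng):
        sk = pytest.importorskip("sklearn.metrics")
        y = rng.integers(0, 2, 300)
        p = rng.integers(0, 2, 300)
        out = binary_metrics(confusion(y, p, 2), positive=1)
        assert out["precision"] == pytest.approx(100 * sk.precision_score(y, p))
        assert out["recall"] == pytest.approx(100 * sk.recall_score(y, p))
        assert out["f1"] == pytest.approx(100 * sk.f1_score(y, p))
        # macro averages, three classes
        y3, p3 = rng.integers(0, 3, 300), rng.integers(0, 3, 300)
        out3 = multiclass_metrics(confusion(y3, p3, 3))
        assert out3["precision"] == pytest.approx(100 * sk.precision_score(y3, p3, average="macro"))
        assert out3["f1"] == pytest.approx(100 * sk.f1_score(y3, p3, average="macro"))

    def test_zero_denominator_flagged_not_nan(self):
        cm = np.array([[10, 0], [5, 0]])  # nothing predicted positive
        out = binary_metrics(cm, positive=1)
        assert out["precision"] == 0.0 and out["recall"] == 0.0
        assert any("zero denominator" in f for f in out["flags"])

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            metrics(np.zeros((2, 2), dtype=int))


class TestCrossValidate:
    def test_aggregate_matrix_covers_dataset_and_repeats(self, two_class_features):
        batch = two_class_features
        r1 = cross_validate(batch, batch.labels, n_folds=10, seed=11)
        r2 = cross_validate(batch, batch.labels, n_folds=10, seed=11)
        assert r1.aggregate_cm.sum() == len(batch)
        assert r1.to_json_dict() == r2.to_json_dict()
        np.testing.assert_array_equal(r1.aggregate_cm, r2.aggregate_cm)

    def test_separable_synthetic_accuracy(self, two_class_features):
        batch = two_class_features
        report = cross_validate(batch, batch.labels, n_folds=10, seed=3)
        assert report.mean["accuracy"] >= 95.0

    def test_report_files(self, two_class_features, tmp_path):
        batch = two_class_features
        report = cross_validate(batch, batch.labels, n_folds=10, seed=5)
        report.save_json(tmp_path / "r.json")
        report.save_csv(tmp_path / "r.csv")
        report.save_confusion_csv(tmp_path / "cm.csv")
        lines = (tmp_path / "r.csv").read_text().splitlines()
        assert len(lines) == 1 + 10 + 2  # header + folds + mean + std
        assert (tmp_path / "cm.csv").read_text().count(",") == 2
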