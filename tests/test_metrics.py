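import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kneeadl.metrics import (
    EvalReport,
    SplitSpec,
    class_metrics,
    confusion,
    evaluate_predictions,
    f1_score,
    split_dataset,
    write_report,
)


def brute_force_confusion(true, pred, k):
    matrix = np.zeros((k, k), dtype=np.int64)
    for t, p in zip(true, pred):
        for i in range(k):
            for j in range(k):
                if t == i and p == j:
                    matrix[i, j] += 1
    return matrix


def brute_force_metrics(matrix):
    """Definition-level oracle for precision/recall/F1/accuracy."""
    k = matrix.shape[0]
    out = []
    for c in range(k):
        tp = matrix[c, c]
        fp = sum(matrix[r, c] for r in range(k)) - tp
        fn = sum(matrix[c, r] for r in range(k)) - tp
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall else 0.0)
        out.append((precision, recall, f1, tp + fn))
    accuracy = sum(matrix[c, c] for c in range(k)) / matrix.sum()
    return out, accuracy


class TestSplitDataset:
    def test_exact_70_11_19_at_100_per_class(self):
        labels = np.repeat(np.arange(8), 100)
        tr, va, te = split_dataset(labels, SplitSpec(seed=1))
        for c in range(8):
            assert (labels[tr] == c).sum() == 70
            assert (labels[va] == c).sum() == 11
            assert (labels[te] == c).sum() == 19

    def test_three_window_class_keeps_all_and_feeds_train(self):
        labels = np.array([0, 0, 0] + [1] * 100)
        tr, va, te = split_dataset(labels, SplitSpec(seed=0))
        counts = [(labels[part] == 0).sum() for part in (tr, va, te)]
        assert sum(counts) == 3
        assert counts[0] >= 1
        # largest-remainder enumeration: floors (2,0,0); the leftover
        # goes to test (remainder .57 beats .33 and .10)
        assert counts == [2, 0, 1]

    def test_disjoint_and_exhaustive(self, rng):
        labels = rng.integers(0, 8, size=537)
        tr, va, te = split_dataset(labels, SplitSpec(seed=7))
        all_idx = np.concatenate([tr, va, te])
        assert len(all_idx) == len(labels)
        assert len(np.unique(all_idx)) == len(labels)

    def test_same_seed_identical_split(self, rng):
        labels = rng.integers(0, 8, size=400)
        s1 = split_dataset(labels, SplitSpec(seed=3))
        s2 = split_dataset(labels, SplitSpec(seed=3))
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a, b)

    def test_grouped_split_keeps_recordings_whole(self, rng):
        labels = np.repeat(np.arange(4), 60)
        groups = np.array([f"rec_{c}_{i // 6}" for c, i in
                           zip(labels, np.tile(np.arange(60), 4))])
        spec = SplitSpec(seed=5, group_by_recording=True)
        tr, va, te = split_dataset(labels, spec, groups=groups)
        for g in np.unique(groups):
            members = np.nonzero(groups == g)[0]
            in_parts = [np.isin(members, part).any() for part in (tr, va, te)]
            assert sum(in_parts) == 1, f"recording {g} spans splits"

    def test_grouped_split_requires_groups(self):
        labels = np.repeat(np.arange(2), 10)
        with pytest.raises(ValueError, match="groups"):
            split_dataset(labels, SplitSpec(group_by_recording=True))

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SplitSpec(fractions=(0.6, 0.1, 0.2))


class TestConfusion:
    def test_all_correct_is_diagonal(self):
        y = np.array([0, 1, 2, 2, 1])
        m = confusion(y, y, 3)
        assert (m == np.diag([1, 2, 2])).all()

    def test_single_misclassification(self):
        # true stair_descent (7) predicted stair_ascent (6)
        m = confusion([7], [6], 8)
        assert m[7, 6] == 1 and m.sum() == 1

    def test_matches_brute_force_on_random_labelings(self, rng):
        for _ in range(5):
            n = int(rng.integers(1, 200))
            t = rng.integers(0, 8, size=n)
            p = rng.integers(0, 8, size=n)
            np.testing.assert_array_equal(confusion(t, p, 8),
                                          brute_force_confusion(t, p, 8))

    def test_row_sums_are_supports(self, rng):
        t = rng.integers(0, 5, size=100)
        p = rng.integers(0, 5, size=100)
        m = confusion(t, p, 5)
        np.testing.assert_array_equal(m.sum(axis=1), np.bincount(t, minlength=5))

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 9], [0, 1], 8)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion([0, 1], [0], 8)


class TestClassMetrics:
    def test_recall_21_of_support_24(self):
        matrix = np.zeros((2, 2), dtype=int)
        matrix[0, 0] = 21
        matrix[0, 1] = 3   # support 24
        matrix[1, 1] = 10
        report = class_metrics(matrix)
        assert report.per_class[0].recall == pytest.approx(0.875)
        assert report.per_class[0].support == 24

    def test_f1_from_printed_precision_recall_pairs(self):
        assert round(f1_score(0.95, 0.88), 2) == 0.91
        assert round(f1_score(0.88, 0.97), 2) == 0.92

    def test_zero_denominator_flagged(self):
        matrix = np.array([[5, 0], [0, 0]])
        report = class_metrics(matrix)
        assert report.per_class[1].degenerate
        assert report.per_class[1].precision == 0.0

    @given(st.integers(0, 10**6))
    @settings(max_examples=30, deadline=None)
    def test_oracle_equivalence_on_random_matrices(self, seed):
        rng = np.random.Generator(np.random.PCG64(seed))
        k = int(rng.integers(2, 9))
        matrix = rng.integers(0, 20, size=(k, k))
        matrix[rng.integers(0, k), rng.integers(0, k)] += 1  # non-empty
        report = class_metrics(matrix)
        oracle, accuracy = brute_force_metrics(matrix)
        for m, (p, r, f1, support) in zip(report.per_class, oracle):
            assert m.precision == pytest.approx(p)
            assert m.recall == pytest.approx(r)
            assert m.f1 == pytest.approx(f1)
            assert m.support == support
        assert report.accuracy == pytest.approx(accuracy)

    @given(st.integers(0, 10**6))
    @settings(max_examples=30, deadline=None)
    def test_micro_accuracy_equals_weighted_recall(self, seed):
        rng = np.random.Generator(np.random.PCG64(seed))
        t = rng.integers(0, 6, size=150)
        p = rng.integers(0, 6, size=150)
        report = class_metrics(confusion(t, p, 6))
        assert report.weighted["recall"] == pytest.approx(report.accuracy)

    def test_macro_f1_bounded_by_class_f1(self, rng):
        matrix = rng.integers(0, 30, size=(8, 8)) + np.eye(8, dtype=int)
        report = class_metrics(matrix)
        f1s = [m.f1 for m in report.per_class]
        assert min(f1s) <= report.macro["f1"] <= max(f1s)

    def test_agrees_with_sklearn(self, rng):
        sklearn = pytest.importorskip("sklearn.metrics")
        t = rng.integers(0, 8, size=300)
        p = rng.integers(0, 8, size=300)
        report = class_metrics(confusion(t, p, 8))
        p_, r_, f_, s_ = sklearn.precision_recall_fscore_support(
            t, p, labels=range(8), zero_division=0)
        for c, m in enumerate(report.per_class):
            assert m.precision == pytest.approx(p_[c])
            assert m.recall == pytest.approx(r_[c])
            assert m.f1 == pytest.approx(f_[c])
            assert m.support == s_[c]


class TestWriteReport:
    def make_report(self, rng):
        t = rng.integers(0, 8, size=200)
        p = np.where(rng.random(200) < 0.9, t, rng.integers(0, 8, size=200))
        names = tuple(f"activity_{i}" for i in range(8))
        return evaluate_predictions(t, p, names)

    def test_json_round_trip(self, rng, tmp_path):
        report = self.make_report(rng)
        json_path, _ = write_report(report, tmp_path / "report")
        loaded = EvalReport.from_dict(json.loads(json_path.read_text()))
        assert loaded.accuracy == report.accuracy
        np.testing.assert_array_equal(loaded.matrix, report.matrix)

    def test_csv_has_exactly_10_data_rows(self, rng, tmp_path):
        _, csv_path = write_report(self.make_report(rng), tmp_path / "report")
        rows = csv_path.read_text().strip().splitlines()
        assert len(rows) == 11  # header + 8 classes + accuracy + weighted

    def test_accuracy_cell_consistent_with_matrix(self, rng, tmp_path):
        report = self.make_report(rng)
        json_path, csv_path = write_report(report, tmp_path / "report")
        payload = json.loads(json_path.read_text())
        matrix = np.asarray(payload["confusion_matrix"])
        accuracy_row = csv_path.read_text().strip().splitlines()[-2].split(",")
        assert float(accuracy_row[3]) == pytest.approx(
            matrix.trace() / matrix.sum(), abs=0.0051)

    def test_supports_sum_to_total(self, rng):
        report = self.make_report(rng)
        assert sum(m.support for m in report.per_class) == report.total
        np.testing.assert_array_equal(
            report.matrix.sum(axis=1),
            [m.support for m in report.per_class])
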