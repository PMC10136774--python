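import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from histocurate import (
    FoldPredictions,
    aggregate_folds,
    auc_mann_whitney,
    bootstrap_ci,
    compute_metrics,
    make_folds,
)
from oracles import bf_auc, bf_metrics


class TestMakeFolds:
    def test_fold_sizes_and_disjointness(self):
        subjects = [f"s{i}" for i in range(10)]
        plan = make_folds(subjects, n_folds=20, val_fraction=0.2, rng=0)
        assert plan.n_folds == 20
        for train, val in plan.folds:
            assert len(val) == 2 and len(train) == 8
            assert not set(train) & set(val)

    def test_validation_union_covers_most_subjects(self):
        subjects = [f"s{i}" for i in range(10)]
        plan = make_folds(subjects, n_folds=20, val_fraction=0.2, rng=7)
        covered = set().union(*(set(val) for _, val in plan.folds))
        assert len(covered) >= 9

    def test_bad_val_fraction_rejected(self):
        with pytest.raises(ValueError):
            make_folds(["a", "b"], 5, 1.5, rng=0)

    def test_grouping_is_by_subject_not_patch(self):
        # repeated subject ids collapse to one subject before splitting
        plan = make_folds(["a"] * 5 + ["b"] * 3 + ["c", "d"], n_folds=5, val_fraction=0.25, rng=1)
        for train, val in plan.folds:
            assert set(train) | set(val) == {"a", "b", "c", "d"}


class TestComputeMetrics:
    def test_perfect_classifier_scores_all_ones(self):
        y = np.array([0, 1, 0, 1])
        m = compute_metrics(y, y, y.astype(float))
        assert all(m[k] == 1.0 for k in ("accuracy", "sensitivity", "specificity",
                                         "precision", "npv", "f1", "auc"))

    def test_contingency_hand_values(self):
        y_true = np.array([1] * 10 + [0] * 10)
        y_pred = np.array([1] * 9 + [0] + [0] * 8 + [1] * 2)
        m = compute_metrics(y_true, y_pred)
        assert m["sensitivity"] == pytest.approx(0.9)
        assert m["specificity"] == pytest.approx(0.8)
        assert m["accuracy"] == pytest.approx(0.85)
        assert m["precision"] == pytest.approx(9 / 11)
        assert m["npv"] == pytest.approx(8 / 9)

    def test_single_class_truth_has_no_auc(self):
        m = compute_metrics([1, 1], [1, 0], [0.9, 0.1])
        assert m["auc"] is None
        assert m["specificity"] is None  # no negatives: TN+FP = 0

    def test_auc_matches_pairwise_oracle_and_sklearn(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 31))
            y = rng.integers(0, 2, size=n)
            if y.min() == y.max():
                continue
            s = np.round(rng.random(n), 1)  # coarse scores force ties
            ours = auc_mann_whitney(y, s)
            assert ours == pytest.approx(bf_auc(y, s))
            assert ours == pytest.approx(roc_auc_score(y, s))


class TestAggregateFolds:
    @staticmethod
    def _fold(y_true, y_pred, scores=None):
        y_true, y_pred = np.asarray(y_true), np.asarray(y_pred)
        scores = y_pred.astype(float) if scores is None else np.asarray(scores)
        return FoldPredictions(y_true, y_pred, scores, np.arange(len(y_true)))

    def test_identical_folds_equal_single_fold(self):
        f = self._fold([1, 0, 1, 0], [1, 0, 0, 0], [0.9, 0.2, 0.4, 0.1])
        pooled, per_fold, _ = aggregate_folds([f, f])
        assert pooled == per_fold[0]

    def test_pooled_f1_differs_from_mean_of_fold_f1(self):
        # fold A: TP=1, FN=1 (plus one TN); fold B: TP=9, one TN
        fold_a = self._fold([1, 1, 0], [1, 0, 0])
        fold_b = self._fold([1] * 9 + [0], [1] * 9 + [0])
        pooled, per_fold, _ = aggregate_folds([fold_a, fold_b])
        assert pooled["f1"] == pytest.approx(20 / 21)
        mean_f1 = np.mean([m["f1"] for m in per_fold])
        assert mean_f1 == pytest.approx((2 / 3 + 1.0) / 2)
        assert pooled["f1"] != pytest.approx(mean_f1)

    def test_pooled_auc_equals_oracle_on_concatenated_scores(self, rng):
        folds = []
        for _ in range(3):
            y = rng.integers(0, 2, size=12)
            s = rng.random(12)
            folds.append(self._fold(y, (s > 0.5).astype(int), s))
        pooled, _, merged = aggregate_folds(folds)
        assert pooled["auc"] == pytest.approx(bf_auc(merged.y_true, merged.y_score))

    def test_patch_order_does_not_change_metrics(self, rng):
        y = rng.integers(0, 2, size=30)
        s = rng.random(30)
        f = self._fold(y, (s > 0.5).astype(int), s)
        perm = rng.permutation(30)
        g = FoldPredictions(y[perm], f.y_pred[perm], s[perm], f.subjects[perm])
        assert aggregate_folds([f])[0] == aggregate_folds([g])[0]


class TestBootstrapCI:
    def test_degenerate_data_gives_zero_width_accuracy_ci(self):
        n = 20
        pooled = FoldPredictions(
            y_true=np.array([0, 1] * (n // 2)),
            y_pred=np.array([0, 1] * (n // 2)),
            y_score=np.array([0.0, 1.0] * (n // 2)),
            subjects=np.arange(n),
        )
        cis, skipped = bootstrap_ci(pooled, B=200, rng=0)
        assert cis["accuracy"] == (1.0, 1.0)

    def test_ci_brackets_point_estimate(self, rng):
        n = 100
        y = rng.integers(0, 2, size=n)
        s = np.clip(y + rng.normal(0, 0.6, n), 0, 1)
        pooled = FoldPredictions(y, (s > 0.5).astype(int), s, np.arange(n))
        point = compute_metrics(y, pooled.y_pred, s)
        cis, _ = bootstrap_ci(pooled, B=300, rng=1)
        for metric in ("accuracy", "auc", "f1"):
            lo, hi = cis[metric]
            assert lo <= point[metric] <= hi

    def test_small_bootstrap_rejected(self):
        pooled = FoldPredictions(np.array([0, 1]), np.array([0, 1]),
                                 np.array([0.1, 0.9]), np.array([0, 1]))
        with pytest.raises(ValueError, match="200"):
            bootstrap_ci(pooled, B=50)


def test_metric_suite_matches_contingency_oracle_on_random_instances(rng):
    for _ in range(30):
        n = int(rng.integers(4, 51))
        y_true = rng.integers(0, 2, size=n)
        y_pred = rng.integers(0, 2, size=n)
        ours = compute_metrics(y_true, y_pred)
        expected = bf_metrics(y_true.tolist(), y_pred.tolist())
        for k, v in expected.items():
            if v is None:
                assert ours[k] is None
            else:
                assert ours[k] == pytest.approx(v)
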