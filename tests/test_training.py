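import numpy as np
import pytest

from histocurate import (
    CombinedLabelSpace,
    LRScheduleParams,
    ReferenceClassifier,
    cosine_lr,
    make_stage_plan,
    run_stage_plan,
)


class TestCosineSchedule:
    PARAMS = LRScheduleParams(eta_max=0.1, eta_min=0.001, cycle_epochs=29, batches_per_epoch=10)

    def test_starts_at_eta_max(self):
        assert cosine_lr(0, self.PARAMS) == pytest.approx(0.1)

    def test_half_cycle_is_midpoint(self):
        assert cosine_lr(self.PARAMS.cycle_batches // 2, self.PARAMS) == pytest.approx(
            (0.1 + 0.001) / 2
        )

    def test_restarts_at_cycle_boundary(self):
        T = self.PARAMS.cycle_batches
        assert cosine_lr(T, self.PARAMS) == pytest.approx(0.1)
        assert cosine_lr(T - 1, self.PARAMS) < 0.002

    def test_bounded_and_nonincreasing_within_cycle(self):
        rates = [cosine_lr(t, self.PARAMS) for t in range(self.PARAMS.cycle_batches)]
        assert all(0.001 <= r <= 0.1 for r in rates)
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_default_floor_is_two_orders_below_peak(self):
        assert LRScheduleParams(eta_max=0.5).floor == pytest.approx(0.005)


class TestStagePlan:
    def test_two_stage_pretraining_gives_four_stages_in_order(self):
        plan = make_stage_plan(True)
        assert [s.dataset_role for s in plan] == ["pretrain", "pretrain", "target", "target"]
        assert [("feature_extractor" in s.trainable_groups) for s in plan] == [
            False, True, False, True,
        ]

    def test_single_stage_plan_trains_target_only(self):
        plan = make_stage_plan(False)
        assert [s.dataset_role for s in plan] == ["target", "target"]

    def test_coarse_stages_never_unfreeze_the_feature_extractor(self):
        for plan in (make_stage_plan(True), make_stage_plan(False)):
            assert "feature_extractor" not in plan[0].trainable_groups
            assert plan[0].trainable_groups == {"classifier_head"}


class TestCombinedLabelSpace:
    SPACE = CombinedLabelSpace(["cohortA", "cohortB"], ["GS3", "GS4"])

    def test_two_by_two_product_has_four_classes(self):
        assert self.SPACE.n_classes == 4
        pairs = {self.SPACE.decode(i) for i in range(4)}
        assert pairs == {("cohortA", "GS3"), ("cohortA", "GS4"),
                         ("cohortB", "GS3"), ("cohortB", "GS4")}

    def test_reduction_sums_sources_per_grade(self):
        scores = np.zeros(4)
        scores[self.SPACE.encode("cohortA", "GS3")] = 0.4
        scores[self.SPACE.encode("cohortB", "GS3")] = 0.3
        scores[self.SPACE.encode("cohortA", "GS4")] = 0.2
        scores[self.SPACE.encode("cohortB", "GS4")] = 0.1
        np.testing.assert_allclose(self.SPACE.reduce_to_grade(scores)[0], [0.7, 0.3])

    def test_reduction_conserves_total_probability(self, rng):
        scores = rng.dirichlet(np.ones(4), size=10)
        reduced = self.SPACE.reduce_to_grade(scores)
        np.testing.assert_allclose(reduced.sum(axis=1), 1.0)
        assert reduced.shape == (10, 2)

    def test_unknown_source_rejected(self):
        with pytest.raises(ValueError, match="unknown source"):
            self.SPACE.encode("cohortC", "GS3")


class TestReferenceClassifier:
    def test_separable_fixture_holdout_accuracy(self, separable_set, separable_features):
        X, y = separable_features, separable_set.labels
        idx = np.random.default_rng(3).permutation(len(y))
        tr, te = idx[: len(y) // 2], idx[len(y) // 2 :]
        clf = ReferenceClassifier(n_classes=2, seed=0)
        clf.fit(X[tr], y[tr])
        assert (clf.predict(X[te]) == y[te]).mean() > 0.95

    def test_scores_rows_sum_to_one(self, separable_set, separable_features):
        clf = ReferenceClassifier(n_classes=2, seed=0)
        clf.fit(separable_features[:50], separable_set.labels[:50], epochs=3)
        scores = clf.predict_scores(separable_features[:20])
        np.testing.assert_allclose(scores.sum(axis=1), 1.0, atol=1e-9)

    def test_frozen_feature_extractor_changes_only_head(self, separable_set, separable_features):
        clf = ReferenceClassifier(n_classes=2, seed=0)
        clf.fit(separable_features[:64], separable_set.labels[:64], epochs=2)
        before = clf.parameter_snapshot()
        clf.fit(
            separable_features[:64],
            separable_set.labels[:64],
            trainable_groups=frozenset({"classifier_head"}),
            epochs=2,
        )
        for key, tensor in clf.params["feature_extractor"].items():
            np.testing.assert_array_equal(tensor, before["feature_extractor"][key])
        assert any(
            not np.array_equal(clf.params["classifier_head"][k], before["classifier_head"][k])
            for k in before["classifier_head"]
        )

    def test_predict_before_fit_raises(self):
        with pytest.raises(RuntimeError, match="fit"):
            ReferenceClassifier().predict_scores(np.zeros((1, 5)))


class TestRunStagePlan:
    def test_stage_masks_are_respected(self, separable_set, separable_features):
        clf = ReferenceClassifier(n_classes=2, seed=1)
        X, y = separable_features, separable_set.labels
        log = run_stage_plan(
            clf,
            make_stage_plan(True),
            {"pretrain": (X[::2], y[::2]), "target": (X[1::2], y[1::2])},
            epochs_per_stage=2,
        )
        assert [e["stage"] for e in log] == [1, 2, 3, 4]
        for entry in log[1:]:  # first stage has no prior snapshot to diff
            assert entry["changed_groups"] <= entry["trainable_groups"]
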