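"""Grouped fold planning, evaluation metrics, and the CV harness."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import f1_score

from phubsense import (
    EvalReport,
    ModelConfig,
    SyntheticDatasetSpec,
    TrainConfig,
    evaluate,
    gen_dataset,
    make_fold_plan,
    preprocess_dataset,
    run_cross_validation,
)

SUBJECTS_30 = [f"S{i:03d}" for i in range(30)]


class TestFoldPlan:
    def test_thirty_subjects_make_ten_groups_of_three(self):
        plan = make_fold_plan(SUBJECTS_30, seed=0)
        assert len(plan.groups) == 10
        assert all(len(g) == 3 for g in plan.groups)
        assert sorted(s for g in plan.groups for s in g) == SUBJECTS_30

    def test_each_fold_partitions_subjects_7_2_1(self):
        plan = make_fold_plan(SUBJECTS_30, seed=4)
        assert len(plan.folds) == 10
        for fold in plan.folds:
            assert len(fold["train"]) == 21
            assert len(fold["val"]) == 6
            assert len(fold["test"]) == 3
            combined = fold["train"] + fold["val"] + fold["test"]
            assert sorted(combined) == SUBJECTS_30  # partition, no leakage

    def test_every_group_is_the_test_set_exactly_once(self):
        plan = make_fold_plan(SUBJECTS_30, seed=1)
        test_sets = [tuple(f["test"]) for f in plan.folds]
        assert sorted(test_sets) == sorted(tuple(sorted(g)) for g in plan.groups)

    def test_seeded_determinism(self):
        a = make_fold_plan(SUBJECTS_30, seed=9)
        b = make_fold_plan(SUBJECTS_30, seed=9)
        assert a.folds == b.folds

    def test_indivisible_subject_count_rejected(self):
        with pytest.raises(ValueError):
            make_fold_plan(SUBJECTS_30[:29], seed=0)

    def test_test_folds_hold_900_pairs_at_protocol_scale(self):
        # 3 test subjects x 300 pairs each = 900 held-out pairs per fold
        ds = gen_dataset(SyntheticDatasetSpec())
        per_subject = {}
        for m in ds._meta:
            per_subject[m["subject_id"]] = per_subject.get(m["subject_id"], 0) + 1
        plan = make_fold_plan(sorted(per_subject), seed=0)
        for fold in plan.folds:
            assert sum(per_subject[s] for s in fold["test"]) == 900


class TestEvaluate:
    def test_binary_style_counts_give_point_nine(self):
        # TP=50, TN=40, FP=5, FN=5 -> accuracy (50+40)/100 = 0.9
        y_true = ["pos"] * 55 + ["neg"] * 45
        y_pred = ["pos"] * 50 + ["neg"] * 5 + ["pos"] * 5 + ["neg"] * 40
        rep = evaluate(y_true, y_pred)
        assert rep.accuracy == pytest.approx(0.9)

    def test_accuracy_equals_trace_over_sum(self, rng):
        y_true = rng.integers(0, 9, 500)
        y_pred = rng.integers(0, 9, 500)
        rep = evaluate(y_true, y_pred)
        assert rep.accuracy == pytest.approx(
            np.trace(rep.confusion) / rep.confusion.sum()
        )

    def test_confusion_matches_brute_force_counts(self, rng):
        y_true = rng.integers(0, 4, 200)
        y_pred = rng.integers(0, 4, 200)
        rep = evaluate(y_true, y_pred, labels=[0, 1, 2, 3])
        brute = np.zeros((4, 4), int)
        for t, p in zip(y_true, y_pred):
            brute[t, p] += 1
        np.testing.assert_array_equal(rep.confusion, brute)

    def test_macro_f1_matches_sklearn_reference(self, rng):
        y_true = rng.integers(0, 3, 120)
        y_pred = rng.integers(0, 3, 120)
        rep = evaluate(y_true, y_pred, labels=[0, 1, 2])
        assert rep.macro_f1 == pytest.approx(
            f1_score(y_true, y_pred, average="macro")
        )

    def test_perfect_predictions(self):
        rep = evaluate([0, 1, 2] * 5, [0, 1, 2] * 5)
        assert rep.accuracy == 1.0 and rep.macro_f1 == 1.0
        assert np.all(np.diag(rep.confusion_percent) == 100.0)

    def test_confusion_percent_rows_sum_to_100(self, rng):
        y_true = rng.integers(0, 5, 300)
        y_pred = rng.integers(0, 5, 300)
        rep = evaluate(y_true, y_pred)
        np.testing.assert_allclose(rep.confusion_percent.sum(axis=1), 100.0)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.integers(0, 3), min_size=2, max_size=60))
    def test_accuracy_is_fraction_correct(self, ys):
        y_true = np.array(ys)
        y_pred = np.roll(y_true, 1)
        rep = evaluate(y_true, y_pred, labels=[0, 1, 2, 3])
        assert rep.accuracy == pytest.approx(np.mean(y_true == y_pred))

    def test_empty_or_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError):
            evaluate([], [])
        with pytest.raises(ValueError):
            evaluate([0, 1], [0])

    def test_report_serialises(self):
        rep = evaluate([0, 1], [1, 1])
        d = rep.to_dict()
        assert isinstance(d["accuracy"], float)
        assert len(d["confusion"]) == 2


class TestPreprocess:
    def test_shapes_and_ranges(self, tiny_dataset):
        cfg = ModelConfig(alpha=0.25, beta=1.0, base_resolution=32,
                          gadf_input_side=32, se_ratio=8, stat_dim_out=16)
        X, y, subjects = preprocess_dataset(tiny_dataset, cfg)
        n = len(tiny_dataset)
        assert X["env"].shape == (n, 32, 32, 3)
        assert X["gadf"].shape == (n, 32, 32, 3)
        assert X["stats"].shape == (n, 63)
        assert y.shape == (n,) and subjects.shape == (n,)
        assert 0.0 <= X["env"].min() and X["env"].max() <= 1.0
        assert 0.0 <= X["gadf"].min() and X["gadf"].max() <= 1.0


class TestCrossValidation:
    @staticmethod
    def _setup(tiny_dataset, epochs):
        cfg = ModelConfig(alpha=0.25, beta=1.0, base_resolution=32,
                          gadf_input_side=32, se_ratio=8, stat_dim_out=16, seed=0)
        tc = TrainConfig(learning_rate=0.02, batch_size=8, epochs=epochs, seed=0)
        X, y, subjects = preprocess_dataset(tiny_dataset, cfg)
        plan = make_fold_plan(sorted(set(subjects)), seed=0, n_groups=2)
        return X, y, subjects, plan, cfg, tc

    def test_tiny_run_produces_reports_and_histories(self, tiny_dataset):
        X, y, subjects, plan, cfg, tc = self._setup(tiny_dataset, epochs=2)
        res = run_cross_validation(X, y, subjects, plan, cfg, tc, folds=[0])
        assert len(res.fold_reports) == 1
        rep = res.fold_reports[0]
        assert isinstance(rep, EvalReport)
        assert 0.0 <= rep.accuracy <= 1.0
        assert len(res.histories[0]) == 2
        assert res.mean_accuracy == pytest.approx(rep.accuracy)

    def test_cv_is_deterministic(self, tiny_dataset):
        X, y, subjects, plan, cfg, tc = self._setup(tiny_dataset, epochs=1)
        r1 = run_cross_validation(X, y, subjects, plan, cfg, tc, folds=[0])
        r2 = run_cross_validation(X, y, subjects, plan, cfg, tc, folds=[0])
        assert r1.mean_accuracy == r2.mean_accuracy
        np.testing.assert_array_equal(
            r1.fold_reports[0].confusion, r2.fold_reports[0].confusion
        )

    def test_leaky_fold_plan_is_rejected(self, tiny_dataset):
        X, y, subjects, plan, cfg, tc = self._setup(tiny_dataset, epochs=1)
        plan.folds[0]["train"] = sorted(set(subjects))  # leak test subjects
        with pytest.raises(AssertionError, match="leakage"):
            run_cross_validation(X, y, subjects, plan, cfg, tc, folds=[0])


def test_plot_confusion_writes_png(tmp_path, rng):
    from phubsense import plot_confusion

    rep = evaluate(rng.integers(0, 3, 60), rng.integers(0, 3, 60))
    out = tmp_path / "conf.png"
    plot_confusion(rep, str(out))
    assert out.stat().st_size > 0
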