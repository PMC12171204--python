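"""Fold construction, metric oracles, ROC, and the leakage-free CV contract."""

import numpy as np
import pytest

from bioharkit.evaluation import (
    confusion_matrix,
    cross_validate,
    make_subject_folds,
    metrics_from_confusion,
    roc_ovr,
)

from conftest import COHORT_SEED


class TestSubjectFolds:
    def test_partition_is_disjoint_and_exhaustive(self):
        subjects = [f"s{i}" for i in range(10)]
        plan = make_subject_folds(subjects, 5, seed=1)
        flat = [s for g in plan.groups for s in g]
        assert sorted(flat) == sorted(subjects)
        assert all(len(g) == 2 for g in plan.groups)

    def test_leave_one_subject_out(self):
        subjects = [f"s{i}" for i in range(6)]
        plan = make_subject_folds(subjects, 6, seed=0)
        assert all(len(g) == 1 for g in plan.groups)

    def test_group_sizes_differ_by_at_most_one(self):
        plan = make_subject_folds([f"s{i}" for i in range(11)], 4, seed=2)
        sizes = [len(g) for g in plan.groups]
        assert max(sizes) - min(sizes) <= 1

    def test_more_folds_than_subjects_rejected(self):
        with pytest.raises(ValueError):
            make_subject_folds([f"s{i}" for i in range(10)], 11)


def _confusion_loops(y_true, y_pred, classes):
    mat = np.zeros((len(classes), len(classes)), dtype=int)
    for r, cr in enumerate(classes):
        for c, cc in enumerate(classes):
            mat[r, c] = sum(
                1 for t, p in zip(y_true, y_pred) if t == cr and p == cc
            )
    return mat


class TestConfusionMatrix:
    def test_hand_example(self):
        mat = confusion_matrix([0, 0, 1], [0, 1, 1], [0, 1])
        np.testing.assert_array_equal(mat, [[1, 1], [0, 1]])

    def test_perfect_predictions_diagonal(self):
        y = [2, 0, 1, 2, 0]
        mat = confusion_matrix(y, y, [0, 1, 2])
        assert np.all(mat == np.diag(np.diag(mat)))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_counting_oracle_and_sklearn(self, seed):
        from sklearn.metrics import confusion_matrix as sk_confusion

        rng = np.random.default_rng(seed)
        y_true = rng.integers(0, 4, 500)
        y_pred = rng.integers(0, 4, 500)
        ours = confusion_matrix(y_true, y_pred, [0, 1, 2, 3])
        np.testing.assert_array_equal(ours, _confusion_loops(y_true, y_pred, [0, 1, 2, 3]))
        np.testing.assert_array_equal(ours, sk_confusion(y_true, y_pred, labels=[0, 1, 2, 3]))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="class_order"):
            confusion_matrix([0, 5], [0, 0], [0, 1])


class TestMetricsFromConfusion:
    def test_hand_example(self):
        m = metrics_from_confusion(np.array([[1, 1], [0, 1]]))
        assert m["precision"][0] == 1.0 and m["recall"][0] == 0.5
        assert m["precision"][1] == 0.5 and m["recall"][1] == 1.0
        assert m["accuracy"] == pytest.approx(2 / 3)

    def test_diagonal_matrix_perfect(self):
        m = metrics_from_confusion(np.diag([5, 3, 7]))
        assert all(v == 1.0 for v in m["precision"].values())
        assert all(v == 1.0 for v in m["f1"].values())
        assert m["accuracy"] == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_per_class_counting_oracle(self, seed):
        rng = np.random.default_rng(seed)
        conf = rng.integers(0, 30, (6, 6))
        m = metrics_from_confusion(conf)
        for c in range(6):
            tp = conf[c, c]
            fp = conf[:, c].sum() - tp
            fn = conf[c, :].sum() - tp
            p = tp / (tp + fp) if tp + fp else 0.0
            r = tp / (tp + fn) if tp + fn else 0.0
            assert m["precision"][c] == pytest.approx(p, abs=1e-12)
            assert m["recall"][c] == pytest.approx(r, abs=1e-12)
            if p + r > 0:
                assert m["f1"][c] == pytest.approx(2 * p * r / (p + r), abs=1e-12)

    def test_zero_denominator_flagged(self):
        conf = np.array([[0, 0], [3, 4]])  # class 0 never occurs as truth=pred col 0? row 0 empty
        m = metrics_from_confusion(conf)
        assert 0 in m["zero_division_classes"]

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            metrics_from_confusion(np.zeros((3, 3), dtype=int))


class TestRocOvr:
    def test_perfect_separation_auc_one(self):
        y = np.array([0, 0, 1, 1, 2, 2])
        P = np.eye(3)[y] * 0.9 + 0.05
        roc = roc_ovr(y, P / P.sum(1, keepdims=True), [0, 1, 2])
        assert all(r["auc"] == pytest.approx(1.0) for r in roc.values())

    def test_label_independent_scores_auc_half(self):
        rng = np.random.default_rng(0)
        n = 2000
        y = rng.integers(0, 2, n)
        p = rng.uniform(0, 1, n)
        P = np.c_[p, 1 - p]
        roc = roc_ovr(y, P, [0, 1])
        assert abs(roc[0]["auc"] - 0.5) < 0.05
        assert abs(roc[1]["auc"] - 0.5) < 0.05

    def test_reversal_symmetry(self):
        rng = np.random.default_rng(1)
        n = 500
        y = rng.integers(0, 2, n)
        p = rng.uniform(0, 1, n)
        auc = roc_ovr(y, np.c_[p, 1 - p], [0, 1])[0]["auc"]
        auc_rev = roc_ovr(y, np.c_[1 - p, p], [0, 1])[0]["auc"]
        assert abs(auc_rev - (1 - auc)) < 1e-9

    def test_matches_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        n = 400
        y = rng.integers(0, 3, n)
        P = rng.dirichlet(np.ones(3), n)
        roc = roc_ovr(y, P, [0, 1, 2])
        for c in range(3):
            ref = roc_auc_score((y == c).astype(int), P[:, c])
            assert roc[c]["auc"] == pytest.approx(ref, abs=1e-10)

    def test_absent_class_flagged(self):
        y = np.array([0, 0, 0, 1])
        P = np.full((4, 3), 1 / 3)
        roc = roc_ovr(y, P, [0, 1, 2])
        assert roc[2]["auc"] is None and roc[2]["flag"] == "class absent"


class TestCrossValidate:
    def test_report_structure_and_aggregation_identity(self, cv_report):
        assert len(cv_report.folds) == 5
        assert cv_report.mean_accuracy == pytest.approx(
            np.mean([f.accuracy for f in cv_report.folds]), abs=1e-12
        )
        for f in cv_report.folds:
            assert f.accuracy == pytest.approx(
                np.trace(f.confusion) / f.confusion.sum(), abs=1e-12
            )

    def test_no_subject_spans_folds(self, cv_report):
        seen: set[str] = set()
        for f in cv_report.folds:
            assert not (seen & set(f.test_subjects))
            seen.update(f.test_subjects)

    def test_normalized_confusion_rows_sum_to_one(self, cv_report):
        row_sums = cv_report.pooled_confusion_normalized.sum(axis=1)
        occupied = cv_report.pooled_confusion.sum(axis=1) > 0
        np.testing.assert_allclose(row_sums[occupied], 1.0, atol=1e-9)

    def test_standardizer_fit_on_training_subjects_only(self, cv_report, synthetic_features):
        # leakage contract: recompute each fold's standardization mean/std
        # independently from the training-subject windows
        X, y, subjects, _ = synthetic_features
        for f in cv_report.folds:
            train_mask = ~np.isin(subjects, f.test_subjects)
            mean = X[train_mask].mean(axis=0)
            std = X[train_mask].std(axis=0)
            std = np.where(std > 0, std, 1.0)
            np.testing.assert_allclose(f.standardizer_mean, mean, atol=1e-10)
            np.testing.assert_allclose(f.standardizer_std, std, atol=1e-10)

    def test_deterministic_given_seed(self, synthetic_features, synthetic_cfg, cv_report):
        X, y, subjects, _ = synthetic_features
        again = cross_validate(
            X, y, subjects,
            config={"lda": synthetic_cfg["lda"], "classifier": synthetic_cfg["classifier"]},
            k=5, seed=COHORT_SEED,
        )
        np.testing.assert_array_equal(again.y_pred_pooled, cv_report.y_pred_pooled)
        np.testing.assert_array_equal(again.proba_pooled, cv_report.proba_pooled)

    def test_fold_missing_class_is_skipped(self, rng):
        # subject s9 holds the only windows of class 2: when s9 is a training
        # subject everything is fine, but the fold testing on the class-2
        # holder trains without class 2 -> that fold must be skipped
        n_per = 6
        X, y, subjects = [], [], []
        for i in range(4):
            X.append(rng.standard_normal((n_per, 3)) + i)
            y.extend([i % 2] * n_per)
            subjects.extend([f"s{i}"] * n_per)
        X.append(rng.standard_normal((n_per, 3)) + 10)
        y.extend([2] * n_per)
        subjects.extend(["s9"] * n_per)
        X = np.vstack(X)
        with pytest.warns(UserWarning, match="missing a class"):
            report = cross_validate(
                np.asarray(X), np.asarray(y), np.asarray(subjects, dtype=object),
                config={"classifier": {"backend": "logistic"}}, k=5, seed=0,
            )
        assert len(report.skipped_folds) >= 1
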