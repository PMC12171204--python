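"""Subject-wise k-fold cross-validation, classification metrics, and
one-vs-rest ROC/AUC.

Folds partition *subjects*, never windows: each subject's data lands
entirely in the training or the test side of a fold, eliminating
subject-identity leakage. Per fold the pipeline fits feature
standardization, LDA, and the classifier on training subjects only, then
evaluates on the held-out subjects. Per-fold accuracy / precision / recall
/ F1 come from the fold confusion matrix; overall numbers are the
arithmetic fold averages, and the pooled confusion matrix is additionally
row-normalized for reporting. ROC curves are computed per class
one-vs-rest over the pooled test predictions of all folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np

from bioharkit.classifier_dbn import fit_dbn, predict_proba
from bioharkit.reduction_lda import fit_lda, transform


@dataclass
class FoldPlan:
    """Disjoint subject groups S_1..S_k."""

    k: int
    groups: list[list[str]]
    seed: int


@dataclass
class FoldMetrics:
    """Metrics for one cross-validation fold."""

    fold_index: int
    accuracy: float
    per_class_precision: dict[int, float]
    per_class_recall: dict[int, float]
    per_class_f1: dict[int, float]
    confusion: np.ndarray
    class_order: list[int]
    zero_division_classes: list[int] = field(default_factory=list)
    test_subjects: list[str] = field(default_factory=list)
    standardizer_mean: np.ndarray | None = None
    standardizer_std: np.ndarray | None = None


@dataclass
class EvaluationReport:
    """Aggregated cross-validation outcome."""

    folds: list[FoldMetrics]
    mean_accuracy: float            # Eq-style arithmetic average of fold accuracies
    mean_precision: float           # average of fold macro precisions
    mean_recall: float              # average of fold macro recalls
    pooled_accuracy: float          # sample-weighted over all pooled test windows
    macro_accuracy: float           # mean of pooled row-normalized diagonal
    pooled_confusion: np.ndarray
    pooled_confusion_normalized: np.ndarray
    class_order: list[int]
    roc: dict[int, dict[str, Any]]  # per class: fpr, tpr, auc (or flagged absent)
    y_true_pooled: np.ndarray = field(default=None)
    y_pred_pooled: np.ndarray = field(default=None)
    proba_pooled: np.ndarray = field(default=None)
    skipped_folds: list[int] = field(default_factory=list)


def make_subject_folds(subject_ids: list[str], k: int, seed: int = 0) -> FoldPlan:
    """Seeded random partition of subjects into k nearly equal groups."""
    subjects = sorted(set(map(str, subject_ids)))
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(subjects):
        raise ValueError(f"k={k} exceeds distinct subject count {len(subjects)}")
    rng = np.random.default_rng(seed)
    perm = [subjects[i] for i in rng.permutation(len(subjects))]
    groups = [sorted(perm[i::k]) for i in range(k)]
    return FoldPlan(k=k, groups=groups, seed=seed)


def confusion_matrix(
    y_true: np.ndarray, y_pred: np.ndarray, class_order: list[int]
) -> np.ndarray:
    """Count matrix: entry (r, c) = windows of true class r predicted c."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    index = {int(c): i for i, c in enumerate(class_order)}
    mat = np.zeros((len(class_order), len(class_order)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if int(t) not in index or int(p) not in index:
            raise ValueError(f"label outside class_order: true={t}, pred={p}")
        mat[index[int(t)], index[int(p)]] += 1
    return mat


def metrics_from_confusion(
    confusion: np.ndarray, class_order: list[int] | None = None
) -> dict[str, Any]:
    """Per-class one-vs-rest precision/recall/F1 and overall accuracy.

    Classes with a zero precision or recall denominator report 0 and are
    listed under ``zero_division_classes``.
    """
    confusion = np.asarray(confusion)
    if confusion.ndim != 2 or confusion.shape[0] != confusion.shape[1]:
        raise ValueError("confusion must be square")
    if np.any(confusion < 0):
        raise ValueError("confusion entries must be non-negative")
    total = int(confusion.sum())
    if total == 0:
        raise ValueError("empty confusion matrix")
    n = confusion.shape[0]
    classes = list(class_order) if class_order is not None else list(range(n))
    precision: dict[int, float] = {}
    recall: dict[int, float] = {}
    f1: dict[int, float] = {}
    flagged: list[int] = []
    for i, c in enumerate(classes):
        tp = confusion[i, i]
        fp = confusion[:, i].sum() - tp
        fn = confusion[i, :].sum() - tp
        p = tp / (tp + fp) if (tp + fp) > 0 else 0.0
        r = tp / (tp + fn) if (tp + fn) > 0 else 0.0
        if (tp + fp) == 0 or (tp + fn) == 0:
            flagged.append(c)
        precision[c] = float(p)
        recall[c] = float(r)
        f1[c] = float(2 * p * r / (p + r)) if (p + r) > 0 else 0.0
    return {
        "accuracy": float(np.trace(confusion)) / total,
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "zero_division_classes": flagged,
    }


def roc_ovr(
    y_true: np.ndarray, probability_matrix: np.ndarray, class_order: list[int]
) -> dict[int, dict[str, Any]]:
    """Per-class one-vs-rest ROC points and trapezoidal AUC.

    Thresholds sweep each class's predicted probabilities from high to low;
    a class absent from ``y_true`` is flagged with ``auc=None``.
    """
    y_true = np.asarray(y_true)
    P = np.asarray(probability_matrix, dtype=np.float64)
    if P.shape != (len(y_true), len(class_order)):
        raise ValueError("probability matrix shape mismatch")
    out: dict[int, dict[str, Any]] = {}
    for j, c in enumerate(class_order):
        pos = (y_true == c).astype(np.int64)
        n_pos = int(pos.sum())
        n_neg = len(pos) - n_pos
        if n_pos == 0 or n_neg == 0:
            out[int(c)] = {"fpr": None, "tpr": None, "auc": None, "flag": "class absent"}
            continue
        scores = P[:, j]
        order = np.argsort(-scores, kind="stable")
        sorted_pos = pos[order]
        sorted_scores = scores[order]
        tp_cum = np.cumsum(sorted_pos)
        fp_cum = np.cumsum(1 - sorted_pos)
        # collapse ties: keep the last point of each distinct score
        distinct = np.r_[np.diff(sorted_scores) != 0, True]
        tpr = np.r_[0.0, tp_cum[distinct] / n_pos]
        fpr = np.r_[0.0, fp_cum[distinct] / n_neg]
        auc = float(np.trapezoid(tpr, fpr))
        out[int(c)] = {"fpr": fpr, "tpr": tpr, "auc": auc, "flag": None}
    return out


def _standardize_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    return mean, std


DEFAULT_PIPELINE_CONFIG: dict[str, Any] = {
    "lda": {"n_components": None, "shrinkage": 1e-4},
    "classifier": {
        "backend": "dbn",
        "architecture": (64, 32),
        "pretrain_epochs": 30,
        "finetune_epochs": 100,
        "pretrain_lr": 0.05,
        "finetune_lr": 0.05,
        "batch_size": 32,
        "patience": 10,
        "momentum": 0.9,
    },
}


def _merged_pipeline_config(config: Mapping[str, Any] | None) -> dict[str, Any]:
    merged = {k: dict(v) for k, v in DEFAULT_PIPELINE_CONFIG.items()}
    if config:
        for key, val in config.items():
            if key not in merged:
                raise KeyError(f"unknown pipeline config key {key!r}")
            for sub, v in val.items():
                if sub not in merged[key]:
                    raise KeyError(f"unknown pipeline config key {key}.{sub!r}")
                merged[key][sub] = v
    return merged


def _fit_predict_fold(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    cfg: dict[str, Any],
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Standardize -> LDA -> standardize -> classifier, fit on train only."""
    mean, std = _standardize_fit(X_train)
    Xtr = (X_train - mean) / std
    Xte = (X_test - mean) / std
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        projection = fit_lda(
            Xtr, y_train, n_components=cfg["lda"]["n_components"],
            shrinkage=cfg["lda"]["shrinkage"],
        )
    Ztr = transform(Xtr, projection)
    Zte = transform(Xte, projection)
    zmean, zstd = _standardize_fit(Ztr)
    Ztr = (Ztr - zmean) / zstd
    Zte = (Zte - zmean) / zstd
    clf = cfg["classifier"]
    if clf["backend"] == "logistic":
        from sklearn.linear_model import LogisticRegression

        model = LogisticRegression(max_iter=1000, random_state=seed)
        model.fit(Ztr, y_train)
        proba = model.predict_proba(Zte)
        class_labels = model.classes_
    else:
        model = fit_dbn(
            Ztr,
            y_train,
            architecture=tuple(clf["architecture"]),
            pretrain_epochs=clf["pretrain_epochs"],
            finetune_epochs=clf["finetune_epochs"],
            pretrain_lr=clf["pretrain_lr"],
            finetune_lr=clf["finetune_lr"],
            batch_size=clf["batch_size"],
            patience=clf["patience"],
            momentum=clf["momentum"],
            seed=seed,
        )
        proba = predict_proba(model, Zte)
        class_labels = model.class_labels
    y_pred = class_labels[np.argmax(proba, axis=1)]
    return y_pred, proba, mean, std


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    subjects: np.ndarray,
    config: Mapping[str, Any] | None = None,
    k: int = 5,
    seed: int = 0,
) -> EvaluationReport:
    """Leakage-free subject-wise k-fold cross-validation.

    Parameters
    ----------
    X, y, subjects
        Feature matrix, integer labels, and per-window subject IDs (feature
        extraction is per-window and fits nothing, so it may be shared
        across folds).
    config
        Optional overrides of :data:`DEFAULT_PIPELINE_CONFIG`
        (``lda`` and ``classifier`` sections).
    k, seed
        Fold count and root seed. The seed drives the subject partition and
        per-fold classifier seeds.

    A fold whose training subjects miss a class entirely is skipped with a
    warning and recorded in ``skipped_folds``.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    subjects = np.asarray([str(s) for s in subjects], dtype=object)
    cfg = _merged_pipeline_config(config)
    class_order = sorted(int(c) for c in np.unique(y))
    plan = make_subject_folds(list(subjects), k, seed)
    rng = np.random.default_rng(seed)
    fold_seeds = rng.integers(0, 2**31 - 1, size=k)

    folds: list[FoldMetrics] = []
    skipped: list[int] = []
    y_true_all: list[np.ndarray] = []
    y_pred_all: list[np.ndarray] = []
    proba_all: list[np.ndarray] = []

    for i, test_group in enumerate(plan.groups):
        test_mask = np.isin(subjects, test_group)
        train_mask = ~test_mask
        y_train = y[train_mask]
        if set(class_order) - set(int(c) for c in np.unique(y_train)):
            warnings.warn(f"fold {i}: training set missing a class; skipped", stacklevel=2)
            skipped.append(i)
            continue
        y_pred, proba, mean, std = _fit_predict_fold(
            X[train_mask], y_train, X[test_mask], cfg, int(fold_seeds[i])
        )
        y_test = y[test_mask]
        conf = confusion_matrix(y_test, y_pred, class_order)
        m = metrics_from_confusion(conf, class_order)
        folds.append(
            FoldMetrics(
                fold_index=i,
                accuracy=m["accuracy"],
                per_class_precision=m["precision"],
                per_class_recall=m["recall"],
                per_class_f1=m["f1"],
                confusion=conf,
                class_order=class_order,
                zero_division_classes=m["zero_division_classes"],
                test_subjects=list(test_group),
                standardizer_mean=mean,
                standardizer_std=std,
            )
        )
        y_true_all.append(y_test)
        y_pred_all.append(y_pred)
        proba_all.append(proba)

    if not folds:
        raise ValueError("every fold was skipped; cannot evaluate")

    def _macro(d: dict[int, float], excluded: list[int]) -> float:
        vals = [v for c, v in d.items() if c not in excluded]
        return float(np.mean(vals)) if vals else 0.0

    mean_accuracy = float(np.mean([f.accuracy for f in folds]))
    mean_precision = float(
        np.mean([_macro(f.per_class_precision, f.zero_division_classes) for f in folds])
    )
    mean_recall = float(
        np.mean([_macro(f.per_class_recall, f.zero_division_classes) for f in folds])
    )

    pooled_conf = np.sum([f.confusion for f in folds], axis=0)
    row_sums = pooled_conf.sum(axis=1, keepdims=True)
    normalized = np.divide(
        pooled_conf, row_sums, out=np.zeros_like(pooled_conf, dtype=np.float64),
        where=row_sums > 0,
    )
    diag = np.diag(normalized)[row_sums[:, 0] > 0]

    y_true_pooled = np.concatenate(y_true_all)
    y_pred_pooled = np.concatenate(y_pred_all)
    proba_pooled = np.vstack(proba_all)

    return EvaluationReport(
        folds=folds,
        mean_accuracy=mean_accuracy,
        mean_precision=mean_precision,
        mean_recall=mean_recall,
        pooled_accuracy=float(np.trace(pooled_conf)) / float(pooled_conf.sum()),
        macro_accuracy=float(np.mean(diag)),
        pooled_confusion=pooled_conf,
        pooled_confusion_normalized=normalized,
        class_order=class_order,
        roc=roc_ovr(y_true_pooled, proba_pooled, class_order),
        y_true_pooled=y_true_pooled,
        y_pred_pooled=y_pred_pooled,
        proba_pooled=proba_pooled,
        skipped_folds=skipped,
    )


def report_to_dict(report: EvaluationReport) -> dict[str, Any]:
    """JSON-serializable view of an :class:`EvaluationReport`."""
    return {
        "k": len(report.folds) + len(report.skipped_folds),
        "class_order": report.class_order,
        "mean_accuracy": report.mean_accuracy,
        "mean_precision": report.mean_precision,
        "mean_recall": report.mean_recall,
        "pooled_accuracy": report.pooled_accuracy,
        "macro_accuracy": report.macro_accuracy,
        "pooled_confusion": report.pooled_confusion.tolist(),
        "pooled_confusion_normalized": report.pooled_confusion_normalized.tolist(),
        "per_fold": [
            {
                "fold": f.fold_index,
                "accuracy": f.accuracy,
                "precision": f.per_class_precision,
                "recall": f.per_class_recall,
                "f1": f.per_class_f1,
                "confusion": f.confusion.tolist(),
                "test_subjects": f.test_subjects,
            }
            for f in report.folds
        ],
        "auc": {c: r["auc"] for c, r in report.roc.items()},
        "skipped_folds": report.skipped_folds,
    }
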