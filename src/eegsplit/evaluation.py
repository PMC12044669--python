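"""Confusion matrices, classification reports, cross-validation and ROC.

All metric arithmetic is implemented here from the confusion counts —
accuracy (TP+TN)/n, precision TP/(TP+FP), recall TP/(TP+FN), F1 as the
harmonic mean — with the MDD class (label 1) as positive. The healthy-class
metrics are the same formulas with the roles of TP/TN and FP/FN swapped.
Report-level "Precision/Recall/F1" single columns are support-weighted
averages of the per-class values; weighted recall equals accuracy
identically. 0/0 degeneracies resolve to 0 by documented convention.

Display rounding is half-up to 4 decimals (the convention of the printed
tables), not banker's rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

from .errors import InputError
from .preprocessing import FeatureMatrix

POSITIVE_CLASS = 1  # MDD


def round_half_up(x: float, ndigits: int = 4) -> float:
    """Round with ties away from zero, as printed report tables do."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """2x2 counts with MDD (label 1) as the positive class.

    Layout convention: [[TP, FP], [FN, TN]].
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise InputError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def as_array(self) -> np.ndarray:
        return np.array([[self.tp, self.fp], [self.fn, self.tn]], dtype=np.int64)


def confusion(y_true: Sequence[int], y_pred: Sequence[int]) -> ConfusionMatrix:
    """Count TP/FP/FN/TN with positive class 1 (MDD)."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise InputError("y_true and y_pred must be 1-D of equal length")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if not np.isin(arr, (0, 1)).all():
            raise InputError(f"{name} contains labels outside {{0, 1}}")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    return ConfusionMatrix(tp, fp, fn, tn)


def accuracy(cm: ConfusionMatrix) -> float:
    """(TP + TN) / (TP + TN + FP + FN)."""
    if cm.total == 0:
        raise InputError("cannot compute accuracy of an empty confusion matrix")
    return (cm.tp + cm.tn) / cm.total


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def precision_recall_f1(
    cm: ConfusionMatrix, for_class: str = "mdd"
) -> tuple[float, float, float]:
    """Per-class precision, recall and F1.

    MDD: P = TP/(TP+FP), R = TP/(TP+FN). Healthy: P = TN/(TN+FN),
    R = TN/(TN+FP). F1 = 2PR/(P+R). Undefined ratios (0/0) are 0.
    """
    key = for_class.lower()
    if key in ("mdd", "1", "positive"):
        p = _safe_div(cm.tp, cm.tp + cm.fp)
        r = _safe_div(cm.tp, cm.tp + cm.fn)
    elif key in ("healthy", "0", "negative"):
        p = _safe_div(cm.tn, cm.tn + cm.fn)
        r = _safe_div(cm.tn, cm.tn + cm.fp)
    else:
        raise InputError(f"for_class must be 'healthy' or 'mdd', got {for_class!r}")
    f1 = _safe_div(2 * p * r, p + r)
    return p, r, f1


@dataclass(frozen=True)
class ClassificationReport:
    """Accuracy, per-class and support-weighted precision/recall/F1."""

    accuracy: float
    precision_healthy: float
    recall_healthy: float
    f1_healthy: float
    precision_mdd: float
    recall_mdd: float
    f1_mdd: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    support_healthy: int
    support_mdd: int

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    def rounded(self, ndigits: int = 4) -> dict:
        return {
            k: (round_half_up(v, ndigits) if isinstance(v, float) else v)
            for k, v in self.as_dict().items()
        }


def report_from_confusion(cm: ConfusionMatrix) -> ClassificationReport:
    """Build the full report from counts alone."""
    acc = accuracy(cm)
    ph, rh, fh = precision_recall_f1(cm, "healthy")
    pm, rm, fm = precision_recall_f1(cm, "mdd")
    sh = cm.tn + cm.fp  # true healthy instances
    sm = cm.tp + cm.fn  # true MDD instances
    n = sh + sm
    wp = _safe_div(ph * sh + pm * sm, n)
    wr = _safe_div(rh * sh + rm * sm, n)
    wf = _safe_div(fh * sh + fm * sm, n)
    return ClassificationReport(
        accuracy=acc,
        precision_healthy=ph, recall_healthy=rh, f1_healthy=fh,
        precision_mdd=pm, recall_mdd=rm, f1_mdd=fm,
        weighted_precision=wp, weighted_recall=wr, weighted_f1=wf,
        support_healthy=sh, support_mdd=sm,
    )


def classification_report(
    y_true: Sequence[int], y_pred: Sequence[int]
) -> ClassificationReport:
    """Per-class metrics plus support-weighted averages from predictions."""
    return report_from_confusion(confusion(y_true, y_pred))


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CVResult:
    """Per-fold accuracies and their arithmetic mean."""

    fold_accuracies: tuple[float, ...]
    mean: float

    @classmethod
    def from_folds(cls, folds: Sequence[float]) -> "CVResult":
        folds = tuple(float(f) for f in folds)
        if not folds:
            raise InputError("need at least one fold")
        return cls(folds, sum(folds) / len(folds))


def kfold_cv(
    estimator,
    features: FeatureMatrix,
    folds: int = 4,
    seed: int = 0,
    grouping: str = "epoch",
    return_indices: bool = False,
):
    """k-fold cross-validated accuracy of a classifier on a FeatureMatrix.

    ``epoch`` grouping uses stratified folds over epochs (near-equal fold
    sizes, ±1); ``subject`` grouping keeps each subject's epochs in one
    fold (group-aware, leakage-safe). ``estimator`` is any scikit-learn
    classifier; it is cloned per fold.
    """
    from sklearn.base import clone
    from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold

    if folds < 2:
        raise InputError("folds must be >= 2")
    if grouping not in ("epoch", "subject"):
        raise InputError("grouping must be 'epoch' or 'subject'")
    X, y = features.values, features.labels
    if len(np.unique(y)) < 2:
        raise InputError("cross-validation needs both classes")
    if np.unique(y, return_counts=True)[1].min() < folds:
        raise InputError("each fold must be able to contain both classes")

    if grouping == "epoch":
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        split = splitter.split(X, y)
    else:
        splitter = StratifiedGroupKFold(n_splits=folds, shuffle=True, random_state=seed)
        split = splitter.split(X, y, groups=features.groups)

    accs = []
    test_folds = []
    for train_idx, test_idx in split:
        model = clone(estimator)
        model.fit(X[train_idx], y[train_idx])
        cm = confusion(y[test_idx], model.predict(X[test_idx]))
        accs.append(accuracy(cm))
        test_folds.append(test_idx)
    result = CVResult.from_folds(accs)
    return (result, test_folds) if return_indices else result


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------


def roc_auc(
    y_true: Sequence[int], scores: Sequence[float]
) -> tuple[np.ndarray, float]:
    """ROC points and trapezoidal AUC from a threshold sweep.

    Returns ``(points, auc)`` where points is an array of (FPR, TPR) rows
    ordered from (0, 0) to (1, 1). The trapezoid rule over the tie-grouped
    sweep equals the probabilistic statistic
    ``P(s+ > s-) + 0.5 P(s+ = s-)``.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=np.float64)
    if y_true.shape != scores.shape or y_true.ndim != 1:
        raise InputError("y_true and scores must be 1-D of equal length")
    if not np.isin(y_true, (0, 1)).all():
        raise InputError("y_true contains labels outside {0, 1}")
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        raise InputError("ROC needs both classes present")

    order = np.argsort(-scores, kind="stable")
    y_sorted = y_true[order]
    s_sorted = scores[order]
    # cumulative counts at each distinct-threshold boundary (ties grouped)
    distinct = np.r_[np.flatnonzero(np.diff(s_sorted)), len(s_sorted) - 1]
    tp_cum = np.cumsum(y_sorted == 1)[distinct]
    fp_cum = np.cumsum(y_sorted == 0)[distinct]
    tpr = np.r_[0.0, tp_cum / n_pos]
    fpr = np.r_[0.0, fp_cum / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc
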