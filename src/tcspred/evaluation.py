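"""Classifier evaluation: confusion metrics, ROC/AUC, stratified k-fold
cross-validation, and paired ROC comparison.

The four threshold metrics are the standard ones for an imbalanced
binary problem:

    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    MCC         = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

MCC matters most here: with ~10x more non-interacting than interacting
pairs, accuracy alone is dominated by the majority class.  AUC is the
probability that a random positive outscores a random negative, ties
counted one half.  Two ROC curves built from paired scores on the same
examples are compared with DeLong's test for correlated AUCs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_auc_score, roc_curve as _sk_roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from tcspred.errors import DataError

__all__ = [
    "ConfusionMetrics", "RocCurve", "confusion_metrics", "roc_auc",
    "kfold_split", "cross_validate", "compare_roc", "CrossValResult",
]


@dataclass
class ConfusionMetrics:
    TP: int
    FP: int
    TN: int
    FN: int
    sensitivity: float
    specificity: float
    accuracy: float
    mcc: float
    #: names of metrics whose denominator was zero (value defined as 0)
    degenerate: tuple[str, ...] = ()


@dataclass
class RocCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    scores: np.ndarray = field(default_factory=lambda: np.array([]))
    labels: np.ndarray = field(default_factory=lambda: np.array([]))


def _safe_div(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def confusion_metrics(labels: np.ndarray, scores: np.ndarray,
                      threshold: float = 0.5) -> ConfusionMetrics:
    """Threshold the scores at ``threshold`` and evaluate the four
    metrics; any zero denominator defines the metric as 0 and flags it."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.size == 0:
        raise DataError("empty evaluation input")
    if labels.shape != scores.shape:
        raise DataError("labels and scores must align")
    pred = scores >= threshold
    tp = int(((labels == 1) & pred).sum())
    fn = int(((labels == 1) & ~pred).sum())
    tn = int(((labels == 0) & ~pred).sum())
    fp = int(((labels == 0) & pred).sum())
    flags: list[str] = []
    sens = _safe_div(tp, tp + fn, "sensitivity", flags)
    spec = _safe_div(tn, tn + fp, "specificity", flags)
    acc = _safe_div(tp + tn, tp + tn + fp + fn, "accuracy", flags)
    denom = float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        flags.append("mcc")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / np.sqrt(denom)
    return ConfusionMetrics(tp, fp, tn, fn, sens, spec, acc, float(mcc),
                            tuple(flags))


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> RocCurve:
    """ROC curve (threshold sweep over unique scores, trapezoid AUC);
    equals the pairwise probability P(score+ > score-) + 0.5 P(=)."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(set(labels.tolist())) < 2:
        raise DataError("both classes must be present for a ROC curve")
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    auc = float(roc_auc_score(labels, scores))
    return RocCurve(thr, fpr, tpr, auc, scores=scores, labels=labels)


def kfold_split(labels: np.ndarray, k: int, seed: int = 0) -> list[np.ndarray]:
    """Deterministic stratified k-fold assignment: per class, fold sizes
    differ by at most one.  A class with fewer than k members is spread
    as evenly as possible, with a warning."""
    labels = np.asarray(labels, dtype=int)
    if k > len(labels):
        raise DataError(f"k={k} exceeds dataset size {len(labels)}")
    if k < 2:
        raise DataError("k must be at least 2")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    start = 0
    for cls in sorted(set(labels.tolist())):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < k:
            warnings.warn(f"class {cls} has {len(idx)} < k={k} members; "
                          "spreading as evenly as possible", stacklevel=2)
        idx = rng.permutation(idx)
        for j, i in enumerate(idx):
            folds[(start + j) % k].append(int(i))
        start += len(idx)  # offset so small classes rotate across folds
    return [np.array(sorted(f), dtype=int) for f in folds]


@dataclass
class CrossValResult:
    fold_metrics: list[ConfusionMetrics]
    fold_aucs: list[float]
    pooled: ConfusionMetrics
    pooled_roc: RocCurve

    @property
    def mean_fold_auc(self) -> float:
        return float(np.mean(self.fold_aucs)) if self.fold_aucs else float("nan")


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 10,
    seed: int = 0,
    c: float = 1.0,
    g: float = 1.0,
    class_weighted: bool = True,
    threshold: float = 0.5,
) -> CrossValResult:
    """Stratified k-fold cross-validation of the RBF-SVM at fixed (c, g).

    Each fold is scored by a model trained on the remaining folds, with
    decision values min-max normalised within the training folds (bounds
    frozen, held-out values clamped).  The pooled ROC is computed over
    all held-out scores; per-fold AUCs are also reported because the two
    conventions can differ.
    """
    from tcspred.meta_svm import _class_weights, normalize_decision_values  # noqa: PLC0415

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    folds = kfold_split(y, k, seed)
    weights = _class_weights(y) if class_weighted else {0: 1.0, 1: 1.0}
    pooled_scores = np.zeros(len(y))
    fold_metrics: list[ConfusionMetrics] = []
    fold_aucs: list[float] = []
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(y)), test_idx)
        if len(set(y[train_idx].tolist())) < 2:
            raise DataError(f"fold {i}: training side has a single class")
        svc = SVC(kernel="rbf", C=c, gamma=g, class_weight=weights)
        svc.fit(X[train_idx], y[train_idx])
        dv_train = svc.decision_function(X[train_idx])
        lo, hi = dv_train.min(), dv_train.max()
        dv_test = svc.decision_function(X[test_idx])
        if hi - lo < 1e-12:
            scores = np.full(len(test_idx), 0.5)
        else:
            scores = np.clip((dv_test - lo) / (hi - lo), 0.0, 1.0)
        pooled_scores[test_idx] = scores
        fold_metrics.append(confusion_metrics(y[test_idx], scores, threshold))
        if len(set(y[test_idx].tolist())) == 2:
            fold_aucs.append(roc_auc(y[test_idx], scores).auc)
    pooled_roc = roc_auc(y, pooled_scores)
    pooled = confusion_metrics(y, pooled_scores, threshold)
    return CrossValResult(fold_metrics, fold_aucs, pooled, pooled_roc)


# ---------------------------------------------------------------------------
# DeLong paired ROC comparison
# ---------------------------------------------------------------------------

def _midrank_placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Placement values V10 (per positive) and V01 (per negative) of the
    Mann-Whitney kernel, ties counted one half."""
    m, n = len(pos), len(neg)
    allv = np.concatenate([pos, neg])
    r_all = rankdata(allv)
    r_pos = rankdata(pos)
    r_neg = rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    auc = float(v10.mean())
    return v10, v01, auc


def compare_roc(curve_a: RocCurve, curve_b: RocCurve) -> tuple[float, float]:
    """DeLong test for two correlated AUCs built from paired scores on
    the same examples; returns ``(delta_auc, two_sided_p)`` with
    ``delta_auc = auc_a - auc_b``."""
    if curve_a.labels.size == 0 or curve_b.labels.size == 0:
        raise DataError("curves must carry their scores and labels")
    if not np.array_equal(curve_a.labels, curve_b.labels):
        raise DataError("paired comparison requires identical examples/labels")
    labels = curve_a.labels
    pos = labels == 1
    neg = labels == 0
    m, n = int(pos.sum()), int(neg.sum())
    v10 = np.zeros((2, m))
    v01 = np.zeros((2, n))
    aucs = np.zeros(2)
    for i, curve in enumerate((curve_a, curve_b)):
        v10[i], v01[i], aucs[i] = _midrank_placements(
            curve.scores[pos], curve.scores[neg])
    s10 = np.cov(v10)
    s01 = np.cov(v01)
    var = s10[0, 0] / m + s10[1, 1] / m - 2 * s10[0, 1] / m \
        + s01[0, 0] / n + s01[1, 1] / n - 2 * s01[0, 1] / n
    delta = float(aucs[0] - aucs[1])
    if var <= 0:
        if abs(delta) > 1e-12:
            warnings.warn("degenerate DeLong variance with nonzero AUC "
                          "difference", stacklevel=2)
        return delta, 1.0
    z = delta / np.sqrt(var)
    p = float(2.0 * norm.sf(abs(z)))
    return delta, min(p, 1.0)
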