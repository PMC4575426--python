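"""Six-feature SVM meta-classifier.

The six per-method interaction scores --- ordered (i2h, MT, GF, PP, GN,
GO) --- form the feature vector of a candidate HK-RR pair.  An RBF-kernel
SVM is trained on labelled pairs with the minority class up-weighted by
the class ratio (interacting pairs are roughly ten times rarer than
non-interacting ones in curated data), the error cost c and kernel width
g selected by grid search maximising mean k-fold cross-validated AUC,
and raw decision values min-max normalised to [0, 1] using bounds frozen
at training time.

A method that cannot produce evidence for a pair (e.g. too few common
species for the coevolution scores, or no evaluable reference genome)
is imputed as 0 and flagged in a missing mask; the mask itself is not
fed to the SVM, keeping the vector six-dimensional.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from tcspred.errors import DataError, MissingFeature
from tcspred.io_data import TcsPair

FEATURE_ORDER = ("i2h", "mt", "gf", "pp", "gn", "go")


@dataclass
class FeatureVector:
    """Scores of the six methods for one pair, missing entries imputed
    as 0 and flagged."""

    scores: np.ndarray
    missing_mask: np.ndarray
    pair_ref: TcsPair | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.scores.shape != (6,) or self.missing_mask.shape != (6,):
            raise DataError("feature vector must have exactly six entries")
        if not np.all(np.isfinite(self.scores)):
            raise DataError("feature vector entries must be finite")
        if np.any(self.scores[self.missing_mask] != 0.0):
            raise DataError("missing entries must be imputed as 0")


def assemble_features(
    pair: TcsPair,
    scorers: dict[str, Callable[[TcsPair], float]],
) -> FeatureVector:
    """Run the six per-method scorers on a pair with error containment:
    a scorer that raises or signals missing evidence contributes a 0
    with its mask bit set.  All six missing is an error (the pair is
    unpredictable)."""
    unknown = set(scorers) - set(FEATURE_ORDER)
    if unknown:
        raise DataError(f"unknown feature names: {sorted(unknown)}")
    scores = np.zeros(6)
    mask = np.zeros(6, dtype=bool)
    for i, name in enumerate(FEATURE_ORDER):
        fn = scorers.get(name)
        if fn is None:
            mask[i] = True
            continue
        try:
            scores[i] = float(fn(pair))
        except MissingFeature:
            scores[i] = 0.0
            mask[i] = True
        except Exception as exc:  # noqa: BLE001 -- contain, don't abort the batch
            warnings.warn(f"scorer {name} failed on {pair.key}: {exc}",
                          stacklevel=2)
            scores[i] = 0.0
            mask[i] = True
    if mask.all():
        raise DataError(f"pair {pair.key}: all six features missing")
    return FeatureVector(scores, mask, pair)


def normalize_decision_values(values: Sequence[float]) -> np.ndarray:
    """Min-max scale decision values to [0, 1]; an all-equal input maps
    to 0.5 everywhere (no ranking information)."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise DataError("empty decision-value list")
    lo, hi = v.min(), v.max()
    if hi == lo:
        return np.full_like(v, 0.5)
    return (v - lo) / (hi - lo)


@dataclass
class TrainedModel:
    """Fitted RBF-SVM with its selection and normalisation state.

    Decision values are reproduced from the stored support vectors as
    ``f(x) = sum_i alpha_i exp(-g ||sv_i - x||^2) + intercept`` so a
    model restored from disk scores identically to the freshly trained
    one.
    """

    c: float
    g: float
    class_weights: dict[int, float]
    support_vectors: np.ndarray
    dual_coef: np.ndarray
    intercept: float
    norm_min: float
    norm_max: float
    seed: int
    cv_auc: float = float("nan")
    feature_order: tuple[str, ...] = FEATURE_ORDER
    degenerate: bool = field(default=False)

    def __post_init__(self) -> None:
        if self.c <= 0 or self.g <= 0:
            raise DataError("c and g must be positive")
        if self.norm_min >= self.norm_max and not self.degenerate:
            raise DataError("norm bounds must satisfy norm_min < norm_max")

    def decision_values(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        sq = ((self.support_vectors[None, :, :] - X[:, None, :]) ** 2).sum(axis=2)
        return (np.exp(-self.g * sq) @ self.dual_coef) + self.intercept

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Normalised prediction scores in [0, 1], clamped to the
        training-time bounds."""
        if self.degenerate:
            warnings.warn("degenerate normalisation bounds; returning 0.5",
                          stacklevel=2)
            return np.full(np.atleast_2d(X).shape[0], 0.5)
        raw = self.decision_values(X)
        return np.clip((raw - self.norm_min) / (self.norm_max - self.norm_min),
                       0.0, 1.0)

    # -- serialisation ----------------------------------------------------
    def save(self, path: str | Path) -> None:
        payload = {
            "c": self.c, "g": self.g,
            "class_weights": {str(k): v for k, v in self.class_weights.items()},
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "intercept": self.intercept,
            "norm_min": self.norm_min, "norm_max": self.norm_max,
            "seed": self.seed, "cv_auc": self.cv_auc,
            "feature_order": list(self.feature_order),
            "degenerate": self.degenerate,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        d = json.loads(Path(path).read_text())
        return cls(
            c=d["c"], g=d["g"],
            class_weights={int(k): v for k, v in d["class_weights"].items()},
            support_vectors=np.array(d["support_vectors"], dtype=float),
            dual_coef=np.array(d["dual_coef"], dtype=float),
            intercept=d["intercept"],
            norm_min=d["norm_min"], norm_max=d["norm_max"],
            seed=d["seed"], cv_auc=d.get("cv_auc", float("nan")),
            feature_order=tuple(d["feature_order"]),
            degenerate=d.get("degenerate", False))


def _class_weights(y: np.ndarray) -> dict[int, float]:
    """Weight the minority class by the class ratio N_majority/N_minority."""
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("training labels contain a single class")
    if n_pos <= n_neg:
        return {0: 1.0, 1: n_neg / n_pos}
    return {0: n_pos / n_neg, 1: 1.0}


def _cv_auc(X: np.ndarray, y: np.ndarray, c: float, g: float,
            weights: dict[int, float], k: int, seed: int) -> float:
    k_eff = min(k, int((y == 1).sum()), int((y == 0).sum()))
    if k_eff < 2:
        raise DataError("too few members of a class for cross-validation")
    skf = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    aucs = []
    for tr, te in skf.split(X, y):
        if len(set(y[tr])) < 2 or len(set(y[te])) < 2:
            continue
        svc = SVC(kernel="rbf", C=c, gamma=g, class_weight=weights)
        svc.fit(X[tr], y[tr])
        aucs.append(roc_auc_score(y[te], svc.decision_function(X[te])))
    if not aucs:
        raise DataError("no valid cross-validation fold")
    return float(np.mean(aucs))


def grid_search_train(
    X: np.ndarray,
    y: np.ndarray,
    c_grid: Sequence[float] | None = None,
    g_grid: Sequence[float] | None = None,
    k: int = 10,
    seed: int = 0,
    class_weighted: bool = True,
) -> TrainedModel:
    """Select (c, g) on the powers-of-two lattice by mean k-fold CV AUC
    (ties resolved toward smaller c, then smaller g), refit on all data
    with minority-class weighting, and freeze the decision-value
    normalisation bounds from the training set.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or len(X) != len(y):
        raise DataError("X must be 2-D and aligned with y")
    if c_grid is None:
        c_grid = [2.0 ** e for e in range(-5, 16, 2)]
    if g_grid is None:
        g_grid = [2.0 ** e for e in range(-15, 4, 2)]
    if not len(c_grid) or not len(g_grid):
        raise DataError("empty hyperparameter grid")
    weights = _class_weights(y) if class_weighted else {0: 1.0, 1: 1.0}
    best: tuple[float, float, float] | None = None  # (auc, c, g)
    for c in sorted(c_grid):
        for g in sorted(g_grid):
            auc = _cv_auc(X, y, c, g, weights, k, seed)
            if best is None or auc > best[0] + 1e-12:
                best = (auc, c, g)
    assert best is not None
    cv_auc, c, g = best
    svc = SVC(kernel="rbf", C=c, gamma=g, class_weight=weights)
    svc.fit(X, y)
    # collapse sklearn's fitted state into plain arrays
    dual = svc.dual_coef_[0].copy()
    dv_svc = svc.decision_function(X)
    model = TrainedModel(
        c=c, g=g, class_weights=weights,
        support_vectors=svc.support_vectors_.copy(),
        dual_coef=dual, intercept=float(svc.intercept_[0]),
        norm_min=0.0, norm_max=1.0, seed=seed, cv_auc=cv_auc,
        degenerate=False)
    dv = model.decision_values(X)
    if not np.allclose(dv, dv_svc, atol=1e-8):
        raise AssertionError("reconstructed decision function disagrees "
                             "with the fitted SVM")
    lo, hi = float(dv.min()), float(dv.max())
    if hi - lo < 1e-12:
        model.degenerate = True
        model.norm_min, model.norm_max = lo, lo + 1.0
        warnings.warn("all training decision values equal; scores degenerate "
                      "to 0.5", stacklevel=2)
    else:
        model.norm_min, model.norm_max = lo, hi
    return model


def predict_score(model: TrainedModel, x: FeatureVector | np.ndarray) -> float:
    """Normalised interaction score in [0, 1] for a single pair."""
    vec = x.scores if isinstance(x, FeatureVector) else np.asarray(x, float)
    return float(model.predict_scores(vec[None, :])[0])


def features_to_matrix(fvs: Sequence[FeatureVector]) -> np.ndarray:
    return np.vstack([fv.scores for fv in fvs])
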