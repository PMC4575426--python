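import math

import numpy as np
import pytest

from tcspred.errors import DataError
from tcspred.evaluation import (
    compare_roc,
    confusion_metrics,
    cross_validate,
    kfold_split,
    roc_auc,
)
from tcspred.synthetic_fixtures import SimulationSpec, simulate_feature_table


def auc_pairwise_oracle(labels, scores):
    """O(n^2) pairwise-comparison definition of the AUC."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusionMetrics:
    @staticmethod
    def _from_counts(tp, fn, tn, fp, threshold=0.5):
        labels = [1] * (tp + fn) + [0] * (tn + fp)
        scores = [1.0] * tp + [0.0] * fn + [0.0] * tn + [1.0] * fp
        return confusion_metrics(np.array(labels), np.array(scores), threshold)

    def test_perfect_classifier(self):
        m = self._from_counts(tp=5, fn=0, tn=5, fp=0)
        assert (m.sensitivity, m.specificity, m.accuracy, m.mcc) == (1, 1, 1, 1)

    def test_chance_classifier(self):
        m = self._from_counts(tp=1, fn=1, tn=1, fp=1)
        assert (m.sensitivity, m.specificity, m.accuracy) == (0.5, 0.5, 0.5)
        assert m.mcc == 0.0

    def test_matches_formula_oracle(self):
        tp, fn, tn, fp = 18, 4, 300, 19
        m = self._from_counts(tp, fn, tn, fp)
        assert (m.TP, m.FN, m.TN, m.FP) == (tp, fn, tn, fp)
        assert m.sensitivity == pytest.approx(tp / (tp + fn))
        assert m.specificity == pytest.approx(tn / (tn + fp))
        assert m.accuracy == pytest.approx((tp + tn) / (tp + tn + fp + fn))
        assert m.mcc == pytest.approx(
            (tp * tn - fp * fn)
            / math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)))

    def test_zero_denominator_flagged(self):
        m = self._from_counts(tp=0, fn=0, tn=3, fp=1)
        assert m.sensitivity == 0.0
        assert "sensitivity" in m.degenerate and "mcc" in m.degenerate

    def test_mcc_invariant_under_class_and_prediction_swap(self, rng):
        labels = rng.integers(0, 2, size=60)
        scores = rng.random(60)
        m = confusion_metrics(labels, scores)
        # swapping classes and predictions transposes TP<->TN and FP<->FN;
        # continuous scores never sit exactly on the threshold
        m_sw = confusion_metrics(1 - labels, 1.0 - scores, threshold=0.5)
        assert (m_sw.TP, m_sw.TN, m_sw.FP, m_sw.FN) == (m.TN, m.TP, m.FN, m.FP)
        assert m_sw.mcc == pytest.approx(m.mcc)

    def test_empty_input_rejected(self):
        with pytest.raises(DataError):
            confusion_metrics(np.array([]), np.array([]))


class TestRocAuc:
    def test_perfect_separation(self):
        curve = roc_auc(np.array([0, 0, 1, 1]), np.array([0.1, 0.2, 0.8, 0.9]))
        assert curve.auc == 1.0

    def test_all_ties_give_half(self):
        curve = roc_auc(np.array([0, 1, 0, 1]), np.full(4, 0.5))
        assert curve.auc == pytest.approx(0.5)

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(10):
            labels = rng.integers(0, 2, size=30)
            if len(set(labels.tolist())) < 2:
                continue
            scores = np.round(rng.random(30), 1)  # coarse grid forces ties
            curve = roc_auc(labels, scores)
            assert curve.auc == pytest.approx(auc_pairwise_oracle(labels, scores))

    def test_curve_monotone(self, rng):
        labels = rng.integers(0, 2, size=50)
        labels[:2] = [0, 1]
        curve = roc_auc(labels, rng.random(50))
        assert np.all(np.diff(curve.fpr) >= 0)
        assert np.all(np.diff(curve.tpr) >= 0)

    def test_score_negation_complements_auc(self, rng):
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        scores = rng.normal(size=40)  # continuous: ties have measure zero
        a1 = roc_auc(labels, scores).auc
        a2 = roc_auc(labels, -scores).auc
        assert a1 + a2 == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            roc_auc(np.ones(5, dtype=int), np.random.rand(5))


class TestKfold:
    def test_stratification_exact(self):
        labels = np.array([1] * 10 + [0] * 90)
        folds = kfold_split(labels, k=10, seed=4)
        for fold in folds:
            assert labels[fold].sum() == 1
            assert len(fold) == 10

    def test_disjoint_and_covering(self, rng):
        labels = rng.integers(0, 2, size=53)
        labels[:4] = [0, 0, 1, 1]
        folds = kfold_split(labels, k=5, seed=1)
        allidx = np.concatenate(folds)
        assert len(allidx) == 53
        assert len(set(allidx.tolist())) == 53

    def test_deterministic(self):
        labels = np.array([0, 1] * 20)
        f1 = kfold_split(labels, k=5, seed=9)
        f2 = kfold_split(labels, k=5, seed=9)
        assert all(np.array_equal(a, b) for a, b in zip(f1, f2))

    def test_small_class_spread_with_warning(self):
        labels = np.array([1] * 3 + [0] * 27)
        with pytest.warns(UserWarning, match="spreading"):
            folds = kfold_split(labels, k=5, seed=0)
        pos_per_fold = [int(labels[f].sum()) for f in folds]
        assert max(pos_per_fold) <= 1

    def test_k_larger_than_dataset_rejected(self):
        with pytest.raises(DataError):
            kfold_split(np.array([0, 1]), k=3)


class TestCrossValidate:
    def test_separable_dataset_pools_to_auc_one(self, separable_table):
        X, y = separable_table
        res = cross_validate(X, y, k=10, seed=2, c=1.0, g=0.125)
        assert res.pooled_roc.auc == 1.0

    def test_label_permutation_null_centres_on_half(self):
        X, _ = simulate_feature_table(
            SimulationSpec(seed=0, n_pairs=240, class_separation=0.0,
                           imbalance=0.25))
        aucs = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            y = rng.permutation([1] * 48 + [0] * 192)
            aucs.append(cross_validate(X, np.array(y), k=5, seed=seed,
                                       c=1.0, g=0.5).pooled_roc.auc)
        assert abs(np.mean(aucs) - 0.5) < 0.07

    def test_leave_one_out_degenerate_runs(self):
        X, y = simulate_feature_table(
            SimulationSpec(seed=3, n_pairs=20, class_separation=3.0,
                           imbalance=1.0))
        res = cross_validate(X, y, k=len(y), seed=0, c=1.0, g=0.5)
        assert len(res.fold_metrics) == 20

    def test_fold_seed_stability(self, separable_table):
        X, y = separable_table
        aucs = [cross_validate(X, y, k=5, seed=s, c=1.0, g=0.125).pooled_roc.auc
                for s in range(5)]
        assert max(aucs) - min(aucs) < 0.05


class TestCompareRoc:
    def test_identical_curves(self, rng):
        labels = rng.integers(0, 2, size=40)
        labels[:2] = [0, 1]
        scores = rng.random(40)
        c = roc_auc(labels, scores)
        delta, p = compare_roc(c, c)
        assert delta == 0.0 and p == 1.0

    def test_antisymmetry(self, rng):
        labels = rng.integers(0, 2, size=100)
        labels[:2] = [0, 1]
        ca = roc_auc(labels, rng.random(100) + 0.3 * labels)
        cb = roc_auc(labels, rng.random(100))
        d_ab, p_ab = compare_roc(ca, cb)
        d_ba, p_ba = compare_roc(cb, ca)
        assert d_ab == pytest.approx(-d_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_detects_planted_auc_gap(self):
        detections = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = rng.integers(0, 2, size=500)
            y[:2] = [0, 1]
            strong = y * 2.1 + rng.normal(size=500)   # AUC ~ 0.93
            weak = y * 1.35 + rng.normal(size=500)    # AUC ~ 0.83
            ca, cb = roc_auc(y, strong), roc_auc(y, weak)
            _, p = compare_roc(ca, cb)
            detections += p < 0.05
        assert detections >= 14

    def test_mismatched_examples_rejected(self, rng):
        la = np.array([0, 1, 0, 1])
        lb = np.array([1, 1, 0, 0])
        ca = roc_auc(la, rng.random(4))
        cb = roc_auc(lb, rng.random(4))
        with pytest.raises(DataError):
            compare_roc(ca, cb)
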