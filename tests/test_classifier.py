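"""mRMR selection, CV training, lock-down, prediction, confusion metrics."""


import numpy as np
import pandas as pd
import pytest

from glandrisk.classifier import (
    FittedClassifier,
    apply_bins,
    confusion_metrics,
    crossval_train,
    discretize,
    lock_down,
    mrmr_select,
    mutual_information,
    predict_risk,
)
from glandrisk.errors import DomainError, SchemaError, ValidationError


def greedy_oracle(D: pd.DataFrame, y: np.ndarray, m: int) -> list[str]:
    """Exhaustive per-step search of the MID objective on discrete data."""
    cols = list(D.columns)
    sel: list[str] = []
    for _ in range(m):
        best, best_score = None, -np.inf
        for c in cols:
            if c in sel:
                continue
            score = mutual_information(D[c].to_numpy(), y)
            if sel:
                score -= np.mean([mutual_information(D[c].to_numpy(), D[s].to_numpy()) for s in sel])
            if score > best_score:
                best, best_score = c, score
        sel.append(best)
    return sel


class TestDiscretize:
    def test_three_levels_at_mu_pm_sigma(self):
        X = pd.DataFrame({"f": [-10.0, 0.0, 10.0]})
        levels, _ = discretize(X)
        assert list(levels["f"]) == [0, 1, 2]

    def test_constant_column_level_one(self):
        X = pd.DataFrame({"f": [3.0, 3.0, 3.0, 3.0]})
        levels, _ = discretize(X)
        assert (levels["f"] == 1).all()

    def test_edges_idempotent(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        levels, edges = discretize(X)
        assert apply_bins(X, edges).equals(levels)


class TestMutualInformation:
    def test_identical_balanced_binary_one_bit(self):
        a = np.tile([0, 1], 50)
        assert mutual_information(a, a) == pytest.approx(1.0, abs=1e-12)

    def test_independent_patterns_near_zero(self):
        a = np.tile([0, 1], 50)
        b = np.tile([0, 0, 1, 1], 25)
        assert mutual_information(a, b) < 0.02

    def test_constant_zero_bits(self, rng):
        a = np.zeros(40, dtype=int)
        b = rng.integers(0, 3, size=40)
        assert mutual_information(a, b) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(DomainError):
            mutual_information(np.zeros(3), np.zeros(4))


class TestMrmr:
    def test_max_relevance_first_pick(self, rng):
        y = rng.integers(0, 2, size=60)
        X = pd.DataFrame({"f1": y * 10.0, "f2": rng.normal(size=60)})
        res = mrmr_select(X, y, 1)
        assert res.selected == ["f1"]

    def test_duplicate_feature_penalized(self, rng):
        """A copy of an already-selected feature loses to an independent one."""
        n = 400
        y = rng.integers(0, 2, size=n)
        flip1 = rng.random(n) < 0.1
        flip3 = rng.random(n) < 0.1
        f1 = np.where(flip1, 1 - y, y) * 3.0
        f3 = np.where(flip3, 1 - y, y) * 3.0
        # f2 is an exact copy of f1: its redundancy with f1 is the full
        # entropy of f1, which exceeds its relevance, so the second pick
        # must be the independently noisy f3
        X = pd.DataFrame({"f1": f1, "f2": f1.copy(), "f3": f3})
        res = mrmr_select(X, y, 2)
        assert res.selected == ["f1", "f3"]

    def test_m_truncated_with_flag(self, rng):
        X = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
        y = rng.integers(0, 2, size=30)
        res = mrmr_select(X, y, 10)
        assert len(res.selected) == 3
        assert res.truncated

    def test_greedy_equals_exhaustive_oracle(self, rng):
        """Greedy selection matches per-step exhaustive search, 50 tables."""
        for _ in range(50):
            n_feat = int(rng.integers(3, 7))
            n = int(rng.integers(20, 40))
            X = pd.DataFrame(
                rng.normal(size=(n, n_feat)), columns=[f"f{i}" for i in range(n_feat)]
            )
            y = rng.integers(0, 2, size=n)
            if len(np.unique(y)) < 2:
                continue
            m = int(rng.integers(1, n_feat + 1))
            res = mrmr_select(X, y, m)
            D, _ = discretize(X)
            assert res.selected == greedy_oracle(D, y, m)


def separable_data(rng, n=200, sep=4.0):
    y = np.repeat([0, 1], n // 2)
    X = pd.DataFrame(
        {
            "a": rng.normal(0, 1, n) + sep * y,
            "b": rng.normal(0, 1, n) - sep * y,
        }
    )
    return X, y


class TestCrossvalTrain:
    @pytest.mark.parametrize("model_type", ["svm", "rf", "dac"])
    def test_separable_high_accuracy(self, rng, model_type):
        X, y = separable_data(rng)
        fit = crossval_train(X, y, model_type, seed=1)
        assert fit.mean_cv_accuracy >= 0.95

    def test_permutation_null_accuracy_half(self, rng):
        X, _ = separable_data(rng)
        accs = []
        for rep in range(20):
            y = np.random.default_rng(rep).permutation(np.repeat([0, 1], 100))
            accs.append(crossval_train(X, y, "svm", seed=rep).mean_cv_accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.1

    def test_seed_determinism(self, rng):
        X, y = separable_data(rng)
        a = crossval_train(X, y, "rf", seed=7)
        b = crossval_train(X, y, "rf", seed=7)
        assert a.cv_accuracies == b.cv_accuracies

    def test_small_class_rejected(self, rng):
        X = pd.DataFrame({"a": np.arange(10.0)})
        y = np.array([0] * 7 + [1] * 3)
        with pytest.raises(DomainError):
            crossval_train(X, y, "svm", folds=5)


class TestLockDown:
    @staticmethod
    def _cand(model_type, accs):
        return FittedClassifier(
            model_type=model_type, selected_features=["a"], estimator=None,
            cv_accuracies=accs, seed=0,
        )

    def test_best_accuracy_wins(self):
        locked = lock_down(
            [self._cand("svm", [0.88]), self._cand("dac", [0.72]), self._cand("rf", [0.75])]
        )
        assert locked.model_type == "svm"
        assert locked.locked

    def test_single_candidate(self):
        assert lock_down([self._cand("rf", [0.5])]).model_type == "rf"

    def test_tie_prefers_svm(self):
        locked = lock_down([self._cand("rf", [0.8]), self._cand("svm", [0.8])])
        assert locked.model_type == "svm"

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            lock_down([])


class TestPredictRisk:
    def _locked(self, rng):
        X, y = separable_data(rng)
        fit = crossval_train(X, y, "svm", seed=1)
        return lock_down([fit]), X, y

    def test_resubstitution_accuracy(self, rng):
        locked, X, y = self._locked(rng)
        pred = predict_risk(locked, X)
        assert ((pred == "positive") == (y == 1)).mean() >= 0.95

    def test_empty_table(self, rng):
        locked, X, _ = self._locked(rng)
        assert len(predict_risk(locked, X.iloc[:0])) == 0

    def test_column_order_irrelevant(self, rng):
        locked, X, _ = self._locked(rng)
        assert (predict_risk(locked, X[["b", "a"]]) == predict_risk(locked, X)).all()

    def test_missing_feature_named(self, rng):
        locked, X, _ = self._locked(rng)
        with pytest.raises(SchemaError, match="b"):
            predict_risk(locked, X[["a"]])

    def test_unlocked_rejected(self, rng):
        X, y = separable_data(rng)
        fit = crossval_train(X, y, "svm", seed=1)
        with pytest.raises(ValidationError):
            predict_risk(fit, X)


class TestConfusionMetrics:
    def test_validation_cohort_counts(self):
        """Counts from the validation cohort reproduce the printed metrics."""
        pred = np.array([1] * 74 + [0] * 195)
        truth = np.array([1] * 48 + [0] * 26 + [1] * 6 + [0] * 189)
        cm = confusion_metrics(pred, truth)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (48, 26, 6, 189)
        assert round(cm.accuracy, 3) == 0.881
        assert round(cm.ppv, 3) == 0.649
        assert round(cm.npv, 3) == 0.969

    def test_perfect_prediction(self):
        v = np.array([1, 0, 1, 0, 1])
        cm = confusion_metrics(v, v)
        assert cm.accuracy == cm.ppv == cm.npv == cm.sensitivity == cm.specificity == 1.0

    def test_no_predicted_positives_flags_ppv(self):
        cm = confusion_metrics(np.zeros(10, int), np.array([1] * 3 + [0] * 7))
        assert not cm.ppv_defined
        assert np.isnan(cm.ppv)
        assert cm.npv_defined

    def test_identities_random_vectors(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 60))
            pred = rng.integers(0, 2, n)
            truth = rng.integers(0, 2, n)
            cm = confusion_metrics(pred, truth)
            assert cm.tp + cm.fp + cm.tn + cm.fn == n
            assert cm.accuracy == pytest.approx((cm.tp + cm.tn) / n)
            if cm.ppv_defined:
                assert cm.ppv == pytest.approx(cm.tp / (cm.tp + cm.fp))
            if cm.npv_defined:
                assert cm.npv == pytest.approx(cm.tn / (cm.tn + cm.fn))
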