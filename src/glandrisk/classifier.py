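"""Recurrence risk classifier: mRMR selection, CV training, lock-down.

Feature selection is greedy minimum-redundancy-maximum-relevance (the
MID "difference" scheme): after discretizing every feature into three
levels at mean +/- SD, the first feature maximizes mutual information
with the label and each later pick maximizes
``I(f; y) - mean_{s in S} I(f; s)``.  The selected features feed three
candidate classifiers (linear SVM, random forest, linear discriminant),
compared by stratified five-fold cross-validation; the best is locked
and thereafter immutable.  Class-weighted losses are on by default
because recurrence cohorts are imbalanced (roughly one in five).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import mutual_info_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import DomainError, SchemaError, ValidationError

MODEL_TYPES = ("svm", "rf", "dac")
#: lock-down tie-break preference
_MODEL_PRIORITY = {"svm": 0, "rf": 1, "dac": 2}

POSITIVE = "positive"
NEGATIVE = "negative"


def discretize(X: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bin each column into 3 levels at mu +/- sigma (population SD).

    Returns (levels, edges): level 0 below mu - sigma, 1 within, 2
    above; a constant column maps entirely to level 1.  ``edges`` has
    rows ``lo``/``hi`` per column and reproduces the levels when
    re-applied.
    """
    if len(X) < 2:
        raise DomainError("discretization needs at least 2 rows")
    mu = X.mean(axis=0)
    sigma = X.std(axis=0, ddof=0)
    lo, hi = mu - sigma, mu + sigma
    edges = pd.DataFrame({"lo": lo, "hi": hi}).T
    return apply_bins(X, edges), edges


def apply_bins(X: pd.DataFrame, edges: pd.DataFrame) -> pd.DataFrame:
    """Apply previously computed mu +/- sigma edges to a feature table."""
    levels = pd.DataFrame(1, index=X.index, columns=X.columns, dtype=int)
    for c in X.columns:
        lo, hi = edges.loc["lo", c], edges.loc["hi", c]
        if hi > lo:
            levels.loc[X[c] < lo, c] = 0
            levels.loc[X[c] > hi, c] = 2
    return levels


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """Plug-in mutual information between two discrete vectors, in bits."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 1:
        raise DomainError("mutual_information needs two equal-length vectors")
    return float(mutual_info_score(a, b) / np.log(2.0))


@dataclass
class MrmrResult:
    """Outcome of greedy mRMR selection."""

    selected: list[str]
    scores: list[float]
    edges: pd.DataFrame
    truncated: bool = False


def mrmr_select(X: pd.DataFrame, y: np.ndarray, m: int) -> MrmrResult:
    """Greedy forward mRMR (MID scheme) on a continuous feature table.

    Ties break by column order.  ``m`` larger than the number of columns
    is truncated with a flag rather than an error.
    """
    y = np.asarray(y)
    if m < 1:
        raise DomainError("m must be >= 1")
    if len(np.unique(y)) < 2:
        raise DomainError("mrmr_select needs at least 2 classes in y")
    truncated = m > X.shape[1]
    m = min(m, X.shape[1])
    D, edges = discretize(X)
    cols = list(X.columns)
    relevance = {c: mutual_information(D[c].to_numpy(), y) for c in cols}
    selected: list[str] = []
    scores: list[float] = []
    redundancy = {c: 0.0 for c in cols}  # running sum of I(c; s) over selected s
    while len(selected) < m:
        best, best_score = None, -np.inf
        for c in cols:
            if c in selected:
                continue
            score = relevance[c]
            if selected:
                score -= redundancy[c] / len(selected)
            if score > best_score:  # strict: ties keep the earlier column
                best, best_score = c, score
        selected.append(best)
        scores.append(float(best_score))
        db = D[best].to_numpy()
        for c in cols:
            if c not in selected:
                redundancy[c] += mutual_information(D[c].to_numpy(), db)
    return MrmrResult(selected=selected, scores=scores, edges=edges, truncated=truncated)


def _make_estimator(model_type: str, seed: int):
    if model_type == "svm":
        return Pipeline(
            [
                ("scale", StandardScaler()),
                ("clf", SVC(kernel="linear", C=1.0, class_weight="balanced")),
            ]
        )
    if model_type == "rf":
        return RandomForestClassifier(
            n_estimators=500, class_weight="balanced", random_state=seed
        )
    if model_type == "dac":
        return Pipeline(
            [("scale", StandardScaler()), ("clf", LinearDiscriminantAnalysis())]
        )
    raise DomainError(f"unknown model type {model_type!r}")


@dataclass
class FittedClassifier:
    """A trained candidate (or locked) recurrence classifier."""

    model_type: str
    selected_features: list[str]
    estimator: object
    cv_accuracies: list[float]
    seed: int
    locked: bool = False
    metadata: dict = dc_field(default_factory=dict)

    @property
    def mean_cv_accuracy(self) -> float:
        return float(np.mean(self.cv_accuracies))


def crossval_train(
    X: pd.DataFrame,
    y: np.ndarray,
    model_type: str,
    folds: int = 5,
    seed: int = 0,
) -> FittedClassifier:
    """Stratified k-fold CV then refit on all rows.

    Per-fold held-out accuracies are recorded; folds are deterministic
    given the seed.  A class with fewer members than folds raises.
    """
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise DomainError("need two classes to train")
    if counts.min() < folds:
        raise DomainError(
            f"stratification impossible: a class has {counts.min()} < {folds} members"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    Xv = X.to_numpy(dtype=float)
    for tr, te in skf.split(Xv, y):
        est = _make_estimator(model_type, seed)
        est.fit(Xv[tr], y[tr])
        accs.append(float((est.predict(Xv[te]) == y[te]).mean()))
    final = _make_estimator(model_type, seed)
    final.fit(Xv, y)
    return FittedClassifier(
        model_type=model_type,
        selected_features=list(X.columns),
        estimator=final,
        cv_accuracies=accs,
        seed=seed,
        metadata={"folds": folds, "class_weight": "balanced", "n": int(len(y))},
    )


def lock_down(candidates: list[FittedClassifier]) -> FittedClassifier:
    """Pick the candidate with highest mean CV accuracy and freeze it.

    Exact ties prefer svm, then rf, then dac.
    """
    if not candidates:
        raise DomainError("lock_down needs at least one candidate")
    best = min(
        candidates,
        key=lambda c: (-c.mean_cv_accuracy, _MODEL_PRIORITY.get(c.model_type, 99)),
    )
    locked = copy.deepcopy(best)
    locked.locked = True
    return locked


def predict_risk(model: FittedClassifier, X: pd.DataFrame) -> np.ndarray:
    """Binary risk labels ("positive"/"negative") for each row.

    Features are bound by name, so column order is irrelevant; a missing
    selected feature raises a schema error naming it.
    """
    if not model.locked:
        raise ValidationError("model must be locked before prediction")
    missing = [c for c in model.selected_features if c not in X.columns]
    if missing:
        raise SchemaError(f"feature table missing selected features: {missing}")
    if len(X) == 0:
        return np.array([], dtype=object)
    pred = model.estimator.predict(X[model.selected_features].to_numpy(dtype=float))
    return np.where(pred == 1, POSITIVE, NEGATIVE)


@dataclass
class ConfusionMetrics:
    """2x2 confusion counts and derived fractions.

    ppv/npv are NaN with their defined-flag cleared when the respective
    denominator is zero.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    ppv: float
    npv: float
    sensitivity: float
    specificity: float
    ppv_defined: bool = True
    npv_defined: bool = True


def confusion_metrics(pred: np.ndarray, truth: np.ndarray) -> ConfusionMetrics:
    """Confusion counts and accuracy/PPV/NPV/sensitivity/specificity.

    ``pred`` and ``truth`` are binary (1/0 or "positive"/"negative").
    """
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape or pred.ndim != 1 or len(pred) < 1:
        raise DomainError("confusion_metrics needs two equal-length vectors")
    p = (pred == 1) | (pred == POSITIVE)
    t = (truth == 1) | (truth == POSITIVE)
    tp = int((p & t).sum())
    fp = int((p & ~t).sum())
    tn = int((~p & ~t).sum())
    fn = int((~p & t).sum())
    n = tp + fp + tn + fn
    acc = (tp + tn) / n
    ppv_def, npv_def = (tp + fp) > 0, (tn + fn) > 0
    sens = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    spec = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    return ConfusionMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=acc,
        ppv=tp / (tp + fp) if ppv_def else float("nan"),
        npv=tn / (tn + fn) if npv_def else float("nan"),
        sensitivity=sens,
        specificity=spec,
        ppv_defined=ppv_def,
        npv_defined=npv_def,
    )
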