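"""JSON (de)serialization of locked classifiers.

Models are stored as plain JSON so a locked classifier is auditable and
diffable: selected feature names, standardization statistics and linear
coefficients for the SVM / discriminant models, or a full tree dump for
the random forest.  Loaded models predict through small self-contained
predictors, independent of the scikit-learn estimator objects that
produced them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from sklearn.pipeline import Pipeline

from .classifier import FittedClassifier
from .errors import SchemaError


class LinearPredictor:
    """Standardize-then-linear-decision binary predictor."""

    def __init__(self, mean, scale, coef, intercept):
        self.mean = np.asarray(mean, dtype=float)
        self.scale = np.asarray(scale, dtype=float)
        self.coef = np.asarray(coef, dtype=float)
        self.intercept = float(intercept)

    def predict(self, X: np.ndarray) -> np.ndarray:
        z = (np.asarray(X, dtype=float) - self.mean) / self.scale
        return (z @ self.coef + self.intercept > 0).astype(int)


class ForestPredictor:
    """Majority-vote predictor over dumped decision trees."""

    def __init__(self, trees: list[dict]):
        self.trees = trees

    def _tree_prob(self, tree: dict, x: np.ndarray) -> np.ndarray:
        node = 0
        left, right = tree["children_left"], tree["children_right"]
        feat, thr, value = tree["feature"], tree["threshold"], tree["value"]
        while left[node] != -1:
            node = left[node] if x[feat[node]] <= thr[node] else right[node]
        v = np.asarray(value[node], dtype=float)
        return v / v.sum()

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty(len(X), dtype=int)
        for i, x in enumerate(X):
            probs = np.mean([self._tree_prob(t, x) for t in self.trees], axis=0)
            out[i] = int(np.argmax(probs))
        return out


def _dump_estimator(model: FittedClassifier) -> dict:
    est = model.estimator
    if model.model_type in {"svm", "dac"}:
        assert isinstance(est, Pipeline)
        scaler, clf = est.named_steps["scale"], est.named_steps["clf"]
        return {
            "kind": "linear",
            "mean": scaler.mean_.tolist(),
            "scale": scaler.scale_.tolist(),
            "coef": np.ravel(clf.coef_).tolist(),
            "intercept": float(np.ravel(clf.intercept_)[0]),
        }
    trees = []
    for t in est.estimators_:
        tt = t.tree_
        trees.append(
            {
                "children_left": tt.children_left.tolist(),
                "children_right": tt.children_right.tolist(),
                "feature": tt.feature.tolist(),
                "threshold": tt.threshold.tolist(),
                "value": tt.value[:, 0, :].tolist(),
            }
        )
    return {"kind": "forest", "trees": trees}


def save_model(path: str | Path, model: FittedClassifier) -> None:
    doc = {
        "model_type": model.model_type,
        "selected_features": model.selected_features,
        "cv_accuracies": model.cv_accuracies,
        "seed": model.seed,
        "locked": model.locked,
        "metadata": model.metadata,
        "estimator": _dump_estimator(model),
    }
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


def load_model(path: str | Path) -> FittedClassifier:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    for key in ("model_type", "selected_features", "estimator"):
        if key not in doc:
            raise SchemaError(f"model file missing field {key!r}")
    dump = doc["estimator"]
    if dump["kind"] == "linear":
        est = LinearPredictor(dump["mean"], dump["scale"], dump["coef"], dump["intercept"])
    else:
        est = ForestPredictor(dump["trees"])
    return FittedClassifier(
        model_type=doc["model_type"],
        selected_features=list(doc["selected_features"]),
        estimator=est,
        cv_accuracies=list(doc.get("cv_accuracies", [])),
        seed=int(doc.get("seed", 0)),
        locked=bool(doc.get("locked", False)),
        metadata=doc.get("metadata", {}),
    )
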