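"""End-to-end orchestration: segment -> extract -> select/train -> predict
-> survival, as one reproducible, seeded run.

Every output artifact records the run seed and a hash of the effective
configuration; rerunning with the same inputs and config reproduces
byte-identical feature tables and model files.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as grio
from .catalog import CatalogConfig, extract_features, feature_manifest, feature_names
from .classifier import (
    FittedClassifier,
    confusion_metrics,
    crossval_train,
    lock_down,
    mrmr_select,
    predict_risk,
    POSITIVE,
)
from .errors import GlandRiskError
from .model_io import save_model
from .segmentation import SegParams, segment_glands
from .survival import cox_fit, logrank_test

DEFAULT_MODELS = ("svm", "rf", "dac")


@dataclass
class RunConfig:
    """Configuration of one pipeline run."""

    images_dir: str
    cohort_csv: str
    out_dir: str
    mrmr_m: int = 5
    models: tuple[str, ...] = DEFAULT_MODELS
    seed: int = 0
    catalog: CatalogConfig = field(default_factory=CatalogConfig)
    seg: SegParams = field(default_factory=SegParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a run configuration from a YAML mapping.

        Recognized keys mirror the dataclass fields; ``catalog`` and
        ``seg`` may be nested mappings overriding individual defaults.
        """
        import yaml

        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(doc, dict):
            raise GlandRiskError(f"config {path} must be a YAML mapping")
        catalog = CatalogConfig(**doc.pop("catalog", {}))
        seg = SegParams(**doc.pop("seg", {}))
        known = {"images_dir", "cohort_csv", "out_dir", "mrmr_m", "models", "seed"}
        unknown = set(doc) - known
        if unknown:
            raise GlandRiskError(f"unknown config keys: {sorted(unknown)}")
        if "models" in doc:
            doc["models"] = tuple(doc["models"])
        return cls(catalog=catalog, seg=seg, **doc)

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "mrmr_m": self.mrmr_m,
                "models": list(self.models),
                "seed": self.seed,
                "catalog": asdict(self.catalog),
                "seg": asdict(self.seg),
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except GlandRiskError as exc:
                raise GlandRiskError(f"stage {name!r}: {exc}") from exc
            except FileNotFoundError as exc:
                raise GlandRiskError(f"stage {name!r}: missing input {exc}") from exc

        return wrapped

    return deco


@_stage("extract")
def _features_for_cohort(cfg: RunConfig, cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-image feature extraction; prefers imported contours when present."""
    images_dir = Path(cfg.images_dir)
    rows = []
    for image_id in cohort["image_id"]:
        contours = images_dir / f"{image_id}.geojson"
        if contours.exists():
            glands = grio.read_contours(contours)
        else:
            img = None
            for suffix in (".png", ".tif", ".tiff"):
                cand = images_dir / f"{image_id}{suffix}"
                if cand.exists():
                    img = grio.read_image(cand)
                    break
            if img is None:
                raise GlandRiskError(f"no image or contours for {image_id!r} in {images_dir}")
            glands = segment_glands(img, cfg.seg)
        vec = extract_features(glands, cfg.catalog)
        row = {"image_id": image_id, **vec.values}
        rows.append(row)
    return pd.DataFrame(rows)


@_stage("train")
def _train(cfg: RunConfig, features: pd.DataFrame, cohort: pd.DataFrame):
    X = features.drop(columns=["image_id"])
    y = cohort["recurrence"].to_numpy()
    sel = mrmr_select(X, y, cfg.mrmr_m)
    Xsel = X[sel.selected]
    candidates = [
        crossval_train(Xsel, y, model_type=m, folds=5, seed=cfg.seed) for m in cfg.models
    ]
    locked = lock_down(candidates)
    return sel, candidates, locked


def evaluate(
    model: FittedClassifier, features: pd.DataFrame, cohort: pd.DataFrame
) -> dict:
    """Confusion metrics, 2x2 counts and the recurrence-rate ratio.

    The ratio compares the recurrence rate among predicted-positive
    patients to that among predicted-negative patients; it is reported
    as inf when no predicted-negative patient recurred, NaN when a group
    is empty.  Row order of the inputs is irrelevant (joined on
    image_id).
    """
    merged = cohort.merge(features, on="image_id", how="inner", validate="one_to_one")
    X = merged[[c for c in features.columns if c != "image_id"]]
    pred = predict_risk(model, X)
    truth = merged["recurrence"].to_numpy()
    cm = confusion_metrics(pred, truth)
    pos, neg = cm.tp + cm.fp, cm.tn + cm.fn
    rate_pos = cm.tp / pos if pos else float("nan")
    rate_neg = cm.fn / neg if neg else float("nan")
    if np.isnan(rate_pos) or np.isnan(rate_neg):
        ratio = float("nan")
    elif rate_neg == 0:
        ratio = float("inf") if rate_pos > 0 else float("nan")
    else:
        ratio = rate_pos / rate_neg
    return {
        "counts": {"tp": cm.tp, "fp": cm.fp, "tn": cm.tn, "fn": cm.fn},
        "accuracy": cm.accuracy,
        "ppv": cm.ppv,
        "npv": cm.npv,
        "sensitivity": cm.sensitivity,
        "specificity": cm.specificity,
        "recurrence_rate_ratio": ratio,
        "predictions": pred,
    }


@_stage("survival")
def _survival_report(cohort: pd.DataFrame, pred: np.ndarray) -> dict:
    risk = (pred == POSITIVE).astype(int)
    t = cohort["survival_time"].to_numpy(dtype=float)
    e = cohort["event"].to_numpy()
    out: dict = {}
    if risk.min() == risk.max():
        out["logrank"] = None  # single predicted group: no contrast to test
        out["cox"] = None
        return out
    chi2, p = logrank_test((t[risk == 1], e[risk == 1]), (t[risk == 0], e[risk == 0]))
    out["logrank"] = {"chi2": chi2, "p": p}
    if e.sum() >= 1:
        fit = cox_fit(pd.DataFrame({"risk_positive": risk}), t, e, mode="univariate")[0]
        out["cox"] = {
            "hr": fit.hr,
            "ci95": list(fit.ci95),
            "p": fit.p,
            "converged": fit.converged,
        }
    else:
        out["cox"] = None
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline and return the run manifest.

    Writes features.csv, features.manifest.csv, model.json, risk.csv and
    report.json under ``cfg.out_dir``; the manifest lists each output
    with its SHA-256 hash, plus the seed and config hash.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    cohort_path = Path(cfg.cohort_csv)
    if not cohort_path.exists():
        raise GlandRiskError(f"stage 'load': cohort CSV not found: {cohort_path}")
    cohort = grio.read_cohort(cohort_path)
    timings["load"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    features = _features_for_cohort(cfg, cohort)
    timings["extract"] = time.perf_counter() - t0
    features_path = out_dir / "features.csv"
    features.to_csv(features_path, index=False)
    feature_manifest(cfg.catalog).to_csv(out_dir / "features.manifest.csv", index=False)

    t0 = time.perf_counter()
    sel, candidates, locked = _train(cfg, features, cohort)
    timings["train"] = time.perf_counter() - t0
    locked.metadata.update({"config_hash": cfg.config_hash(), "mrmr_scores": sel.scores})
    model_path = out_dir / "model.json"
    save_model(model_path, locked)

    t0 = time.perf_counter()
    ev = evaluate(locked, features, cohort)
    pred = ev.pop("predictions")
    risk = pd.DataFrame(
        {"patient_id": cohort["patient_id"], "image_id": cohort["image_id"], "risk": pred}
    )
    risk_path = out_dir / "risk.csv"
    risk.to_csv(risk_path, index=False)
    timings["predict"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    surv = _survival_report(cohort, pred)
    timings["survival"] = time.perf_counter() - t0

    report = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "selected_features": sel.selected,
        "cv_accuracy": {c.model_type: c.mean_cv_accuracy for c in candidates},
        "locked_model": locked.model_type,
        "evaluation": ev,
        "survival": surv,
    }
    report_path = out_dir / "report.json"
    report_path.write_text(json.dumps(report, indent=2), encoding="utf-8")

    outputs = {
        p.name: _sha256(p)
        for p in (features_path, model_path, risk_path, report_path)
    }
    manifest = {
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "outputs": outputs,
        "timings_s": timings,
        "n_features": len(feature_names(cfg.catalog)),
    }
    (out_dir / "run_manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return manifest
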