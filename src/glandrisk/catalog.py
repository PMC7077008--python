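"""Image-level feature catalog.

Assembles one named feature vector per image/core from three families:

a. image-wide aggregations (mean/sd/median/range) of per-gland shape
   descriptors — ``<agg>_<descriptor>``;
b. image-wide aggregations of neighborhood ("local") statistics of the
   same descriptors — ``<agg>_<descriptor>_<stat>``, the local-disorder
   family (e.g. ``mean_circularity_entropy`` is the image mean of each
   gland's neighborhood circularity entropy, and
   ``sd_fractal_dimension_energy`` the image SD of neighborhood
   fractal-dimension energy);
c. mean/SD orientation-tensor measures — ``mean_tensor_<measure>`` /
   ``sd_tensor_<measure>``.

The default catalog is frozen (size ``CATALOG_SIZE``) and its manifest
records each feature's family and parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import FeatureVector, GlandSet
from .cooccurrence import (
    DEFAULT_BINS,
    DEFAULT_K,
    DEFAULT_RADIUS_HOPS,
    MEASURE_NAMES,
    build_graph,
    image_tensor_features,
)
from .errors import ValidationError
from .morphometry import DESCRIPTOR_NAMES, local_statistic, shape_descriptors

AGGREGATIONS = ("mean", "sd", "median", "range")
LOCAL_STATS = ("mean", "sd", "entropy", "energy")

#: the five features the locked recurrence classifier is known by
SIGNATURE_FEATURES = (
    "mean_tensor_info_measure1",
    "mean_tensor_contrast_average",
    "mean_circularity_entropy",
    "mean_tensor_contrast_energy",
    "sd_fractal_dimension_energy",
)


@dataclass(frozen=True)
class CatalogConfig:
    descriptors: tuple[str, ...] = DESCRIPTOR_NAMES
    local_stats: tuple[str, ...] = LOCAL_STATS
    aggregations: tuple[str, ...] = AGGREGATIONS
    k: int = DEFAULT_K
    B: int = DEFAULT_BINS
    radius_hops: int = DEFAULT_RADIUS_HOPS
    nbins_entropy: int = 10

    def __post_init__(self) -> None:
        if not (self.descriptors and self.local_stats and self.aggregations):
            raise ValidationError("descriptor/stat/aggregation selections must be non-empty")
        for d in self.descriptors:
            if d not in DESCRIPTOR_NAMES:
                raise ValidationError(f"unknown descriptor {d!r}")
        names = feature_names(self)
        if len(names) != len(set(names)):
            raise ValidationError("catalog produces duplicate feature names")


def feature_names(cfg: CatalogConfig) -> list[str]:
    """Catalog feature names in extraction order."""
    names: list[str] = []
    for agg in cfg.aggregations:
        for d in cfg.descriptors:
            names.append(f"{agg}_{d}")
    for agg in cfg.aggregations:
        for d in cfg.descriptors:
            for st in cfg.local_stats:
                names.append(f"{agg}_{d}_{st}")
    for prefix in ("mean", "sd"):
        for m in MEASURE_NAMES:
            names.append(f"{prefix}_tensor_{m}")
    return names


#: frozen size of the default catalog
CATALOG_SIZE = len(feature_names(CatalogConfig()))


def _aggregate(agg: str, v: np.ndarray) -> float:
    if agg == "mean":
        return float(v.mean())
    if agg == "sd":
        return float(v.std()) if len(v) > 1 else 0.0
    if agg == "median":
        return float(np.median(v))
    if agg == "range":
        return float(v.max() - v.min())
    raise ValidationError(f"unknown aggregation {agg!r}")


def extract_features(glands: GlandSet, cfg: CatalogConfig | None = None) -> FeatureVector:
    """Extract the full named feature vector for one image.

    Deterministic and invariant to gland ordering.  An empty GlandSet
    yields an all-zero vector with the warning flag set.
    """
    cfg = cfg or CatalogConfig()
    names = feature_names(cfg)
    if len(glands) == 0:
        return FeatureVector(
            image_id=glands.image_id, values={n: 0.0 for n in names}, warning=True
        )
    order = np.argsort([g.id for g in glands])  # order-invariance
    gl = [glands.glands[i] for i in order]
    gset = GlandSet(image_id=glands.image_id, glands=gl, provenance=glands.provenance)
    desc_rows = [shape_descriptors(g).scalars() for g in gset]
    desc = {d: np.array([r[d] for r in desc_rows]) for d in cfg.descriptors}
    graph = build_graph(gset.centroids, k=cfg.k)
    neighborhoods = [sorted({i} | set(graph.adjacency[i])) for i in range(len(gset))]
    values: dict[str, float] = {}
    for agg in cfg.aggregations:
        for d in cfg.descriptors:
            values[f"{agg}_{d}"] = _aggregate(agg, desc[d])
    local = {
        (d, st): local_statistic(desc[d], neighborhoods, st, nbins=cfg.nbins_entropy)
        for d in cfg.descriptors
        for st in cfg.local_stats
    }
    for agg in cfg.aggregations:
        for d in cfg.descriptors:
            for st in cfg.local_stats:
                values[f"{agg}_{d}_{st}"] = _aggregate(agg, local[(d, st)])
    tensor, _ = image_tensor_features(gset, k=cfg.k, B=cfg.B, radius_hops=cfg.radius_hops)
    values.update(tensor)
    assert list(values.keys()) == names
    return FeatureVector(image_id=glands.image_id, values=values, warning=False)


def feature_manifest(cfg: CatalogConfig | None = None) -> pd.DataFrame:
    """One row per catalog feature: name, family, parameters.

    Row order matches :func:`extract_features` exactly.
    """
    cfg = cfg or CatalogConfig()
    rows = []
    for agg in cfg.aggregations:
        for d in cfg.descriptors:
            rows.append(
                {"name": f"{agg}_{d}", "family": "shape_aggregate",
                 "parameters": f"agg={agg};descriptor={d}"}
            )
    for agg in cfg.aggregations:
        for d in cfg.descriptors:
            for st in cfg.local_stats:
                rows.append(
                    {"name": f"{agg}_{d}_{st}", "family": "local_disorder",
                     "parameters": (
                         f"agg={agg};descriptor={d};stat={st};"
                         f"k={cfg.k};nbins={cfg.nbins_entropy}"
                     )}
                )
    for prefix in ("mean", "sd"):
        for m in MEASURE_NAMES:
            rows.append(
                {"name": f"{prefix}_tensor_{m}", "family": "orientation_tensor",
                 "parameters": (
                     f"agg={prefix};measure={m};k={cfg.k};B={cfg.B};"
                     f"radius_hops={cfg.radius_hops}"
                 )}
            )
    return pd.DataFrame(rows)


def extract_cohort_features(
    layouts: list[GlandSet], cfg: CatalogConfig | None = None
) -> pd.DataFrame:
    """Feature table (rows = images, columns = catalog order)."""
    cfg = cfg or CatalogConfig()
    vecs = [extract_features(gs, cfg) for gs in layouts]
    df = pd.DataFrame([v.values for v in vecs])
    df.insert(0, "image_id", [v.image_id for v in vecs])
    return df
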