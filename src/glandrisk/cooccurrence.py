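"""Orientation co-occurrence ("tensor") disorder features.

Gland long-axis orientations are quantized into ``B`` axial bins; for
each gland, the orientations of neighboring gland pairs (edges of a
symmetrized k-nearest-neighbor graph within a hop radius) are
accumulated into a symmetric B x B joint distribution, from which
Haralick-type second-order statistics are computed.  Contrast terms use
the circular bin distance ``d(i, j) = min(|i-j|, B - |i-j|)`` because
orientation is periodic: bins 0 and B-1 are adjacent.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from scipy.spatial import cKDTree

from .core import GlandSet
from .errors import DomainError

DEFAULT_BINS = 18
DEFAULT_K = 5
DEFAULT_RADIUS_HOPS = 1


@dataclass
class GlandGraph:
    """Symmetrized k-nearest-neighbor graph over gland centroids."""

    n: int
    edges: set[tuple[int, int]]
    k: int

    def __post_init__(self) -> None:
        self.adjacency: list[list[int]] = [[] for _ in range(self.n)]
        for a, b in sorted(self.edges):
            self.adjacency[a].append(b)
            self.adjacency[b].append(a)

    def ball(self, node: int, radius_hops: int) -> set[int]:
        """Nodes within radius_hops of node (including node)."""
        seen = {node}
        frontier = {node}
        for _ in range(radius_hops):
            frontier = {
                nb for u in frontier for nb in self.adjacency[u]
            } - seen
            seen |= frontier
        return seen


@dataclass
class CooccurrenceMatrix:
    """Normalized symmetric joint distribution of neighbor orientation bins.

    ``empty_edges`` marks the isolated-gland convention: when a gland has
    no edge in its neighborhood the matrix is uniform (1/B^2) and flagged
    rather than NaN.
    """

    B: int
    p: np.ndarray
    empty_edges: bool = False


def build_graph(centroids: np.ndarray, k: int) -> GlandGraph:
    """k-nearest-neighbor graph on (x, y) centroids, union-symmetrized.

    k is capped at n - 1; a single gland yields a valid empty graph.
    """
    centroids = np.asarray(centroids, dtype=float).reshape(-1, 2)
    n = len(centroids)
    if n == 0:
        raise DomainError("cannot build a neighborhood graph on zero glands")
    if k < 1:
        raise DomainError("k must be >= 1")
    k = min(k, n - 1)
    edges: set[tuple[int, int]] = set()
    if k >= 1:
        tree = cKDTree(centroids)
        _, idx = tree.query(centroids, k=k + 1)
        idx = np.atleast_2d(idx)
        for i in range(n):
            for j in idx[i, 1:]:
                a, b = (i, int(j)) if i < j else (int(j), i)
                edges.add((a, b))
    return GlandGraph(n=n, edges=edges, k=k)


def quantize_orientation(theta_deg: float | np.ndarray, B: int) -> np.ndarray | int:
    """Axial angle(s) in [0, 180) to bin index floor(theta / (180/B)).

    180 wraps to bin 0 (floating-point guard only; 180 itself is outside
    the domain).
    """
    if B < 2:
        raise DomainError("need at least 2 orientation bins")
    theta = np.asarray(theta_deg, dtype=float)
    if np.any(theta < 0) or np.any(theta >= 180.0):
        raise DomainError("orientation outside [0, 180)")
    bins = np.floor(theta / (180.0 / B)).astype(int) % B
    return int(bins) if np.isscalar(theta_deg) else bins


def local_cooccurrence(
    bins: np.ndarray,
    graph: GlandGraph,
    gland: int,
    radius_hops: int = DEFAULT_RADIUS_HOPS,
    B: int = DEFAULT_BINS,
) -> CooccurrenceMatrix:
    """Co-occurrence matrix of orientation bins around one gland.

    Every edge whose two endpoints lie within ``radius_hops`` of the
    gland contributes symmetrically at (b_i, b_j) and (b_j, b_i); the
    matrix is normalized to sum 1.  An isolated gland returns the
    flagged uniform matrix.
    """
    if not 0 <= gland < graph.n:
        raise DomainError(f"gland {gland} not in graph of size {graph.n}")
    ball = graph.ball(gland, radius_hops)
    p = np.zeros((B, B), dtype=float)
    n_edges = 0
    for u in ball:
        for v in graph.adjacency[u]:
            if u < v and v in ball:
                p[bins[u], bins[v]] += 1.0
                p[bins[v], bins[u]] += 1.0
                n_edges += 1
    if n_edges == 0:
        return CooccurrenceMatrix(B=B, p=np.full((B, B), 1.0 / B**2), empty_edges=True)
    return CooccurrenceMatrix(B=B, p=p / p.sum(), empty_edges=False)


@dataclass
class TensorMeasures:
    """Haralick-type statistics of an orientation co-occurrence matrix."""

    contrast_energy: float
    contrast_average: float
    contrast_variance: float
    entropy: float
    energy: float
    correlation: float
    intensity_average: float
    intensity_variance: float
    intensity_entropy: float
    info_measure1: float
    info_measure2: float
    max_probability: float
    diag_dominance: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}


MEASURE_NAMES = tuple(f.name for f in fields(TensorMeasures))


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def circular_distance(B: int) -> np.ndarray:
    """B x B matrix of circular bin distances min(|i-j|, B-|i-j|)."""
    i = np.arange(B)
    d = np.abs(i[:, None] - i[None, :])
    return np.minimum(d, B - d)


def tensor_measures(M: CooccurrenceMatrix) -> TensorMeasures:
    """All second-order measures of one co-occurrence matrix.

    Contrast terms are moments of the circular-distance profile
    q(d) = sum_{d(i,j)=d} p(i,j).  info_measure1 is
    (HXY - HXY1)/max(HX, HY), which is <= 0 and equals 0 exactly when
    the matrix factorizes into its marginals; info_measure2 is
    sqrt(1 - exp(-2(HXY2 - HXY))).  Degenerate marginals follow the
    0*log0 = 0 and 0/0 = 0 conventions.
    """
    p = M.p
    B = M.B
    d = circular_distance(B)
    contrast_average = float((d * p).sum())
    contrast_energy = float((d.astype(float) ** 2 * p).sum())
    contrast_variance = float(((d - contrast_average) ** 2 * p).sum())
    hxy = _entropy_bits(p.ravel())
    energy = float((p**2).sum())
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    outer = px[:, None] * py[None, :]
    with np.errstate(divide="ignore"):
        log_outer = np.where(outer > 0, np.log2(np.where(outer > 0, outer, 1.0)), 0.0)
    hxy1 = float(-(p * log_outer).sum())
    hxy2 = _entropy_bits(outer.ravel())
    hx = _entropy_bits(px)
    hy = _entropy_bits(py)
    denom = max(hx, hy)
    info1 = (hxy - hxy1) / denom if denom > 0 else 0.0
    info2 = float(np.sqrt(max(1.0 - np.exp(-2.0 * max(hxy2 - hxy, 0.0)), 0.0)))
    i = np.arange(B, dtype=float)
    mu_x = float((i * px).sum())
    mu_y = float((i * py).sum())
    var_x = float(((i - mu_x) ** 2 * px).sum())
    var_y = float(((i - mu_y) ** 2 * py).sum())
    if var_x > 0 and var_y > 0:
        corr = float(((i[:, None] * i[None, :] * p).sum() - mu_x * mu_y) / np.sqrt(var_x * var_y))
    else:
        corr = 0.0
    return TensorMeasures(
        contrast_energy=contrast_energy,
        contrast_average=contrast_average,
        contrast_variance=contrast_variance,
        entropy=hxy,
        energy=energy,
        correlation=corr,
        intensity_average=mu_x,
        intensity_variance=var_x,
        intensity_entropy=_entropy_bits(px),
        info_measure1=float(info1),
        info_measure2=info2,
        max_probability=float(p.max()),
        diag_dominance=float(np.trace(p)),
    )


def image_tensor_features(
    glands: GlandSet,
    k: int = DEFAULT_K,
    B: int = DEFAULT_BINS,
    radius_hops: int = DEFAULT_RADIUS_HOPS,
) -> tuple[dict[str, float], bool]:
    """Mean/SD of per-gland tensor measures across an image.

    Returns (features, warning): feature names are
    ``mean_tensor_<measure>`` and ``sd_tensor_<measure>``; the warning
    flag is set (with an all-zero vector) for an empty GlandSet.
    """
    names = [f"mean_tensor_{m}" for m in MEASURE_NAMES] + [
        f"sd_tensor_{m}" for m in MEASURE_NAMES
    ]
    if len(glands) == 0:
        return {n: 0.0 for n in names}, True
    graph = build_graph(glands.centroids, k=k)
    bins = quantize_orientation(glands.orientations_deg, B)
    rows = np.empty((len(glands), len(MEASURE_NAMES)))
    for gi in range(len(glands)):
        m = tensor_measures(local_cooccurrence(bins, graph, gi, radius_hops, B))
        rows[gi] = [getattr(m, name) for name in MEASURE_NAMES]
    means = rows.mean(axis=0)
    sds = rows.std(axis=0) if len(glands) > 1 else np.zeros(len(MEASURE_NAMES))
    out = {f"mean_tensor_{m}": float(v) for m, v in zip(MEASURE_NAMES, means)}
    out.update({f"sd_tensor_{m}": float(v) for m, v in zip(MEASURE_NAMES, sds)})
    return out, False
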