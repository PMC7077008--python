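"""Orientation co-occurrence: graph, quantization, Haralick-type measures."""

import numpy as np
import pytest

from glandrisk.cooccurrence import (
    CooccurrenceMatrix,
    build_graph,
    circular_distance,
    image_tensor_features,
    local_cooccurrence,
    quantize_orientation,
    tensor_measures,
)
from glandrisk.errors import DomainError
from glandrisk.synthetic import SynthConfig, sample_layout


def brute_force_measures(p: np.ndarray) -> dict:
    """Independent double-loop evaluation of every measure's formula."""
    B = p.shape[0]
    out = {}
    ca = ce = 0.0
    for i in range(B):
        for j in range(B):
            d = min(abs(i - j), B - abs(i - j))
            ca += d * p[i, j]
            ce += d * d * p[i, j]
    cv = 0.0
    for i in range(B):
        for j in range(B):
            d = min(abs(i - j), B - abs(i - j))
            cv += (d - ca) ** 2 * p[i, j]
    out["contrast_average"], out["contrast_energy"], out["contrast_variance"] = ca, ce, cv
    hxy = -sum(
        p[i, j] * np.log2(p[i, j]) for i in range(B) for j in range(B) if p[i, j] > 0
    )
    out["entropy"] = hxy
    out["energy"] = sum(p[i, j] ** 2 for i in range(B) for j in range(B))
    px = [sum(p[i, j] for j in range(B)) for i in range(B)]
    py = [sum(p[i, j] for i in range(B)) for j in range(B)]
    hx = -sum(v * np.log2(v) for v in px if v > 0)
    hy = -sum(v * np.log2(v) for v in py if v > 0)
    hxy1 = -sum(
        p[i, j] * np.log2(px[i] * py[j])
        for i in range(B)
        for j in range(B)
        if p[i, j] > 0 and px[i] * py[j] > 0
    )
    hxy2 = -sum(
        px[i] * py[j] * np.log2(px[i] * py[j])
        for i in range(B)
        for j in range(B)
        if px[i] * py[j] > 0
    )
    denom = max(hx, hy)
    out["info_measure1"] = (hxy - hxy1) / denom if denom > 0 else 0.0
    out["info_measure2"] = np.sqrt(max(1 - np.exp(-2 * max(hxy2 - hxy, 0.0)), 0.0))
    mu_x = sum(i * px[i] for i in range(B))
    mu_y = sum(j * py[j] for j in range(B))
    var_x = sum((i - mu_x) ** 2 * px[i] for i in range(B))
    var_y = sum((j - mu_y) ** 2 * py[j] for j in range(B))
    out["intensity_average"] = mu_x
    out["intensity_variance"] = var_x
    out["intensity_entropy"] = hx
    if var_x > 0 and var_y > 0:
        cov = sum(i * j * p[i, j] for i in range(B) for j in range(B)) - mu_x * mu_y
        out["correlation"] = cov / np.sqrt(var_x * var_y)
    else:
        out["correlation"] = 0.0
    out["max_probability"] = p.max()
    out["diag_dominance"] = sum(p[i, i] for i in range(B))
    return out


def random_symmetric(rng, B=6):
    m = rng.random((B, B))
    m = m + m.T
    return m / m.sum()


class TestBuildGraph:
    def test_collinear_chain(self):
        g = build_graph(np.array([[0, 0], [10, 0], [20, 0]], float), k=1)
        assert g.edges == {(0, 1), (1, 2)}

    def test_k_capped_complete_graph(self):
        pts = np.random.default_rng(0).random((7, 2)) * 100
        g = build_graph(pts, k=10)
        assert len(g.edges) == 7 * 6 // 2

    def test_single_gland_empty_graph(self):
        g = build_graph(np.array([[5.0, 5.0]]), k=3)
        assert g.edges == set()

    def test_zero_glands_rejected(self):
        with pytest.raises(DomainError):
            build_graph(np.empty((0, 2)), k=1)


class TestQuantize:
    @pytest.mark.parametrize("theta, expected", [(0.0, 0), (179.9, 17), (90.0, 9)])
    def test_examples(self, theta, expected):
        assert quantize_orientation(theta, 18) == expected

    def test_domain(self):
        with pytest.raises(DomainError):
            quantize_orientation(180.0, 18)
        with pytest.raises(DomainError):
            quantize_orientation(-0.1, 18)
        with pytest.raises(DomainError):
            quantize_orientation(10.0, 1)


class TestLocalCooccurrence:
    def test_shared_bin_all_mass_diagonal(self):
        pts = np.array([[0, 0], [10, 0], [0, 10], [10, 10]], float)
        g = build_graph(pts, k=3)
        bins = np.array([4, 4, 4, 4])
        M = local_cooccurrence(bins, g, 0, radius_hops=1, B=18)
        assert M.p[4, 4] == pytest.approx(1.0)
        assert tensor_measures(M).contrast_energy == 0.0

    def test_single_edge_half_half(self):
        g = build_graph(np.array([[0, 0], [10, 0]], float), k=1)
        M = local_cooccurrence(np.array([2, 5]), g, 0, B=18)
        assert M.p[2, 5] == pytest.approx(0.5)
        assert M.p[5, 2] == pytest.approx(0.5)

    def test_isolated_gland_uniform_flagged(self):
        g = build_graph(np.array([[0.0, 0.0]]), k=1)
        M = local_cooccurrence(np.array([3]), g, 0, B=18)
        assert M.empty_edges
        assert np.allclose(M.p, 1 / 18**2)

    def test_normalized_and_symmetric(self, rng):
        gs, _ = sample_layout(SynthConfig(n_glands=25, field_size=448, seed=8))
        g = build_graph(gs.centroids, k=5)
        bins = quantize_orientation(gs.orientations_deg, 18)
        for gi in range(len(gs)):
            M = local_cooccurrence(bins, g, gi, B=18)
            assert M.p.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.allclose(M.p, M.p.T, atol=1e-9)


class TestTensorMeasures:
    def test_diagonal_matrix_zero_contrast(self, rng):
        p = np.diag(rng.random(8))
        m = tensor_measures(CooccurrenceMatrix(B=8, p=p / p.sum()))
        assert m.contrast_average == 0.0
        assert m.contrast_energy == 0.0
        assert m.contrast_variance == 0.0
        assert m.diag_dominance == pytest.approx(1.0)

    def test_uniform_matrix_identities(self):
        B = 4
        m = tensor_measures(CooccurrenceMatrix(B=B, p=np.full((B, B), 1 / B**2)))
        assert m.entropy == pytest.approx(2 * np.log2(B), abs=1e-12)
        assert m.energy == pytest.approx(1 / B**2, abs=1e-12)

    def test_product_matrix_zero_info1(self, rng):
        px = rng.random(6)
        px /= px.sum()
        py = px[::-1].copy()
        p = np.outer(px, py)
        m = tensor_measures(CooccurrenceMatrix(B=6, p=p))
        assert m.info_measure1 == pytest.approx(0.0, abs=1e-12)

    def test_single_pair_distance_three(self):
        B = 18
        p = np.zeros((B, B))
        p[1, 4] = p[4, 1] = 0.5
        m = tensor_measures(CooccurrenceMatrix(B=B, p=p))
        assert m.contrast_energy == pytest.approx(9.0)
        assert m.contrast_average == pytest.approx(3.0)

    def test_entropy_and_energy_bounds(self, rng):
        for _ in range(20):
            p = random_symmetric(rng)
            m = tensor_measures(CooccurrenceMatrix(B=6, p=p))
            assert 0 <= m.entropy <= 2 * np.log2(6) + 1e-12
            assert 0 < m.energy <= 1
            assert -1 - 1e-12 <= m.info_measure1 <= 1e-12

    def test_brute_force_oracle_50_matrices(self, rng):
        for _ in range(50):
            p = random_symmetric(rng)
            mine = tensor_measures(CooccurrenceMatrix(B=6, p=p)).as_dict()
            ref = brute_force_measures(p)
            for k, v in ref.items():
                assert mine[k] == pytest.approx(v, abs=1e-10), k


class TestImageTensorFeatures:
    def _layout(self, seed, kappa, n=25):
        return sample_layout(SynthConfig(n_glands=n, field_size=448, seed=seed, kappa=kappa))[0]

    def test_aligned_zero_contrast(self):
        from conftest import ellipse_polygon, gland_from_polygon
        from glandrisk.core import GlandSet

        polys = [ellipse_polygon(40 + 90 * i, 40 + 90 * j, 30, 12) for i in range(3) for j in range(3)]
        glands = [gland_from_polygon(p, shape=(320, 320), gland_id=k) for k, p in enumerate(polys)]
        gs = GlandSet(image_id="grid", glands=glands)
        feats, warn = image_tensor_features(gs)
        assert not warn
        assert feats["mean_tensor_contrast_energy"] == pytest.approx(0.0, abs=1e-12)

    def test_uniform_entropy_exceeds_aligned(self):
        for seed in range(10):
            dis = image_tensor_features(self._layout(seed, kappa=0.0))[0]
            ali = image_tensor_features(self._layout(seed + 100, kappa=200.0))[0]
            assert dis["mean_tensor_entropy"] > ali["mean_tensor_entropy"]

    def test_contrast_average_monotone_in_kappa(self):
        levels = (0.0, 2.0, 20.0)
        wins = {pair: 0 for pair in ((0, 1), (1, 2))}
        for seed in range(20):
            vals = [
                image_tensor_features(self._layout(seed + 37 * i, kappa=k))[0][
                    "mean_tensor_contrast_average"
                ]
                for i, k in enumerate(levels)
            ]
            for a, b in wins:
                wins[(a, b)] += vals[b] <= vals[a]
        for pair, w in wins.items():
            assert w >= 14, pair  # majority ordering

    def test_whole_bin_rotation_invariance(self):
        gs = self._layout(3, kappa=1.0)
        base = image_tensor_features(gs)[0]
        shifted_gs = gs
        for g in shifted_gs:
            g.orientation_deg = (g.orientation_deg + 30.0) % 180.0  # 3 whole bins
        rot = image_tensor_features(shifted_gs)[0]
        # correlation and the marginal moment measures reference the linear
        # bin index, so only the circular/permutation-invariant measures are
        # exactly shift-invariant
        variant = ("correlation", "intensity_average", "intensity_variance")
        for k in base:
            if any(k.endswith(v) for v in variant):
                continue
            assert rot[k] == pytest.approx(base[k], abs=1e-12), k

    def test_empty_set_zero_sentinel(self):
        from glandrisk.core import GlandSet

        feats, warn = image_tensor_features(GlandSet(image_id="empty", glands=[]))
        assert warn
        assert all(v == 0.0 for v in feats.values())
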