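"""Shared fixtures: analytic shapes with known descriptors."""

from __future__ import annotations

import numpy as np
import pytest

from glandrisk.core import Gland, GlandSet, rasterize_polygon
from glandrisk.morphometry import orientation_from_mask


def regular_polygon(cx, cy, r, n=256, phase=0.0):
    """Vertices of a regular n-gon approximating a circle of radius r."""
    phi = np.linspace(0, 2 * np.pi, n, endpoint=False) + phase
    return np.column_stack([cx + r * np.cos(phi), cy + r * np.sin(phi)])


def ellipse_polygon(cx, cy, a, b, theta_deg=0.0, n=256):
    phi = np.linspace(0, 2 * np.pi, n, endpoint=False)
    x, y = a * np.cos(phi), b * np.sin(phi)
    t = np.radians(theta_deg)
    rot = np.array([[np.cos(t), -np.sin(t)], [np.sin(t), np.cos(t)]])
    pts = (rot @ np.vstack([x, y])).T
    return pts + [cx, cy]


def koch_polyline(iterations: int, span: float) -> np.ndarray:
    """Koch-curve polyline of the given iteration depth and horizontal span."""
    pts = np.array([[0.0, 0.0], [float(span), 0.0]])
    rot = np.array([[0.5, -np.sqrt(3) / 2], [np.sqrt(3) / 2, 0.5]])
    for _ in range(iterations):
        new = []
        for a, b in zip(pts[:-1], pts[1:]):
            d = (b - a) / 3
            p1, p3 = a + d, a + 2 * d
            new += [a, p1, p1 + rot @ d, p3]
        new.append(pts[-1])
        pts = np.array(new)
    return pts


def gland_from_polygon(verts: np.ndarray, shape=None, gland_id: int = 0) -> Gland:
    """Rasterize a polygon into a validated Gland on a tight canvas."""
    verts = np.asarray(verts, dtype=float)
    if shape is None:
        shape = (int(np.ceil(verts[:, 1].max())) + 2, int(np.ceil(verts[:, 0].max())) + 2)
    mask = rasterize_polygon(verts, shape)
    theta, degen = orientation_from_mask(mask)
    ys, xs = np.nonzero(mask)
    return Gland(
        id=gland_id,
        boundary=verts,
        mask=mask,
        centroid=(float(xs.mean()), float(ys.mean())),
        orientation_deg=theta,
        degenerate=degen,
    )


def gland_set_from_polygons(polys, shape, image_id="fixture") -> GlandSet:
    glands = [gland_from_polygon(p, shape=shape, gland_id=i) for i, p in enumerate(polys)]
    return GlandSet(image_id=image_id, glands=glands)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
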