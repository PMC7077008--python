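"""Per-gland orientation, shape and size descriptors.

Orientation is the axial angle of the principal axis of the mask's second
central moments, reported in degrees on ``[0, 180)`` in the shared image
frame (x = column, y = row).  Shape descriptors combine the boundary
polygon (perimeter, convexity, boundary Fourier spectrum, box-counting
fractal dimension) with the rasterized mask (area, moment-based axis
statistics).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
from shapely.geometry import Polygon

from .core import Gland, polygon_of
from .errors import DomainError, ValidationError

#: box side lengths (pixels) used for the box-counting fit
BOX_SIZES = (2, 4, 8, 16, 32, 64)

#: every boundary is rescaled to this span before box counting, so the
#: fixed box-size range always probes the same relative scales and the
#: estimate is scale-invariant by construction
_FD_NORM_SPAN = 512.0

#: number of boundary Fourier harmonics reported
N_FOURIER = 10

_DEGENERATE_EIG_RTOL = 0.01  # eigenvalue gap below 1% => isotropic


def _second_moments(mask: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Central second-moment matrix [[mxx, mxy], [mxy, myy]] and centroid."""
    rows = np.flatnonzero(mask.any(axis=1))
    cols = np.flatnonzero(mask.any(axis=0))
    sub = mask[rows[0] : rows[-1] + 1, cols[0] : cols[-1] + 1]
    ys, xs = np.nonzero(sub)
    ys = ys + rows[0]
    xs = xs + cols[0]
    cx, cy = xs.mean(), ys.mean()
    dx, dy = xs - cx, ys - cy
    m = np.array(
        [[np.mean(dx * dx), np.mean(dx * dy)], [np.mean(dx * dy), np.mean(dy * dy)]]
    )
    return m, (float(cx), float(cy))


def orientation_from_mask(mask: np.ndarray) -> tuple[float, bool]:
    """Principal-axis angle in [0, 180) and a degeneracy flag.

    The angle is measured from the +x axis toward +y (row) in the image
    frame.  When the two moment eigenvalues differ by less than 1% the
    shape is treated as isotropic: the flag is set and the angle is 0 by
    convention.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 5:
        raise DomainError("orientation needs a mask of at least 5 pixels")
    m, _ = _second_moments(mask)
    evals = np.linalg.eigvalsh(m)
    lo, hi = float(evals[0]), float(evals[1])
    if hi <= 0 or (hi - lo) < _DEGENERATE_EIG_RTOL * hi:
        return 0.0, True
    theta = 0.5 * np.arctan2(2.0 * m[0, 1], m[0, 0] - m[1, 1])
    deg = float(np.degrees(theta) % 180.0)
    if deg >= 180.0:  # fp guard
        deg = 0.0
    return deg, False


def orientation(g: Gland) -> tuple[float, bool]:
    """Axial orientation of a gland's mask (degrees in [0, 180), flag)."""
    return orientation_from_mask(g.mask)


def _resample_closed(vertices: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polygon to n equally spaced arc-length points.

    The traversal is anchored at the lexicographically smallest vertex so
    the sample set is invariant under a cyclic shift of the vertex list.
    """
    v = np.asarray(vertices, dtype=float)
    anchor = np.lexsort((v[:, 1], v[:, 0]))[0]
    v = np.roll(v, -anchor, axis=0)
    v = np.vstack([v, v[:1]])
    seg = np.linalg.norm(np.diff(v, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total <= 0:
        raise DomainError("degenerate boundary with zero perimeter")
    t = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(t, s, v[:, 0])
    y = np.interp(t, s, v[:, 1])
    return np.column_stack([x, y])


def _densify(vertices: np.ndarray, step: float) -> np.ndarray:
    """Points along the closed polyline at spacing <= step."""
    v = np.asarray(vertices, dtype=float)
    v = np.vstack([v, v[:1]])
    seg = np.linalg.norm(np.diff(v, axis=0), axis=1)
    total = float(seg.sum())
    n = max(int(np.ceil(total / step)), 16)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    t = np.linspace(0.0, total, n, endpoint=False)
    x = np.interp(t, s, v[:, 0])
    y = np.interp(t, s, v[:, 1])
    return np.column_stack([x, y])


def fractal_dimension(boundary: np.ndarray) -> float:
    """Box-counting dimension of a boundary polyline.

    The boundary is densified to sub-pixel spacing, rasterized, and the
    number of occupied boxes N(s) is counted on grids of side
    ``s in BOX_SIZES`` anchored at the bounding-box corner.  The returned
    value is the least-squares slope of log N(s) against log(1/s).
    Boundaries are first rescaled uniformly to a 512 px span so the
    fixed box sizes probe the same relative scales for every gland.
    """
    b = np.asarray(boundary, dtype=float)
    if b.ndim != 2 or b.shape[1] != 2 or b.shape[0] < 3:
        raise DomainError("boundary must be an (n>=3, 2) coordinate array")
    span = float(max(np.ptp(b[:, 0]), np.ptp(b[:, 1])))
    if span < BOX_SIZES[0]:
        raise DomainError(
            f"boundary span {span:.2f}px is below the smallest box size"
        )
    b = b * (_FD_NORM_SPAN / span)
    pts = _densify(b, step=0.5)
    if pts.shape[0] < 16:
        raise DomainError("boundary has fewer than 16 points after resampling")
    pix = np.floor(pts - pts.min(axis=0)).astype(np.int64)
    counts = []
    for s in BOX_SIZES:
        boxes = pix // s
        counts.append(len(np.unique(boxes[:, 0] * (1 << 32) + boxes[:, 1])))
    x = np.log(1.0 / np.array(BOX_SIZES, dtype=float))
    y = np.log(np.array(counts, dtype=float))
    slope = float(np.polyfit(x, y, 1)[0])
    return slope


def fourier_energies(boundary: np.ndarray, n_harmonics: int = N_FOURIER) -> np.ndarray:
    """Normalized magnitudes of the first boundary Fourier harmonics.

    The closed boundary is arc-length resampled to 128 points (anchored at
    the lexicographically smallest vertex, so the spectrum is invariant
    under a cyclic shift of the vertex list), transformed as a complex
    signal x + iy, and harmonic k is reported as
    sqrt(|Z_k|^2 + |Z_-k|^2) normalized by harmonic 1.
    """
    pts = _resample_closed(boundary, 128)
    z = pts[:, 0] + 1j * pts[:, 1]
    spec = np.fft.fft(z - z.mean())
    mags = np.array(
        [np.hypot(abs(spec[k]), abs(spec[-k])) for k in range(1, n_harmonics + 1)]
    )
    if mags[0] <= 0:
        raise DomainError("degenerate boundary: first harmonic has zero energy")
    return mags / mags[0]


@dataclass
class ShapeDescriptors:
    """Scalar shape/size descriptors for one gland (pixel units)."""

    area: float
    perimeter: float
    circularity: float
    eccentricity: float
    solidity: float
    axis_ratio: float
    equivalent_diameter: float
    fractal_dimension: float
    fourier_energy: np.ndarray

    def scalars(self) -> dict[str, float]:
        """Flat name -> value map (Fourier harmonics expanded)."""
        out = {
            f.name: float(getattr(self, f.name))
            for f in fields(self)
            if f.name != "fourier_energy"
        }
        for i, v in enumerate(self.fourier_energy, start=1):
            out[f"fourier_energy_{i}"] = float(v)
        return out


#: descriptor names produced by :func:`shape_descriptors`, catalog order
DESCRIPTOR_NAMES = (
    "area",
    "perimeter",
    "circularity",
    "eccentricity",
    "solidity",
    "axis_ratio",
    "equivalent_diameter",
    "fractal_dimension",
) + tuple(f"fourier_energy_{i}" for i in range(1, N_FOURIER + 1))


def shape_descriptors(g: Gland) -> ShapeDescriptors:
    """Compute all shape/size descriptors for one gland.

    Area comes from the mask (pixel count); perimeter from the boundary
    polygon; circularity is 4*pi*A/P^2 (1 for a disc); solidity is the
    polygon area over its convex-hull area; eccentricity and the
    minor/major axis ratio come from the mask's second moments.
    """
    poly = polygon_of(g.boundary)
    area = float(g.mask.sum())
    if area <= 0:
        raise ValidationError(f"gland {g.id}: empty mask")
    perim = float(poly.length)
    if perim <= 0:
        raise ValidationError(f"gland {g.id}: zero perimeter")
    circularity = 4.0 * np.pi * area / perim**2
    hull: Polygon = poly.convex_hull
    solidity = float(poly.area / hull.area) if hull.area > 0 else 1.0
    m, _ = _second_moments(g.mask)
    evals = np.linalg.eigvalsh(m)
    lo, hi = max(float(evals[0]), 0.0), max(float(evals[1]), 1e-12)
    ecc = float(np.sqrt(max(1.0 - lo / hi, 0.0)))
    axis_ratio = float(np.sqrt(lo / hi))
    eqd = float(np.sqrt(4.0 * area / np.pi))
    fd = fractal_dimension(g.boundary)
    fe = fourier_energies(g.boundary)
    return ShapeDescriptors(
        area=area,
        perimeter=perim,
        circularity=float(circularity),
        eccentricity=ecc,
        solidity=min(solidity, 1.0),
        axis_ratio=axis_ratio,
        equivalent_diameter=eqd,
        fractal_dimension=fd,
        fourier_energy=fe,
    )


def local_statistic(
    values: np.ndarray,
    neighborhoods: list[list[int]],
    stat: str,
    nbins: int = 10,
) -> np.ndarray:
    """Neighborhood statistic of a per-gland value, one result per gland.

    ``neighborhoods[i]`` lists the gland indices making up gland i's
    neighborhood (conventionally the gland itself plus its graph
    neighbors).  ``stat`` is one of mean/sd/entropy/energy; entropy is in
    bits with 0*log0 = 0 and energy is the sum of squared bin
    proportions.  For entropy/energy, values are binned into ``nbins``
    equal bins spanning the observed min-max range of the whole image;
    a constant image yields entropy 0 and energy 1.
    """
    values = np.asarray(values, dtype=float)
    if stat not in {"mean", "sd", "entropy", "energy"}:
        raise DomainError(f"unknown statistic {stat!r}")
    if any(len(nb) == 0 for nb in neighborhoods):
        raise DomainError("every neighborhood must be non-empty")
    if stat in {"entropy", "energy"}:
        if nbins < 2:
            raise DomainError("entropy/energy need nbins >= 2")
        lo, hi = float(values.min()), float(values.max())
        # a spread at float-rounding scale is a constant image, not signal
        if hi - lo > 1e-9 * max(abs(hi), abs(lo), 1.0):
            binned = np.minimum(
                ((values - lo) / (hi - lo) * nbins).astype(int), nbins - 1
            )
        else:
            binned = np.zeros(len(values), dtype=int)
    out = np.empty(len(neighborhoods), dtype=float)
    for i, nb in enumerate(neighborhoods):
        v = values[nb]
        if stat == "mean":
            out[i] = v.mean()
        elif stat == "sd":
            out[i] = v.std()
        else:
            p = np.bincount(binned[nb], minlength=nbins) / len(nb)
            p = p[p > 0]
            if stat == "entropy":
                out[i] = float(-(p * np.log2(p)).sum())
            else:
                out[i] = float((p**2).sum())
    return out
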