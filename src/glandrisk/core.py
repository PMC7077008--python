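"""Core domain types for gland-level histomorphometry.

Conventions shared by every module:

* coordinates are 0-based ``(x, y) = (column, row)`` with pixel centers at
  integer positions;
* polygons are sequences of ``(x, y)`` vertices in pixel units, implicitly
  closed (first vertex is not repeated);
* gland orientations are axial angles in degrees on ``[0, 180)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import shapely
from shapely.geometry import Polygon

from .errors import ValidationError


@dataclass
class GlandImage:
    """An RGB histology raster (TMA core or tile).

    Parameters
    ----------
    pixels
        ``(height, width, 3)`` uint8 array.
    id
        Identifier, usually the file stem.
    pixel_size
        Physical side length of one pixel in micrometres, if known.
    """

    pixels: np.ndarray
    id: str = ""
    pixel_size: Optional[float] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValidationError(
                f"GlandImage pixels must be (H, W, 3), got shape {px.shape}"
            )
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValidationError("GlandImage must be at least 1x1")
        self.pixels = px.astype(np.uint8, copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class Gland:
    """One segmented gland.

    ``boundary`` is a simple closed polygon in ``(x, y)`` pixel coordinates;
    ``mask`` is a binary raster aligned with the source image; ``centroid``
    is the mask centroid; ``orientation_deg`` is the axial angle of the
    principal axis in ``[0, 180)``.  ``degenerate`` marks near-isotropic
    shapes whose orientation is conventionally set to 0.
    """

    id: int
    boundary: np.ndarray
    mask: np.ndarray
    centroid: tuple[float, float]
    orientation_deg: float
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.boundary = np.asarray(self.boundary, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def area(self) -> int:
        return int(self.mask.sum())


@dataclass
class GlandSet:
    """An ordered collection of glands from one image."""

    image_id: str
    glands: list[Gland] = field(default_factory=list)
    provenance: str = "segmented"

    def __post_init__(self) -> None:
        ids = [g.id for g in self.glands]
        if len(ids) != len(set(ids)):
            raise ValidationError(f"duplicate gland ids in GlandSet {self.image_id!r}")

    def __len__(self) -> int:
        return len(self.glands)

    def __iter__(self) -> Iterator[Gland]:
        return iter(self.glands)

    def __getitem__(self, i: int) -> Gland:
        return self.glands[i]

    @property
    def centroids(self) -> np.ndarray:
        """(n, 2) array of gland centroids in (x, y) order."""
        return np.array([g.centroid for g in self.glands], dtype=float).reshape(-1, 2)

    @property
    def orientations_deg(self) -> np.ndarray:
        return np.array([g.orientation_deg for g in self.glands], dtype=float)


@dataclass
class FeatureVector:
    """Named morphometric features for one image/core.

    ``values`` preserves insertion order (the catalog order).  ``warning``
    is set when the vector was filled with a zero sentinel because the
    image contained no glands.
    """

    image_id: str
    values: dict[str, float]
    warning: bool = False

    def __post_init__(self) -> None:
        bad = [k for k, v in self.values.items() if not np.isfinite(v)]
        if bad:
            raise ValidationError(f"non-finite feature values: {bad[:5]}")

    @property
    def names(self) -> list[str]:
        return list(self.values.keys())

    def as_array(self) -> np.ndarray:
        return np.array(list(self.values.values()), dtype=float)


def polygon_of(vertices: np.ndarray) -> Polygon:
    """Shapely polygon from an (n, 2) vertex array, validated simple."""
    vertices = np.asarray(vertices, dtype=float)
    if vertices.ndim != 2 or vertices.shape[1] != 2 or vertices.shape[0] < 3:
        raise ValidationError("polygon needs at least 3 (x, y) vertices")
    poly = Polygon(vertices)
    if not poly.is_simple or not poly.is_valid:
        raise ValidationError("polygon is self-intersecting or otherwise invalid")
    return poly


def rasterize_polygon(
    vertices: np.ndarray, shape: tuple[int, int]
) -> np.ndarray:
    """Binary mask of a simple polygon on an (H, W) grid.

    A pixel belongs to the polygon iff its integer-coordinate center lies
    inside (even-odd rule; equivalent to winding for simple polygons).
    """
    poly = polygon_of(vertices)
    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    minx, miny, maxx, maxy = poly.bounds
    x0 = max(int(np.floor(minx)), 0)
    x1 = min(int(np.ceil(maxx)), w - 1)
    y0 = max(int(np.floor(miny)), 0)
    y1 = min(int(np.ceil(maxy)), h - 1)
    if x1 < x0 or y1 < y0:
        return mask
    xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
    inside = shapely.contains_xy(poly, xs.ravel(), ys.ravel())
    mask[y0 : y1 + 1, x0 : x1 + 1] = inside.reshape(xs.shape)
    return mask


def validate_gland(g: Gland) -> None:
    """Check every Gland invariant; raise ValidationError on the first failure.

    Used by readers, the segmenter and the synthetic generator so that any
    Gland observed downstream satisfies the same contract.
    """
    polygon_of(g.boundary)  # >= 3 vertices, simple
    if g.mask.sum() == 0:
        raise ValidationError(f"gland {g.id}: empty mask")
    if not (0.0 <= g.orientation_deg < 180.0):
        raise ValidationError(
            f"gland {g.id}: orientation {g.orientation_deg} outside [0, 180)"
        )


def luminance(pixels: np.ndarray) -> np.ndarray:
    """Rec. 601 luma of an (H, W, 3) uint8 raster, as float in [0, 255]."""
    px = np.asarray(pixels, dtype=float)
    return 0.299 * px[..., 0] + 0.587 * px[..., 1] + 0.114 * px[..., 2]
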