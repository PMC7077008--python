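"""Readers and writers for images, gland contours, label masks and tables.

Formats: PNG/TIFF rasters, GeoJSON polygon collections in pixel
coordinates, 16-bit label TIFFs (0 = background, k = gland k) and
comma-separated UTF-8 CSV tables.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .core import Gland, GlandImage, GlandSet, rasterize_polygon, validate_gland
from .errors import FormatError, SchemaError, ValidationError
from .morphometry import orientation_from_mask

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff"}

REQUIRED_COHORT_COLUMNS = ("patient_id", "image_id", "recurrence", "survival_time", "event")


def read_image(path: str | Path) -> GlandImage:
    """Load a PNG or TIFF raster as an RGB :class:`GlandImage`.

    Greyscale rasters are replicated to three channels; the image id is
    the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() not in _IMAGE_SUFFIXES:
        raise FormatError(f"unsupported image format: {path.suffix!r}")
    try:
        px = iio.imread(path)
    except Exception as exc:  # corrupted / not an image
        raise FormatError(f"could not decode {path}: {exc}") from exc
    px = np.asarray(px)
    if px.ndim == 2:
        px = np.stack([px] * 3, axis=-1)
    elif px.ndim == 3 and px.shape[2] == 4:
        px = px[:, :, :3]
    elif px.ndim != 3 or px.shape[2] != 3:
        raise FormatError(f"unsupported raster shape {px.shape} in {path}")
    return GlandImage(pixels=px.astype(np.uint8), id=path.stem)


def write_image(path: str | Path, img: GlandImage) -> None:
    iio.imwrite(Path(path), img.pixels)


def glands_from_polygons(
    polygons: list[np.ndarray],
    image_id: str,
    shape: tuple[int, int] | None = None,
    provenance: str = "imported",
) -> GlandSet:
    """Build a validated GlandSet from raw polygon vertex arrays.

    When ``shape`` is omitted, masks are rasterized on the tight bounding
    canvas of all polygons.
    """
    if shape is None:
        if polygons:
            maxx = max(float(np.max(p[:, 0])) for p in polygons)
            maxy = max(float(np.max(p[:, 1])) for p in polygons)
            shape = (int(np.ceil(maxy)) + 2, int(np.ceil(maxx)) + 2)
        else:
            shape = (1, 1)
    glands = []
    for k, verts in enumerate(polygons):
        try:
            mask = rasterize_polygon(verts, shape)
        except ValidationError as exc:
            raise ValidationError(f"polygon {k}: {exc}") from exc
        if mask.sum() == 0:
            raise ValidationError(f"polygon {k}: rasterizes to an empty mask")
        ys, xs = np.nonzero(mask)
        theta, degen = orientation_from_mask(mask) if mask.sum() >= 5 else (0.0, True)
        g = Gland(
            id=k,
            boundary=np.asarray(verts, dtype=float),
            mask=mask,
            centroid=(float(xs.mean()), float(ys.mean())),
            orientation_deg=theta,
            degenerate=degen,
        )
        validate_gland(g)
        glands.append(g)
    return GlandSet(image_id=image_id, glands=glands, provenance=provenance)


def read_contours(path: str | Path, shape: tuple[int, int] | None = None) -> GlandSet:
    """Load a GeoJSON FeatureCollection of polygons as an imported GlandSet.

    Coordinates are pixel (x, y).  A self-intersecting polygon raises a
    :class:`ValidationError` naming the offending feature index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path} is not valid JSON/GeoJSON") from exc
    if doc.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    polys = []
    for k, feat in enumerate(doc.get("features", [])):
        geom = feat.get("geometry", {})
        if geom.get("type") != "Polygon":
            raise FormatError(f"feature {k}: only Polygon geometries are supported")
        ring = np.asarray(geom["coordinates"][0], dtype=float)
        if len(ring) > 1 and np.allclose(ring[0], ring[-1]):
            ring = ring[:-1]  # GeoJSON repeats the first vertex
        polys.append(ring)
    return glands_from_polygons(polys, image_id=path.stem, shape=shape)


def write_contours(path: str | Path, glands: GlandSet) -> None:
    """Write gland boundaries as a GeoJSON FeatureCollection (pixel coords)."""
    features = []
    for g in glands:
        ring = np.vstack([g.boundary, g.boundary[:1]]).tolist()
        features.append(
            {
                "type": "Feature",
                "properties": {
                    "gland_id": g.id,
                    "orientation_deg": g.orientation_deg,
                    "degenerate": g.degenerate,
                },
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    doc = {
        "type": "FeatureCollection",
        "properties": {"image_id": glands.image_id, "provenance": glands.provenance},
        "features": features,
    }
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


def write_label_mask(path: str | Path, glands: GlandSet, shape: tuple[int, int]) -> None:
    """16-bit label TIFF: 0 = background, k+1 = gland with index k."""
    lab = np.zeros(shape, dtype=np.uint16)
    for k, g in enumerate(glands):
        lab[g.mask] = k + 1
    tifffile.imwrite(Path(path), lab)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Load a clinical cohort CSV.

    Required columns: patient_id, image_id, recurrence, survival_time,
    event.  recurrence/event must be binary and survival_time
    non-negative; extra covariate columns pass through untouched.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort table missing required columns: {missing}")
    if df["patient_id"].duplicated().any():
        raise ValidationError("duplicate patient_id in cohort table")
    if (df["survival_time"] < 0).any():
        raise ValidationError("negative survival_time in cohort table")
    for col in ("recurrence", "event"):
        if not df[col].isin([0, 1]).all():
            raise ValidationError(f"column {col!r} must be binary 0/1")
    return df
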