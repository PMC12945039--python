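"""Region-of-interest handling: tumour outlines, exclusions, mask, area.

Annotations are GeoJSON FeatureCollections of polygons in pixel coordinates
(x rightward, y downward, origin at the image's top-left corner; the pixel
with indices (row i, column j) occupies the unit square [j, j+1) x [i, i+1)
and its centre sits at (j+0.5, i+0.5)).  Each feature carries a ``role``
property, ``tumour`` or ``exclusion``, and exclusions may carry a
``category`` (adnexa, vessel, adipose, lymphoid, artefact, ulcer).

The analysis mask is rasterized with a pixel-centre-in-polygon rule:
a pixel belongs to the ROI iff its centre lies inside the union of tumour
polygons and outside the union of exclusion polygons.  The assessed area is
the true-pixel count times the pixel area in mm^2.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import Polygon, shape
from shapely.ops import unary_union

logger = logging.getLogger(__name__)

__all__ = ["ROISet", "load_roi", "roi_from_polygons", "filter_nuclei", "roi_to_geojson"]

EXCLUSION_CATEGORIES = ("adnexa", "vessel", "adipose", "lymphoid", "artefact", "ulcer")


@dataclass
class ROISet:
    """Tumour polygons minus exclusions, with the rasterized analysis mask."""

    tumour: list[Polygon]
    exclusions: list[Polygon]
    mask: np.ndarray  # boolean, image shape
    microns_per_pixel: float
    exclusion_categories: list[str] = field(default_factory=list)

    @property
    def area_mm2(self) -> float:
        """Assessed tissue area: true-pixel count x (um/px)^2 / 1e6."""
        return float(self.mask.sum()) * self.microns_per_pixel**2 / 1e6

    @property
    def bounds_um(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the mask's bounding box in um."""
        h, w = self.mask.shape
        return (0.0, 0.0, w * self.microns_per_pixel, h * self.microns_per_pixel)


def _rasterize(polys: list[Polygon], shape_px: tuple[int, int]) -> np.ndarray:
    """Pixel-centre-in-polygon rasterization of a polygon union."""
    h, w = shape_px
    out = np.zeros((h, w), dtype=bool)
    if not polys:
        return out
    geom = unary_union(polys)
    # evaluate only within the geometry's bounding box
    xmin, ymin, xmax, ymax = geom.bounds
    j0, j1 = max(0, int(np.floor(xmin - 0.5))), min(w, int(np.ceil(xmax + 0.5)))
    i0, i1 = max(0, int(np.floor(ymin - 0.5))), min(h, int(np.ceil(ymax + 0.5)))
    if j1 <= j0 or i1 <= i0:
        return out
    jj, ii = np.meshgrid(np.arange(j0, j1), np.arange(i0, i1))
    inside = shapely.contains_xy(geom, jj + 0.5, ii + 0.5)
    out[i0:i1, j0:j1] = inside
    return out


def _validate_polygon(coords, label: str) -> Polygon:
    if len(coords) < 3:
        raise ValueError(f"{label}: polygon needs at least 3 vertices")
    poly = Polygon(coords)
    if not poly.is_valid:
        raise ValueError(f"{label}: invalid (self-intersecting?) polygon ring")
    return poly


def roi_from_polygons(
    tumour: list,
    exclusions: list,
    image_shape: tuple[int, int],
    microns_per_pixel: float,
    exclusion_categories: list[str] | None = None,
) -> ROISet:
    """Build an ROISet from coordinate lists (pixel units)."""
    if not tumour:
        raise ValueError("ROI must contain at least one tumour polygon")
    tum = [
        p if isinstance(p, Polygon) else _validate_polygon(p, f"tumour[{i}]")
        for i, p in enumerate(tumour)
    ]
    exc = [
        p if isinstance(p, Polygon) else _validate_polygon(p, f"exclusion[{i}]")
        for i, p in enumerate(exclusions)
    ]
    mask = _rasterize(tum, image_shape)
    if exc:
        mask &= ~_rasterize(exc, image_shape)
    return ROISet(
        tumour=tum,
        exclusions=exc,
        mask=mask,
        microns_per_pixel=microns_per_pixel,
        exclusion_categories=list(exclusion_categories or []),
    )


def load_roi(
    path: str | Path,
    image_shape: tuple[int, int],
    microns_per_pixel: float,
) -> ROISet:
    """Load a GeoJSON annotation file and rasterize the analysis mask.

    Every feature must be a Polygon with a ``role`` property of ``tumour``
    or ``exclusion``.  Raises if no tumour polygon is present or a ring is
    self-intersecting.
    """
    with open(path) as fh:
        doc = json.load(fh)
    tumour: list[Polygon] = []
    exclusions: list[Polygon] = []
    categories: list[str] = []
    for i, feat in enumerate(doc.get("features", [])):
        geom = shape(feat["geometry"])
        if geom.geom_type != "Polygon":
            raise ValueError(f"feature {i}: expected Polygon, got {geom.geom_type}")
        if not geom.is_valid:
            raise ValueError(f"feature {i}: self-intersecting polygon ring")
        if len(geom.exterior.coords) - 1 < 3:
            raise ValueError(f"feature {i}: polygon needs at least 3 vertices")
        role = feat.get("properties", {}).get("role")
        if role == "tumour":
            tumour.append(geom)
        elif role == "exclusion":
            exclusions.append(geom)
            categories.append(feat["properties"].get("category", "artefact"))
        else:
            raise ValueError(f"feature {i}: unknown role {role!r}")
    return roi_from_polygons(
        tumour, exclusions, image_shape, microns_per_pixel, categories
    )


def roi_to_geojson(roiset: ROISet, path: str | Path, hotspot_polygon=None) -> None:
    """Write the ROI (and optionally the hotspot window) as GeoJSON."""
    feats = []
    for poly in roiset.tumour:
        feats.append(_feature(poly, {"role": "tumour"}))
    for k, poly in enumerate(roiset.exclusions):
        props = {"role": "exclusion"}
        if k < len(roiset.exclusion_categories):
            props["category"] = roiset.exclusion_categories[k]
        feats.append(_feature(poly, props))
    if hotspot_polygon is not None:
        feats.append(_feature(hotspot_polygon, {"role": "hotspot"}))
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh, indent=1)


def _feature(poly: Polygon, props: dict) -> dict:
    return {
        "type": "Feature",
        "properties": props,
        "geometry": {
            "type": "Polygon",
            "coordinates": [[list(pt) for pt in poly.exterior.coords]],
        },
    }


def filter_nuclei(nuclei, roiset: ROISet):
    """Set ``inside_roi`` on each nucleus from the mask at its centroid.

    The centroid (in um) is mapped to the pixel containing it; nuclei whose
    centroid falls outside the image are flagged outside and logged.
    Returns the same list, mutated in place.
    """
    h, w = roiset.mask.shape
    mpp = roiset.microns_per_pixel
    for nuc in nuclei:
        x_um, y_um = nuc.centroid_um
        j = int(np.floor(x_um / mpp))
        i = int(np.floor(y_um / mpp))
        if not (0 <= i < h and 0 <= j < w):
            logger.warning("nucleus %d centroid outside image bounds", nuc.id)
            nuc.inside_roi = False
        else:
            nuc.inside_roi = bool(roiset.mask[i, j])
    return nuclei
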