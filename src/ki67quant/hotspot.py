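"""Hotspot analysis: the maximal fixed-area window of Ki-67-positive nuclei.

The hotspot is the 0.3125 mm^2 region containing the most Ki-67-positive
cells, the area convention used for manual hotspot counting with the
prognostic cutoff of 23 positive cells (counts > 23 are "high").  Only the
area is conventionally fixed, not the shape; here the window is an
axis-aligned square of side sqrt(0.3125) mm = 559.02 um.

The search enumerates every window anchored at a pair of nucleus
coordinates (one nucleus on the left edge, one on the top edge) — a
candidate set that provably contains a maximizer for half-open windows —
optionally augmented by a coarse stride grid.  Windows may overhang the ROI
bounding box; what is maximised is the count of positive centroids with
x in [x0, x0+side), y in [y0, y0+side).

The proliferation factor relates the hotspot to the whole section: hotspot
positive-cell density divided by the global density of strongly positive
cells, the global comparator chosen because weak/moderate staining is often
contributed by non-neoplastic cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HOTSPOT_AREA_MM2",
    "HOTSPOT_SIDE_UM",
    "WEBSTER_CUTOFF",
    "HotspotResult",
    "find_hotspot",
    "webster_category",
    "hotspot_density",
    "proliferation_factor",
]

#: Conventional manual hotspot area.
HOTSPOT_AREA_MM2 = 0.3125
#: Side of the square window realising that area, in micrometres.
HOTSPOT_SIDE_UM = float(np.sqrt(HOTSPOT_AREA_MM2) * 1000.0)
#: Positive-cell count above which the hotspot is prognostically "high".
WEBSTER_CUTOFF = 23


@dataclass
class HotspotResult:
    window_origin_um: tuple[float, float]
    positive_count: int
    hotspot_density_per_mm2: float
    webster_category: str  # "low" | "high"
    proliferation_factor: float | None = None
    window_area_mm2: float = HOTSPOT_AREA_MM2


def webster_category(count: int) -> str:
    """Dichotomize a hotspot count: 'low' iff count <= 23, 'high' iff > 23."""
    if count < 0:
        raise ValueError("hotspot count must be non-negative")
    return "high" if count > WEBSTER_CUTOFF else "low"


def hotspot_density(count: int) -> float:
    """Positive cells per mm^2 within the fixed 0.3125 mm^2 hotspot area."""
    if count < 0:
        raise ValueError("hotspot count must be non-negative")
    return count / HOTSPOT_AREA_MM2


def proliferation_factor(
    hotspot_density_per_mm2: float, global_strong_density_per_mm2: float
) -> float | None:
    """Fold difference between hotspot and whole-section Ki-67 burden.

    hotspot positive density / global strong density; ``None`` (undefined)
    when the global strong density is zero.
    """
    if hotspot_density_per_mm2 < 0 or global_strong_density_per_mm2 < 0:
        raise ValueError("densities must be non-negative")
    if global_strong_density_per_mm2 == 0:
        return None
    return hotspot_density_per_mm2 / global_strong_density_per_mm2


def find_hotspot(
    positive_xy_um: np.ndarray,
    bounds_um: tuple[float, float, float, float],
    stride_um: float | None = None,
    side_um: float = HOTSPOT_SIDE_UM,
) -> HotspotResult:
    """Locate the square window of side ``side_um`` maximising the count of
    positive-nucleus centroids.

    Parameters
    ----------
    positive_xy_um : (n, 2) array
        Centroids (x, y) of Ki-67-positive nuclei, in um.
    bounds_um : (xmin, ymin, xmax, ymax)
        ROI bounding box; used for the empty-slide origin and to lay out
        the optional stride grid.
    stride_um : float, optional
        If given, grid origins spaced ``stride_um`` apart across the bounds
        are added to the anchored candidate set.

    Ties are broken by the lexicographically smallest (y0, x0) origin.
    """
    pts = np.asarray(positive_xy_um, dtype=float).reshape(-1, 2)
    xmin, ymin, xmax, ymax = bounds_um
    if len(pts) == 0:
        return HotspotResult(
            window_origin_um=(xmin, ymin),
            positive_count=0,
            hotspot_density_per_mm2=0.0,
            webster_category="low",
        )

    xs = pts[:, 0]
    ys = pts[:, 1]
    cand_x = np.unique(xs)
    cand_y = np.unique(ys)
    if stride_um is not None and stride_um > 0:
        gx = np.arange(xmin, max(xmin, xmax - side_um) + stride_um, stride_um)
        gy = np.arange(ymin, max(ymin, ymax - side_um) + stride_um, stride_um)
        cand_x = np.unique(np.concatenate([cand_x, gx]))
        cand_y = np.unique(np.concatenate([cand_y, gy]))

    best_count = -1
    best_origin = (xmin, ymin)
    # iterate y-origin outermost so the (y0, x0) tie-break falls out of
    # strict-improvement updates over a sorted candidate sweep
    for y0 in cand_y:
        y1 = y0 + side_um
        in_y = (ys >= y0) & (ys < y1)
        if in_y.sum() <= best_count:
            continue
        xs_in = np.sort(xs[in_y])
        for x0 in cand_x:
            lo = np.searchsorted(xs_in, x0, side="left")
            hi = np.searchsorted(xs_in, x0 + side_um, side="left")
            if hi - lo > best_count:
                best_count = hi - lo
                best_origin = (float(x0), float(y0))

    return HotspotResult(
        window_origin_um=best_origin,
        positive_count=int(best_count),
        hotspot_density_per_mm2=hotspot_density(int(best_count)),
        webster_category=webster_category(int(best_count)),
    )
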