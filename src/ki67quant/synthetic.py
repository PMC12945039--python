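"""Synthetic H-DAB histology slides with fully known ground truth.

Generates RGB brightfield-like images of hematoxylin-counterstained nuclei
with planted DAB pseudo-intensities, plus the matching ROI annotation and a
per-nucleus ground-truth table, so the whole analysis pipeline can be tested
end to end without any real slide.  Nuclei are hard disks composited in
optical-density space: each carries a fixed hematoxylin OD and a DAB OD
chosen so its rendered pseudo-intensity equals the planted value up to 8-bit
quantisation (+/- 2 units).

Design notes
------------
* Class membership follows the requested quotas *exactly* via largest-
  remainder apportionment, not multinomial sampling, so downstream count
  assertions are sharp.
* Nuclei never overlap: positions are drawn by rejection sampling against a
  spatial hash with a bounded retry budget, keeping the classical
  segmentation correctness testable.
* Inflammatory infiltration is emulated as extra small nuclei with weak-band
  intensities (granulocytes typically show weak or no Ki-67 signal), flagged
  in the ground truth.
* One private random stream per slide, seeded from the spec; identical spec
  and seed give bit-identical images and tables.

The module also simulates survival cohorts with a known hazard structure for
testing the statistics layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box

from . import metrics as _metrics
from .hotspot import HOTSPOT_SIDE_UM
from .nuclei import DEFAULT_BANDS, ClassBands, Ki67Class
from .roi import ROISet, roi_from_polygons
from .stains import RUIFROK_HDAB, RGBImage, StainBasis, od_from_stains, render_rgb

__all__ = [
    "SpatialLaw",
    "HotspotPlan",
    "SlideSpec",
    "GroundTruth",
    "largest_remainder",
    "generate_slide",
    "plant_hotspot",
    "generate_cohort",
]

CLASS_ORDER = (Ki67Class.NEGATIVE, Ki67Class.WEAK, Ki67Class.MODERATE, Ki67Class.STRONG)

#: Per-class pseudo-intensity bands, each strictly inside the corresponding
#: classification band with a comfortable guard margin against 8-bit
#: quantisation, so planted classes are always recoverable.
DEFAULT_INTENSITY_BANDS: dict[Ki67Class, tuple[float, float]] = {
    Ki67Class.NEGATIVE: (180.0, 250.0),
    Ki67Class.WEAK: (126.0, 164.0),
    Ki67Class.MODERATE: (76.0, 114.0),
    Ki67Class.STRONG: (30.0, 64.0),
}

#: Hematoxylin OD given to every nucleus (counterstain).
NUCLEAR_HEMA_OD = 0.55
#: Minimum clearance between nucleus rims, in um (keeps objects separable).
PLACEMENT_GAP_UM = 1.5
#: Rejection-sampling retry budget per nucleus.
RETRY_BUDGET = 100


@dataclass(frozen=True)
class SpatialLaw:
    """Spatial distribution of nuclei: uniform, or uniform with a circular
    enrichment region whose density is ``enrichment`` times background."""

    kind: str = "uniform"  # "uniform" | "clustered"
    center_um: tuple[float, float] | None = None
    radius_um: float | None = None
    enrichment: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "clustered"):
            raise ValueError(f"unknown spatial law {self.kind!r}")
        if self.kind == "clustered":
            if self.center_um is None or self.radius_um is None:
                raise ValueError("clustered law needs center_um and radius_um")
            if self.enrichment < 1.0:
                raise ValueError("enrichment must be >= 1")


@dataclass(frozen=True)
class HotspotPlan:
    """Plan forcing a known number of positive nuclei into one hotspot-sized
    window (origin in um); the rest of the slide receives the remainder."""

    origin_um: tuple[float, float]
    count: int


@dataclass(frozen=True)
class SlideSpec:
    """Full recipe for one synthetic slide."""

    width_px: int = 1024
    height_px: int = 1024
    microns_per_pixel: float = 0.23
    n_nuclei: int = 500
    class_quotas: tuple[float, float, float, float] = (0.86, 0.06, 0.05, 0.03)
    intensity_bands: dict | None = None
    nucleus_radius_um: tuple[float, float] = (1.8, 2.6)
    spatial_law: SpatialLaw = field(default_factory=SpatialLaw)
    inflammation_fraction: float = 0.0
    exclusion_polygons: tuple = ()
    seed: int = 0
    hotspot_plan: HotspotPlan | None = None
    class_bands: ClassBands = field(default_factory=ClassBands)

    def __post_init__(self) -> None:
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be non-negative")
        if abs(sum(self.class_quotas) - 1.0) > 1e-9:
            raise ValueError("class_quotas must sum to 1")
        if any(q < 0 for q in self.class_quotas):
            raise ValueError("class_quotas must be non-negative")
        rmin, rmax = self.nucleus_radius_um
        if not (0 < rmin <= rmax):
            raise ValueError("nucleus radii must satisfy 0 < min <= max")
        if not (0.0 <= self.inflammation_fraction < 1.0):
            raise ValueError("inflammation_fraction must be in [0, 1)")
        bands = self.bands
        limits = {
            Ki67Class.STRONG: (0.0, self.class_bands.t_strong),
            Ki67Class.MODERATE: (self.class_bands.t_strong, self.class_bands.t_weak),
            Ki67Class.WEAK: (self.class_bands.t_weak, self.class_bands.t_negative),
            Ki67Class.NEGATIVE: (self.class_bands.t_negative, 255.0),
        }
        for cls, (lo, hi) in bands.items():
            llo, lhi = limits[cls]
            if not (llo < lo <= hi < lhi):
                raise ValueError(
                    f"intensity band {lo}-{hi} for {cls} not strictly inside "
                    f"classification band ({llo}, {lhi})"
                )

    @property
    def bands(self) -> dict[Ki67Class, tuple[float, float]]:
        return dict(self.intensity_bands or DEFAULT_INTENSITY_BANDS)

    @property
    def size_um(self) -> tuple[float, float]:
        return (
            self.width_px * self.microns_per_pixel,
            self.height_px * self.microns_per_pixel,
        )


@dataclass
class GroundTruth:
    """Per-nucleus planted records plus the planted slide summary.

    ``records`` columns: id, x_um, y_um, radius_um, planted_class,
    planted_mean_intensity, inflammatory, inside_roi.  The summary is
    computed with the same formulas as the pipeline's slide summary, over
    nuclei inside the ROI mask.
    """

    records: pd.DataFrame
    summary: _metrics.SlideMetrics

    def to_tsv(self, path) -> None:
        self.records.to_csv(path, sep="\t", index=False)


def largest_remainder(n: int, fractions) -> list[int]:
    """Apportion ``n`` items to categories by the largest-remainder rule.

    Counts are the floors of n*f with the remainder distributed in order of
    decreasing fractional part (ties to the earlier category), so counts are
    deterministic and sum exactly to ``n``.
    """
    fractions = list(fractions)
    raw = [n * f for f in fractions]
    counts = [int(math.floor(r)) for r in raw]
    short = n - sum(counts)
    remainders = sorted(
        range(len(fractions)), key=lambda i: (-(raw[i] - counts[i]), i)
    )
    for i in remainders[:short]:
        counts[i] += 1
    return counts


class _SpatialHash:
    """Uniform-grid neighbour lookup for non-overlap rejection sampling."""

    def __init__(self, cell_um: float):
        self.cell = cell_um
        self.grid: dict[tuple[int, int], list[tuple[float, float, float]]] = {}

    def _key(self, x: float, y: float) -> tuple[int, int]:
        return (int(x // self.cell), int(y // self.cell))

    def collides(self, x: float, y: float, r: float, gap: float) -> bool:
        kx, ky = self._key(x, y)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for ox, oy, orad in self.grid.get((kx + dx, ky + dy), ()):
                    lim = r + orad + gap
                    if (x - ox) ** 2 + (y - oy) ** 2 < lim * lim:
                        return True
        return False

    def add(self, x: float, y: float, r: float) -> None:
        self.grid.setdefault(self._key(x, y), []).append((x, y, r))


def _sample_position(
    rng: np.random.Generator,
    spec: SlideSpec,
    r: float,
    region: str,
) -> tuple[float, float]:
    """Draw one candidate centre in um.  ``region`` is 'any', 'window'
    (inside the planted hotspot window) or 'outside' (outside it)."""
    w_um, h_um = spec.size_um
    lo_x, hi_x = r + spec.microns_per_pixel, w_um - r - spec.microns_per_pixel
    lo_y, hi_y = r + spec.microns_per_pixel, h_um - r - spec.microns_per_pixel
    if hi_x <= lo_x or hi_y <= lo_y:
        raise RuntimeError("nucleus radius too large for the slide")

    if region == "window":
        x0, y0 = spec.hotspot_plan.origin_um
        side = HOTSPOT_SIDE_UM
        return (
            rng.uniform(max(lo_x, x0 + r), min(hi_x, x0 + side - r)),
            rng.uniform(max(lo_y, y0 + r), min(hi_y, y0 + side - r)),
        )

    law = spec.spatial_law
    if law.kind == "clustered":
        cx, cy = law.center_um
        rad = law.radius_um
        area_total = (hi_x - lo_x) * (hi_y - lo_y)
        area_cluster = math.pi * rad**2
        q = law.enrichment * area_cluster / (
            area_total - area_cluster + law.enrichment * area_cluster
        )
        if rng.uniform() < q:
            rho = rad * math.sqrt(rng.uniform())
            theta = rng.uniform(0.0, 2.0 * math.pi)
            return (
                min(max(cx + rho * math.cos(theta), lo_x), hi_x),
                min(max(cy + rho * math.sin(theta), lo_y), hi_y),
            )

    while True:
        x = rng.uniform(lo_x, hi_x)
        y = rng.uniform(lo_y, hi_y)
        if region == "outside" and spec.hotspot_plan is not None:
            x0, y0 = spec.hotspot_plan.origin_um
            side = HOTSPOT_SIDE_UM
            if x0 <= x < x0 + side and y0 <= y < y0 + side:
                continue
        return (x, y)


def generate_slide(spec: SlideSpec) -> tuple[RGBImage, GroundTruth, ROISet]:
    """Render one synthetic slide.

    Returns the RGB image, the ground truth (per-nucleus table + planted
    summary over the ROI), and the ROI set (whole image as tumour outline
    minus the spec's exclusion polygons).
    """
    rng = np.random.default_rng(spec.seed)
    rmin, rmax = spec.nucleus_radius_um
    bands = spec.bands

    counts = largest_remainder(spec.n_nuclei, spec.class_quotas)
    classes: list[Ki67Class] = []
    for cls, c in zip(CLASS_ORDER, counts):
        classes.extend([cls] * c)
    inflam_flags = [False] * len(classes)

    # inflammation: extra small weak-band nuclei so the flagged fraction of
    # all nuclei equals inflammation_fraction
    f = spec.inflammation_fraction
    n_inflam = int(round(f / (1.0 - f) * spec.n_nuclei)) if f > 0 else 0
    classes.extend([Ki67Class.WEAK] * n_inflam)
    inflam_flags.extend([True] * n_inflam)

    # route positives into the planted hotspot window first, if any
    placement_region = ["any"] * len(classes)
    if spec.hotspot_plan is not None and spec.hotspot_plan.count > 0:
        pos_idx = [
            i for i, c in enumerate(classes) if c is not Ki67Class.NEGATIVE
        ]
        k = spec.hotspot_plan.count
        if k > len(pos_idx):
            raise ValueError(
                f"hotspot plan wants {k} positives but spec only yields {len(pos_idx)}"
            )
        for i, idx in enumerate(pos_idx):
            placement_region[idx] = "window" if i < k else "outside"

    hash_cell = 2 * rmax + PLACEMENT_GAP_UM
    shash = _SpatialHash(hash_cell)
    rows = []
    for i, cls in enumerate(classes):
        r = rng.uniform(rmin, rmax) if rmax > rmin else rmin
        if inflam_flags[i]:
            r = max(rmin * 0.7, 0.5 * r)  # granulocytes are small
        placed = False
        for _ in range(RETRY_BUDGET):
            x, y = _sample_position(rng, spec, r, placement_region[i])
            if not shash.collides(x, y, r, PLACEMENT_GAP_UM):
                shash.add(x, y, r)
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place nucleus {i} after {RETRY_BUDGET} retries: "
                f"requested density exceeds the non-overlap packing limit for "
                f"radius {r:.2f} um on a "
                f"{spec.size_um[0]:.0f}x{spec.size_um[1]:.0f} um slide"
            )
        lo, hi = bands[cls]
        intensity = rng.uniform(lo, hi)
        rows.append((i, x, y, r, cls.value, intensity, inflam_flags[i]))

    records = pd.DataFrame(
        rows,
        columns=[
            "id",
            "x_um",
            "y_um",
            "radius_um",
            "planted_class",
            "planted_mean_intensity",
            "inflammatory",
        ],
    )

    image = _render(spec, records)
    roiset = _make_roi(spec)

    # flag planted nuclei against the rasterized mask (centroid rule)
    mpp = spec.microns_per_pixel
    if len(records):
        jj = np.floor(records["x_um"].to_numpy() / mpp).astype(int)
        ii = np.floor(records["y_um"].to_numpy() / mpp).astype(int)
        inside = (
            (ii >= 0)
            & (ii < spec.height_px)
            & (jj >= 0)
            & (jj < spec.width_px)
        )
        inside &= roiset.mask[np.clip(ii, 0, spec.height_px - 1),
                              np.clip(jj, 0, spec.width_px - 1)]
        records["inside_roi"] = inside
    else:
        records["inside_roi"] = pd.Series([], dtype=bool)

    in_roi = records[records["inside_roi"]]
    cls_counts = {
        cls: int((in_roi["planted_class"] == cls.value).sum()) for cls in CLASS_ORDER
    }
    summary = _metrics.summarize_counts(
        f"synthetic-{spec.seed}",
        cls_counts[Ki67Class.NEGATIVE],
        cls_counts[Ki67Class.WEAK],
        cls_counts[Ki67Class.MODERATE],
        cls_counts[Ki67Class.STRONG],
        roiset.area_mm2,
    )
    return image, GroundTruth(records=records, summary=summary), roiset


def _render(spec: SlideSpec, records: pd.DataFrame, basis: StainBasis = RUIFROK_HDAB) -> RGBImage:
    """Composite nuclei as hard disks in OD space and render to 8-bit RGB."""
    h_od = np.zeros((spec.height_px, spec.width_px), dtype=np.float64)
    d_od = np.zeros_like(h_od)
    mpp = spec.microns_per_pixel
    for rec in records.itertuples(index=False):
        r_px = rec.radius_um / mpp
        cy, cx = rec.y_um / mpp - 0.5, rec.x_um / mpp - 0.5  # pixel-centre coords
        i0 = max(0, int(math.floor(cy - r_px)))
        i1 = min(spec.height_px, int(math.ceil(cy + r_px)) + 1)
        j0 = max(0, int(math.floor(cx - r_px)))
        j1 = min(spec.width_px, int(math.ceil(cx + r_px)) + 1)
        ii, jj = np.mgrid[i0:i1, j0:j1]
        disk = (ii - cy) ** 2 + (jj - cx) ** 2 <= r_px**2
        dab_od = -math.log10(rec.planted_mean_intensity / 255.0)
        h_od[i0:i1, j0:j1][disk] = NUCLEAR_HEMA_OD
        d_od[i0:i1, j0:j1][disk] = dab_od
    rgb = render_rgb(od_from_stains(h_od, d_od, basis))
    return RGBImage(pixels=rgb, microns_per_pixel=mpp)


def _make_roi(spec: SlideSpec) -> ROISet:
    tumour = [box(0.0, 0.0, float(spec.width_px), float(spec.height_px))]
    exclusions = [
        p if isinstance(p, Polygon) else Polygon(p) for p in spec.exclusion_polygons
    ]
    return roi_from_polygons(
        tumour,
        exclusions,
        (spec.height_px, spec.width_px),
        spec.microns_per_pixel,
        ["artefact"] * len(exclusions),
    )


def plant_hotspot(
    spec: SlideSpec,
    window_positive_count: int,
    origin_um: tuple[float, float] | None = None,
) -> SlideSpec:
    """Return a spec whose generated slide has a guaranteed hotspot.

    Exactly ``window_positive_count`` positive nuclei are routed into one
    hotspot-sized window (default origin: slide centre), and all remaining
    positives are kept outside it.  Raises when the count cannot fit in the
    window at the non-overlap packing density, when the spec does not yield
    enough positives, or when the remainder outside the window would tie or
    exceed the planted window (so no other disjoint window can match it).
    """
    if window_positive_count < 0:
        raise ValueError("window_positive_count must be non-negative")
    if window_positive_count == 0:
        return spec

    w_um, h_um = spec.size_um
    side = HOTSPOT_SIDE_UM
    if origin_um is None:
        origin_um = ((w_um - side) / 2.0, (h_um - side) / 2.0)
    if side > w_um or side > h_um:
        raise ValueError("hotspot window does not fit on the slide")

    rmin, rmax = spec.nucleus_radius_um
    pitch = 2 * rmax + PLACEMENT_GAP_UM
    packing_limit = int((side // pitch) ** 2)
    if window_positive_count > packing_limit:
        raise ValueError(
            f"{window_positive_count} positives cannot be packed into one "
            f"{side:.0f} um window without overlap (limit ~{packing_limit})"
        )
    counts = largest_remainder(spec.n_nuclei, spec.class_quotas)
    n_positive = sum(counts[1:])
    if window_positive_count > n_positive:
        raise ValueError(
            f"spec yields only {n_positive} positive nuclei, "
            f"cannot plant {window_positive_count}"
        )
    if n_positive - window_positive_count >= window_positive_count:
        raise ValueError(
            "remaining positives outside the window could form a rival "
            "hotspot; reduce total positives or raise the planted count"
        )
    return replace(
        spec, hotspot_plan=HotspotPlan(origin_um=origin_um, count=window_positive_count)
    )


def generate_cohort(
    n: int,
    effect: float,
    baseline_hazard: float,
    censor_time: float,
    seed: int,
) -> pd.DataFrame:
    """Simulate a survival cohort with a known proportional-hazards effect.

    The per-record Ki-67 metric is standard normal; survival time is
    exponential with hazard ``baseline_hazard * exp(effect * metric)``,
    administratively censored at ``censor_time``.  The true hazard ratio
    per unit of the metric is exp(effect).

    Returns a DataFrame with columns slide_id, metric, survival_days, event.
    """
    if n < 2:
        raise ValueError("cohort needs n >= 2")
    if baseline_hazard <= 0:
        raise ValueError("baseline_hazard must be positive")
    if censor_time < 0:
        raise ValueError("censor_time must be non-negative")
    rng = np.random.default_rng(seed)
    metric = rng.standard_normal(n)
    hazard = baseline_hazard * np.exp(effect * metric)
    t_event = rng.exponential(1.0 / hazard)
    event = t_event <= censor_time
    return pd.DataFrame(
        {
            "slide_id": [f"case-{i:04d}" for i in range(n)],
            "metric": metric,
            "survival_days": np.minimum(t_event, censor_time),
            "event": event,
        }
    )
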