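"""Per-slide Ki-67 summary metrics, quality scores, and TSV export.

The slide summary reports class counts, the proliferation index (PI, the
percentage of Ki-67-positive nuclei among all assessed nuclei), the H-score

    H = 1 * %weak + 2 * %moderate + 3 * %strong        (0..300)

with percentages taken over all assessed nuclei, and the densities of
positive and strongly positive nuclei per mm^2 of assessed tumour tissue.

Slide quality is scored 0/1/2 on three axes — tissue-section assessability,
inflammatory infiltration, and nuclear segmentation — so that unreliable
slides can be stratified or excluded downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd

from .hotspot import HotspotResult
from .nuclei import Ki67Class, NucleusRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SlideMetrics",
    "QualityScores",
    "summarize_slide",
    "summarize_counts",
    "score_tissue",
    "score_inflammation",
    "score_segmentation",
    "export_slide_tsv",
    "SLIDE_TSV_COLUMNS",
]


@dataclass
class SlideMetrics:
    slide_id: str
    area_mm2: float
    n_negative: int
    n_weak: int
    n_moderate: int
    n_strong: int
    pi_percent: float
    h_score: float
    positive_density_per_mm2: float
    strong_density_per_mm2: float

    @property
    def n_total(self) -> int:
        return self.n_negative + self.n_weak + self.n_moderate + self.n_strong

    @property
    def n_positive(self) -> int:
        return self.n_weak + self.n_moderate + self.n_strong


@dataclass(frozen=True)
class QualityScores:
    """Three-axis 0/1/2 slide quality rubric (2 is best)."""

    tissue: int
    inflammation: int
    segmentation: int

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v not in (0, 1, 2):
                raise ValueError(f"quality score {f.name}={v!r} not in {{0,1,2}}")


def summarize_counts(
    slide_id: str,
    n_negative: int,
    n_weak: int,
    n_moderate: int,
    n_strong: int,
    area_mm2: float,
) -> SlideMetrics:
    """Slide summary from class counts (used by both pipeline and planted
    ground truth, so the two agree by construction)."""
    if not area_mm2 > 0:
        raise ValueError("area_mm2 must be positive")
    n_total = n_negative + n_weak + n_moderate + n_strong
    n_positive = n_weak + n_moderate + n_strong
    if n_total == 0:
        logger.warning("slide %s: no assessed nuclei; PI and H-score set to 0", slide_id)
        pi = h = 0.0
    else:
        pi = 100.0 * n_positive / n_total
        h = (
            1 * (100.0 * n_weak / n_total)
            + 2 * (100.0 * n_moderate / n_total)
            + 3 * (100.0 * n_strong / n_total)
        )
    return SlideMetrics(
        slide_id=slide_id,
        area_mm2=area_mm2,
        n_negative=n_negative,
        n_weak=n_weak,
        n_moderate=n_moderate,
        n_strong=n_strong,
        pi_percent=pi,
        h_score=h,
        positive_density_per_mm2=n_positive / area_mm2,
        strong_density_per_mm2=n_strong / area_mm2,
    )


def summarize_slide(
    nuclei: list[NucleusRecord], area_mm2: float, slide_id: str = "slide"
) -> SlideMetrics:
    """Summarise the nuclei with ``inside_roi`` set over the assessed area."""
    counts = {cls: 0 for cls in Ki67Class}
    for nuc in nuclei:
        if nuc.inside_roi:
            counts[nuc.ki67_class] += 1
    return summarize_counts(
        slide_id,
        counts[Ki67Class.NEGATIVE],
        counts[Ki67Class.WEAK],
        counts[Ki67Class.MODERATE],
        counts[Ki67Class.STRONG],
        area_mm2,
    )


def _check_fraction(f: float) -> float:
    if not (0.0 <= f <= 1.0):
        raise ValueError(f"fraction {f!r} outside [0, 1]")
    return f


def score_tissue(fraction_assessable: float) -> int:
    """Tissue-section score: 2 if >90% assessable, 1 for 50-90%, 0 if <50%."""
    f = _check_fraction(fraction_assessable)
    if f > 0.90:
        return 2
    if f >= 0.50:
        return 1
    return 0


def score_inflammation(fraction_inflammatory: float) -> int:
    """Inflammation score: 2 negligible (<1%), 1 mild (1-10%), 0 marked (>10%)."""
    f = _check_fraction(fraction_inflammatory)
    if f < 0.01:
        return 2
    if f <= 0.10:
        return 1
    return 0


def score_segmentation(fraction_unlabelled: float) -> int:
    """Segmentation score: 2 good (<1% unlabelled), 1 mildly reduced (1-10%),
    0 reduced (>10%)."""
    f = _check_fraction(fraction_unlabelled)
    if f < 0.01:
        return 2
    if f <= 0.10:
        return 1
    return 0


SLIDE_TSV_COLUMNS = [
    "slide_id",
    "area_mm2",
    "n_negative",
    "n_weak",
    "n_moderate",
    "n_strong",
    "n_total",
    "n_positive",
    "pi_percent",
    "h_score",
    "positive_density_per_mm2",
    "strong_density_per_mm2",
    "q_tissue",
    "q_inflammation",
    "q_segmentation",
    "hotspot_count",
    "hotspot_density_per_mm2",
    "webster_category",
    "proliferation_factor",
]


def slide_row(
    metrics: SlideMetrics,
    quality: QualityScores | None = None,
    hotspot: HotspotResult | None = None,
) -> dict:
    """One slide as a dict in the fixed TSV column order.

    Real-valued metrics are rounded to 1 decimal for export; the
    proliferation factor is written to 2 decimals ('' when undefined).
    """
    row = {
        "slide_id": metrics.slide_id,
        "area_mm2": round(metrics.area_mm2, 4),
        "n_negative": metrics.n_negative,
        "n_weak": metrics.n_weak,
        "n_moderate": metrics.n_moderate,
        "n_strong": metrics.n_strong,
        "n_total": metrics.n_total,
        "n_positive": metrics.n_positive,
        "pi_percent": round(metrics.pi_percent, 1),
        "h_score": round(metrics.h_score, 1),
        "positive_density_per_mm2": round(metrics.positive_density_per_mm2, 1),
        "strong_density_per_mm2": round(metrics.strong_density_per_mm2, 1),
        "q_tissue": "" if quality is None else quality.tissue,
        "q_inflammation": "" if quality is None else quality.inflammation,
        "q_segmentation": "" if quality is None else quality.segmentation,
        "hotspot_count": "" if hotspot is None else hotspot.positive_count,
        "hotspot_density_per_mm2": (
            "" if hotspot is None else round(hotspot.hotspot_density_per_mm2, 1)
        ),
        "webster_category": "" if hotspot is None else hotspot.webster_category,
        "proliferation_factor": (
            ""
            if hotspot is None or hotspot.proliferation_factor is None
            else round(hotspot.proliferation_factor, 2)
        ),
    }
    return row


def export_slide_tsv(
    rows: list[dict] | dict,
    path: str | Path,
) -> pd.DataFrame:
    """Write slide rows (from :func:`slide_row`) as a TSV with fixed header."""
    if isinstance(rows, dict):
        rows = [rows]
    df = pd.DataFrame(rows, columns=SLIDE_TSV_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
    return df
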