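"""Config-driven end-to-end orchestration of the Ki-67 workflow.

``run_slide`` executes the full per-slide chain — stain separation, nucleus
detection and classification, ROI masking, slide metrics, hotspot analysis —
and returns one TSV row; ``run_batch`` maps it over many slides with
per-slide failure isolation; ``run_cohort`` joins slide rows to cohort
metadata and produces the summary-table statistics (means with ranges and
SDs, for all slides and for the subset excluding marked inflammation, with
fold changes).
"""

from __future__ import annotations

import configparser
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import cohort as cohort_stats
from .hotspot import HotspotResult, find_hotspot, proliferation_factor
from .metrics import (
    QualityScores,
    SlideMetrics,
    score_inflammation,
    score_segmentation,
    score_tissue,
    slide_row,
    summarize_slide,
)
from .nuclei import ClassBands, DetectionParams, Ki67Class, detect_nuclei, measure_nuclei
from .roi import ROISet, filter_nuclei, load_roi
from .stains import RGBImage, StainBasis, dab_pseudo_intensity, rgb_to_od, separate_stains

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "SlideResult", "run_slide", "run_batch", "run_cohort", "table1_summary"]


@dataclass
class PipelineConfig:
    """All pipeline knobs, round-trippable through a flat INI config file."""

    microns_per_pixel: float = 0.23
    background: float = 255.0
    # stain basis, row-normalized on load
    stain_hematoxylin: tuple[float, float, float] = (0.650, 0.704, 0.286)
    stain_dab: tuple[float, float, float] = (0.268, 0.570, 0.776)
    # detection
    od_threshold: float = 0.15
    smoothing_sigma_um: float = 0.5
    min_area_um2: float = 8.0
    max_area_um2: float = 150.0
    split_min_distance_um: float = 1.5
    # classification bands (pseudo-intensity)
    t_negative: float = 170.0
    t_weak: float = 120.0
    t_strong: float = 70.0
    # hotspot
    hotspot_stride_um: float | None = None
    # statistics
    censor_rule: str = "all-deaths"
    seed: int = 0
    output_dir: str = "."

    @property
    def basis(self) -> StainBasis:
        return StainBasis(
            hematoxylin=np.asarray(self.stain_hematoxylin),
            dab=np.asarray(self.stain_dab),
        )

    @property
    def detection(self) -> DetectionParams:
        return DetectionParams(
            od_threshold=self.od_threshold,
            smoothing_sigma_um=self.smoothing_sigma_um,
            min_area_um2=self.min_area_um2,
            max_area_um2=self.max_area_um2,
            split_min_distance_um=self.split_min_distance_um,
        )

    @property
    def bands(self) -> ClassBands:
        return ClassBands(
            t_negative=self.t_negative, t_weak=self.t_weak, t_strong=self.t_strong
        )

    def to_file(self, path: str | Path) -> None:
        cp = configparser.ConfigParser()
        cp["image"] = {
            "microns_per_pixel": repr(self.microns_per_pixel),
            "background": repr(self.background),
        }
        cp["stains"] = {
            "hematoxylin": " ".join(repr(v) for v in self.stain_hematoxylin),
            "dab": " ".join(repr(v) for v in self.stain_dab),
        }
        cp["detection"] = {
            "od_threshold": repr(self.od_threshold),
            "smoothing_sigma_um": repr(self.smoothing_sigma_um),
            "min_area_um2": repr(self.min_area_um2),
            "max_area_um2": repr(self.max_area_um2),
            "split_min_distance_um": repr(self.split_min_distance_um),
        }
        cp["classification"] = {
            "t_negative": repr(self.t_negative),
            "t_weak": repr(self.t_weak),
            "t_strong": repr(self.t_strong),
        }
        cp["hotspot"] = {
            "stride_um": "" if self.hotspot_stride_um is None else repr(self.hotspot_stride_um)
        }
        cp["statistics"] = {"censor_rule": self.censor_rule, "seed": str(self.seed)}
        cp["output"] = {"dir": self.output_dir}
        with open(path, "w") as fh:
            cp.write(fh)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        cp = configparser.ConfigParser()
        if not cp.read(path):
            raise FileNotFoundError(path)
        g = cp.get
        stride = g("hotspot", "stride_um", fallback="")
        return cls(
            microns_per_pixel=cp.getfloat("image", "microns_per_pixel", fallback=0.23),
            background=cp.getfloat("image", "background", fallback=255.0),
            stain_hematoxylin=tuple(
                float(v) for v in g("stains", "hematoxylin", fallback="0.650 0.704 0.286").split()
            ),
            stain_dab=tuple(
                float(v) for v in g("stains", "dab", fallback="0.268 0.570 0.776").split()
            ),
            od_threshold=cp.getfloat("detection", "od_threshold", fallback=0.15),
            smoothing_sigma_um=cp.getfloat("detection", "smoothing_sigma_um", fallback=0.5),
            min_area_um2=cp.getfloat("detection", "min_area_um2", fallback=8.0),
            max_area_um2=cp.getfloat("detection", "max_area_um2", fallback=150.0),
            split_min_distance_um=cp.getfloat("detection", "split_min_distance_um", fallback=1.5),
            t_negative=cp.getfloat("classification", "t_negative", fallback=170.0),
            t_weak=cp.getfloat("classification", "t_weak", fallback=120.0),
            t_strong=cp.getfloat("classification", "t_strong", fallback=70.0),
            hotspot_stride_um=float(stride) if stride else None,
            censor_rule=g("statistics", "censor_rule", fallback="all-deaths"),
            seed=cp.getint("statistics", "seed", fallback=0),
            output_dir=g("output", "dir", fallback="."),
        )


@dataclass
class SlideResult:
    slide_id: str
    metrics: SlideMetrics
    quality: QualityScores | None
    hotspot: HotspotResult
    nuclei: list
    roiset: ROISet

    @property
    def row(self) -> dict:
        return slide_row(self.metrics, self.quality, self.hotspot)


def _read_image(path: str | Path, microns_per_pixel: float) -> RGBImage:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        px = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        px = iio.imread(path)
    if px.ndim == 3 and px.shape[2] == 4:  # drop alpha
        px = px[..., :3]
    return RGBImage(pixels=px, microns_per_pixel=microns_per_pixel)


def analyze_image(
    image: RGBImage,
    roiset: ROISet,
    config: PipelineConfig = PipelineConfig(),
    slide_id: str = "slide",
    quality_fractions: tuple[float, float, float] | None = None,
) -> SlideResult:
    """Run the analysis chain on an in-memory image + ROI.

    ``quality_fractions``, when given, is (fraction_assessable,
    fraction_inflammatory, fraction_unlabelled) and is turned into the
    three 0/1/2 quality scores.
    """
    t0 = time.perf_counter()
    od = rgb_to_od(image, config.background)
    hema, dab, _ = separate_stains(od, config.basis)
    dab_int = dab_pseudo_intensity(dab)
    labels = detect_nuclei(hema, dab, image.microns_per_pixel, config.detection)
    nuclei = measure_nuclei(
        labels, dab_int, image.microns_per_pixel, roi_mask=None, bands=config.bands
    )
    filter_nuclei(nuclei, roiset)
    if roiset.area_mm2 > 0:
        metrics = summarize_slide(nuclei, roiset.area_mm2, slide_id=slide_id)
    else:
        logger.warning("slide %s: empty ROI mask; zero-count row emitted", slide_id)
        metrics = SlideMetrics(slide_id, 0.0, 0, 0, 0, 0, 0.0, 0.0, 0.0, 0.0)

    positives = np.array(
        [
            n.centroid_um
            for n in nuclei
            if n.inside_roi and n.ki67_class is not Ki67Class.NEGATIVE
        ]
    ).reshape(-1, 2)
    hs = find_hotspot(positives, roiset.bounds_um, stride_um=config.hotspot_stride_um)
    hs.proliferation_factor = proliferation_factor(
        hs.hotspot_density_per_mm2, metrics.strong_density_per_mm2
    )
    quality = None
    if quality_fractions is not None:
        fa, fi, fu = quality_fractions
        quality = QualityScores(
            tissue=score_tissue(fa),
            inflammation=score_inflammation(fi),
            segmentation=score_segmentation(fu),
        )
    logger.info(
        "slide %s: %d nuclei (%d in ROI), area %.3f mm2, %.2f s",
        slide_id,
        len(nuclei),
        sum(n.inside_roi for n in nuclei),
        roiset.area_mm2,
        time.perf_counter() - t0,
    )
    return SlideResult(slide_id, metrics, quality, hs, nuclei, roiset)


def run_slide(
    image_path: str | Path,
    annotation_path: str | Path,
    config: PipelineConfig = PipelineConfig(),
    slide_id: str | None = None,
    quality_fractions: tuple[float, float, float] | None = None,
) -> SlideResult:
    """Analyze one slide from an image file and a GeoJSON annotation."""
    slide_id = slide_id or Path(image_path).stem
    image = _read_image(image_path, config.microns_per_pixel)
    roiset = load_roi(annotation_path, image.shape, config.microns_per_pixel)
    return analyze_image(image, roiset, config, slide_id, quality_fractions)


def run_batch(
    slides: list[tuple[str | Path, str | Path]],
    config: PipelineConfig = PipelineConfig(),
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Analyze a batch; a failing slide is recorded and the batch continues.

    Returns (slide-row DataFrame, list of (slide_id, error) failures).
    """
    from .metrics import SLIDE_TSV_COLUMNS

    rows, failures = [], []
    for image_path, annotation_path in slides:
        sid = Path(image_path).stem
        try:
            rows.append(run_slide(image_path, annotation_path, config, sid).row)
        except Exception as err:  # noqa: BLE001 - batch isolation
            logger.error("slide %s failed: %s", sid, err)
            failures.append((sid, str(err)))
    return pd.DataFrame(rows, columns=SLIDE_TSV_COLUMNS), failures


TABLE1_METRICS = [
    ("h_score", "H-score (0-300)"),
    ("pi_percent", "Proliferation Index (%)"),
    ("positive_density_per_mm2", "Count positive nuclei per mm^2"),
    ("strong_density_per_mm2", "Count strong nuclei per mm^2"),
]


def table1_summary(cohort: pd.DataFrame, inflammation_col: str = "q_inflammation") -> pd.DataFrame:
    """Cohort summary: mean (range; SD) per Ki-67 metric, for all slides and
    the inflammation-excluded subset, with signed fold changes."""
    have_scores = inflammation_col in cohort and cohort[inflammation_col].notna().any()
    excluded = cohort_stats.exclude_inflamed(cohort, inflammation_col) if have_scores else None
    rows = []
    for col, label in TABLE1_METRICS:
        if col not in cohort:
            continue
        v = cohort[col].dropna()
        row = {
            "parameter": label,
            "n": len(v),
            "mean": v.mean(),
            "min": v.min(),
            "max": v.max(),
            "sd": v.std(ddof=1) if len(v) > 1 else 0.0,
        }
        if excluded is not None and len(excluded):
            ve = excluded[col].dropna()
            row.update(
                n_excluded=len(ve),
                mean_excluded=ve.mean(),
                min_excluded=ve.min(),
                max_excluded=ve.max(),
                sd_excluded=ve.std(ddof=1) if len(ve) > 1 else 0.0,
                fold_change=cohort_stats.fold_change(v.mean(), ve.mean()),
            )
        rows.append(row)
    out = pd.DataFrame(rows)
    if excluded is None:
        logger.warning("no inflammation scores present; exclusion columns omitted")
    return out


def run_cohort(
    slide_table: pd.DataFrame,
    metadata: pd.DataFrame | None = None,
    config: PipelineConfig = PipelineConfig(),
) -> dict:
    """Join slide metrics to cohort metadata and compute the summary layer.

    Returns a dict with the joined cohort table, the Table-1-style summary,
    and (when the relevant columns are present) the hotspot-category and
    PI-category summaries.
    """
    if len(slide_table) == 0:
        raise ValueError("need at least one slide row")
    cohort = slide_table
    if metadata is not None:
        missing = set(metadata["slide_id"]) ^ set(slide_table["slide_id"])
        if missing:
            logger.warning("cohort join mismatches for ids: %s", sorted(missing))
        cohort = slide_table.merge(metadata, on="slide_id", how="left", suffixes=("", "_meta"))
    out = {"cohort": cohort, "table1": table1_summary(cohort)}
    if "manual_hotspot_category" in cohort:
        cats = cohort["manual_hotspot_category"].dropna()
        if len(cats):
            out["webster"] = cohort_stats.webster_summary(cats)
    if "pi_percent" in cohort:
        out["pi_categories"] = cohort_stats.pi_category_summary(cohort)
    return out
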