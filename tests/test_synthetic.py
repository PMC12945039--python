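"""Synthetic slide and cohort generators: quotas, determinism, planting."""

import numpy as np
import pandas as pd
import pytest

from ki67quant.hotspot import find_hotspot
from ki67quant.synthetic import (
    SlideSpec,
    SpatialLaw,
    generate_cohort,
    generate_slide,
    largest_remainder,
    plant_hotspot,
)


class TestLargestRemainder:
    @pytest.mark.parametrize(
        "n,fractions,expected",
        [
            (200, (0.6, 0.2, 0.15, 0.05), [120, 40, 30, 10]),
            (0, (0.25, 0.25, 0.25, 0.25), [0, 0, 0, 0]),
            (10, (1.0, 0.0, 0.0, 0.0), [10, 0, 0, 0]),
            (7, (1 / 3, 1 / 3, 1 / 3), [3, 2, 2]),  # remainder to earliest tie
        ],
    )
    def test_exact_apportionment(self, n, fractions, expected):
        assert largest_remainder(n, fractions) == expected

    def test_counts_always_sum_to_n(self, rng):
        for _ in range(50):
            k = int(rng.integers(2, 6))
            f = rng.dirichlet(np.ones(k))
            n = int(rng.integers(0, 5000))
            assert sum(largest_remainder(n, f)) == n


class TestSpecValidation:
    def test_quotas_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SlideSpec(class_quotas=(0.5, 0.2, 0.2, 0.2))

    def test_intensity_band_must_sit_inside_class_band(self):
        with pytest.raises(ValueError, match="not strictly inside"):
            SlideSpec(
                intensity_bands={
                    "negative": (180, 250),
                    "weak": (110, 165),  # 110 falls in the moderate band
                    "moderate": (75, 115),
                    "strong": (30, 65),
                }
            )

    def test_radius_ordering(self):
        with pytest.raises(ValueError):
            SlideSpec(nucleus_radius_um=(3.0, 2.0))

    def test_clustered_law_needs_geometry(self):
        with pytest.raises(ValueError):
            SpatialLaw(kind="clustered")


class TestGenerateSlide:
    def test_empty_spec_gives_blank_white_slide(self):
        spec = SlideSpec(width_px=64, height_px=64, n_nuclei=0, seed=5)
        image, truth, roiset = generate_slide(spec)
        assert (image.pixels == 255).all()
        assert len(truth.records) == 0
        assert truth.summary.n_total == 0
        assert roiset.area_mm2 > 0

    def test_exact_class_quotas(self):
        spec = SlideSpec(
            width_px=900, height_px=900, n_nuclei=200,
            class_quotas=(0.6, 0.2, 0.15, 0.05), seed=2,
        )
        _, truth, _ = generate_slide(spec)
        counts = truth.records.planted_class.value_counts()
        assert counts["negative"] == 120
        assert counts["weak"] == 40
        assert counts["moderate"] == 30
        assert counts["strong"] == 10

    def test_identical_seed_bit_identical_outputs(self):
        spec = SlideSpec(width_px=300, height_px=300, n_nuclei=40, seed=9)
        img1, truth1, _ = generate_slide(spec)
        img2, truth2, _ = generate_slide(spec)
        assert img1.pixels.tobytes() == img2.pixels.tobytes()
        pd.testing.assert_frame_equal(truth1.records, truth2.records)

    def test_different_seed_different_slide(self):
        a, _, _ = generate_slide(SlideSpec(width_px=300, height_px=300, n_nuclei=40, seed=1))
        b, _, _ = generate_slide(SlideSpec(width_px=300, height_px=300, n_nuclei=40, seed=2))
        assert a.pixels.tobytes() != b.pixels.tobytes()

    def test_nuclei_never_overlap(self):
        spec = SlideSpec(width_px=600, height_px=600, n_nuclei=150, seed=3)
        _, truth, _ = generate_slide(spec)
        r = truth.records
        xy = r[["x_um", "y_um"]].to_numpy()
        rad = r.radius_um.to_numpy()
        d = np.linalg.norm(xy[:, None] - xy[None, :], axis=2)
        lim = rad[:, None] + rad[None, :]
        off = ~np.eye(len(r), dtype=bool)
        assert (d[off] > lim[off]).all()

    def test_placement_failure_names_density_limit(self):
        spec = SlideSpec(width_px=100, height_px=100, n_nuclei=500, seed=0)
        with pytest.raises(RuntimeError, match="packing limit"):
            generate_slide(spec)

    def test_planted_summary_equals_metrics_formulas(self, small_slide):
        _, _, truth, roiset = small_slide
        in_roi = truth.records[truth.records.inside_roi]
        n_pos = int((in_roi.planted_class != "negative").sum())
        n_tot = len(in_roi)
        assert truth.summary.n_total == n_tot
        assert truth.summary.pi_percent == pytest.approx(100 * n_pos / n_tot)
        assert truth.summary.positive_density_per_mm2 == pytest.approx(
            n_pos / roiset.area_mm2
        )

    def test_exclusion_polygon_removes_nuclei_from_summary(self):
        spec = SlideSpec(
            width_px=500, height_px=500, n_nuclei=80, seed=4,
            exclusion_polygons=(((0, 0), (250, 0), (250, 250), (0, 250)),),
        )
        _, truth, roiset = generate_slide(spec)
        r = truth.records
        excluded = r[(r.x_um < 250 * 0.23) & (r.y_um < 250 * 0.23)]
        assert not excluded.inside_roi.any()
        assert truth.summary.n_total == int(r.inside_roi.sum())

    def test_inflammation_adds_flagged_weak_nuclei(self):
        spec = SlideSpec(width_px=800, height_px=800, n_nuclei=100,
                         inflammation_fraction=0.2, seed=6)
        _, truth, _ = generate_slide(spec)
        r = truth.records
        assert len(r) == 125  # 100 planted + 25 inflammatory = 20% of 125
        inflam = r[r.inflammatory]
        assert (inflam.planted_class == "weak").all()


class TestPlantHotspot:
    def test_count_zero_is_identity(self):
        spec = SlideSpec(seed=1)
        assert plant_hotspot(spec, 0) == spec

    def test_planted_count_recovered_by_search(self):
        # slide otherwise empty of positives: search must find exactly 30
        spec = SlideSpec(
            width_px=4000, height_px=4000, n_nuclei=30,
            class_quotas=(0.0, 0.0, 0.0, 1.0), seed=7,
        )
        spec = plant_hotspot(spec, 30)
        _, truth, roiset = generate_slide(spec)
        pos = truth.records[truth.records.planted_class != "negative"]
        res = find_hotspot(pos[["x_um", "y_um"]].to_numpy(), roiset.bounds_um)
        assert res.positive_count == 30

    def test_planted_24_is_webster_high(self):
        spec = SlideSpec(
            width_px=4000, height_px=4000, n_nuclei=24,
            class_quotas=(0.0, 0.0, 0.0, 1.0), seed=8,
        )
        spec = plant_hotspot(spec, 24)
        _, truth, roiset = generate_slide(spec)
        pos = truth.records[truth.records.planted_class != "negative"]
        res = find_hotspot(pos[["x_um", "y_um"]].to_numpy(), roiset.bounds_um)
        assert res.positive_count == 24
        assert res.webster_category == "high"

    def test_infeasible_counts_rejected(self):
        spec = SlideSpec(width_px=4000, height_px=4000, n_nuclei=10,
                         class_quotas=(1.0, 0.0, 0.0, 0.0), seed=0)
        with pytest.raises(ValueError, match="positive"):
            plant_hotspot(spec, 5)  # no positives available
        dense = SlideSpec(width_px=4000, height_px=4000, n_nuclei=100_000,
                         class_quotas=(0.0, 0.0, 0.0, 1.0), seed=0)
        with pytest.raises(ValueError, match="packed"):
            plant_hotspot(dense, 100_000)
        small = SlideSpec(n_nuclei=30, class_quotas=(0.0, 0.0, 0.0, 1.0), seed=0)
        with pytest.raises(ValueError, match="fit"):
            plant_hotspot(small, 10)  # 1024 px slide is narrower than the window


class TestGenerateCohort:
    def test_reproducible_under_seed(self):
        a = generate_cohort(50, 0.5, 0.001, 1000, seed=3)
        b = generate_cohort(50, 0.5, 0.001, 1000, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_censor_time_censors_everything(self):
        df = generate_cohort(40, 0.5, 0.001, 0.0, seed=1)
        assert df.event.sum() == 0
        assert (df.survival_days == 0).all()

    def test_validation(self):
        with pytest.raises(ValueError):
            generate_cohort(1, 0.0, 0.001, 100, seed=0)
        with pytest.raises(ValueError):
            generate_cohort(10, 0.0, -1.0, 100, seed=0)
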