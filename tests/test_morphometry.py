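"""Morphometry: ellipse moments, zoning, positive fractions, area ratios."""

import numpy as np
import pytest

from brisma.exceptions import RegionError, ZoneAssignmentError
from brisma.morphometry import (
    NucleusShape,
    classify_zone,
    invasion_ratio,
    nucleus_shapes,
    positive_fraction,
    region_mean_intensity,
)
from brisma.synthetic import (
    make_dextran_image,
    make_invasion_masks,
    make_nuclei_image,
)


def _raster_ellipse(a, b, theta=0.0, size=101):
    c = size / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    dx, dy = xx - c, yy - c
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    return ((u / a) ** 2 + (v / b) ** 2 <= 1.0).astype(np.int32)


class TestNucleusShapes:
    def test_disk_aspect_ratio_unity(self):
        shapes, _ = nucleus_shapes(_raster_ellipse(15, 15))
        assert shapes[0].aspect_ratio == pytest.approx(1.00, abs=0.02)

    def test_ellipse_20_10_aspect_ratio(self):
        shapes, _ = nucleus_shapes(_raster_ellipse(20, 10))
        assert shapes[0].aspect_ratio == pytest.approx(2.00, abs=0.05)

    def test_rotation_invariance(self):
        ar0 = nucleus_shapes(_raster_ellipse(20, 10))[0][0].aspect_ratio
        ar37 = nucleus_shapes(_raster_ellipse(20, 10, np.deg2rad(37)))[0][0].aspect_ratio
        assert ar37 == pytest.approx(ar0, abs=0.05)

    def test_translation_and_scale_invariance(self):
        # sizes large enough that rasterization bias (~1/minor_axis) is
        # below the tolerance on the scaling comparison
        base = nucleus_shapes(_raster_ellipse(48, 24, size=241))[0][0].aspect_ratio
        scaled = nucleus_shapes(_raster_ellipse(96, 48, size=481))[0][0].aspect_ratio
        assert scaled == pytest.approx(base, abs=0.02)

    def test_small_labels_dropped_and_counted(self):
        img = _raster_ellipse(15, 15)
        img[0, 0:3] = 2  # 3-pixel speck
        shapes, dropped = nucleus_shapes(img, min_area=20)
        assert len(shapes) == 1
        assert dropped == 1

    def test_empty_label_image_is_error(self):
        with pytest.raises(RegionError):
            nucleus_shapes(np.zeros((32, 32), dtype=np.int32))


class TestClassifyZone:
    def _disk_mask(self, radius=100, size=221):
        c = size / 2.0
        yy, xx = np.mgrid[0:size, 0:size]
        return ((yy - c) ** 2 + (xx - c) ** 2 <= radius**2).astype(np.uint8)

    def _shape_at(self, r, c):
        return NucleusShape(1, (r, c), 10.0, 8.0, 1.25, 60.0)

    def test_boundary_centroid_is_periphery(self):
        mask = self._disk_mask()
        s = self._shape_at(110.5, 210.0)  # on the rim
        out = classify_zone([s], mask, band=20)
        assert out[0].zone == "periphery"

    def test_center_centroid_is_center(self):
        mask = self._disk_mask()
        out = classify_zone([self._shape_at(110.5, 110.5)], mask, band=20)
        assert out[0].zone == "center"

    def test_centroid_outside_mask_is_error(self):
        mask = self._disk_mask()
        with pytest.raises(ZoneAssignmentError, match="1"):
            classify_zone([self._shape_at(2.0, 2.0)], mask, band=20)

    def test_generator_zone_agreement(self):
        """>= 95% of nuclei land in the generator's assigned zone."""
        nuc = make_nuclei_image(n=150, seed=11)
        shapes, _ = nucleus_shapes(nuc.labels)
        shapes = classify_zone(shapes, nuc.mask, band=nuc.truth["band"])
        truth_zone = {r["label"]: r["zone"] for r in nuc.truth["nuclei"]}
        agreement = np.mean([s.zone == truth_zone[s.label] for s in shapes])
        assert agreement >= 0.95


class TestPositiveFraction:
    def _shapes(self, values):
        return [
            NucleusShape(i, (0.0, 0.0), 10, 8, 1.25, 60, mean_intensity=v)
            for i, v in enumerate(values)
        ]

    def test_all_below_threshold(self):
        res = positive_fraction(self._shapes([90, 95, 100]), [100, 101, 99, 100])
        assert res.fraction == 0.0

    def test_all_above_threshold(self):
        res = positive_fraction(self._shapes([200, 210, 250]), [100, 101, 99, 100])
        assert res.fraction == 1.0
        assert res.n_positive == res.n_total == 3

    def test_empty_controls_is_error(self):
        with pytest.raises(RegionError):
            positive_fraction(self._shapes([100]), [])

    def test_global_rescaling_invariance(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(100, 10, 50)
        ctrl = rng.normal(100, 10, 50)
        r0 = positive_fraction(self._shapes(vals), ctrl)
        r1 = positive_fraction(self._shapes(vals * 7.5), ctrl * 7.5)
        assert r1.fraction == r0.fraction
        assert r1.threshold == pytest.approx(r0.threshold)

    def test_mixture_weight_recovered(self):
        """30% of nuclei shifted by 5 control SDs: recovered fraction lands
        near the mixture weight (mean over 3 generator seeds)."""
        fractions = []
        for seed in (0, 1, 2):
            nuc = make_nuclei_image(n=200, positive_fraction_true=0.30, seed=seed)
            shapes, _ = nucleus_shapes(nuc.labels, intensity=nuc.intensity)
            ctrl = np.random.default_rng(seed + 100).normal(
                nuc.truth["control_mean"], nuc.truth["control_sd"], 200
            )
            fractions.append(positive_fraction(shapes, ctrl).fraction)
        assert np.mean(fractions) == pytest.approx(0.30, abs=0.05)


class TestInvasionRatio:
    def _disk(self, radius, size):
        c = size / 2.0
        yy, xx = np.mgrid[0:size, 0:size]
        return ((yy - c) ** 2 + (xx - c) ** 2 <= radius**2).astype(np.uint8)

    def test_no_invasion(self):
        core = self._disk(40, 101)
        assert invasion_ratio(core, core).ratio == 0.0

    def test_concentric_disks_annulus_ratio(self):
        """Disks of radii 2r and r: (4-1)/1 = 3."""
        assert invasion_ratio(self._disk(50, 221), self._disk(100, 221)).ratio == pytest.approx(
            3.00, abs=0.02
        )

    def test_resolution_invariance(self):
        r1 = invasion_ratio(self._disk(40, 181), self._disk(80, 181)).ratio
        r2 = invasion_ratio(self._disk(80, 361), self._disk(160, 361)).ratio
        assert r2 == pytest.approx(r1, rel=0.01)

    def test_empty_core_is_error(self):
        with pytest.raises(RegionError):
            invasion_ratio(np.zeros((50, 50), dtype=np.uint8), self._disk(20, 50))

    def test_generator_truth_matches_pixel_counts(self):
        core, total, truth = make_invasion_masks(seed=4)
        res = invasion_ratio(core, total)
        assert res.core_area == pytest.approx(truth["core_area"], rel=0.02)
        assert res.ratio == pytest.approx(truth["ratio"], abs=0.02)

    def test_zero_spread_means_zero_ratio(self):
        core, total, truth = make_invasion_masks(spread=0.0, seed=4)
        assert invasion_ratio(core, total).ratio == 0.0
        assert truth["ratio"] == 0.0


class TestRegionMeanIntensity:
    def test_constant_image_scalar_background(self):
        img = np.full((20, 20), 100.0)
        mask = np.ones((20, 20), bool)
        assert region_mean_intensity(img, mask, background=10.0) == pytest.approx(90.0)

    def test_background_image_cancellation(self):
        img = np.random.default_rng(0).uniform(0, 50, (20, 20))
        mask = np.ones((20, 20), bool)
        assert region_mean_intensity(img, mask, background=img) == pytest.approx(0.0)

    def test_empty_mask_is_error(self):
        with pytest.raises(RegionError):
            region_mean_intensity(np.ones((5, 5)), np.zeros((5, 5), bool))

    def test_dextran_level_recovered(self):
        img, mask, truth = make_dextran_image(seed=7)
        value = region_mean_intensity(img, mask, background=truth["background"])
        assert value == pytest.approx(truth["interstitial_level"], rel=0.02)
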