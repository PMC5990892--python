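import math

import numpy as np
import pandas as pd
import pytest

from canolux.hemiphoto import (HemiImage, SkyGrid, _runs_from_bool, binarize,
                               clumping_index_cc, crown_structure, gap_runs,
                               pixel_to_sky, segment_gap_fraction,
                               sky_to_pixel)
from canolux.synth import CrownTruth, gen_canopy_mask

from .conftest import crown_from_gap


def _blank_image(size=241, level=255):
    return HemiImage.from_array(np.full((size, size), level, dtype=np.uint8))


class TestProjection:
    def test_center_maps_to_zenith(self):
        img = _blank_image()
        zen, _ = pixel_to_sky(*img.center, img)
        assert zen == pytest.approx(0.0, abs=1e-9)

    def test_rim_top_is_north_horizon(self):
        img = _blank_image()
        cx, cy = img.center
        zen, az = pixel_to_sky(cx, cy - img.radius, img)
        assert zen == pytest.approx(90.0)
        assert az == pytest.approx(0.0)

    def test_half_radius_right_is_east_45(self):
        img = _blank_image()
        cx, cy = img.center
        zen, az = pixel_to_sky(cx + img.radius / 2, cy, img)
        assert zen == pytest.approx(45.0)
        assert az == pytest.approx(90.0)

    def test_round_trip(self):
        img = _blank_image()
        rng = np.random.default_rng(1)
        zen = rng.uniform(1, 89, 50)
        az = rng.uniform(0, 360, 50)
        x, y = sky_to_pixel(zen, az, img)
        zen2, az2 = pixel_to_sky(x, y, img)
        assert np.allclose(zen, zen2)
        assert np.allclose(az, az2)

    def test_outside_circle_rejected(self):
        img = _blank_image()
        with pytest.raises(ValueError):
            pixel_to_sky(0.0, 0.0, img)


class TestBinarize:
    def test_all_sky_and_all_vegetation(self):
        assert binarize(_blank_image(level=255)).gap_fraction == 1.0
        assert binarize(_blank_image(level=0)).gap_fraction == 0.0

    def test_threshold_boundary_is_vegetation(self):
        mask = binarize(_blank_image(level=131), threshold=131)
        assert mask.gap_fraction == 0.0
        mask = binarize(_blank_image(level=132), threshold=131)
        assert mask.gap_fraction == 1.0

    def test_known_vegetation_fraction_recovered(self):
        rng = np.random.default_rng(3)
        size = 361
        px = np.where(rng.random((size, size)) < 0.30, 0, 255).astype(np.uint8)
        mask = binarize(HemiImage.from_array(px))
        assert mask.gap_fraction == pytest.approx(0.70, abs=0.01)

    def test_color_image_rejected(self):
        with pytest.raises(ValueError):
            HemiImage.from_array(np.zeros((64, 64, 3), dtype=np.uint8))


class TestSegmentGapFraction:
    def test_grid_yields_240_segments_216_used(self):
        grid = SkyGrid()
        assert grid.n_segments == 240
        assert grid.n_used == 216
        seg = segment_gap_fraction(binarize(_blank_image()), grid)
        assert len(seg) == 240
        assert int(seg["used"].sum()) == 216

    def test_uniform_sky_gives_unit_gap_everywhere(self):
        seg = segment_gap_fraction(binarize(_blank_image()))
        assert np.allclose(seg["gap_fraction"], 1.0)

    def test_partition_of_image_circle(self):
        mask = binarize(_blank_image())
        seg = segment_gap_fraction(mask)
        assert seg["pixel_count"].sum() == int(mask.valid.sum())

    def test_recovers_generator_targets(self):
        truth = CrownTruth(ring_gap=np.linspace(0.2, 0.8, 10),
                           ring_cluster_scale=np.zeros(10))
        image, table = gen_canopy_mask(truth, image_size=481, seed=4)
        seg = segment_gap_fraction(binarize(image))
        err = np.abs(seg["gap_fraction"] - table["target_gap"])
        assert err[seg["used"]].mean() < 0.02

    def test_rotation_by_quarter_turn_permutes_slices(self):
        truth = CrownTruth(ring_gap=np.full(10, 0.5),
                           ring_cluster_scale=np.zeros(10))
        image, _ = gen_canopy_mask(truth, image_size=241, seed=9)
        seg = segment_gap_fraction(binarize(image))
        rot = HemiImage.from_array(np.rot90(image.pixels).copy())
        seg_rot = segment_gap_fraction(binarize(rot))
        g = seg.pivot(index="ring", columns="slice",
                      values="gap_fraction").values
        g_rot = seg_rot.pivot(index="ring", columns="slice",
                              values="gap_fraction").values
        # rot90 is a 90-degree counter-clockwise raster rotation = a shift
        # of 6 slices on the 24-slice grid; slice-boundary pixels can land
        # in the neighbouring bin, so agreement is up to pixel quantization
        diff = np.roll(g, -6, axis=1) - g_rot
        assert np.abs(diff).max() < 0.03
        assert np.abs(diff).mean() < 0.003


class TestGapRuns:
    def test_run_length_extraction(self):
        assert _runs_from_bool(np.array([], dtype=bool)).tolist() == []
        arr = np.array([True, False, True, True, False, True])
        assert _runs_from_bool(arr).tolist() == [1, 2, 1]
        assert _runs_from_bool(np.ones(5, dtype=bool)).tolist() == [5]

    def test_closed_segment_has_no_runs(self):
        runs = gap_runs(binarize(_blank_image(level=0)))
        assert all(len(rec.runs) == 0 for rec in runs.values())

    def test_open_segment_runs_span_the_slice(self):
        grid = SkyGrid()
        runs = gap_runs(binarize(_blank_image(level=255)), grid)
        rec = runs[(5, 3)]
        assert rec.runs
        assert all(r == pytest.approx(grid.slice_width, abs=1e-6)
                   for r in rec.runs)
        assert rec.total_deg == pytest.approx(
            grid.slice_width * rec.n_arcs, abs=1e-6)


class TestClumpingIndex:
    def test_identity_when_no_gaps_removed(self):
        """Many small gaps consistent with a random canopy give exactly 1."""
        runs = [0.2] * 30          # tiny gaps, 6 deg of 100 total
        assert clumping_index_cc(runs, 100.0, element_width=2.0) == 1.0

    def test_degenerate_segments_are_missing(self):
        assert math.isnan(clumping_index_cc([], 100.0))
        assert math.isnan(clumping_index_cc([100.0], 100.0))   # fully open
        assert math.isnan(clumping_index_cc([0.4], 0.0))

    def test_single_large_gap_strongly_clumped(self):
        """A gap covering 25% of the arc in otherwise dense canopy."""
        runs = [3.75] + [0.1] * 5
        omega = clumping_index_cc(runs, 15.0, element_width=2.0)
        assert omega < 0.9

    def test_random_canopy_is_unclumped(self, random_crown_structure):
        crown, _ = random_crown_structure
        used = crown.segments[crown.segments["used"]]
        omega = used["clumping"].dropna()
        assert len(omega) >= 200
        assert 0.95 <= omega.mean() <= 1.05
        assert (omega <= 1.0 + 0.05).all()

    def test_clustered_canopy_more_clumped_than_random(self):
        rng_pairs = range(3)
        for s in rng_pairs:
            random = CrownTruth(ring_gap=np.full(10, 0.3),
                                ring_cluster_scale=np.zeros(10))
            clustered = CrownTruth(ring_gap=np.full(10, 0.3),
                                   ring_cluster_scale=np.full(10, 8.0))
            img_r, _ = gen_canopy_mask(random, 481, seed=100 + s)
            img_c, _ = gen_canopy_mask(clustered, 481, seed=200 + s)
            om_r = crown_structure(binarize(img_r)).segments.query(
                "used")["clumping"].mean()
            om_c = crown_structure(binarize(img_c)).segments.query(
                "used")["clumping"].mean()
            assert om_c < om_r

    def test_omega_decreases_with_cluster_size(self):
        means = []
        for scale in (0.0, 3.0, 8.0):
            truth = CrownTruth(ring_gap=np.full(10, 0.3),
                               ring_cluster_scale=np.full(10, scale))
            image, _ = gen_canopy_mask(truth, 481, seed=7)
            crown = crown_structure(binarize(image))
            means.append(crown.segments.query("used")["clumping"].mean())
        assert means[0] > means[1] > means[2]


class TestCrownStructure:
    def test_ci_cv_zero_for_constant_clumping(self):
        crown = crown_from_gap(0.5)
        assert crown.ci_cv == pytest.approx(0.0, abs=1e-12)

    def test_homogeneous_random_crown_has_low_ci_cv(
            self, random_crown_structure):
        crown, _ = random_crown_structure
        assert crown.ci_cv < 0.1

    def test_ring_summary_has_nine_or_eight_bands(self,
                                                  random_crown_structure):
        crown, _ = random_crown_structure
        assert len(crown.ring_summary()) == 9
        eight = crown.ring_summary(eight_bands=True)
        assert len(eight) == 8
        assert eight["n_segments"].iloc[-1] == 48   # two merged rings

    def test_doughnut_profile_monotone_in_generated_direction(self):
        from canolux.synth import gen_doughnut_crown
        image, _ = gen_doughnut_crown(seed=21)
        crown = crown_structure(binarize(image))
        rs = crown.ring_summary()
        top = rs.iloc[:3]
        lateral = rs.iloc[-3:]
        assert top["gap_mean"].mean() > lateral["gap_mean"].mean()
        assert top["clumping_mean"].mean() < lateral["clumping_mean"].mean()

    def test_gap_estimate_unbiased_against_truth(self):
        """Regression of estimated on target per-segment G: slope 1±0.05."""
        est, tru = [], []
        for s in range(3):
            profile = np.linspace(0.15 + 0.05 * s, 0.85, 10)
            truth = CrownTruth(ring_gap=profile,
                               ring_cluster_scale=np.zeros(10))
            image, table = gen_canopy_mask(truth, 481, seed=50 + s)
            seg = segment_gap_fraction(binarize(image))
            used = seg["used"].values
            est.append(seg["gap_fraction"].values[used])
            tru.append(table["target_gap"].values[used])
        est = np.concatenate(est)
        tru = np.concatenate(tru)
        assert len(est) >= 500
        slope, intercept = np.polyfit(tru, est, 1)
        assert slope == pytest.approx(1.0, abs=0.05)
        assert intercept == pytest.approx(0.0, abs=0.02)
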