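"""Imaging pipeline: restoration, Tsai threshold, cleanup, global traits."""

import numpy as np
import pytest

from rootscan.imaging import (
    BinaryMask,
    RasterImage,
    boundary_perimeter,
    convex_hull_area,
    denoise,
    filter_objects,
    flatten_background,
    measure_global_traits,
    segment,
    segment_pipeline,
    skeleton_length,
    to_grayscale_red,
    tsai_moment_threshold,
)

from conftest import image_from, rect_mask


# ---------------------------------------------------------------- channels
class TestRedChannel:
    def test_selects_red_channel_values(self):
        rgb = np.zeros((4, 4, 3))
        rgb[..., 0] = 200
        rgb[..., 1] = 10
        rgb[..., 2] = 10
        out = to_grayscale_red(image_from(rgb))
        assert out.n_channels == 1
        assert np.all(out.pixels == 200)
        assert out.dpi == 300.0

    def test_all_black_stays_black(self):
        out = to_grayscale_red(image_from(np.zeros((3, 3, 3))))
        assert not out.pixels.any()

    def test_single_channel_passthrough_warns(self):
        with pytest.warns(UserWarning):
            out = to_grayscale_red(image_from(np.full((3, 3), 7.0)))
        assert np.all(out.pixels == 7)

    def test_red_contrast_exceeds_green_on_rendered_scene(self, noisy_scene):
        img, truth = noisy_scene
        fg, bg = truth.pixels, ~truth.pixels
        px = img.pixels
        red_contrast = px[..., 0][fg].mean() - px[..., 0][bg].mean()
        green_contrast = px[..., 1][fg].mean() - px[..., 1][bg].mean()
        assert red_contrast >= green_contrast > 0


# ---------------------------------------------------------------- denoise
class TestDenoise:
    def test_constant_image_unchanged(self):
        out = denoise(image_from(np.full((16, 16), 42.0)), 1, 1.0)
        assert np.allclose(out.pixels, 42.0)

    def test_salt_pixel_removed_by_median(self):
        px = np.zeros((9, 9))
        px[4, 4] = 255
        out = denoise(image_from(px), median_radius=1, gaussian_sigma=0)
        assert out.pixels[4, 4] == 0

    def test_zero_radius_disables_median(self):
        px = np.zeros((9, 9))
        px[4, 4] = 255
        out = denoise(image_from(px), median_radius=0, gaussian_sigma=0)
        assert out.pixels[4, 4] == 255

    def test_nonfinite_parameters_rejected(self):
        img = image_from(np.zeros((4, 4)))
        with pytest.raises(ValueError):
            denoise(img, median_radius=1, gaussian_sigma=float("nan"))


# ---------------------------------------------------------------- flattening
class TestFlattenBackground:
    def test_constant_maps_to_midgrey(self):
        out = flatten_background(image_from(np.full((32, 32), 77.0)), 10)
        assert np.allclose(out.pixels, 128.0)

    def test_linear_ramp_suppressed(self):
        ramp = np.tile(np.linspace(0, 80, 200), (60, 1))
        out = flatten_background(image_from(ramp), 25)
        interior = out.pixels[:, 30:-30]
        assert interior.std() < 0.1 * ramp.std()

    def test_gradient_removed_away_from_line(self):
        img = np.tile(np.linspace(0, 80, 300), (100, 1))
        img[48:52, :] += 100.0  # thin bright line
        out = flatten_background(image_from(np.clip(img, 0, 255)), 25)
        # rows more than one window radius away from the line at rows 48-52
        far = out.pixels[0:20, 50:-50]
        assert far.max() - far.min() <= 5.0

    def test_nonpositive_window_rejected(self):
        with pytest.raises(ValueError):
            flatten_background(image_from(np.zeros((4, 4))), 0)


# ---------------------------------------------------------------- Tsai threshold
def _moment_oracle(pixels: np.ndarray) -> int:
    """Exhaustive scan: for each candidate threshold pick the two levels that
    preserve the first two moments and return the t whose binarization best
    matches the third moment."""
    hist = np.bincount(pixels.astype(int).ravel(), minlength=256).astype(float)
    p = hist / hist.sum()
    lv = np.arange(256.0)
    m1 = (p * lv).sum()
    m2 = (p * lv**2).sum()
    m3 = (p * lv**3).sum()
    cum = np.cumsum(p)
    best_t, best_err = None, np.inf
    for t in range(256):
        p0 = cum[t]
        p1 = 1.0 - p0
        if p0 <= 0 or p1 <= 0:
            continue
        var = m2 - m1 * m1
        z0 = m1 - np.sqrt(var * p1 / p0)
        z1 = m1 + np.sqrt(var * p0 / p1)
        err = abs(p0 * z0**3 + p1 * z1**3 - m3)
        if err < best_err - 1e-12:
            best_err, best_t = err, t
    return best_t


class TestTsaiThreshold:
    def test_two_level_image_classified_exactly(self):
        px = np.zeros((10, 10))
        px[:, 5:] = 255
        t = tsai_moment_threshold(image_from(px))
        assert 0 < t + 1 <= 255
        mask = px > t
        assert mask.sum() == 50 and mask[:, 5:].all()

    def test_constant_image_rejected(self):
        with pytest.raises(ValueError):
            tsai_moment_threshold(image_from(np.full((8, 8), 9.0)))

    def test_gaussian_mixture_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(12)
        a = rng.normal(60, 10, 3000)
        b = rng.normal(200, 10, 3000)
        px = np.clip(np.concatenate([a, b]), 0, 255).round().reshape(75, 80)
        assert tsai_moment_threshold(image_from(px)) == _moment_oracle(px)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_exhaustive_oracle_on_random_images(self, seed):
        rng = np.random.default_rng(1000 + seed)
        kind = seed % 3
        if kind == 0:
            px = rng.integers(0, 256, (48, 48)).astype(float)
        elif kind == 1:
            a = rng.normal(rng.uniform(40, 90), rng.uniform(5, 20), 1500)
            b = rng.normal(rng.uniform(150, 220), rng.uniform(5, 20), 1500)
            px = np.clip(np.concatenate([a, b]), 0, 255).round().reshape(50, 60)
        else:
            px = np.clip(rng.normal(128, 40, (48, 48)), 0, 255).round()
        assert tsai_moment_threshold(image_from(px)) == _moment_oracle(px)

    def test_cumulative_fraction_matches_closed_form_mass(self):
        rng = np.random.default_rng(7)
        px = np.clip(
            np.concatenate([rng.normal(70, 12, 2000), rng.normal(190, 15, 2000)]), 0, 255
        ).round().reshape(40, 100)
        hist = np.bincount(px.astype(int).ravel(), minlength=256).astype(float)
        p = hist / hist.sum()
        lv = np.arange(256.0)
        m1, m2, m3 = (p * lv).sum(), (p * lv**2).sum(), (p * lv**3).sum()
        cd = m2 - m1 * m1
        c0 = (m1 * m3 - m2 * m2) / cd
        c1 = (m1 * m2 - m3) / cd
        z0 = (-c1 - np.sqrt(c1 * c1 - 4 * c0)) / 2
        z1 = (-c1 + np.sqrt(c1 * c1 - 4 * c0)) / 2
        p0 = (z1 - m1) / (z1 - z0)
        t = tsai_moment_threshold(image_from(px))
        cum = np.cumsum(p)
        # fraction below the threshold equals the moment-preserving mass
        # within one histogram bin of cumulative mass
        lo = cum[t - 1] if t > 0 else 0.0
        hi = cum[min(t + 1, 255)]
        assert lo - 1e-12 <= p0 <= hi + 1e-12


# ---------------------------------------------------------------- segmentation
class TestSegment:
    def test_all_above_threshold_gives_full_mask(self):
        m = segment(image_from(np.full((5, 5), 200.0)), 100)
        assert m.pixels.all()

    def test_invert_flips_exactly(self):
        rng = np.random.default_rng(0)
        img = image_from(rng.integers(0, 256, (20, 20)).astype(float))
        m = segment(img, 127)
        mi = segment(img, 127, invert=True)
        assert np.array_equal(m.pixels, ~mi.pixels)

    def test_empty_foreground_warns(self):
        with pytest.warns(UserWarning):
            m = segment(image_from(np.zeros((5, 5))), 10)
        assert not m.pixels.any()

    def test_rendered_scene_overlaps_truth(self, noisy_scene):
        img, truth = noisy_scene
        mask = segment_pipeline(img)
        covered = (mask.pixels & truth.pixels).sum() / truth.pixels.sum()
        assert covered >= 0.95


# ---------------------------------------------------------------- object filter
class TestFilterObjects:
    def test_speck_removed_root_kept(self):
        px = np.zeros((60, 60), bool)
        px[5:55, 28:32] = True  # root bar
        px[10:12, 50:52] = True  # 4-px speck
        out = filter_objects(BinaryMask(px, 300), seed=(5, 30), min_area=50)
        assert out.pixels[5:55, 28:32].all()
        assert not out.pixels[10:12, 50:52].any()

    def test_single_component_unchanged(self):
        m = rect_mask(10, 10)
        out = filter_objects(m, seed=(7, 7), min_area=5)
        assert np.array_equal(out.pixels, m.pixels)

    def test_never_adds_foreground(self):
        rng = np.random.default_rng(3)
        px = rng.random((80, 80)) > 0.7
        out = filter_objects(BinaryMask(px, 300), seed=(40, 40), min_area=10)
        assert not (out.pixels & ~px).any()

    def test_seed_far_from_any_component_raises(self):
        px = np.zeros((600, 600), bool)
        px[590:600, 590:600] = True
        with pytest.raises(ValueError):
            filter_objects(BinaryMask(px, 300), seed=(0, 0), min_area=5, search_radius=50)

    def test_condensation_blobs_all_removed(self, reference_plant, default_config):
        from rootscan.synthesis import render_image
        from scipy import ndimage

        img, truth = render_image(reference_plant, 15.0, default_config, seed=3)
        mask = segment_pipeline(img)
        _, n = ndimage.label(mask.pixels, structure=np.ones((3, 3), int))
        assert n == 1


# ---------------------------------------------------------------- perimeter
class TestBoundaryPerimeter:
    def test_rectangle_closed_form(self):
        m = rect_mask(20, 40, dpi=254.0)  # 100 px per cm
        expected = (2 * 19 + 2 * 39) * 2.54 / 254.0
        assert boundary_perimeter(m) == pytest.approx(expected, abs=1e-9)

    def test_single_pixel_zero(self):
        px = np.zeros((5, 5), bool)
        px[2, 2] = True
        assert boundary_perimeter(BinaryMask(px, 300)) == 0.0

    def test_digitized_disc_near_circumference(self):
        r = 50
        yy, xx = np.mgrid[0:111, 0:111]
        disc = (yy - 55) ** 2 + (xx - 55) ** 2 <= r * r
        per_px = boundary_perimeter(BinaryMask(disc, 300)) / (2.54 / 300)
        assert per_px == pytest.approx(2 * np.pi * r, rel=0.05)

    def test_empty_mask_warns_zero(self):
        with pytest.warns(UserWarning):
            assert boundary_perimeter(BinaryMask(np.zeros((4, 4), bool), 300)) == 0.0


# ---------------------------------------------------------------- skeleton length
class TestSkeletonLength:
    def test_horizontal_bar_one_inch(self):
        px = np.zeros((15, 310), bool)
        px[5:10, 5:305] = True  # 300 x 5 px bar at 300 dpi
        length = skeleton_length(BinaryMask(px, 300))
        assert length == pytest.approx(2.54, rel=0.03)

    def test_diagonal_bar_sqrt2_weighting(self):
        n = 40
        px = np.zeros((n + 2, n + 2), bool)
        for i in range(n):
            px[i + 1, i + 1] = True
        length_px = skeleton_length(BinaryMask(px, 300)) / (2.54 / 300)
        assert length_px == pytest.approx((n - 1) * np.sqrt(2), abs=1e-6)

    def test_empty_mask_zero(self):
        assert skeleton_length(BinaryMask(np.zeros((4, 4), bool), 300)) == 0.0

    def test_rendered_scene_total_length_within_5pct(self, reference_plant, noisy_scene):
        img, _ = noisy_scene
        mask = segment_pipeline(img)
        truth_length = reference_plant.traits_at(15.0)["total_root_length"]
        assert skeleton_length(mask) == pytest.approx(truth_length, rel=0.05)


# ---------------------------------------------------------------- convex hull
class TestConvexHull:
    def test_rectangle_hull(self):
        m = rect_mask(21, 41, dpi=254.0)
        expected = 20 * 40 * (2.54 / 254.0) ** 2
        assert convex_hull_area(m) == pytest.approx(expected, rel=1e-9)

    def test_right_triangle(self):
        px = np.zeros((110, 110), bool)
        px[0, 0] = px[0, 100] = px[100, 0] = True
        area_px = convex_hull_area(BinaryMask(px, 300)) / (2.54 / 300) ** 2
        assert area_px == pytest.approx(5000.0, rel=1e-9)

    def test_l_shape_hull_exceeds_area(self):
        px = np.zeros((30, 30), bool)
        px[5:25, 5:10] = True
        px[20:25, 5:25] = True
        m = BinaryMask(px, 300)
        t = measure_global_traits(m)
        assert t.convex_hull_area > t.total_area

    def test_collinear_warns_zero(self):
        px = np.zeros((10, 10), bool)
        px[3, 2:8] = True
        with pytest.warns(UserWarning):
            assert convex_hull_area(BinaryMask(px, 300)) == 0.0


# ---------------------------------------------------------------- global traits
class TestGlobalTraits:
    def test_empty_mask_all_zero(self):
        with pytest.warns(UserWarning):
            t = measure_global_traits(BinaryMask(np.zeros((6, 6), bool), 300))
        assert (t.total_root_length, t.total_area, t.perimeter, t.convex_hull_area) == (
            0.0, 0.0, 0.0, 0.0,
        )

    def test_rectangle_closed_forms(self):
        m = rect_mask(5, 300, dpi=300.0)
        t = measure_global_traits(m)
        assert t.total_area == pytest.approx(5 * 300 * (2.54 / 300) ** 2)
        assert t.perimeter == pytest.approx((2 * 4 + 2 * 299) * 2.54 / 300)
        assert t.convex_hull_area == pytest.approx(4 * 299 * (2.54 / 300) ** 2)
        assert t.total_root_length == pytest.approx(2.54, rel=0.03)

    def test_rendered_scene_recovery(self, reference_plant, noisy_scene):
        img, _ = noisy_scene
        mask = segment_pipeline(img)
        traits = measure_global_traits(mask)
        truth = reference_plant.traits_at(15.0)
        assert traits.total_root_length == pytest.approx(truth["total_root_length"], rel=0.05)
        assert traits.convex_hull_area >= traits.total_area


# ---------------------------------------------------------------- pipeline properties
class TestPipelineProperties:
    def test_deterministic_given_identical_input(self, noisy_scene):
        img, _ = noisy_scene
        m1 = segment_pipeline(img)
        m2 = segment_pipeline(img)
        assert np.array_equal(m1.pixels, m2.pixels)

    def test_denoised_segmentation_robust_to_salt_and_pepper(self, quiet_scene, quiet_config):
        img, truth = quiet_scene
        rng = np.random.default_rng(11)
        noisy = img.pixels.copy()
        flips = rng.random(noisy.shape) < 0.01
        noisy[flips] = rng.choice([0.0, 255.0], size=int(flips.sum()))
        clean_mask = segment_pipeline(img)
        noisy_mask = segment_pipeline(RasterImage(noisy, img.dpi))
        recovered = (noisy_mask.pixels & clean_mask.pixels).sum() / clean_mask.pixels.sum()
        assert recovered >= 0.99

    def test_scale_covariance_across_dpi(self, reference_plant, quiet_config):
        from dataclasses import replace

        from rootscan.synthesis import render_image

        cfg150 = replace(quiet_config, dpi=150.0)
        _, m300 = render_image(reference_plant, 15.0, quiet_config, seed=3, color=False)
        _, m150 = render_image(reference_plant, 15.0, cfg150, seed=3, color=False)
        l300 = skeleton_length(m300)
        l150 = skeleton_length(m150)
        assert l150 == pytest.approx(l300, rel=0.03)
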