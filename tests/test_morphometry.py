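"""Grain screening, cropping, segmentation, and min-rect morphometry."""

import numpy as np
import pytest

from conftest import min_rect_angle_sweep
from panicletraits.calibration import PelDensity
from panicletraits.detection import BBox, DetectionSet, filter_confidence, nms
from panicletraits.morphometry import (
    GrainMeasurement,
    NoGrainBodyError,
    NoMeasurableGrainsError,
    ScreeningConfig,
    crop_grain,
    measure_grains,
    min_bounding_rect,
    panicle_grain_stats,
    screen_grains,
    segment_grain,
)

PEL = PelDensity(mm_per_pixel=0.1, real_radius_mm=25.0, pixel_radius=250.0)


def random_blob(rng, size=50, n_seed=30):
    """A random connected pixel blob grown from a seed point."""
    mask = np.zeros((size, size), dtype=bool)
    r, c = size // 2, size // 2
    mask[r, c] = True
    frontier = [(r, c)]
    while mask.sum() < n_seed and frontier:
        r, c = frontier[int(rng.integers(len(frontier)))]
        dr, dc = rng.integers(-1, 2, 2)
        nr, nc = np.clip(r + dr, 1, size - 2), np.clip(c + dc, 1, size - 2)
        if not mask[nr, nc]:
            mask[nr, nc] = True
            frontier.append((int(nr), int(nc)))
    return mask


class TestScreening:
    def _ds(self, boxes):
        return DetectionSet("img", (200, 200), boxes)

    def test_low_confidence_boxes_all_removed(self):
        d = self._ds([BBox(0, 0, 5, 5, 0.3), BBox(10, 10, 15, 15, 0.69)])
        assert screen_grains(d).boxes == []

    def test_disjoint_confident_boxes_all_retained(self):
        d = self._ds([BBox(0, 0, 5, 5, 0.9), BBox(50, 50, 60, 60, 0.9)])
        assert len(screen_grains(d).boxes) == 2

    def test_equals_nms_then_confidence_composition(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            boxes = []
            for _ in range(8):
                x0, y0 = rng.integers(0, 30, 2)
                w, h = rng.integers(2, 14, 2)
                boxes.append(BBox(float(x0), float(y0), float(x0 + w),
                                  float(y0 + h), round(float(rng.random()), 3)))
            d = self._ds(boxes)
            cfg = ScreeningConfig(conf=0.5, nms_iou=0.4)
            expected = filter_confidence(nms(d, 0.4), 0.5).boxes
            assert screen_grains(d, cfg).boxes == expected

    def test_pairwise_overlap_filter_drops_both_offenders(self):
        d = self._ds([
            BBox(0, 0, 10, 10, 0.9), BBox(2, 0, 12, 10, 0.9),
            BBox(50, 50, 60, 60, 0.9),
        ])
        cfg = ScreeningConfig(conf=0.7, nms_iou=0.9, max_pairwise_iou=0.3)
        out = screen_grains(d, cfg).boxes
        assert out == [BBox(50, 50, 60, 60, 0.9)]

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ScreeningConfig(pad_pixels=1)
        with pytest.raises(ValueError):
            ScreeningConfig(conf=1.5)


class TestCropGrain:
    IMG = np.arange(100 * 100 * 3, dtype=np.uint8).reshape(100, 100, 3)

    def test_unpadded_crop_has_box_shape(self):
        crop, off = crop_grain(self.IMG, BBox(10, 10, 20, 20), 0)
        assert crop.shape == (10, 10, 3)
        assert off == (10, 10)
        assert np.array_equal(crop, self.IMG[10:20, 10:20])

    def test_two_pixel_padding_grows_each_side(self):
        crop, off = crop_grain(self.IMG, BBox(10, 10, 20, 20), 2)
        assert crop.shape == (14, 14, 3)
        assert off == (8, 8)

    def test_padding_clips_at_the_image_edge(self):
        crop, off = crop_grain(self.IMG, BBox(0, 5, 8, 15), 2)
        assert off == (3, 0)  # left offset clipped to 0
        assert crop.shape == (14, 10, 3)
        assert np.array_equal(crop, self.IMG[3:17, 0:10])

    def test_box_fully_outside_is_an_error(self):
        with pytest.raises(ValueError):
            crop_grain(self.IMG, BBox(150, 150, 160, 160), 0)


class TestSegmentGrain:
    def _ellipse_crop(self, bright_on_dark=True):
        crop = np.full((40, 60, 3), 30 if bright_on_dark else 210, np.uint8)
        yy, xx = np.mgrid[:40, :60]
        ell = ((yy - 20) / 12.0) ** 2 + ((xx - 30) / 25.0) ** 2 <= 1
        crop[ell] = 220 if bright_on_dark else 60
        return crop, ell

    @pytest.mark.parametrize("bright_on_dark", [True, False])
    def test_recovers_ellipse_mask_either_polarity(self, bright_on_dark):
        crop, truth = self._ellipse_crop(bright_on_dark)
        mask = segment_grain(crop)
        dice = 2 * (mask & truth).sum() / (mask.sum() + truth.sum())
        assert dice >= 0.95

    def test_uniform_crop_has_no_grain_body(self):
        with pytest.raises(NoGrainBodyError):
            segment_grain(np.full((20, 20, 3), 128, np.uint8))

    def test_small_speck_removed_by_particle_filtering(self):
        crop, truth = self._ellipse_crop()
        crop[2:4, 2:4] = 220  # 4-px speck far from the ellipse
        mask = segment_grain(crop)
        assert not mask[2:4, 2:4].any()
        assert (mask & truth).sum() > 0


class TestMinBoundingRect:
    def test_axis_aligned_block_measures_exactly(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:9, 3:13] = True  # 10 wide x 4 tall
        length, width, angle = min_bounding_rect(mask)
        assert (length, width) == (10.0, 4.0)
        assert angle == 0.0

    def test_rotated_block_measures_with_rotated_angle(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[3:13, 5:9] = True  # 4 wide x 10 tall
        length, width, angle = min_bounding_rect(mask)
        assert (length, width) == (10.0, 4.0)
        assert angle == 90.0

    def test_single_pixel_is_a_unit_square(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[2, 2] = True
        length, width, _ = min_bounding_rect(mask)
        assert (length, width) == (1.0, 1.0)

    def test_empty_mask_is_an_error(self):
        with pytest.raises(ValueError):
            min_bounding_rect(np.zeros((5, 5), dtype=bool))

    def test_never_beats_the_angle_sweep_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(12):
            mask = random_blob(rng, n_seed=int(rng.integers(10, 40)))
            length, width, _ = min_bounding_rect(mask)
            assert length * width <= min_rect_angle_sweep(mask, 0.5) + 1e-6
            assert length >= width > 0

    def test_rotation_consistency_of_dimensions(self):
        def oriented_ellipse(deg):
            yy, xx = np.mgrid[:180, :180]
            th = np.radians(deg)
            u = (xx - 90) * np.cos(th) + (yy - 90) * np.sin(th)
            v = -(xx - 90) * np.sin(th) + (yy - 90) * np.cos(th)
            return (u / 40.0) ** 2 + (v / 20.0) ** 2 <= 1

        l0, w0, _ = min_bounding_rect(oriented_ellipse(0))
        for deg in (15, 30, 45, 75):
            l1, w1, _ = min_bounding_rect(oriented_ellipse(deg))
            assert l1 == pytest.approx(l0, rel=0.03)
            assert w1 == pytest.approx(w0, rel=0.03)


class TestMeasureGrains:
    def test_scene_recovery_of_true_grain_size(self, default_scene):
        from panicletraits.detection import baseline_detect

        img, truth = default_scene
        det = baseline_detect(img)
        meas = measure_grains(img, det, ScreeningConfig(), PEL)
        stats = panicle_grain_stats(meas)
        true_len = np.mean([g.length_mm for g in truth.grains])
        true_wid = np.mean([g.width_mm for g in truth.grains])
        assert stats.mean_length_mm == pytest.approx(true_len, rel=0.03)
        assert stats.mean_width_mm == pytest.approx(true_wid, rel=0.05)
        assert all(m.length_mm >= m.width_mm > 0 for m in meas)
        assert all(m.aspect_ratio >= 1 for m in meas)

    def test_scale_invariance_of_mm_results(self):
        """Doubling image resolution (calibrator included) leaves the mm
        measurements within 2%, because pel density compensates."""
        from panicletraits.calibration import compute_pel_density, detect_calibrator
        from panicletraits.detection import baseline_detect
        from panicletraits.synthetic import SceneSpec, generate_scene

        spec = SceneSpec(image_id="scale", n_grains=10, seed=29)
        means = []
        for s in (spec, spec.scaled(2.0)):
            img, _ = generate_scene(s)
            pel = compute_pel_density(detect_calibrator(img).pixel_radius)
            stats = panicle_grain_stats(
                measure_grains(img, baseline_detect(img), ScreeningConfig(), pel))
            means.append((stats.mean_length_mm, stats.mean_width_mm))
        assert means[1][0] == pytest.approx(means[0][0], rel=0.02)
        assert means[1][1] == pytest.approx(means[0][1], rel=0.02)

    def test_no_detections_means_no_measurable_grains(self, default_scene):
        img, _ = default_scene
        empty = DetectionSet("img", img.shape[:2], [])
        with pytest.raises(NoMeasurableGrainsError):
            measure_grains(img, empty, ScreeningConfig(), PEL)

    def test_missing_pel_density_is_an_error(self, default_scene):
        img, _ = default_scene
        d = DetectionSet("img", img.shape[:2], [BBox(0, 0, 5, 5, 0.9)])
        with pytest.raises(ValueError):
            measure_grains(img, d, ScreeningConfig(), None)


class TestPanicleGrainStats:
    def _gm(self, length, width):
        return GrainMeasurement(
            length_mm=length, width_mm=width, aspect_ratio=length / width,
            length_px=length / 0.1, width_px=width / 0.1, angle=0.0,
        )

    def test_single_grain_stats_equal_that_grain(self):
        stats = panicle_grain_stats([self._gm(9.0, 3.0)])
        assert stats.n_measured == 1
        assert stats.mean_length_mm == 9.0
        assert stats.mean_aspect == 3.0

    def test_means_are_arithmetic(self):
        stats = panicle_grain_stats([self._gm(8, 4), self._gm(10, 4)])
        assert stats.mean_length_mm == pytest.approx(9.0)

    def test_aspect_is_mean_of_ratios_not_ratio_of_means(self):
        stats = panicle_grain_stats([self._gm(8, 3), self._gm(10, 2)])
        # mean of {8/3, 10/2} = 3.8333..., ratio of means would be 9/2.5 = 3.6
        assert stats.mean_aspect == pytest.approx((8 / 3 + 5) / 2)
        assert stats.mean_aspect != pytest.approx(
            stats.mean_length_mm / stats.mean_width_mm)

    def test_empty_list_is_an_error(self):
        with pytest.raises(ValueError):
            panicle_grain_stats([])
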