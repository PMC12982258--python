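"""Unit tests for reference-ROI threshold segmentation."""

import numpy as np
import pytest

from nmoh.segmentation import (
    RoiSet,
    ThresholdConfig,
    VolumetricImage,
    average_measurements,
    reference_statistics,
    segment_subject,
    segment_target,
)


def _rois(shape, lc=None, snc=None):
    ref_l = np.zeros(shape, bool)
    ref_r = np.zeros(shape, bool)
    ref_l[0, :, :] = True
    ref_r[1, :, :] = True
    lc_m = np.zeros(shape) if lc is None else lc
    snc_m = np.zeros(shape) if snc is None else snc
    return RoiSet(ref_l, ref_r, lc_m, snc_m)


class TestAveraging:
    def test_single_measurement_is_identity(self):
        grid = np.arange(24.0).reshape(2, 3, 4)
        out = average_measurements(VolumetricImage(grid))
        np.testing.assert_array_equal(out.grid, grid)

    def test_two_constant_grids_average_to_midpoint(self):
        stack = np.stack([np.full((2, 3, 4), 10.0), np.full((2, 3, 4), 20.0)])
        out = average_measurements(VolumetricImage(stack))
        assert np.all(out.grid == 15.0)

    def test_noise_sd_shrinks_by_sqrt_n(self, rng):
        # standard-error law: averaging N i.i.d. noise grids divides SD by sqrt(N)
        sigma, n_meas = 7.0, 4
        stack = rng.normal(0.0, sigma, size=(n_meas, 50, 50, 40))
        out = average_measurements(VolumetricImage(stack))
        observed = out.grid.std()
        assert observed == pytest.approx(sigma / np.sqrt(n_meas), rel=0.05)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            VolumetricImage(np.zeros((2, 3)))


class TestReferenceStatistics:
    def test_constant_reference(self):
        grid = np.full((4, 4, 2), 100.0)
        mean, sd, n = reference_statistics(VolumetricImage(grid), _rois((4, 4, 2)))
        assert mean == 100.0 and sd == 0.0 and n == 16

    def test_hand_computed_sample_sd(self):
        # pooled reference values {90, 90, 110, 110}: mean 100, sd = sqrt(400/3)
        grid = np.zeros((2, 2, 1))
        grid[0, 0, 0], grid[0, 1, 0] = 90.0, 90.0
        grid[1, 0, 0], grid[1, 1, 0] = 110.0, 110.0
        rois = _rois((2, 2, 1))
        mean, sd, n = reference_statistics(VolumetricImage(grid), rois)
        assert mean == pytest.approx(100.0)
        assert sd == pytest.approx(np.sqrt(400.0 / 3.0))
        assert n == 4

    def test_population_estimator_option(self):
        grid = np.zeros((2, 2, 1))
        grid[0], grid[1] = 90.0, 110.0
        _, sd, _ = reference_statistics(
            VolumetricImage(grid), _rois((2, 2, 1)), sd_estimator="population"
        )
        assert sd == pytest.approx(10.0)

    def test_pooling_is_split_invariant(self, rng):
        # identical pooled value sets give identical statistics however the
        # voxels are distributed over the left/right masks
        shape = (2, 5, 4)
        grid = rng.normal(100, 10, size=shape)
        a = reference_statistics(VolumetricImage(grid), _rois(shape))
        ref_l = np.zeros(shape, bool)
        ref_r = np.zeros(shape, bool)
        ref_l[0, :3], ref_l[1, :2] = True, True  # ragged split, same union
        ref_r[0, 3:], ref_r[1, 2:] = True, True
        b = reference_statistics(
            VolumetricImage(grid), RoiSet(ref_l, ref_r, np.zeros(shape), np.zeros(shape))
        )
        assert a[0] == pytest.approx(b[0]) and a[1] == pytest.approx(b[1])


class TestSegmentTarget:
    def _image_and_rois(self):
        shape = (4, 4, 2)
        grid = np.full(shape, 100.0)
        # reference voxels: half 90, half 110 -> mean 100, choose population sd 10
        grid[0] = 90.0
        grid[1] = 110.0
        lc = np.zeros(shape)
        snc = np.zeros(shape)
        lc[2, 0, 0] = 1.0
        snc[2, 1, 0] = 1.0
        grid[2, 0, 0] = 127.0  # between the SNc and LC thresholds
        grid[2, 1, 0] = 127.0
        return VolumetricImage(grid), _rois(shape, lc, snc)

    def test_thresholds_and_rule_boundaries(self):
        image, rois = self._image_and_rois()
        cfg = ThresholdConfig(sd_estimator="population")
        lc = segment_target(image, rois, cfg, "LC")
        snc = segment_target(image, rois, cfg, "SNc")
        assert lc.threshold_intensity == pytest.approx(128.8)
        assert snc.threshold_intensity == pytest.approx(125.7)
        # a 127-intensity voxel counts for SNc (k=2.57) but not LC (k=2.88)
        assert snc.voxel_count == 1
        assert lc.voxel_count == 0

    def test_volume_arithmetic(self):
        shape = (4, 8, 2)
        grid = np.full(shape, 100.0)
        grid[0] = 90.0
        grid[1] = 110.0
        lc = np.zeros(shape)
        lc[2, :7, 0] = 1.0
        grid[2, :7, 0] = 200.0
        res = segment_target(
            VolumetricImage(grid), _rois(shape, lc=lc), ThresholdConfig(), "LC"
        )
        assert res.voxel_count == 7
        assert res.volume_mm3 == pytest.approx(7 * 0.4563, abs=1e-12)
        assert res.volume_mm3 == res.voxel_count * np.prod((0.39, 0.39, 3.0))

    def test_zero_reference_sd_counts_strictly_above_mean(self):
        shape = (4, 4, 1)
        grid = np.full(shape, 100.0)
        lc = np.zeros(shape)
        lc[2, :, 0] = 1.0
        grid[2, 0, 0] = 100.0  # tie with the mean: excluded (strict inequality)
        grid[2, 1, 0] = 100.0001
        res = segment_target(VolumetricImage(grid), _rois(shape, lc=lc), ThresholdConfig(), "LC")
        assert res.reference_sd == 0.0
        assert res.voxel_count == 1

    def test_suprathreshold_is_subset_of_mask(self, rng):
        shape = (6, 6, 3)
        grid = rng.normal(100, 10, size=shape)
        lc = (rng.random(shape) > 0.5).astype(float)
        lc[0] = lc[1] = 0.0
        lc[2, 0, 0] = 1.0
        res = segment_target(VolumetricImage(grid), _rois(shape, lc=lc), ThresholdConfig(k_lc=0.1), "LC")
        assert not np.any(res.suprathreshold_mask & ~(lc >= 0.5))

    def test_monotone_in_k_and_binarize_p(self, rng):
        shape = (6, 6, 3)
        grid = rng.normal(100, 10, size=shape)
        lc = rng.random(shape)
        lc[0] = lc[1] = 0.0
        lc[3, 3, 1] = 1.0
        img = VolumetricImage(grid)
        rois = _rois(shape, lc=lc)
        counts_k = [
            segment_target(img, rois, ThresholdConfig(k_lc=k, mask_binarize_p=0.2), "LC").voxel_count
            for k in (0.5, 1.0, 2.0, 2.88, 5.76)
        ]
        assert counts_k == sorted(counts_k, reverse=True)
        counts_p = [
            segment_target(img, rois, ThresholdConfig(k_lc=0.5, mask_binarize_p=p), "LC").voxel_count
            for p in (0.1, 0.4, 0.7, 1.0)
        ]
        assert counts_p == sorted(counts_p, reverse=True)

    @pytest.mark.parametrize("a,b", [(2.0, 50.0), (0.5, -30.0), (10.0, 0.0)])
    def test_affine_intensity_equivariance(self, rng, a, b):
        # a*I + b (a > 0) leaves the segmented voxel set unchanged
        shape = (6, 6, 3)
        grid = rng.normal(100, 10, size=shape)
        lc = np.zeros(shape)
        lc[2:, :, :] = 1.0
        rois = _rois(shape, lc=lc)
        cfg = ThresholdConfig(k_lc=1.0)
        base = segment_target(VolumetricImage(grid), rois, cfg, "LC")
        trans = segment_target(VolumetricImage(a * grid + b), rois, cfg, "LC")
        np.testing.assert_array_equal(base.suprathreshold_mask, trans.suprathreshold_mask)

    def test_empty_mask_rejected_with_target_name(self):
        shape = (4, 4, 1)
        grid = np.full(shape, 100.0)
        grid[0] = 90.0
        grid[1] = 110.0
        with pytest.raises(ValueError, match="LC"):
            segment_target(VolumetricImage(grid), _rois(shape), ThresholdConfig(), "LC")


class TestSegmentSubject:
    def test_composition_equals_manual_pipeline(self, rng):
        shape = (6, 6, 3)
        stack = rng.normal(100, 10, size=(3, *shape))
        lc = np.zeros(shape)
        snc = np.zeros(shape)
        lc[3, 3, 1] = 1.0
        snc[4, 4, 1] = 1.0
        stack[:, 3, 3, 1] += 80
        stack[:, 4, 4, 1] += 80
        rois = _rois(shape, lc, snc)
        img = VolumetricImage(stack)
        lc_res, snc_res = segment_subject(img, rois)
        avg = average_measurements(img)
        assert lc_res.voxel_count == segment_target(avg, rois, ThresholdConfig(), "LC").voxel_count
        assert snc_res.voxel_count == segment_target(avg, rois, ThresholdConfig(), "SNc").voxel_count
        assert lc_res.voxel_count == 1 and snc_res.voxel_count == 1

    def test_doubling_k_never_increases_count(self, rng):
        shape = (6, 6, 3)
        grid = rng.normal(100, 10, size=shape)
        lc = np.ones(shape)
        lc[:2] = 0.0
        rois = _rois(shape, lc=lc, snc=lc.copy())
        img = VolumetricImage(grid)
        for k in (0.25, 0.7, 1.3, 2.88):
            c1 = segment_target(img, rois, ThresholdConfig(k_lc=k), "LC").voxel_count
            c2 = segment_target(img, rois, ThresholdConfig(k_lc=2 * k), "LC").voxel_count
            assert c2 <= c1
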