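"""Tests of the 3-way binarization and skeletonization operators,
including bit-exact agreement with naive brute-force oracles."""

import numpy as np
import pytest
from skimage.filters import frangi
from skimage.measure import label

from octaperf.segmentation import (
    SegmentationParams,
    adaptive_median_mask,
    binarize_angiogram,
    combine_masks,
    global_noise_threshold,
    hessian_vessel_mask,
    propose_faz_circles,
    sample_noise_baseline,
    skeletonize,
    top_hat_filter,
)


def brute_force_circle_union(shape, centers, radius):
    mask = np.zeros(shape, dtype=bool)
    for r in range(shape[0]):
        for c in range(shape[1]):
            for cr, cc in centers:
                if (r - cr) ** 2 + (c - cc) ** 2 <= radius**2:
                    mask[r, c] = True
    return mask


class TestNoiseBaseline:
    def test_constant_image(self):
        img = np.full((128, 128), 12, dtype=np.uint8)
        bl = sample_noise_baseline(img, [(64, 64)], radius_px=50)
        assert bl.mean == 12.0 and bl.sd == 0.0

    def test_circle_pixel_count_matches_exhaustive_scan(self):
        img = np.zeros((128, 128), dtype=np.uint8)
        img[brute_force_circle_union(img.shape, [(64, 64)], 50)] = 1
        bl = sample_noise_baseline(img, [(64, 64)], radius_px=50)
        # mean 1 over exactly the in-circle pixels proves identical support
        assert bl.mean == 1.0 and bl.sd == 0.0

    def test_three_disjoint_circles_union_mean(self, rng):
        img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        centers = [(12, 12), (12, 50), (50, 30)]
        union = brute_force_circle_union(img.shape, centers, 8)
        bl = sample_noise_baseline(img, centers, radius_px=8)
        assert bl.mean == pytest.approx(img[union].mean(), abs=1e-12)
        assert bl.sd == pytest.approx(img[union].std(), abs=1e-12)

    def test_out_of_bounds_circle_rejected(self):
        img = np.zeros((64, 64), dtype=np.uint8)
        with pytest.raises(ValueError):
            sample_noise_baseline(img, [(5, 5)], radius_px=10)


class TestTopHat:
    def test_constant_image_gives_zeros(self):
        img = np.full((64, 64), 77, dtype=np.uint8)
        assert np.all(top_hat_filter(img, 12) == 0)

    def test_thin_line_preserved(self):
        img = np.full((64, 64), 10, dtype=np.uint8)
        img[30:33, :] = 200
        out = top_hat_filter(img, 12)
        assert abs(int(out[31, 32]) - 190) <= 1  # line minus background

    @pytest.mark.parametrize("seed", [0, 1])
    def test_bounded_between_zero_and_input(self, seed):
        img = np.random.default_rng(seed).integers(0, 256, (64, 64)).astype(np.uint8)
        out = top_hat_filter(img, 8)
        assert np.all(out >= 0) and np.all(out <= img)


class TestGlobalThreshold:
    def test_all_below_threshold_zeroed(self):
        from octaperf.segmentation import NoiseBaseline

        img = np.full((32, 32), 40, dtype=np.uint8)
        bl = NoiseBaseline(mean=50.0, sd=10.0, centers_px=[(16, 16)], radius_px=5)
        assert np.all(global_noise_threshold(img, bl, k=2.0) == 0)

    def test_zero_sd_thresholds_exactly_at_mean(self):
        from octaperf.segmentation import NoiseBaseline

        img = np.arange(64, dtype=np.uint8).reshape(8, 8)
        bl = NoiseBaseline(mean=31.0, sd=0.0, centers_px=[(4, 4)], radius_px=2)
        out = global_noise_threshold(img, bl, k=2.0)
        assert np.array_equal(out == 0, img <= 31)

    def test_faz_pixels_suppressed_on_synthetic_angiogram(self, sample_angiogram, default_config):
        """The avascular zone carries only background noise; the k=2
        global threshold must suppress at least 95% of its pixels."""
        px = sample_angiogram.pixels
        c = (default_config.image_px - 1) // 2
        radius = int(default_config.faz_radius_mm / default_config.mm_per_px) - 2
        bl = sample_noise_baseline(px, [(c, c)], radius_px=radius)
        out = global_noise_threshold(px, bl, k=2.0)
        rows, cols = np.ogrid[: px.shape[0], : px.shape[1]]
        faz = (rows - c) ** 2 + (cols - c) ** 2 <= radius**2
        assert np.mean(out[faz] == 0) >= 0.95


class TestHessianMask:
    def test_constant_image_empty(self):
        img = np.full((64, 64), 90, dtype=np.uint8)
        assert not hessian_vessel_mask(img).any()

    def test_line_recall(self):
        img = np.zeros((128, 128))
        img[60:62, 10:118] = 180.0
        mask = hessian_vessel_mask(img)
        truth = img > 0
        assert (mask & truth).sum() / truth.sum() >= 0.9

    def test_blob_less_vessel_like_than_line(self):
        """Tubularity: an isolated bright pixel scores lower vesselness
        than a line of the same intensity (checked on the raw multiscale
        response)."""
        line = np.zeros((64, 64))
        line[32, 8:56] = 100.0
        blob = np.zeros((64, 64))
        blob[32, 32] = 100.0
        v_line = frangi(line, sigmas=(1, 2, 3), black_ridges=False)[32, 30]
        v_blob = frangi(blob, sigmas=(1, 2, 3), black_ridges=False)[32, 32]
        assert v_blob < v_line


class TestAdaptiveMedian:
    def test_constant_image_empty_with_positive_offset(self):
        img = np.full((64, 64), 50, dtype=np.uint8)
        assert not adaptive_median_mask(img, 31, offset=2.0).any()

    def test_sparse_stripes_exactly_bright_pixels_foreground(self):
        """With a minority of bright columns at period far below the
        window, every local median equals the dark level, so exactly the
        bright pixels are foreground."""
        img = np.zeros((64, 64), dtype=np.uint8)
        img[:, ::4] = 200
        mask = adaptive_median_mask(img, 31, offset=2.0)
        assert np.array_equal(mask, img == 200)

    def test_matches_naive_sliding_window_oracle_bitwise(self, rng):
        """Exact agreement with an O(N w^2) per-pixel median comparison
        (symmetric boundary padding) on a 64x64 instance."""
        img = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        w, off = 31, 2.0
        mask = adaptive_median_mask(img, w, off)
        pad = w // 2
        p = np.pad(img, pad, mode="symmetric")
        oracle = np.zeros_like(mask)
        for r in range(64):
            for c in range(64):
                oracle[r, c] = img[r, c] > np.median(p[r : r + w, c : c + w]) + off
        assert np.array_equal(mask, oracle)

    def test_window_validation(self):
        img = np.zeros((16, 16), dtype=np.uint8)
        with pytest.raises(ValueError):
            adaptive_median_mask(img, 4)
        with pytest.raises(ValueError):
            adaptive_median_mask(img, 31)


class TestCombineMasks:
    def test_identical_masks_unchanged(self, rng):
        m = rng.random((32, 32)) > 0.5
        assert np.array_equal(combine_masks(m, m).mask, m)

    def test_disjoint_masks_empty(self):
        a = np.zeros((16, 16), bool)
        b = np.zeros((16, 16), bool)
        a[:8], b[8:] = True, True
        assert not combine_masks(a, b).mask.any()

    def test_popcount_matches_brute_force(self, rng):
        a = rng.random((64, 64)) > 0.4
        b = rng.random((64, 64)) > 0.6
        out = combine_masks(a, b)
        count = sum(
            1 for r in range(64) for c in range(64) if a[r, c] and b[r, c]
        )
        assert out.mask.sum() == count
        # AND-dominance: the combined map is a subset of each branch
        assert not (out.mask & ~a).any() and not (out.mask & ~b).any()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            combine_masks(np.zeros((4, 4), bool), np.zeros((5, 5), bool))


class TestSkeletonize:
    def test_wide_bar_reduces_to_centerline(self):
        bar = np.zeros((20, 120), bool)
        bar[8:13, 10:110] = True
        skel = skeletonize(bar).mask
        assert abs(int(skel.sum()) - 100) <= 4

    def test_single_pixel_preserved(self):
        m = np.zeros((8, 8), bool)
        m[4, 4] = True
        assert np.array_equal(skeletonize(m).mask, m)

    def test_empty_map_empty_skeleton(self):
        assert not skeletonize(np.zeros((8, 8), bool)).mask.any()

    def test_containment_and_component_count(self, sample_angiogram, default_config):
        from octaperf.pipeline import synthetic_noise_circles

        centers, radius = synthetic_noise_circles(default_config)
        params = SegmentationParams(faz_circles=centers, circle_radius_px=radius)
        vm, _ = binarize_angiogram(sample_angiogram, params)
        skel = skeletonize(vm).mask
        assert not (skel & ~vm.mask).any()  # skeleton subset of map
        n_map = label(vm.mask, connectivity=2).max()
        n_skel = label(skel, connectivity=2).max()
        assert n_skel == n_map


class TestFullBinarization:
    def test_noise_floor_below_two_percent(self):
        """On a pure-noise image (no vessels) the final AND map stays
        below 2% density at default parameters."""
        noise = np.clip(
            np.random.default_rng(1).normal(30, 8, (304, 304)), 0, 255
        ).astype(np.uint8)
        params = SegmentationParams(
            faz_circles=[(151, 151), (148, 154), (154, 148)], circle_radius_px=11
        )
        vm, _ = binarize_angiogram(noise, params)
        assert vm.mask.mean() < 0.02

    def test_proposed_circles_land_in_dark_center(self, sample_angiogram, default_config):
        radius = 8
        centers = propose_faz_circles(sample_angiogram, radius, 3)
        assert len(centers) == 3
        n = default_config.image_px
        for r, c in centers:
            assert radius <= r < n - radius and radius <= c < n - radius
            # within the central search region around the avascular zone
            assert abs(r - n / 2) < n * 0.25 and abs(c - n / 2) < n * 0.25
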