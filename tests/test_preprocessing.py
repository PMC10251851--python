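"""Foreground segmentation, tiling, and blank-patch filtering.

The Otsu implementation is held to exact agreement with an exhaustive
per-threshold scan; tiling to exact grid arithmetic and an independent
pixel-counting oracle for the 50%-foreground emission rule."""

import numpy as np
import pytest

from slideattn.preprocessing import (DegenerateHistogramError, ForegroundMask,
                                     SlideImage,
                                     is_background, iter_patches,
                                     otsu_threshold,
                                     otsu_threshold_from_histogram,
                                     read_patch, segment_foreground,
                                     tile_slide)


def brute_force_otsu(counts, centers):
    """Independent exhaustive scan of the between-class variance.

    Returns the first threshold attaining the maximum within a relative
    tolerance (exact ties arise whenever a cut moves across empty bins)."""
    counts = np.asarray(counts, float)
    total = counts.sum()
    sigmas = []
    for i, t in enumerate(centers):
        n0 = counts[:i + 1].sum()
        n1 = total - n0
        if n0 == 0 or n1 == 0:
            sigmas.append(-np.inf)
            continue
        w0, w1 = n0 / total, n1 / total
        mu0 = (counts[:i + 1] * centers[:i + 1]).sum() / n0
        mu1 = (counts[i + 1:] * centers[i + 1:]).sum() / n1
        sigmas.append(w0 * w1 * (mu0 - mu1) ** 2)
    sigmas = np.asarray(sigmas)
    peak = sigmas.max()
    for i, s in enumerate(sigmas):
        if s >= peak - 1e-10 * abs(peak):
            return centers[i]


class TestOtsu:
    def test_two_spike_histogram(self):
        counts = np.zeros(256)
        centers = np.linspace(0, 1, 256)
        i_lo = np.argmin(np.abs(centers - 0.1))
        i_hi = np.argmin(np.abs(centers - 0.9))
        counts[i_lo], counts[i_hi] = 40, 60
        thr = otsu_threshold_from_histogram(counts, centers)
        assert 0.1 <= thr < 0.9
        values = np.array([0.1] * 40 + [0.9] * 60)
        assert ((values > thr) == (values == 0.9)).all()

    def test_degenerate_histogram_raises(self):
        with pytest.raises(DegenerateHistogramError):
            otsu_threshold(np.full(100, 0.7))

    def test_matches_exhaustive_scan_on_random_histograms(self, rng):
        centers = np.linspace(0, 1, 256)
        for _ in range(25):
            counts = rng.integers(0, 50, size=256).astype(float)
            if np.count_nonzero(counts) < 2:
                continue
            assert otsu_threshold_from_histogram(counts, centers) == \
                brute_force_otsu(counts, centers)

    def test_matches_scan_on_random_channel(self, rng):
        values = rng.random((64, 64))
        counts, edges = np.histogram(values, bins=256)
        centers = (edges[:-1] + edges[1:]) / 2
        assert otsu_threshold(values) == brute_force_otsu(counts, centers)

    def test_all_white_slide_degenerate(self):
        slide = SlideImage(image=np.full((256, 256, 3), 255, np.uint8), mpp=0.5)
        with pytest.raises(DegenerateHistogramError):
            segment_foreground(slide, downsample=8)


def full_mask(shape, downsample=32):
    return ForegroundMask(mask=np.ones((shape[0] // downsample,
                                        shape[1] // downsample), bool),
                          downsample=downsample, otsu_threshold=0.5)


class TestTiling:
    def test_exact_grid_on_fully_foreground_slide(self):
        slide = SlideImage(image=np.zeros((896, 896, 3), np.uint8), mpp=0.5)
        grid = tile_slide(slide, full_mask((896, 896)))
        assert len(grid) == 4
        assert sorted(map(tuple, grid.coords.tolist())) == \
            [(0, 0), (0, 448), (448, 0), (448, 448)]

    def test_partial_edge_patches_dropped(self):
        slide = SlideImage(image=np.zeros((1000, 1000, 3), np.uint8), mpp=0.5)
        grid = tile_slide(slide, full_mask((1000, 1000), 8))
        assert len(grid) == 4

    def test_emission_matches_pixel_counting_oracle(self, rng):
        ds = 32
        h = w = 1792
        mask_small = rng.random((h // ds, w // ds)) < 0.4
        mask = ForegroundMask(mask=mask_small, downsample=ds, otsu_threshold=0.3)
        slide = SlideImage(image=np.zeros((h, w, 3), np.uint8), mpp=0.5)
        grid = tile_slide(slide, mask)
        expected = []
        for y in range(0, h - 448 + 1, 448):
            for x in range(0, w - 448 + 1, 448):
                block = mask_small[y // ds:(y + 448) // ds,
                                   x // ds:(x + 448) // ds]
                frac = sum(bool(v) for row in block for v in row) / block.size
                if frac >= 0.5:
                    expected.append((x, y))
        assert sorted(map(tuple, grid.coords.tolist())) == sorted(expected)

    def test_patches_disjoint_and_readable(self):
        slide = SlideImage(
            image=np.arange(896 * 896 * 3, dtype=np.uint32).reshape(
                896, 896, 3).astype(np.uint8), mpp=0.5)
        grid = tile_slide(slide, full_mask((896, 896)))
        seen = set()
        for entry, patch in iter_patches(slide, grid):
            assert patch.shape == (448, 448, 3)
            key = (entry.x, entry.y)
            assert key not in seen
            seen.add(key)

    def test_resampling_footprint_and_upsample_guard(self):
        slide = SlideImage(image=np.zeros((896, 896, 3), np.uint8), mpp=0.25)
        grid = tile_slide(slide, full_mask((896, 896), 8), target_mpp=0.5)
        # 448 target pixels at 0.5 mpp cover 896 base pixels at 0.25 mpp
        assert (grid.entries["w"] == 896).all() and len(grid) == 1
        patch = read_patch(slide, 0, 0, 896, 896)
        assert patch.shape == (448, 448, 3)
        coarse = SlideImage(image=np.zeros((896, 896, 3), np.uint8), mpp=5.0)
        with pytest.raises(ValueError):
            tile_slide(coarse, full_mask((896, 896), 8), target_mpp=0.5)


class TestBackgroundFilter:
    def test_all_white_patch_excluded(self):
        assert is_background(np.full((448, 448, 3), 255, np.uint8)) is True

    def test_saturated_tissue_patch_kept(self, rng):
        patch = np.zeros((448, 448, 3), np.uint8)
        patch[...] = (150, 40, 160)
        assert is_background(patch) is False

    def test_exactly_eighty_percent_background_is_kept(self):
        # "exceeding 80%" is strict: exactly 80% stays in
        patch = np.zeros((10, 10, 3), np.uint8)
        patch[...] = (150, 40, 160)
        flat = patch.reshape(-1, 3)
        flat[:80] = 255
        patch = flat.reshape(10, 10, 3)
        assert is_background(patch) is False
        flat[80] = 255  # one more pixel tips it over
        assert is_background(flat.reshape(10, 10, 3)) is True

    def test_shape_validation(self):
        with pytest.raises(ValueError):
            is_background(np.zeros((448, 448), np.uint8))
        with pytest.raises(ValueError):
            is_background(np.zeros((4, 4, 3), np.float64))
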