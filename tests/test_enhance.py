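"""CLAHE: histogram clipping, regional transforms, bilinear blending."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vertascan.enhance import (
    ClaheParams,
    apply_clahe,
    build_region_transforms,
    clahe,
    clip_histogram,
)


def brute_force_blend(img, grid):
    """Independent per-pixel evaluation of the four-center bilinear blend."""
    maxv = grid.max_value
    n_bins = grid.transforms.shape[2]
    out = np.empty(img.shape, dtype=float)
    cy, cx = grid.centers_y, grid.centers_x
    for row in range(img.shape[0]):
        for col in range(img.shape[1]):
            r = int(img[row, col]) * n_bins // (maxv + 1)
            i = int(np.searchsorted(cy, row, side="right")) - 1
            j = int(np.searchsorted(cx, col, side="right")) - 1
            i0 = min(max(i, 0), len(cy) - 1)
            j0 = min(max(j, 0), len(cx) - 1)
            i1 = min(i0 + 1, len(cy) - 1)
            j1 = min(j0 + 1, len(cx) - 1)
            y = 0.0 if i1 == i0 or row <= cy[i0] else min((row - cy[i0]) / (cy[i1] - cy[i0]), 1.0)
            x = 0.0 if j1 == j0 or col <= cx[j0] else min((col - cx[j0]) / (cx[j1] - cx[j0]), 1.0)
            t_a = grid.transforms[i0, j0, r]
            t_b = grid.transforms[i0, j1, r]
            t_c = grid.transforms[i1, j0, r]
            t_d = grid.transforms[i1, j1, r]
            s = (1 - y) * ((1 - x) * t_a + x * t_b) + y * ((1 - x) * t_c + x * t_d)
            out[row, col] = min(max(round(s), 0), maxv)
    return out.astype(img.dtype)


class TestClipHistogram:
    def test_no_bin_over_limit_passes_through(self):
        assert np.array_equal(clip_histogram([2, 2, 2], 5), [2, 2, 2])

    def test_excess_redistributed_uniformly(self):
        out = clip_histogram([10, 0, 0, 0], 3)
        assert out.sum() == pytest.approx(10)
        # first pass caps at 3 and spreads 7/4 per bin; the residue pass
        # re-caps bin 0 and spreads the rest
        assert np.all(out[1:] == out[1])
        assert out[0] <= 3 + out[1]

    def test_count_conservation_and_bound_vs_bruteforce(self):
        rng = np.random.default_rng(0)
        hist = rng.integers(0, 400, size=256).astype(float)
        limit = 120.0
        out = clip_histogram(hist, limit)
        assert out.sum() == pytest.approx(hist.sum())
        excess = np.maximum(hist - limit, 0).sum()
        assert out.max() <= limit + np.ceil(excess / 256)
        # brute-force iterative redistribution reaches the same invariants
        bf = hist.copy()
        for _ in range(100):
            over = np.maximum(bf - limit, 0)
            if over.sum() < 1e-9:
                break
            bf = np.minimum(bf, limit) + over.sum() / bf.size
        assert bf.sum() == pytest.approx(hist.sum())
        assert abs(out.max() - bf.max()) <= excess / 256 + 1e-6

    def test_empty_histogram_rejected(self):
        with pytest.raises(ValueError):
            clip_histogram(np.array([]), 3)

    @given(
        st.lists(st.integers(min_value=0, max_value=500), min_size=2, max_size=64),
        st.floats(min_value=1.0, max_value=400.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_conservation_property(self, hist, limit):
        out = clip_histogram(np.array(hist, dtype=float), limit)
        assert out.sum() == pytest.approx(float(sum(hist)))
        assert np.all(out >= 0)


class TestRegionTransforms:
    def test_constant_image_gives_identical_regional_transforms(self):
        img = np.full((32, 32), 77, dtype=np.uint8)
        grid = build_region_transforms(img, ClaheParams(tiles_x=2, tiles_y=2))
        assert np.allclose(grid.transforms, grid.transforms[0, 0])
        # the occupied level maps to one fixed output level in every region
        out = apply_clahe(img, grid)
        assert len(np.unique(out)) == 1

    def test_regional_locality(self):
        img = np.zeros((16, 16), dtype=np.uint8)
        img[:, 8:] = 255
        grid = build_region_transforms(img, ClaheParams(tiles_x=2, tiles_y=1))
        assert not np.allclose(grid.transforms[0, 0], grid.transforms[0, 1])

    def test_transforms_match_clipped_cdf_oracle(self):
        rng = np.random.default_rng(1)
        img = rng.integers(0, 256, size=(64, 64), dtype=np.uint8)
        p = ClaheParams(tiles_x=2, tiles_y=2, clip_limit=2.0)
        grid = build_region_transforms(img, p)
        for i, sy in enumerate((slice(0, 32), slice(32, 64))):
            for j, sx in enumerate((slice(0, 32), slice(32, 64))):
                region = img[sy, sx]
                hist = np.bincount(region.ravel(), minlength=256).astype(float)
                limit = max(1.0, 2.0 * region.size / 256)
                clipped = np.minimum(hist, limit)
                excess = hist.sum() - clipped.sum()
                clipped += excess / 256
                over = clipped - limit
                res = over[over > 0].sum()
                if res > 0:
                    clipped = np.minimum(clipped, limit) + res / 256
                cdf = np.cumsum(clipped)
                assert np.allclose(grid.transforms[i, j], cdf / cdf[-1] * 255)

    def test_transforms_monotone(self):
        rng = np.random.default_rng(2)
        img = rng.integers(0, 256, size=(40, 40), dtype=np.uint8)
        grid = build_region_transforms(img, ClaheParams(tiles_x=4, tiles_y=4))
        assert np.all(np.diff(grid.transforms, axis=2) >= 0)

    def test_tiles_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            build_region_transforms(np.zeros((4, 4), dtype=np.uint8), ClaheParams(tiles_x=8, tiles_y=8))

    def test_huge_clip_limit_reduces_to_plain_equalization(self):
        rng = np.random.default_rng(3)
        img = rng.integers(0, 256, size=(32, 32), dtype=np.uint8)
        p = ClaheParams(tiles_x=1, tiles_y=1, clip_limit=1e9)
        grid = build_region_transforms(img, p)
        hist = np.bincount(img.ravel(), minlength=256).astype(float)
        cdf = np.cumsum(hist)
        assert np.allclose(grid.transforms[0, 0], cdf / cdf[-1] * 255)


class TestApplyClahe:
    def test_pixel_at_region_center_uses_single_transform(self):
        # 62x62 with 2x2 tiles puts region centers on integer pixels
        rng = np.random.default_rng(4)
        img = rng.integers(0, 256, size=(62, 62), dtype=np.uint8)
        grid = build_region_transforms(img, ClaheParams(tiles_x=2, tiles_y=2))
        out = apply_clahe(img, grid)
        for i, cy in enumerate(grid.centers_y.astype(int)):
            for j, cx in enumerate(grid.centers_x.astype(int)):
                r = img[cy, cx]
                assert out[cy, cx] == round(grid.transforms[i, j, r])

    def test_midpoint_pixel_averages_four_transforms(self):
        # hand-built grid with integer centers so the exact midpoint
        # (x = y = 1/2) falls on a pixel: the blend is the plain average
        from vertascan.enhance import RegionTransformGrid

        rng = np.random.default_rng(7)
        transforms = np.sort(rng.uniform(0, 255, size=(2, 2, 256)), axis=2)
        grid = RegionTransformGrid(
            transforms=transforms,
            centers_y=np.array([10.0, 20.0]),
            centers_x=np.array([10.0, 20.0]),
            shape=(31, 31),
            max_value=255,
        )
        img = np.full((31, 31), 123, dtype=np.uint8)
        out = apply_clahe(img, grid)
        assert out[15, 15] == round(transforms[:, :, 123].mean())
        # and at a center, the single regional transform applies
        assert out[10, 10] == round(transforms[0, 0, 123])

    def test_full_image_matches_bruteforce_blend(self):
        rng = np.random.default_rng(5)
        img = rng.integers(0, 256, size=(64, 64), dtype=np.uint8)
        grid = build_region_transforms(img, ClaheParams(tiles_x=2, tiles_y=2, clip_limit=2.5))
        assert np.array_equal(apply_clahe(img, grid), brute_force_blend(img, grid))

    def test_output_within_bit_depth(self):
        rng = np.random.default_rng(6)
        img = rng.integers(0, 65536, size=(32, 48), dtype=np.uint16)
        out = clahe(img, ClaheParams(tiles_x=4, tiles_y=3))
        assert out.dtype == np.uint16
        assert out.min() >= 0 and out.max() <= 65535

    def test_dimension_mismatch_rejected(self):
        img = np.zeros((32, 32), dtype=np.uint8)
        grid = build_region_transforms(img, ClaheParams(tiles_x=2, tiles_y=2))
        with pytest.raises(ValueError):
            apply_clahe(np.zeros((16, 16), dtype=np.uint8), grid)


@pytest.mark.parametrize(
    "kwargs",
    [dict(tiles_x=0), dict(clip_limit=0.0), dict(n_bins=1), dict(tiles_y=-1)],
)
def test_invalid_params_rejected(kwargs):
    with pytest.raises(ValueError):
        ClaheParams(**kwargs)
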