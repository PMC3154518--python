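"""Contrast-limited adaptive histogram equalization (CLAHE).

Cervical radiographs have very poor contrast; plain global histogram
equalization barely changes them.  CLAHE divides the image into a grid of
contextual regions, equalizes each region's histogram after clipping its
highest peaks (which limits noise amplification in homogeneous areas), and
removes the visible tile boundaries by bilinearly blending, at every pixel,
the mapping functions of the four surrounding region centers:

    s = (1-y)[(1-x) T_A(r) + x T_B(r)] + y[(1-x) T_C(r) + x T_D(r)]

where ``r`` is the input grey level, ``T_k`` the clipped-equalization
transform of region ``k`` and ``x, y`` the normalized horizontal/vertical
distances of the pixel from the upper-left center.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ClaheParams",
    "RegionTransformGrid",
    "clip_histogram",
    "build_region_transforms",
    "apply_clahe",
    "clahe",
]


@dataclass(frozen=True)
class ClaheParams:
    """Parameters of the contextual-region equalization.

    tiles_x, tiles_y
        number of contextual regions horizontally / vertically.
    clip_limit
        relative contrast factor > 0, expressed as a multiple of the
        uniform bin height (region pixel count / n_bins); converted to an
        absolute per-bin ceiling per region.
    n_bins
        histogram bin count (256 covers 8-bit input exactly).
    """

    tiles_x: int = 8
    tiles_y: int = 8
    clip_limit: float = 2.0
    n_bins: int = 256

    def __post_init__(self) -> None:
        if self.tiles_x < 1 or self.tiles_y < 1:
            raise ValueError("tile counts must be >= 1")
        if self.clip_limit <= 0:
            raise ValueError("clip_limit must be > 0")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


@dataclass(frozen=True)
class RegionTransformGrid:
    """Per-region monotone grey-level mappings and their center coordinates.

    transforms
        array of shape (tiles_y, tiles_x, n_bins); ``transforms[i, j, r]``
        is the output level for input bin ``r`` in region (i, j).
    centers_y, centers_x
        region-center pixel coordinates (row / column), each of length
        tiles_y / tiles_x.
    shape
        (rows, cols) of the image the grid was built from.
    max_value
        output range ceiling (255 for 8-bit input, 65535 for 16-bit).
    """

    transforms: np.ndarray
    centers_y: np.ndarray
    centers_x: np.ndarray
    shape: tuple[int, int]
    max_value: int


def _bit_depth_max(img: np.ndarray) -> int:
    if img.dtype == np.uint8:
        return 255
    if img.dtype == np.uint16:
        return 65535
    raise TypeError(f"expected uint8 or uint16 grayscale image, got {img.dtype}")


def clip_histogram(hist: np.ndarray, clip_limit_abs: float) -> np.ndarray:
    """Clip histogram peaks at ``clip_limit_abs`` and redistribute the excess.

    The count above the ceiling is pooled and spread uniformly over all
    bins.  Because the uniform share can push bins back over the ceiling, a
    single second pass caps those bins again and spreads the residue once
    more.  The total count is conserved exactly.
    """
    hist = np.asarray(hist, dtype=float)
    if hist.size == 0:
        raise ValueError("empty histogram: degenerate region")
    if np.any(hist < 0):
        raise ValueError("histogram counts must be non-negative")
    if clip_limit_abs < 1:
        raise ValueError("clip_limit_abs must be >= 1")

    clipped = np.minimum(hist, clip_limit_abs)
    excess = hist.sum() - clipped.sum()
    clipped = clipped + excess / hist.size
    # residue sweep: one more cap-and-spread round
    over = clipped - clip_limit_abs
    residue = over[over > 0].sum()
    if residue > 0:
        clipped = np.minimum(clipped, clip_limit_abs) + residue / hist.size
    return clipped


def _tile_slices(n: int, tiles: int) -> list[slice]:
    bounds = np.linspace(0, n, tiles + 1).round().astype(int)
    return [slice(bounds[i], bounds[i + 1]) for i in range(tiles)]


def build_region_transforms(img: np.ndarray, params: ClaheParams) -> RegionTransformGrid:
    """Build one clipped-equalization mapping per contextual region.

    Each region's histogram (n_bins over the full bit-depth range) is
    clipped and turned into a mapping through its cumulative distribution
    scaled to the full output range, which is monotone non-decreasing by
    construction.
    """
    img = np.asarray(img)
    maxv = _bit_depth_max(img)
    rows, cols = img.shape
    if rows < params.tiles_y or cols < params.tiles_x:
        raise ValueError("tiles larger than image")

    ys = _tile_slices(rows, params.tiles_y)
    xs = _tile_slices(cols, params.tiles_x)
    transforms = np.empty((params.tiles_y, params.tiles_x, params.n_bins))
    centers_y = np.array([(s.start + s.stop - 1) / 2.0 for s in ys])
    centers_x = np.array([(s.start + s.stop - 1) / 2.0 for s in xs])

    edges = np.linspace(0, maxv + 1, params.n_bins + 1)
    for i, sy in enumerate(ys):
        for j, sx in enumerate(xs):
            region = img[sy, sx]
            hist, _ = np.histogram(region, bins=edges)
            n_pix = region.size
            limit = max(1.0, params.clip_limit * n_pix / params.n_bins)
            clipped = clip_histogram(hist.astype(float), limit)
            cdf = np.cumsum(clipped)
            transforms[i, j] = cdf / cdf[-1] * maxv
    return RegionTransformGrid(transforms, centers_y, centers_x, (rows, cols), maxv)


def apply_clahe(img: np.ndarray, grid: RegionTransformGrid) -> np.ndarray:
    """Blend the four surrounding region transforms bilinearly at each pixel.

    Interior pixels use the full four-center blend; pixels in the border
    band outside the rectangle spanned by region centers degenerate to
    linear interpolation along the nearest edge pair and to the single
    nearest transform at the image corners (obtained here by clamping the
    neighbor indices, which makes the two coincident transforms collapse
    the blend).
    """
    img = np.asarray(img)
    if img.shape != grid.shape:
        raise ValueError("grid was built from an image of different dimensions")
    maxv = grid.max_value
    n_bins = grid.transforms.shape[2]
    rows, cols = img.shape

    # fractional tile-center coordinates of every pixel
    fy = np.interp(np.arange(rows), grid.centers_y, np.arange(grid.centers_y.size))
    fx = np.interp(np.arange(cols), grid.centers_x, np.arange(grid.centers_x.size))
    i0 = np.clip(np.floor(fy).astype(int), 0, grid.centers_y.size - 1)
    j0 = np.clip(np.floor(fx).astype(int), 0, grid.centers_x.size - 1)
    i1 = np.clip(i0 + 1, 0, grid.centers_y.size - 1)
    j1 = np.clip(j0 + 1, 0, grid.centers_x.size - 1)
    y = (fy - i0)[:, None]
    x = (fx - j0)[None, :]

    r = (img.astype(np.int64) * n_bins) // (maxv + 1)  # bin index per pixel
    ii0 = i0[:, None]
    ii1 = i1[:, None]
    jj0 = j0[None, :]
    jj1 = j1[None, :]
    t_a = grid.transforms[ii0, jj0, r]
    t_b = grid.transforms[ii0, jj1, r]
    t_c = grid.transforms[ii1, jj0, r]
    t_d = grid.transforms[ii1, jj1, r]
    s = (1 - y) * ((1 - x) * t_a + x * t_b) + y * ((1 - x) * t_c + x * t_d)
    out = np.clip(np.rint(s), 0, maxv)
    return out.astype(img.dtype)


def clahe(img: np.ndarray, params: ClaheParams | None = None) -> np.ndarray:
    """Full CLAHE: build the region transform grid and apply the blend."""
    params = params or ClaheParams()
    return apply_clahe(img, build_region_transforms(img, params))
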