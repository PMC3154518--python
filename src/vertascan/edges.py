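"""Canny edge detection for radiographs.

Four stages, kept separately callable because the corner detector and the
profile models reuse intermediate products:

1. Gaussian smoothing — convolution with the normalized kernel sampled from
   G(x, y) = 1/(2 pi sigma^2) exp(-(x^2+y^2)/(2 sigma^2)).
2. Sobel gradients — correlation with the two 3x3 masks, giving Gx, Gy,
   magnitude G = sqrt(Gx^2 + Gy^2) and direction theta = atan2(Gy, Gx).
3. Non-maxima suppression — a pixel survives only if its magnitude is >=
   both neighbors sampled along the gradient direction quantized to
   {0, 45, 90, 135} degrees, thinning ridges to one pixel.
4. Hysteresis — pixels above the high threshold are edges; pixels between
   the thresholds are kept only if connected (4- or 8-neighborhood) to an
   accepted pixel; pixels below the low threshold are rejected.

An optional recursive smoothing backend (Deriche's exponential-trigonometric
approximation of the Gaussian) provides smoothing whose cost is independent
of sigma; it agrees with the FIR kernel to well under 1% RMS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

__all__ = [
    "CannyParams",
    "GradientField",
    "EdgeMap",
    "gaussian_kernel",
    "gaussian_smooth",
    "deriche_smooth",
    "sobel_gradients",
    "nonmax_suppression",
    "hysteresis",
    "canny",
    "resolve_thresholds",
]

SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
SOBEL_Y = np.array([[-1, -2, -1], [0, 0, 0], [1, 2, 1]], dtype=float)


@dataclass(frozen=True)
class CannyParams:
    """Detector parameters.

    sigma
        Gaussian standard deviation in pixels.
    low_threshold, high_threshold
        hysteresis thresholds; interpreted as absolute gradient magnitudes
        when ``threshold_mode == "absolute"`` and as quantiles in [0, 1] of
        the positive NMS magnitude distribution when ``"quantile"``.
    connectivity
        4 or 8, the neighbor rule used by "connected".
    smoother
        "fir" (direct kernel convolution) or "deriche" (recursive).
    """

    sigma: float = 1.4
    low_threshold: float = 10.0
    high_threshold: float = 25.0
    connectivity: int = 8
    threshold_mode: str = "absolute"
    smoother: str = "fir"

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if not 0 <= self.low_threshold <= self.high_threshold:
            raise ValueError("need 0 <= low_threshold <= high_threshold")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.threshold_mode not in ("absolute", "quantile"):
            raise ValueError("threshold_mode must be 'absolute' or 'quantile'")
        if self.smoother not in ("fir", "deriche"):
            raise ValueError("smoother must be 'fir' or 'deriche'")


@dataclass(frozen=True)
class GradientField:
    """Per-pixel Sobel responses, magnitude and direction (radians)."""

    gx: np.ndarray
    gy: np.ndarray
    magnitude: np.ndarray
    direction: np.ndarray


@dataclass(frozen=True)
class EdgeMap:
    """Boolean edge mask plus the thresholds that produced it."""

    mask: np.ndarray
    low: float = 0.0
    high: float = 0.0
    connectivity: int = 8


def gaussian_kernel(sigma: float, radius: int | None = None) -> np.ndarray:
    """Normalized 2D Gaussian kernel sampled at integer offsets.

    Truncated at ``radius`` (default ceil(3 sigma)) and normalized to unit
    sum so constants are preserved.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if radius is None:
        radius = int(np.ceil(3 * sigma))
    ax = np.arange(-radius, radius + 1, dtype=float)
    xx, yy = np.meshgrid(ax, ax)
    k = np.exp(-(xx**2 + yy**2) / (2 * sigma**2)) / (2 * np.pi * sigma**2)
    return k / k.sum()


def gaussian_smooth(img: np.ndarray, sigma: float) -> np.ndarray:
    """Convolve with the sampled Gaussian kernel (reflective padding)."""
    k = gaussian_kernel(sigma)
    return ndimage.convolve(np.asarray(img, dtype=float), k, mode="reflect")


# -- Deriche recursive smoothing ------------------------------------------
# Causal impulse response approximating the Gaussian (Deriche's 4th-order
# exponential-trigonometric fit):
#   h+(n) = [a0 cos(w0 n/s) + a1 sin(w0 n/s)] e^(-b0 n/s)
#         + [c0 cos(w1 n/s) + c1 sin(w1 n/s)] e^(-b1 n/s),  n >= 0
_DER_A0, _DER_A1, _DER_B0, _DER_W0 = 1.6800, 3.7350, 1.7830, 0.6318
_DER_C0, _DER_C1, _DER_B1, _DER_W1 = -0.6803, -0.2598, 1.7230, 1.9970


def _deriche_coeffs(sigma: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Order-4 recursion (causal num, anticausal num, denom) for one axis.

    The denominator comes from the four poles e^{(-b +/- i w)/sigma}; the
    causal numerator is fitted so the recursion reproduces the first four
    samples of h+; the anticausal numerator follows from the symmetry
    h-(n) = h+(-n) for n <= -1.  The pair is normalized to unit DC gain.
    """

    def h_plus(n: np.ndarray) -> np.ndarray:
        t = n / sigma
        return (_DER_A0 * np.cos(_DER_W0 * t) + _DER_A1 * np.sin(_DER_W0 * t)) * np.exp(
            -_DER_B0 * t
        ) + (_DER_C0 * np.cos(_DER_W1 * t) + _DER_C1 * np.sin(_DER_W1 * t)) * np.exp(-_DER_B1 * t)

    p = np.array(
        [
            np.exp((-_DER_B0 + 1j * _DER_W0) / sigma),
            np.exp((-_DER_B0 - 1j * _DER_W0) / sigma),
            np.exp((-_DER_B1 + 1j * _DER_W1) / sigma),
            np.exp((-_DER_B1 - 1j * _DER_W1) / sigma),
        ]
    )
    denom = np.real(np.poly(p))  # [1, d1, d2, d3, d4]
    h = h_plus(np.arange(4, dtype=float))
    num = np.empty(4)
    num[0] = h[0]
    for k in range(1, 4):
        num[k] = h[k] + np.dot(denom[1 : k + 1], h[k - 1 :: -1])
    # anticausal numerator (applied to the reversed signal, lag 1..4)
    anti = np.empty(5)
    anti[0] = 0.0
    for k in range(1, 4):
        anti[k] = num[k] - denom[k] * num[0]
    anti[4] = -denom[4] * num[0]
    # unit DC gain: total gain = (sum(num) + sum(anti)) / sum(denom)
    gain = (num.sum() + anti.sum()) / denom.sum()
    return num / gain, anti / gain, denom


def _deriche_axis(arr: np.ndarray, num: np.ndarray, anti: np.ndarray, denom: np.ndarray, axis: int) -> np.ndarray:
    causal = signal.lfilter(num, denom, arr, axis=axis)
    rev = np.flip(arr, axis=axis)
    anticausal = np.flip(signal.lfilter(anti, denom, rev, axis=axis), axis=axis)
    return causal + anticausal


def deriche_smooth(img: np.ndarray, sigma: float) -> np.ndarray:
    """Recursive Gaussian smoothing; cost independent of sigma.

    Reflective padding of width ceil(4 sigma) emulates the FIR boundary
    handling before the two separable recursive passes.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    num, anti, denom = _deriche_coeffs(sigma)
    pad = int(np.ceil(4 * sigma)) + 4
    arr = np.pad(np.asarray(img, dtype=float), pad, mode="reflect")
    arr = _deriche_axis(arr, num, anti, denom, axis=0)
    arr = _deriche_axis(arr, num, anti, denom, axis=1)
    return arr[pad:-pad, pad:-pad]


def sobel_gradients(img: np.ndarray) -> GradientField:
    """Apply the two Sobel masks (as correlation) and derive G and theta.

    The one-pixel border, where the masks would read outside the image, is
    zeroed.  theta uses the two-argument arctangent so Gx = 0 is defined.
    """
    img = np.asarray(img, dtype=float)
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError("image must be at least 3x3")
    gx = ndimage.correlate(img, SOBEL_X, mode="constant")
    gy = ndimage.correlate(img, SOBEL_Y, mode="constant")
    for g in (gx, gy):
        g[0, :] = g[-1, :] = 0.0
        g[:, 0] = g[:, -1] = 0.0
    mag = np.hypot(gx, gy)
    theta = np.arctan2(gy, gx)
    return GradientField(gx=gx, gy=gy, magnitude=mag, direction=theta)


_NMS_OFFSETS = {0: (0, 1), 1: (1, 1), 2: (1, 0), 3: (1, -1)}  # (drow, dcol)


def nonmax_suppression(field: GradientField) -> np.ndarray:
    """Zero every pixel that is not a maximum along its gradient direction.

    The direction is quantized to four bins; a pixel survives iff its
    magnitude is >= both neighbors along the quantized direction.  The
    one-pixel border is zeroed (its neighbors are undefined).
    """
    mag = field.magnitude
    deg = np.rad2deg(field.direction) % 180.0
    bins = np.floor((deg + 22.5) / 45.0).astype(int) % 4
    out = np.zeros_like(mag)
    padded = np.pad(mag, 1, mode="constant")
    rows, cols = mag.shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    keep = np.zeros(mag.shape, dtype=bool)
    for b, (dr, dc) in _NMS_OFFSETS.items():
        sel = bins == b
        n1 = padded[rr[sel] + 1 + dr, cc[sel] + 1 + dc]
        n2 = padded[rr[sel] + 1 - dr, cc[sel] + 1 - dc]
        m = mag[sel]
        keep[sel] = (m >= n1) & (m >= n2)
    out[keep] = mag[keep]
    out[0, :] = out[-1, :] = 0.0
    out[:, 0] = out[:, -1] = 0.0
    return out


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    raise ValueError("connectivity must be 4 or 8")


def hysteresis(nms: np.ndarray, low: float, high: float, connectivity: int = 8) -> EdgeMap:
    """Two-threshold edge acceptance.

    Pixels > high are accepted outright; pixels in [low, high] are accepted
    iff their candidate component (under the chosen connectivity) touches
    an above-high pixel; pixels < low are rejected.
    """
    if low > high:
        raise ValueError("low threshold must not exceed high threshold")
    nms = np.asarray(nms, dtype=float)
    candidates = (nms >= low) & (nms > 0)
    strong = nms > high
    labels, n = ndimage.label(candidates, structure=_structure(connectivity))
    if n == 0:
        mask = np.zeros_like(candidates)
    else:
        has_strong = np.zeros(n + 1, dtype=bool)
        has_strong[np.unique(labels[strong & candidates])] = True
        has_strong[0] = False
        mask = has_strong[labels]
    return EdgeMap(mask=mask, low=low, high=high, connectivity=connectivity)


def resolve_thresholds(nms: np.ndarray, params: CannyParams) -> tuple[float, float]:
    """Turn quantile-mode thresholds into absolute magnitudes."""
    if params.threshold_mode == "absolute":
        return params.low_threshold, params.high_threshold
    vals = nms[nms > 0]
    if vals.size == 0:
        return np.inf, np.inf
    low = float(np.quantile(vals, params.low_threshold))
    high = float(np.quantile(vals, params.high_threshold))
    return low, high


def canny(img: np.ndarray, params: CannyParams | None = None) -> EdgeMap:
    """Smoothing -> Sobel -> non-maxima suppression -> hysteresis."""
    params = params or CannyParams()
    smooth = deriche_smooth if params.smoother == "deriche" else gaussian_smooth
    blurred = smooth(img, params.sigma)
    field = sobel_gradients(blurred)
    nms = nonmax_suppression(field)
    low, high = resolve_thresholds(nms, params)
    return hysteresis(nms, low, high, params.connectivity)
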