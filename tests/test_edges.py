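"""Canny stages: smoothing, Sobel, non-maxima suppression, hysteresis."""

import numpy as np
import pytest

from vertascan.edges import (
    CannyParams,
    GradientField,
    canny,
    deriche_smooth,
    gaussian_kernel,
    gaussian_smooth,
    hysteresis,
    nonmax_suppression,
    sobel_gradients,
)


class TestGaussianSmooth:
    def test_constant_image_preserved(self):
        img = np.full((16, 16), 42.0)
        assert np.allclose(gaussian_smooth(img, 1.5), 42.0)

    def test_unnormalized_center_value(self):
        sigma = 1.3
        k = gaussian_kernel(sigma)
        # normalized kernel is proportional to the analytic form; its
        # center / corner ratio matches the analytic ratio
        r = k.shape[0] // 2
        analytic = np.exp(0.0) / np.exp(-(2 * r**2) / (2 * sigma**2))
        assert k[r, r] / k[0, 0] == pytest.approx(analytic)
        # the analytic center value before normalization
        assert 1 / (2 * np.pi * sigma**2) == pytest.approx(0.0941745, rel=1e-4)

    def test_impulse_response_equals_sampled_kernel(self):
        sigma = 1.1
        img = np.zeros((21, 21))
        img[10, 10] = 1.0
        out = gaussian_smooth(img, sigma)
        radius = int(np.ceil(3 * sigma))
        ax = np.arange(-radius, radius + 1, dtype=float)
        xx, yy = np.meshgrid(ax, ax)
        k = np.exp(-(xx**2 + yy**2) / (2 * sigma**2)) / (2 * np.pi * sigma**2)
        k /= k.sum()
        sl = slice(10 - radius, 10 + radius + 1)
        assert np.allclose(out[sl, sl], k, atol=1e-12)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            gaussian_smooth(np.zeros((5, 5)), 0.0)

    @pytest.mark.parametrize("sigma", [1.0, 1.4, 3.0])
    def test_deriche_agrees_with_fir_within_1pct_rms(self, sigma):
        rng = np.random.default_rng(8)
        img = gaussian_smooth(rng.uniform(0, 255, size=(96, 96)), 1.0)
        a = gaussian_smooth(img, sigma)
        b = deriche_smooth(img, sigma)
        rms = np.sqrt(np.mean((a - b) ** 2))
        assert rms / np.sqrt(np.mean(a**2)) < 0.01


class TestSobel:
    def test_vertical_step_response(self):
        img = np.zeros((9, 9))
        img[:, 4:] = 255.0
        f = sobel_gradients(img)
        # interior pixel in the last zero column, adjacent to the step
        assert abs(f.gx[4, 3]) == 4 * 255
        assert f.gy[4, 3] == 0.0

    def test_constant_image_zero_gradient(self):
        f = sobel_gradients(np.full((8, 8), 9.0))
        assert np.all(f.magnitude == 0)

    def test_magnitude_and_direction_identities(self):
        rng = np.random.default_rng(9)
        f = sobel_gradients(rng.uniform(0, 255, size=(12, 12)))
        assert np.allclose(f.magnitude**2, f.gx**2 + f.gy**2)
        sel = (f.gx > 0) & (np.abs(f.gx - f.gy) < 1e-9)
        assert np.allclose(f.direction[sel], np.pi / 4)
        # 3-4-5 triangle check on synthetic components
        assert np.hypot(3.0, 4.0) == 5.0

    def test_small_image_rejected(self):
        with pytest.raises(ValueError):
            sobel_gradients(np.zeros((2, 5)))


def _field(mag, theta):
    mag = np.asarray(mag, dtype=float)
    theta = np.broadcast_to(np.asarray(theta, dtype=float), mag.shape)
    return GradientField(gx=mag * np.cos(theta), gy=mag * np.sin(theta), magnitude=mag, direction=theta)


def brute_force_nms(field):
    """Literal per-pixel neighbor comparison over the 4 quantized directions."""
    mag = field.magnitude
    deg = np.rad2deg(field.direction) % 180.0
    bins = np.floor((deg + 22.5) / 45.0).astype(int) % 4
    offs = {0: (0, 1), 1: (1, 1), 2: (1, 0), 3: (1, -1)}
    out = np.zeros_like(mag)
    for r in range(1, mag.shape[0] - 1):
        for c in range(1, mag.shape[1] - 1):
            dr, dc = offs[bins[r, c]]
            if mag[r, c] >= mag[r + dr, c + dc] and mag[r, c] >= mag[r - dr, c - dc]:
                out[r, c] = mag[r, c]
    return out


class TestNonmaxSuppression:
    def test_zero_field_all_zero(self):
        f = _field(np.zeros((6, 6)), 0.0)
        assert np.all(nonmax_suppression(f) == 0)

    def test_horizontal_gradient_local_maximum_survives(self):
        mag = np.zeros((3, 5))
        mag[1] = [0, 1, 5, 1, 0]
        f = _field(mag, 0.0)  # gradient along +x
        out = nonmax_suppression(f)
        assert out[1, 2] == 5
        assert out[1, 1] == 0 and out[1, 3] == 0

    def test_matches_bruteforce_oracle_on_random_field(self):
        rng = np.random.default_rng(10)
        mag = rng.uniform(0, 10, size=(20, 20))
        theta = rng.uniform(-np.pi, np.pi, size=(20, 20))
        f = GradientField(
            gx=mag * np.cos(theta), gy=mag * np.sin(theta), magnitude=mag, direction=theta
        )
        assert np.array_equal(nonmax_suppression(f), brute_force_nms(f))

    def test_output_values_subset_of_input(self):
        rng = np.random.default_rng(11)
        f = sobel_gradients(rng.uniform(0, 255, size=(16, 16)))
        out = nonmax_suppression(f)
        nz = out > 0
        assert np.all(out[nz] == f.magnitude[nz])


def bfs_hysteresis(nms, low, high, connectivity=8):
    """Direct rule application: accept > high, grow through [low, high]."""
    from collections import deque

    cand = (nms >= low) & (nms > 0)
    accepted = nms > high
    queue = deque(map(tuple, np.argwhere(accepted & cand)))
    seen = set(queue)
    offs = (
        [(-1, 0), (1, 0), (0, -1), (0, 1)]
        if connectivity == 4
        else [(a, b) for a in (-1, 0, 1) for b in (-1, 0, 1) if (a, b) != (0, 0)]
    )
    while queue:
        r, c = queue.popleft()
        for dr, dc in offs:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nms.shape[0] and 0 <= cc < nms.shape[1]:
                if cand[rr, cc] and (rr, cc) not in seen:
                    seen.add((rr, cc))
                    queue.append((rr, cc))
    out = np.zeros_like(cand)
    for r, c in seen:
        out[r, c] = True
    return out


class TestHysteresis:
    def test_chain_grows_through_midrange(self):
        nms = np.zeros((3, 6))
        nms[1, 1:5] = [120, 60, 60, 40]
        em = hysteresis(nms, low=50, high=100)
        assert em.mask[1, 1] and em.mask[1, 2] and em.mask[1, 3]
        assert not em.mask[1, 4]

    def test_all_below_low_empty(self):
        nms = np.full((4, 4), 3.0)
        assert not hysteresis(nms, low=50, high=100).mask.any()

    def test_all_above_high_all_accepted(self):
        rng = np.random.default_rng(12)
        nms = rng.uniform(101, 200, size=(5, 5))
        assert hysteresis(nms, low=50, high=100).mask.all()

    def test_low_above_high_rejected(self):
        with pytest.raises(ValueError):
            hysteresis(np.zeros((3, 3)), low=5, high=1)

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_bfs_oracle(self, connectivity):
        rng = np.random.default_rng(13)
        nms = rng.uniform(0, 100, size=(30, 30))
        nms[rng.uniform(size=(30, 30)) < 0.5] = 0.0
        em = hysteresis(nms, low=30, high=70, connectivity=connectivity)
        assert np.array_equal(em.mask, bfs_hysteresis(nms, 30, 70, connectivity))

    def test_edge_map_invariants(self):
        rng = np.random.default_rng(14)
        nms = rng.uniform(0, 100, size=(20, 20))
        nms[rng.uniform(size=(20, 20)) < 0.6] = 0.0
        low, high = 25.0, 60.0
        em = hysteresis(nms, low, high)
        assert np.all(nms[em.mask] >= low)
        # every accepted pixel connects to an above-high pixel
        from scipy import ndimage

        labels, _ = ndimage.label(em.mask, structure=np.ones((3, 3)))
        for lbl in np.unique(labels[labels > 0]):
            assert (nms[labels == lbl] > high).any()

    def test_raising_high_threshold_never_adds_pixels(self):
        rng = np.random.default_rng(15)
        nms = rng.uniform(0, 100, size=(25, 25))
        nms[rng.uniform(size=(25, 25)) < 0.5] = 0.0
        prev = hysteresis(nms, 20, 40).mask
        for high in (50, 60, 80):
            cur = hysteresis(nms, 20, high).mask
            assert not (cur & ~prev).any()
            prev = cur


class TestCanny:
    def test_white_square_boundary_within_1px(self):
        img = np.zeros((64, 64), dtype=np.uint8)
        img[20:45, 18:47] = 255
        em = canny(img, CannyParams(sigma=1.4, low_threshold=30, high_threshold=80))
        ys, xs = np.nonzero(em.mask)
        assert len(ys) > 80
        # true boundary: rectangle between the on/off pixel centers
        top, bot, left, right = 19.5, 44.5, 17.5, 46.5
        for y, x in zip(ys, xs):
            dy = min(abs(y - top), abs(y - bot))
            dx = min(abs(x - left), abs(x - right))
            inside_x = left <= x <= right
            inside_y = top <= y <= bot
            cands = [float(np.hypot(dy, dx))]
            if inside_x:
                cands.append(dy)
            if inside_y:
                cands.append(dx)
            assert min(cands) <= 1.0

    def test_constant_image_empty(self):
        assert not canny(np.full((32, 32), 90, dtype=np.uint8)).mask.any()

    def test_noisy_step_edge_within_1px(self):
        rng = np.random.default_rng(16)
        img = np.full((64, 64), 40.0)
        img[:, 32:] = 160.0
        img = np.clip(img + rng.normal(0, 3, img.shape), 0, 255).astype(np.uint8)
        em = canny(img, CannyParams())
        ys, xs = np.nonzero(em.mask)
        assert len(ys) >= 50
        assert np.all(np.abs(xs - 31.5) <= 1.0)


@pytest.mark.parametrize(
    "kwargs",
    [dict(sigma=0), dict(low_threshold=5, high_threshold=2), dict(connectivity=5)],
)
def test_invalid_canny_params_rejected(kwargs):
    with pytest.raises(ValueError):
        CannyParams(**kwargs)
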