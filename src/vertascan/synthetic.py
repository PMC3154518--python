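"""Synthetic cervical-spine radiograph generation with exact ground truth.

Real cervical radiographs (five vertebral bodies C3-C7 stacked along a
curved spine axis, very poor contrast, blended contours) cannot be
redistributed, so every stage of the pipeline is exercised on rendered
stand-ins: brighter convex quadrilateral "vertebral bodies" with rounded
corners placed along a bowed axis, Gaussian-blurred boundaries, a smooth
illumination ramp and additive Gaussian noise.  The generator returns the
exact geometry it rendered — per-vertebra corner coordinates, dense
boundary contours, the anterior-corner landmark sequence used by the
spine-curvature model, and full 12-landmark shapes for the ASM — so
detection and segmentation errors can be measured without external data.

All coordinates are (x, y) = (column, row), origin top-left, y downward.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon
from skimage.draw import polygon as draw_polygon

from .shapemodel import ShapeModel, generate_shape

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "render_radiograph",
    "spine_ground_truth",
    "sample_training_shapes",
    "vertebra_landmarks",
    "ANTERIOR_CORNER_INDICES",
    "LANDMARKS_PER_VERTEBRA",
]

#: 12 landmarks per vertebra: each side carries a corner plus two
#: intermediate points; index 0 = upper-anterior, 3 = upper-posterior,
#: 6 = lower-posterior, 9 = lower-anterior corner.
LANDMARKS_PER_VERTEBRA = 12
ANTERIOR_CORNER_INDICES = (0, 9)
_CORNER_INDICES = (0, 3, 6, 9)


@dataclass(frozen=True)
class SyntheticSpec:
    """Rendering conditions for one synthetic radiograph.

    Defaults emulate a desk-scale low-contrast cervical film: 512x512
    frame, five bodies, 45 grey levels of body/background contrast on an
    80-level background, sigma = 1.5 px boundary blur, additive Gaussian
    noise sigma = 3 and a 25-level diagonal illumination ramp.  The full
    film scale (1763x1755) is available through ``image_size``.
    """

    image_size: tuple[int, int] = (512, 512)  # (height, width)
    n_vertebrae: int = 5
    curvature: float = 35.0  # lateral bow of the spine axis, px
    vertebra_size: tuple[float, float] = (88.0, 48.0)  # (width, height) px
    intensity_contrast: float = 45.0
    background_level: float = 80.0
    noise_sd: float = 3.0
    illumination_gradient: float = 25.0
    boundary_blur: float = 1.5
    corner_radius: float = 2.0  # 0 disables rounding (plain polygons)
    shape_jitter: float = 2.5  # per-corner positional jitter SD, px
    size_jitter: float = 0.05  # relative per-vertebra scale jitter SD
    margin: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.image_size) <= 0 or self.n_vertebrae < 1:
            raise ValueError("sizes and counts must be positive")
        if self.vertebra_size[0] <= 0 or self.vertebra_size[1] <= 0:
            raise ValueError("vertebra_size must be positive")
        if self.noise_sd < 0 or self.boundary_blur < 0:
            raise ValueError("noise_sd and boundary_blur must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Exact rendered geometry.

    corners
        (n_vertebrae, 4, 2) quadrilateral corners, order upper-anterior,
        upper-posterior, lower-posterior, lower-anterior.
    boundaries
        per-vertebra dense boundary polylines (closed, (m, 2)).
    anterior_landmarks
        (2 n_vertebrae, 2) spine-curvature landmark sequence: upper then
        lower anterior corner of each vertebra, top to bottom.
    shapes
        (n_vertebrae, 12, 2) full ASM landmark shapes.
    roi_clicks
        (top, bottom): upper-anterior corner of the first body and
        lower-anterior corner of the last.
    labels
        vertebra names, C3 downward.
    """

    corners: np.ndarray
    boundaries: list[np.ndarray]
    anterior_landmarks: np.ndarray
    shapes: np.ndarray
    roi_clicks: tuple[np.ndarray, np.ndarray]
    labels: list[str] = field(default_factory=list)


def vertebra_landmarks(corners: np.ndarray) -> np.ndarray:
    """Interpolate the 12-landmark shape from a 4-corner quadrilateral."""
    corners = np.asarray(corners, dtype=float)
    pts = []
    for s in range(4):
        a, b = corners[s], corners[(s + 1) % 4]
        for f in (0.0, 1 / 3, 2 / 3):
            pts.append(a + f * (b - a))
    return np.array(pts)


def spine_ground_truth(spec: SyntheticSpec) -> GroundTruth:
    """Geometry of one synthetic spine, without rendering.

    The axis runs vertically from margin to margin, bowed laterally by a
    half-sine of amplitude ``curvature``; each body is a jittered
    rectangle rotated to the local axis tangent.
    """
    h, w = spec.image_size
    rng = np.random.default_rng(spec.seed)
    vw, vh = spec.vertebra_size
    y0, y1 = spec.margin, h - spec.margin
    if y1 - y0 < spec.n_vertebrae * vh:
        raise ValueError("vertebrae do not fit the image at this margin")
    ts = (np.arange(spec.n_vertebrae) + 0.5) / spec.n_vertebrae

    def axis_x(t: float) -> float:
        return w / 2 + spec.curvature * np.sin(np.pi * t) - spec.curvature / 2

    corners_all = []
    shapes = []
    local = np.array(
        [[-vw / 2, -vh / 2], [vw / 2, -vh / 2], [vw / 2, vh / 2], [-vw / 2, vh / 2]]
    )
    for t in ts:
        cx, cy = axis_x(t), y0 + t * (y1 - y0)
        # tangent angle of the bowed axis
        dx = spec.curvature * np.pi * np.cos(np.pi * t) / (y1 - y0)
        ang = np.arctan2(dx, 1.0)
        c, s = np.cos(ang), np.sin(ang)
        rot = np.array([[c, -s], [s, c]])
        scale = 1.0 + spec.size_jitter * rng.standard_normal()
        quad = (scale * local) @ rot.T + [cx, cy]
        quad = quad + spec.shape_jitter * rng.standard_normal(quad.shape)
        corners_all.append(quad)
        shapes.append(vertebra_landmarks(quad))

    corners = np.array(corners_all)
    shapes = np.array(shapes)
    anterior = np.array(
        [p for quad in corners for p in (quad[0], quad[3])]
    )  # UA then LA, top to bottom
    boundaries = [_dense_boundary(q, spec.corner_radius) for q in corners]
    labels = [f"C{3 + i}" for i in range(spec.n_vertebrae)]
    return GroundTruth(
        corners=corners,
        boundaries=boundaries,
        anterior_landmarks=anterior,
        shapes=shapes,
        roi_clicks=(corners[0, 0].copy(), corners[-1, 3].copy()),
        labels=labels,
    )


def _rounded_polygon(quad: np.ndarray, radius: float) -> Polygon:
    poly = Polygon(quad)
    if radius > 0:
        poly = poly.buffer(-radius, join_style="mitre").buffer(radius, quad_segs=16)
    return poly


def _dense_boundary(quad: np.ndarray, radius: float, step: float = 0.5) -> np.ndarray:
    poly = _rounded_polygon(quad, radius)
    ring = poly.exterior
    n = max(16, int(np.ceil(ring.length / step)))
    pts = [ring.interpolate(d) for d in np.linspace(0, ring.length, n, endpoint=False)]
    out = np.array([[p.x, p.y] for p in pts])
    return np.vstack([out, out[:1]])


def render_radiograph(spec: SyntheticSpec) -> tuple[np.ndarray, GroundTruth]:
    """Render one synthetic radiograph; deterministic per seed.

    Returns the uint8 image and its exact :class:`GroundTruth`.
    """
    gt = spine_ground_truth(spec)
    h, w = spec.image_size
    img = np.full((h, w), float(spec.background_level))
    for quad in gt.corners:
        poly = _rounded_polygon(quad, spec.corner_radius)
        xs, ys = poly.exterior.xy
        rr, cc = draw_polygon(np.array(ys), np.array(xs), shape=(h, w))
        img[rr, cc] = spec.background_level + spec.intensity_contrast
    if spec.boundary_blur > 0:
        img = ndimage.gaussian_filter(img, spec.boundary_blur)
    if spec.illumination_gradient:
        yy, xx = np.mgrid[0:h, 0:w]
        ramp = (xx + yy) / (w + h - 2) - 0.5
        img = img + spec.illumination_gradient * ramp
    # noise drawn from a stream independent of the geometry jitter
    rng = np.random.default_rng([spec.seed, 7919])
    if spec.noise_sd > 0:
        img = img + spec.noise_sd * rng.standard_normal(img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), gt


def sample_training_shapes(
    model: ShapeModel, n: int, coeff_sd_scale: float = 1.0, seed: int = 0
) -> list[np.ndarray]:
    """Draw posed shapes x_bar + P b from a known model.

    Mode coefficients are zero-mean Gaussian with SD
    ``coeff_sd_scale * sqrt(lambda_i)``; each draw receives a random
    similarity pose (rotation within +/- 0.4 rad, log-normal scale spread
    0.15 around 80, translation uniform in [100, 400]).  Deterministic per
    seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    shapes = []
    sd = coeff_sd_scale * np.sqrt(model.variances)
    for _ in range(n):
        b = rng.standard_normal(model.n_modes) * sd
        x = generate_shape(model, b)
        ang = rng.uniform(-0.4, 0.4)
        scale = 80.0 * np.exp(0.15 * rng.standard_normal())
        c, s = np.cos(ang), np.sin(ang)
        x = scale * (x @ np.array([[c, -s], [s, c]]).T) + rng.uniform(100, 400, size=2)
        shapes.append(x)
    return shapes


def vertebra_training_data(
    n_images: int = 8, seed: int = 0, base: SyntheticSpec | None = None
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Rendered images paired with their ground-truth vertebra shapes.

    Each rendered spine contributes one image/shape pair per vertebra (the
    image reference is shared), giving ``n_images * n_vertebrae`` training
    pairs for the shape and profile models.
    """
    base = base or SyntheticSpec()
    imgs: list[np.ndarray] = []
    shapes: list[np.ndarray] = []
    for i in range(n_images):
        spec = replace(base, seed=seed * 1000 + i)
        img, gt = render_radiograph(spec)
        for shp in gt.shapes:
            imgs.append(img)
            shapes.append(shp)
    return imgs, shapes


def curvature_training_samples(
    n: int = 50, seed: int = 0, base: SyntheticSpec | None = None
) -> list[np.ndarray]:
    """Anterior-corner landmark sequences from n synthetic spines.

    Curvature varies uniformly in [5, 65] px across samples so the mean
    shape captures an average bow rather than one fixed geometry.
    """
    base = base or SyntheticSpec()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        spec = replace(
            base,
            seed=int(rng.integers(0, 2**31 - 1)),
            curvature=float(rng.uniform(5.0, 65.0)),
        )
        out.append(spine_ground_truth(spec).anterior_landmarks)
    return out
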