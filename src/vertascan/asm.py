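"""Active Shape Model search with grey-level profile matching.

During training, the local grey-level variation is evaluated around each
landmark: the magnitude of the directional derivative of intensity is
sampled along the landmark's normal, normalized, and summarized across the
training set by a mean profile and covariance per landmark.  During search,
each landmark of the current shape slides along its normal over
``2*search_range + 1`` candidate positions and moves to the one whose
sampled profile is closest to the landmark's mean profile in Mahalanobis
distance (g - g_bar)^T S^-1 (g - g_bar).  The proposed landmark cloud is
then regularized through the statistical shape model (pose fit plus mode
coefficients clamped to +/- 3 sqrt(lambda)), and the step repeats until the
landmarks stop moving — i.e. the profile match no longer improves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .shapemodel import ShapeModel, as_shape, generate_shape, project_shape

__all__ = [
    "ProfileModel",
    "AsmFitResult",
    "landmark_normals",
    "sample_profile",
    "build_profile_models",
    "mahalanobis_cost",
    "asm_search_step",
    "segment_vertebra",
]


@dataclass(frozen=True)
class ProfileModel:
    """Per-landmark mean gradient profile and covariance.

    means
        (n_landmarks, 2k+1) mean normalized profiles.
    covariances
        (n_landmarks, 2k+1, 2k+1) regularized sample covariances.
    k
        profile half-length; profiles carry 2k+1 samples at unit spacing.
    """

    means: np.ndarray
    covariances: np.ndarray
    k: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "_inv", np.linalg.inv(self.covariances))

    @property
    def n_landmarks(self) -> int:
        return self.means.shape[0]

    def to_json(self, path) -> None:
        import json
        from pathlib import Path

        Path(path).write_text(
            json.dumps(
                {"means": self.means.tolist(), "covariances": self.covariances.tolist(), "k": self.k}
            )
        )

    @staticmethod
    def from_json(path) -> "ProfileModel":
        import json
        from pathlib import Path

        d = json.loads(Path(path).read_text())
        return ProfileModel(
            means=np.array(d["means"], dtype=float),
            covariances=np.array(d["covariances"], dtype=float),
            k=int(d["k"]),
        )


@dataclass(frozen=True)
class AsmFitResult:
    """Outcome of an iterative ASM fit."""

    final_shape: np.ndarray
    iterations: int
    converged: bool
    movements: list[float]


def landmark_normals(shape: np.ndarray) -> np.ndarray:
    """Unit normals, perpendicular to the chord between each landmark's
    neighbors; the shape is treated as closed."""
    pts = as_shape(shape)
    tang = np.roll(pts, -1, axis=0) - np.roll(pts, 1, axis=0)
    normals = np.column_stack([-tang[:, 1], tang[:, 0]])
    norms = np.hypot(*normals.T)
    if np.any(norms == 0):
        raise ValueError("degenerate shape: coincident neighbor landmarks")
    return normals / norms[:, None]


def _interp(img: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Bilinear intensity lookup at (x, y) points, edge-padded."""
    return ndimage.map_coordinates(
        np.asarray(img, dtype=float),
        [points[..., 1].ravel(), points[..., 0].ravel()],
        order=1,
        mode="nearest",
    ).reshape(points.shape[:-1])


def _profiles(img: np.ndarray, centers: np.ndarray, normals: np.ndarray, k: int) -> np.ndarray:
    """Normalized |directional derivative| profiles for a batch of centers.

    centers, normals: (..., 2).  Returns (..., 2k+1).
    """
    steps = np.arange(-(k + 1), k + 2, dtype=float)  # 2k+3 intensity taps
    pos = centers[..., None, :] + steps[:, None] * normals[..., None, :]
    intens = _interp(img, pos)
    deriv = (intens[..., 2:] - intens[..., :-2]) / 2.0
    prof = np.abs(deriv)
    norm = prof.sum(axis=-1, keepdims=True)
    return np.divide(prof, norm, out=np.zeros_like(prof), where=norm > 0)


def sample_profile(img: np.ndarray, point, normal, k: int = 6) -> np.ndarray:
    """Gradient-intensity profile at one landmark.

    2k+1 samples of |dI/dn| at unit steps along the unit normal, centered
    on the landmark, normalized by the sum of absolute values.  Samples
    falling outside the image are clipped by edge padding.
    """
    normal = np.asarray(normal, dtype=float)
    n = np.hypot(*normal)
    if n == 0:
        raise ValueError("zero normal direction")
    point = np.asarray(point, dtype=float)
    return _profiles(img, point[None, :], (normal / n)[None, :], k)[0]


def build_profile_models(imgs: list, shapes: list, k: int = 6) -> ProfileModel:
    """Train per-landmark profile statistics from image/shape pairs.

    The covariance is regularized by adding delta*I with
    delta = 1e-6 * trace / profile length, keeping it invertible even for
    (near-)identical training profiles.
    """
    if len(imgs) != len(shapes) or len(imgs) < 2:
        raise ValueError("need >= 2 image/shape training pairs")
    arrs = [as_shape(s) for s in shapes]
    n_landmarks = arrs[0].shape[0]
    if any(a.shape[0] != n_landmarks for a in arrs):
        raise ValueError("inconsistent landmark counts")
    stacks = []
    for img, shp in zip(imgs, arrs):
        normals = landmark_normals(shp)
        stacks.append(_profiles(img, shp, normals, k))
    data = np.stack(stacks)  # (n_train, n_landmarks, L)
    means = data.mean(axis=0)
    length = 2 * k + 1
    covs = np.empty((n_landmarks, length, length))
    for j in range(n_landmarks):
        centered = data[:, j, :] - means[j]
        cov = centered.T @ centered / (data.shape[0] - 1)
        delta = 1e-6 * max(np.trace(cov), 1.0) / length
        covs[j] = cov + delta * np.eye(length)
    return ProfileModel(means=means, covariances=covs, k=k)


def mahalanobis_cost(profile: np.ndarray, mean: np.ndarray, covariance: np.ndarray) -> float:
    """(g - g_bar)^T S^-1 (g - g_bar), via a linear solve."""
    d = np.asarray(profile, dtype=float) - np.asarray(mean, dtype=float)
    if d.shape[0] != covariance.shape[0]:
        raise ValueError("profile and model dimensions differ")
    return float(d @ np.linalg.solve(covariance, d))


def _shape_cost(img: np.ndarray, shape: np.ndarray, profiles: ProfileModel) -> float:
    normals = landmark_normals(shape)
    g = _profiles(img, shape, normals, profiles.k)
    d = g - profiles.means
    return float(np.einsum("ij,ijk,ik->", d, profiles._inv, d))


def asm_search_step(
    img: np.ndarray,
    current,
    shape_model: ShapeModel,
    profiles: ProfileModel,
    search_range: int = 4,
) -> np.ndarray:
    """One ASM update.

    Every landmark is proposed at the best of 2*search_range+1 candidate
    positions along its normal (minimum Mahalanobis profile cost; ties go
    to the smallest displacement), then the proposal is regularized through
    the shape model: similarity pose refit plus mode coefficients clamped
    to the +/- 3 SD allowable region.
    """
    shape = as_shape(current)
    normals = landmark_normals(shape)
    offsets = np.concatenate(
        [[0]] + [[-i, i] for i in range(1, search_range + 1)]
    )  # ordered by |offset| so argmin ties keep the smallest move
    centers = shape[:, None, :] + offsets[None, :, None] * normals[:, None, :]
    g = _profiles(img, centers, normals[:, None, :], profiles.k)  # (n, m, L)
    d = g - profiles.means[:, None, :]
    costs = np.einsum("nmi,nij,nmj->nm", d, profiles._inv, d)
    best = np.argmin(costs, axis=1)  # offsets ordered by |offset|: ties stay put
    proposed = centers[np.arange(len(shape)), best]
    b, pose = project_shape(shape_model, proposed)
    return generate_shape(shape_model, b, pose)


def segment_vertebra(
    img: np.ndarray,
    init,
    shape_model: ShapeModel,
    profiles: ProfileModel,
    tol: float = 0.5,
    max_iter: int = 50,
    search_range: int = 4,
) -> AsmFitResult:
    """Iterate ASM steps until the landmarks effectively stop moving.

    Convergence is declared when the mean landmark movement of a step
    falls below ``tol`` (px); as a secondary stop, a step that worsens the
    total profile cost is rejected and the previous shape is kept ("the
    match is no more improved").  Deterministic given image, init, models.
    """
    current = as_shape(init)
    movements: list[float] = []
    if max_iter == 0:
        return AsmFitResult(final_shape=current, iterations=0, converged=False, movements=movements)
    cost = _shape_cost(img, current, profiles)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        new = asm_search_step(img, current, shape_model, profiles, search_range)
        move = float(np.hypot(*(new - current).T).mean())
        new_cost = _shape_cost(img, new, profiles)
        if move < tol:
            current = new
            movements.append(move)
            converged = True
            break
        if new_cost >= cost:
            converged = True  # no further improvement
            break
        movements.append(move)
        current, cost = new, new_cost
    return AsmFitResult(final_shape=current, iterations=it, converged=converged, movements=movements)
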