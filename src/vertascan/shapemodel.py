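"""Statistical shape modelling: Procrustes alignment and PCA shape models.

A shape is an ordered set of n 2D landmarks.  Training shapes carry an
arbitrary similarity pose (position, orientation, scale), so a relevant
statistical model first removes that pose by generalized Procrustes
alignment: every shape is similarity-fitted to the evolving normalized
mean until the mean stabilizes.  PCA of the aligned landmark vectors then
yields the point-distribution model

    x = x_bar + P b,

where x_bar is the mean shape (2n-vector), P the matrix of the t leading
orthonormal eigenvectors of the landmark covariance, and b the mode
coefficients, conventionally constrained to |b_i| <= 3 sqrt(lambda_i) so
generated shapes stay within the population's allowable region.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "PoseParams",
    "ShapeModel",
    "procrustes_pair",
    "procrustes_align_set",
    "build_pca_model",
    "generate_shape",
    "project_shape",
    "as_shape",
]


def as_shape(x) -> np.ndarray:
    """Coerce to an (n, 2) float landmark array."""
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(-1, 2)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("shape must be an (n, 2) landmark array")
    if not np.all(np.isfinite(arr)):
        raise ValueError("landmark coordinates must be finite")
    return arr


@dataclass(frozen=True)
class PoseParams:
    """Similarity transform: y = scale * R(rotation) x + translation."""

    scale: float
    rotation: float
    translation: np.ndarray

    def __post_init__(self) -> None:
        if self.scale <= 0:
            raise ValueError("scale must be > 0")

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        return self.scale * np.array([[c, -s], [s, c]])

    def apply(self, shape: np.ndarray) -> np.ndarray:
        return as_shape(shape) @ self.matrix.T + self.translation

    def inverse_apply(self, shape: np.ndarray) -> np.ndarray:
        return (as_shape(shape) - self.translation) @ np.linalg.inv(self.matrix).T

    @staticmethod
    def identity() -> "PoseParams":
        return PoseParams(scale=1.0, rotation=0.0, translation=np.zeros(2))


@dataclass(frozen=True)
class ShapeModel:
    """Point-distribution model: mean shape, orthonormal modes, variances."""

    mean: np.ndarray  # (2n,) flattened [x0, y0, x1, y1, ...]
    modes: np.ndarray  # (2n, t), orthonormal columns
    variances: np.ndarray  # (t,), descending
    total_variance: float

    @property
    def n_landmarks(self) -> int:
        return self.mean.size // 2

    @property
    def n_modes(self) -> int:
        return self.modes.shape[1]

    @property
    def mean_shape(self) -> np.ndarray:
        return self.mean.reshape(-1, 2)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "mean": self.mean.tolist(),
            "modes": self.modes.tolist(),
            "variances": self.variances.tolist(),
            "total_variance": self.total_variance,
            "n_landmarks": self.n_landmarks,
        }
        Path(path).write_text(json.dumps(payload))

    @staticmethod
    def from_json(path: str | Path) -> "ShapeModel":
        d = json.loads(Path(path).read_text())
        return ShapeModel(
            mean=np.array(d["mean"], dtype=float),
            modes=np.array(d["modes"], dtype=float).reshape(len(d["mean"]), -1),
            variances=np.array(d["variances"], dtype=float),
            total_variance=float(d["total_variance"]),
        )


def _centroid_size(shape: np.ndarray) -> float:
    centered = shape - shape.mean(axis=0)
    return float(np.sqrt((centered**2).sum()))


def procrustes_pair(moving, fixed) -> tuple[PoseParams, np.ndarray, float]:
    """Best orientation-preserving similarity fit of ``moving`` onto ``fixed``.

    Returns the pose minimizing the summed squared landmark distances, the
    transformed copy of ``moving``, and the residual (that minimum).  Uses
    the complex-regression closed form; reflections are not allowed.
    """
    X = as_shape(moving)
    Y = as_shape(fixed)
    if X.shape != Y.shape:
        raise ValueError("landmark counts differ")
    xc = X.mean(axis=0)
    yc = Y.mean(axis=0)
    zx = (X[:, 0] - xc[0]) + 1j * (X[:, 1] - xc[1])
    zy = (Y[:, 0] - yc[0]) + 1j * (Y[:, 1] - yc[1])
    denom = np.vdot(zx, zx).real
    if denom == 0:
        raise ValueError("degenerate shape: all landmarks coincide")
    a = np.vdot(zx, zy) / denom  # scale * e^{i rotation}
    scale = float(np.abs(a))
    if scale == 0:
        raise ValueError("degenerate pair: zero optimal scale")
    rotation = float(np.angle(a))
    pose = PoseParams(scale=scale, rotation=rotation, translation=np.zeros(2))
    translation = yc - pose.matrix @ xc
    pose = PoseParams(scale=scale, rotation=rotation, translation=translation)
    aligned = pose.apply(X)
    residual = float(((aligned - Y) ** 2).sum())
    return pose, aligned, residual


def _normalize_mean(mean: np.ndarray) -> np.ndarray:
    """Fix the similarity gauge: origin centroid, unit centroid size,
    first-to-last landmark axis pointing along +y (top to bottom)."""
    m = mean - mean.mean(axis=0)
    size = _centroid_size(m)
    if size == 0:
        raise ValueError("degenerate mean shape")
    m = m / size
    axis = m[-1] - m[0]
    ang = np.arctan2(axis[1], axis[0])
    rot = np.pi / 2 - ang  # rotate chord onto +y
    c, s = np.cos(rot), np.sin(rot)
    return m @ np.array([[c, -s], [s, c]]).T


def procrustes_align_set(
    shapes: list, tol: float = 1e-8, max_iter: int = 100
) -> tuple[list[np.ndarray], np.ndarray]:
    """Generalized Procrustes alignment of a training set.

    Iteratively aligns every shape to the current normalized mean and
    recomputes the mean until it moves less than ``tol`` (RMS per
    coordinate).  Returns the aligned shapes and the final mean.
    """
    arrs = [as_shape(s) for s in shapes]
    if len(arrs) < 2:
        raise ValueError("need at least 2 shapes")
    n = arrs[0].shape[0]
    if any(a.shape[0] != n for a in arrs):
        raise ValueError("inconsistent landmark counts")
    mean = _normalize_mean(arrs[0])
    aligned = arrs
    for _ in range(max_iter):
        aligned = [procrustes_pair(a, mean)[1] for a in arrs]
        new_mean = _normalize_mean(np.mean(aligned, axis=0))
        move = float(np.sqrt(((new_mean - mean) ** 2).mean()))
        mean = new_mean
        if move < tol:
            return aligned, mean
    raise RuntimeError(
        f"Procrustes alignment did not converge in {max_iter} iterations "
        f"(last mean movement {move:.3g} > tol {tol:.3g})"
    )


def build_pca_model(aligned: list, variance_fraction: float = 0.95) -> ShapeModel:
    """PCA of aligned landmark vectors; keep the smallest mode count whose
    cumulative variance reaches ``variance_fraction`` of the total."""
    if not 0 < variance_fraction <= 1:
        raise ValueError("variance_fraction must be in (0, 1]")
    data = np.array([as_shape(s).ravel() for s in aligned])
    if data.shape[0] < 2:
        raise ValueError("need at least 2 aligned shapes")
    mean = data.mean(axis=0)
    centered = data - mean
    cov = centered.T @ centered / (data.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # numerical dust relative to the coordinate scale is not real variance
    floor = (1e-9 * max(1.0, float(np.abs(data).max()))) ** 2
    evals[evals < floor] = 0.0
    total = float(evals.sum())
    if total <= 0:
        return ShapeModel(mean=mean, modes=np.empty((mean.size, 0)), variances=np.empty(0), total_variance=0.0)
    cum = np.cumsum(evals) / total
    t = int(np.searchsorted(cum, variance_fraction - 1e-12) + 1)
    return ShapeModel(
        mean=mean,
        modes=evecs[:, :t],
        variances=evals[:t],
        total_variance=total,
    )


def generate_shape(
    model: ShapeModel, b: np.ndarray | None = None, pose: PoseParams | None = None
) -> np.ndarray:
    """Instantiate x = pose(x_bar + P b) as an (n, 2) landmark array."""
    if b is None:
        b = np.zeros(model.n_modes)
    b = np.asarray(b, dtype=float)
    if b.shape != (model.n_modes,):
        raise ValueError(f"b must have length {model.n_modes}")
    x = (model.mean + model.modes @ b).reshape(-1, 2)
    if pose is not None:
        x = pose.apply(x)
    return x


def clamp_coefficients(model: ShapeModel, b: np.ndarray, n_sd: float = 3.0) -> np.ndarray:
    lim = n_sd * np.sqrt(model.variances)
    return np.clip(b, -lim, lim)


def project_shape(
    model: ShapeModel,
    shape,
    n_sd: float = 3.0,
    max_iter: int = 25,
    tol: float = 1e-10,
) -> tuple[np.ndarray, PoseParams]:
    """Model-frame coefficients and pose best explaining an image shape.

    Alternates the Procrustes pose fit of the current model instance onto
    the shape with the tangent projection b = P^T (pose^-1(shape) - x_bar)
    until b stabilizes, then clamps b to +/- n_sd standard deviations per
    mode.  For a shape generated from in-range (b, pose) this recovers
    both exactly (the alternation's fixed point).
    """
    target = as_shape(shape)
    if target.shape[0] != model.n_landmarks:
        raise ValueError("landmark counts differ")
    b = np.zeros(model.n_modes)
    pose = PoseParams.identity()
    for _ in range(max_iter):
        instance = (model.mean + model.modes @ b).reshape(-1, 2)
        pose, _, _ = procrustes_pair(instance, target)
        resid = pose.inverse_apply(target).ravel() - model.mean
        new_b = model.modes.T @ resid
        if np.allclose(new_b, b, atol=tol, rtol=0):
            b = new_b
            break
        b = new_b
    return clamp_coefficients(model, b, n_sd), pose
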