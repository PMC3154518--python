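"""Vertebra localization from detected corners via a spine-curvature model.

Among all corners found by the polygonal approximation, the ones belonging
to vertebral bodies must be singled out.  A statistical model of the spine
curvature — whose landmarks are the anterior vertebra corners, upper and
lower per body, top to bottom — provides the prior: the user marks the
upper anterior corner of C3 and the lower anterior corner of C7, the mean
curvature shape is similarity-aligned onto those two clicks, and each model
landmark is then matched to the closest detected corner.  Matching proceeds
strictly from the top of the image downward, and corners lying above the
last matched one leave the candidate pool, so upper and lower corners of
successive vertebrae cannot swap.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import shapemodel
from .contours import CornerSet
from .shapemodel import ShapeModel, as_shape

__all__ = [
    "CurvatureModel",
    "RoiClicks",
    "VertebraAnchors",
    "build_curvature_model",
    "align_model_to_roi",
    "match_corners",
    "two_point_similarity",
    "init_vertebra_shape",
    "locate_vertebrae",
]


@dataclass(frozen=True)
class CurvatureModel:
    """Mean spine-curvature shape: anterior corners, top to bottom.

    Stored in the normalized model frame (centroid at the origin, unit
    centroid size, first-to-last landmark chord along +y); default 10
    landmarks = upper + lower anterior corner for each of C3-C7.
    """

    mean_shape: np.ndarray

    def __post_init__(self) -> None:
        axis = self.mean_shape[-1] - self.mean_shape[0]
        proj = (self.mean_shape - self.mean_shape[0]) @ axis
        if np.any(np.diff(proj) <= 0):
            raise ValueError("landmarks must be strictly ordered along the model axis")

    @property
    def n_landmarks(self) -> int:
        return len(self.mean_shape)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"mean_shape": self.mean_shape.tolist()}))

    @staticmethod
    def from_json(path: str | Path) -> "CurvatureModel":
        d = json.loads(Path(path).read_text())
        return CurvatureModel(mean_shape=np.array(d["mean_shape"], dtype=float))


@dataclass(frozen=True)
class RoiClicks:
    """The two user-marked points bounding the region of interest:
    upper anterior corner of C3 and lower anterior corner of C7."""

    top: np.ndarray
    bottom: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "top", np.asarray(self.top, dtype=float))
        object.__setattr__(self, "bottom", np.asarray(self.bottom, dtype=float))
        if np.allclose(self.top, self.bottom):
            raise ValueError("ROI clicks must be distinct points")


@dataclass(frozen=True)
class VertebraAnchors:
    """Corner assignment for every curvature-model landmark.

    positions
        (n, 2) chosen coordinates (matched corner, or the model-predicted
        position for unmatched landmarks).
    matched
        (n,) bool, whether a detected corner was assigned.
    corner_index
        (n,) index into the corner set (-1 where unmatched).
    labels
        per-landmark vertebra name (pairs of landmarks share a label).
    """

    positions: np.ndarray
    matched: np.ndarray
    corner_index: np.ndarray
    labels: list[str]

    def vertebra(self, label: str) -> np.ndarray:
        sel = [i for i, l in enumerate(self.labels) if l == label]
        return self.positions[sel]


def build_curvature_model(samples: list) -> CurvatureModel:
    """Mean of Procrustes-aligned anterior-corner landmark sequences."""
    aligned, mean = shapemodel.procrustes_align_set(samples)
    return CurvatureModel(mean_shape=mean)


def two_point_similarity(src_a, src_b, dst_a, dst_b):
    """The unique orientation-preserving similarity mapping src_a -> dst_a
    and src_b -> dst_b exactly.  Returns a function on (n, 2) arrays."""
    src_a = np.asarray(src_a, dtype=float)
    src_b = np.asarray(src_b, dtype=float)
    dst_a = np.asarray(dst_a, dtype=float)
    dst_b = np.asarray(dst_b, dtype=float)
    zs = complex(*(src_b - src_a))
    if zs == 0:
        raise ValueError("source anchor points coincide")
    zd = complex(*(dst_b - dst_a))
    a = zd / zs

    def apply(points) -> np.ndarray:
        pts = as_shape(points)
        z = (pts[:, 0] - src_a[0]) + 1j * (pts[:, 1] - src_a[1])
        w = a * z
        return np.column_stack([w.real + dst_a[0], w.imag + dst_a[1]])

    return apply


def align_model_to_roi(model: CurvatureModel, clicks: RoiClicks) -> np.ndarray:
    """Place the mean curvature shape so its first landmark falls on the
    top click and its last on the bottom click, exactly."""
    f = two_point_similarity(model.mean_shape[0], model.mean_shape[-1], clicks.top, clicks.bottom)
    return f(model.mean_shape)


def _vertebra_labels(n_landmarks: int) -> list[str]:
    return [f"C{3 + i // 2}" for i in range(n_landmarks)]


def match_corners(
    positioned: np.ndarray,
    corners: CornerSet | np.ndarray,
    max_radius: float | None = None,
) -> VertebraAnchors:
    """Assign each positioned landmark its nearest detected corner.

    Landmarks are processed strictly top to bottom (their model order).
    A corner is a candidate only if it has not been used and its projection
    on the top-to-bottom axis is not above the last matched corner's, which
    enforces the monotone ordering.  Landmarks with no candidate within
    ``max_radius`` (default: a quarter of the landmark spacing along the
    axis) are flagged unmatched and keep their model-predicted position.
    """
    positioned = as_shape(positioned)
    pts = corners.corners if isinstance(corners, CornerSet) else np.asarray(corners, dtype=float)
    if len(pts) == 0:
        raise ValueError("empty corner set")
    n = len(positioned)
    axis = positioned[-1] - positioned[0]
    span = float(np.hypot(*axis))
    u = axis / span
    if max_radius is None:
        max_radius = 0.25 * span / n
    proj = pts @ u
    available = np.ones(len(pts), dtype=bool)
    min_proj = -np.inf
    positions = positioned.copy()
    matched = np.zeros(n, dtype=bool)
    corner_index = np.full(n, -1, dtype=int)
    for i in range(n):
        cand = available & (proj >= min_proj)
        if cand.any():
            d = np.hypot(*(pts[cand] - positioned[i]).T)
            j_local = int(np.argmin(d))
            if d[j_local] <= max_radius:
                j = np.flatnonzero(cand)[j_local]
                positions[i] = pts[j]
                matched[i] = True
                corner_index[i] = j
                available[j] = False
                min_proj = proj[j]
    return VertebraAnchors(
        positions=positions,
        matched=matched,
        corner_index=corner_index,
        labels=_vertebra_labels(n),
    )


def init_vertebra_shape(
    model: ShapeModel, upper_anterior, lower_anterior, anterior_indices: tuple[int, int] = (0, 9)
) -> np.ndarray:
    """Initial ASM shape for one vertebra: the mean vertebra shape carried
    by the two-point similarity that lands its anterior corner landmarks on
    the two matched anchors."""
    mean = model.mean_shape
    ia, ib = anterior_indices
    f = two_point_similarity(mean[ia], mean[ib], upper_anterior, lower_anterior)
    return f(mean)


def locate_vertebrae(
    model: CurvatureModel,
    clicks: RoiClicks,
    corners: CornerSet | np.ndarray,
    max_radius: float | None = None,
) -> VertebraAnchors:
    """Align the curvature model on the ROI clicks and match corners."""
    return match_corners(align_model_to_roi(model, clicks), corners, max_radius)
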