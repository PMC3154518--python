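"""Reading and writing images, landmark tables and corner files.

Images are 8- or 16-bit grayscale PNG/TIFF/PGM handled through imageio;
landmark training sets travel as CSV (shape_id, landmark_index, x, y) or
JSON; corner files are CSV with columns contour_id, x, y.  All coordinates
are 0-based with x = column and y = row, origin at the top-left.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .contours import CornerSet

__all__ = [
    "read_image",
    "write_image",
    "read_landmarks_csv",
    "write_landmarks_csv",
    "read_landmarks_json",
    "write_landmarks_json",
    "read_corners_csv",
    "write_corners_csv",
]


def read_image(path: str | Path) -> np.ndarray:
    """Load a grayscale image; RGB(A) input is averaged to one channel."""
    img = iio.imread(path)
    if img.ndim == 3:
        dtype = img.dtype
        img = img[..., :3].mean(axis=2).astype(dtype)
    if img.dtype not in (np.uint8, np.uint16):
        raise TypeError(f"unsupported image dtype {img.dtype}; expected uint8/uint16")
    return img


def write_image(path: str | Path, img: np.ndarray) -> None:
    iio.imwrite(path, np.asarray(img))


def write_landmarks_csv(path: str | Path, shapes: list[np.ndarray]) -> None:
    rows = [
        {"shape_id": si, "landmark_index": li, "x": p[0], "y": p[1]}
        for si, shape in enumerate(shapes)
        for li, p in enumerate(np.asarray(shape, dtype=float))
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_landmarks_csv(path: str | Path) -> list[np.ndarray]:
    df = pd.read_csv(path)
    shapes = []
    for _, grp in df.groupby("shape_id", sort=True):
        grp = grp.sort_values("landmark_index")
        shapes.append(grp[["x", "y"]].to_numpy(dtype=float))
    return shapes


def write_landmarks_json(path: str | Path, shapes: list[np.ndarray]) -> None:
    Path(path).write_text(json.dumps([np.asarray(s, dtype=float).tolist() for s in shapes]))


def read_landmarks_json(path: str | Path) -> list[np.ndarray]:
    return [np.array(s, dtype=float) for s in json.loads(Path(path).read_text())]


def write_corners_csv(path: str | Path, corners: CornerSet) -> None:
    pd.DataFrame(
        {
            "contour_id": corners.provenance,
            "x": corners.corners[:, 0],
            "y": corners.corners[:, 1],
        }
    ).to_csv(path, index=False)


def read_corners_csv(path: str | Path) -> CornerSet:
    df = pd.read_csv(path)
    return CornerSet(
        corners=df[["x", "y"]].to_numpy(dtype=float),
        provenance=df["contour_id"].to_numpy(dtype=int),
    )
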