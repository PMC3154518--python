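"""Edge-map contour tracing and corner detection by polygonal approximation.

A corner is defined geometrically: a point lying at the intersection of two
segment lines of a polygonal approximation of an edge contour.  Working on
gradient intensity directly (Harris-style detectors) performs poorly on
low-contrast radiographs, so the pipeline instead traces the binary Canny
edge map into ordered point chains and simplifies each chain with the
Douglas-Peucker recursion: the farthest point from the chord joining the
chain's extremities is kept (and recursed on) whenever its distance exceeds
epsilon, otherwise every point between the extremities is dropped.
Interior vertices of the simplified polylines whose turning angle is large
enough are emitted as corners.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Contour",
    "PolylineApprox",
    "CornerSet",
    "trace_contours",
    "douglas_peucker",
    "detect_corners",
    "point_segment_distances",
]


@dataclass(frozen=True)
class Contour:
    """Ordered 8-connected chain of edge pixels, (x, y) = (col, row)."""

    points: np.ndarray
    closed: bool = False

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class PolylineApprox:
    """Retained vertices of a contour after Douglas-Peucker at epsilon."""

    vertices: np.ndarray
    indices: np.ndarray  # positions of the vertices in the source contour
    epsilon: float
    closed: bool = False


@dataclass(frozen=True)
class CornerSet:
    """Detected corner coordinates with per-corner contour provenance."""

    corners: np.ndarray  # (m, 2) as (x, y)
    provenance: np.ndarray  # (m,) contour index

    def __len__(self) -> int:
        return len(self.corners)


_NEIGHBORS = [(-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1)]


def _junction_map(mask: np.ndarray) -> np.ndarray:
    """Pixels whose 8-neighborhood splits into >= 3 connected runs.

    A plain degree > 2 test misfires on staircase doubles (non-maxima
    suppression regularly leaves paired pixels along near-diagonal edges),
    which would break chains in the middle of smooth contours; counting
    0->1 transitions around the neighbor cycle flags only true branch
    points.
    """
    rows, cols = mask.shape
    p = np.pad(mask, 1)
    seqs = [p[1 + dr : rows + 1 + dr, 1 + dc : cols + 1 + dc] for dr, dc in _NEIGHBORS]
    trans = np.zeros(mask.shape, dtype=int)
    for i in range(8):
        trans += (~seqs[i]) & seqs[(i + 1) % 8]
    return mask & (trans >= 3)


def _merge_chains(
    chains: list[list[tuple[int, int]]], gap: float
) -> list[list[tuple[int, int]]]:
    """Join chains whose loose ends lie within ``gap`` pixels.

    Junction breaking and pixel doubling cut looped edges into fragments
    whose cut points sit next to each other; greedily splicing the closest
    end pair (nearest first, deterministic tie order) reconstructs the
    chain while leaving genuinely separate edges alone.
    """

    from scipy.spatial import cKDTree

    chains = [list(ch) for ch in chains]
    n = len(chains)
    if n < 2:
        return chains
    # two endpoint records per chain: (chain id, 0=start / 1=end)
    ends = np.array(
        [ch[0] for ch in chains] + [ch[-1] for ch in chains], dtype=float
    )
    owner = np.concatenate([np.arange(n), np.arange(n)])
    which = np.concatenate([np.zeros(n, int), np.ones(n, int)])
    tree = cKDTree(ends)
    cand = []
    for a, b in tree.query_pairs(gap):
        d = float(np.hypot(*(ends[a] - ends[b])))
        cand.append((d, min(a, b), max(a, b)))
    cand.sort()

    alive = np.ones(2 * n, dtype=bool)  # endpoint still exposed
    root = list(range(n))  # chain id -> current merged chain slot

    def find(i: int) -> int:
        while root[i] != i:
            root[i] = root[root[i]]
            i = root[i]
        return i

    # endpoint record -> (slot, side) kept consistent under merges
    end_slot = {e: (int(owner[e]), int(which[e])) for e in range(2 * n)}
    exposed: dict[int, list[int]] = {i: [i, i + n] for i in range(n)}

    for d, a, b in cand:
        if not (alive[a] and alive[b]):
            continue
        ca, cb = find(end_slot[a][0]), find(end_slot[b][0])
        if ca == cb:
            continue  # same chain: closure handled later
        sa = 0 if exposed[ca][0] == a else 1
        sb = 0 if exposed[cb][0] == b else 1
        A, B = chains[ca], chains[cb]
        if sa == 1 and sb == 0:
            A = A + B
        elif sa == 1 and sb == 1:
            A = A + B[::-1]
        elif sa == 0 and sb == 0:
            A = A[::-1] + B
        else:
            A = B + A
        alive[a] = alive[b] = False
        keep_a = exposed[ca][1 - sa]
        keep_b = exposed[cb][1 - sb]
        chains[ca] = A
        root[cb] = ca
        # the merged chain's exposed ends are the two untouched ones
        new_start, new_end = (keep_a, keep_b) if sa == 1 else (keep_b, keep_a)
        # orient records to the merged chain's actual start/end points
        if tuple(ends[new_start]) != tuple(map(float, A[0])):
            new_start, new_end = new_end, new_start
        exposed[ca] = [new_start, new_end]
        end_slot[new_start] = (ca, 0)
        end_slot[new_end] = (ca, 1)
    out = [chains[i] for i in range(n) if find(i) == i]
    return out


def trace_contours(
    edges,
    min_length: int = 1,
    thin: bool = False,
    closed_gap: int = 2,
    merge_gap: float = 3.0,
) -> list[Contour]:
    """Convert a boolean edge map into ordered 8-connected point chains.

    Moore-style following with visited marking: open chains start at
    endpoint pixels (at most one edge neighbor) and grow greedily in both
    directions; junction pixels (neighborhood splitting into three or more
    runs) break chains.  Fragments whose loose ends meet within
    ``merge_gap`` pixels are spliced back together (junction cuts land on
    looped edges, often exactly at the corners to be detected later), and
    a chain whose own ends meet within ``closed_gap`` pixels (Chebyshev)
    counts as closed (first point repeated at the end).  Chains shorter
    than ``min_length`` are discarded.  Every edge pixel belongs to at
    most one contour.

    ``thin=True`` first reduces the mask to a one-pixel skeleton
    (morphological thinning); usually unnecessary since the junction rule
    tolerates staircase doubles, and thinning can nibble corner apexes.
    """
    mask = np.asarray(getattr(edges, "mask", edges), dtype=bool)
    if thin:
        from skimage.morphology import thin as _thin

        mask = _thin(mask)
    rows, cols = mask.shape
    padded = np.pad(mask, 1)
    # neighbor degree of each edge pixel
    deg = np.zeros(mask.shape, dtype=int)
    for dr, dc in _NEIGHBORS:
        deg += padded[1 + dr : rows + 1 + dr, 1 + dc : cols + 1 + dc]
    deg[~mask] = 0
    junction = _junction_map(mask)

    visited = np.zeros_like(mask)

    def extend(r: int, c: int) -> list[tuple[int, int]]:
        """Greedy one-direction walk from (r, c), excluding the seed."""
        path: list[tuple[int, int]] = []
        while True:
            nxt = None
            for dr, dc in _NEIGHBORS:
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols and mask[rr, cc] and not visited[rr, cc]:
                    nxt = (rr, cc)
                    break
            if nxt is None:
                return path
            r, c = nxt
            path.append(nxt)
            visited[r, c] = True
            if junction[r, c]:  # junctions terminate chains
                return path

    def walk(r: int, c: int) -> list[tuple[int, int]]:
        # both directions from the seed, so a chain never breaks at the
        # (arbitrary) pixel the traversal happened to start from
        visited[r, c] = True
        fwd = extend(r, c)
        bwd = extend(r, c)
        return bwd[::-1] + [(r, c)] + fwd

    raw: list[list[tuple[int, int]]] = []
    # pass 1: open chains from endpoint pixels
    for r, c in np.argwhere(mask & (deg <= 1)):
        if not visited[r, c]:
            raw.append(walk(int(r), int(c)))
    # pass 2: remaining pixels lie on cycles or junction-cut fragments
    for r, c in np.argwhere(mask & ~visited & ~junction):
        if not visited[r, c]:
            raw.append(walk(int(r), int(c)))
    # junction pixels not swallowed by any walk
    for r, c in np.argwhere(junction & ~visited):
        raw.append([(int(r), int(c))])
        visited[r, c] = True

    if merge_gap > 0:
        raw = _merge_chains(raw, merge_gap)

    contours: list[Contour] = []
    for chain in raw:
        if len(chain) < min_length:
            continue
        endd = max(abs(chain[0][0] - chain[-1][0]), abs(chain[0][1] - chain[-1][1]))
        # long loops may lose a few pixels to junction cuts; allow the end
        # gap to grow with chain length (capped) before declaring them open
        gap_allow = max(float(closed_gap), min(merge_gap + 0.04 * len(chain), 3.0 * merge_gap))
        closed = (
            len(chain) > 2
            and endd >= 1
            and (endd <= closed_gap or np.hypot(*(np.subtract(chain[0], chain[-1]))) <= gap_allow)
        )
        pts = np.array(chain, dtype=float)[:, ::-1]  # (row, col) -> (x, y)
        if closed:
            pts = np.vstack([pts, pts[:1]])
        contours.append(Contour(points=pts, closed=closed))
    return contours


def point_segment_distances(points: np.ndarray, e1: np.ndarray, e2: np.ndarray) -> np.ndarray:
    """Distance of each point to the line through e1 and e2.

    Falls back to the Euclidean distance to e1 when the extremities
    coincide.
    """
    points = np.atleast_2d(points)
    d = e2 - e1
    norm = np.hypot(*d)
    if norm == 0:
        return np.hypot(*(points - e1).T)
    rel = points - e1
    return np.abs(d[0] * rel[:, 1] - d[1] * rel[:, 0]) / norm


def _dp_open(points: np.ndarray, epsilon: float) -> list[int]:
    """Iterative Douglas-Peucker on an open polyline; returns kept indices."""
    n = len(points)
    keep = np.zeros(n, dtype=bool)
    keep[0] = keep[-1] = True
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if j - i < 2:  # no point between the extremities: not reducible
            continue
        seg = points[i + 1 : j]
        dists = point_segment_distances(seg, points[i], points[j])
        a = int(np.argmax(dists))  # ties: lowest index wins
        if dists[a] > epsilon:
            k = i + 1 + a
            keep[k] = True
            stack.append((i, k))
            stack.append((k, j))
    return list(np.flatnonzero(keep))


def douglas_peucker(contour: Contour | np.ndarray, epsilon: float) -> PolylineApprox:
    """Polygonal approximation by the recursive farthest-point rule.

    Open contours use the recursion directly.  Closed contours (the rule is
    stated for open polylines only) are first split at their two mutually
    farthest points and each half is approximated independently.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if isinstance(contour, Contour):
        pts = contour.points
        closed = contour.closed
    else:
        pts = np.asarray(contour, dtype=float)
        closed = False
    if closed and len(pts) > 1 and np.array_equal(pts[0], pts[-1]):
        pts = pts[:-1]
    if len(pts) < 2:
        raise ValueError("contour must have at least 2 points")

    if not closed or len(pts) < 4:
        idx = _dp_open(pts, epsilon)
    else:
        # mutually farthest pair (chunked O(n^2) pairwise distances)
        best = (-1.0, 0, 1)
        for i0 in range(0, len(pts), 512):
            block = pts[i0 : i0 + 512]
            d2 = ((block[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
            k = int(np.argmax(d2))
            bi, bj = divmod(k, len(pts))
            if d2[bi, bj] > best[0]:
                best = (d2[bi, bj], i0 + bi, bj)
        i, j = sorted(best[1:])
        half1 = pts[i : j + 1]
        half2 = np.vstack([pts[j:], pts[: i + 1]])
        keep1 = [i + k for k in _dp_open(half1, epsilon)]
        keep2 = [(j + k) % len(pts) for k in _dp_open(half2, epsilon)]
        idx = sorted(set(keep1) | set(keep2))
    idx_arr = np.array(idx, dtype=int)
    return PolylineApprox(vertices=pts[idx_arr], indices=idx_arr, epsilon=float(epsilon), closed=closed)


def _turning_angles(vertices: np.ndarray, closed: bool) -> tuple[np.ndarray, np.ndarray]:
    """Turning angle (deg, 0 = straight) at each interior vertex."""
    v = vertices
    if closed:
        prev = np.roll(v, 1, axis=0)
        nxt = np.roll(v, -1, axis=0)
        idx = np.arange(len(v))
    else:
        if len(v) < 3:
            return np.array([], dtype=int), np.array([])
        prev, nxt = v[:-2], v[2:]
        v = v[1:-1]
        idx = np.arange(1, len(vertices) - 1)
    d1 = v - prev
    d2 = nxt - v
    ang = np.abs(
        np.rad2deg(
            np.arctan2(d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0], (d1 * d2).sum(axis=1))
        )
    )
    return idx, ang


def detect_corners(
    contours: list[Contour],
    epsilon: float = 4.0,
    min_angle: float = 30.0,
    max_angle: float = 150.0,
) -> CornerSet:
    """Corners = interior polygonal-approximation vertices with a real bend.

    Each contour is simplified at ``epsilon``; interior vertices whose
    turning angle falls within [min_angle, max_angle] degrees are emitted
    (near-collinear vertices and hairpin reversals are dropped).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    corners: list[np.ndarray] = []
    prov: list[int] = []
    for ci, contour in enumerate(contours):
        if len(contour.points) < 3:
            continue
        approx = douglas_peucker(contour, epsilon)
        idx, ang = _turning_angles(approx.vertices, approx.closed)
        for k in range(len(idx)):
            if min_angle <= ang[k] <= max_angle:
                corners.append(approx.vertices[idx[k]])
                prov.append(ci)
    if corners:
        return CornerSet(corners=np.array(corners), provenance=np.array(prov))
    return CornerSet(corners=np.empty((0, 2)), provenance=np.empty((0,), dtype=int))
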