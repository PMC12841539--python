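"""Convexity-defect detection and contour cutting (the fine-optimization stage).

A cluster of touching convex kernels binarizes into one blob whose contour
pinches inward at each adhesion neck. Those pinch points are exactly the deep
defects of the contour relative to its convex hull: for a hull edge AB and a
contour point C on the arc it subtends, the defect depth is the distance from
C to the line AB,

    depth = |cross(AB, AC)| / ||AB||.

Necks between kernels produce defects deeper than ~8 px, while surface
wrinkles stay much shallower, so cutting the blob between paired deep-defect
points separates the kernels without disturbing genuine boundaries.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import line as _draw_line

__all__ = [
    "trace_boundary",
    "convex_hull",
    "defect_depth",
    "ConvexityDefect",
    "find_defects",
    "split_at_defects",
    "polygon_pixel_area",
    "count_objects",
    "DEFAULT_DEPTH_THRESHOLD",
]

logger = logging.getLogger(__name__)

#: Minimum convexity-defect depth (px) treated as a true adhesion point.
DEFAULT_DEPTH_THRESHOLD = 8.0

_EIGHT = np.ones((3, 3), dtype=bool)

# Moore neighborhood in clockwise order starting east, as (dr, dc)
_MOORE = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]


def trace_boundary(mask: np.ndarray) -> np.ndarray:
    """Ordered closed outer boundary of the first 8-connected region in a mask.

    Moore-neighbor border following with Jacob's stopping criterion, starting
    from the topmost-leftmost foreground pixel. Returns an (N, 2) array of
    (row, col) pixel coordinates; a single isolated pixel yields one point.
    """
    mask = np.asarray(mask, dtype=bool)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("mask is empty")
    start = (int(rows[0]), int(cols[0]))  # topmost, then leftmost
    h, w = mask.shape

    def fg(r, c):
        return 0 <= r < h and 0 <= c < w and mask[r, c]

    dir_index = {off: i for i, off in enumerate(_MOORE)}
    contour = [start]
    cur = start
    back = 4  # backtrack points west of start (background by raster-scan order)
    max_steps = 4 * rows.size + 8
    for _ in range(max_steps):
        nxt = None
        for k in range(1, 9):
            d = (back + k) % 8
            r, c = cur[0] + _MOORE[d][0], cur[1] + _MOORE[d][1]
            if fg(r, c):
                # backtrack of the new pixel: the background neighbor scanned
                # just before it, re-expressed relative to the new pixel
                pd = (back + k - 1) % 8
                br = cur[0] + _MOORE[pd][0] - r
                bc = cur[1] + _MOORE[pd][1] - c
                nxt, back = (r, c), dir_index[(br, bc)]
                break
        if nxt is None:  # isolated pixel
            break
        if nxt == start and back == 4:
            break  # Jacob's criterion: start re-entered in the initial state
        contour.append(nxt)
        cur = nxt
    else:
        # safety: trim to the first return to start
        for i in range(1, len(contour)):
            if contour[i] == start:
                contour = contour[:i]
                break
    return np.asarray(contour, dtype=np.int64)


def convex_hull(points: np.ndarray) -> np.ndarray:
    """Convex hull of 2-D points by Andrew's monotone chain.

    Returns hull vertices (a subset of the input points) in counter-clockwise
    order with respect to (x=col, y=row) axes. Raises on fewer than 3
    non-collinear points.
    """
    pts = np.unique(np.asarray(points, dtype=np.float64), axis=0)
    if pts.shape[0] < 3:
        raise ValueError("need at least 3 distinct points for a convex hull")
    # sort by (row, col); cross product in (row, col) plane
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]

    def cross(o, a, b):
        return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])

    lower: list[np.ndarray] = []
    for p in pts:
        while len(lower) >= 2 and cross(lower[-2], lower[-1], p) <= 0:
            lower.pop()
        lower.append(p)
    upper: list[np.ndarray] = []
    for p in pts[::-1]:
        while len(upper) >= 2 and cross(upper[-2], upper[-1], p) <= 0:
            upper.pop()
        upper.append(p)
    hull = np.asarray(lower[:-1] + upper[:-1])
    if hull.shape[0] < 3:
        raise ValueError("points are collinear; hull is degenerate")
    return hull


def defect_depth(a, b, c) -> float:
    """Distance from point ``c`` to the line through ``a`` and ``b``.

    ``|cross(AB, AC)| / ||AB||`` — the depth of a convexity defect whose hull
    edge is AB and whose farthest contour point is C.
    """
    ax, ay = float(a[0]), float(a[1])
    bx, by = float(b[0]), float(b[1])
    cx, cy = float(c[0]), float(c[1])
    if ax == bx and ay == by:
        raise ValueError("hull edge endpoints coincide")
    area = abs((bx - ax) * (cy - ay) - (by - ay) * (cx - ax))
    return area / math.hypot(bx - ax, by - ay)


@dataclass(frozen=True)
class ConvexityDefect:
    """One defect: hull edge (start, end), its deepest contour point, depth in px."""

    hull_start: tuple[int, int]
    hull_end: tuple[int, int]
    farthest_point: tuple[int, int]
    depth: float


def find_defects(
    contour: np.ndarray, depth_threshold: float = DEFAULT_DEPTH_THRESHOLD
) -> list[ConvexityDefect]:
    """Convexity defects of a closed contour, deepest first.

    For every hull edge, the contour point of maximal depth on the arc the
    edge subtends is a candidate; only candidates at least
    ``depth_threshold`` px deep are returned.
    """
    if depth_threshold <= 0:
        raise ValueError("depth_threshold must be positive")
    contour = np.asarray(contour)
    if contour.shape[0] < 4:
        return []
    try:
        hull = convex_hull(contour)
    except ValueError:
        return []
    # map hull vertices to their first index along the contour
    index_of: dict[tuple[int, int], int] = {}
    for i, p in enumerate(map(tuple, contour.tolist())):
        if p not in index_of:
            index_of[p] = i
    hull_idx = sorted(index_of[tuple(map(int, v))] for v in hull.tolist()
                      if tuple(map(int, v)) in index_of)
    if len(hull_idx) < 2:
        return []
    n = contour.shape[0]
    defects: list[ConvexityDefect] = []
    for k, i in enumerate(hull_idx):
        j = hull_idx[(k + 1) % len(hull_idx)]
        a, b = contour[i], contour[j]
        if (a == b).all():
            continue
        arc = np.arange(i + 1, j) if j > i else np.concatenate(
            [np.arange(i + 1, n), np.arange(0, j)]
        )
        if arc.size == 0:
            continue
        pts = contour[arc].astype(np.float64)
        ab = b.astype(np.float64) - a
        cross = np.abs(
            ab[0] * (pts[:, 1] - a[1]) - ab[1] * (pts[:, 0] - a[0])
        )
        depths = cross / math.hypot(ab[0], ab[1])
        # one hull edge can subtend several necks (e.g. a chain of kernels
        # whose outer tangent is a single edge): report the deepest point of
        # every contiguous above-threshold run, not just the global maximum
        idx = np.flatnonzero(depths >= depth_threshold)
        if idx.size == 0:
            continue
        for run in np.split(idx, np.flatnonzero(np.diff(idx) > 1) + 1):
            m = int(run[np.argmax(depths[run])])
            defects.append(
                ConvexityDefect(
                    hull_start=(int(a[0]), int(a[1])),
                    hull_end=(int(b[0]), int(b[1])),
                    farthest_point=(int(contour[arc[m]][0]), int(contour[arc[m]][1])),
                    depth=float(depths[m]),
                )
            )
    defects.sort(key=lambda d: -d.depth)
    return defects


def _line4(p: tuple[int, int], q: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """4-connected digital segment from p to q.

    Diagonal Bresenham steps get an intermediate axial pixel inserted: an
    8-connected line cannot disconnect an 8-connected region (pieces stay
    diagonally adjacent across it), a 4-connected one can.
    """
    rr, cc = _draw_line(p[0], p[1], q[0], q[1])
    out_r, out_c = [rr[0]], [cc[0]]
    for k in range(1, rr.size):
        if rr[k] != rr[k - 1] and cc[k] != cc[k - 1]:
            out_r.append(rr[k])
            out_c.append(cc[k - 1])
        out_r.append(rr[k])
        out_c.append(cc[k])
    return np.asarray(out_r), np.asarray(out_c)


def _segment_inside(mask: np.ndarray, p: tuple[int, int], q: tuple[int, int]) -> bool:
    rr, cc = _line4(p, q)
    return bool(mask[rr, cc].all())


def _cut_segment(mask: np.ndarray, p: tuple[int, int], q: tuple[int, int]) -> None:
    rr, cc = _line4(p, q)
    mask[rr, cc] = False


def _fallback_cut(mask: np.ndarray, defect: ConvexityDefect) -> bool:
    """Cut from the defect point along its depth direction to the boundary.

    The depth direction points from the hull edge through the farthest point;
    marching that ray from the defect point crosses the blob to the opposite
    boundary. Returns False if no interior ray exists.
    """
    a = np.asarray(defect.hull_start, dtype=np.float64)
    b = np.asarray(defect.hull_end, dtype=np.float64)
    c = np.asarray(defect.farthest_point, dtype=np.float64)
    ab = b - a
    norm = math.hypot(ab[0], ab[1])
    if norm == 0:
        return False
    # unit normal of AB oriented from the edge toward C
    n1 = np.array([-ab[1], ab[0]]) / norm
    if np.dot(c - a, n1) < 0:
        n1 = -n1
    h, w = mask.shape
    pos = c.copy()
    path = []
    for _ in range(h + w):
        pos = pos + n1
        r, cl = int(round(pos[0])), int(round(pos[1]))
        if not (0 <= r < h and 0 <= cl < w) or not mask[r, cl]:
            break
        path.append((r, cl))
    if not path:
        return False
    _cut_segment(mask, defect.farthest_point, path[-1])
    # extend one pixel past the far end so the cut reaches background
    return True


def split_at_defects(
    mask: np.ndarray,
    depth_threshold: float = DEFAULT_DEPTH_THRESHOLD,
    max_iter: int = 10,
    pair_distance_floor: float = 3.0,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Iteratively cut a blob at its convexity defects until none remain deep.

    Each iteration re-traces every 8-connected region of the working mask,
    finds the deepest remaining defect, pairs it with the nearest other
    defect point of the same region whose connecting segment stays inside the
    foreground (a 1-px-wide cut is drawn between them), and falls back to a
    cut along the defect's depth direction when no partner exists. Stops when
    no defect reaches ``depth_threshold`` or after ``max_iter`` cuts (then a
    warning is logged and the mask is returned as cut so far).

    Returns the cut mask and the list of final region contours.
    """
    work = np.asarray(mask, dtype=bool).copy()
    for _ in range(max_iter):
        regions, n = ndimage.label(work, structure=_EIGHT)
        deepest: ConvexityDefect | None = None
        deepest_region = 0
        region_defects: dict[int, list[ConvexityDefect]] = {}
        slices = ndimage.find_objects(regions)
        for lab in range(1, n + 1):
            sl = slices[lab - 1]
            sub = regions[sl] == lab
            contour = trace_boundary(sub)
            contour[:, 0] += sl[0].start
            contour[:, 1] += sl[1].start
            defs = find_defects(contour, depth_threshold)
            if defs:
                region_defects[lab] = defs
                if deepest is None or defs[0].depth > deepest.depth:
                    deepest = defs[0]
                    deepest_region = lab
        if deepest is None:
            break
        partners = [
            d for d in region_defects[deepest_region]
            if d.farthest_point != deepest.farthest_point
        ]
        partners.sort(
            key=lambda d: math.dist(d.farthest_point, deepest.farthest_point)
        )
        cut_done = False
        for cand in partners:
            if math.dist(cand.farthest_point, deepest.farthest_point) < pair_distance_floor:
                continue
            if _segment_inside(work, deepest.farthest_point, cand.farthest_point):
                _cut_segment(work, deepest.farthest_point, cand.farthest_point)
                cut_done = True
                break
        if not cut_done:
            cut_done = _fallback_cut(work, deepest)
        if not cut_done:
            break
    else:
        logger.warning(
            "split_at_defects hit the iteration cap (%d); deep defects may remain",
            max_iter,
        )
    regions, n = ndimage.label(work, structure=_EIGHT)
    contours = []
    slices = ndimage.find_objects(regions)
    for lab in range(1, n + 1):
        sl = slices[lab - 1]
        sub = regions[sl] == lab
        contour = trace_boundary(sub)
        contour[:, 0] += sl[0].start
        contour[:, 1] += sl[1].start
        contours.append(contour)
    return work, contours


def polygon_pixel_area(contour: np.ndarray) -> float:
    """Digital area enclosed by (and including) a pixel-boundary polygon.

    Shoelace area of the pixel-center polygon plus half the boundary length
    plus one (Pick's theorem), matching the enclosed-pixel count for simple
    digital regions.
    """
    contour = np.asarray(contour, dtype=np.float64)
    if contour.shape[0] < 3:
        return float(contour.shape[0])
    x, y = contour[:, 1], contour[:, 0]
    shoelace = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    b = np.unique(contour, axis=0).shape[0]
    return shoelace + b / 2.0 + 1.0


def count_objects(contours: list[np.ndarray], min_area: float = 0.0) -> int:
    """Number of contours enclosing at least ``min_area`` pixels."""
    if min_area < 0:
        raise ValueError("min_area must be non-negative")
    return sum(1 for c in contours if polygon_pixel_area(c) >= min_area)
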