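"""Geometry kernel for closed 2D drawing contours.

Contours live in screen coordinates (y axis pointing down) and are stored
as an ordered circular list of points, first point not repeated.  All
cross-shape analyses operate on contours resampled to a common point
count (:data:`STANDARD_N`, 360 by default) with equal arc spacing.

Orientation is normalized at construction so that traversal is clockwise
on screen, i.e. the signed shoelace area of the stored order (computed
with the mathematical y-up formula) is negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import LineString, Polygon

__all__ = [
    "STANDARD_N",
    "ClosedContour",
    "ContourSegment",
    "resample_contour",
    "perimeter",
    "area",
    "signed_area",
    "leftmost_start_index",
    "straight_fraction",
    "turning_angles",
    "cut_part",
    "self_intersects",
]

#: Standard resampling count used by every cross-shape analysis.
STANDARD_N = 360

StrokeMeta = list[tuple[str, int]]  # runs of ("freehand"|"straight", start index)

_MODES = ("freehand", "straight")


@dataclass(frozen=True)
class ClosedContour:
    """A simple closed polygonal contour in y-down screen coordinates.

    Parameters
    ----------
    points
        Array of shape (n, 2), n >= 3; the closing edge from the last
        point back to the first is implicit.
    stroke_meta
        Optional run-length encoding of the drawing mode of each edge:
        ``[(mode, start_index), ...]`` with mode ``"freehand"`` or
        ``"straight"``; run *k* covers edges ``start_k .. start_{k+1}-1``.
    shape_id, category
        Optional bookkeeping carried through dataset I/O.
    """

    points: np.ndarray
    stroke_meta: Optional[StrokeMeta] = None
    shape_id: Optional[str] = None
    category: Optional[int] = None

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
            raise ValueError("a closed contour needs an (n, 2) array with n >= 3")
        if not np.all(np.isfinite(pts)):
            raise ValueError("contour coordinates must be finite")
        meta = self.stroke_meta
        if _shoelace(pts) > 0:  # enforce clockwise-on-screen storage
            pts = pts[::-1].copy()
            if meta is not None:
                meta = _reverse_stroke_meta(meta, len(pts))
        pts = np.ascontiguousarray(pts)
        pts.setflags(write=False)
        object.__setattr__(self, "points", pts)
        if meta is not None:
            meta = _normalize_stroke_meta(meta, len(pts))
        object.__setattr__(self, "stroke_meta", meta)

    @property
    def n(self) -> int:
        return len(self.points)

    def with_meta(self, **kw) -> "ClosedContour":
        return replace(self, **kw)

    def edge_modes(self) -> Optional[np.ndarray]:
        """Per-edge drawing mode as an array of ``"freehand"``/``"straight"``."""
        if self.stroke_meta is None:
            return None
        modes = np.empty(self.n, dtype=object)
        runs = self.stroke_meta
        for k, (mode, start) in enumerate(runs):
            stop = runs[k + 1][1] if k + 1 < len(runs) else self.n + runs[0][1]
            for i in range(start, stop):
                modes[i % self.n] = mode
        if any(m is None for m in modes):  # partial meta: default freehand
            modes = np.array([m if m is not None else "freehand" for m in modes],
                             dtype=object)
        return modes

    def polygon(self) -> Polygon:
        return Polygon(self.points)


@dataclass(frozen=True)
class ContourSegment:
    """Half-open circular index range ``start .. start+length-1`` (mod n)."""

    contour: ClosedContour
    start: int
    length: int

    def __post_init__(self) -> None:
        n = self.contour.n
        if not (1 <= self.length <= n):
            raise ValueError(f"segment length {self.length} outside 1..{n}")
        object.__setattr__(self, "start", int(self.start) % n)
        object.__setattr__(self, "length", int(self.length))

    def indices(self) -> np.ndarray:
        return (self.start + np.arange(self.length)) % self.contour.n

    def points(self) -> np.ndarray:
        return self.contour.points[self.indices()]

    def contains_index(self, i: int) -> bool:
        return (int(i) - self.start) % self.contour.n < self.length

    @property
    def end(self) -> int:
        """Index one past the last point (mod n)."""
        return (self.start + self.length) % self.contour.n

    def median_index(self) -> int:
        """Circular median point: half the arc length, rounded to lower index."""
        return (self.start + (self.length - 1) // 2) % self.contour.n

    def arc_length(self) -> float:
        pts = self.points()
        if len(pts) < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))

    def part_polygon(self) -> Polygon:
        """Polygon of the segment's points closed by the chord to its far end."""
        idx = np.append(self.indices(), self.end)
        return Polygon(self.contour.points[idx])

    def overlaps(self, other: "ContourSegment") -> bool:
        a = set(self.indices().tolist())
        return bool(a.intersection(other.indices().tolist()))


# ---------------------------------------------------------------------------
# basic measures

def _shoelace(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def signed_area(contour: ClosedContour) -> float:
    """Signed shoelace area under the mathematical y-up convention."""
    return _shoelace(contour.points)


def perimeter(contour: ClosedContour) -> float:
    """Total edge length including the closing edge."""
    pts = contour.points
    d = pts - np.roll(pts, -1, axis=0)
    return float(np.sum(np.hypot(d[:, 0], d[:, 1])))


def area(contour: ClosedContour) -> float:
    """Absolute enclosed area; raises on self-intersecting input."""
    if self_intersects(contour):
        raise ValueError("area is undefined for a self-intersecting contour")
    return abs(_shoelace(contour.points))


def leftmost_start_index(contour: ClosedContour) -> int:
    """Index of the minimum-x point; ties by minimum y, then lowest index."""
    pts = contour.points
    order = np.lexsort((np.arange(len(pts)), pts[:, 1], pts[:, 0]))
    return int(order[0])


# ---------------------------------------------------------------------------
# resampling

def _cumulative_arc(pts: np.ndarray) -> np.ndarray:
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def resample_contour(contour: ClosedContour, n_points: int) -> ClosedContour:
    """Resample to exactly ``n_points`` equally spaced along the arc.

    The first output point is the original point 0; stroke metadata, if
    present, is carried over by arc position.
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    pts = contour.points
    cum = _cumulative_arc(pts)
    total = cum[-1]
    if total <= 0:
        raise ValueError("cannot resample a degenerate (zero-perimeter) contour")
    targets = np.arange(n_points) * (total / n_points)
    closed = np.vstack([pts, pts[:1]])
    x = np.interp(targets, cum, closed[:, 0])
    y = np.interp(targets, cum, closed[:, 1])
    new_pts = np.column_stack([x, y])
    meta = None
    if contour.stroke_meta is not None:
        modes = contour.edge_modes()
        # mode of each new edge = mode of the original edge under its midpoint
        mids = (targets + total / (2 * n_points)) % total
        orig_edge = np.clip(np.searchsorted(cum, mids, side="right") - 1,
                            0, len(pts) - 1)
        new_modes = [modes[i] for i in orig_edge]
        meta = _encode_runs(new_modes)
    return ClosedContour(new_pts, stroke_meta=meta,
                         shape_id=contour.shape_id, category=contour.category)


# ---------------------------------------------------------------------------
# straightness

def turning_angles(contour: ClosedContour) -> np.ndarray:
    """Absolute exterior turning angle (radians) at each vertex."""
    pts = contour.points
    v1 = pts - np.roll(pts, 1, axis=0)
    v2 = np.roll(pts, -1, axis=0) - pts
    ang1 = np.arctan2(v1[:, 1], v1[:, 0])
    ang2 = np.arctan2(v2[:, 1], v2[:, 0])
    turn = np.angle(np.exp(1j * (ang2 - ang1)))
    return np.abs(turn)


def straight_fraction(contour: ClosedContour, *, window: int = 1,
                      threshold_deg: float = 1.0,
                      use_stroke_meta: bool = True) -> float:
    """Fraction of the contour drawn with straight lines.

    When stroke metadata is present (and ``use_stroke_meta``), the fraction
    is the arc length of straight-mode edges over the perimeter.  Otherwise
    a geometric classifier is used: vertex *i* counts as straight when the
    total absolute turning angle over vertices ``i-window .. i+window``
    stays below ``threshold_deg`` degrees per vertex, and the fraction is
    straight vertices over all vertices.
    """
    if use_stroke_meta and contour.stroke_meta is not None:
        modes = contour.edge_modes()
        pts = contour.points
        d = np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1)
        total = float(np.sum(d))
        straight = float(np.sum(d[[m == "straight" for m in modes]]))
        return straight / total if total > 0 else 0.0
    turn = turning_angles(contour)
    k = int(window)
    width = 2 * k + 1
    kernel_sum = sum(np.roll(turn, s) for s in range(-k, k + 1))
    # 0.1 deg guard band: resampling wobbles window sums by ~0.02 deg, so
    # constant curvature exactly at the threshold (a circle at 360 points
    # under the 1 deg/vertex default) must still count as curved
    thresh = np.deg2rad(threshold_deg) * width - np.deg2rad(0.1)
    return float(np.mean(kernel_sum < thresh))


# ---------------------------------------------------------------------------
# chord cuts and simplicity

def chord_inside(contour: ClosedContour, i: int, j: int,
                 *, tol: float = 1e-9) -> bool:
    """Whether the open chord between points i and j lies inside the polygon."""
    pts = contour.points
    p, q = pts[int(i) % contour.n], pts[int(j) % contour.n]
    d = q - p
    if np.hypot(*d) <= tol:
        return False
    eps = 1e-6
    inner = LineString([p + eps * d, q - eps * d])
    poly = contour.polygon()
    if not poly.is_valid:
        poly = poly.buffer(0)
    return bool(poly.buffer(tol).contains(inner))


def cut_part(contour: ClosedContour, i: int, j: int
             ) -> tuple[ContourSegment, ContourSegment]:
    """Split the contour along the interior chord i--j.

    Returns the two complementary circular segments (half-open at the far
    chord endpoint, so their lengths sum to n).  The chord must lie
    strictly inside the polygon except at its endpoints, mirroring the
    part-picking interface rule that the delineating line may not cross
    the shape.
    """
    n = contour.n
    i, j = int(i) % n, int(j) % n
    if i == j:
        raise ValueError("chord endpoints must differ")
    if not chord_inside(contour, i, j):
        raise ValueError(f"chord {i}-{j} does not lie inside the shape")
    len1 = (j - i) % n
    return (ContourSegment(contour, i, len1),
            ContourSegment(contour, j, n - len1))


def self_intersects(contour: ClosedContour) -> bool:
    """True iff any two non-adjacent edges of the closed contour intersect."""
    poly = Polygon(contour.points)
    return not poly.is_valid


# ---------------------------------------------------------------------------
# stroke-meta helpers

def _encode_runs(modes: Sequence[str]) -> StrokeMeta:
    runs: StrokeMeta = []
    for i, m in enumerate(modes):
        if not runs or runs[-1][0] != m:
            runs.append((str(m), i))
    if len(runs) > 1 and runs[0][0] == runs[-1][0]:
        pass  # circular merge is implicit: run boundaries only matter between runs
    return runs


def _normalize_stroke_meta(meta: StrokeMeta, n: int) -> StrokeMeta:
    runs = [(str(m), int(s) % n) for m, s in meta]
    for m, _ in runs:
        if m not in _MODES:
            raise ValueError(f"unknown stroke mode {m!r}")
    runs.sort(key=lambda r: r[1])
    return runs


def _reverse_stroke_meta(meta: StrokeMeta, n: int) -> StrokeMeta:
    """Stroke meta after reversing point order (edge e -> edge n-1-e)."""
    modes = np.empty(n, dtype=object)
    runs = _normalize_stroke_meta(meta, n)
    for k, (mode, start) in enumerate(runs):
        stop = runs[k + 1][1] if k + 1 < len(runs) else n + runs[0][1]
        for i in range(start, stop):
            modes[i % n] = mode
    modes = [m if m is not None else "freehand" for m in modes]
    # reversing points maps the edge between v_i and v_{i+1} to the edge
    # between new vertices n-1-i-1+... : edge i -> edge n-2-i (mod n)
    rev = [modes[(n - 2 - i) % n] for i in range(n)]
    return _encode_runs(rev)
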