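"""Geometry kernel: resampling, measures, chord cuts, straightness."""

import numpy as np
import pytest

from oneshotshapes.contour import (ClosedContour, area, cut_part,
                                   leftmost_start_index, perimeter,
                                   resample_contour, self_intersects,
                                   signed_area, straight_fraction)

from conftest import random_simple_polygon


class TestBasicMeasures:
    def test_perimeter_square_and_rectangle(self, square):
        assert perimeter(square) == pytest.approx(4.0)
        rect = ClosedContour(np.array([[0.0, 0], [2, 0], [2, 1], [0, 1]]))
        assert perimeter(rect) == pytest.approx(6.0)

    def test_perimeter_matches_edge_sum_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            c = random_simple_polygon(rng)
            pts = c.points
            # brute-force pairwise edge summation
            total = 0.0
            for i in range(len(pts)):
                total += float(np.hypot(*(pts[(i + 1) % len(pts)] - pts[i])))
            assert perimeter(c) == pytest.approx(total, abs=1e-12)

    def test_area_examples(self, square):
        assert area(square) == pytest.approx(1.0)
        tri = ClosedContour(np.array([[0.0, 0], [1, 0], [0, 1]]))
        assert area(tri) == pytest.approx(0.5)

    def test_area_monte_carlo_oracle(self):
        rng = np.random.default_rng(2)
        c = random_simple_polygon(rng, 15)
        pts = c.points
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        samples = rng.uniform(lo, hi, size=(200_000, 2))
        from shapely.geometry import Polygon
        from shapely import contains_xy
        poly = Polygon(pts)
        inside = contains_xy(poly, samples[:, 0], samples[:, 1])
        mc = inside.mean() * np.prod(hi - lo)
        assert area(c) == pytest.approx(mc, rel=0.01)

    def test_area_rejects_self_intersection(self):
        bow = ClosedContour(np.array([[0.0, 0], [1, 1], [1, 0], [0, 1]]))
        with pytest.raises(ValueError):
            area(bow)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        c = random_simple_polygon(rng)
        ang = 0.7
        rot = np.array([[np.cos(ang), -np.sin(ang)],
                        [np.sin(ang), np.cos(ang)]])
        moved = ClosedContour(c.points @ rot.T + np.array([5.0, -3.0]))
        assert perimeter(moved) == pytest.approx(perimeter(c), rel=1e-9)
        assert area(moved) == pytest.approx(area(c), rel=1e-9)

    def test_orientation_normalized_clockwise(self, square):
        # stored order must have negative shoelace area (y-up formula)
        assert signed_area(square) < 0


class TestLeftmostStart:
    def test_tie_broken_by_min_y(self, square):
        i = leftmost_start_index(square)
        assert tuple(square.points[i]) == (0.0, 0.0)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(4)
        c = random_simple_polygon(rng)
        i = leftmost_start_index(c)
        shifted = ClosedContour(c.points + np.array([100.0, -40.0]))
        assert leftmost_start_index(shifted) == i

    def test_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            c = random_simple_polygon(rng)
            best = 0
            for k in range(1, c.n):
                x, y = c.points[k]
                bx, by = c.points[best]
                if (x, y, k) < (bx, by, best):
                    best = k
            assert leftmost_start_index(c) == best


class TestResampling:
    def test_square_identity_case(self, square):
        r = resample_contour(square, 4)
        assert np.allclose(r.points, square.points)

    def test_equal_spacing_and_count(self, circle1000):
        # arc positions along the source contour must be k * P / n,
        # checked against a shapely line-projection oracle
        from shapely.geometry import LineString, Point

        r = resample_contour(circle1000, 360)
        assert r.n == 360
        closed = np.vstack([circle1000.points, circle1000.points[:1]])
        line = LineString(closed)
        pos = np.array([line.project(Point(p)) for p in r.points])
        expected = np.arange(360) * line.length / 360
        assert np.allclose(pos, expected, atol=1e-6 * line.length)
        assert perimeter(r) == pytest.approx(2 * np.pi, rel=1e-3)

    def test_idempotence(self):
        # exact for an already equally spaced input; approximate for
        # arbitrary polygons (chords near corners differ from arcs)
        th = np.arange(360) * 2 * np.pi / 360
        regular = ClosedContour(np.column_stack([np.cos(th), np.sin(th)]))
        again = resample_contour(regular, 360)
        assert np.allclose(again.points, regular.points, atol=1e-9)
        # square corners land exactly on sample points (arc multiples of
        # P/360), so re-resampling is also exact there
        square = ClosedContour(np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]]))
        once = resample_contour(square, 360)
        twice = resample_contour(once, 360)
        assert np.allclose(once.points, twice.points, atol=1e-9)

    def test_perimeter_preserved_on_smooth_shapes(self, circle1000):
        for n in (180, 360, 720):
            r = resample_contour(circle1000, n)
            assert perimeter(r) == pytest.approx(perimeter(circle1000),
                                                 rel=0.005)

    def test_degenerate_contour_rejected(self):
        degenerate = ClosedContour(np.zeros((3, 2)) + 1.0)
        with pytest.raises(ValueError):
            resample_contour(degenerate, 10)


class TestStraightFraction:
    def test_square_high(self, square):
        sq = resample_contour(square, 360)
        assert straight_fraction(sq) >= 0.95

    def test_circle_low(self, circle1000):
        c = resample_contour(circle1000, 360)
        assert straight_fraction(c) <= 0.05

    def test_stadium_matches_arc_share(self):
        # lower half: unit-diameter semicircle; upper edge + sides straight
        th = np.linspace(np.pi, 2 * np.pi, 200)
        arc = np.column_stack([0.5 + 0.5 * np.cos(th), 0.5 * np.sin(th)])
        top = np.array([[1.0, 0.0], [1.0, 0.7], [0.0, 0.7], [0.0, 0.0]])
        c = resample_contour(ClosedContour(np.vstack([arc[:-1], top])), 360)
        frac = straight_fraction(c)
        straight_len = 1.0 + 0.7 + 0.7
        expected = straight_len / (straight_len + np.pi * 0.5)
        assert frac == pytest.approx(expected, abs=0.1)

    def test_straightening_an_arc_raises_fraction(self, circle1000):
        c = resample_contour(circle1000, 360)
        pts = c.points.copy()
        # replace a quarter arc by its chord (a polyline)
        i0, i1 = 40, 130
        chord = np.linspace(pts[i0], pts[i1], i1 - i0 + 1)
        pts[i0:i1 + 1] = chord
        straightened = resample_contour(ClosedContour(pts), 360)
        assert straight_fraction(straightened) > straight_fraction(c)

    def test_stroke_meta_takes_precedence(self, square):
        sq = resample_contour(square.with_meta(stroke_meta=[("freehand", 0)]),
                              360)
        assert straight_fraction(sq) == 0.0
        assert straight_fraction(sq, use_stroke_meta=False) >= 0.95


class TestCutPart:
    def test_square_opposite_corners(self, square):
        s1, s2 = cut_part(square, 0, 2)
        assert s1.length == 2 and s2.length == 2
        assert sorted(np.concatenate([s1.indices(), s2.indices()])) == [0, 1, 2, 3]

    def test_concavity_chord_rejected(self):
        # U-shape: the chord between the two prong tips spans the notch
        # opening and exits the polygon, so the pick must be refused
        u = ClosedContour(np.array([
            [0.0, 0], [3, 0], [3, 3], [2, 3], [2, 1], [1, 1], [1, 3],
            [0, 3]], dtype=float))
        assert not self_intersects(u)
        tip_a = next(i for i, p in enumerate(u.points)
                     if tuple(p) == (1.0, 3.0))
        tip_b = next(i for i, p in enumerate(u.points)
                     if tuple(p) == (2.0, 3.0))
        with pytest.raises(ValueError):
            cut_part(u, tip_a, tip_b)
        # an interior chord on the same shape is accepted
        a = next(i for i, p in enumerate(u.points) if tuple(p) == (0.0, 0.0))
        b = next(i for i, p in enumerate(u.points) if tuple(p) == (1.0, 1.0))
        s1, s2 = cut_part(u, a, b)
        assert s1.length + s2.length == u.n

    def test_convex_polygon_chords_partition(self):
        rng = np.random.default_rng(7)
        th = np.sort(rng.uniform(0, 2 * np.pi, 12))
        c = ClosedContour(np.column_stack([np.cos(th), np.sin(th)]))
        for _ in range(20):
            i, j = rng.choice(c.n, size=2, replace=False)
            if (j - i) % c.n in (1, c.n - 1):
                continue  # adjacent: chord lies on the boundary
            s1, s2 = cut_part(c, int(i), int(j))
            assert s1.length + s2.length == c.n
            assert set(s1.indices()) | set(s2.indices()) == set(range(c.n))
            assert not set(s1.indices()) & set(s2.indices())

    def test_same_endpoint_rejected(self, square):
        with pytest.raises(ValueError):
            cut_part(square, 1, 1)


class TestSelfIntersects:
    def test_examples(self, square):
        assert not self_intersects(square)
        bow = ClosedContour(np.array([[0.0, 0], [1, 1], [1, 0], [0, 1]]))
        assert self_intersects(bow)

    def test_matches_brute_force_pairs_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            pts = rng.uniform(0, 1, size=(8, 2))
            c = None
            try:
                c = ClosedContour(pts)
            except ValueError:
                continue
            assert self_intersects(c) == _brute_force_intersects(c.points)


def _brute_force_intersects(pts: np.ndarray) -> bool:
    n = len(pts)
    edges = [(pts[i], pts[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if j == i or (j + 1) % n == i or (i + 1) % n == j:
                continue
            if _segments_cross(*edges[i], *edges[j]):
                return True
    return False


def _segments_cross(p1, p2, p3, p4) -> bool:
    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        return 0 if abs(v) < 1e-12 else (1 if v > 0 else -1)

    d1, d2 = orient(p3, p4, p1), orient(p3, p4, p2)
    d3, d4 = orient(p1, p2, p3), orient(p1, p2, p4)
    if d1 != d2 and d3 != d4:
        return True
    return False
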