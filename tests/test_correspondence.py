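"""Part circles, order relations, gap changes, correspondence fields."""

import itertools

import numpy as np
import pytest

from oneshotshapes.contour import ClosedContour, ContourSegment
from oneshotshapes.correspondence import (GAP, CorrespondencePair, PartCircle,
                                          PartPick, build_part_circle,
                                          classify_gap_changes,
                                          compare_part_order,
                                          corresponding_area_fraction,
                                          point_correspondence_field,
                                          regress_area_on_similarity)


def _ring(n=36, r=1.0):
    th = np.arange(n) * 2 * np.pi / n
    return ClosedContour(np.column_stack([r * np.cos(th), r * np.sin(th)]))


def _seg(contour, start, length):
    return ContourSegment(contour, start, length)


class TestPartCircle:
    def test_full_cover_three_parts(self):
        c = _ring(36)
        # traversal starts at the left-most point; cover the ring fully
        picks = [("A", _seg(c, 0, 12)), ("B", _seg(c, 12, 12)),
                 ("C", _seg(c, 24, 12))]
        circle = build_part_circle(c, picks)
        assert sorted(circle.entries) == ["A", "B", "C"]
        assert GAP not in circle.entries

    def test_gaps_between_parts(self):
        c = _ring(36)
        picks = [("A", _seg(c, 0, 8)), ("C", _seg(c, 18, 8))]
        circle = build_part_circle(c, picks)
        # scan oracle: per-point labels, run-length merged circularly
        assert set(circle.entries) == {"A", "C", GAP}
        assert len(circle.entries) == 4  # A, gap, C, gap in some rotation

    def test_no_picks_single_gap(self):
        circle = build_part_circle(_ring(12), [])
        assert circle.entries == (GAP,)

    def test_overlapping_picks_rejected(self):
        c = _ring(36)
        with pytest.raises(ValueError):
            build_part_circle(c, [("A", _seg(c, 0, 10)),
                                  ("B", _seg(c, 5, 10))])

    def test_matches_point_scan_oracle(self):
        rng = np.random.default_rng(4)
        c = _ring(60)
        for _ in range(25):
            starts = np.sort(rng.choice(60, size=3, replace=False))
            picks = []
            prev_end = None
            for k, s in enumerate(starts):
                nxt = starts[(k + 1) % 3]
                max_len = (nxt - s) % 60
                if max_len < 2:
                    continue
                length = int(rng.integers(1, max_len))
                picks.append((f"P{k}", _seg(c, int(s), length)))
            got = build_part_circle(c, picks)
            assert got.entries == _scan_oracle(c, picks)


def _scan_oracle(contour, picks):
    from oneshotshapes.contour import leftmost_start_index
    n = contour.n
    labels = [GAP] * n
    for lab, seg in picks:
        for i in seg.indices():
            labels[i] = lab
    start = leftmost_start_index(contour)
    seq = [labels[(start + k) % n] for k in range(n)]
    merged = [seq[0]]
    for v in seq[1:]:
        if v != merged[-1]:
            merged.append(v)
    if len(merged) > 1 and merged[0] == merged[-1]:
        merged.pop()
    return tuple(merged)


class TestCompareOrder:
    def test_rotation_is_identical(self):
        assert compare_part_order(PartCircle(("A", "B", "C")),
                                  PartCircle(("B", "C", "A"))) == "identical"

    def test_reversal(self):
        assert compare_part_order(PartCircle(("A", "B", "C")),
                                  PartCircle(("C", "B", "A"))) == "reversed"

    def test_shuffle(self):
        assert compare_part_order(PartCircle(("A", "B", "C", "D")),
                                  PartCircle(("A", "C", "B", "D"))) == "shuffled"

    def test_two_labels_undefined(self):
        assert compare_part_order(PartCircle(("A", "B")),
                                  PartCircle(("B", "A"))) == "undefined"

    def test_no_shared_labels(self):
        assert compare_part_order(
            PartCircle(("A",)), PartCircle(("Z",))) == "undefined_no_shared"

    def test_gaps_ignored(self):
        a = PartCircle(("A", GAP, "B", "C", GAP))
        b = PartCircle(("B", "C", GAP, "A"))
        assert compare_part_order(a, b) == "identical"

    def test_matches_exhaustive_cyclic_oracle(self):
        labels = ["A", "B", "C", "D"]
        base = PartCircle(tuple(labels))
        for perm in itertools.permutations(labels):
            got = compare_part_order(base, PartCircle(perm))
            rots = [list(perm[r:] + perm[:r]) for r in range(4)]
            if labels in rots:
                expect = "identical"
            elif labels[::-1] in rots:
                expect = "reversed"
            else:
                expect = "shuffled"
            assert got == expect

    def test_reverse_property_any_circle(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            k = int(rng.integers(3, 7))
            labels = tuple(f"L{i}" for i in range(k))
            rolled = tuple(np.roll(np.array(labels, dtype=object),
                                   int(rng.integers(k))))
            assert compare_part_order(PartCircle(labels),
                                      PartCircle(rolled[::-1])) == "reversed"
            assert compare_part_order(PartCircle(labels),
                                      PartCircle(rolled)) == "identical"


class TestGapChanges:
    def test_omission(self):
        e = PartCircle(("A", GAP, "B", "C"))
        v = PartCircle(("A", "B", "C"))
        changes = classify_gap_changes(e, v)
        assert [c.kind for c in changes] == ["omission"]
        assert changes[0].between == ("A", "B")

    def test_addition(self):
        e = PartCircle(("A", "B"))
        v = PartCircle(("A", GAP, "B"))
        assert [c.kind for c in classify_gap_changes(e, v)] == ["addition"]

    def test_substitution(self):
        e = PartCircle(("A", GAP, "B"))
        v = PartCircle(("A", GAP, "B"))
        kinds = [c.kind for c in classify_gap_changes(e, v)]
        assert kinds == ["substitution"]

    def test_exhaustive_interval_truth_table(self):
        # all 4 interval states between two shared labels
        expect = {(False, False): [], (True, False): ["omission"],
                  (False, True): ["addition"], (True, True): ["substitution"]}
        for gap_e, gap_v in expect:
            e = ("A",) + ((GAP,) if gap_e else ()) + ("B",)
            v = ("A",) + ((GAP,) if gap_v else ()) + ("B",)
            got = [c.kind for c in classify_gap_changes(PartCircle(e),
                                                        PartCircle(v))
                   if c.between == ("A", "B")]
            assert got == expect[(gap_e, gap_v)], (gap_e, gap_v)

    def test_requires_shared_label(self):
        with pytest.raises(ValueError):
            classify_gap_changes(PartCircle(("A",)), PartCircle(("B",)))


class TestCorrespondenceField:
    def test_single_pick_maps_to_median(self):
        ex, var = _ring(36), _ring(36)
        pair = CorrespondencePair(
            "t", "r0", "L",
            PartPick("ex", 6, 15),    # exemplar segment 6..15 (10 points)
            PartPick("v", 0, 9))
        target, support = point_correspondence_field(var, [pair], ex)
        med = ContourSegment(ex, 6, 10).median_index()
        assert med == 6 + (10 - 1) // 2
        assert (target[:10] == med).all()
        assert (support[:10] == 1).all()
        assert (target[10:] == -1).all()

    def test_two_identical_raters_support(self):
        ex, var = _ring(36), _ring(36)
        pairs = [CorrespondencePair("t", f"r{i}", "L",
                                    PartPick("ex", 0, 5), PartPick("v", 0, 5))
                 for i in range(2)]
        _, support = point_correspondence_field(var, pairs, ex)
        assert support[:6].tolist() == [2] * 6

    def test_modal_assignment_wins(self):
        ex, var = _ring(36), _ring(36)
        seg_a, seg_b = (0, 9), (18, 27)
        pairs = []
        for i in range(3):
            pairs.append(CorrespondencePair("t", f"a{i}", "L",
                                            PartPick("ex", *seg_a),
                                            PartPick("v", 0, 5)))
        for i in range(2):
            pairs.append(CorrespondencePair("t", f"b{i}", "L",
                                            PartPick("ex", *seg_b),
                                            PartPick("v", 0, 5)))
        target, support = point_correspondence_field(var, pairs, ex)
        expected_med = ContourSegment(ex, 0, 10).median_index()
        assert (target[:6] == expected_med).all()
        assert (support[:6] == 5).all()


class TestAreaFraction:
    def test_no_picks_zero(self):
        ex = _ring(36)
        assert corresponding_area_fraction(ex, []) == 0.0

    def test_rest_of_shape_full(self):
        ex = _ring(36)
        pair = CorrespondencePair("t", "r0", "L",
                                  PartPick("ex", rest=True),
                                  PartPick("v", rest=True))
        assert corresponding_area_fraction(ex, [pair]) == pytest.approx(1.0)

    def test_two_disjoint_picks_monte_carlo(self):
        rng = np.random.default_rng(6)
        ex = _ring(72)
        pairs = [CorrespondencePair("t", "r0", "L1",
                                    PartPick("ex", 0, 17), PartPick("v", 0, 17)),
                 CorrespondencePair("t", "r0", "L2",
                                    PartPick("ex", 30, 50), PartPick("v", 30, 50))]
        frac = corresponding_area_fraction(ex, pairs)
        # Monte-Carlo union-area oracle
        from shapely.geometry import Polygon
        from shapely import contains_xy
        poly = Polygon(ex.points)
        p1 = ContourSegment(ex, 0, 18).part_polygon()
        p2 = ContourSegment(ex, 30, 21).part_polygon()
        pts = rng.uniform(-1, 1, size=(300_000, 2))
        inside = contains_xy(poly, pts[:, 0], pts[:, 1])
        in_union = (contains_xy(p1, pts[:, 0], pts[:, 1])
                    | contains_xy(p2, pts[:, 0], pts[:, 1])) & inside
        mc = in_union.sum() / inside.sum()
        assert frac == pytest.approx(mc, abs=0.01)

    def test_monotone_in_picks(self):
        ex = _ring(36)
        p1 = [CorrespondencePair("t", "r0", "L1",
                                 PartPick("ex", 0, 8), PartPick("v", 0, 8))]
        p2 = p1 + [CorrespondencePair("t", "r0", "L2",
                                      PartPick("ex", 15, 25),
                                      PartPick("v", 15, 25))]
        assert corresponding_area_fraction(ex, p2) >= \
            corresponding_area_fraction(ex, p1)

    def test_regression_trivial_cases(self):
        mids = np.linspace(0.05, 0.95, 10)
        res = regress_area_on_similarity(1 - 0.5 * mids, mids)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(-0.5)
        flat = regress_area_on_similarity(np.full(10, 0.4), mids)
        assert flat.slope == pytest.approx(0.0, abs=1e-12)
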