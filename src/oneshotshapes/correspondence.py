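"""Part-correspondence analysis between exemplars and variations.

Raters delineate a part on the exemplar with an interior chord, pick the
polygon on one side of it, and then pick the corresponding part on the
variation.  From these paired picks we derive: a per-point correspondence
field (which exemplar point each variation point maps to, and how often),
the fraction of the exemplar's area seen as corresponding, cyclic "part
circles" of labelled parts and gaps, the order relation between two part
circles (identical / reversed / shuffled), and gap-change records
(omission / addition / substitution of parts).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from shapely.ops import unary_union

from .contour import ClosedContour, ContourSegment, leftmost_start_index
from .stats import TrendResult, ols

__all__ = [
    "GAP",
    "PartPick",
    "CorrespondencePair",
    "PartCircle",
    "GapChange",
    "point_correspondence_field",
    "corresponding_area_fraction",
    "regress_area_on_similarity",
    "build_part_circle",
    "compare_part_order",
    "classify_gap_changes",
]

#: Sentinel for a stretch of contour not assigned to any corresponding part.
GAP = "__GAP__"


@dataclass(frozen=True)
class PartPick:
    """One picked part: the segment from point ``i`` clockwise to ``j``.

    ``rest`` flags the special "rest of the shape" pick (everything not
    yet picked), which carries no chord.
    """

    shape_id: str
    i: int = 0
    j: int = 0
    rest: bool = False

    def segment(self, contour: ClosedContour) -> ContourSegment:
        if self.rest:
            raise ValueError("a rest-of-shape pick has no chord segment")
        n = contour.n
        length = (self.j - self.i) % n + 1
        return ContourSegment(contour, self.i, length)


@dataclass(frozen=True)
class CorrespondencePair:
    trial: str
    rater: str
    label: str
    exemplar_pick: PartPick
    variation_pick: PartPick


@dataclass(frozen=True)
class PartCircle:
    """Cyclic run-length-merged sequence of part labels and GAP markers,
    anchored at the shape's left-most point and read clockwise."""

    entries: tuple

    def labels(self) -> list:
        return [e for e in self.entries if e != GAP]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class GapChange:
    kind: str                 # "omission" | "addition" | "substitution"
    between: tuple            # (label before, label after) in exemplar order


# ---------------------------------------------------------------------------
# per-point aggregation

def point_correspondence_field(
        variation: ClosedContour,
        pairs: Sequence[CorrespondencePair],
        exemplar: ClosedContour,
) -> tuple[np.ndarray, np.ndarray]:
    """Map each variation point to its modal exemplar counterpart.

    For every variation point, each rater pick including it votes for the
    exemplar segment of that pair; the winning (modal) segment's circular
    median point becomes the target (ties: lower segment start).  Returns
    ``(target, support)`` where ``target[i]`` is the exemplar point index
    (-1 when no rater included point i) and ``support[i]`` counts raters
    who included it in any pick.
    """
    n = variation.n
    target = np.full(n, -1, dtype=int)
    support = np.zeros(n, dtype=int)
    votes: list[Counter] = [Counter() for _ in range(n)]
    raters_at: list[set] = [set() for _ in range(n)]
    for pair in pairs:
        if pair.variation_pick.rest or pair.exemplar_pick.rest:
            continue
        vseg = pair.variation_pick.segment(variation)
        eseg = pair.exemplar_pick.segment(exemplar)
        for idx in vseg.indices():
            votes[idx][(eseg.start, eseg.length)] += 1
            raters_at[idx].add(pair.rater)
    for i in range(n):
        support[i] = len(raters_at[i])
        if votes[i]:
            (start, length), _ = min(votes[i].items(),
                                     key=lambda kv: (-kv[1], kv[0]))
            target[i] = ContourSegment(exemplar, start, length).median_index()
    return target, support


# ---------------------------------------------------------------------------
# corresponding area

def _trial_union_fraction(exemplar: ClosedContour,
                          picks: Sequence[PartPick]) -> float:
    poly = exemplar.polygon()
    if any(p.rest for p in picks):
        # rest-of-shape covers everything not yet picked, so together with
        # the chord picks the whole exemplar corresponds
        return 1.0
    polys = []
    for p in picks:
        part = p.segment(exemplar).part_polygon()
        if not part.is_valid:
            part = part.buffer(0)
        polys.append(part)
    if not polys:
        return 0.0
    union = unary_union(polys).intersection(poly)
    return float(union.area / poly.area)


def corresponding_area_fraction(
        exemplar: ClosedContour,
        pairs: Sequence[CorrespondencePair],
        *,
        all_trials: Optional[Sequence[tuple[str, str]]] = None,
) -> float:
    """Fraction of the exemplar's area covered by picked exemplar parts.

    Pick polygons (segment plus closing chord) are unioned per
    (trial, rater), averaged over raters within a trial, then over
    trials.  ``all_trials`` optionally lists every (trial, rater) run so
    that trials where a rater saw no correspondence enter as 0; trials
    whose pick polygons are degenerate are excluded.
    """
    groups: dict[tuple[str, str], list[PartPick]] = {}
    if all_trials is not None:
        for key in all_trials:
            groups[tuple(key)] = []
    for pair in pairs:
        groups.setdefault((pair.trial, pair.rater), []).append(
            pair.exemplar_pick)
    per_trial: dict[str, list[float]] = {}
    for (trial, _rater), picks in groups.items():
        try:
            frac = _trial_union_fraction(exemplar, picks)
        except Exception:
            continue  # degenerate pick polygon: trial flagged out
        per_trial.setdefault(trial, []).append(frac)
    if not per_trial:
        return 0.0
    return float(np.mean([np.mean(v) for v in per_trial.values()]))


def regress_area_on_similarity(fractions, similarity_midpoints) -> TrendResult:
    """OLS of mean corresponding-area fraction on bin similarity midpoint."""
    return ols(similarity_midpoints, fractions)


# ---------------------------------------------------------------------------
# part circles

def build_part_circle(shape: ClosedContour,
                      labelled_picks: Sequence[tuple[str, ContourSegment]]
                      ) -> PartCircle:
    """Scan the contour clockwise from its left-most point into a part circle.

    Each point contributes its part label, or GAP when unpicked; runs of
    equal values are merged (circularly).  Overlapping picks violate the
    picking interface and raise.  Rest-of-shape picks must be excluded by
    the caller: they are not localized parts.
    """
    n = shape.n
    owner = np.full(n, -1, dtype=int)
    for k, (_label, seg) in enumerate(labelled_picks):
        idx = seg.indices()
        if np.any(owner[idx] >= 0):
            raise ValueError("picks overlap: each point may belong to one part")
        owner[idx] = k
    start = leftmost_start_index(shape)
    entries: list = []
    for off in range(n):
        o = owner[(start + off) % n]
        val = GAP if o < 0 else labelled_picks[o][0]
        if not entries or entries[-1] != val:
            entries.append(val)
    if len(entries) > 1 and entries[0] == entries[-1]:
        entries.pop()  # circular merge of first and last run
    return PartCircle(tuple(entries))


def _cyclic_label_sequence(circle: PartCircle, shared: set) -> list:
    seq = [e for e in circle.entries if e in shared]
    return seq


def _is_rotation(a: list, b: list) -> bool:
    if len(a) != len(b):
        return False
    if not a:
        return True
    n = len(a)
    return any(b == a[r:] + a[:r] for r in range(n))


def compare_part_order(exemplar_circle: PartCircle,
                       variation_circle: PartCircle) -> str:
    """Classify the cyclic order relation of the shared labels.

    Gap entries are ignored; with two or fewer shared labels the relation
    is ``"undefined"`` (a two-element cyclic array equals its reversal),
    and ``"undefined_no_shared"`` when the circles share no label at all.
    Otherwise: ``"identical"`` when the variation's shared-label cycle is
    a rotation of the exemplar's, ``"reversed"`` when it is a rotation of
    the reversal, ``"shuffled"`` otherwise.
    """
    le = set(exemplar_circle.labels())
    lv = set(variation_circle.labels())
    shared = le & lv
    if not shared:
        return "undefined_no_shared"
    if len(shared) <= 2:
        return "undefined"
    a = _cyclic_label_sequence(exemplar_circle, shared)
    b = _cyclic_label_sequence(variation_circle, shared)
    if len(set(a)) != len(a) or len(set(b)) != len(b):
        # a label split into several runs cannot be ordered cleanly
        return "shuffled"
    if _is_rotation(a, b):
        return "identical"
    if _is_rotation(a[::-1], b):
        return "reversed"
    return "shuffled"


def classify_gap_changes(exemplar_circle: PartCircle,
                         variation_circle: PartCircle) -> list[GapChange]:
    """Gap bookkeeping between consecutive shared labels.

    For each interval between consecutive shared labels in the exemplar's
    cyclic order, the variation's interval is read clockwise from the
    first label to the second: a gap only in the exemplar is an omission,
    only in the variation an addition, in both a substitution.
    """
    shared = set(exemplar_circle.labels()) & set(variation_circle.labels())
    if not shared:
        raise ValueError("gap analysis needs at least one shared label")
    changes: list[GapChange] = []
    e_seq = list(exemplar_circle.entries)
    v_seq = list(variation_circle.entries)
    anchors = [e for e in e_seq if e in shared]
    m = len(anchors)
    for k in range(m if m > 1 else 0):
        l1, l2 = anchors[k], anchors[(k + 1) % m]
        gap_e = _interval_has_gap(e_seq, l1, l2, shared)
        gap_v = _interval_has_gap(v_seq, l1, l2, shared)
        kind = None
        if gap_e and not gap_v:
            kind = "omission"
        elif gap_v and not gap_e:
            kind = "addition"
        elif gap_e and gap_v:
            kind = "substitution"
        if kind:
            changes.append(GapChange(kind, (l1, l2)))
    if m == 1:
        l1 = anchors[0]
        gap_e = _interval_has_gap(e_seq, l1, l1, shared)
        gap_v = _interval_has_gap(v_seq, l1, l1, shared)
        if gap_e and not gap_v:
            changes.append(GapChange("omission", (l1, l1)))
        elif gap_v and not gap_e:
            changes.append(GapChange("addition", (l1, l1)))
        elif gap_e and gap_v:
            changes.append(GapChange("substitution", (l1, l1)))
    return changes


def _interval_has_gap(seq: list, l1, l2, shared: set) -> bool:
    """Any GAP strictly between l1 and the next occurrence of l2, cyclically."""
    n = len(seq)
    try:
        i = seq.index(l1)
    except ValueError:
        return False
    last_off = n if l1 == l2 else n - 1
    for off in range(1, last_off + 1):
        e = seq[(i + off) % n]
        if e == l2 and (l1 != l2 or off == n):
            break
        if e == GAP:
            return True
    return False
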