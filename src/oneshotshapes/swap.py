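"""Distinctive-part-swap stimulus synthesis.

A shape's distinctive part is the largest consecutive contour run whose
aggregated distinctiveness score exceeds 75 at every point; its
indistinctive part is the same-length window with the lowest mean score.
Swap stimuli replace one of these with a donor category's exemplar part,
fitted into the gap by the similarity transform (rotation + uniform
scale + translation) that maps the donor part's endpoints exactly onto
the gap's endpoints, keeping the mirror solution that points outward.
The full design crosses 8 base categories x 7 donor categories x 2
conditions x 5 base shapes = 560 stimuli, with automated screening
(simple polygon, minimum point clearance) standing in for the study's
manual curation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from shapely.geometry import Polygon

from .contour import (ClosedContour, ContourSegment, STANDARD_N,
                      resample_contour, self_intersects)
from .distinctiveness import DistinctivenessField, high_score_regions

__all__ = [
    "SwapStimulus",
    "extract_distinctive_part",
    "select_indistinctive_part",
    "transplant_part",
    "screen_stimulus",
    "build_swap_design",
]


@dataclass(frozen=True)
class SwapStimulus:
    base_id: str
    base_category: int
    donor_category: int
    condition: str                  # "distinctive" | "indistinctive"
    removed: tuple                  # (start, length) on the base contour
    inserted: tuple                 # (start, length) on the donor contour
    rotation: float                 # radians
    scale: float
    translation: tuple
    contour: ClosedContour
    screened: bool


def extract_distinctive_part(field: DistinctivenessField,
                             contour: ClosedContour,
                             threshold: float = 75.0) -> ContourSegment:
    """Largest run with every point strictly above threshold.

    Ties break toward higher mean score, then lower start index.  A shape
    with no point above threshold is ineligible and raises.
    """
    regions = high_score_regions(field, contour, threshold)
    if not regions:
        raise ValueError(
            f"no point exceeds {threshold}: shape has no distinctive part")
    return max(regions, key=lambda r: (r.length,
                                       float(np.mean(field.scores[r.indices()])),
                                       -r.start))


def select_indistinctive_part(field: DistinctivenessField,
                              contour: ClosedContour,
                              n_points: int,
                              exclude: ContourSegment) -> ContourSegment:
    """Minimum-mean-score window of exactly ``n_points`` avoiding ``exclude``.

    Ties break toward the lowest start index.
    """
    n = contour.n
    if n_points >= n - exclude.length:
        raise ValueError("no window of that size fits outside the excluded part")
    excluded = np.zeros(n, dtype=bool)
    excluded[exclude.indices()] = True
    best = None
    for start in range(n):
        idx = (start + np.arange(n_points)) % n
        if excluded[idx].any():
            continue
        mean = float(np.mean(field.scores[idx]))
        if best is None or mean < best[0] - 1e-12:
            best = (mean, start)
    if best is None:
        raise ValueError("no feasible indistinctive window")
    return ContourSegment(contour, best[1], n_points)


def _two_point_similarity(src0, src1, dst0, dst1):
    """Proper similarity transform (as a complex pair a, b: z -> a z + b)
    mapping src0 -> dst0 and src1 -> dst1."""
    s0, s1 = complex(*src0), complex(*src1)
    d0, d1 = complex(*dst0), complex(*dst1)
    if s0 == s1:
        raise ValueError("zero-length donor chord")
    a = (d1 - d0) / (s1 - s0)
    b = d0 - a * s0
    return a, b


def transplant_part(recipient: ClosedContour,
                    gap: ContourSegment,
                    donor_part: ContourSegment,
                    *, resample_n: Optional[int] = None
                    ) -> tuple[ClosedContour, dict]:
    """Replace the ``gap`` segment of the recipient by the donor part.

    The donor points are mapped by the endpoint-fitting similarity
    transform; of the two mirror solutions the one whose interior lies
    outside the recipient's remaining body (outward-pointing) is kept.
    The result is re-closed and resampled to the standard point count.
    Returns the new contour and the transform parameters.
    """
    if resample_n is None:
        resample_n = STANDARD_N
    rec = recipient.points
    n = recipient.n
    # anchors: the recipient points adjacent to the removed run
    a_idx = (gap.start - 1) % n
    b_idx = gap.end
    A, B = rec[a_idx], rec[b_idx]
    donor_pts = donor_part.points()
    if len(donor_pts) < 2:
        raise ValueError("donor part needs at least 2 points")
    candidates = []
    for mirrored in (False, True):
        pts = donor_pts.copy()
        if mirrored:
            # reflect across the donor chord before fitting
            pts = _reflect_across(pts, donor_pts[0], donor_pts[-1])
        a, b = _two_point_similarity(pts[0], pts[-1], A, B)
        z = pts[:, 0] + 1j * pts[:, 1]
        w = a * z + b
        mapped = np.column_stack([w.real, w.imag])
        candidates.append((mirrored, a, b, mapped))
    # remaining body: recipient minus the gap run, closed by chord A-B
    keep_idx = [(b_idx + k) % n for k in range(((a_idx - b_idx) % n) + 1)]
    body = Polygon(rec[keep_idx])
    if not body.is_valid:
        body = body.buffer(0)
    chosen = None
    for mirrored, a, b, mapped in candidates:
        interior = mapped[1:-1] if len(mapped) > 2 else mapped
        inside = np.mean([body.contains(_point(p)) for p in interior])
        if chosen is None or inside < chosen[0]:
            chosen = (inside, mirrored, a, b, mapped)
    _, mirrored, a, b, mapped = chosen
    new_pts = np.vstack([rec[keep_idx], mapped[1:-1]])
    out = ClosedContour(new_pts, shape_id=recipient.shape_id,
                        category=recipient.category)
    out = resample_contour(out, resample_n)
    transform = dict(rotation=float(np.angle(a)), scale=float(abs(a)),
                     translation=(float(b.real), float(b.imag)),
                     mirrored=bool(mirrored))
    return out, transform


def _point(p):
    from shapely.geometry import Point
    return Point(p)


def _reflect_across(pts: np.ndarray, p0, p1) -> np.ndarray:
    d = np.asarray(p1, float) - np.asarray(p0, float)
    L = np.hypot(*d)
    if L == 0:
        raise ValueError("zero-length donor chord")
    u = d / L
    rel = pts - p0
    proj = rel @ u
    perp = rel - np.outer(proj, u)
    return pts - 2 * perp


def screen_stimulus(contour: ClosedContour,
                    *, min_clearance: float = 1e-3) -> tuple[bool, str]:
    """Automated artefact screen: simple polygon and point clearance.

    Returns ``(passed, reason)``; the clearance check rejects near-
    self-touching contours whose non-neighbouring points come closer than
    ``min_clearance`` x mean edge length.
    """
    if self_intersects(contour):
        return False, "self-intersection"
    pts = contour.points
    n = len(pts)
    edge = np.mean(np.linalg.norm(np.roll(pts, -1, axis=0) - pts, axis=1))
    d2 = np.sum((pts[None, :, :] - pts[:, None, :]) ** 2, axis=-1)
    i, j = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    ring_dist = np.minimum((i - j) % n, (j - i) % n)
    mask = ring_dist > 2
    if mask.any():
        min_d = float(np.sqrt(d2[mask].min()))
        if min_d < min_clearance * edge:
            return False, "insufficient clearance"
    return True, ""


def build_swap_design(shapes: dict, fields: dict, exemplars: dict,
                      exemplar_fields: dict, rng: np.random.Generator,
                      *, categories: Optional[Sequence[int]] = None,
                      donors_per_category: int = 7,
                      conditions: tuple = ("distinctive", "indistinctive"),
                      bases_per_cell: int = 5,
                      threshold: float = 75.0
                      ) -> tuple[list[SwapStimulus], list[dict]]:
    """Enumerate the full swap design (8 x 7 x 2 x 5 = 560 under defaults).

    ``shapes``: category -> list of base contours; ``fields``: shape id ->
    DistinctivenessField; ``exemplars`` / ``exemplar_fields``: per-category
    donor exemplar and its field.  Base candidates are drawn in seeded
    order per cell until ``bases_per_cell`` pass screening; unfillable
    cells are reported in the returned shortfall list.
    """
    if categories is None:
        categories = sorted(shapes)
    stimuli: list[SwapStimulus] = []
    shortfalls: list[dict] = []
    donor_parts: dict = {}
    for cat in categories:
        ex = exemplars[cat]
        ef = exemplar_fields[cat]
        dist = extract_distinctive_part(ef, ex, threshold)
        indist = select_indistinctive_part(ef, ex, dist.length, dist)
        donor_parts[cat] = {"distinctive": dist, "indistinctive": indist}
    for cat in categories:
        donors = [d for d in categories if d != cat][:donors_per_category]
        base_pool = list(shapes[cat])
        for donor in donors:
            for condition in conditions:
                order = rng.permutation(len(base_pool))
                filled = 0
                for bi in order:
                    if filled >= bases_per_cell:
                        break
                    base = base_pool[bi]
                    f = fields.get(base.shape_id)
                    if f is None:
                        continue
                    try:
                        dist_seg = extract_distinctive_part(f, base, threshold)
                        if condition == "distinctive":
                            removed = dist_seg
                        else:
                            removed = select_indistinctive_part(
                                f, base, dist_seg.length, dist_seg)
                        donor_seg = donor_parts[donor][condition]
                        new, tr = transplant_part(base, removed, donor_seg)
                    except (ValueError, RuntimeError):
                        continue
                    ok, _reason = screen_stimulus(new)
                    if not ok:
                        continue
                    sid = (f"{base.shape_id}_swap_{condition[:4]}_from{donor}")
                    stimuli.append(SwapStimulus(
                        base_id=base.shape_id, base_category=cat,
                        donor_category=donor, condition=condition,
                        removed=(removed.start, removed.length),
                        inserted=(donor_seg.start, donor_seg.length),
                        rotation=tr["rotation"], scale=tr["scale"],
                        translation=tr["translation"],
                        contour=new.with_meta(shape_id=sid),
                        screened=True))
                    filled += 1
                if filled < bases_per_cell:
                    shortfalls.append(dict(category=cat, donor=donor,
                                           condition=condition,
                                           filled=filled,
                                           wanted=bases_per_cell))
    return stimuli, shortfalls
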