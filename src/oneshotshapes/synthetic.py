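"""Synthetic drawing cohorts with known ground truth.

Exemplars are built from a main body (a jittered polygon for the
polygonal class, a low-frequency radial Fourier blob for the curved
class) with 0-5 parts attached at fixed angular slots: positive
protrusions (spikes, blocks, smooth bumps) or negative indentations.
Variations apply part-preserving strategies with recorded ground truth:
warp (smooth radial jitter that preserves point order), shuffle
(permuting parts among slots), reversal (a geometric mirror, reversing
the cyclic part order), and omission / addition / substitution of parts.

Simulated rater responses for the similarity, classification,
correspondence and painting experiments are derived from that ground
truth with controllable noise, so every analysis stage can be exercised
and checked against the generator's records.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .contour import (ClosedContour, STANDARD_N, chord_inside,
                      resample_contour, self_intersects, turning_angles)
from .correspondence import CorrespondencePair, PartPick

__all__ = [
    "PartAnnotation",
    "ExemplarSpec",
    "VariationSpec",
    "VariationRecord",
    "RaterProfile",
    "Cohort",
    "generate_exemplar",
    "generate_variation",
    "generate_cohort",
    "simulate_similarity_ratings",
    "simulate_classification",
    "simulate_correspondence",
    "simulate_paintings",
    "simulate_copy_discrimination",
    "simulate_swap_classification",
    "classify_cyclic_order",
]

CENTER = np.array([250.0, 250.0])
BASE_RADIUS = 150.0
#: Angular slots (radians) where parts may attach; body corners sit between.
SLOT_ANGLES = np.deg2rad(np.array([30.0, 90.0, 150.0, 210.0, 270.0, 330.0]))
_BODY_CORNER_ANGLES = np.deg2rad(np.arange(0.0, 360.0, 60.0))


@dataclass(frozen=True)
class PartAnnotation:
    """Ground-truth part: an angular window on the body with a profile."""

    label: str
    slot: float                 # window centre angle, radians
    width: float                # angular width, radians
    amplitude: float            # radial extent as a fraction of BASE_RADIUS
    polarity: str               # "positive" | "negative"
    profile: str                # "spike" | "block" | "bump"
    weight: float               # ground-truth distinctiveness in [0, 1]


@dataclass(frozen=True)
class ExemplarSpec:
    category: int
    curvature_class: str        # "polygonal" | "curved"
    corner_radii: tuple         # polygonal body: radius factor per corner
    fourier: tuple              # curved body: (k, amplitude, phase) triples
    parts: tuple                # PartAnnotation, disjoint windows
    seed: int


@dataclass(frozen=True)
class VariationSpec:
    category: int
    drawer: int
    strategies: frozenset
    warp_magnitude: float
    permutation: object         # "identity" | "reversed" | dict label->slot
    omitted: tuple = ()
    added: tuple = ()           # PartAnnotation
    substituted: tuple = ()     # (old label, PartAnnotation)
    seed: int = 0


@dataclass(frozen=True)
class RaterProfile:
    rater: str
    placement_noise: float = 0.04
    confusability: float = 0.12
    bundling: float = 0.0
    tier2_prob: float = 0.7
    tier3_prob: float = 0.4


@dataclass
class VariationRecord:
    shape_id: str
    category: int
    drawer: int
    drawing_index: int
    contour: ClosedContour
    spec: VariationSpec
    retained: tuple             # labels present in exemplar and variation
    spans: dict                 # label -> (start, length) on the variation
    order_class: str            # identical | reversed | shuffled | undefined
    deviation: float            # ground-truth dissimilarity magnitude


@dataclass
class Cohort:
    exemplars: dict             # category -> (ClosedContour, ExemplarSpec)
    exemplar_spans: dict        # category -> {label: (start, length)}
    records: list
    seed: int

    def __post_init__(self) -> None:
        self._by_id = {r.shape_id: r for r in self.records}

    def record(self, shape_id: str) -> VariationRecord:
        return self._by_id[shape_id]

    def contour(self, shape_id: str) -> ClosedContour:
        return self._by_id[shape_id].contour

    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            dict(shape=r.shape_id, category=r.category, drawer=r.drawer,
                 drawing_index=r.drawing_index, deviation=r.deviation,
                 order_class=r.order_class,
                 n_retained=len(r.retained),
                 n_omitted=len(r.spec.omitted),
                 n_added=len(r.spec.added),
                 n_substituted=len(r.spec.substituted))
            for r in self.records])


# ---------------------------------------------------------------------------
# contour construction

def _angdiff(a, b):
    return np.angle(np.exp(1j * (a - b)))


def _polygonal_points(spec_corners: np.ndarray, parts: Sequence[PartAnnotation],
                      mirror: bool) -> np.ndarray:
    """Vertex list of the polygonal body with part vertices spliced in."""
    corner_angles = _BODY_CORNER_ANGLES
    corner_r = BASE_RADIUS * np.asarray(spec_corners, dtype=float)
    corners = np.column_stack([np.cos(corner_angles), np.sin(corner_angles)])
    corners = corners * corner_r[:, None]

    def radius_on_edge(theta: float) -> float:
        """Distance from centre to the body polygon along direction theta."""
        k = int(np.floor((theta % (2 * np.pi)) / np.deg2rad(60.0))) % 6
        p1, p2 = corners[k], corners[(k + 1) % 6]
        d = np.array([np.cos(theta), np.sin(theta)])
        e = p2 - p1
        mat = np.column_stack([d, -e])
        s, _t = np.linalg.solve(mat, p1)
        return float(s)

    verts: list[tuple[float, np.ndarray]] = [
        (corner_angles[k], corners[k]) for k in range(6)]
    for part in parts:
        a, w = part.slot, part.width
        sign = 1.0 if part.polarity == "positive" else -1.0
        amp = sign * part.amplitude * BASE_RADIUS
        t0, t1 = a - w / 2, a + w / 2
        r0, r1 = radius_on_edge(t0), radius_on_edge(t1)
        ra = radius_on_edge(a)
        seq = [(t0, r0)]
        if part.profile == "spike":
            seq.append((a, ra + amp))
        elif part.profile == "block":
            seq.append((a - w / 4, radius_on_edge(a - w / 4) + amp))
            seq.append((a + w / 4, radius_on_edge(a + w / 4) + amp))
        else:  # smooth-ish bump approximated by three vertices
            seq.append((a - w / 4, radius_on_edge(a - w / 4) + 0.8 * amp))
            seq.append((a, ra + amp))
            seq.append((a + w / 4, radius_on_edge(a + w / 4) + 0.8 * amp))
        seq.append((t1, r1))
        for theta, r in seq:
            verts.append((theta % (2 * np.pi),
                          np.array([r * np.cos(theta), r * np.sin(theta)])))
    verts.sort(key=lambda tr: tr[0])
    pts = np.array([p for _t, p in verts]) + CENTER
    if mirror:
        pts = np.column_stack([2 * CENTER[0] - pts[:, 0], pts[:, 1]])
    return pts


def _curved_points(fourier: Sequence[tuple], parts: Sequence[PartAnnotation],
                   mirror: bool, n_dense: int = 720) -> np.ndarray:
    theta = np.arange(n_dense) * (2 * np.pi / n_dense)
    r = np.ones_like(theta)
    for k, amp, phase in fourier:
        r = r + amp * np.cos(k * theta + phase)
    r = r * BASE_RADIUS
    for part in parts:
        sign = 1.0 if part.polarity == "positive" else -1.0
        d = _angdiff(theta, part.slot)
        inside = np.abs(d) < part.width / 2
        bump = 0.5 * (1 + np.cos(2 * np.pi * d[inside] / part.width))
        r[inside] += sign * part.amplitude * BASE_RADIUS * bump
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)]) + CENTER
    if mirror:
        pts = np.column_stack([2 * CENTER[0] - pts[:, 0], pts[:, 1]])
    return pts


def _build_contour(spec: ExemplarSpec, parts: Sequence[PartAnnotation],
                   mirror: bool = False, *, resample_n: int = STANDARD_N
                   ) -> tuple[ClosedContour, dict]:
    if spec.curvature_class == "polygonal":
        pts = _polygonal_points(np.asarray(spec.corner_radii), parts, mirror)
        meta = [("straight", 0)]
    else:
        pts = _curved_points(spec.fourier, parts, mirror)
        meta = [("freehand", 0)]
    contour = ClosedContour(pts, stroke_meta=meta)
    contour = resample_contour(contour, resample_n)
    spans = {}
    angles = np.arctan2(contour.points[:, 1] - CENTER[1],
                        contour.points[:, 0] - CENTER[0])
    for part in parts:
        slot = np.pi - part.slot if mirror else part.slot
        mask = np.abs(_angdiff(angles, slot)) <= part.width / 2 + 1e-9
        runs = _runs_of(mask)
        if not runs:
            raise RuntimeError(f"part {part.label} has an empty span")
        start, length = max(runs, key=lambda r: r[1])
        spans[part.label] = (start, length)
    return contour, spans


def _runs_of(mask: np.ndarray) -> list[tuple[int, int]]:
    n = len(mask)
    if mask.all():
        return [(0, n)]
    if not mask.any():
        return []
    first_false = int(np.argmin(mask))
    rolled = np.roll(mask, -first_false)
    runs, start = [], None
    for i, v in enumerate(rolled):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append(((start + first_false) % n, i - start))
            start = None
    if start is not None:
        runs.append(((start + first_false) % n, n - start))
    return runs


# ---------------------------------------------------------------------------
# exemplars

def _draw_part(rng: np.random.Generator, label: str, slot: float,
               curvature_class: str, polarity: Optional[str] = None,
               weight: float = 0.4) -> PartAnnotation:
    if polarity is None:
        polarity = "negative" if rng.random() < 0.25 else "positive"
    width = np.deg2rad(rng.uniform(26.0, 38.0))
    if polarity == "positive":
        amplitude = rng.uniform(0.22, 0.45)
    else:
        amplitude = rng.uniform(0.15, 0.28)
    if curvature_class == "polygonal":
        profile = "spike" if rng.random() < 0.6 else "block"
    else:
        profile = "bump"
    return PartAnnotation(label, slot, width, amplitude, polarity,
                          profile, weight)


def generate_exemplar(n_parts: int, curvature_class: str, seed: int,
                      *, category: int = 0,
                      polarities: Optional[Sequence[str]] = None,
                      resample_n: int = STANDARD_N
                      ) -> tuple[ClosedContour, ExemplarSpec, dict]:
    """Build an exemplar with ``n_parts`` annotated parts.

    Returns the contour, the spec (the parametric recipe all variations
    derive from) and the part spans on the resampled contour.
    """
    if not 0 <= n_parts <= 5:
        raise ValueError("n_parts must lie in 0..5")
    for attempt in range(10):
        rng = np.random.default_rng((seed, attempt))
        corner_radii = tuple(rng.uniform(0.85, 1.15, size=6))
        fourier = tuple((k, rng.uniform(0.02, 0.07), rng.uniform(0, 2 * np.pi))
                        for k in (2, 3, 4))
        slot_idx = np.round(np.linspace(0, len(SLOT_ANGLES), n_parts,
                                        endpoint=False)).astype(int)
        signature = int(rng.integers(n_parts)) if n_parts else -1
        parts = []
        for p, si in enumerate(slot_idx):
            pol = polarities[p] if polarities else None
            weight = 1.0 if p == signature else float(rng.uniform(0.2, 0.6))
            parts.append(_draw_part(rng, f"P{p}", float(SLOT_ANGLES[si]),
                                    curvature_class, pol, weight))
        spec = ExemplarSpec(category, curvature_class, corner_radii,
                            fourier, tuple(parts), seed)
        try:
            contour, spans = _build_contour(spec, parts,
                                            resample_n=resample_n)
        except RuntimeError:
            continue
        if not self_intersects(contour):
            contour = contour.with_meta(shape_id=f"ex{category}",
                                        category=category)
            return contour, spec, spans
    raise RuntimeError(f"could not build a simple exemplar (seed={seed})")


# ---------------------------------------------------------------------------
# variations

def classify_cyclic_order(ex_order: Sequence, var_order: Sequence) -> str:
    """Relation of two cyclic label sequences over the same label set."""
    a, b = list(ex_order), list(var_order)
    if set(a) != set(b):
        raise ValueError("orders must cover the same labels")
    if len(a) <= 2:
        return "undefined"
    rots = [b[r:] + b[:r] for r in range(len(b))]
    if a in rots:
        return "identical"
    if a[::-1] in rots:
        return "reversed"
    return "shuffled"


def _warp_parts(parts: Sequence[PartAnnotation], m: float,
                rng: np.random.Generator) -> list[PartAnnotation]:
    out = []
    for p in parts:
        amp = p.amplitude * float(np.clip(1 + rng.normal(0, 0.30 * m), 0.5, 1.6))
        amp = float(np.clip(amp, 0.12, 0.5))
        width = p.width * float(np.clip(1 + rng.normal(0, 0.18 * m), 0.6, 1.4))
        width = float(np.clip(width, np.deg2rad(18), np.deg2rad(46)))
        slot = p.slot + float(np.clip(rng.normal(0, 0.08 * m), -0.09, 0.09))
        out.append(replace(p, amplitude=amp, width=width, slot=slot))
    return out


def generate_variation(exemplar_spec: ExemplarSpec, vspec: VariationSpec,
                       *, exemplar_contour: Optional[ClosedContour] = None,
                       resample_n: int = STANDARD_N) -> VariationRecord:
    """Realize a variation and record its ground truth.

    With warp magnitude 0 and no strategies the exemplar is reproduced
    exactly.  The recorded ``order_class`` classifies the *induced*
    cyclic arrangement of retained parts (a 3-part "shuffle" is always a
    rotation or a reflection, never genuinely shuffled).
    """
    rng = np.random.default_rng(vspec.seed)
    m = vspec.warp_magnitude
    parts = {p.label: p for p in exemplar_spec.parts}
    # part-set edits
    for lab in vspec.omitted:
        parts.pop(lab)
    for old, new in vspec.substituted:
        parts.pop(old)
        parts[new.label] = new
    for new in vspec.added:
        parts[new.label] = new
    # slot permutation over retained exemplar parts
    if isinstance(vspec.permutation, dict):
        parts = {lab: (replace(p, slot=vspec.permutation[lab])
                       if lab in vspec.permutation else p)
                 for lab, p in parts.items()}
    mirror = vspec.permutation == "reversed"
    part_list = _warp_parts(list(parts.values()), m, rng) if m > 0 \
        else list(parts.values())
    # body warp
    corner_radii = exemplar_spec.corner_radii
    fourier = exemplar_spec.fourier
    if m > 0:
        corner_radii = tuple(np.clip(
            np.asarray(corner_radii) * (1 + rng.normal(0, 0.25 * m, 6)),
            0.65, 1.35))
        fourier = tuple((k, float(np.clip(a * (1 + rng.normal(0, 0.5 * m)) +
                                          rng.normal(0, 0.03 * m),
                                          0.0, 0.12)),
                         ph + rng.normal(0, 0.45 * m))
                        for k, a, ph in fourier)
    work_spec = replace(exemplar_spec, corner_radii=corner_radii,
                        fourier=fourier)
    contour = spans = None
    for attempt in range(8):
        try:
            contour, spans = _build_contour(work_spec, part_list,
                                            mirror=mirror,
                                            resample_n=resample_n)
        except RuntimeError:
            contour = None
        if contour is not None and not self_intersects(contour):
            break
        # shrink amplitudes and retry
        part_list = [replace(p, amplitude=p.amplitude * 0.85)
                     for p in part_list]
        contour = None
    if contour is None:
        raise RuntimeError(
            f"variation infeasible after retries (seed={vspec.seed})")
    retained = tuple(lab for lab in parts
                     if lab in {p.label for p in exemplar_spec.parts})
    order_class = _ground_truth_order(exemplar_spec, spans, retained)
    deviation = _deviation(exemplar_spec, vspec, contour,
                           exemplar_contour, order_class)
    sid = f"c{vspec.category}_d{vspec.drawer:02d}_s{vspec.seed}"
    contour = contour.with_meta(shape_id=sid, category=vspec.category)
    return VariationRecord(sid, vspec.category, vspec.drawer, 0, contour,
                           vspec, retained, spans, order_class, deviation)


def _ground_truth_order(exemplar_spec: ExemplarSpec, var_spans: dict,
                        retained: tuple) -> str:
    if len(retained) <= 2:
        return "undefined"
    ex_parts = {p.label: p.slot for p in exemplar_spec.parts}
    # orientation normalization stores the contour clockwise on screen,
    # which traverses the construction angle in decreasing order
    ex_order = sorted(retained, key=lambda lab: -(ex_parts[lab] % (2 * np.pi)))
    var_order = sorted(retained, key=lambda lab: var_spans[lab][0])
    return classify_cyclic_order(ex_order, var_order)


def _deviation(exemplar_spec, vspec, contour, exemplar_contour,
               order_class) -> float:
    geom = 0.0
    if exemplar_contour is not None and exemplar_contour.n == contour.n:
        a = contour.points - contour.points.mean(axis=0)
        b = exemplar_contour.points - exemplar_contour.points.mean(axis=0)
        geom = float(np.mean(np.linalg.norm(a - b, axis=1))) / BASE_RADIUS
    n_changes = (len(vspec.omitted) + len(vspec.added)
                 + len(vspec.substituted))
    return geom + 0.15 * n_changes + 0.1 * (order_class
                                            in ("reversed", "shuffled"))


# ---------------------------------------------------------------------------
# cohort

#: Parts per category and curvature class, echoing the study's 0-5 range.
CATEGORY_LAYOUT = (
    (1, 0, "polygonal", None),
    (2, 1, "curved", ("negative",)),       # the indentation exemplar
    (3, 2, "polygonal", None),
    (4, 3, "curved", None),
    (5, 4, "polygonal", None),
    (6, 5, "curved", None),
    (7, 3, "polygonal", None),
    (8, 4, "curved", None),
)


def _variation_spec(exemplar_spec: ExemplarSpec, drawer: int,
                    magnitude: float, rng: np.random.Generator,
                    seed: int, *, strategy_probs: Optional[dict] = None
                    ) -> VariationSpec:
    probs = dict(shuffle=0.12, reverse=0.05, omit=0.12, add=0.10,
                 substitute=0.10)
    if strategy_probs:
        probs.update(strategy_probs)
    # creative (high-magnitude) drawers also edit the part structure more
    factor = float(np.clip(magnitude / 0.34, 0.2, 1.8))
    probs = {k: min(v * factor, 0.9) for k, v in probs.items()}
    labels = [p.label for p in exemplar_spec.parts]
    strategies = {"warp"}
    permutation: object = "identity"
    omitted: tuple = ()
    added: tuple = ()
    substituted: tuple = ()
    slots_used = {p.label: p.slot for p in exemplar_spec.parts}
    if len(labels) >= 3 and rng.random() < probs["shuffle"]:
        perm = _nontrivial_permutation(labels, rng)
        if perm is not None:
            permutation = {lab: slots_used[perm[lab]] for lab in labels}
            strategies.add("shuffle")
    if permutation == "identity" and rng.random() < probs["reverse"]:
        permutation = "reversed"
        strategies.add("reverse")
    if labels and rng.random() < probs["omit"]:
        omitted = (str(rng.choice(labels)),)
        strategies.add("omit")
    free_slots = [s for s in SLOT_ANGLES
                  if all(abs(_angdiff(s, sl)) > np.deg2rad(50)
                         for lab, sl in slots_used.items()
                         if lab not in omitted)]
    if free_slots and rng.random() < probs["add"]:
        part = _draw_part(rng, f"A{seed % 1000}", float(rng.choice(free_slots)),
                          exemplar_spec.curvature_class,
                          weight=float(rng.uniform(0.2, 0.7)))
        added = (part,)
        strategies.add("add")
    remaining = [lab for lab in labels if lab not in omitted]
    if remaining and rng.random() < probs["substitute"]:
        old = str(rng.choice(remaining))
        new = _draw_part(rng, f"S{seed % 1000}", slots_used[old],
                         exemplar_spec.curvature_class,
                         weight=float(rng.uniform(0.2, 0.7)))
        substituted = ((old, new),)
        strategies.add("substitute")
    return VariationSpec(exemplar_spec.category, drawer,
                         frozenset(strategies), magnitude, permutation,
                         omitted, added, substituted, seed)


def _nontrivial_permutation(labels: list, rng: np.random.Generator,
                            tries: int = 30) -> Optional[dict]:
    """A slot permutation whose induced cyclic order is genuinely shuffled
    (requires >= 4 labels; with 3 every arrangement is a rotation or a
    reflection)."""
    if len(labels) < 4:
        return None
    for _ in range(tries):
        perm = list(rng.permutation(labels))
        if classify_cyclic_order(labels, perm) == "shuffled":
            return dict(zip(labels, perm))
    return None


def generate_cohort(n_drawers: int = 17,
                    n_variations_per_exemplar_per_drawer: int = 12,
                    n_exemplars: int = 8, seed: int = 0,
                    *, resample_n: int = STANDARD_N,
                    strategy_probs: Optional[dict] = None) -> Cohort:
    """Simulate the full drawing study (defaults: 17 x 12 x 8 = 1632).

    Each drawer has a characteristic warp magnitude (evenly spread over
    [0.08, 0.6]) so the cohort induces a stable creativity ordering.
    """
    ss = np.random.SeedSequence(seed)
    exemplars = {}
    exemplar_spans = {}
    layout = CATEGORY_LAYOUT[:n_exemplars]
    if n_exemplars > len(CATEGORY_LAYOUT):
        raise ValueError("at most 8 exemplar categories are defined")
    ex_seeds = ss.spawn(len(layout))
    for (cat, n_parts, curv, pols), child in zip(layout, ex_seeds):
        s = int(child.generate_state(1)[0] % (2 ** 31))
        contour, spec, spans = generate_exemplar(
            n_parts, curv, s, category=cat, polarities=pols,
            resample_n=resample_n)
        exemplars[cat] = (contour, spec)
        exemplar_spans[cat] = spans
    drawer_mag = np.linspace(0.08, 0.6, max(n_drawers, 1))
    records = []
    rec_ss = ss.spawn(1)[0]
    rng = np.random.default_rng(rec_ss)
    for cat, _n_parts, _curv, _pols in layout:
        ex_contour, ex_spec = exemplars[cat]
        for drawer in range(n_drawers):
            for k in range(n_variations_per_exemplar_per_drawer):
                vseed = int(rng.integers(2 ** 31))
                mag = float(np.clip(drawer_mag[drawer]
                                    * rng.uniform(0.7, 1.3), 0.02, 0.9))
                vspec = _variation_spec(ex_spec, drawer, mag, rng, vseed,
                                        strategy_probs=strategy_probs)
                rec = generate_variation(ex_spec, vspec,
                                         exemplar_contour=ex_contour,
                                         resample_n=resample_n)
                rec.drawing_index = k + 1
                rec.shape_id = f"c{cat}_d{drawer:02d}_v{k + 1:02d}"
                rec.contour = rec.contour.with_meta(shape_id=rec.shape_id)
                records.append(rec)
    return Cohort(exemplars, exemplar_spans, records, seed)


# ---------------------------------------------------------------------------
# simulated rater responses

def simulate_similarity_ratings(cohort: Cohort, n_raters: int = 12,
                                noise: float = 0.04, seed: int = 0
                                ) -> pd.DataFrame:
    """Placement table: x positions monotone in ground-truth deviation.

    Each rater has their own axis origin and scale (the analysis must be
    invariant to both); the exemplar sits at the rater's origin.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for r in range(n_raters):
        x0 = 80.0 + 15.0 * r
        scale = 600.0 + 25.0 * r
        for rec in cohort.records:
            eps = rng.normal(0, noise) if noise > 0 else 0.0
            x = x0 + scale * max(rec.deviation + eps, 0.0)
            rows.append(dict(rater=f"r{r:02d}", category=rec.category,
                             shape=rec.shape_id, x=x, x_exemplar=x0))
    return pd.DataFrame(rows)


def simulate_classification(cohort: Cohort, shape_ids: Sequence[str],
                            n_raters: int = 15, confusability: float = 0.12,
                            seed: int = 0) -> pd.DataFrame:
    """8-way choices: correct with probability 1 - confusability, else
    uniform over the remaining categories."""
    rng = np.random.default_rng(seed)
    cats = sorted(cohort.exemplars)
    rows = []
    for r in range(n_raters):
        for sid in shape_ids:
            true = cohort.record(sid).category
            if rng.random() < 1 - confusability:
                resp = true
            else:
                others = [c for c in cats if c != true]
                resp = int(rng.choice(others)) if others else true
            rows.append(dict(rater=f"r{r:02d}", shape=sid,
                             true_category=true, response=resp))
    return pd.DataFrame(rows)


# -- correspondence ---------------------------------------------------------

def _pick_from_span(contour: ClosedContour, start: int, length: int,
                    lo_cap: int, hi_cap: int) -> Optional[tuple[int, int]]:
    """Chord endpoints (i, j) for the segment.

    Prefers endpoints whose chord is interior (widening the segment
    stepwise, capped to stay clear of neighbouring picks); when no
    interior chord exists (wide body stretches over concavities) the
    exact endpoints are used anyway -- the simulated rater idealizes the
    picking interface rather than fragmenting the region.
    """
    n = contour.n
    if length >= n:
        return None
    for d in (0, 2, 4, 6, 8, 10):
        dl, dr = min(d, lo_cap), min(d, hi_cap)
        i = (start - dl) % n
        j = (start + length - 1 + dr) % n
        if (j - i) % n + 1 >= n:
            break
        if chord_inside(contour, i, j):
            return i, j
    return start % n, (start + length - 1) % n


def _stretch_subruns(n: int, lo: int, hi: int,
                     blocked: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Maximal clean runs inside circular index range [lo, hi] (inclusive)
    after removing blocked (start, length) spans."""
    length = (hi - lo) % n + 1
    mask = np.ones(length, dtype=bool)
    for bs, bl in blocked:
        for k in range(bl):
            off = (bs + k - lo) % n
            if off < length:
                mask[off] = False
    runs = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append(((lo + start) % n, i - start))
            start = None
    if start is not None:
        runs.append(((lo + start) % n, length - start))
    return runs


def simulate_correspondence(cohort: Cohort,
                            trials: Sequence[tuple[str, str, bool]],
                            n_raters: int = 15, bundling: float = 0.0,
                            cross_pick_prob: float = 0.35,
                            seed: int = 0) -> list[CorrespondencePair]:
    """Simulated part-correspondence picks.

    ``trials`` holds (trial id, variation shape id, same_category flag).
    For same-category trials the rater pairs every retained part by
    ground truth and pairs the body stretches between consecutive
    retained parts by their anchor pair; with probability ``bundling`` a
    part pick is merged with its following stretch pick.  Cross-category
    trials yield at most one small body-to-body pick.
    """
    rng = np.random.default_rng(seed)
    pairs: list[CorrespondencePair] = []
    for trial_id, sid, same in trials:
        rec = cohort.record(sid)
        ex_contour, ex_spec = cohort.exemplars[rec.category]
        ex_spans = cohort.exemplar_spans[rec.category]
        for r in range(n_raters):
            rater = f"r{r:02d}"
            if not same:
                if rng.random() < cross_pick_prob:
                    p = _cross_pick(ex_contour, rec.contour, ex_spans,
                                    rec.spans, rng)
                    if p is not None:
                        e_pick, v_pick = p
                        pairs.append(CorrespondencePair(
                            trial_id, rater, f"{trial_id}:x",
                            e_pick, v_pick))
                continue
            pairs.extend(_same_category_picks(
                trial_id, rater, ex_contour, ex_spans, rec, bundling, rng))
    return pairs


def _cross_pick(ex_contour, var_contour, ex_spans, var_spans, rng):
    n = ex_contour.n
    part_idx = set()
    for s, l in ex_spans.values():
        part_idx.update((s + k) % n for k in range(l))
    for _ in range(20):
        start = int(rng.integers(n))
        length = 25
        idx = {(start + k) % n for k in range(length)}
        if idx & part_idx:
            continue
        e = _pick_from_span(ex_contour, start, length, 0, 0)
        v = _pick_from_span(var_contour, int(rng.integers(var_contour.n)),
                            length, 0, 0)
        if e and v:
            return (PartPick(ex_contour.shape_id or "ex", *e),
                    PartPick(var_contour.shape_id or "var", *v))
    return None


def _same_category_picks(trial_id, rater, ex_contour, ex_spans, rec,
                         bundling, rng) -> list[CorrespondencePair]:
    n = ex_contour.n
    retained = [lab for lab in rec.retained if lab in rec.spans]
    ex_sid = ex_contour.shape_id or "ex"
    v_sid = rec.shape_id
    out: list[CorrespondencePair] = []
    if not retained:
        # no part anchors: pair two half-body stretches
        half = n // 2
        for k, (s, l) in enumerate(((0, half), (half, n - half))):
            e = _pick_from_span(ex_contour, s, l, 0, 0)
            v = _pick_from_span(rec.contour, s, l, 0, 0)
            if e and v:
                out.append(CorrespondencePair(
                    trial_id, rater, f"{trial_id}:{rater}:half{k}",
                    PartPick(ex_sid, *e), PartPick(v_sid, *v)))
        return out

    ex_order = sorted(retained, key=lambda lab: ex_spans[lab][0])
    var_order = sorted(retained, key=lambda lab: rec.spans[lab][0])
    m = len(ex_order)

    def caps(order, spans, ncont, lab):
        k = order.index(lab)
        s, l = spans[lab]
        prev_lab = order[k - 1]
        next_lab = order[(k + 1) % m]
        ps, pl = spans[prev_lab]
        gap_lo = (s - (ps + pl)) % ncont
        ns, _nl = spans[next_lab]
        gap_hi = (ns - (s + l)) % ncont
        return max((gap_lo - 2) // 2, 0), max((gap_hi - 2) // 2, 0)

    # part picks
    part_picks: dict[str, tuple] = {}
    for lab in retained:
        es, el = ex_spans[lab]
        vs, vl = rec.spans[lab]
        if m == 1:
            e_caps = v_caps = (4, 4)
        else:
            e_caps = caps(ex_order, ex_spans, n, lab)
            v_caps = caps(var_order, rec.spans, rec.contour.n, lab)
        e = _pick_from_span(ex_contour, es, el, *e_caps)
        v = _pick_from_span(rec.contour, vs, vl, *v_caps)
        if e and v:
            part_picks[lab] = (e, v)

    # directed stretches, matched across shapes by unordered anchor pair;
    # when both directed stretches share one pair (two anchors), the
    # candidate with the closest length wins (handles mirrored variations)
    ex_stretches = _anchor_stretches(ex_order, ex_spans, part_picks, 0, n,
                                     _nonretained_spans_ex(rec, ex_spans))
    var_stretches = _anchor_stretches(var_order, rec.spans, part_picks, 1,
                                      rec.contour.n,
                                      _nonretained_spans_var(rec))
    stretch_pairs: dict[tuple, tuple] = {}
    unmatched = dict(var_stretches)
    for dkey, (es, el) in ex_stretches.items():
        pair = frozenset(dkey)
        cands = [k for k in unmatched if frozenset(k) == pair]
        if not cands:
            continue
        vkey = min(cands, key=lambda k: abs(unmatched[k][1] - el))
        vs, vl = unmatched.pop(vkey)
        e = _pick_from_span(ex_contour, es, el, 0, 0)
        v = _pick_from_span(rec.contour, vs, vl, 0, 0)
        if e and v:
            stretch_pairs[dkey] = (e, v, vkey)

    if bundling > 0:
        for lab in list(part_picks):
            # optionally merge a part with its following stretch, when that
            # stretch is contiguous with the part on both shapes
            k = ex_order.index(lab)
            nxt = ex_order[(k + 1) % m]
            dkey = (lab, nxt)
            if dkey in stretch_pairs and rng.random() < bundling:
                _e, _v, vkey = stretch_pairs[dkey]
                if vkey[0] == lab:  # stretch follows the part on both shapes
                    (ei, _ej), (vi, _vj) = part_picks[lab]
                    (_sei, sej), (_svi, svj), _vk = stretch_pairs.pop(dkey)
                    part_picks[lab] = ((ei, sej), (vi, svj))

    for lab, (e, v) in part_picks.items():
        out.append(CorrespondencePair(trial_id, rater,
                                      f"{trial_id}:{rater}:{lab}",
                                      PartPick(ex_sid, *e),
                                      PartPick(v_sid, *v)))
    for dkey, (e, v, _vkey) in stretch_pairs.items():
        kname = "|".join(dkey)
        out.append(CorrespondencePair(trial_id, rater,
                                      f"{trial_id}:{rater}:arc:{kname}",
                                      PartPick(ex_sid, *e),
                                      PartPick(v_sid, *v)))
    return out


def _nonretained_spans_ex(rec: VariationRecord,
                          ex_spans: dict) -> list[tuple[int, int]]:
    """Exemplar spans of omitted/substituted parts (blocked for stretches)."""
    labs = list(rec.spec.omitted) + [old for old, _new in rec.spec.substituted]
    return [ex_spans[lab] for lab in labs if lab in ex_spans]


def _nonretained_spans_var(rec: VariationRecord) -> list[tuple[int, int]]:
    """Variation spans of added/substituted-in parts."""
    labs = ([p.label for p in rec.spec.added]
            + [new.label for _old, new in rec.spec.substituted])
    return [rec.spans[lab] for lab in labs if lab in rec.spans]


def _anchor_stretches(order, spans, part_picks, side, ncont, blocked):
    """Directed stretches between consecutive anchors:
    {(from label, to label): (start, length)}.

    Each stretch runs from the end of one part pick to the start of the
    next; blocked spans (non-retained parts) are removed and only the
    first clean sub-run is kept, leaving the remainder unpicked.
    """
    m = len(order)
    out = {}
    if m < 2:
        if m == 1:
            lab = order[0]
            if lab in part_picks:
                pick = part_picks[lab][side]
                lo = (pick[1] + 1) % ncont
                hi = (pick[0] - 1) % ncont
                if (hi - lo) % ncont + 1 >= 6:
                    runs = _stretch_subruns(ncont, lo, hi, blocked)
                    if runs and runs[0][1] >= 6:
                        out[(lab, lab)] = runs[0]
        return out
    for k in range(m):
        la, lb = order[k], order[(k + 1) % m]
        if la not in part_picks or lb not in part_picks:
            continue
        pa = part_picks[la][side]
        pb = part_picks[lb][side]
        lo = (pa[1] + 1) % ncont
        hi = (pb[0] - 1) % ncont
        span_len = (hi - lo) % ncont + 1
        if span_len < 6 or span_len >= ncont:
            continue
        runs = _stretch_subruns(ncont, lo, hi, blocked)
        if runs and runs[0][1] >= 6:
            out[(la, lb)] = runs[0]
    return out


# -- paintings --------------------------------------------------------------

def _salient_spans(cohort: Cohort, sid: str) -> list[tuple[int, int, float]]:
    """Ground-truth spans ranked by distinctiveness weight (desc).

    For exemplars the spec's parts are used; for variations the parts
    actually present (retained, added, substituted-in).  Shapes without
    parts fall back to the window of maximal curvature — distinctiveness
    as a geometric outlier.
    """
    if sid.startswith("ex"):
        cat = int(sid[2:])
        contour, spec = cohort.exemplars[cat]
        spans = cohort.exemplar_spans[cat]
        weights = {p.label: p.weight for p in spec.parts}
    else:
        rec = cohort.record(sid)
        contour = rec.contour
        spans = rec.spans
        weights = {p.label: p.weight
                   for p in rec.spec.added + tuple(
                       new for _o, new in rec.spec.substituted)}
        ex_spec = cohort.exemplars[rec.category][1]
        for p in ex_spec.parts:
            if p.label in rec.retained:
                weights[p.label] = p.weight
    ranked = sorted(((lab, w) for lab, w in weights.items() if lab in spans),
                    key=lambda lw: -lw[1])
    out = [(spans[lab][0], spans[lab][1], w) for lab, w in ranked]
    if not out:
        turn = turning_angles(contour)
        smooth = sum(np.roll(turn, s) for s in range(-2, 3))
        centre = int(np.argmax(smooth))
        out = [((centre - 10) % contour.n, 21, 1.0)]
    return out


def simulate_paintings(cohort: Cohort, shape_ids: Sequence[str],
                       n_raters: int = 10, tier2_prob: float = 0.7,
                       tier3_prob: float = 0.4, jitter_sd: float = 1.5,
                       seed: int = 0) -> dict:
    """Tiered distinctiveness paintings keyed by shape id.

    Every rater paints tier 1 on the top-weight span (endpoints jittered),
    and optionally tiers 2/3 on the next-ranked spans.  Returns
    {shape_id: [Painting, ...]}.
    """
    from .distinctiveness import Painting

    rng = np.random.default_rng(seed)
    out: dict = {}
    for sid in shape_ids:
        contour = (cohort.exemplars[int(sid[2:])][0] if sid.startswith("ex")
                   else cohort.contour(sid))
        n = contour.n
        ranked = _salient_spans(cohort, sid)
        paintings = []
        for r in range(n_raters):
            tiers = np.zeros(n, dtype=int)
            plan = [(1, 1.0), (2, tier2_prob), (3, tier3_prob)]
            for (tier, prob), span in zip(plan, ranked):
                if rng.random() >= prob:
                    continue
                s, l, _w = span
                ds = int(round(rng.normal(0, jitter_sd)))
                de = int(round(rng.normal(0, jitter_sd)))
                start = (s + ds) % n
                length = int(np.clip(l - ds + de, 3, n))
                idx = (start + np.arange(length)) % n
                free = tiers[idx] == 0
                tiers[idx[free]] = tier
            if not np.any(tiers == 1):  # interface rule: tier 1 mandatory
                s, l, _w = ranked[0]
                tiers[(s + np.arange(l)) % n] = 1
            paintings.append(Painting(f"r{r:02d}", sid, tiers))
        out[sid] = paintings
    return out


# -- copy discrimination (2-AFC) --------------------------------------------

def simulate_copy_discrimination(cohort: Cohort, n_raters: int = 15,
                                 variations_per_category: int = 45,
                                 repeats: int = 3,
                                 copy_deviation_sd: float = 0.02,
                                 discrimination_noise: float = 0.05,
                                 seed: int = 0) -> pd.DataFrame:
    """2-AFC trials: which of copy vs variation is the exemplar's copy?

    Copies deviate from the exemplar by a small |N(0, sd)| magnitude; the
    rater answers correctly with probability Phi((dev_variation -
    dev_copy) / noise), so near-copies are hard and creative variations
    easy.  Returns one row per trial with a ``correct`` flag.
    """
    from scipy.stats import norm

    rng = np.random.default_rng(seed)
    rows = []
    for cat in sorted(cohort.exemplars):
        recs = [r for r in cohort.records if r.category == cat]
        recs = sorted(recs, key=lambda r: r.deviation)
        step = max(len(recs) // variations_per_category, 1)
        chosen = recs[::step][:variations_per_category]
        for rep in range(repeats):
            for r in range(n_raters):
                for rec in chosen:
                    dev_copy = abs(rng.normal(0, copy_deviation_sd))
                    p = norm.cdf((rec.deviation - dev_copy)
                                 / discrimination_noise)
                    rows.append(dict(rater=f"r{r:02d}", category=cat,
                                     shape=rec.shape_id, repeat=rep,
                                     correct=bool(rng.random() < p)))
    return pd.DataFrame(rows)


# -- swap-stimulus classification -------------------------------------------

def simulate_swap_classification(stimuli, cohort: Cohort,
                                 n_raters: int = 15,
                                 w_body: float = 1.0, w_dist: float = 1.6,
                                 w_indist: float = 0.9, tau: float = 0.55,
                                 seed: int = 0) -> pd.DataFrame:
    """Classify swap stimuli with an evidence model keyed on ground truth.

    Category evidence: the base category contributes ``w_body`` (its main
    body) plus ``w_dist`` when its distinctive part is intact (it is
    removed in the distinctive condition); the donor category contributes
    ``w_dist`` or ``w_indist`` depending on which of its parts was swapped
    in.  Choices are softmax over the eight categories at temperature
    ``tau``.  Pass ``stimuli=None`` entries via ``condition='none'`` rows
    for unswapped baselines.
    """
    rng = np.random.default_rng(seed)
    cats = sorted(cohort.exemplars)
    rows = []
    for stim in stimuli:
        if isinstance(stim, tuple):  # (shape_id, base_category) unswapped
            sid, base_cat = stim
            donor_cat, condition = None, "none"
        else:
            sid = stim.contour.shape_id
            base_cat, donor_cat = stim.base_category, stim.donor_category
            condition = stim.condition
        ev = {c: 0.0 for c in cats}
        ev[base_cat] += w_body
        if condition != "distinctive":
            ev[base_cat] += w_dist        # base's distinctive part intact
        if condition == "distinctive":
            ev[donor_cat] += w_dist
        elif condition == "indistinctive":
            ev[donor_cat] += w_indist
        logits = np.array([ev[c] / tau for c in cats])
        p = np.exp(logits - logits.max())
        p /= p.sum()
        for r in range(n_raters):
            resp = int(rng.choice(cats, p=p))
            rows.append(dict(rater=f"r{r:02d}", shape=sid,
                             true_category=base_cat,
                             donor_category=donor_cat, condition=condition,
                             response=resp, correct=resp == base_cat))
    return pd.DataFrame(rows)
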