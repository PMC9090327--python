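"""Aggregation of tiered distinctiveness paintings and the randomized null.

Raters paint up to three tiers on a shape's silhouette (tier 1 = most
distinctive, then 2, 3; at least one tier-1 run is required).  Each point
scores 3 per tier-1 response, 2 per tier-2 and 1 per tier-3, and the sum
is normalized to 0-100 by the highest possible score (3 x number of
raters).  High-score regions are maximal circular runs strictly above a
threshold (75 by default).  The randomized null keeps each tier's usage
frequency, number of painted areas and run lengths from the human corpus
but places the runs uniformly at random on the contour.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .contour import ClosedContour, ContourSegment, perimeter
from .stats import ks_2samp as _ks_2samp
from .stats import pearson_r

__all__ = [
    "TIER_WEIGHTS",
    "Painting",
    "DistinctivenessField",
    "NullModel",
    "aggregate_paintings",
    "high_score_regions",
    "high_region_perimeter_fraction",
    "fit_null_model",
    "sample_null_paintings",
    "compare_agreement",
    "correlate_part_distinctiveness",
]

#: Score added per response at each tier.
TIER_WEIGHTS = {1: 3, 2: 2, 3: 1}


@dataclass(frozen=True)
class Painting:
    """One rater's tier assignment per contour point (0 = unpainted)."""

    rater: str
    shape_id: str
    tiers: np.ndarray  # int array over the resampled contour, values 0..3

    def __post_init__(self) -> None:
        t = np.asarray(self.tiers, dtype=int)
        if t.ndim != 1:
            raise ValueError("tiers must be a 1-D per-point array")
        if t.min() < 0 or t.max() > 3:
            raise ValueError("tier values must lie in 0..3")
        if not np.any(t == 1):
            raise ValueError("at least one point must be painted tier 1")
        t.setflags(write=False)
        object.__setattr__(self, "tiers", t)


@dataclass(frozen=True)
class DistinctivenessField:
    shape_id: str
    scores: np.ndarray          # normalized 0-100 per point
    n_raters: int
    max_raw: int                # highest possible raw score = 3 * n_raters

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=float)
        if s.min() < 0 or s.max() > 100 + 1e-9:
            raise ValueError("normalized scores must lie in [0, 100]")
        s.setflags(write=False)
        object.__setattr__(self, "scores", s)


@dataclass(frozen=True)
class NullModel:
    """Empirical per-tier painting statistics for one category."""

    tier_usage: dict            # tier -> fraction of paintings using it
    run_lengths: dict           # tier -> list of observed run lengths
    area_counts: dict           # tier -> list of observed runs-per-painting
    category: Optional[int] = None


def aggregate_paintings(paintings: Sequence[Painting]) -> DistinctivenessField:
    """Sum 3/2/1 tier weights per point and normalize to 0-100."""
    if not paintings:
        raise ValueError("need at least one painting to aggregate")
    n = len(paintings[0].tiers)
    raw = np.zeros(n, dtype=float)
    for p in paintings:
        if len(p.tiers) != n:
            raise ValueError("paintings must share one resampled point count")
        for tier, w in TIER_WEIGHTS.items():
            raw[p.tiers == tier] += w
    max_raw = 3 * len(paintings)
    return DistinctivenessField(paintings[0].shape_id,
                                100.0 * raw / max_raw,
                                len(paintings), max_raw)


def _circular_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal circular runs of True as (start, length) pairs."""
    n = len(mask)
    if not mask.any():
        return []
    if mask.all():
        return [(0, n)]
    # rotate so position 0 is False, then find linear runs
    first_false = int(np.argmin(mask))
    rolled = np.roll(mask, -first_false)
    runs = []
    start = None
    for i, v in enumerate(rolled):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append(((start + first_false) % n, i - start))
            start = None
    if start is not None:
        runs.append(((start + first_false) % n, n - start))
    return runs


def high_score_regions(field: DistinctivenessField,
                       contour: ClosedContour,
                       threshold: float = 75.0) -> list[ContourSegment]:
    """Maximal circular runs of points scoring strictly above threshold."""
    mask = field.scores > threshold
    return [ContourSegment(contour, s, l) for s, l in _circular_runs(mask)]


def high_region_perimeter_fraction(field: DistinctivenessField,
                                   contour: ClosedContour,
                                   threshold: float = 75.0,
                                   mode: str = "largest") -> float:
    """Arc length of high-score region(s) as a fraction of the perimeter.

    ``mode="largest"`` (default) uses the single largest consecutive
    region; ``mode="total"`` sums all regions.
    """
    regions = high_score_regions(field, contour, threshold)
    if not regions:
        return 0.0
    per = perimeter(contour)
    if mode == "largest":
        # a full-cover region has no closing chord gap, so use arc including
        # the wrap edge when length == n
        best = max(regions, key=lambda r: r.length)
        if best.length == contour.n:
            return 1.0
        return _region_arc(best) / per
    if mode == "total":
        if regions[0].length == contour.n:
            return 1.0
        return sum(_region_arc(r) for r in regions) / per
    raise ValueError("mode must be 'largest' or 'total'")


def _region_arc(seg: ContourSegment) -> float:
    """Arc length of a region, counting the half-edges to its neighbours.

    Each point owns half of each adjacent edge, so a run of k points out
    of n equally spaced points covers k/n of the perimeter.
    """
    contour = seg.contour
    pts = contour.points
    n = contour.n
    idx = seg.indices()
    prev_edge = np.linalg.norm(pts[idx] - pts[(idx - 1) % n], axis=1)
    next_edge = np.linalg.norm(pts[(idx + 1) % n] - pts[idx], axis=1)
    return float(0.5 * (prev_edge.sum() + next_edge.sum()))


# ---------------------------------------------------------------------------
# randomized null

def fit_null_model(paintings: Sequence[Painting],
                   category: Optional[int] = None) -> NullModel:
    """Estimate tier usage, run-length and area-count distributions."""
    if not paintings:
        raise ValueError("need at least one painting to fit the null model")
    usage: dict = {}
    lengths: dict = {t: [] for t in TIER_WEIGHTS}
    counts: dict = {t: [] for t in TIER_WEIGHTS}
    for t in TIER_WEIGHTS:
        used = 0
        for p in paintings:
            runs = _circular_runs(p.tiers == t)
            if runs:
                used += 1
                counts[t].append(len(runs))
                lengths[t].extend(l for _s, l in runs)
        usage[t] = used / len(paintings)
    usage[1] = 1.0  # tier 1 is mandatory by the painting interface
    return NullModel(usage, lengths, counts, category)


def sample_null_paintings(model: NullModel, shape: ClosedContour,
                          n_raters: int, rng: np.random.Generator,
                          *, shape_id: Optional[str] = None,
                          max_retries: int = 200) -> list[Painting]:
    """Draw randomized paintings matching the corpus statistics.

    Run counts and lengths are resampled from the empirical distributions;
    placement is uniform on the contour; tiers never overlap within one
    sampled rater (rejection-resampled with fresh lengths on failure) and
    tier 1 is always present.
    """
    n = shape.n
    sid = shape_id or (shape.shape_id or "shape")
    out = []
    for r in range(n_raters):
        tiers = _sample_one_null(model, n, rng, max_retries)
        out.append(Painting(f"null{r}", sid, tiers))
    return out


def _sample_one_null(model: NullModel, n: int, rng: np.random.Generator,
                     max_retries: int) -> np.ndarray:
    for _attempt in range(max_retries):
        tiers = np.zeros(n, dtype=int)
        ok = True
        for t in sorted(TIER_WEIGHTS):
            if t != 1 and rng.random() >= model.tier_usage.get(t, 0.0):
                continue
            counts = model.area_counts.get(t) or []
            lengths = model.run_lengths.get(t) or []
            if not counts or not lengths:
                if t == 1:
                    ok = False
                continue
            k = int(rng.choice(counts))
            for _run in range(k):
                length = min(int(rng.choice(lengths)), n)
                if not _place_run(tiers, t, length, rng):
                    ok = False
                    break
            if not ok:
                break
        if ok and np.any(tiers == 1):
            return tiers
    raise RuntimeError("could not place null painting runs without overlap")


def _place_run(tiers: np.ndarray, tier: int, length: int,
               rng: np.random.Generator, tries: int = 50) -> bool:
    n = len(tiers)
    for _ in range(tries):
        start = int(rng.integers(n))
        idx = (start + np.arange(length)) % n
        if not np.any(tiers[idx]):
            tiers[idx] = tier
            return True
    return False


# ---------------------------------------------------------------------------
# comparisons

def compare_agreement(human_fractions, null_fractions) -> tuple[float, float]:
    """Two-sample KS test on per-shape high-score perimeter fractions."""
    return _ks_2samp(human_fractions, null_fractions)


def correlate_part_distinctiveness(
        segment_pairs: Sequence[tuple[ContourSegment, ContourSegment]],
        exemplar_field: "DistinctivenessField | dict",
        variation_fields: Optional[dict] = None) -> tuple[float, float]:
    """Pearson r between exemplar-part and variation-part mean scores.

    ``segment_pairs`` holds (exemplar segment, variation segment) pairs;
    fields are looked up by the segment's contour ``shape_id`` when dicts
    are given, else a single exemplar field is used for the first element.
    """
    if len(segment_pairs) < 3:
        raise ValueError("need at least 3 part pairs for a correlation")
    xs, ys = [], []
    for eseg, vseg in segment_pairs:
        ef = (exemplar_field[eseg.contour.shape_id]
              if isinstance(exemplar_field, dict) else exemplar_field)
        vf = (variation_fields[vseg.contour.shape_id]
              if variation_fields is not None else ef)
        xs.append(float(np.mean(ef.scores[eseg.indices()])))
        ys.append(float(np.mean(vf.scores[vseg.indices()])))
    return pearson_r(xs, ys)
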