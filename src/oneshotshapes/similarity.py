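"""Similarity-space analysis of placement ratings.

Raters arrange a category's variations along an axis relative to the
exemplar; per rater the absolute distances are rescaled so the exemplar
sits at 0 and the rater's most distant shape at 1, then averaged across
raters.  Derived statistics: a per-drawer creativity index (mean perceived
similarity of a drawer's variations), the within-session order trend
(does the drawing's serial position predict similarity?), and
similarity-spanning stimulus subsets picked from equal-width bins.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .stats import TrendResult, ols

__all__ = [
    "normalize_ratings",
    "aggregate_similarity",
    "creativity_index",
    "order_trend",
    "select_spanning_subset",
]


def normalize_ratings(placements: pd.DataFrame) -> pd.Series:
    """Normalize one rater x one category of placements to [0, 1].

    ``placements`` needs columns ``x`` and ``x_exemplar``.  The value is
    ``|x - x_exemplar|`` rescaled by the rater's most distant shape, which
    makes it invariant under affine rescaling of the rater's axis.
    """
    if len(placements) == 0:
        raise ValueError("no placements to normalize")
    d = (placements["x"] - placements["x_exemplar"]).abs().astype(float)
    dmax = d.max()
    if dmax <= 0:
        raise ValueError("degenerate scale: every shape placed at the exemplar")
    return d / dmax


def normalize_table(placements: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`normalize_ratings` per (rater, category); adds column ``s``."""
    out = placements.copy()
    out["s"] = (out.groupby(["rater", "category"], group_keys=False)
                .apply(normalize_ratings, include_groups=False))
    return out


def aggregate_similarity(normalized: pd.DataFrame) -> pd.DataFrame:
    """Per-shape mean similarity across raters.

    Returns a frame indexed by shape with columns ``s`` (mean), ``var``
    (unbiased between-rater variance) and ``n_raters``.  Shapes missing
    for some raters are averaged over the raters who placed them.
    """
    g = normalized.groupby("shape")["s"]
    out = pd.DataFrame({"s": g.mean(), "var": g.var(ddof=1),
                        "n_raters": g.count()})
    cat = normalized.groupby("shape")["category"].first()
    out["category"] = cat
    return out


def creativity_index(records: pd.DataFrame, scores: pd.DataFrame) -> pd.DataFrame:
    """Per-drawer mean perceived similarity with standard error.

    Lower mean similarity = drawings further from the exemplar = a more
    creative drawer.  ``records`` maps shapes to drawers (columns ``shape``,
    ``drawer``); ``scores`` comes from :func:`aggregate_similarity`.
    """
    merged = records.merge(scores["s"], left_on="shape", right_index=True)
    g = merged.groupby("drawer")["s"]
    return pd.DataFrame({"mean_s": g.mean(),
                         "sem": g.std(ddof=1) / np.sqrt(g.count()),
                         "n": g.count()})


def order_trend(records: pd.DataFrame, scores: pd.DataFrame
                ) -> tuple[dict, TrendResult]:
    """OLS of similarity on within-session drawing index (1..12).

    Returns per-drawer trends (drawer -> TrendResult, or None when fewer
    than 3 drawings) and the pooled trend over all drawings.
    """
    merged = records.merge(scores["s"], left_on="shape", right_index=True)
    per_drawer: dict = {}
    for drawer, grp in merged.groupby("drawer"):
        if len(grp) < 3:
            per_drawer[drawer] = None
            continue
        per_drawer[drawer] = ols(grp["drawing_index"], grp["s"])
    pooled = ols(merged["drawing_index"], merged["s"])
    return per_drawer, pooled


def select_spanning_subset(scores: pd.DataFrame, n_bins: int) -> list:
    """Pick one shape per equal-width similarity bin over [0, 1].

    Within each bin the shape with the lowest between-rater variance wins
    (ties: lower shape id).  Empty bins are filled from neighbouring bins
    in the order +1, -1, +2, -2, ... with a not-yet-used shape, or left
    out when no spare remains.  Returned ids are in bin order, so their
    mean similarities are non-decreasing up to the borrowed fills.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if len(scores) == 0:
        raise ValueError("no scores to select from")
    if n_bins > len(scores):
        warnings.warn("more bins than shapes; returning fewer ids")
    s = scores["s"].clip(0, 1)
    bins = np.minimum((s * n_bins).astype(int), n_bins - 1)
    by_bin: dict[int, list] = {}
    for b in range(n_bins):
        grp = scores.loc[bins == b]
        # candidates ordered by variance, ties by shape id
        by_bin[b] = list(grp.sort_index(kind="stable")
                         .sort_values("var", kind="stable").index)
    used: set = set()
    chosen: dict[int, object] = {}
    for b in range(n_bins):  # primary pass: min-variance shape per bin
        for sid in by_bin[b]:
            if sid not in used:
                chosen[b] = sid
                used.add(sid)
                break
    for b in range(n_bins):  # fill pass for empty bins
        if b in chosen:
            continue
        for dist in range(1, n_bins):
            filled = False
            for nb in (b + dist, b - dist):
                if not 0 <= nb < n_bins:
                    continue
                spare = [sid for sid in by_bin[nb] if sid not in used]
                if spare:
                    chosen[b] = spare[0]
                    used.add(spare[0])
                    filled = True
                    break
            if filled:
                break
    return [chosen[b] for b in sorted(chosen)]
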