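"""Statistical machinery for the drawing-categorization analyses.

One-sided exact binomial tests with Bonferroni adjustment, confusion
matrices over the eight shape categories, Cohen's h / d effect sizes,
regression and correlation wrappers, and the a-priori sample-size
calculators (normal-approximation binomial and noncentral-t).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import asin, ceil, sqrt
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "BinomialTestResult",
    "TrendResult",
    "EffectSize",
    "SampleSizeResult",
    "ConfusionMatrix",
    "binomial_test_one_sided",
    "bonferroni_alpha",
    "confusion_analysis",
    "cohens_h",
    "binomial_sample_size",
    "t_test_sample_size",
    "t_test",
    "pearson_r",
    "ols",
    "ks_2samp",
]


@dataclass(frozen=True)
class BinomialTestResult:
    k: int
    n: int
    p0: float
    p_value: float
    proportion: float
    alternative: str = "greater"


@dataclass(frozen=True)
class TrendResult:
    """Ordinary least-squares fit of y on x (single regressor)."""
    slope: float
    intercept: float
    r_squared: float
    f_stat: float
    df: tuple[int, int]
    p_value: float


@dataclass(frozen=True)
class EffectSize:
    kind: str  # "cohens_h" | "cohens_d"
    value: float


@dataclass(frozen=True)
class SampleSizeResult:
    n: int
    params: dict
    exact_n: Optional[int] = None


@dataclass(frozen=True)
class ConfusionMatrix:
    counts: pd.DataFrame          # true category x response, raw counts
    proportions: pd.DataFrame     # row-normalized
    p_values: pd.DataFrame        # one-sided vs chance, tail per direction
    direction: pd.DataFrame       # "above" / "below" chance
    significant: pd.DataFrame     # at the Bonferroni-adjusted alpha
    alpha: float
    chance: float


def binomial_test_one_sided(k: int, n: int, p0: float,
                            alternative: str = "greater") -> BinomialTestResult:
    """Exact one-sided binomial test; upper tail P(X >= k) by default."""
    if not 0 < p0 < 1:
        raise ValueError("p0 must lie strictly between 0 and 1")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    res = sps.binomtest(int(k), int(n), p0, alternative=alternative)
    return BinomialTestResult(int(k), int(n), float(p0), float(res.pvalue),
                              k / n if n else float("nan"), alternative)


def bonferroni_alpha(family_alpha: float, m: int) -> float:
    """Per-test alpha under Bonferroni correction for m tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return family_alpha / m


def cohens_h(p1: float, p2: float) -> EffectSize:
    """Effect size for two proportions: h = 2 asin(sqrt p1) - 2 asin(sqrt p2)."""
    for p in (p1, p2):
        if not 0 <= p <= 1:
            raise ValueError("proportions must lie in [0, 1]")
    return EffectSize("cohens_h", 2 * asin(sqrt(p1)) - 2 * asin(sqrt(p2)))


def confusion_analysis(choices: pd.DataFrame, *, n_categories: int = 8,
                       family_alpha: float = 0.05,
                       adjust_m: Optional[int] = None) -> ConfusionMatrix:
    """Confusion matrix with per-cell one-sided binomial tests vs chance.

    ``choices`` needs columns ``true_category`` and ``response``.  Each cell
    is tested against chance 1/n_categories: diagonal-direction cells with
    observed proportion above chance use the upper tail, others the lower
    tail.  The per-cell alpha is Bonferroni-adjusted for ``adjust_m`` tests
    (default: the number of possible outcomes per row).
    """
    cats = list(range(1, n_categories + 1))
    counts = (choices.groupby(["true_category", "response"]).size()
              .unstack(fill_value=0).reindex(index=cats, columns=cats,
                                             fill_value=0))
    chance = 1.0 / n_categories
    m = adjust_m if adjust_m is not None else n_categories
    alpha = bonferroni_alpha(family_alpha, m)
    row_n = counts.sum(axis=1)
    props = counts.div(row_n.replace(0, np.nan), axis=0)
    pvals = pd.DataFrame(np.nan, index=cats, columns=cats)
    direction = pd.DataFrame("", index=cats, columns=cats)
    for t in cats:
        n = int(row_n[t])
        if n == 0:
            continue
        for r in cats:
            k = int(counts.loc[t, r])
            above = k / n >= chance
            alt = "greater" if above else "less"
            pvals.loc[t, r] = binomial_test_one_sided(k, n, chance, alt).p_value
            direction.loc[t, r] = "above" if above else "below"
    significant = pvals < alpha
    return ConfusionMatrix(counts, props, pvals, direction, significant,
                           alpha, chance)


# ---------------------------------------------------------------------------
# sample sizes

def binomial_sample_size(p0: float, p1: float, alpha: float, power: float
                         ) -> SampleSizeResult:
    """Trials needed for a one-sided one-sample binomial test (upper tail).

    The headline ``n`` uses the normal-approximation formula
    ``n = ceil(((z_{1-a} sqrt(p0 q0) + z_{1-b} sqrt(p1 q1)) / (p1-p0))^2)``;
    an exact-binomial search result is reported alongside in ``exact_n``.
    """
    if not (0 < p0 < p1 < 1):
        raise ValueError("need 0 < p0 < p1 < 1")
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must lie in (0, 1)")
    za = sps.norm.ppf(1 - alpha)
    zb = sps.norm.ppf(power)
    n = ceil(((za * sqrt(p0 * (1 - p0)) + zb * sqrt(p1 * (1 - p1)))
              / (p1 - p0)) ** 2)
    exact_n = _exact_binomial_n(p0, p1, alpha, power, hint=n)
    return SampleSizeResult(int(n), dict(p0=p0, p1=p1, alpha=alpha,
                                         power=power, sidedness="one",
                                         design="one_sample"),
                            exact_n=exact_n)


def exact_binomial_power(n: int, p0: float, p1: float, alpha: float) -> float:
    """Power of the exact one-sided (upper-tail) binomial test at size n."""
    k_crit = int(sps.binom.isf(alpha, n, p0)) + 1  # smallest k with P(X>=k)<=alpha
    while k_crit > 0 and sps.binom.sf(k_crit - 1, n, p0) <= alpha:
        k_crit -= 1
    k_crit += 1
    return float(sps.binom.sf(k_crit - 1, n, p1))


def _exact_binomial_n(p0, p1, alpha, power, hint: int) -> Optional[int]:
    for n in range(max(2, hint // 2), 2 * hint + 200):
        if exact_binomial_power(n, p0, p1, alpha) >= power:
            return n
    return None


def t_test_power(n_per_group: int, d: float, alpha: float,
                 sidedness: str = "one", design: str = "two_sample") -> float:
    """Noncentral-t power of a t-test at the given per-group size."""
    a = alpha if sidedness == "one" else alpha / 2
    if design == "two_sample":
        df = 2 * n_per_group - 2
        nc = d * sqrt(n_per_group / 2.0)
    else:
        df = n_per_group - 1
        nc = d * sqrt(n_per_group)
    if df < 1:
        return 0.0
    t_crit = sps.t.ppf(1 - a, df)
    return float(sps.nct.sf(t_crit, df, nc))


def t_test_sample_size(d: float, alpha: float, power: float,
                       sidedness: str = "one", design: str = "two_sample"
                       ) -> SampleSizeResult:
    """Smallest total n whose noncentral-t power reaches the target.

    For the two-sample design, groups are equal and ``n`` is the total
    across both groups.
    """
    if d <= 0:
        raise ValueError("d must be positive")
    lo, hi = 2, 4
    while t_test_power(hi, d, alpha, sidedness, design) < power:
        hi *= 2
        if hi > 10 ** 8:
            raise ValueError("required sample size out of range")
    while lo < hi:
        mid = (lo + hi) // 2
        if t_test_power(mid, d, alpha, sidedness, design) >= power:
            hi = mid
        else:
            lo = mid + 1
    n_group = lo
    total = 2 * n_group if design == "two_sample" else n_group
    return SampleSizeResult(int(total),
                            dict(d=d, alpha=alpha, power=power,
                                 sidedness=sidedness, design=design,
                                 n_per_group=int(n_group)))


# ---------------------------------------------------------------------------
# wrappers

def t_test(sample1, sample2=None, *, kind: str = "pooled",
           alternative: str = "greater"):
    """t-test returning (t, df, p); pooled two-sample by default."""
    a = np.asarray(sample1, dtype=float)
    if sample2 is None:
        res = sps.ttest_1samp(a, 0.0, alternative=alternative)
        df = len(a) - 1
    else:
        b = np.asarray(sample2, dtype=float)
        equal_var = kind == "pooled"
        res = sps.ttest_ind(a, b, equal_var=equal_var, alternative=alternative)
        df = (len(a) + len(b) - 2) if equal_var else float(res.df)
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            raise ValueError("degenerate (zero-variance) samples")
    return float(res.statistic), df, float(res.pvalue)


def pearson_r(x, y) -> tuple[float, float]:
    r, p = sps.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(r), float(p)


def ols(x, y) -> TrendResult:
    """Simple OLS of y on x with intercept, reporting R^2, F(1, n-2), p."""
    import statsmodels.api as sm

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 points for a trend")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    f = float(model.fvalue) if np.isfinite(model.fvalue) else 0.0
    p = float(model.f_pvalue) if np.isfinite(model.f_pvalue) else 1.0
    return TrendResult(slope=float(model.params[1]),
                       intercept=float(model.params[0]),
                       r_squared=float(model.rsquared),
                       f_stat=f,
                       df=(1, int(model.df_resid)),
                       p_value=p)


def ks_2samp(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (exact for small samples)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    method = "exact" if min(len(a), len(b)) <= 25 else "asymp"
    res = sps.ks_2samp(a, b, method=method)
    return float(res.statistic), float(res.pvalue)
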