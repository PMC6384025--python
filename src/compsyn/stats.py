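"""Statistical tests used by the competition analyses.

All tests follow the conventions of the quantification they serve:

* two-sample comparisons use the pooled-variance Student t-test
  (df = n1 + n2 - 2), not Welch;
* one-way ANOVA is followed by Tukey's HSD, with adjusted p-values from the
  studentized-range distribution;
* contingency contrasts use Fisher's exact test with the two-sided
  "sum of all tables no more probable than the observed one" convention;
* group data are summarized as mean ± SEM with the (n-1)-denominator SD.

p-values are returned at full precision; rounding to a printed number of
decimals is the caller's concern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "TestResult",
    "PairwiseResult",
    "mean_sem",
    "t_tail_p",
    "f_tail_p",
    "two_sample_t",
    "one_sample_t",
    "one_way_anova",
    "tukey_hsd",
    "fisher_exact_two_sided",
]


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sem: float
    n: int


@dataclass(frozen=True)
class PairwiseResult:
    """One Tukey HSD contrast."""

    group_a: int
    group_b: int
    mean_diff: float
    q: float
    p_adj: float


@dataclass(frozen=True)
class TestResult:
    name: str
    statistic: float
    df: float | tuple[float, float]
    pvalue: float
    groups: tuple[GroupSummary, ...] = ()
    pairwise: tuple[PairwiseResult, ...] = ()


def mean_sem(x) -> GroupSummary:
    """Mean, standard error of the mean (SD/(n-1) denominator over sqrt n), n."""
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1 or arr.size < 1:
        raise ValueError("expected a non-empty 1-D sample")
    n = arr.size
    sem = float(arr.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan")
    return GroupSummary(float(arr.mean()), sem, n)


def t_tail_p(t_value: float, df: float) -> float:
    """Two-sided tail probability of Student's t: 2·(1 − CDF(|t|; df))."""
    if df <= 0:
        raise ValueError("df must be positive")
    return float(2.0 * sps.t.sf(abs(t_value), df))


def f_tail_p(f_value: float, df1: float, df2: float) -> float:
    """Upper tail probability of the F distribution."""
    if df1 <= 0 or df2 <= 0:
        raise ValueError("df must be positive")
    return float(sps.f.sf(f_value, df1, df2))


def two_sample_t(x, y) -> TestResult:
    """Pooled-variance two-tailed Student's t-test (df = n1 + n2 − 2)."""
    gx, gy = mean_sem(x), mean_sem(y)
    if gx.n < 2 or gy.n < 2:
        raise ValueError("each sample needs n >= 2")
    ax, ay = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    df = gx.n + gy.n - 2
    ss = ax.var(ddof=1) * (gx.n - 1) + ay.var(ddof=1) * (gy.n - 1)
    pooled = ss / df
    if pooled == 0:
        if gx.mean == gy.mean:
            return TestResult("two_sample_t", 0.0, df, 1.0, (gx, gy))
        raise ValueError("zero pooled variance with unequal means")
    t = (gx.mean - gy.mean) / math.sqrt(pooled * (1 / gx.n + 1 / gy.n))
    return TestResult("two_sample_t", float(t), df, t_tail_p(t, df), (gx, gy))


def one_sample_t(x, mu0: float = 0.0) -> TestResult:
    """Two-tailed one-sample t-test of mean(x) against mu0 (df = n − 1)."""
    g = mean_sem(x)
    if g.n < 2:
        raise ValueError("sample needs n >= 2")
    if g.sem == 0:
        if g.mean == mu0:
            return TestResult("one_sample_t", 0.0, g.n - 1, 1.0, (g,))
        raise ValueError("zero variance with mean != mu0")
    t = (g.mean - mu0) / g.sem
    return TestResult("one_sample_t", float(t), g.n - 1, t_tail_p(t, g.n - 1), (g,))


def one_way_anova(groups, tukey: bool = True) -> TestResult:
    """One-way fixed-effects ANOVA, F with df (k−1, N−k), plus Tukey HSD.

    Parameters
    ----------
    groups
        Sequence of 1-D samples, one per group (k >= 2, each n >= 2).
    tukey
        Attach all-pairs Tukey HSD results (default True).
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrs)
    if k < 2 or any(a.size < 2 for a in arrs):
        raise ValueError("need >= 2 groups with n >= 2 each")
    ns = np.array([a.size for a in arrs])
    N = int(ns.sum())
    means = np.array([a.mean() for a in arrs])
    grand = float(np.concatenate(arrs).mean())
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(a.var(ddof=0) * a.size for a in arrs))
    df1, df2 = k - 1, N - k
    ms_between = ss_between / df1
    ms_within = ss_within / df2
    if ms_within == 0:
        if ss_between == 0:
            return TestResult(
                "one_way_anova", 0.0, (df1, df2), 1.0,
                tuple(mean_sem(a) for a in arrs),
            )
        raise ValueError("zero within-group variance with unequal means")
    F = ms_between / ms_within
    summaries = tuple(mean_sem(a) for a in arrs)
    pairs = tuple(tukey_hsd(arrs, ms_within, df2)) if tukey else ()
    return TestResult(
        "one_way_anova", float(F), (df1, df2), f_tail_p(F, df1, df2),
        summaries, pairs,
    )


def tukey_hsd(groups, ms_within: float | None = None, df: int | None = None):
    """All-pairs Tukey HSD on the groups of a one-way layout.

    Adjusted p-values come from the studentized-range distribution with
    parameters (k, N−k); unequal group sizes use the Tukey–Kramer standard
    error.  ``ms_within``/``df`` may be supplied by the caller (as
    :func:`one_way_anova` does) or are recomputed here.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrs)
    if ms_within is None or df is None:
        N = sum(a.size for a in arrs)
        df = N - k
        ms_within = sum(a.var(ddof=0) * a.size for a in arrs) / df
    out: list[PairwiseResult] = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(arrs[i].mean() - arrs[j].mean())
            se = math.sqrt(ms_within / 2 * (1 / arrs[i].size + 1 / arrs[j].size))
            if se == 0:
                q, p = (0.0, 1.0) if diff == 0 else (float("inf"), 0.0)
            else:
                q = abs(diff) / se
                p = float(sps.studentized_range.sf(q, k, df))
            out.append(PairwiseResult(i, j, diff, float(q), min(max(p, 0.0), 1.0)))
    return out


def fisher_exact_two_sided(table, mode: str = "sum_small") -> TestResult:
    """Fisher's exact test on a 2×2 table of non-negative integer counts.

    ``mode="sum_small"`` (default): two-sided p is the sum of the
    probabilities, under the conditional hypergeometric law with the observed
    margins fixed, of every table whose point probability does not exceed the
    observed table's (up to a 1e-12 relative tolerance for float ties).
    ``mode="doubled"``: twice the smaller one-tailed p, capped at 1.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(arr < 0) or not np.issubdtype(arr.dtype, np.integer):
        if not np.all(arr == np.floor(arr)) or np.any(arr < 0):
            raise ValueError("cells must be non-negative integers")
        arr = arr.astype(np.int64)
    a, b = int(arr[0, 0]), int(arr[0, 1])
    c, d = int(arr[1, 0]), int(arr[1, 1])
    n = a + b + c + d
    r1 = a + b      # first-row margin
    c1 = a + c      # first-column margin
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, c1, r1)
    p_obs = float(sps.hypergeom.pmf(a, n, c1, r1))
    if mode == "sum_small":
        p = float(pmf[pmf <= p_obs * (1 + 1e-12)].sum())
    elif mode == "doubled":
        lower = float(pmf[support <= a].sum())
        upper = float(pmf[support >= a].sum())
        p = 2 * min(lower, upper)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    p = min(max(p, 0.0), 1.0)
    odds = math.inf if b * c == 0 and a * d > 0 else (
        (a * d) / (b * c) if b * c else math.nan
    )
    return TestResult("fisher_exact", odds, 1, p)
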