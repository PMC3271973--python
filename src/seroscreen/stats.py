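"""Serum-validation statistics.

Group summaries and their exact pooling, two-sample t tests (from raw
values or from published summary statistics alone), one-way ANOVA with
Bonferroni-corrected pairwise post-hoc comparisons, fold changes, and the
age-correlation check.  The default two-sample test is Welch's (unequal
variances); the pooled-variance Student variant is available where the
classical identity F = t^2 is wanted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from collections.abc import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "pool_summaries",
    "welch_t_from_summaries",
    "ttest_raw",
    "anova_bonferroni",
    "fold_change",
    "pearson_r2",
]


@dataclass(frozen=True)
class TestResult:
    """Outcome of a hypothesis test.

    ``statistic`` is t or F, ``df`` the (possibly fractional) degrees of
    freedom — a tuple for F — and ``p`` the two-sided p-value.
    ``adjusted_p`` is set when a multiplicity correction applies.
    """

    statistic: float
    df: float | tuple[float, float]
    p: float
    comparison: str = ""
    adjusted_p: float | None = None
    note: str | None = None


def pool_summaries(
    groups: Sequence[tuple[int, float, float | None]],
) -> tuple[int, float, float]:
    """Exactly pool (n, mean, sd) summaries of disjoint groups.

    Returns (N, pooled mean, pooled sd) equal to the moments of the
    concatenated raw data:

        mean = sum(n_i m_i) / N
        var  = [sum((n_i-1) s_i^2) + sum(n_i (m_i - mean)^2)] / (N - 1)

    ``sd`` may be None for n=1 groups (it contributes no within-group sum
    of squares).  Pooled sd is NaN when N < 2.
    """
    if not groups:
        raise ValueError("no groups to pool")
    ns = np.array([g[0] for g in groups], dtype=float)
    means = np.array([g[1] for g in groups], dtype=float)
    if (ns < 1).any():
        raise ValueError("group sizes must be >= 1")
    for n, _, sd in groups:
        if n >= 2 and sd is None:
            raise ValueError("sd required for groups with n >= 2")
    sds = np.array([0.0 if g[2] is None else g[2] for g in groups], dtype=float)
    big_n = ns.sum()
    mean = float((ns * means).sum() / big_n)
    if big_n < 2:
        return int(big_n), mean, float("nan")
    within = ((ns - 1) * sds**2).sum()
    between = (ns * (means - mean) ** 2).sum()
    var = (within + between) / (big_n - 1)
    return int(big_n), mean, float(math.sqrt(var))


def welch_t_from_summaries(
    m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> TestResult:
    """Welch two-sample t test from summary statistics only.

    Uses the Welch statistic with the Welch–Satterthwaite degrees of
    freedom; two-sided p from the t distribution.  Degenerate zero-sd
    inputs are resolved by convention: equal means give p = 1, unequal
    means give the p = 0 limit (flagged in ``note``).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("summary t test needs n >= 2 in both groups")
    if s1 < 0 or s2 < 0:
        raise ValueError("standard deviations must be >= 0")
    v1, v2 = s1**2 / n1, s2**2 / n2
    if v1 + v2 == 0:
        if m1 == m2:
            return TestResult(0.0, float(n1 + n2 - 2), 1.0, note="zero variance, equal means")
        return TestResult(
            math.copysign(math.inf, m1 - m2),
            float(n1 + n2 - 2),
            0.0,
            note="zero variance, unequal means (limit)",
        )
    t = (m1 - m2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = float(2 * sps.t.sf(abs(t), df))
    return TestResult(float(t), float(df), p)


def ttest_raw(
    a: Sequence[float], b: Sequence[float], variant: str = "welch"
) -> TestResult:
    """Two-sided two-sample t test on raw values.

    variant 'welch' (default) makes no equal-variance assumption;
    'pooled' is the classical Student test with pooled variance.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown variant: {variant}")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return welch_t_from_summaries(
            a.mean(), 0.0, len(a), b.mean(), 0.0, len(b)
        )
    res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return TestResult(float(res.statistic), float(res.df), float(res.pvalue))


def anova_bonferroni(
    groups: Mapping[str, Sequence[float]],
    pairwise_variant: str = "welch",
) -> tuple[TestResult, list[TestResult]]:
    """One-way ANOVA plus Bonferroni-adjusted pairwise post-hoc t tests.

    The Bonferroni family is all k(k-1)/2 pairwise comparisons:
    adjusted_p = min(1, p * n_pairs).  When every value in every group is
    identical the ANOVA is degenerate and reported as F = 0, p = 1.
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise ValueError(f"group {k!r} needs n >= 2")
    big_n = sum(len(v) for v in arrays.values())
    df_between = len(labels) - 1
    df_within = big_n - len(labels)
    concat = np.concatenate(list(arrays.values()))
    if concat.std(ddof=0) == 0:
        overall = TestResult(
            0.0, (float(df_between), float(df_within)), 1.0, note="degenerate: all values identical"
        )
    else:
        f, p = sps.f_oneway(*arrays.values())
        overall = TestResult(float(f), (float(df_between), float(df_within)), float(p))

    n_pairs = len(labels) * (len(labels) - 1) // 2
    pairwise = []
    for i, ka in enumerate(labels):
        for kb in labels[i + 1 :]:
            res = ttest_raw(arrays[ka], arrays[kb], variant=pairwise_variant)
            pairwise.append(
                TestResult(
                    res.statistic,
                    res.df,
                    res.p,
                    comparison=f"{ka} vs {kb}",
                    adjusted_p=min(1.0, res.p * n_pairs),
                    note=res.note,
                )
            )
    return overall, pairwise


def fold_change(mean_case: float, mean_ref: float) -> float:
    """Ratio of case mean to reference mean (reporting may round to "~k×")."""
    if mean_ref <= 0:
        raise ValueError("reference mean must be > 0")
    return mean_case / mean_ref


def pearson_r2(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation; NaN when either vector has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired vectors with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("values must be finite")
    if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
        return float("nan")
    r = sps.pearsonr(x, y).statistic
    return float(r * r)
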