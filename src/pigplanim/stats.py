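"""Statistical analyses of the posture-group data.

Covers the study's four analyses: descriptive summaries per posture group,
Spearman rank correlation between live weight and covered area within a
group, mean comparisons between posture groups (Welch's t, also computable
straight from published summary statistics), and all-pairs group-weight
comparisons with Tukey-Kramer adjustment plus compact-letter display.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "SampleSummary",
    "TestResult",
    "PairwiseResult",
    "describe",
    "spearman",
    "welch_t_from_summary",
    "welch_t",
    "pairwise_comparison",
    "significance_letters",
]


@dataclass(frozen=True)
class SampleSummary:
    """n, mean, SD (n−1 denominator), min, max of one sample."""

    n: int
    mean: float
    sd: float
    min: float
    max: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float
    p_value: float
    method: str


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    difference: float
    statistic: float
    p_adjusted: float
    significant: bool


def describe(values: Sequence[float]) -> SampleSummary:
    """Descriptive summary; sample SD uses the n−1 denominator (0 for n=1)."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("cannot describe an empty sample")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return SampleSummary(
        n=int(arr.size), mean=float(arr.mean()), sd=sd,
        min=float(arr.min()), max=float(arr.max()),
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, TestResult]:
    """Spearman rho on average ranks with a t-approximation p-value.

    Ties get average ranks; the p-value uses the t statistic
    ``rho·sqrt((n−2)/(1−rho²))`` on n−2 degrees of freedom. Constant input
    in either variable leaves the correlation undefined and raises.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D samples")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant sample")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2
    if abs(rho) >= 1.0:
        t, p = math.copysign(math.inf, rho), 0.0
    else:
        t = rho * math.sqrt(df / (1.0 - rho * rho))
        p = 2.0 * sps.t.sf(abs(t), df)
    return rho, TestResult(statistic=t, df=df, p_value=p, method="spearman-t")


def welch_t_from_summary(s1: SampleSummary, s2: SampleSummary) -> TestResult:
    """Welch's two-sample t-test computed from summary statistics.

    Uses the Welch-Satterthwaite degrees of freedom; robust to the unequal
    group sizes and variances of the posture groups. With equal n and equal
    SD it coincides with the pooled-variance test.
    """
    if s1.n < 2 or s2.n < 2:
        raise ValueError("both groups need n >= 2")
    v1, v2 = s1.sd**2 / s1.n, s2.sd**2 / s2.n
    se2 = v1 + v2
    if se2 == 0:
        stat = 0.0 if s1.mean == s2.mean else math.inf
        return TestResult(stat, s1.n + s2.n - 2,
                          1.0 if stat == 0 else 0.0, "welch-t")
    stat = (s1.mean - s2.mean) / math.sqrt(se2)
    df = se2**2 / (v1**2 / (s1.n - 1) + v2**2 / (s2.n - 1))
    p = 2.0 * sps.t.sf(abs(stat), df)
    return TestResult(statistic=stat, df=df, p_value=p, method="welch-t")


def welch_t(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Welch's t on raw samples (via :func:`describe`)."""
    return welch_t_from_summary(describe(a), describe(b))


def _tukey_p(q: float, k: int, df: float) -> float:
    return float(sps.studentized_range.sf(q, k, df))


def pairwise_comparison(
    groups: Mapping[str, Sequence[float] | SampleSummary],
    alpha: float = 0.05,
) -> tuple[list[PairwiseResult], dict[str, str]]:
    """All-pairs comparison of group means with Tukey-Kramer adjustment.

    Equivalent, for a one-way fixed-effects layout, to comparing least-square
    means with the Tukey method: the error variance is the pooled one-way
    MSE, each pair's studentized-range statistic is
    ``|mean_i − mean_j| / sqrt(MSE/2 · (1/n_i + 1/n_j))`` (the Kramer
    correction for unbalanced n), and p-values come from the studentized
    range distribution with k groups and N−k error df. Accepts raw samples
    or :class:`SampleSummary` objects. Returns the pairwise results and a
    compact-letter display (groups sharing a letter do not differ at
    ``alpha``).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    summaries = {
        name: (g if isinstance(g, SampleSummary) else describe(g))
        for name, g in groups.items()
    }
    for name, s in summaries.items():
        if s.n < 2:
            raise ValueError(f"group {name!r} needs n >= 2")
    k = len(summaries)
    n_total = sum(s.n for s in summaries.values())
    df_err = n_total - k
    mse = sum((s.n - 1) * s.sd**2 for s in summaries.values()) / df_err
    results = []
    for a, b in itertools.combinations(summaries, 2):
        sa, sb = summaries[a], summaries[b]
        diff = sa.mean - sb.mean
        se = math.sqrt(mse / 2.0 * (1.0 / sa.n + 1.0 / sb.n))
        q = abs(diff) / se if se > 0 else (0.0 if diff == 0 else math.inf)
        p = _tukey_p(q, k, df_err) if math.isfinite(q) else 0.0
        results.append(
            PairwiseResult(a, b, diff, q, p, p < alpha)
        )
    letters = significance_letters(
        list(summaries),
        {(r.group_a, r.group_b): r.significant for r in results},
    )
    return results, letters


def significance_letters(
    names: Sequence[str],
    significant: Mapping[tuple[str, str], bool],
) -> dict[str, str]:
    """Compact letter display by the insert-and-absorb algorithm.

    Groups listed in ``names`` order (ties broken by that order); two groups
    share a letter iff their pair is not flagged significant.
    """
    def differs(a: str, b: str) -> bool:
        return significant.get((a, b), significant.get((b, a), False))

    sets: list[set[str]] = [set(names)]
    for (a, b), sig in significant.items():
        if not sig:
            continue
        for s in list(sets):
            if a in s and b in s:
                sets.remove(s)
                sa, sb = s - {b}, s - {a}
                for cand in (sa, sb):
                    if not any(cand <= other for other in sets):
                        sets.append(cand)
    # absorb: drop any set contained in another
    sets = [s for s in sets if not any(s < other for other in sets)]
    # order letter sets by the first member's position for stable output
    order = {n: i for i, n in enumerate(names)}
    sets.sort(key=lambda s: min(order[m] for m in s))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out: dict[str, str] = {n: "" for n in names}
    for letter, s in zip(alphabet, sets):
        for n in names:
            if n in s:
                out[n] += letter
    return out
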