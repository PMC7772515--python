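"""Normality-gated statistical workflow for morphometry comparisons.

Test selection mirrors common practice in quantitative EM studies:
normality of each sample is assessed by Shapiro-Wilk at alpha = 0.05;
correlations use Pearson when both variables pass and Spearman (midrank
ties) otherwise; two-group comparisons use Student's t versus
Mann-Whitney U; three or more groups use one-way ANOVA versus
Kruskal-Wallis, followed by all pairwise comparisons with Bonferroni
correction (adjusted p capped at 1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "ComparisonResult",
    "DegenerateDataError",
    "ALPHA",
    "is_normal",
    "choose_and_correlate",
    "choose_and_compare",
    "bonferroni",
    "stars",
]

ALPHA = 0.05


class DegenerateDataError(ValueError):
    """Raised for inputs on which the requested statistic is undefined."""


@dataclass(frozen=True)
class StatResult:
    """Outcome of one statistical test."""

    test_name: str
    statistic: float
    p_value: float
    direction: str = ""
    n_per_group: tuple[int, ...] = ()
    correction: str = "none"
    p_adjusted: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value out of [0, 1]: {self.p_value}")

    @property
    def p_final(self) -> float:
        return self.p_value if self.p_adjusted is None else self.p_adjusted

    @property
    def significant(self) -> bool:
        return self.p_final < ALPHA

    @property
    def stars(self) -> str:
        return stars(self.p_final)


@dataclass(frozen=True)
class ComparisonResult:
    """Omnibus test plus (for >= 3 groups) Bonferroni-corrected pairwise tests."""

    omnibus: StatResult
    pairwise: tuple[StatResult, ...] = ()
    group_labels: tuple[str, ...] = ()


def stars(p: float) -> str:
    """Significance stars: * p<0.05, ** p<0.01, *** p<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def bonferroni(p_raw: float, n_tests: int) -> float:
    """Bonferroni-adjusted p value, capped at 1."""
    return min(1.0, p_raw * n_tests)


def is_normal(x: np.ndarray, alpha: float = ALPHA) -> bool:
    """Shapiro-Wilk normality gate at the given alpha."""
    x = np.asarray(x, dtype=float)
    if np.all(x == x[0]):
        return False
    return sps.shapiro(x).pvalue > alpha


def choose_and_correlate(
    x: Sequence[float], y: Sequence[float], alpha: float = ALPHA
) -> StatResult:
    """Pearson correlation when both variables pass Shapiro-Wilk normality,
    Spearman rank correlation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be paired (equal length)")
    if x.size < 4:
        raise ValueError(f"need n >= 4 paired observations, got {x.size}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DegenerateDataError("correlation undefined for a constant variable")
    if is_normal(x, alpha) and is_normal(y, alpha):
        r, p = sps.pearsonr(x, y)
        name = "pearson"
    else:
        r, p = sps.spearmanr(x, y)
        name = "spearman"
    direction = "positive" if r > 0 else ("negative" if r < 0 else "none")
    return StatResult(
        test_name=name,
        statistic=float(r),
        p_value=float(p),
        direction=direction,
        n_per_group=(int(x.size),),
    )


def _two_group(
    a: np.ndarray, b: np.ndarray, alpha: float, labels: tuple[str, str]
) -> StatResult:
    if is_normal(a, alpha) and is_normal(b, alpha):
        stat, p = sps.ttest_ind(a, b)
        name = "student_t"
    else:
        stat, p = sps.mannwhitneyu(a, b, alternative="two-sided")
        name = "mann_whitney_u"
    if a.mean() > b.mean():
        direction = f"{labels[0]}>{labels[1]}"
    elif a.mean() < b.mean():
        direction = f"{labels[0]}<{labels[1]}"
    else:
        direction = "none"
    return StatResult(
        test_name=name,
        statistic=float(stat),
        p_value=float(p),
        direction=direction,
        n_per_group=(int(a.size), int(b.size)),
    )


def choose_and_compare(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    alpha: float = ALPHA,
) -> ComparisonResult:
    """Compare two or more groups with normality-gated test selection.

    Two groups: Student's t (both Shapiro-normal) or Mann-Whitney U.
    Three or more: one-way ANOVA (all normal) or Kruskal-Wallis, followed
    by all pairwise two-group tests with Bonferroni-adjusted p values.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for i, g in enumerate(arrays):
        if g.size < 3:
            raise ValueError(f"group {i} has n = {g.size} < 3")
    if labels is None:
        labels = tuple(f"g{i}" for i in range(len(arrays)))
    labels = tuple(str(l) for l in labels)

    if len(arrays) == 2:
        omnibus = _two_group(arrays[0], arrays[1], alpha, (labels[0], labels[1]))
        return ComparisonResult(omnibus=omnibus, group_labels=labels)

    if all(is_normal(g, alpha) for g in arrays):
        stat, p = sps.f_oneway(*arrays)
        name = "anova_oneway"
    else:
        stat, p = sps.kruskal(*arrays)
        name = "kruskal_wallis"
    omnibus = StatResult(
        test_name=name,
        statistic=float(stat),
        p_value=float(p),
        n_per_group=tuple(int(g.size) for g in arrays),
    )
    pairs = list(itertools.combinations(range(len(arrays)), 2))
    m = len(pairs)
    pairwise = []
    for i, j in pairs:
        res = _two_group(arrays[i], arrays[j], alpha, (labels[i], labels[j]))
        pairwise.append(
            StatResult(
                test_name=res.test_name,
                statistic=res.statistic,
                p_value=res.p_value,
                direction=res.direction,
                n_per_group=res.n_per_group,
                correction=f"bonferroni_x{m}",
                p_adjusted=bonferroni(res.p_value, m),
            )
        )
    return ComparisonResult(
        omnibus=omnibus, pairwise=tuple(pairwise), group_labels=labels
    )
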