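"""Exact small-sample statistics for enrichment comparisons.

Fisher's exact test on 2x2 tables with the sample odds ratio (a*d)/(b*c) and a
Woolf confidence interval, the unpaired Wilcoxon rank-sum test, and the paired
Wilcoxon signed-rank test. P-values come from scipy; exact methods are used
for small tie-free samples and a tie/continuity-corrected normal approximation
otherwise.

Two-sided Fisher extremeness is probability-based (all tables with the same
margins whose hypergeometric probability does not exceed the observed
table's), the common convention. The conditional-MLE odds ratio is not
computed; the sample odds ratio is reported, infinite when b*c = 0 with
a*d > 0 and undefined (NaN) when a margin is zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "ContingencyTable2x2",
    "TestResult",
    "fisher_exact",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank",
    "sample_odds_ratio",
    "odds_ratio_ci",
]

_TAILS = {"two-sided", "greater", "less"}


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cell counts; rows index group membership, columns feature presence."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    tails: str
    odds_ratio: float | None = None
    odds_ratio_ci: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 + 1e-12):
            raise ValueError(f"p-value out of range: {self.p_value}")


def _coerce_table(t) -> ContingencyTable2x2:
    if isinstance(t, ContingencyTable2x2):
        return t
    arr = np.asarray(t)
    if arr.shape == (2, 2):
        return ContingencyTable2x2(*(int(x) for x in arr.ravel()))
    if arr.shape == (4,):
        return ContingencyTable2x2(*(int(x) for x in arr))
    raise ValueError("expected a 2x2 table or 4 counts (a, b, c, d)")


def sample_odds_ratio(t) -> float:
    """(a*d)/(b*c); inf when b*c = 0 with a*d > 0, NaN on a zero margin."""
    t = _coerce_table(t)
    if min(t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d) == 0:
        return math.nan
    if t.b * t.c == 0:
        return math.inf if t.a * t.d > 0 else math.nan
    return (t.a * t.d) / (t.b * t.c)


def odds_ratio_ci(t, level: float = 0.95) -> tuple[float, float]:
    """Woolf (log) confidence interval for the odds ratio.

    With any zero cell the Haldane-Anscombe 0.5 correction is applied to all
    cells before taking logs.
    """
    t = _coerce_table(t)
    cells = np.array([t.a, t.b, t.c, t.d], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    log_or = math.log(cells[0] * cells[3] / (cells[1] * cells[2]))
    se = math.sqrt((1.0 / cells).sum())
    z = sps.norm.ppf(0.5 + level / 2)
    return (math.exp(log_or - z * se), math.exp(log_or + z * se))


def fisher_exact(t, tails: str = "two-sided") -> TestResult:
    """Fisher's exact test on a 2x2 table with fixed margins."""
    if tails not in _TAILS:
        raise ValueError(f"tails must be one of {sorted(_TAILS)}")
    t = _coerce_table(t)
    res = sps.fisher_exact(t.as_array(), alternative=tails)
    orat = sample_odds_ratio(t)
    ci = odds_ratio_ci(t) if not math.isnan(orat) else None
    return TestResult(
        statistic=orat,
        p_value=min(1.0, float(res.pvalue)),
        method="fisher-exact",
        tails=tails,
        odds_ratio=orat,
        odds_ratio_ci=ci,
    )


def _has_ties(values: np.ndarray) -> bool:
    return len(np.unique(values)) < len(values)


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], tails: str = "two-sided"
) -> TestResult:
    """Unpaired two-sample rank test (Wilcoxon rank-sum / Mann-Whitney).

    Exact enumeration when the pooled sample is tie-free with at most 12
    observations; otherwise the normal approximation with midranks, tie
    correction and continuity correction.
    """
    if tails not in _TAILS:
        raise ValueError(f"tails must be one of {sorted(_TAILS)}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    exact = (pooled.size <= 12) and not _has_ties(pooled)
    res = sps.mannwhitneyu(
        x, y, alternative=tails, method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=min(1.0, float(res.pvalue)),
        method="ranksum-exact" if exact else "ranksum-normal",
        tails=tails,
    )


def wilcoxon_signed_rank(diffs: Sequence[float], tails: str = "two-sided") -> TestResult:
    """Paired signed-rank test on a vector of differences.

    Zero differences are dropped; tied magnitudes get midranks. Exact
    enumeration over sign patterns for tie-free samples of at most 15 nonzero
    differences, continuity-corrected normal approximation otherwise.
    """
    if tails not in _TAILS:
        raise ValueError(f"tails must be one of {sorted(_TAILS)}")
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences are zero")
    exact = (d.size <= 15) and not _has_ties(np.abs(d))
    res = sps.wilcoxon(
        d,
        alternative=tails,
        method="exact" if exact else "approx",
        correction=True,
        zero_method="wilcox",
    )
    return TestResult(
        statistic=float(res.statistic),
        p_value=min(1.0, float(res.pvalue)),
        method="signedrank-exact" if exact else "signedrank-normal",
        tails=tails,
    )
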