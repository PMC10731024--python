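"""Statistical routing and summaries applied to every metric table.

Normality is checked with Shapiro-Wilk for samples of n ≤ 50 and
Kolmogorov–Smirnov against a fitted normal for n > 50.  Two groups are
compared with a two-sided t-test (Welch by default — robust to unequal
variances; classic Student selectable); three or more with one-way ANOVA
followed by all-pairs t-tests under a Sidak correction
p_adj = 1 − (1 − p)^m.  Distributions are summarized as mean, 25/75th
percentile, min and max.  When a normality check fails the parametric
result is still reported but flagged, rather than silently switching
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core_io import InsufficientDataError


@dataclass
class NormalityResult:
    test_used: str  # "shapiro-wilk" | "kolmogorov-smirnov"
    statistic: float
    p_value: float
    n: int
    normal: bool = True

    def __post_init__(self) -> None:
        self.normal = self.p_value >= 0.05


@dataclass
class PairwiseComparison:
    group_a: str
    group_b: str
    statistic: float
    p_raw: float
    p_adjusted: float


@dataclass
class GroupComparison:
    """Result of a two-group t-test or a >2-group ANOVA with Sidak post hoc."""

    groups: dict
    test_used: str
    statistic: float
    p_value: float
    pairwise: list[PairwiseComparison] = field(default_factory=list)
    normality: dict = field(default_factory=dict)
    alpha: float = 0.05
    flags: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def normality_route(values) -> NormalityResult:
    """Route a sample to the appropriate normality test by its size.

    n < 50 uses Shapiro-Wilk; n > 50 uses Kolmogorov–Smirnov against a
    normal fitted to the sample; n = 50 exactly is routed to Shapiro-Wilk
    (declared tie-break).  Fewer than 3 observations are insufficient.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise InsufficientDataError("normality test needs at least 3 observations")
    if n <= 50:
        stat, p = sps.shapiro(x)
        return NormalityResult("shapiro-wilk", float(stat), float(p), n)
    stat, p = sps.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    return NormalityResult("kolmogorov-smirnov", float(stat), float(p), n)


def sidak_adjust(p: float, m: int) -> float:
    """Sidak multiple-comparison adjustment p_adj = 1 − (1 − p)^m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return float(1.0 - (1.0 - p) ** m)


def compare_groups(
    groups: dict[str, np.ndarray] | list,
    alpha: float = 0.05,
    equal_var: bool = False,
    check_normality: bool = True,
) -> GroupComparison:
    """Two-sided t-test for 2 groups; ANOVA + Sidak all-pairs for more.

    ``equal_var=False`` (default) uses Welch's t-test for the two-group
    route and for post hoc pairs.  Normality of each group is checked and
    a failed check flags — but does not change — the parametric result.
    """
    if not isinstance(groups, dict):
        groups = {f"group{i + 1}": g for i, g in enumerate(groups)}
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    for name, arr in arrays.items():
        if len(arr) < 2:
            raise InsufficientDataError(f"group {name!r} has fewer than 2 observations")

    flags: list[str] = []
    normality: dict[str, NormalityResult] = {}
    if check_normality:
        for name, arr in arrays.items():
            try:
                res = normality_route(arr)
                normality[name] = res
                if not res.normal:
                    flags.append(f"group {name!r} failed its normality check (p={res.p_value:.3g})")
            except InsufficientDataError:
                flags.append(f"group {name!r} too small for a normality check")

    names = list(arrays)
    if len(arrays) == 2:
        a, b = arrays[names[0]], arrays[names[1]]
        stat, p = sps.ttest_ind(a, b, equal_var=equal_var)
        test = "student-t" if equal_var else "welch-t"
        return GroupComparison(groups, test, float(stat), float(p), [], normality, alpha, flags)

    stat, p = sps.f_oneway(*arrays.values())
    pairs = list(combinations(names, 2))
    m = len(pairs)
    pairwise = []
    for na, nb in pairs:
        t, p_raw = sps.ttest_ind(arrays[na], arrays[nb], equal_var=equal_var)
        pairwise.append(
            PairwiseComparison(na, nb, float(t), float(p_raw), sidak_adjust(float(p_raw), m))
        )
    return GroupComparison(
        groups, "anova+sidak", float(stat), float(p), pairwise, normality, alpha, flags
    )


def summary_block(values) -> dict:
    """Mean, 25/75th percentile (linear interpolation), min and max."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise InsufficientDataError("empty sample")
    return {
        "mean": float(x.mean()),
        "p25": float(np.percentile(x, 25)),
        "p75": float(np.percentile(x, 75)),
        "min": float(x.min()),
        "max": float(x.max()),
    }


def comparison_table(comparison: GroupComparison) -> pd.DataFrame:
    """Flatten a comparison into a table for CSV export."""
    rows = [
        {
            "comparison": "omnibus",
            "test": comparison.test_used,
            "statistic": comparison.statistic,
            "p_raw": comparison.p_value,
            "p_adjusted": comparison.p_value,
        }
    ]
    for pw in comparison.pairwise:
        rows.append(
            {
                "comparison": f"{pw.group_a} vs {pw.group_b}",
                "test": "pairwise-t",
                "statistic": pw.statistic,
                "p_raw": pw.p_raw,
                "p_adjusted": pw.p_adjusted,
            }
        )
    return pd.DataFrame(rows)
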