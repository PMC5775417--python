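"""Statistical comparison of aggregated binding parameters across conditions.

Inference is done on the log scale (pK, logα), the standard practice for
binding parameters whose sampling distributions are approximately normal
after the log transform.  Two procedures are provided, matching how
replicated binding parameters are compared across receptor constructs and
ionic conditions: one-way ANOVA with Tukey's HSD post-hoc test for three or
more groups, and the classical unpaired two-tailed Student t test (equal
variances) for a pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy import stats as sps

__all__ = ["GroupEstimates", "AnovaTukeyResult", "TTestResult", "anova_tukey", "t_test_unpaired"]

SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class GroupEstimates:
    """Per-experiment parameter estimates (log scale) for one condition."""

    label: str
    values: Tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", tuple(float(v) for v in self.values))
        if len(self.values) < 2:
            raise ValueError(
                f"group {self.label!r} needs >= 2 values, got {len(self.values)}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"group {self.label!r} contains non-finite values")


@dataclass(frozen=True)
class AnovaTukeyResult:
    f_stat: float
    p_value: float
    pairwise: Dict[Tuple[str, str], float]

    def significant_pairs(self, alpha: float = SIGNIFICANCE_LEVEL):
        return {pair: p for pair, p in self.pairwise.items() if p < alpha}


@dataclass(frozen=True)
class TTestResult:
    t_stat: float
    p_value: float


def _check_groups(groups: Sequence[GroupEstimates]) -> None:
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    pooled_within = sum(
        np.var(g.values, ddof=1) * (len(g.values) - 1) for g in groups
    )
    if pooled_within == 0:
        raise ValueError(
            "all groups are degenerate (zero within-group variance); "
            "ANOVA/t statistics are undefined"
        )


def anova_tukey(groups: Sequence[GroupEstimates]) -> AnovaTukeyResult:
    """One-way ANOVA plus Tukey HSD adjusted pairwise p-values."""
    _check_groups(groups)
    samples = [np.asarray(g.values) for g in groups]
    f_stat, p_value = sps.f_oneway(*samples)
    hsd = sps.tukey_hsd(*samples)
    pairwise: Dict[Tuple[str, str], float] = {}
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            pairwise[(groups[i].label, groups[j].label)] = float(hsd.pvalue[i, j])
    return AnovaTukeyResult(f_stat=float(f_stat), p_value=float(p_value), pairwise=pairwise)


def t_test_unpaired(a: GroupEstimates, b: GroupEstimates) -> TTestResult:
    """Classical two-sample Student t test (equal variances), two-tailed."""
    _check_groups([a, b])
    t_stat, p_value = sps.ttest_ind(a.values, b.values, equal_var=True)
    return TTestResult(t_stat=float(t_stat), p_value=float(p_value))
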