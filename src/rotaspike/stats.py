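"""Group-level statistics for layer and cell-type comparisons.

Two tests cover every population comparison in the reports: the two-sided
Mann-Whitney U (rank-sum) test for continuous per-cell statistics (HD index,
theta index, spike half-width, negativity amplitude) and Fisher's exact test
for proportions (fraction of HD cells per layer).  Both delegate to
scipy.stats; Mann-Whitney uses scipy's exact enumeration when both groups
have at most 8 observations and the pooled sample is tie-free, and the
tie-corrected normal approximation otherwise (scipy's ``method="auto"``
switch).  No multiple-comparison correction is applied, and that choice is
recorded in the comparison metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = ["GroupComparison", "mann_whitney", "fisher_exact"]


@dataclass(frozen=True)
class GroupComparison:
    statistic_name: str
    groups: tuple[str, str]
    medians: tuple[Optional[float], Optional[float]]
    n: tuple[int, int]
    p_value: float
    test_name: str  #: {"mann_whitney", "fisher_exact"}
    multiple_comparison_correction: str = "none"

    def to_dict(self) -> dict:
        return {
            "statistic_name": self.statistic_name,
            "groups": list(self.groups),
            "medians": list(self.medians),
            "n": list(self.n),
            "p_value": self.p_value,
            "test_name": self.test_name,
            "multiple_comparison_correction": self.multiple_comparison_correction,
        }


def mann_whitney(
    group_a: Sequence[float],
    group_b: Sequence[float],
    statistic_name: str = "value",
    group_names: tuple[str, str] = ("A", "B"),
) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of two value groups."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        p = 1.0  # all-identical values carry no rank information
    else:
        p = float(
            sps.mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue
        )
    return GroupComparison(
        statistic_name=statistic_name,
        groups=group_names,
        medians=(float(np.median(a)), float(np.median(b))),
        n=(a.size, b.size),
        p_value=p,
        test_name="mann_whitney",
    )


def fisher_exact(
    table: Sequence[Sequence[int]],
    statistic_name: str = "proportion",
    group_names: tuple[str, str] = ("A", "B"),
) -> GroupComparison:
    """Two-sided Fisher exact test on a 2x2 count table.

    Rows are groups, columns are outcome counts (e.g. [HD, non-HD]); the
    two-sided p sums hypergeometric probabilities no larger than the observed
    table's.  The per-group "medians" slot carries the outcome proportions.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer):
        raise ValueError("table must hold non-negative integer counts")
    p = float(sps.fisher_exact(t, alternative="two-sided").pvalue)
    props = tuple(
        float(row[0] / row.sum()) if row.sum() > 0 else None for row in t
    )
    return GroupComparison(
        statistic_name=statistic_name,
        groups=group_names,
        medians=props,
        n=(int(t[0].sum()), int(t[1].sum())),
        p_value=p,
        test_name="fisher_exact",
    )
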