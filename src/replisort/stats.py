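"""Group statistics for sorted-cell comparisons.

The colocalization fractions are compared between cell-cycle groups with a
two-sided Mann–Whitney U test (rank-based, no normality assumption,
unpaired design), matching common practice for per-cell microscopy
readouts.  Summaries report mean ± s.e.m. plus median and IQR, since the
test itself is rank-based.  No multiple-testing correction is applied; the
p-values are raw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    method: str  # "exact" or "normal-approximation"
    flags: set[str] = field(default_factory=set)


def mann_whitney(
    values_a: Sequence[float],
    values_b: Sequence[float],
    group_a: str = "a",
    group_b: str = "b",
) -> GroupComparison:
    """Two-sided Mann–Whitney U test between two samples.

    The exact null distribution is used when ``min(n_a, n_b) <= 8`` and the
    pooled sample has no ties; otherwise the normal approximation with tie
    and continuity correction.  Identical samples with zero variation are
    reported as p = 1 with a "no-variation" flag.
    """
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both groups need at least one value")
    flags: set[str] = set()
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        flags.add("no-variation")
        return GroupComparison(group_a, group_b, len(a), len(b),
                               len(a) * len(b) / 2, 1.0, "exact", flags)
    has_ties = len(np.unique(pooled)) < len(pooled)
    if min(len(a), len(b)) <= 8 and not has_ties:
        method = "exact"
    else:
        method = "normal-approximation"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided",
        method="exact" if method == "exact" else "asymptotic",
        use_continuity=True,
    )
    return GroupComparison(group_a, group_b, len(a), len(b),
                           float(res.statistic), float(min(res.pvalue, 1.0)),
                           method, flags)


def group_summary(frame: pd.DataFrame, value: str = "f1", by: str = "phase") -> pd.DataFrame:
    """Per-group n, mean ± s.e.m., median and IQR of one value column."""
    rows = []
    for name, grp in frame.groupby(by, dropna=True):
        vals = grp[value].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            rows.append((name, 0, np.nan, np.nan, np.nan, np.nan))
            continue
        sem = float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        rows.append((name, len(vals), float(np.mean(vals)), sem, float(med), float(q3 - q1)))
    return pd.DataFrame(rows, columns=[by, "n", "mean", "sem", "median", "iqr"])
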