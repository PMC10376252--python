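"""Cohort bookkeeping and nonparametric group comparisons.

Per-video metrics (PS/cm^2, mean activation frequency) are aggregated by
cell line and condition; group contrasts use the two-sided Mann-Whitney U
test, exact when feasible, with p < 0.05 considered significant.  Summaries
are reported as mean +/- SD (sample SD, n-1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "Summary",
    "GroupComparison",
    "manifest_totals",
    "mann_whitney",
    "summarize",
    "compare_groups",
]

SIGNIFICANCE_LEVEL = 0.05
#: exact null enumeration is used when the pooled sample has no ties and at
#: most this many observations; beyond it the normal approximation with tie
#: correction takes over
EXACT_MAX_POOLED_N = 25


@dataclass
class Summary:
    mean: float
    sd: Optional[float]  # None for n = 1 (sample SD undefined)
    n: int

    def __str__(self) -> str:
        if self.sd is None:
            return f"{self.mean:.3g} (n=1, SD undefined)"
        return f"{self.mean:.3g} ± {self.sd:.3g}"


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    U: float
    p_value: float
    summary_a: Summary
    summary_b: Summary
    method: str

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_LEVEL


def summarize(values: Sequence[float]) -> Summary:
    """Mean +/- sample SD of a metric list; SD undefined for a single value."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot summarize an empty list")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else None
    return Summary(mean=float(arr.mean()), sd=sd, n=arr.size)


def mann_whitney(
    a: Sequence[float],
    b: Sequence[float],
    alternative: str = "two-sided",
    group_a: str = "A",
    group_b: str = "B",
) -> GroupComparison:
    """Mann-Whitney U comparison of two metric samples.

    The exact null distribution is used when the pooled data are tie-free
    and small (<= 25 observations), which covers the group sizes of a
    per-line optical-mapping contrast; otherwise the normal approximation
    with tie correction (and continuity correction) is applied.  U is
    reported for the first sample, so 0 <= U <= n_a * n_b.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and pooled.size <= EXACT_MAX_POOLED_N:
        method = "exact"
    else:
        method = "asymptotic"
    res = scipy.stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return GroupComparison(
        group_a=group_a, group_b=group_b, n_a=a.size, n_b=b.size,
        U=float(res.statistic), p_value=float(res.pvalue),
        summary_a=summarize(a), summary_b=summarize(b), method=method,
    )


def manifest_totals(manifest: pd.DataFrame) -> dict:
    """Experiment accounting over a recording manifest.

    Returns total videos, videos per condition, total differentiation
    batches and mean videos per batch (NaN when there are no batches).
    """
    required = {"line", "condition", "n_videos", "n_batches"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")
    total_videos = int(manifest["n_videos"].sum())
    total_batches = int(manifest["n_batches"].sum())
    by_cond = manifest.groupby("condition")["n_videos"].sum()
    return {
        "total_videos": total_videos,
        "videos_no_dox": int(by_cond.get("No DOX", 0)),
        "videos_dox": int(by_cond.get("DOX", 0)),
        "total_batches": total_batches,
        "mean_videos_per_batch": (
            total_videos / total_batches if total_batches > 0 else float("nan")
        ),
    }


def compare_groups(
    metrics: pd.DataFrame,
    value_col: str,
    group_col: str = "condition",
    by: str = "line",
) -> pd.DataFrame:
    """Per-line basal-vs-DOX Mann-Whitney contrasts of a per-video metric.

    ``metrics`` must have one row per video with columns ``by`` (e.g. cell
    line), ``group_col`` (e.g. condition) and ``value_col``.  Returns one row
    per ``by`` level with group summaries, U and the two-sided p-value.
    """
    rows = []
    for level, sub in metrics.groupby(by, sort=True):
        groups = sorted(sub[group_col].unique())
        if len(groups) != 2:
            continue
        ga, gb = groups[::-1] if "No DOX" in groups else groups
        va = sub.loc[sub[group_col] == ga, value_col].dropna()
        vb = sub.loc[sub[group_col] == gb, value_col].dropna()
        if va.empty or vb.empty:
            continue
        cmp = mann_whitney(va, vb, group_a=str(ga), group_b=str(gb))
        rows.append({
            by: level,
            "metric": value_col,
            "group_a": cmp.group_a,
            "group_b": cmp.group_b,
            "n_a": cmp.n_a,
            "n_b": cmp.n_b,
            "mean_a": cmp.summary_a.mean,
            "sd_a": cmp.summary_a.sd,
            "mean_b": cmp.summary_b.mean,
            "sd_b": cmp.summary_b.sd,
            "U": cmp.U,
            "p_value": cmp.p_value,
            "significant": cmp.significant,
            "method": cmp.method,
        })
    return pd.DataFrame(rows)
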