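"""Knockout-efficiency computation and group statistics for FACS readouts.

Knockout efficiency is the raw percentage of reporter-negative cells —
no background subtraction, matching the assay's operational definition.
Because an unedited reporter line carries a small negative background
(~0.5%) and promoter steric hindrance can silence a few percent more, an
optional corrected estimator (ko − bg)/(1 − bg) is provided behind a flag.

Group summaries are mean ± SEM; paired comparisons (e.g. the same target
site cut with a 17 nt vs a 20 nt guide) use the paired t-test or the exact
Wilcoxon signed-rank test; more than two groups use one-way ANOVA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "KORecord",
    "GroupSummary",
    "TestResult",
    "ko_efficiency",
    "corrected_ko_efficiency",
    "summarize_group",
    "paired_comparison",
    "anova",
    "significance_stars",
    "summarize_counts_table",
]

#: sample sizes up to which the Wilcoxon null is computed by exact enumeration
WILCOXON_EXACT_MAX_N = 25


@dataclass(frozen=True)
class KORecord:
    """One replicate's FACS readout for one guide in one cell line."""

    cell_line: str
    guide_name: str
    spacer_class: str
    replicate: int
    n_total: int
    n_gfp_neg: int

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if not (0 <= self.n_gfp_neg <= self.n_total):
            raise ValueError("n_gfp_neg outside [0, n_total]")

    @property
    def ko_percent(self) -> float:
        return ko_efficiency(self.n_gfp_neg, self.n_total)


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sem: float
    n: int
    sem_defined: bool = True

    def __str__(self) -> str:
        sem = f"{self.sem:.2f}" if self.sem_defined else "NA"
        return f"{self.mean:.2f} ± {sem} (n={self.n})"


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    p_value: float
    n_pairs: int
    degenerate: bool = False
    note: str = ""

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def ko_efficiency(n_gfp_neg: int, n_total: int) -> float:
    """Raw knockout percentage: 100 × negatives / total."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if n_gfp_neg < 0 or n_gfp_neg > n_total:
        raise ValueError("n_gfp_neg outside [0, n_total]")
    return 100.0 * n_gfp_neg / n_total

def corrected_ko_efficiency(ko_percent: float, background_percent: float) -> float:
    """Background-corrected knockout: 100 × (ko − bg) / (100 − bg), floored
    at 0.  Optional — the primary readout is the raw percentage."""
    if not (0 <= background_percent < 100):
        raise ValueError("background_percent outside [0, 100)")
    return max(0.0, 100.0 * (ko_percent - background_percent) / (100.0 - background_percent))


def summarize_group(values: Sequence[float]) -> GroupSummary:
    """Mean ± SEM of a group of percentages.  A singleton has no defined
    SEM; it is reported as 0 with ``sem_defined=False``."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("empty group")
    if vals.size == 1:
        return GroupSummary(mean=float(vals[0]), sem=0.0, n=1, sem_defined=False)
    sem = float(np.std(vals, ddof=1) / math.sqrt(vals.size))
    return GroupSummary(mean=float(vals.mean()), sem=sem, n=int(vals.size))


def paired_comparison(
    a: Sequence[float], b: Sequence[float], method: str = "paired_t"
) -> TestResult:
    """Two-sided paired comparison of index-aligned measurements.

    ``paired_t`` is Student's t on the within-pair differences; ``wilcoxon``
    is the signed-rank test with an exact permutation null at n ≤ 25.
    Zero-variance differences (including a == b) are flagged degenerate
    rather than returned as a numeric statistic.
    """
    if method not in ("paired_t", "wilcoxon"):
        raise ValueError(f"unknown method {method!r}")
    x = np.asarray(list(a), dtype=float)
    y = np.asarray(list(b), dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    if np.allclose(d, d[0]):
        if np.allclose(d, 0):
            return TestResult(method, 0.0, 1.0, n, degenerate=True, note="a == b")
        return TestResult(
            method, math.copysign(math.inf, d[0]), 0.0, n,
            degenerate=True, note="constant nonzero difference",
        )
    if method == "paired_t":
        res = stats.ttest_rel(x, y)
        return TestResult("paired_t", float(res.statistic), float(res.pvalue), n)
    if method == "wilcoxon":
        mode = "exact" if n <= WILCOXON_EXACT_MAX_N else "approx"
        res = stats.wilcoxon(x, y, alternative="two-sided", method=mode)
        return TestResult("wilcoxon", float(res.statistic), float(res.pvalue), n)
    raise ValueError(f"unknown method {method!r}")


def anova(*groups: Sequence[float]) -> TestResult:
    """One-way ANOVA across more than two groups."""
    if len(groups) < 3:
        raise ValueError("ANOVA is for more than two groups; use paired_comparison")
    res = stats.f_oneway(*[np.asarray(list(g), dtype=float) for g in groups])
    return TestResult("anova", float(res.statistic), float(res.pvalue),
                      n_pairs=sum(len(g) for g in groups))


def significance_stars(p: float) -> str:
    """Conventional star notation: * <0.05, ** <0.01, *** <0.001, else ns."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def summarize_counts_table(
    counts: pd.DataFrame, by: Sequence[str] = ("cell_line", "guide", "class")
) -> pd.DataFrame:
    """Per-group mean ± SEM of knockout percentages from a per-replicate
    counts table (columns: ``n_total``, ``n_gfp_neg`` plus grouping keys)."""
    df = counts.copy()
    df["ko_percent"] = 100.0 * df["n_gfp_neg"] / df["n_total"]
    rows = []
    for keys, grp in df.groupby(list(by)):
        s = summarize_group(grp["ko_percent"])
        rec = dict(zip(by, keys if isinstance(keys, tuple) else (keys,)))
        rec.update(mean=s.mean, sem=s.sem, n=s.n)
        rows.append(rec)
    return pd.DataFrame(rows)
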