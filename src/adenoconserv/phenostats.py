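"""Tumor-multiplicity, survival, and qPCR fold-change statistics.

Tumor counts are overdispersed and non-normal, so group comparisons use
nonparametric tests: Kruskal-Wallis across >2 genotype groups and the
two-sided Wilcoxon rank-sum test for pairs (exact by enumeration on small
tie-free cohorts, normal approximation with tie and continuity corrections
otherwise).  Survival over a fixed study horizon is summarized both as the
fraction surviving and as Kaplan-Meier product-limit curves.  qPCR
amplification-cycle differences translate to fold changes as 2**deltaCT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import ExpressionStudy


class PhenoStatsError(ValueError):
    pass


@dataclass
class CountTable:
    """Genotype/treatment-labelled tumor counts: label -> integer counts."""

    groups: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        clean = {}
        for label, counts in self.groups.items():
            arr = np.asarray(counts)
            if arr.size < 1:
                raise PhenoStatsError(f"group {label!r} is empty")
            if np.any(arr < 0) or not np.allclose(arr, np.round(arr)):
                raise PhenoStatsError(
                    f"group {label!r}: counts must be non-negative integers"
                )
            clean[label] = arr.astype(int)
        self.groups = clean

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (label, int(c)) for label, counts in self.groups.items() for c in counts
        ]
        return pd.DataFrame(rows, columns=["group", "count"])


@dataclass
class SurvivalData:
    """Per-animal records: group label, time in days, event flag.

    event=True means the animal became moribund at ``time``; event=False
    means it was censored (alive at sacrifice).
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"group", "time", "event"}
        if not required.issubset(self.records.columns):
            raise PhenoStatsError(f"records need columns {sorted(required)}")
        if (self.records["time"] <= 0).any():
            raise PhenoStatsError("all times must be positive")


@dataclass(frozen=True)
class CtMeasure:
    """One qPCR sample: cycle difference vs the reference gene.

    Technical replicate variation above 5% fails the QC flag.
    """

    sample_id: str
    tissue_class: str
    delta_ct: float
    replicate_cv: float

    @property
    def passes_qc(self) -> bool:
        return self.replicate_cv <= 0.05


@dataclass(frozen=True)
class WilcoxonResult:
    W: float
    p: float
    mode: str  # "exact" or "normal_approx"


def kruskal_wallis(table: CountTable) -> tuple[float, float]:
    """Kruskal-Wallis H (midrank ties correction) and chi-square p.

    Intended for comparisons over three or more groups; two groups are
    accepted but the rank-sum test is the usual choice there.
    """
    if len(table.groups) < 2:
        raise PhenoStatsError("kruskal_wallis needs >= 2 groups")
    pooled = np.concatenate(list(table.groups.values()))
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0  # fully tied data carry no rank information
    h, p = stats.kruskal(*table.groups.values())
    return float(h), float(p)


def wilcoxon_rank_sum(a, b, exact_max_n: int = 20) -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum test.

    Exact null enumeration when the combined sample size is at most
    ``exact_max_n`` and there are no ties; otherwise the normal
    approximation with tie and continuity corrections.  The mode actually
    used is recorded in the result.  W is the rank sum of the first sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise PhenoStatsError("both groups must be non-empty")
    combined = np.concatenate([a, b])
    tie_free = np.unique(combined).size == combined.size
    if tie_free and combined.size <= exact_max_n:
        mode = "exact"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact")
    else:
        mode = "normal_approx"
        res = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=True
        )
    w = float(res.statistic) + a.size * (a.size + 1) / 2.0  # U -> rank sum of a
    return WilcoxonResult(W=w, p=float(min(res.pvalue, 1.0)), mode=mode)


def survival_fraction(survived: int, total: int) -> float:
    """Percent surviving to the study horizon, at one decimal (e.g. 16.7)."""
    if total <= 0:
        raise PhenoStatsError("total must be positive")
    if not 0 <= survived <= total:
        raise PhenoStatsError("survived must lie in [0, total]")
    return round(100.0 * survived / total, 1)


def kaplan_meier(data: SurvivalData) -> dict[str, pd.DataFrame]:
    """Product-limit survival curves per group.

    Returns, per group, a step function as a DataFrame with columns
    ``time`` and ``survival``; censored animals leave the risk set without
    a downward step.
    """
    from lifelines import KaplanMeierFitter

    curves: dict[str, pd.DataFrame] = {}
    for label, sub in data.records.groupby("group", sort=False):
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time"], event_observed=sub["event"].astype(bool))
        sf = kmf.survival_function_
        curves[label] = pd.DataFrame(
            {"time": sf.index.to_numpy(dtype=float),
             "survival": sf.iloc[:, 0].to_numpy(dtype=float)}
        )
    return curves


def pooled_mean(cells: list[tuple[float, int]]) -> float:
    """Sample-size-weighted mean of (mean, n) cells, at one decimal.

    Pools per-generation summary rows of a genotype column into the overall
    column mean.
    """
    if not cells:
        raise PhenoStatsError("pooled_mean needs at least one cell")
    if any(n <= 0 for _, n in cells):
        raise PhenoStatsError("all cell sizes must be positive")
    total_n = sum(n for _, n in cells)
    return round(sum(m * n for m, n in cells) / total_n, 1)


def fold_change_from_ct(n: float) -> float:
    """Fold change 2**n from an amplification-cycle difference n (deltaCT)."""
    if not np.isfinite(n):
        raise PhenoStatsError("cycle difference must be finite")
    return float(2.0 ** n)


def center_by_gene(
    studies: list[ExpressionStudy], genes: list[str] | set[str]
) -> pd.DataFrame:
    """Deviation from gene- and genus-specific mean expression (log2).

    For each requested gene and each study, subtracts that gene's mean
    across the study's samples; blocks are concatenated column-wise for
    heatmap export.  Row order follows ``sorted(genes)``.
    """
    genes = sorted(genes)
    blocks = []
    for study in studies:
        pos = {g: i for i, g in enumerate(study.gene_ids)}
        missing = [g for g in genes if g not in pos]
        if missing:
            raise PhenoStatsError(
                f"genes missing in study {study.genus!r}: {missing[:5]}"
            )
        rows = [pos[g] for g in genes]
        block = study.values[rows, :]
        block = block - block.mean(axis=1, keepdims=True)
        blocks.append(
            pd.DataFrame(
                block,
                index=genes,
                columns=[f"{study.genus}:{s}" for s in study.sample_ids],
            )
        )
    return pd.concat(blocks, axis=1)
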