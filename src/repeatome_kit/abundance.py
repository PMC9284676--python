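"""Genome-size arithmetic and descriptive/comparative abundance statistics.

Mass/size conversion uses the standard 1 pg = 978 Mbp constant, which
reproduces published monoploid Mbp columns exactly (5.09 pg -> 4978.02 Mbp).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import PG_TO_MBP, RepeatAbundanceTable

__all__ = [
    "pg_to_mbp",
    "mbp_to_pg",
    "monoploid_size",
    "cluster_genome_proportion",
    "AbundanceSummary",
    "summarize",
    "KruskalWallisResult",
    "kruskal_wallis",
]


def pg_to_mbp(mass_pg: float) -> float:
    """Convert a DNA mass in picograms to megabase pairs (1 pg = 978 Mbp)."""
    if mass_pg < 0:
        raise ValueError("mass must be non-negative")
    return mass_pg * PG_TO_MBP


def mbp_to_pg(size_mbp: float) -> float:
    if size_mbp < 0:
        raise ValueError("size must be non-negative")
    return size_mbp / PG_TO_MBP


def monoploid_size(c2_pg: float, ploidy: int) -> float:
    """Monoploid genome size 1Cx (pg) = holoploid 2C (pg) / ploidy."""
    if ploidy < 2 or ploidy % 2 != 0:
        raise ValueError("ploidy must be an even integer >= 2")
    if c2_pg <= 0:
        raise ValueError("2C must be positive")
    return c2_pg / ploidy


def cluster_genome_proportion(n_cluster_reads: int, n_total_reads: int) -> float:
    """Genome proportion (%) of a read cluster: 100 * reads-in-cluster /
    total reads fed to the clustering (e.g. 331 of 500000 -> 0.0662%)."""
    if n_total_reads <= 0:
        raise ValueError("n_total_reads must be positive")
    if not 0 <= n_cluster_reads <= n_total_reads:
        raise ValueError("n_cluster_reads must be in [0, n_total_reads]")
    return 100.0 * n_cluster_reads / n_total_reads


@dataclass
class AbundanceSummary:
    """Descriptive summary of an abundance table (over non-missing cells)."""

    family_mean: pd.Series
    family_min: pd.Series
    family_max: pd.Series
    sample_total: pd.Series
    total_mean: float
    total_min: float
    total_max: float
    all_missing_families: list[str]


def summarize(table: RepeatAbundanceTable) -> AbundanceSummary:
    """Per-family mean/min/max and the per-sample total repeat proportion.

    The total uses a designated "Total" column when the table carries one
    (published tables print it), otherwise the row sum over families.
    Families with no measured value are flagged and excluded from the
    min/max/mean series.
    """
    df = table.values
    if df.empty:
        raise ValueError("empty abundance table")
    all_missing = [c for c in df.columns if df[c].isna().all()]
    measured = df.drop(columns=all_missing)
    totals = table.totals()
    return AbundanceSummary(
        family_mean=measured.mean(axis=0, skipna=True),
        family_min=measured.min(axis=0, skipna=True),
        family_max=measured.max(axis=0, skipna=True),
        sample_total=totals,
        total_mean=float(totals.mean()),
        total_min=float(totals.min()),
        total_max=float(totals.max()),
        all_missing_families=all_missing,
    )


@dataclass
class KruskalWallisResult:
    h: float  # tie-corrected H statistic
    df: int  # k - 1
    p_value: float  # chi-square upper tail


def kruskal_wallis(values, group_labels) -> KruskalWallisResult:
    """Kruskal-Wallis rank test across caller-supplied groups.

    Tie-corrected H with a chi-square(k-1) upper-tail p-value; identical
    values in every group give H = 0, p = 1 by convention.
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    if values.shape != group_labels.shape:
        raise ValueError("values and group_labels must have equal length")
    groups = [values[group_labels == g] for g in pd.unique(group_labels)]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    if np.all(values == values[0]):
        return KruskalWallisResult(h=0.0, df=len(groups) - 1, p_value=1.0)
    h, p = stats.kruskal(*groups)
    return KruskalWallisResult(h=float(h), df=len(groups) - 1, p_value=float(p))
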