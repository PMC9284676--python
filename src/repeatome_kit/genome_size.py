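"""Phylogenetically corrected correlation of repeat amounts with monoploid
genome size and per-repeat contribution to pairwise genome-size differences.

Independent contrasts follow Felsenstein's pruning recursion: at each
internal node of a fully bifurcating tree the contrast is
``(x_i - x_j) / sqrt(v_i + v_j)``, the ancestral value is the
1/v-weighted mean of the children, and the parent branch is augmented by
``v_i * v_j / (v_i + v_j)``.  Contrasts have expectation zero, so their
correlation is computed without re-centering (regression through the
origin), the standard contrasts convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContrastSet",
    "CorrelationResult",
    "ContributionResult",
    "independent_contrasts",
    "pearson_test",
    "repeat_gs_correlation",
    "pairwise_contribution",
]


@dataclass
class ContrastSet:
    """Standardized contrasts, one per internal node (n - 1 for n tips)."""

    node_ids: list[int]
    contrasts: np.ndarray
    variances: np.ndarray  # expected variance: sum of adjusted child branches


def independent_contrasts(tree: dendropy.Tree, trait: dict[str, float]) -> ContrastSet:
    """Felsenstein's independent contrasts on a fully bifurcating tree."""
    values: dict[int, float] = {}
    lengths: dict[int, float] = {}
    contrasts: list[float] = []
    variances: list[float] = []
    node_ids: list[int] = []
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            if label not in trait:
                raise ValueError(f"trait missing for tip {label!r}")
            bl = node.edge.length
            if bl is None or bl <= 0:
                raise ValueError(f"tip {label!r} has a non-positive branch length")
            values[id(node)] = float(trait[label])
            lengths[id(node)] = float(bl)
            continue
        children = node.child_nodes()
        if len(children) != 2:
            raise ValueError(
                "tree has a polytomy (or unifurcation); resolve it to a fully "
                "bifurcating tree before computing contrasts"
            )
        ci, cj = children
        vi, vj = lengths[id(ci)], lengths[id(cj)]
        xi, xj = values[id(ci)], values[id(cj)]
        var = vi + vj
        contrasts.append((xi - xj) / math.sqrt(var))
        variances.append(var)
        node_ids.append(id(node))
        # 1/v-weighted mean, written so a constant trait stays exactly constant
        values[id(node)] = xj + vj * (xi - xj) / (vi + vj)
        parent_bl = node.edge.length if node.edge.length and node.parent_node else 0.0
        lengths[id(node)] = parent_bl + vi * vj / (vi + vj)
    n_tips = sum(1 for _ in tree.leaf_node_iter())
    assert len(contrasts) == n_tips - 1
    return ContrastSet(
        node_ids=node_ids,
        contrasts=np.asarray(contrasts),
        variances=np.asarray(variances),
    )


@dataclass
class CorrelationResult:
    r: float
    r2: float
    p_value: float
    n: int


def pearson_test(x, y, center: bool = True) -> CorrelationResult:
    """Pearson correlation with a two-sided t-test p-value.

    ``center=False`` computes the through-the-origin (uncentered) version
    used for independent contrasts, with n - 1 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    if center:
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError("zero variance in x or y")
        r = float(stats.pearsonr(x, y).statistic)
        dof = n - 2
    else:
        sx, sy = float(x @ x), float(y @ y)
        if sx == 0 or sy == 0:
            raise ValueError("zero variance in x or y")
        r = float((x @ y) / math.sqrt(sx * sy))
        dof = n - 1
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * math.sqrt(dof / (1.0 - r * r))
        p = float(2.0 * stats.t.sf(abs(t), dof))
    return CorrelationResult(r=r, r2=r * r, p_value=p, n=n)


def repeat_gs_correlation(
    amounts_mbp: pd.DataFrame,
    genome_sizes_mbp: pd.Series,
    tree: dendropy.Tree,
) -> dict[str, CorrelationResult | None]:
    """Per-family correlation of repeat amount with monoploid genome size,
    both reduced to independent contrasts on the shared tree.

    ``amounts_mbp`` is samples x families (absolute Mbp of 1Cx);
    families whose contrasts are untestable (constant amount) map to None.
    """
    tips = [lf.taxon.label for lf in tree.leaf_node_iter()]
    usable = [t for t in tips if t in amounts_mbp.index and t in genome_sizes_mbp.index]
    if len(usable) < 4:
        raise ValueError("need at least 4 tips with both amounts and genome sizes")
    if set(usable) != set(tips):
        tree = tree.extract_tree_with_taxa_labels(usable)
    gs_trait = {t: float(genome_sizes_mbp[t]) for t in usable}
    gs_contrasts = independent_contrasts(tree, gs_trait).contrasts
    out: dict[str, CorrelationResult | None] = {}
    for fam in amounts_mbp.columns:
        trait = {t: float(amounts_mbp.at[t, fam]) for t in usable}
        fam_contrasts = independent_contrasts(tree, trait).contrasts
        try:
            out[fam] = pearson_test(fam_contrasts, gs_contrasts, center=False)
        except ValueError:
            out[fam] = None  # not testable (constant amount)
    return out


@dataclass
class ContributionResult:
    """Average % contribution of each family to pairwise genome-size
    differences, plus the per-family amount range (Mbp)."""

    contribution_pct: pd.Series
    min_mbp: pd.Series
    max_mbp: pd.Series
    n_pairs: int
    n_pairs_excluded: int


def pairwise_contribution(
    amounts_mbp: pd.DataFrame,
    genome_sizes_mbp: pd.Series,
    rel_floor: float = 0.01,
) -> ContributionResult:
    """For every unordered sample pair (a, b) with GS_a > GS_b the family
    share is ``100 * (A_fa - A_fb) / (GS_a - GS_b)``; the contribution is the
    mean share over pairs.  Pairs whose genome sizes differ by less than
    ``rel_floor`` times the mean genome size are excluded (division guard).
    Shares can be negative for families anti-correlated with genome size.
    """
    samples = [s for s in amounts_mbp.index if s in genome_sizes_mbp.index]
    if len(samples) < 2:
        raise ValueError("need at least 2 samples with amounts and genome sizes")
    gs = genome_sizes_mbp[samples].astype(float)
    floor = rel_floor * float(gs.mean())
    shares = []
    excluded = 0
    for a, b in combinations(samples, 2):
        if gs[a] < gs[b]:
            a, b = b, a
        dg = gs[a] - gs[b]
        if abs(dg) < floor:
            excluded += 1
            continue
        shares.append(100.0 * (amounts_mbp.loc[a] - amounts_mbp.loc[b]) / dg)
    if not shares:
        raise ValueError("all sample pairs excluded by the genome-size floor")
    share_df = pd.DataFrame(shares)
    return ContributionResult(
        contribution_pct=share_df.mean(axis=0),
        min_mbp=amounts_mbp.loc[samples].min(axis=0),
        max_mbp=amounts_mbp.loc[samples].max(axis=0),
        n_pairs=len(shares),
        n_pairs_excluded=excluded,
    )
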