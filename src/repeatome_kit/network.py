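"""Neighbor-Joining trees per repeat cluster and consensus split networks
over the resulting tree set.

NJ follows Saitou & Nei: repeatedly join the pair minimizing
``Q_ij = (n - 2) d_ij - sum_k d_ik - sum_k d_jk`` with the standard
branch-length formulas.  A negative branch length is clamped to zero and
the deficit transferred to the branch of the joined partner, preserving the
path length between the two joined nodes; ties in Q are broken by the
lowest (i, j) index pair in the current matrix order.

The consensus network keeps every nontrivial split occurring in more than a
threshold fraction of the input trees (default 0.25, below majority rule so
conflicting signal stays visible), weighted by the mean branch length over
the trees containing it.  The result may contain incompatible splits; at
threshold >= 0.5 it reduces to the (compatible) majority-rule split set.
"""

from __future__ import annotations

import numpy as np
import dendropy

from .distance import DistanceMatrix
from .io import SplitSet, canonical_split

__all__ = [
    "neighbor_joining",
    "tree_splits",
    "consensus_network",
    "robinson_foulds",
]


def neighbor_joining(d: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei Neighbor-Joining on a distance matrix; returns an unrooted
    dendropy tree (internal nodes of degree 3)."""
    labels = list(d.species)
    m = np.array(d.matrix, dtype=float)
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    if np.isnan(m).any():
        raise ValueError("distance matrix contains NaN")

    taxon_ns = dendropy.TaxonNamespace(labels)
    nodes = [dendropy.Node(taxon=taxon_ns.get_taxon(lab)) for lab in labels]

    def attach(parent, child, length):
        parent.add_child(child)
        child.edge.length = max(0.0, round(length, 12))

    while n > 3:
        r = m.sum(axis=1)
        q = (n - 2) * m - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # lowest (i, j) index pair on ties
        best = np.inf
        bi = bj = -1
        for i in range(n):
            for j in range(i + 1, n):
                if q[i, j] < best - 1e-12:
                    best = q[i, j]
                    bi, bj = i, j
        li = m[bi, bj] / 2.0 + (r[bi] - r[bj]) / (2.0 * (n - 2))
        lj = m[bi, bj] - li
        # clamp-and-transfer for negative branch lengths
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        parent = dendropy.Node()
        attach(parent, nodes[bi], li)
        attach(parent, nodes[bj], lj)
        new_d = 0.5 * (m[bi, :] + m[bj, :] - m[bi, bj])
        keep = [k for k in range(n) if k not in (bi, bj)]
        m2 = np.zeros((n - 1, n - 1))
        m2[: n - 2, : n - 2] = m[np.ix_(keep, keep)]
        m2[n - 2, : n - 2] = m2[: n - 2, n - 2] = new_d[keep]
        m = m2
        nodes = [nodes[k] for k in keep] + [parent]
        n -= 1

    # final three-point join
    center = dendropy.Node()
    a = (m[0, 1] + m[0, 2] - m[1, 2]) / 2.0
    b = (m[0, 1] + m[1, 2] - m[0, 2]) / 2.0
    c = (m[0, 2] + m[1, 2] - m[0, 1]) / 2.0
    for node, length in zip(nodes, (a, b, c)):
        attach(center, node, length)
    tree = dendropy.Tree(taxon_namespace=taxon_ns, seed_node=center)
    tree.is_rooted = False
    return tree


def tree_splits(tree: dendropy.Tree) -> SplitSet:
    """One split per edge of the tree, weighted by branch length; trivial
    (single-tip) splits carry their pendant lengths.  Treats the tree as
    unrooted: the two edges of a degree-2 root map to one split whose
    weight is the sum of the two branch lengths."""
    taxa = tuple(sorted(lf.taxon.label for lf in tree.leaf_node_iter()))
    ss = SplitSet(taxa=taxa)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        if len(below) == len(taxa):
            continue
        ss.add(below, weight=node.edge.length or 0.0)
    return ss


def consensus_network(
    trees: list[dendropy.Tree], threshold: float = 0.25
) -> SplitSet:
    """Split system containing every nontrivial split present in more than
    ``threshold`` of the trees (plus all trivial splits); split weight is
    the mean branch length over the trees containing the split."""
    if not trees:
        raise ValueError("need at least one tree")
    if not 0.0 <= threshold < 1.0:
        raise ValueError("threshold must be in [0, 1)")
    tipsets = [frozenset(lf.taxon.label for lf in t.leaf_node_iter()) for t in trees]
    ref = tipsets[0]
    for k, ts in enumerate(tipsets[1:], start=2):
        if ts != ref:
            extra = sorted(ts ^ ref)
            raise ValueError(
                f"tree {k} has a different tip set (symmetric difference: {extra})"
            )
    taxa = tuple(sorted(ref))
    counts: dict[frozenset, int] = {}
    weights: dict[frozenset, list[float]] = {}
    for t in trees:
        ss = tree_splits(t)
        for side, (w, _) in ss.splits.items():
            counts[side] = counts.get(side, 0) + 1
            weights.setdefault(side, []).append(w)
    m = len(trees)
    out = SplitSet(taxa=taxa)
    n = len(taxa)
    for side, cnt in counts.items():
        support = cnt / m
        trivial = not (2 <= len(side) <= n - 2)
        if trivial or support > threshold:
            out.add(side, weight=float(np.mean(weights[side])), support=support)
    return out


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds distance: size of the symmetric difference between
    the two trees' nontrivial split sets."""
    tips1 = {lf.taxon.label for lf in t1.leaf_node_iter()}
    tips2 = {lf.taxon.label for lf in t2.leaf_node_iter()}
    if tips1 != tips2:
        raise ValueError(
            f"tip sets differ (symmetric difference: {sorted(tips1 ^ tips2)})"
        )
    s1 = set(tree_splits(t1).nontrivial())
    s2 = set(tree_splits(t2).nontrivial())
    return len(s1 ^ s2)
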