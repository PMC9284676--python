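"""Blomberg's K and its permutation test for trait data on a rooted tree.

K compares the observed ratio of tip variance to phylogenetically corrected
variance against its Brownian-motion expectation on the same tree:

    a_hat = (1' V^-1 x) / (1' V^-1 1)
    MSE0  = (x - a_hat 1)' (x - a_hat 1) / (n - 1)
    MSE   = (x - a_hat 1)' V^-1 (x - a_hat 1) / (n - 1)
    K     = (MSE0 / MSE) / [(tr V - n / (1' V^-1 1)) / (n - 1)]

with V the Brownian covariance matrix (shared root-to-MRCA path lengths).
K ~ 1 means the trait is consistent with Brownian evolution on the tree,
K ~ 0 means no phylogenetic signal, K > 1 more signal than expected.

The significance test randomizes tip values; the statistic is the
phylogenetically corrected MSE (smaller = more signal) and the p-value uses
the add-one rule, so the smallest attainable p is 1 / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np

__all__ = ["SignalResult", "phylo_covariance", "blomberg_k", "k_permutation_test"]


def phylo_covariance(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Brownian-motion covariance of the tips of a rooted tree:
    ``V_ij`` = root-to-MRCA(i, j) path length, ``V_ii`` = tip depth."""
    root = tree.seed_node
    if tree.is_rooted is False and len(root.child_nodes()) != 2:
        raise ValueError(
            "tree is unrooted; root it first (outgroup or midpoint rooting)"
        )
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    v = np.zeros((n, n))
    depth: dict[int, float] = {id(root): 0.0}
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
    leafsets: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = idx[node.taxon.label]
            leafsets[id(node)] = [i]
            v[i, i] = depth[id(node)]
            continue
        children = node.child_nodes()
        sets = [leafsets[id(c)] for c in children]
        for a in range(len(sets)):
            for b in range(a + 1, len(sets)):
                for i in sets[a]:
                    for j in sets[b]:
                        v[i, j] = v[j, i] = depth[id(node)]
        leafsets[id(node)] = [i for s in sets for i in s]
    return labels, v


def _k_terms(v: np.ndarray):
    vinv = np.linalg.inv(v)
    ones = np.ones(len(v))
    vinv1 = vinv @ ones
    s = float(ones @ vinv1)
    expected = (np.trace(v) - len(v) / s) / (len(v) - 1)
    return vinv, vinv1, s, expected


def _mse_pair(x: np.ndarray, vinv: np.ndarray, vinv1: np.ndarray, s: float):
    n = len(x)
    a_hat = float(x @ vinv1) / s
    r = x - a_hat
    mse0 = float(r @ r) / (n - 1)
    mse = float(r @ vinv @ r) / (n - 1)
    return mse0, mse


def blomberg_k(tree: dendropy.Tree, trait: dict[str, float]) -> float:
    """Blomberg's K for a tip trait on a rooted tree with branch lengths."""
    labels, v = phylo_covariance(tree)
    x = np.array([float(trait[lab]) for lab in labels])
    if np.ptp(x) == 0:
        raise ValueError("K undefined for a constant trait")
    vinv, vinv1, s, expected = _k_terms(v)
    mse0, mse = _mse_pair(x, vinv, vinv1, s)
    return (mse0 / mse) / expected


@dataclass
class SignalResult:
    k: float
    p_value: float
    mse_observed: float
    n_tips: int
    n_permutations: int
    seed: int


def k_permutation_test(
    tree: dendropy.Tree,
    trait: dict[str, float],
    n_perm: int = 999,
    seed: int = 0,
) -> SignalResult:
    """Permutation test for phylogenetic signal: shuffle tip values
    uniformly, score each shuffle by the corrected MSE, and report
    ``p = (1 + #{permuted MSE <= observed}) / (n_perm + 1)``."""
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    labels, v = phylo_covariance(tree)
    x = np.array([float(trait[lab]) for lab in labels])
    if np.ptp(x) == 0:
        raise ValueError("K undefined for a constant trait")
    vinv, vinv1, s, expected = _k_terms(v)
    mse0, mse = _mse_pair(x, vinv, vinv1, s)
    k = (mse0 / mse) / expected
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(x) for _ in range(n_perm)])
    a_hat = (perms @ vinv1) / s
    resid = perms - a_hat[:, None]
    mse_perm = np.einsum("pi,ij,pj->p", resid, vinv, resid) / (len(x) - 1)
    n_le = int(np.sum(mse_perm <= mse))
    p = (1 + n_le) / (n_perm + 1)
    return SignalResult(
        k=k,
        p_value=p,
        mse_observed=mse,
        n_tips=len(x),
        n_permutations=n_perm,
        seed=seed,
    )
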