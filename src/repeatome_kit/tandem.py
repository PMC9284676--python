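"""Graph-topology characterization of tandem-repeat (5S rDNA-like) read
clusters: connected-component index, loop counting, type classification,
and a simplified k-mer cycle score.

A clean tandem repeat with a single monomer family yields a circular
cluster graph (one loop, type 1); two ribotypes sharing the conserved gene
segment yield interconnected loops (type 2).  The loop count operationalizes
the visual classification of cluster-graph shapes.

Read-similarity graphs of tandem repeats are locally dense: overlapping
reads form triangles along the circle.  The loop count is therefore the
number of *essential* cycles — the cycle rank ``E - V + components`` of the
pruned graph minus the rank (over GF(2)) of its triangle boundaries, i.e.
the first Betti number of the graph with all triangles filled.  On sparse
graphs without triangles (a plain cycle, a theta graph) this equals the
cycle rank; on dense overlap bands it counts one loop per monomer circle
instead of one per redundant local chord.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io import HitGraph

__all__ = [
    "TandemGraphMetrics",
    "connected_component_index",
    "simplify_and_count_loops",
    "kmer_cycle_score",
    "characterize_tandem_cluster",
]


def _as_nx(graph) -> nx.Graph:
    return graph.graph if isinstance(graph, HitGraph) else graph


def connected_component_index(graph) -> float:
    """C = size of the largest connected component / number of nodes."""
    g = _as_nx(graph)
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    largest = max((len(c) for c in nx.connected_components(g)), default=0)
    return largest / g.number_of_nodes()


def _triangle_rank_gf2(g: nx.Graph) -> int:
    """Rank over GF(2) of the triangle boundary matrix of ``g`` (rows =
    triangles, columns = edges), via bitset Gaussian elimination."""
    edge_idx = {frozenset(e): i for i, e in enumerate(g.edges())}
    pivots: dict[int, int] = {}  # pivot bit -> row bitmask
    rank = 0
    adj = {u: set(g.neighbors(u)) for u in g.nodes()}
    order = {u: i for i, u in enumerate(g.nodes())}
    for u in g.nodes():
        for v in adj[u]:
            if order[v] <= order[u]:
                continue
            for w in adj[u] & adj[v]:
                if order[w] <= order[v]:
                    continue
                row = (
                    (1 << edge_idx[frozenset((u, v))])
                    | (1 << edge_idx[frozenset((u, w))])
                    | (1 << edge_idx[frozenset((v, w))])
                )
                while row:
                    piv = row.bit_length() - 1
                    if piv in pivots:
                        row ^= pivots[piv]
                    else:
                        pivots[piv] = row
                        rank += 1
                        break
    return rank


def simplify_and_count_loops(
    graph, prune_weight_frac: float = 0.1
) -> tuple[int, int | str]:
    """Count the essential loops of a tandem-cluster graph and classify it.

    Edges lighter than ``prune_weight_frac`` times the median edge weight
    are removed, the graph is restricted to its largest component, and
    degree-1 nodes are iteratively trimmed (degree-2 chains need no explicit
    contraction: the loop count is invariant under it).  The loop count is
    the triangle-filled first Betti number (see module docstring);
    ``shape_type`` is 1 for a single loop, 2 for two or more, and the string
    ``"linear/ambiguous"`` for a loop-free (tree-like) residue.
    """
    g = _as_nx(graph).copy()
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    weights = [d.get("weight", 1.0) for _, _, d in g.edges(data=True)]
    if weights:
        cutoff = prune_weight_frac * float(np.median(weights))
        g.remove_edges_from(
            [
                (u, v)
                for u, v, d in g.edges(data=True)
                if d.get("weight", 1.0) < cutoff
            ]
        )
    components = list(nx.connected_components(g))
    if not components:
        return 0, "linear/ambiguous"
    g = g.subgraph(max(components, key=len)).copy()
    while True:
        leaves = [u for u in g.nodes() if g.degree(u) <= 1]
        if not leaves:
            break
        g.remove_nodes_from(leaves)
    if g.number_of_nodes() == 0:
        return 0, "linear/ambiguous"
    cycle_rank = g.number_of_edges() - g.number_of_nodes() + 1
    beta = cycle_rank - _triangle_rank_gf2(g)
    if beta <= 0:
        return max(beta, 0), "linear/ambiguous"
    return beta, (1 if beta == 1 else 2)


def kmer_cycle_score(reads, k: int = 11) -> float:
    """Fraction of all k-mer occurrences lying on the dominant simple cycle
    of the k-mer (de Bruijn) graph.

    Starting from the most frequent k-mer, a greedy best-neighbor walk
    follows the highest-count successor (ties broken lexicographically) and
    closes when it revisits a k-mer on the walk.  Error-free reads densely
    covering one circular monomer give a score near 1; unrelated sequence
    gives no cycle (score 0); a second ribotype diverts part of the k-mer
    mass off the dominant cycle.
    """
    reads = list(reads)
    if not reads or any(len(r) < k for r in reads):
        raise ValueError(f"all reads must be at least {k} bases long")
    counts: Counter[str] = Counter()
    for r in reads:
        for i in range(len(r) - k + 1):
            counts[r[i : i + k]] += 1
    total = sum(counts.values())
    start = min(counts, key=lambda s: (-counts[s], s))
    walk = [start]
    pos = {start: 0}
    while True:
        succ = [
            walk[-1][1:] + b for b in "ACGT" if (walk[-1][1:] + b) in counts
        ]
        if not succ:
            warnings.warn("k-mer walk ended without closing a cycle", stacklevel=2)
            return 0.0
        nxt = min(succ, key=lambda s: (-counts[s], s))
        if nxt in pos:
            cycle = walk[pos[nxt] :]
            return sum(counts[s] for s in cycle) / total
        pos[nxt] = len(walk)
        walk.append(nxt)


@dataclass
class TandemGraphMetrics:
    """Per-cluster tandem-repeat metrics (one row of a cluster report)."""

    cluster_id: str
    n_reads: int
    genome_proportion_pct: float | None
    connected_component_index: float
    loop_count: int
    shape_type: int | str
    kmer_score: float | None


def characterize_tandem_cluster(
    graph,
    cluster_id: str = "TND",
    reads=None,
    k: int = 11,
    prune_weight_frac: float = 0.1,
    n_total_reads: int | None = None,
) -> TandemGraphMetrics:
    """Bundle the tandem metrics for one cluster graph (k-mer score only
    when the reads themselves are supplied)."""
    g = _as_nx(graph)
    n_reads = g.number_of_nodes()
    proportion = (
        100.0 * n_reads / n_total_reads if n_total_reads else None
    )
    beta, shape = simplify_and_count_loops(g, prune_weight_frac)
    return TandemGraphMetrics(
        cluster_id=cluster_id,
        n_reads=n_reads,
        genome_proportion_pct=proportion,
        connected_component_index=connected_component_index(g),
        loop_count=beta,
        shape_type=shape,
        kmer_score=None if reads is None else kmer_cycle_score(reads, k),
    )
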