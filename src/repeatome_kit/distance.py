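"""Per-cluster species x species observed/expected similarity matrices and
their distance transforms.

The expected edge count is the uniform-random-edges null: the cluster's
``E_c`` edges are placed uniformly over all ``C(N_c, 2)`` node pairs, so a
species pair (s, t) expects ``E_c * n_s * n_t / C(N_c, 2)`` edges and a
species expects ``E_c * C(n_s, 2) / C(N_c, 2)`` intra-species edges.  The
observed/expected ratio is 1 everywhere for an exchangeable (uniform) graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .io import HitGraph

__all__ = [
    "ClusterSimilarityMatrix",
    "DistanceMatrix",
    "observed_expected_matrix",
    "euclidean_profile_distance",
    "inverse_similarity_distance",
    "filter_complete_clusters",
    "FilterReport",
]


@dataclass
class ClusterSimilarityMatrix:
    """Species x species observed/expected edge-count ratios for one cluster.

    The diagonal holds the intra-species ratio; NaN marks a pair whose
    expectation (and observation) is zero, i.e. missing information.
    """

    cluster_id: str
    species: list[str]
    matrix: np.ndarray
    read_counts: dict[str, int]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.species), len(self.species)):
            raise ValueError("matrix shape must match the species list")
        if np.nanmax(np.abs(m - m.T), initial=0.0) > 1e-12:
            raise ValueError("similarity matrix must be symmetric")
        if np.nanmin(m, initial=0.0) < 0:
            raise ValueError("ratios must be non-negative")
        self.matrix = m

    @property
    def has_missing(self) -> bool:
        return bool(np.isnan(self.matrix).any())

    def offdiag(self) -> np.ndarray:
        mask = ~np.eye(len(self.species), dtype=bool)
        return self.matrix[mask]


@dataclass
class DistanceMatrix:
    """Square symmetric non-negative distance matrix with a transform tag."""

    species: list[str]
    matrix: np.ndarray
    transform: str  # "euclidean" | "inverse"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.species), len(self.species)):
            raise ValueError("matrix shape must match the species list")
        if not np.all(np.isfinite(m)):
            raise ValueError("distances must be finite")
        if np.max(np.abs(m - m.T), initial=0.0) > 1e-9:
            raise ValueError("distance matrix must be symmetric")
        if np.max(np.abs(np.diag(m)), initial=0.0) > 0:
            raise ValueError("distance matrix diagonal must be zero")
        if m.min(initial=0.0) < 0:
            raise ValueError("distances must be non-negative")
        self.matrix = m


def observed_expected_matrix(
    graph: HitGraph | nx.Graph, cluster_id: str = "CL1"
) -> ClusterSimilarityMatrix:
    """Observed/expected inter- and intra-species edge counts for a cluster.

    Species with zero reads in the cluster are absent from the matrix; a
    single-species cluster is an error (no interspecies information).
    """
    sub = graph.cluster_subgraph(cluster_id) if isinstance(graph, HitGraph) else graph
    if sub.number_of_nodes() == 0:
        raise ValueError(f"cluster {cluster_id!r} has no reads")
    counts: dict[str, int] = {}
    for _, d in sub.nodes(data=True):
        counts[d["species"]] = counts.get(d["species"], 0) + 1
    species = sorted(counts)
    if len(species) < 2:
        raise ValueError(f"cluster {cluster_id!r} contains a single species")
    idx = {s: i for i, s in enumerate(species)}
    n_nodes = sub.number_of_nodes()
    e_total = sub.number_of_edges()
    observed = np.zeros((len(species), len(species)))
    for a, b in sub.edges():
        i, j = idx[sub.nodes[a]["species"]], idx[sub.nodes[b]["species"]]
        observed[i, j] += 1
        if i != j:
            observed[j, i] += 1
    total_pairs = n_nodes * (n_nodes - 1) / 2.0
    ratio = np.full_like(observed, np.nan)
    for i, s in enumerate(species):
        for j, t in enumerate(species):
            if i == j:
                pairs = counts[s] * (counts[s] - 1) / 2.0
            else:
                pairs = counts[s] * counts[t]
            expected = e_total * pairs / total_pairs
            if expected > 0:
                ratio[i, j] = observed[i, j] / expected
            # expected == 0 with observed == 0 stays NaN (missing)
    return ClusterSimilarityMatrix(
        cluster_id=cluster_id, species=species, matrix=ratio, read_counts=counts
    )


def euclidean_profile_distance(sim: ClusterSimilarityMatrix) -> DistanceMatrix:
    """d(a, b) = Euclidean distance between the species' similarity profiles
    (rows of the ratio matrix, diagonal columns included)."""
    if sim.has_missing:
        raise ValueError(
            f"cluster {sim.cluster_id!r} has missing ratios; filter first"
        )
    m = sim.matrix
    diff = m[:, None, :] - m[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(species=list(sim.species), matrix=d, transform="euclidean")


def inverse_similarity_distance(sim: ClusterSimilarityMatrix) -> DistanceMatrix:
    """d(a, b) = 1 / S_ab for a != b (zero diagonal).  Requires strictly
    positive off-diagonal similarities; not a metric in general."""
    m = sim.matrix
    off = ~np.eye(len(sim.species), dtype=bool)
    if sim.has_missing or np.any(m[off] <= 0):
        raise ValueError(
            f"cluster {sim.cluster_id!r} has zero or missing similarities; filter first"
        )
    d = np.zeros_like(m)
    d[off] = 1.0 / m[off]
    return DistanceMatrix(species=list(sim.species), matrix=d, transform="inverse")


@dataclass
class FilterReport:
    n_input: int
    n_retained: int
    discarded: dict[str, str] = field(default_factory=dict)  # cluster -> reason


def filter_complete_clusters(
    matrices: list[ClusterSimilarityMatrix],
    all_species: list[str] | None = None,
) -> tuple[list[ClusterSimilarityMatrix], FilterReport]:
    """Retain clusters with complete information: every species present and
    every off-diagonal ratio positive and non-missing.  Clusters with NA or
    zero interspecies values are discarded, with a per-cluster reason."""
    if all_species is None:
        all_species = sorted({s for m in matrices for s in m.species})
    retained = []
    report = FilterReport(n_input=len(matrices), n_retained=0)
    for m in matrices:
        missing_sp = sorted(set(all_species) - set(m.species))
        if missing_sp:
            report.discarded[m.cluster_id] = f"species absent: {', '.join(missing_sp)}"
            continue
        off = m.offdiag()
        if np.isnan(off).any():
            report.discarded[m.cluster_id] = "missing (NA) interspecies ratio"
            continue
        if np.any(off <= 0):
            report.discarded[m.cluster_id] = "zero interspecies ratio"
            continue
        retained.append(m)
    report.n_retained = len(retained)
    return retained, report
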