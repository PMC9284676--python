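"""Per-read intraspecific vs interspecific similarity-hit ratios (Hs/Ho)
and their log-ratio histograms.

A read's Hs counts its similarity hits to same-species reads, Ho its hits
to reads of all other species.  Because species contribute unequal read
numbers, the ratio is per-capita normalized:

    rho = [Hs / (n_s - 1)] / [Ho / (N - n_s)]

with ``n_s`` the read count of the read's species and ``N`` the cluster
total.  A conservative repeat produces rho ~ 1 (log10 ~ 0); a diversified
repeat produces larger ratios.  Reads with Hs = Ho = 0 carry no evidence
and are excluded; reads with only same-species hits are capped at the
histogram maximum, reads with only other-species hits floored at the
histogram minimum, so extreme reads remain counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io import HitGraph

__all__ = [
    "HitRatioRecord",
    "RatioHistogram",
    "read_hit_counts",
    "hs_ho_ratio",
    "cluster_hit_ratios",
    "log_ratio_histogram",
]

LOG_RANGE = (-2.0, 3.0)  # default log10 span of the histograms


@dataclass
class HitRatioRecord:
    read_id: str
    species: str
    hs: int
    ho: int
    rho: float | None  # None when the read has no hits at all
    log10_rho: float | None


def read_hit_counts(
    graph: HitGraph | nx.Graph, cluster: str | None = None
) -> list[tuple[str, str, int, int]]:
    """Per-read neighbor counts partitioned by species equality:
    returns ``(read_id, species, Hs, Ho)`` tuples."""
    if isinstance(graph, HitGraph):
        g = graph.cluster_subgraph(cluster) if cluster is not None else graph.graph
    else:
        g = graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty cluster subgraph")
    out = []
    for node, data in sorted(g.nodes(data=True)):
        sp = data["species"]
        hs = ho = 0
        for nb in g.neighbors(node):
            if g.nodes[nb]["species"] == sp:
                hs += 1
            else:
                ho += 1
        out.append((node, sp, hs, ho))
    return out


def hs_ho_ratio(
    hs: int,
    ho: int,
    n_species_reads: int,
    n_total_reads: int,
    log_range: tuple[float, float] = LOG_RANGE,
) -> float | None:
    """Per-capita normalized Hs/Ho ratio for one read.

    Returns None for an uninformative (0, 0) read; caps Ho = 0 reads at the
    histogram maximum and floors Hs = 0 reads at the histogram minimum.
    """
    if n_species_reads < 2:
        raise ValueError("need at least 2 reads of the read's species")
    if n_total_reads <= n_species_reads:
        raise ValueError("need reads from at least one other species")
    if hs < 0 or ho < 0:
        raise ValueError("hit counts must be non-negative")
    if hs == 0 and ho == 0:
        return None
    if ho == 0:
        return 10.0 ** log_range[1]
    if hs == 0:
        return 10.0 ** log_range[0]
    intra = hs / (n_species_reads - 1)
    inter = ho / (n_total_reads - n_species_reads)
    return intra / inter


def cluster_hit_ratios(
    graph: HitGraph, cluster: str | None = None,
    log_range: tuple[float, float] = LOG_RANGE,
) -> list[HitRatioRecord]:
    """Hs/Ho records for every read of a cluster (species with a single
    read are skipped: their intraspecific rate is undefined)."""
    counts = read_hit_counts(graph, cluster)
    n_by_species: dict[str, int] = {}
    for _, sp, _, _ in counts:
        n_by_species[sp] = n_by_species.get(sp, 0) + 1
    n_total = len(counts)
    records = []
    for read, sp, hs, ho in counts:
        if n_by_species[sp] < 2 or n_total <= n_by_species[sp]:
            continue
        rho = hs_ho_ratio(hs, ho, n_by_species[sp], n_total, log_range)
        records.append(
            HitRatioRecord(
                read_id=read,
                species=sp,
                hs=hs,
                ho=ho,
                rho=rho,
                log10_rho=None if rho is None else float(np.log10(rho)),
            )
        )
    return records


@dataclass
class RatioHistogram:
    bin_edges: np.ndarray  # on the log10 scale
    counts: np.ndarray
    mode_center: float
    frac_conserved: float  # fraction of scored reads with |log10 rho| < 0.2
    n_scored: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def log_ratio_histogram(
    ratios,
    bins: int = 40,
    log_range: tuple[float, float] = LOG_RANGE,
) -> RatioHistogram:
    """Histogram of log10 Hs/Ho ratios over ``log_range`` (default [-2, 3],
    wide enough for the long diversified tails).  Capped/floored ratios land
    in the edge bins; counts sum to the number of scored reads."""
    vals = np.asarray([r for r in ratios if r is not None], dtype=float)
    if vals.size == 0:
        raise ValueError("no scored reads to histogram")
    if np.any(vals <= 0):
        raise ValueError("ratios must be positive")
    logs = np.log10(vals)
    lo, hi = log_range
    logs = np.clip(logs, lo, np.nextafter(hi, lo))
    counts, edges = np.histogram(logs, bins=bins, range=log_range)
    centers = 0.5 * (edges[:-1] + edges[1:])
    mode_center = float(centers[int(np.argmax(counts))])
    frac = float(np.mean(np.abs(np.log10(vals)) < 0.2))
    return RatioHistogram(
        bin_edges=edges,
        counts=counts,
        mode_center=mode_center,
        frac_conserved=frac,
        n_scored=int(vals.size),
    )
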