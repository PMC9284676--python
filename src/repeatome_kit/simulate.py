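"""Seeded synthetic repeatome datasets.

The generator produces data with the statistical structure the downstream
analyses assume, at desk scale:

* a pure-birth (Yule) species tree rescaled to root-to-tip depth 1,
* per-cluster repeat amounts: *signal* clusters evolve as exp(Brownian
  motion) on the tree (positive, right-skewed, tree-correlated), *noise*
  clusters are i.i.d. log-normal,
* genome sizes composed additively of the repeat amounts plus an
  unclassified fraction (so conservation GS = sum(amounts) + unclassified
  holds exactly by construction),
* per-cluster read-similarity graphs with within-species edge probability
  ``p_in`` and between-species probability ``p_in * c * exp(-lam * d_st)``
  for tree distance ``d_st`` (``c`` is repeat conservatism, ``lam`` the
  similarity decay rate),
* tandem-repeat (5S rDNA-like) clusters: reads sampled from random circular
  offsets of one or two monomer ribotypes that share an identical gene
  segment, with edges connecting reads sharing at least ``min_shared_kmers``
  k-mers.

One RNG stream per seed, consumed in documented order
(tree -> per-cluster amounts -> per-cluster graphs), so runs reproduce.
"""

from __future__ import annotations

import json
import math
import random
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .io import PG_TO_MBP, HitGraph, RepeatAbundanceTable, GenomeSizeRecord, serialize_newick

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_tree",
    "simulate_bm_traits",
    "simulate_repeatome",
    "simulate_tandem_cluster",
]


def _species_labels(n: int) -> list[str]:
    if n > 99:
        raise ValueError("at most 99 species supported by the 3-character code scheme")
    return [f"s{i + 1:02d}" for i in range(n)]


def simulate_tree(n_tips: int, seed: int) -> dendropy.Tree:
    """Pure-birth (Yule) tree on ``n_tips`` species, rescaled so every
    root-to-tip path has length 1 (ultrametric).  Deterministic per seed.

    Forward simulation at unit birth rate: while k lineages are extant the
    next split waits Exp(k); a uniformly chosen lineage splits; after the
    n-th birth one more Exp(n) waiting time runs to the present, so every
    terminal branch is strictly positive.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    labels = _species_labels(n_tips)
    taxon_ns = dendropy.TaxonNamespace(labels)
    root = dendropy.Node()
    # root split at time 0: two initial lineages
    active: list[tuple[dendropy.Node, float]] = []  # (node, birth time)
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append((child, 0.0))
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / k)
        i = int(rng.integers(0, k))
        node, birth = active.pop(i)
        node.edge.length = t - birth
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append((child, t))
    t += rng.exponential(1.0 / n_tips)
    order = rng.permutation(n_tips)
    for (node, birth), j in zip(active, order):
        node.edge.length = t - birth
        node.taxon = taxon_ns.get_taxon(labels[j])
    tree = dendropy.Tree(taxon_namespace=taxon_ns, seed_node=root)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length /= t
    tree.is_rooted = True
    return tree


def simulate_bm_traits(
    tree: dendropy.Tree,
    sigma2: float,
    root_value: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> dict[str, float]:
    """Brownian-motion trait on the tree: each branch adds an independent
    Normal(0, sigma2 * branch length) increment; tip value = root value plus
    the root-to-tip path sum."""
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    values = {id(tree.seed_node): float(root_value)}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        bl = node.edge.length or 0.0
        if bl < 0:
            raise ValueError("negative branch length")
        incr = rng.normal(0.0, math.sqrt(sigma2 * bl)) if sigma2 * bl > 0 else 0.0
        values[id(node)] = values[id(node.parent_node)] + incr
    return {
        lf.taxon.label: values[id(lf)] for lf in tree.leaf_node_iter()
    }


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic comparative-clustering run.

    Defaults are desk-scale stand-ins for a genome-skimming comparative run:
    8 species, 12 clusters, 40 reads per species per cluster; amounts are in
    Mbp on the monoploid (1Cx) scale.
    """

    n_species: int = 8
    tree_seed: int = 0
    data_seed: int = 0
    n_signal_clusters: int = 8
    n_noise_clusters: int = 4
    reads_per_species_per_cluster: int = 40
    bm_sigma2: float = 0.25
    p_in: float = 0.5
    conservatism: float = 0.3  # c = p_out / p_in at zero tree distance
    decay: float = 1.0  # lam: similarity decay with tree distance
    unclassified_fraction: float = 0.05
    # amount scale: exp(BM) around ~250 Mbp gives Loliinae-like 1Cx sums
    log_amount_root: float = math.log(250.0)
    log_noise_mean: float = math.log(150.0)
    log_noise_sd: float = 0.5

    def validate(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        if min(self.n_signal_clusters, self.n_noise_clusters) < 0:
            raise ValueError("cluster counts must be >= 0")
        if self.n_signal_clusters + self.n_noise_clusters < 1:
            raise ValueError("need at least one cluster")
        if self.reads_per_species_per_cluster < 1:
            raise ValueError("reads_per_species_per_cluster must be >= 1")
        if not 0 < self.p_in <= 1:
            raise ValueError("p_in must be in (0, 1]")
        if not 0 < self.conservatism <= 1:
            raise ValueError("conservatism must be in (0, 1]")
        if self.decay < 0:
            raise ValueError("decay must be >= 0")
        if not 0 <= self.unclassified_fraction < 1:
            raise ValueError("unclassified_fraction must be in [0, 1)")
        if self.bm_sigma2 < 0:
            raise ValueError("bm_sigma2 must be >= 0")


@dataclass
class SyntheticDataset:
    """Bundle produced by :func:`simulate_repeatome`."""

    config: SimulationConfig
    tree: dendropy.Tree
    amounts_mbp: pd.DataFrame  # samples x clusters, Mbp of 1Cx
    abundance: RepeatAbundanceTable  # same matrix as % of 1Cx
    genome_sizes: list[GenomeSizeRecord]
    hitgraphs: dict[str, HitGraph]
    truth_labels: dict[str, str]  # cluster -> "signal" | "noise"

    @property
    def genome_size_mbp(self) -> pd.Series:
        return pd.Series(
            {r.sample_id: r.cx1_mbp for r in self.genome_sizes}, name="cx1_mbp"
        )

    def write(self, outdir: str | Path) -> dict[str, str]:
        """Emit the pipeline's file formats plus a truth JSON; returns the
        mapping of artifact name -> path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        p = outdir / "tree.nwk"
        p.write_text(serialize_newick(self.tree))
        paths["tree"] = str(p)
        p = outdir / "abundance_pct.tsv"
        self.abundance.values.to_csv(p, sep="\t", index_label="sample")
        paths["abundance"] = str(p)
        p = outdir / "amounts_mbp.tsv"
        self.amounts_mbp.to_csv(p, sep="\t", index_label="sample")
        paths["amounts"] = str(p)
        p = outdir / "genome_sizes.tsv"
        rows = [
            {
                "sample": r.sample_id,
                "ploidy": r.ploidy,
                "c2_pg": r.c2_pg,
                "cx1_pg": r.cx1_pg,
                "cx1_mbp": r.cx1_mbp,
            }
            for r in self.genome_sizes
        ]
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        paths["genome_sizes"] = str(p)
        p = outdir / "hitsort.tsv"
        with open(p, "w") as fh:
            for cl in sorted(self.hitgraphs):
                g = self.hitgraphs[cl].graph
                for a, b, d in sorted(g.edges(data=True)):
                    fh.write(f"{a}\t{b}\t{d['weight']}\t{cl}\n")
        paths["hitsort"] = str(p)
        p = outdir / "truth.json"
        p.write_text(
            json.dumps(
                {"labels": self.truth_labels, "config": asdict(self.config)},
                indent=1,
                sort_keys=True,
            )
        )
        paths["truth"] = str(p)
        return paths


def _patristic_matrix(tree: dendropy.Tree, labels: list[str]) -> np.ndarray:
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return d


def simulate_repeatome(config: SimulationConfig) -> SyntheticDataset:
    """Generate one full synthetic comparative-clustering dataset."""
    config.validate()
    tree = simulate_tree(config.n_species, config.tree_seed)
    labels = _species_labels(config.n_species)
    rng = np.random.default_rng(config.data_seed)
    n_clusters = config.n_signal_clusters + config.n_noise_clusters
    cluster_ids = [f"CL{i + 1:03d}" for i in range(n_clusters)]
    truth = {}
    amounts = pd.DataFrame(index=labels, columns=cluster_ids, dtype=float)
    # RNG order: amounts first (one draw block per cluster), then graphs
    for k, cl in enumerate(cluster_ids):
        if k < config.n_signal_clusters:
            truth[cl] = "signal"
            trait = simulate_bm_traits(
                tree, config.bm_sigma2, root_value=config.log_amount_root, rng=rng
            )
            amounts[cl] = pd.Series({s: math.exp(v) for s, v in trait.items()})
        else:
            truth[cl] = "noise"
            draws = rng.normal(config.log_noise_mean, config.log_noise_sd, len(labels))
            amounts[cl] = np.exp(draws)

    total_repeat = amounts.sum(axis=1)
    gs_mbp = total_repeat / (1.0 - config.unclassified_fraction)
    abundance_pct = amounts.div(gs_mbp, axis=0) * 100.0
    abundance = RepeatAbundanceTable(values=abundance_pct)
    genome_sizes = []
    for s in labels:
        cx1_pg = gs_mbp[s] / PG_TO_MBP
        genome_sizes.append(
            GenomeSizeRecord(
                sample_id=s,
                cx1_pg=cx1_pg,
                cx1_mbp=gs_mbp[s],
                c2_pg=2 * cx1_pg,
                ploidy=2,
            )
        )

    dmat = _patristic_matrix(tree, labels)
    m = config.reads_per_species_per_cluster
    hitgraphs: dict[str, HitGraph] = {}
    for cl in cluster_ids:
        hg = HitGraph()
        read_ids = {
            s: [f"{s}_{cl}_{i:03d}" for i in range(m)] for s in labels
        }
        for s in labels:
            for r in read_ids[s]:
                hg.add_read(r, species=s, cluster=cl)
        for i, s in enumerate(labels):
            for j in range(i, len(labels)):
                t = labels[j]
                if i == j:
                    p = config.p_in
                    mask = rng.random((m, m)) < p
                    for a in range(m):
                        for b in range(a + 1, m):
                            if mask[a, b]:
                                w = 80.0 + 20.0 * rng.random()
                                hg.add_hit(read_ids[s][a], read_ids[s][b], round(w, 1))
                else:
                    p = config.p_in * config.conservatism * math.exp(
                        -config.decay * dmat[i, j]
                    )
                    mask = rng.random((m, m)) < p
                    for a in range(m):
                        for b in range(m):
                            if mask[a, b]:
                                w = 80.0 + 20.0 * rng.random()
                                hg.add_hit(read_ids[s][a], read_ids[t][b], round(w, 1))
        hitgraphs[cl] = hg

    return SyntheticDataset(
        config=config,
        tree=tree,
        amounts_mbp=amounts,
        abundance=abundance,
        genome_sizes=genome_sizes,
        hitgraphs=hitgraphs,
        truth_labels=truth,
    )


# ---------------------------------------------------------------------------
# Tandem-repeat (5S rDNA-like) clusters
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=length))


def _kmers(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def simulate_tandem_cluster(
    monomer_length: int = 340,
    n_ribotypes: int = 1,
    shared_gene_length: int = 120,
    n_reads: int = 80,
    read_length: int = 100,
    kmer_k: int = 11,
    min_shared_kmers: int = 30,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[list[str], HitGraph, int]:
    """Simulate a tandem-repeat cluster: reads from random circular offsets
    of one or two monomer ribotypes.

    With two ribotypes both monomers share an identical leading gene segment
    of ``shared_gene_length`` bp (the conserved tandem gene) and differ in
    the remaining spacer.  Reads land in a single similarity graph whose
    edges connect read pairs sharing at least ``min_shared_kmers`` k-mers
    (edge weight = number of shared k-mers).  Returns
    ``(reads, hitgraph, truth_type)`` with ``truth_type = n_ribotypes``.
    """
    if n_ribotypes not in (1, 2):
        raise ValueError("n_ribotypes must be 1 or 2")
    if read_length >= monomer_length:
        raise ValueError("read_length must be smaller than monomer_length")
    if n_ribotypes == 2 and shared_gene_length >= monomer_length:
        raise ValueError("shared_gene_length must be smaller than monomer_length")
    if kmer_k >= read_length:
        raise ValueError("kmer_k must be smaller than read_length")
    rng = np.random.default_rng(seed)
    monomers = [_random_seq(rng, monomer_length)]
    if n_ribotypes == 2:
        gene = monomers[0][:shared_gene_length]
        monomers.append(gene + _random_seq(rng, monomer_length - shared_gene_length))

    reads: list[str] = []
    for _ in range(n_reads):
        mono = monomers[int(rng.integers(0, n_ribotypes))]
        off = int(rng.integers(0, monomer_length))
        circ = mono + mono
        read = circ[off : off + read_length]
        if error_rate > 0:
            chars = list(read)
            hits = np.nonzero(rng.random(read_length) < error_rate)[0]
            for pos in hits:
                alternatives = [b for b in _BASES if b != chars[pos]]
                chars[pos] = alternatives[int(rng.integers(0, 3))]
            read = "".join(chars)
        reads.append(read)

    hg = HitGraph()
    ids = [f"s01_TND_{i:03d}" for i in range(n_reads)]
    for rid in ids:
        hg.add_read(rid, species="s01", cluster="TND")
    kmer_sets = [_kmers(r, kmer_k) for r in reads]
    for a in range(n_reads):
        for b in range(a + 1, n_reads):
            shared = len(kmer_sets[a] & kmer_sets[b])
            if shared >= min_shared_kmers:
                hg.add_hit(ids[a], ids[b], float(shared))
    return reads, hg, n_ribotypes
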