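"""End-to-end orchestration: run the analysis stages from one config.

A run is driven either by real input files (abundance TSV, genome-size TSV,
hitsort TSV, Newick tree) or by a :class:`~repeatome_kit.simulate.SimulationConfig`;
exactly one of the two must be active.  Stages execute in dependency order

    io -> distances -> njnet;  abundance;  gscorr;  signal;  hsho;  tandem

and every run writes a manifest (package version, seed, parameter hash,
output checksums) so that identical config + seed reproduces byte-identical
numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .abundance import kruskal_wallis, summarize
from .distance import (
    euclidean_profile_distance,
    filter_complete_clusters,
    inverse_similarity_distance,
    observed_expected_matrix,
)
from .genome_size import pairwise_contribution, repeat_gs_correlation
from .hsho import cluster_hit_ratios, log_ratio_histogram
from .io import (
    parse_abundance_table,
    parse_genome_size_table,
    parse_hitsort,
    parse_newick,
    serialize_newick,
    write_distance_phylip,
    write_splits_nexus,
)
from .network import consensus_network, neighbor_joining, tree_splits
from .signal import k_permutation_test
from .simulate import SimulationConfig, simulate_repeatome, simulate_tandem_cluster
from .tandem import characterize_tandem_cluster

__all__ = ["PipelineConfig", "run_pipeline", "ALL_STAGES"]

ALL_STAGES = ("abundance", "distances", "njnet", "gscorr", "signal", "hsho", "tandem")

log = logging.getLogger("repeatome_kit")


@dataclass
class PipelineConfig:
    """One pipeline run: inputs (or a simulation), stage toggles, thresholds."""

    outdir: str = "repeatome_out"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES
    # real inputs (mutually exclusive with `simulation`)
    abundance_tsv: str | None = None
    genome_size_tsv: str | None = None
    hitsort_tsv: str | None = None
    tree_newick: str | None = None
    simulation: SimulationConfig | None = None
    # thresholds
    consensus_threshold: float = 0.25
    prune_weight_frac: float = 0.1
    n_permutations: int = 199
    species_code_length: int = 3
    cladogram: bool = False  # unit branch lengths for the signal stage

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        raw = yaml.safe_load(text) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        if "stages" in raw:
            cfg.stages = tuple(raw["stages"])
        return cfg

    def validate(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        real = [self.abundance_tsv, self.genome_size_tsv, self.hitsort_tsv,
                self.tree_newick]
        if self.simulation is not None and any(p is not None for p in real):
            raise ValueError("config must use either real inputs or simulation, not both")
        if self.simulation is None:
            needs = {
                "abundance": ["abundance_tsv"],
                "distances": ["hitsort_tsv"],
                "njnet": ["hitsort_tsv"],
                "gscorr": ["abundance_tsv", "genome_size_tsv", "tree_newick"],
                "signal": ["abundance_tsv", "tree_newick"],
                "hsho": ["hitsort_tsv"],
                "tandem": ["hitsort_tsv"],
            }
            for stage in self.stages:
                for attr in needs[stage]:
                    if getattr(self, attr) is None:
                        raise ValueError(
                            f"stage {stage!r} requires input {attr!r}, which is missing"
                        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages; returns the manifest dictionary."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    timings: dict[str, float] = {}
    results: dict = {}

    def emit(name: str, text: str) -> Path:
        p = outdir / name
        p.write_text(text)
        written.append(p)
        return p

    # ---- io stage -------------------------------------------------------
    t0 = time.perf_counter()
    if config.simulation is not None:
        sim = config.simulation
        dataset = simulate_repeatome(sim)
        for p in dataset.write(outdir / "simulated").values():
            written.append(Path(p))
        abundance = dataset.abundance
        tree = dataset.tree
        genome_sizes = dataset.genome_sizes
        hitgraph = None  # per-cluster graphs already split
        cluster_graphs = {cl: hg.graph for cl, hg in dataset.hitgraphs.items()}
    else:
        dataset = None
        abundance = (
            parse_abundance_table(Path(config.abundance_tsv).read_text())
            if config.abundance_tsv
            else None
        )
        genome_sizes = (
            parse_genome_size_table(Path(config.genome_size_tsv).read_text())
            if config.genome_size_tsv
            else None
        )
        tree = parse_newick(Path(config.tree_newick).read_text()) if config.tree_newick else None
        if tree is not None and len(tree.seed_node.child_nodes()) > 2:
            tree.reroot_at_midpoint(update_bipartitions=False)
        hitgraph = (
            parse_hitsort(
                Path(config.hitsort_tsv).read_text(), config.species_code_length
            )
            if config.hitsort_tsv
            else None
        )
        cluster_graphs = (
            {cl: hitgraph.cluster_subgraph(cl) for cl in hitgraph.clusters}
            if hitgraph is not None
            else {}
        )
    timings["io"] = time.perf_counter() - t0

    gs_series = (
        pd.Series({r.sample_id: r.cx1_mbp for r in genome_sizes})
        if genome_sizes
        else None
    )

    # ---- abundance ------------------------------------------------------
    if "abundance" in config.stages:
        t0 = time.perf_counter()
        summary = summarize(abundance)
        payload = {
            "total_mean": summary.total_mean,
            "total_min": summary.total_min,
            "total_max": summary.total_max,
            "family_mean": {k: round(v, 6) for k, v in summary.family_mean.items()},
        }
        if abundance.group_labels:
            labels = [abundance.group_labels[s] for s in abundance.sample_ids]
            kw = kruskal_wallis(summary.sample_total.to_numpy(), labels)
            payload["kruskal_wallis_total"] = {
                "h": kw.h, "df": kw.df, "p_value": kw.p_value
            }
        emit("abundance_summary.json", json.dumps(payload, indent=1, sort_keys=True))
        results["abundance"] = payload
        timings["abundance"] = time.perf_counter() - t0

    # ---- distances ------------------------------------------------------
    sims = None
    if "distances" in config.stages or "njnet" in config.stages:
        t0 = time.perf_counter()
        sims = []
        for cl in sorted(cluster_graphs):
            try:
                sims.append(observed_expected_matrix(cluster_graphs[cl], cl))
            except ValueError as exc:
                log.info("cluster %s skipped: %s", cl, exc)
        retained, report = filter_complete_clusters(sims)
        results["distances"] = {
            "n_input": report.n_input,
            "n_retained": report.n_retained,
            "discarded": report.discarded,
        }
        dmats = {}
        for m in retained:
            dmats[m.cluster_id] = {
                "euclidean": euclidean_profile_distance(m),
                "inverse": inverse_similarity_distance(m),
            }
        if "distances" in config.stages:
            for cl, both in dmats.items():
                for tag, dm in both.items():
                    emit(
                        f"dist_{cl}_{tag}.phy",
                        write_distance_phylip(dm.species, dm.matrix),
                    )
            emit(
                "distance_filter_report.json",
                json.dumps(results["distances"], indent=1, sort_keys=True),
            )
        timings["distances"] = time.perf_counter() - t0

    # ---- njnet ----------------------------------------------------------
    if "njnet" in config.stages:
        t0 = time.perf_counter()
        nets = {}
        for tag in ("euclidean", "inverse"):
            trees = []
            newicks = []
            for cl in sorted(dmats):
                nj = neighbor_joining(dmats[cl][tag])
                trees.append(nj)
                newicks.append(f"[{cl}] " + serialize_newick(nj).strip())
            if trees:
                net = consensus_network(trees, config.consensus_threshold)
                emit(f"consensus_{tag}.nex", write_splits_nexus(net))
                emit(f"nj_trees_{tag}.nwk", "\n".join(newicks) + "\n")
                nets[tag] = net
        results["njnet"] = {
            tag: {"n_splits": len(net), "n_nontrivial": len(net.nontrivial())}
            for tag, net in nets.items()
        }
        timings["njnet"] = time.perf_counter() - t0

    # ---- gscorr ---------------------------------------------------------
    if "gscorr" in config.stages:
        t0 = time.perf_counter()
        # absolute amounts (Mbp) reconstructed as (% of 1C)/100 x 1Cx Mbp
        common = [s for s in abundance.sample_ids if s in gs_series.index]
        amounts = abundance.values.loc[common].mul(gs_series[common], axis=0) / 100.0
        corr = repeat_gs_correlation(amounts, gs_series, tree)
        contrib = pairwise_contribution(amounts, gs_series)
        rows = []
        for fam in amounts.columns:
            c = corr[fam]
            rows.append(
                {
                    "family": fam,
                    "r2": None if c is None else round(c.r2, 6),
                    "p_value": None if c is None else c.p_value,
                    "min_mbp": round(contrib.min_mbp[fam], 3),
                    "max_mbp": round(contrib.max_mbp[fam], 3),
                    "contribution_pct": round(contrib.contribution_pct[fam], 4),
                }
            )
        df = pd.DataFrame(rows)
        emit("gs_correlation.tsv", df.to_csv(sep="\t", index=False))
        results["gscorr"] = {"n_families": len(rows), "n_pairs": contrib.n_pairs}
        timings["gscorr"] = time.perf_counter() - t0

    # ---- signal ---------------------------------------------------------
    if "signal" in config.stages:
        t0 = time.perf_counter()
        sig_tree = tree.clone(depth=1)
        if config.cladogram:
            for e in sig_tree.preorder_edge_iter():
                if e.length is not None:
                    e.length = 1.0
        rows = []
        for j, fam in enumerate(abundance.family_ids):
            col = abundance.values[fam]
            trait = {s: float(col[s]) for s in abundance.sample_ids if pd.notna(col[s])}
            tips = {lf.taxon.label for lf in sig_tree.leaf_node_iter()}
            if not tips <= set(trait):
                continue
            try:
                res = k_permutation_test(
                    sig_tree,
                    trait,
                    n_perm=config.n_permutations,
                    seed=config.seed + j,
                )
            except ValueError:
                continue  # constant trait: K undefined
            rows.append(
                {"family": fam, "k": round(res.k, 6), "p_value": res.p_value,
                 "n_permutations": res.n_permutations}
            )
        df = pd.DataFrame(rows)
        emit("phylo_signal.tsv", df.to_csv(sep="\t", index=False))
        results["signal"] = {"n_tested": len(rows)}
        timings["signal"] = time.perf_counter() - t0

    # ---- hsho -----------------------------------------------------------
    if "hsho" in config.stages:
        t0 = time.perf_counter()
        rows = []
        for cl in sorted(cluster_graphs):
            g = cluster_graphs[cl]
            if len({d["species"] for _, d in g.nodes(data=True)}) < 2:
                continue
            records = cluster_hit_ratios(
                dataset.hitgraphs[cl] if dataset else hitgraph, cluster=cl
            )
            ratios = [r.rho for r in records]
            scored = [r for r in ratios if r is not None]
            if not scored:
                continue
            hist = log_ratio_histogram(ratios)
            rows.append(
                {
                    "cluster": cl,
                    "n_scored": hist.n_scored,
                    "mode_log10": round(hist.mode_center, 4),
                    "frac_conserved": round(hist.frac_conserved, 4),
                }
            )
        df = pd.DataFrame(rows)
        emit("hs_ho_summary.tsv", df.to_csv(sep="\t", index=False))
        results["hsho"] = {"n_clusters": len(rows)}
        timings["hsho"] = time.perf_counter() - t0

    # ---- tandem ---------------------------------------------------------
    if "tandem" in config.stages:
        t0 = time.perf_counter()
        rows = []
        if config.simulation is not None:
            # simulation mode carries no tandem reads: generate one cluster
            # of each truth type from the run seed
            for truth in (1, 2):
                reads, hg, _ = simulate_tandem_cluster(
                    n_ribotypes=truth, seed=config.seed + truth
                )
                metrics = characterize_tandem_cluster(
                    hg,
                    cluster_id=f"TND{truth}",
                    reads=reads,
                    prune_weight_frac=config.prune_weight_frac,
                )
                rows.append({**asdict(metrics), "truth_type": truth})
        else:
            for cl in sorted(cluster_graphs):
                metrics = characterize_tandem_cluster(
                    cluster_graphs[cl],
                    cluster_id=cl,
                    prune_weight_frac=config.prune_weight_frac,
                )
                rows.append(asdict(metrics))
        df = pd.DataFrame(rows)
        emit("tandem_metrics.tsv", df.to_csv(sep="\t", index=False))
        results["tandem"] = {"n_clusters": len(rows)}
        timings["tandem"] = time.perf_counter() - t0

    # ---- manifest -------------------------------------------------------
    cfg_dict = asdict(config)
    manifest = {
        "package": "repeatome-kit",
        "version": __version__,
        "seed": config.seed,
        "stages": list(config.stages),
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "outputs": {
            str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(written))
        },
        "timings_s": {k: round(v, 4) for k, v in timings.items()},
        "results": results,
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True, default=str)
    )
    return manifest


def setup_logging(verbose: bool = True) -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
    )
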