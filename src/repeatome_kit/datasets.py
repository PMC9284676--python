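"""Bundled reference tables for the Loliinae grasses (subtribe Loliinae:
fescues and ray-grasses), transcribed from published summary tables.

Three small TSVs ship with the package:

* ``loliinae_repeat_proportions.tsv`` — per-sample genome proportion (% of
  the holoploid 1C genome) of each annotated repeat family, with the
  printed per-sample total, for 47 samples in three evolutionary groups
  (BL = broad-leaved, FL = fine-leaved, Sch = Schedonorus).
* ``loliinae_genome_sizes.tsv`` — holoploid 2C (pg), ploidy and derived
  monoploid 1Cx (pg, Mbp) for the 23 samples with flow-cytometry data.
* ``loliinae_5s_clusters.tsv`` — 5S rDNA cluster-graph features (reads in
  cluster, genome proportion, k-mer score, connected-component index,
  graph shape type) for 43 samples.
"""

from __future__ import annotations

import io as _io
from importlib import resources

import pandas as pd

from .io import GenomeSizeRecord, RepeatAbundanceTable, parse_abundance_table

__all__ = [
    "load_repeat_proportions",
    "load_genome_sizes",
    "load_5s_clusters",
]


def _read(name: str) -> str:
    return (resources.files("repeatome_kit") / "data" / name).read_text()


def load_repeat_proportions() -> RepeatAbundanceTable:
    """Repeat genome-proportion table (47 Loliinae samples x 28 repeat
    families + printed total), with group labels attached."""
    df = pd.read_csv(
        _io.StringIO(_read("loliinae_repeat_proportions.tsv")), sep="\t"
    )
    groups = dict(zip(df["sample"], df["group"]))
    body = df.drop(columns=["group", "lineage"]).set_index("sample")
    text = "sample\t" + "\t".join(body.columns) + "\n"
    for s, row in body.iterrows():
        text += s + "\t" + "\t".join(str(v) for v in row) + "\n"
    table = parse_abundance_table(text)
    table.group_labels = groups
    return table


def load_genome_sizes() -> list[GenomeSizeRecord]:
    """Genome sizes of the 23 Loliinae samples with cytometry data."""
    df = pd.read_csv(
        _io.StringIO(_read("loliinae_genome_sizes.tsv")), sep="\t"
    )
    return [
        GenomeSizeRecord(
            sample_id=r["sample"],
            c2_pg=float(r["c2_pg"]),
            ploidy=int(r["ploidy"]),
            cx1_pg=float(r["cx1_pg"]),
            cx1_mbp=float(r["cx1_mbp"]),
        )
        for _, r in df.iterrows()
    ]


def load_5s_clusters() -> pd.DataFrame:
    """5S rDNA cluster-graph feature table (43 Loliinae samples)."""
    return pd.read_csv(
        _io.StringIO(_read("loliinae_5s_clusters.tsv")), sep="\t"
    )
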