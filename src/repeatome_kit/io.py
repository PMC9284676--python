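"""Readers, writers and the shared data model of the pipeline.

Formats handled here are the ones a comparative repeatome study touches:

* abundance tables (samples x repeat families, percent of the holoploid 1C genome),
* genome-size tables (2C in pg, ploidy, derived monoploid 1Cx sizes),
* ``hitsort`` read-similarity edge lists as emitted by graph-based read
  clustering (read names carry a fixed-length species code prefix),
* Newick trees,
* NEXUS SPLITS blocks (consensus-network output, SplitsTree-compatible),
* lower-triangle PHYLIP distance matrices.

Missing abundance cells are *absent* (NaN), never zero: a printed ``0`` in an
abundance table means a measured zero.
"""

from __future__ import annotations

import io as _io
import math
import re
import warnings
from dataclasses import dataclass, field

import dendropy
import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "RepeatAbundanceTable",
    "GenomeSizeRecord",
    "HitGraph",
    "SplitSet",
    "ParseError",
    "parse_abundance_table",
    "parse_genome_size_table",
    "parse_hitsort",
    "parse_newick",
    "serialize_newick",
    "write_splits_nexus",
    "read_splits_nexus",
    "write_distance_phylip",
    "read_distance_phylip",
]

PG_TO_MBP = 978.0  # 1 pg of DNA = 978 Mbp (Dolezel conversion constant)


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# Abundance tables
# ---------------------------------------------------------------------------

@dataclass
class RepeatAbundanceTable:
    """Samples x repeat-family matrix of genome proportions (% of 1C).

    ``values`` is a DataFrame indexed by sample id with one column per repeat
    family; NaN marks a missing (unmeasured) cell, 0.0 a measured zero.
    ``group_labels`` optionally maps sample -> evolutionary group.
    """

    values: pd.DataFrame
    group_labels: dict[str, str] | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ParseError(f"duplicate sample ids: {dups}")
        arr = self.values.to_numpy(dtype=float)
        if np.nanmin(arr, initial=0.0) < 0:
            raise ValueError("abundance table contains negative entries")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def family_ids(self) -> list[str]:
        return list(self.values.columns)

    def totals(self) -> pd.Series:
        """Per-sample total proportion: a designated total column if present,
        otherwise the row sum over families (missing cells ignored)."""
        for col in self.values.columns:
            if str(col).strip().lower().rstrip("(%) ").rstrip() == "total":
                return self.values[col]
        return self.values.sum(axis=1, skipna=True)


def parse_abundance_table(text: str) -> RepeatAbundanceTable:
    """Parse a TSV abundance table: header row of family names, first column
    of sample ids, numeric body.  Blank or NA cells become missing (NaN)."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise ParseError("empty abundance table")
    header = lines[0].rstrip("\n").split("\t")
    families = [h.strip() for h in header[1:]]
    samples: list[str] = []
    rows: list[list[float]] = []
    na_tokens = {"", "na", "nan", "n/a", "-", "–"}
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.rstrip("\n").split("\t")
        sample = cells[0].strip()
        if not sample:
            raise ParseError(f"line {lineno}: empty sample id")
        vals: list[float] = []
        for j, cell in enumerate(cells[1:], start=1):
            tok = cell.strip()
            if tok.lower() in na_tokens:
                vals.append(math.nan)
                continue
            try:
                vals.append(float(tok))
            except ValueError:
                col = families[j - 1] if j - 1 < len(families) else f"#{j}"
                raise ParseError(
                    f"non-numeric cell {tok!r} at row {sample!r}, column {col!r}"
                ) from None
        vals += [math.nan] * (len(families) - len(vals))
        samples.append(sample)
        rows.append(vals[: len(families)])
    if len(set(samples)) != len(samples):
        dups = sorted({s for s in samples if samples.count(s) > 1})
        raise ParseError(f"duplicate sample ids: {dups}")
    df = pd.DataFrame(rows, index=samples, columns=families, dtype=float)
    return RepeatAbundanceTable(values=df)


# ---------------------------------------------------------------------------
# Genome sizes
# ---------------------------------------------------------------------------

@dataclass
class GenomeSizeRecord:
    """Genome-size measurements for one sample.

    2C is the holoploid genome size; 1Cx = 2C / ploidy is the monoploid size.
    The Mbp column of published tables is usually derived from the unrounded
    1Cx value, so the consistency checks use rounding-aware tolerances.
    """

    sample_id: str
    cx1_pg: float
    cx1_mbp: float
    c2_pg: float | None = None
    ploidy: int | None = None

    def __post_init__(self) -> None:
        if self.ploidy is not None:
            if self.ploidy < 2 or self.ploidy % 2 != 0:
                raise ValueError(f"{self.sample_id}: ploidy must be an even integer >= 2")
            if self.c2_pg is not None:
                derived = self.c2_pg / self.ploidy
                if abs(derived - self.cx1_pg) > 0.0051:
                    raise ValueError(
                        f"{self.sample_id}: 1Cx {self.cx1_pg} inconsistent with "
                        f"2C/ploidy = {derived:.4f}"
                    )
        # allow for the table's 1Cx being printed rounded at 2 decimals
        if abs(self.cx1_pg * PG_TO_MBP - self.cx1_mbp) > 0.006 * PG_TO_MBP:
            raise ValueError(
                f"{self.sample_id}: 1Cx Mbp {self.cx1_mbp} inconsistent with "
                f"{self.cx1_pg} pg x {PG_TO_MBP}"
            )


def parse_genome_size_table(text: str) -> list[GenomeSizeRecord]:
    """Parse a genome-size TSV with columns
    ``sample  [group]  ploidy  c2_pg  cx1_pg  cx1_mbp`` (header required)."""
    df = pd.read_csv(_io.StringIO(text), sep="\t")
    cols = {c.lower(): c for c in df.columns}
    required = ["sample", "cx1_pg", "cx1_mbp"]
    for r in required:
        if r not in cols:
            raise ParseError(f"genome size table missing column {r!r}")
    records = []
    for _, row in df.iterrows():
        ploidy = row[cols["ploidy"]] if "ploidy" in cols else None
        c2 = row[cols["c2_pg"]] if "c2_pg" in cols else None
        records.append(
            GenomeSizeRecord(
                sample_id=str(row[cols["sample"]]),
                cx1_pg=float(row[cols["cx1_pg"]]),
                cx1_mbp=float(row[cols["cx1_mbp"]]),
                c2_pg=None if c2 is None or pd.isna(c2) else float(c2),
                ploidy=None if ploidy is None or pd.isna(ploidy) else int(ploidy),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Hitsort read-similarity graphs
# ---------------------------------------------------------------------------

class HitGraph:
    """Undirected read-similarity graph.

    Thin wrapper around :class:`networkx.Graph`; nodes are read ids carrying
    ``species`` and ``cluster`` attributes, edges carry a positive similarity
    ``weight``.  Duplicate edges are collapsed keeping the maximum weight.
    """

    def __init__(self) -> None:
        self.graph = nx.Graph()
        self.n_self_pairs_skipped = 0

    def add_read(self, read_id: str, species: str, cluster: str = "CL1") -> None:
        self.graph.add_node(read_id, species=species, cluster=cluster)

    def add_hit(self, read_a: str, read_b: str, weight: float) -> None:
        if read_a == read_b:
            self.n_self_pairs_skipped += 1
            return
        if weight <= 0:
            raise ValueError(f"non-positive similarity weight {weight}")
        if self.graph.has_edge(read_a, read_b):
            if weight > self.graph[read_a][read_b]["weight"]:
                self.graph[read_a][read_b]["weight"] = weight
        else:
            self.graph.add_edge(read_a, read_b, weight=weight)

    # -- queries ----------------------------------------------------------
    def species_of(self, read_id: str) -> str:
        return self.graph.nodes[read_id]["species"]

    @property
    def clusters(self) -> list[str]:
        return sorted({d["cluster"] for _, d in self.graph.nodes(data=True)})

    @property
    def species(self) -> list[str]:
        return sorted({d["species"] for _, d in self.graph.nodes(data=True)})

    def cluster_subgraph(self, cluster: str) -> nx.Graph:
        nodes = [n for n, d in self.graph.nodes(data=True) if d["cluster"] == cluster]
        return self.graph.subgraph(nodes)

    def species_read_counts(self, cluster: str | None = None) -> dict[str, int]:
        counts: dict[str, int] = {}
        for _, d in self.graph.nodes(data=True):
            if cluster is not None and d["cluster"] != cluster:
                continue
            counts[d["species"]] = counts.get(d["species"], 0) + 1
        return counts


def parse_hitsort(
    text: str, species_code_length: int = 3, cluster: str | None = None
) -> HitGraph:
    """Parse a hitsort TSV into a :class:`HitGraph`.

    Each line is ``readA<TAB>readB<TAB>weight`` with an optional fourth
    column giving the cluster id.  Read names start with a fixed-length
    species code (default 3 characters, the naming scheme of comparative
    read-clustering runs); the code must be followed by an underscore.
    Self pairs are skipped (counted); duplicate pairs keep the max weight.
    """
    hg = HitGraph()
    for lineno, ln in enumerate(text.splitlines(), start=1):
        if not ln.strip() or ln.startswith("#"):
            continue
        parts = ln.rstrip("\n").split("\t")
        if len(parts) not in (3, 4):
            raise ParseError(f"line {lineno}: expected 3 or 4 tab-separated fields")
        ra, rb, w = parts[0].strip(), parts[1].strip(), parts[2].strip()
        cl = parts[3].strip() if len(parts) == 4 else (cluster or "CL1")
        try:
            weight = float(w)
        except ValueError:
            raise ParseError(f"line {lineno}: non-numeric weight {w!r}") from None
        if weight <= 0:
            raise ParseError(f"line {lineno}: non-positive weight {weight}")
        for r in (ra, rb):
            if len(r) <= species_code_length or r[species_code_length] != "_":
                raise ParseError(
                    f"line {lineno}: read name {r!r} lacks a "
                    f"{species_code_length}-character species code prefix"
                )
            hg.add_read(r, species=r[:species_code_length], cluster=cl)
        hg.add_hit(ra, rb, weight)
    if hg.n_self_pairs_skipped:
        warnings.warn(
            f"hitsort: skipped {hg.n_self_pairs_skipped} self pair(s)",
            stacklevel=2,
        )
    return hg


# ---------------------------------------------------------------------------
# Newick trees (dendropy-backed)
# ---------------------------------------------------------------------------

def parse_newick(text: str) -> dendropy.Tree:
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise ParseError(f"invalid Newick: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ParseError("duplicate tip labels in Newick tree")
    return tree


def serialize_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip() + "\n"


# ---------------------------------------------------------------------------
# Split sets and NEXUS SPLITS blocks
# ---------------------------------------------------------------------------

def canonical_split(side, taxa) -> frozenset:
    """Canonical representation of a bipartition: the side *not* containing
    the first taxon in sorted order (a split equals its complement)."""
    taxa = sorted(taxa)
    side = frozenset(side)
    comp = frozenset(taxa) - side
    if not side or not comp:
        raise ValueError("a split must bipartition the taxon set properly")
    return comp if taxa[0] in side else side


@dataclass
class SplitSet:
    """Weighted bipartitions of a taxon set (a consensus-network product).

    ``splits`` maps the canonical side of each bipartition (see
    :func:`canonical_split`) to a ``(weight, support)`` pair, weight >= 0 and
    support in [0, 1].
    """

    taxa: tuple[str, ...]
    splits: dict[frozenset, tuple[float, float]] = field(default_factory=dict)

    def add(self, side, weight: float, support: float = 1.0) -> None:
        key = canonical_split(side, self.taxa)
        if not (math.isfinite(weight) and weight >= 0):
            raise ValueError(f"invalid split weight {weight}")
        if not 0.0 <= support <= 1.0:
            raise ValueError(f"invalid split support {support}")
        if key in self.splits:  # merge (e.g. two root-adjacent edges)
            w0, s0 = self.splits[key]
            self.splits[key] = (w0 + weight, max(s0, support))
        else:
            self.splits[key] = (weight, support)

    def nontrivial(self) -> dict[frozenset, tuple[float, float]]:
        n = len(self.taxa)
        return {s: ws for s, ws in self.splits.items() if 2 <= len(s) <= n - 2}

    def __len__(self) -> int:
        return len(self.splits)


def _quote(label: str) -> str:
    if re.search(r"[\s'();,\[\]]", label):
        return "'" + label.replace("'", "''") + "'"
    return label


def write_splits_nexus(splits: SplitSet) -> str:
    """Serialize a SplitSet as a SplitsTree-compatible NEXUS SPLITS block."""
    if not splits.taxa:
        raise ValueError("empty taxon set")
    taxa = list(splits.taxa)
    index = {t: i + 1 for i, t in enumerate(taxa)}
    out = ["#NEXUS", "", "BEGIN TAXA;", f"DIMENSIONS NTAX={len(taxa)};", "TAXLABELS"]
    out += [f"  [{i + 1}] {_quote(t)}" for i, t in enumerate(taxa)]
    out += [";", "END;", "", "BEGIN SPLITS;",
            f"DIMENSIONS NTAX={len(taxa)} NSPLITS={len(splits.splits)};",
            "FORMAT LABELS=NO WEIGHTS=YES CONFIDENCES=YES;", "MATRIX"]
    items = sorted(
        splits.splits.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
    )
    for side, (weight, support) in items:
        idx = " ".join(str(index[t]) for t in sorted(side, key=taxa.index))
        out.append(f"  {weight:.6f} {support:.6f} {idx},")
    out += [";", "END;", ""]
    return "\n".join(out)


def read_splits_nexus(text: str) -> SplitSet:
    """Read back the SPLITS NEXUS produced by :func:`write_splits_nexus`."""
    taxa: list[str] = []
    lines = iter(text.splitlines())
    in_taxa = in_matrix = False
    splits_rows: list[tuple[float, float, list[int]]] = []
    for ln in lines:
        s = ln.strip()
        if s.upper() == "TAXLABELS":
            in_taxa = True
            continue
        if in_taxa:
            if s == ";":
                in_taxa = False
                continue
            m = re.match(r"\[\d+\]\s+(.*)", s)
            label = m.group(1) if m else s
            if label.startswith("'") and label.endswith("'"):
                label = label[1:-1].replace("''", "'")
            taxa.append(label)
            continue
        if s.upper() == "MATRIX":
            in_matrix = True
            continue
        if in_matrix:
            if s == ";":
                in_matrix = False
                continue
            parts = s.rstrip(",").split()
            weight, support = float(parts[0]), float(parts[1])
            idx = [int(p) for p in parts[2:]]
            splits_rows.append((weight, support, idx))
    if not taxa:
        raise ParseError("no TAXA block found in splits NEXUS")
    ss = SplitSet(taxa=tuple(taxa))
    for weight, support, idx in splits_rows:
        ss.add({taxa[i - 1] for i in idx}, weight, support)
    return ss


# ---------------------------------------------------------------------------
# PHYLIP distance matrices
# ---------------------------------------------------------------------------

def write_distance_phylip(labels, matrix) -> str:
    """Lower-triangle PHYLIP distance format at 6-decimal fixed precision."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(labels):
        raise ValueError("matrix must be square and match the label list")
    if np.max(np.abs(m - m.T)) > 1e-9:
        raise ValueError("distance matrix is asymmetric beyond 1e-9")
    if np.max(np.abs(np.diag(m))) > 1e-9:
        raise ValueError("distance matrix diagonal must be zero")
    out = [f"{len(labels)}"]
    for i, lab in enumerate(labels):
        row = " ".join(f"{m[i, j]:.6f}" for j in range(i))
        out.append(f"{lab:<12s}{(' ' + row) if row else ''}".rstrip())
    return "\n".join(out) + "\n"


def read_distance_phylip(text: str):
    """Read a lower-triangle PHYLIP matrix; returns ``(labels, ndarray)``."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    n = int(lines[0].split()[0])
    labels: list[str] = []
    m = np.zeros((n, n))
    for i, ln in enumerate(lines[1 : n + 1]):
        parts = ln.split()
        labels.append(parts[0])
        vals = [float(v) for v in parts[1 : i + 1]]
        if len(vals) != i:
            raise ParseError(f"row {i + 1}: expected {i} distances, got {len(vals)}")
        m[i, :i] = vals
        m[:i, i] = vals
    return labels, m
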