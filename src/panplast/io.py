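"""Standard-format I/O and the package's coordinate conventions.

Internal coordinates are 0-based half-open ``[start, end)``; GFF3 input
(1-based inclusive) is converted at the boundary.  Nucleotide sequences are
normalized to uppercase over the alphabet ``{A, C, G, T, N}``: any other
character (IUPAC ambiguity codes included) is masked to ``N``, and k-mers
containing ``N`` are skipped downstream.

All writers are deterministic: identical inputs produce byte-identical
output files (fixed field order, ``repr``-based float formatting).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import networkx as nx
import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

_VALID = set("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# domain records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Contig:
    contig_id: str
    sequence: str
    circular: bool = False


@dataclass
class GenomeRecord:
    """One genome: an ordered collection of replicons/contigs."""

    genome_id: str
    contigs: list[Contig]

    def __post_init__(self) -> None:
        ids = [c.contig_id for c in self.contigs]
        if len(set(ids)) != len(ids):
            raise FormatError(f"duplicate contig id in genome {self.genome_id!r}")
        for c in self.contigs:
            if not c.sequence:
                raise FormatError(
                    f"empty sequence for contig {c.contig_id!r} in {self.genome_id!r}"
                )

    def contig(self, contig_id: str) -> Contig:
        for c in self.contigs:
            if c.contig_id == contig_id:
                return c
        raise KeyError(contig_id)


@dataclass(frozen=True)
class GeneRecord:
    """A protein-coding gene: 0-based half-open coordinates on its contig."""

    gene_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    protein: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"gene {self.gene_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id!r}: strand must be '+' or '-'")


@dataclass(frozen=True)
class QualityRecord:
    """Completeness/contamination estimates consumed as input metadata."""

    genome_id: str
    completion: float
    contamination: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.completion) and math.isfinite(self.contamination)):
            raise FormatError(f"non-finite quality values for {self.genome_id!r}")
        if not (0 <= self.completion <= 100) or self.contamination < 0:
            raise FormatError(f"quality values out of range for {self.genome_id!r}")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def normalize_nucleotides(seq: str) -> str:
    """Uppercase and mask every non-ACGT character to N."""
    up = seq.upper()
    if set(up) <= _VALID:
        return up
    return "".join(c if c in _VALID else "N" for c in up)


def read_genome_fasta(path: str | Path, genome_id: str | None = None) -> GenomeRecord:
    """Read one genome from a nucleotide FASTA file (one record per contig).

    Contig order follows file order.  A trailing ``circular=true`` token in a
    record description marks that contig as circular.
    """
    path = Path(path)
    gid = genome_id if genome_id is not None else path.stem
    contigs: list[Contig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate contig id {rec.id!r} in {path}")
        seen.add(rec.id)
        circular = "circular=true" in rec.description.lower()
        contigs.append(Contig(rec.id, normalize_nucleotides(str(rec.seq)), circular))
    if not contigs:
        raise FormatError(f"no FASTA records in {path}")
    return GenomeRecord(gid, contigs)


def read_gff3_genes(
    path: str | Path,
    protein_fasta_path: str | Path,
    genome_id: str | None = None,
) -> list[GeneRecord]:
    """Read CDS features from a GFF3 file plus their protein translations.

    GFF3 1-based inclusive coordinates are converted to internal 0-based
    half-open ones.  CDS features whose ID has no record in the protein FASTA
    are dropped with a warning.  Genes are returned sorted by
    (contig, start, gene_id).
    """
    path = Path(path)
    gid = genome_id if genome_id is not None else path.stem
    proteins = {
        rec.id: str(rec.seq) for rec in SeqIO.parse(str(protein_fasta_path), "fasta")
    }
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="error",
        )
    except ValueError as exc:  # gffutils signals ID collisions as ValueError
        raise FormatError(f"bad GFF3 {path}: {exc}") from exc
    genes: list[GeneRecord] = []
    seen: set[str] = set()
    for feat in db.features_of_type("CDS"):
        if feat.end < feat.start:
            raise FormatError(f"{path}: feature {feat.id!r} has end < start")
        if feat.id in seen:
            raise FormatError(f"{path}: duplicate gene id {feat.id!r}")
        seen.add(feat.id)
        prot = proteins.get(feat.id)
        if prot is None:
            logger.warning("gene %s has no protein record; dropped", feat.id)
            continue
        genes.append(
            GeneRecord(
                gene_id=feat.id,
                genome_id=gid,
                contig_id=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand if feat.strand in ("+", "-") else "+",
                protein=prot,
            )
        )
    genes.sort(key=lambda g: (g.contig_id, g.start, g.gene_id))
    return genes


def read_quality_table(path: str | Path) -> list[QualityRecord]:
    """Read a TSV of genome quality estimates.

    Requires columns ``genome_id``, ``completion``, ``contamination``; any
    unparsable row aborts the read.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["genome_id", "completion", "contamination"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"quality table {path}: missing column(s) {missing}")
    records = []
    for _, row in df.iterrows():
        try:
            records.append(
                QualityRecord(
                    genome_id=str(row["genome_id"]),
                    completion=float(row["completion"]),
                    contamination=float(row["contamination"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise FormatError(
                f"quality table {path}: bad row for {row['genome_id']!r}: {exc}"
            ) from exc
    ids = [r.genome_id for r in records]
    if len(set(ids)) != len(ids):
        raise FormatError(f"quality table {path}: duplicate genome_id")
    return records


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """Minimal phylogenetic tree node: leaves carry names, edges lengths."""

    name: str | None = None
    length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def tips(self) -> list["TreeNode"]:
        if self.is_leaf():
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.tips())
        return out

    def tip_distance_matrix(self) -> tuple[list[str], np.ndarray]:
        """Leaf names plus the matrix of path lengths between all leaf pairs."""
        paths: dict[str, list[tuple[int, float]]] = {}

        def walk(node: TreeNode, trail: list[tuple[int, float]]) -> None:
            here = trail + [(id(node), node.length or 0.0)]
            if node.is_leaf():
                paths[str(node.name)] = here
            for c in node.children:
                walk(c, here)

        walk(self, [])
        names = sorted(paths)
        n = len(names)
        mat = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                pi, pj = paths[names[i]], paths[names[j]]
                shared = 0
                for (a, _), (b, _) in zip(pi, pj):
                    if a != b:
                        break
                    shared += 1
                d = sum(l for _, l in pi[shared:]) + sum(l for _, l in pj[shared:])
                mat[i, j] = mat[j, i] = d
        return names, mat


def write_newick(tree: TreeNode) -> str:
    """Serialize a tree to Newick with full-precision branch lengths."""
    seen: set[int] = set()

    def render(node: TreeNode) -> str:
        if id(node) in seen:
            raise ValueError("cyclic tree structure")
        seen.add(id(node))
        if node.is_leaf():
            label = node.name or ""
        else:
            label = "(" + ",".join(render(c) for c in node.children) + ")"
            if node.name:
                label += node.name
        if node.length is not None:
            label += f":{float(node.length)!r}"
        return label

    return render(tree) + ";"


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    """Write a graph to GraphML, preserving node and edge attributes.

    Nodes and edges are emitted in sorted order so output is deterministic.
    """
    ordered = nx.Graph()
    ordered.add_nodes_from(sorted(graph.nodes(data=True)))
    ordered.add_edges_from(
        sorted((min(u, v), max(u, v), d) for u, v, d in graph.edges(data=True))
    )
    nx.write_graphml(ordered, str(path))


def write_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a DataFrame as TSV with a header row and no index column."""
    table.to_csv(path, sep="\t", index=False)


def write_genome_fasta(genome: GenomeRecord, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for c in genome.contigs:
            desc = " circular=true" if c.circular else ""
            fh.write(f">{c.contig_id}{desc}\n")
            for i in range(0, len(c.sequence), width):
                fh.write(c.sequence[i : i + width] + "\n")


def write_gff3_genes(genes: Sequence[GeneRecord], path: str | Path) -> None:
    """Write genes as GFF3 CDS features (converting back to 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.contig_id, g.start, g.gene_id)):
            fh.write(
                "\t".join(
                    [
                        g.contig_id,
                        "panplast",
                        "CDS",
                        str(g.start + 1),
                        str(g.end),
                        ".",
                        g.strand,
                        "0",
                        f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )


def write_protein_fasta(
    proteins: Mapping[str, str], path: str | Path, width: int = 80
) -> None:
    with open(path, "w") as fh:
        for gene_id in sorted(proteins):
            fh.write(f">{gene_id}\n")
            seq = proteins[gene_id]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_quality_table(records: Iterable[QualityRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.genome_id, r.completion, r.contamination) for r in records],
        columns=["genome_id", "completion", "contamination"],
    )
    write_tsv(df, path)
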