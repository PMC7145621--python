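"""Homologous protein families by the 80/80 single-linkage rule.

Two protein-coding genes are linked when a Smith-Waterman local alignment of
their products (BLOSUM62, gap open 11 / extend 1, so a gap of length L costs
11 + (L - 1)) reaches at least 80% identity over the aligned columns AND
covers at least 80% of *both* sequences.  Families are the connected
components of the resulting link graph (single linkage), so every gene -
paralogs included - ends up in exactly one family; genes with no passing
pair form singleton families.

Identity uses aligned columns as denominator, gap columns included, which
penalizes indel-riddled alignments.  Coverage of a sequence is the aligned
span divided by its full length.  Requiring both coverages keeps the pass
relation symmetric, which single linkage needs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import networkx as nx
from Bio import Align
from Bio.Align import substitution_matrices


@dataclass(frozen=True)
class FamilyThresholds:
    min_identity: float = 0.8
    min_coverage: float = 0.8

    def __post_init__(self) -> None:
        for v in (self.min_identity, self.min_coverage):
            if not (0 < v <= 1):
                raise ValueError("thresholds must be in (0, 1]")


@dataclass(frozen=True)
class AlignmentStats:
    """Identity and per-sequence coverage of the optimal local alignment."""

    identity: float
    coverage_a: float
    coverage_b: float
    score: float = 0.0

    def passes(self, thresholds: FamilyThresholds) -> bool:
        return (
            self.identity >= thresholds.min_identity
            and min(self.coverage_a, self.coverage_b) >= thresholds.min_coverage
        )


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def align_pair(protein_a: str, protein_b: str) -> AlignmentStats:
    """Optimal Smith-Waterman local alignment statistics for two proteins.

    Among co-optimal alignments the first in the aligner's deterministic
    traceback order is reported.  A pair with no positive-scoring local
    alignment gets identity and coverage 0.
    """
    if not protein_a or not protein_b:
        raise ValueError("cannot align an empty protein sequence")
    result = _ALIGNER.align(protein_a, protein_b)
    if result.score <= 0:
        return AlignmentStats(0.0, 0.0, 0.0, float(result.score))
    aln = result[0]
    sa, sb = str(aln[0]), str(aln[1])
    columns = len(sa)
    identities = sum(1 for x, y in zip(sa, sb) if x == y and x != "-")
    span_a = int(aln.coordinates[0, -1] - aln.coordinates[0, 0])
    span_b = int(aln.coordinates[1, -1] - aln.coordinates[1, 0])
    return AlignmentStats(
        identity=identities / columns,
        coverage_a=span_a / len(protein_a),
        coverage_b=span_b / len(protein_b),
        score=float(aln.score),
    )


def candidate_pairs(
    proteins: Mapping[str, str], word_size: int = 4
) -> Iterator[tuple[str, str]]:
    """All protein pairs sharing at least one common ``word_size``-mer.

    A conservative prefilter at the 80/80 operating point for sequences of
    >= 20 residues: two sequences passing 80% identity over 80% of their
    length necessarily share an exact 4-mer.  Sequences shorter than the
    word size are paired with everything.
    """
    by_word: dict[str, list[str]] = {}
    short: list[str] = []
    order = sorted(proteins)
    for gene_id in order:
        seq = proteins[gene_id]
        if len(seq) < word_size:
            short.append(gene_id)
            continue
        for i in range(len(seq) - word_size + 1):
            by_word.setdefault(seq[i : i + word_size], []).append(gene_id)
    seen: set[tuple[str, str]] = set()
    for members in by_word.values():
        uniq = sorted(set(members))
        for a, b in itertools.combinations(uniq, 2):
            if (a, b) not in seen:
                seen.add((a, b))
                yield a, b
    for s in short:
        for other in order:
            if other == s:
                continue
            pair = (min(s, other), max(s, other))
            if pair not in seen:
                seen.add(pair)
                yield pair


def cluster_families(
    passing_pairs: Iterable[tuple[str, str]], all_gene_ids: Iterable[str]
) -> dict[str, str]:
    """Single-linkage families from pre-screened passing pairs.

    Families are connected components of the pass graph, numbered ``FAM1,
    FAM2, ...`` by decreasing size then lexicographically smallest member,
    so the labeling is invariant to input order.
    """
    graph = nx.Graph()
    graph.add_nodes_from(all_gene_ids)
    graph.add_edges_from(passing_pairs)
    components = sorted(
        nx.connected_components(graph), key=lambda c: (-len(c), min(c))
    )
    return {
        gene: f"FAM{rank}"
        for rank, comp in enumerate(components, start=1)
        for gene in comp
    }


def build_families(
    proteins: Mapping[str, str],
    thresholds: FamilyThresholds = FamilyThresholds(),
) -> dict[str, str]:
    """End-to-end family construction: prefilter, align, threshold, cluster."""
    passing = (
        (a, b)
        for a, b in candidate_pairs(proteins)
        if align_pair(proteins[a], proteins[b]).passes(thresholds)
    )
    return cluster_families(passing, proteins.keys())
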