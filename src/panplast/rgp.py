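"""Regions of genomic plasticity (RGPs).

Projecting the partitioned pangenome onto a genome tags every gene
persistent, shell or cloud.  An RGP is a run of consecutive shell/cloud
genes whose genomic span exceeds 3 kb - a candidate horizontally acquired
region or genomic island.  Detection is a maximal-scoring-segment scan:
walking the genes of a contig in coordinate order, each shell/cloud gene
adds ``variable_gain`` (+1) and each persistent gene adds
``persistent_penalty`` (-3) to a running score; a segment closes when the
running score drops to <= 0 or the contig ends, and the candidate region is
the segment prefix achieving the maximum score.  Candidates are kept when
their score reaches ``min_score`` (4) and their genomic span (first gene
start to last gene end) strictly exceeds ``min_length`` (3000 bp).  With the
default constants a single persistent gene interrupting a strong variable
region is tolerated, but two consecutive persistent genes break it.

Circular contigs are scanned with a doubled walk so a region crossing the
origin is found exactly once; such a region is reported with
``end > contig length``, i.e. coordinates wrap modulo the contig.

RGPs of strains from one species cluster are compared by shared family
content: 100 * |families(query) & families(target)| / |families(query)|.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from panplast.io import GeneRecord
from panplast.pangenome import PartitionModel

logger = logging.getLogger(__name__)

VARIABLE = ("shell", "cloud")


@dataclass(frozen=True)
class RGPScoring:
    variable_gain: int = 1
    persistent_penalty: int = -3
    min_score: int = 4
    min_length: int = 3000

    def __post_init__(self) -> None:
        if self.variable_gain <= 0 or self.persistent_penalty >= 0 or self.min_length <= 0:
            raise ValueError("invalid RGP scoring constants")

    def gene_score(self, label: str) -> int:
        return self.variable_gain if label in VARIABLE else self.persistent_penalty


@dataclass(frozen=True)
class ProjectedGene:
    """A gene with its partition label, in coordinate order on its contig."""

    gene_id: str
    family: str
    start: int
    end: int
    label: str


@dataclass
class RGP:
    rgp_id: str
    genome_id: str
    contig_id: str
    start: int
    end: int  # may exceed contig length when the region wraps a circular origin
    genes: list[str]
    families: set[str]
    score: int

    @property
    def span(self) -> int:
        return self.end - self.start


def project_partitions(
    gene_records: Iterable[GeneRecord],
    family_of: Mapping[str, str],
    partitions: PartitionModel | Mapping[str, str],
) -> dict[tuple[str, str], list[ProjectedGene]]:
    """Tag every gene with its family's partition, per contig in gene order.

    ``partitions`` is either a fitted :class:`PartitionModel` or a plain
    family -> partition mapping.  A gene whose family has no label is an
    error.
    """
    labels = partitions.labels if isinstance(partitions, PartitionModel) else partitions
    out: dict[tuple[str, str], list[ProjectedGene]] = {}
    for g in gene_records:
        fam = family_of.get(g.gene_id)
        if fam is None:
            raise KeyError(f"gene {g.gene_id!r} has no family")
        label = labels.get(fam)
        if label is None:
            raise KeyError(f"family {fam!r} has no partition label")
        out.setdefault((g.genome_id, g.contig_id), []).append(
            ProjectedGene(g.gene_id, fam, g.start, g.end, label)
        )
    for genes in out.values():
        genes.sort(key=lambda p: (p.start, p.gene_id))
    return out


def _scan(scores: Sequence[int]) -> list[tuple[int, int, int]]:
    """Maximal-scoring segments of a score sequence.

    Returns (first index, last index, score) triples.  A segment closes when
    the running score drops to <= 0 or the sequence ends; the candidate is
    the prefix achieving the maximum running score (first peak on ties), and
    the walk resumes just after that peak.
    """
    out = []
    i, n = 0, len(scores)
    while i < n:
        cur = 0
        best = 0
        best_end = None
        j = i
        while j < n:
            cur += scores[j]
            if cur > best:
                best = cur
                best_end = j
            if cur <= 0:
                break
            j += 1
        if best_end is not None:
            out.append((i, best_end, best))
            i = best_end + 1
        else:
            i = j + 1
    return out


def detect_rgps(
    projected: Sequence[ProjectedGene],
    genome_id: str,
    contig_id: str,
    scoring: RGPScoring = RGPScoring(),
    circular: bool = False,
    contig_length: int | None = None,
) -> list[RGP]:
    """Score-based RGP detection on one contig's projected genes.

    Reported regions satisfy score >= min_score and genomic span strictly
    greater than min_length; leading/trailing persistent genes are trimmed.
    Regions on one contig are gene-disjoint.  For a circular contig
    (``contig_length`` required) the gene list is walked twice with shifted
    coordinates so origin-crossing regions are detected once.
    """
    genes = sorted(projected, key=lambda p: (p.start, p.gene_id))
    n = len(genes)
    if n == 0:
        return []
    if circular:
        if contig_length is None:
            raise ValueError("circular scan requires contig_length")
        walk = genes + [
            ProjectedGene(g.gene_id, g.family, g.start + contig_length,
                          g.end + contig_length, g.label)
            for g in genes
        ]
    else:
        walk = list(genes)

    scores = [scoring.gene_score(g.label) for g in walk]
    regions: list[RGP] = []
    seen: set[frozenset[int]] = set()
    for s_idx, e_idx, seg_score in _scan(scores):
        # trim persistent ends (defensive: scan segments start and end variable)
        while s_idx <= e_idx and walk[s_idx].label not in VARIABLE:
            s_idx += 1
        while e_idx >= s_idx and walk[e_idx].label not in VARIABLE:
            e_idx -= 1
        if e_idx < s_idx:
            continue
        if circular:
            if s_idx >= n:
                continue
            if (e_idx - s_idx + 1) > n:  # whole contig variable: cap at one turn
                e_idx = s_idx + n - 1
            key = frozenset(idx % n for idx in range(s_idx, e_idx + 1))
            if key in seen:
                continue
            seen.add(key)
        member = walk[s_idx : e_idx + 1]
        score = sum(scoring.gene_score(g.label) for g in member)
        span = member[-1].end - member[0].start
        if score < scoring.min_score or span <= scoring.min_length:
            continue
        regions.append(
            RGP(
                rgp_id="",
                genome_id=genome_id,
                contig_id=contig_id,
                start=member[0].start,
                end=member[-1].end,
                genes=[g.gene_id for g in member],
                families={g.family for g in member},
                score=score,
            )
        )
    regions.sort(key=lambda r: r.start)
    for k, r in enumerate(regions, start=1):
        r.rgp_id = f"RGP_{genome_id}_{contig_id}_{k}"
    return regions


def detect_rgps_genome(
    projected: Mapping[tuple[str, str], Sequence[ProjectedGene]],
    scoring: RGPScoring = RGPScoring(),
    circular_contigs: frozenset[tuple[str, str]] | set[tuple[str, str]] = frozenset(),
    contig_lengths: Mapping[tuple[str, str], int] | None = None,
) -> list[RGP]:
    """Run the scan on every contig of a projected genome collection."""
    out: list[RGP] = []
    for (genome_id, contig_id), genes in sorted(projected.items()):
        circ = (genome_id, contig_id) in circular_contigs
        length = None
        if circ:
            if contig_lengths is None:
                raise ValueError("contig_lengths required for circular contigs")
            length = contig_lengths[(genome_id, contig_id)]
        out.extend(
            detect_rgps(genes, genome_id, contig_id, scoring, circ, length)
        )
    return out


def match_rgps(
    query: RGP, candidates: Iterable[RGP]
) -> list[tuple[str, float]]:
    """Rank candidate RGPs (same species cluster) by shared family content.

    The percentage denominator is the query's family set.  Sorted by
    descending shared percentage, ties by target id.
    """
    if not query.families:
        raise ValueError(f"query RGP {query.rgp_id!r} has an empty family set")
    rows = []
    for target in candidates:
        if target.rgp_id == query.rgp_id and target.genome_id == query.genome_id:
            continue
        shared = 100.0 * len(query.families & target.families) / len(query.families)
        rows.append((target.rgp_id, shared))
    rows.sort(key=lambda t: (-t[1], t[0]))
    return rows


def rgp_annotation_crosslinks(
    rgps: Sequence[RGP],
    feature_table: Iterable[tuple[str, str]] = (),
    known_genes: set[str] | None = None,
) -> dict[str, dict[str, int]]:
    """Count externally annotated genes (AMR, virulence, ...) per RGP.

    ``feature_table`` holds (gene_id, category) rows produced by external
    annotation tools; this function only cross-links, it predicts nothing.
    Rows referencing genes outside ``known_genes`` (when given) are skipped
    with a warning; flags on genes outside any RGP are ignored.
    """
    categories: dict[str, set[str]] = {}
    for gene_id, category in feature_table:
        if known_genes is not None and gene_id not in known_genes:
            logger.warning("feature table references unknown gene %s; skipped", gene_id)
            continue
        categories.setdefault(category, set()).add(gene_id)
    out: dict[str, dict[str, int]] = {}
    for r in rgps:
        gene_set = set(r.genes)
        out[r.rgp_id] = {
            cat: len(gene_set & flagged) for cat, flagged in sorted(categories.items())
        }
    return out
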