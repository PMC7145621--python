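"""Synthetic genomes, proteins and pangenomes with known truth.

Every pipeline stage is testable offline against fixtures produced here:

- :func:`mutate_sequence` / :func:`simulate_species` exercise the
  distance-vs-divergence relation and species clustering (genomes of one
  species are independent mutations of a shared ancestor, species ancestors
  independent mutations of a common root);
- :func:`simulate_protein_families` plants protein families (independent
  random prototypes, 5% within-family point mutation) for family recovery;
- :func:`simulate_pangenome` plants a full pangenome: persistent / shell /
  cloud families with class-specific presence probabilities (0.99 / 0.5 /
  0.05 by default; shell presence is drawn once per genome per block of 30
  families, giving the co-occurrence structure a neighborhood-aware
  partitioner can exploit), a conserved backbone gene order, and optional
  cloud-gene islands of a requested genomic span inserted contiguously - the
  ground truth for RGP detection.

All generators are deterministic given their seed.  Every planted family is
guaranteed to occur in at least one genome (an all-absent draw is re-seeded
into one random genome), so planted per-partition counts are exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from panplast.io import (
    Contig,
    GeneRecord,
    GenomeRecord,
    QualityRecord,
    write_genome_fasta,
    write_gff3_genes,
    write_protein_fasta,
    write_quality_table,
    write_tsv,
)

_DNA = np.frombuffer(b"ACGT", dtype=np.uint8)
_AA = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)

INTERGENIC_GAP = 100  # bp between backbone genes
ISLAND_GAP = 50  # bp between genes inside a planted island


def _random_codes(length: int, rng: np.random.Generator, n_symbols: int) -> np.ndarray:
    return rng.integers(0, n_symbols, size=length, dtype=np.int64)


def _codes_to_str(codes: np.ndarray, alphabet: np.ndarray) -> str:
    return alphabet[codes].tobytes().decode("ascii")


def _mutate_codes(
    codes: np.ndarray, rate: float, rng: np.random.Generator, n_symbols: int
) -> np.ndarray:
    """Substitute each symbol with probability ``rate`` to a uniformly chosen
    *different* symbol; length is preserved."""
    mask = rng.random(codes.size) < rate
    shift = rng.integers(1, n_symbols, size=int(mask.sum()), dtype=np.int64)
    out = codes.copy()
    out[mask] = (out[mask] + shift) % n_symbols
    return out


def random_dna(length: int, rng: np.random.Generator) -> str:
    return _codes_to_str(_random_codes(length, rng, 4), _DNA)


def random_protein(length: int, rng: np.random.Generator) -> str:
    return _codes_to_str(_random_codes(length, rng, 20), _AA)


def mutate_sequence(seq: str, rate: float, seed: int | np.random.Generator) -> str:
    """Point-mutate a DNA sequence at a per-base substitution rate."""
    if not (0 <= rate <= 1):
        raise ValueError("rate must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lut = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i
    codes = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        raise ValueError("mutate_sequence expects an ACGT sequence")
    return _codes_to_str(_mutate_codes(codes, rate, rng, 4), _DNA)


def mutate_protein(seq: str, rate: float, rng: np.random.Generator) -> str:
    lut = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate(_AA):
        lut[b] = i
    codes = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    return _codes_to_str(_mutate_codes(codes, rate, rng, 20), _AA)


# ---------------------------------------------------------------------------
# species-level fixtures
# ---------------------------------------------------------------------------


def simulate_species(
    n_species: int,
    genomes_per_species: int,
    genome_length: int,
    rate_within: float,
    rate_between: float,
    seed: int,
) -> tuple[list[GenomeRecord], dict[str, str]]:
    """Planted species: one ancestor per species, members independent
    mutations of it at ``rate_within``; ancestors are mutations of a common
    root at ``rate_between``.  Returns genomes plus truth labels."""
    if not rate_within < rate_between:
        raise ValueError("rate_within must be < rate_between")
    rng = np.random.default_rng(seed)
    root = _random_codes(genome_length, rng, 4)
    genomes: list[GenomeRecord] = []
    truth: dict[str, str] = {}
    for s in range(n_species):
        ancestor = _mutate_codes(root, rate_between, rng, 4)
        for g in range(genomes_per_species):
            member = _mutate_codes(ancestor, rate_within, rng, 4)
            gid = f"sp{s + 1}_g{g + 1}"
            genomes.append(
                GenomeRecord(gid, [Contig(f"{gid}_c1", _codes_to_str(member, _DNA))])
            )
            truth[gid] = f"species{s + 1}"
    return genomes, truth


def simulate_protein_families(
    n_families: int = 3,
    genes_per_family: int = 4,
    length: int = 200,
    within_rate: float = 0.05,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str]]:
    """Planted protein families: independent random prototypes, members
    point-mutated at ``within_rate``.  Returns (proteins, truth labels)."""
    rng = np.random.default_rng(seed)
    proteins: dict[str, str] = {}
    truth: dict[str, str] = {}
    for f in range(n_families):
        proto = _random_codes(length, rng, 20)
        for g in range(genes_per_family):
            gene_id = f"fam{f + 1}_gene{g + 1}"
            proteins[gene_id] = _codes_to_str(
                _mutate_codes(proto, within_rate, rng, 20), _AA
            )
            truth[gene_id] = f"truth{f + 1}"
    return proteins, truth


# ---------------------------------------------------------------------------
# pangenome fixtures
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions for a planted pangenome."""

    n_genomes: int = 30
    n_persistent: int = 300
    n_shell: int = 300
    n_cloud: int = 400
    p_persistent: float = 0.99
    p_shell: float = 0.5
    p_cloud: float = 0.05
    shell_block_size: int = 30
    rgp_islands: tuple[tuple[int, int], ...] = ()  # (n cloud genes, span in bp)
    p_island: float = 0.3  # probability a genome carries a given island
    protein_length_range: tuple[int, int] = (120, 260)
    within_family_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_persistent, self.p_shell, self.p_cloud, self.p_island):
            if not (0 <= p <= 1):
                raise ValueError("presence probabilities must be in [0, 1]")


@dataclass
class SimulatedPangenome:
    """A planted pangenome and all its truth tables."""

    spec: SimulationSpec
    genomes: list[GenomeRecord]
    genes: list[GeneRecord]
    proteins: dict[str, str]
    family_truth: dict[str, str]  # gene -> planted family
    partition_truth: dict[str, str]  # planted family -> persistent/shell/cloud
    rgp_truth: dict[str, list[tuple[str, int, int]]]  # genome -> (contig, start, end)
    quality: list[QualityRecord] = field(default_factory=list)

    def genome_of(self) -> dict[str, str]:
        return {g.gene_id: g.genome_id for g in self.genes}


def simulate_pangenome(spec: SimulationSpec) -> SimulatedPangenome:
    """Generate genomes realizing a planted pangenome (see module docstring).

    Present backbone genes are laid on one linear contig per genome in a
    conserved order; islands are inserted as contiguous runs of dedicated
    cloud families whose gene lengths are synthesized so the island's
    genomic span matches the requested one.
    """
    rng = np.random.default_rng(spec.seed)
    N = spec.n_genomes
    classes = (
        ["persistent"] * spec.n_persistent
        + ["shell"] * spec.n_shell
        + ["cloud"] * spec.n_cloud
    )
    fam_ids = [f"TF{i:05d}" for i in range(len(classes))]
    partition_truth = dict(zip(fam_ids, classes))

    lo, hi = spec.protein_length_range
    proto_len = {f: int(rng.integers(lo, hi + 1)) for f in fam_ids}
    prototypes = {f: _random_codes(proto_len[f], rng, 20) for f in fam_ids}

    # presence matrix, by class
    M = len(fam_ids)
    present = np.zeros((M, N), dtype=bool)
    for i, cls in enumerate(classes):
        if cls == "persistent":
            present[i] = rng.random(N) < spec.p_persistent
        elif cls == "cloud":
            present[i] = rng.random(N) < spec.p_cloud
    # shell presence: one draw per genome per block of shell families
    shell_idx = [i for i, c in enumerate(classes) if c == "shell"]
    for b0 in range(0, len(shell_idx), spec.shell_block_size):
        block = shell_idx[b0 : b0 + spec.shell_block_size]
        draws = rng.random(N) < spec.p_shell
        for i in block:
            present[i] = draws
    # no family may be absent everywhere
    for i in range(M):
        if not present[i].any():
            present[i, rng.integers(N)] = True

    # islands: dedicated cloud families, present as a unit
    island_fams: list[list[str]] = []
    island_prot_len: list[int] = []
    island_carriers: list[np.ndarray] = []
    for isl, (n_genes_isl, span) in enumerate(spec.rgp_islands):
        aa_len = (span - (n_genes_isl - 1) * ISLAND_GAP) // n_genes_isl // 3
        if aa_len < 10:
            raise ValueError(
                f"island {isl}: span {span} too small for {n_genes_isl} genes"
            )
        fams = [f"TI{isl:02d}_{g:02d}" for g in range(n_genes_isl)]
        island_fams.append(fams)
        island_prot_len.append(int(aa_len))
        for f in fams:
            partition_truth[f] = "cloud"
            prototypes[f] = _random_codes(int(aa_len), rng, 20)
        carriers = rng.random(N) < spec.p_island
        if not carriers.any():
            carriers[rng.integers(N)] = True
        island_carriers.append(carriers)

    backbone_order = [fam_ids[i] for i in rng.permutation(M)]
    fam_row = {f: i for i, f in enumerate(fam_ids)}

    genomes: list[GenomeRecord] = []
    genes: list[GeneRecord] = []
    proteins: dict[str, str] = {}
    family_truth: dict[str, str] = {}
    rgp_truth: dict[str, list[tuple[str, int, int]]] = {}
    for g in range(N):
        gid = f"g{g + 1:03d}"
        contig_id = f"{gid}_c1"
        layout: list[tuple[str, int]] = [
            (f, 3 * proto_len[f]) for f in backbone_order if present[fam_row[f], g]
        ]
        # insert carried islands at random backbone slots (stable order)
        inserts: list[tuple[int, list[tuple[str, int]]]] = []
        for isl in range(len(island_fams)):
            if island_carriers[isl][g]:
                slot = int(rng.integers(1, max(len(layout), 2)))
                inserts.append(
                    (slot, [(f, 3 * island_prot_len[isl]) for f in island_fams[isl]])
                )
        inserts.sort(key=lambda t: t[0], reverse=True)
        island_members: dict[str, int] = {}
        for slot, block in inserts:
            layout[slot:slot] = block
            for f, _ in block:
                island_members[f] = 1

        pos = INTERGENIC_GAP
        island_spans: dict[int, list[int]] = {}
        prev_island_fam = False
        for order_idx, (f, gene_len) in enumerate(layout):
            is_island = f in island_members
            gap = ISLAND_GAP if (is_island and prev_island_fam) else INTERGENIC_GAP
            if order_idx > 0:
                pos += gap
            start, end = pos, pos + gene_len
            pos = end
            gene_id = f"{gid}_{order_idx + 1:05d}"
            prot = _codes_to_str(
                _mutate_codes(prototypes[f], spec.within_family_rate, rng, 20), _AA
            )
            genes.append(GeneRecord(gene_id, gid, contig_id, start, end, "+", prot))
            proteins[gene_id] = prot
            family_truth[gene_id] = f
            if is_island:
                isl = int(f[2:4])
                island_spans.setdefault(isl, []).extend([start, end])
            prev_island_fam = is_island
        rgp_truth[gid] = [
            (contig_id, min(v), max(v)) for isl, v in sorted(island_spans.items())
        ]
        contig_len = pos + INTERGENIC_GAP
        genomes.append(
            GenomeRecord(gid, [Contig(contig_id, random_dna(contig_len, rng))])
        )
    quality = [QualityRecord(g.genome_id, 100.0, 0.0) for g in genomes]
    return SimulatedPangenome(
        spec=spec,
        genomes=genomes,
        genes=genes,
        proteins=proteins,
        family_truth=family_truth,
        partition_truth=partition_truth,
        rgp_truth=rgp_truth,
        quality=quality,
    )


# ---------------------------------------------------------------------------
# fixture directories
# ---------------------------------------------------------------------------


def write_fixture_dir(sim: SimulatedPangenome, outdir: str | Path) -> None:
    """Write a simulated pangenome as FASTA + GFF3 + TSV truth tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_genome: dict[str, list[GeneRecord]] = {}
    for g in sim.genes:
        by_genome.setdefault(g.genome_id, []).append(g)
    for genome in sim.genomes:
        write_genome_fasta(genome, outdir / f"{genome.genome_id}.fna")
        write_gff3_genes(by_genome.get(genome.genome_id, []), outdir / f"{genome.genome_id}.gff3")
    write_protein_fasta(sim.proteins, outdir / "proteins.faa")
    write_quality_table(sim.quality, outdir / "quality.tsv")
    write_tsv(
        pd.DataFrame(
            sorted((g, f) for g, f in sim.family_truth.items()),
            columns=["gene_id", "family_id"],
        ),
        outdir / "truth_families.tsv",
    )
    write_tsv(
        pd.DataFrame(
            sorted(sim.partition_truth.items()), columns=["family_id", "partition"]
        ),
        outdir / "truth_partitions.tsv",
    )
    write_tsv(
        pd.DataFrame(
            [
                (genome, contig, start, end)
                for genome, spans in sorted(sim.rgp_truth.items())
                for contig, start, end in spans
            ],
            columns=["genome_id", "contig_id", "start", "end"],
        ),
        outdir / "truth_rgps.tsv",
    )
    write_tsv(
        pd.DataFrame(
            sorted((g.gene_id, g.genome_id, g.contig_id, g.start, g.end, g.strand) for g in sim.genes),
            columns=["gene_id", "genome_id", "contig_id", "start", "end", "strand"],
        ),
        outdir / "genes.tsv",
    )
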