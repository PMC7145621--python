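"""Bottom-s MinHash sketching of genomes and Mash-style distances.

A genome is reduced to the ``s`` smallest 64-bit hash values over its
canonical k-mers (the lexicographic minimum of each k-mer and its reverse
complement; windows containing ``N`` are skipped).  The Jaccard index of two
k-mer sets is estimated from the merged bottom-s sketch, and converted to a
genomic distance with

    d = -(1/k) * ln(2j / (1 + j)),

which approximates the per-base divergence of the two genomes under a
Poisson model of random substitution.  ``j = 0`` is mapped to ``d = 1`` by
convention and ``d`` is clamped to ``[0, 1]``.

Hashing is a seedable splitmix64 finalizer applied to the 2-bit packed
canonical k-mer, computed vectorized over whole contigs.  The contract is
determinism given ``(k, s, hash_seed)``; bit-compatibility with other
MinHash implementations is not promised.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from panplast.io import GenomeRecord

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# base -> 2-bit code, everything else (incl. N) -> -1
_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass(frozen=True)
class SketchParams:
    """k-mer length, sketch size and hash seed of a MinHash sketch."""

    k: int = 18
    s: int = 5000
    hash_seed: int = 42

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.k > 31:
            raise ValueError("k > 31 does not fit the 2-bit packing")
        if self.s < 1:
            raise ValueError("sketch size must be >= 1")


@dataclass
class Sketch:
    """Bottom-s MinHash sketch of one genome."""

    genome_id: str
    params: SketchParams
    hashes: np.ndarray  # uint64, strictly increasing, length <= s
    total_kmers: int  # distinct canonical k-mers seen

    def __post_init__(self) -> None:
        self.hashes = np.asarray(self.hashes, dtype=np.uint64)
        if self.hashes.size and np.any(np.diff(self.hashes.astype(np.uint64)) <= 0):
            raise ValueError("sketch hashes must be strictly increasing")
        if self.hashes.size > self.params.s:
            raise ValueError("sketch larger than s")


@dataclass(frozen=True)
class DistanceEntry:
    a: str
    b: str
    shared: int
    j: float
    d: float


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with a zero diagonal."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T) or np.any(
            np.diag(self.values) != 0
        ):
            raise ValueError("matrix must be symmetric with zero diagonal")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.index.name = "genome_id"
        df.to_csv(path, sep="\t")

    def to_phylip(self) -> str:
        lines = [str(len(self.ids))]
        for i, name in enumerate(self.ids):
            row = " ".join(f"{v:.6f}" for v in self.values[i])
            lines.append(f"{name} {row}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# k-mer extraction
# ---------------------------------------------------------------------------


def canonical_kmers(sequence: str, k: int) -> Iterator[str]:
    """Yield the canonical k-mer of every valid window of ``sequence``.

    The canonical form is the lexicographic minimum of the k-mer and its
    reverse complement.  Windows containing a character outside ACGT are
    skipped; sequences shorter than k yield nothing.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(sequence)
    for i in range(n - k + 1):
        kmer = sequence[i : i + k]
        if any(c not in "ACGT" for c in kmer):
            continue
        rc = kmer.translate(_COMPLEMENT)[::-1]
        yield min(kmer, rc)


def _canonical_codes(sequence: str, k: int) -> np.ndarray:
    """2-bit packed canonical k-mer codes of all valid windows (vectorized).

    Packing is big-endian in the sequence (first base most significant), so
    numeric order of codes equals lexicographic order of k-mer strings.
    """
    codes = _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    n = codes.size
    if n < k:
        return np.empty(0, dtype=np.uint64)
    m = n - k + 1
    bad = (codes < 0).astype(np.int32)
    cs = np.concatenate(([0], np.cumsum(bad)))
    valid = (cs[k:] - cs[:-k]) == 0
    c64 = codes.astype(np.int64).clip(min=0).astype(np.uint64)
    fwd = np.zeros(m, dtype=np.uint64)
    rev = np.zeros(m, dtype=np.uint64)
    for i in range(k):
        fwd = (fwd << np.uint64(2)) | c64[i : m + i]
        rev |= (np.uint64(3) - c64[i : m + i]) << np.uint64(2 * i)
    return np.minimum(fwd, rev)[valid]


def _splitmix64(x: np.ndarray, seed: int) -> np.ndarray:
    """Seedable splitmix64 finalizer over a uint64 array."""
    z = x ^ np.uint64(seed * 0x9E3779B97F4A7C15 % (1 << 64))
    z = (z + np.uint64(0x9E3779B97F4A7C15)).astype(np.uint64)
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


def build_sketch(genome: GenomeRecord, params: SketchParams) -> Sketch:
    """Sketch a genome: the s smallest distinct hashes of its canonical k-mers.

    All contigs contribute to one k-mer pool (the union over replicons).
    Circular contigs are sketched linearly: the at most k-1 wrap-around
    k-mers are ignored.
    """
    if not genome.contigs:
        raise ValueError(f"genome {genome.genome_id!r} has no contigs")
    parts = [_canonical_codes(c.sequence, params.k) for c in genome.contigs]
    codes = np.unique(np.concatenate(parts)) if parts else np.empty(0, np.uint64)
    if codes.size == 0:
        logger.warning(
            "genome %s: no k-mer survives N-masking; empty sketch", genome.genome_id
        )
        return Sketch(genome.genome_id, params, np.empty(0, np.uint64), 0)
    hashes = np.unique(_splitmix64(codes, params.hash_seed))
    return Sketch(genome.genome_id, params, hashes[: params.s], int(codes.size))


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def jaccard_estimate(x: Sketch, y: Sketch) -> tuple[int, float]:
    """Merged bottom-s Jaccard estimate between two sketches.

    The s smallest hashes of the union of the two sketches are formed; the
    estimate is the fraction of those present in both sketches.  Exact when
    s is at least the size of the union of the two k-mer sets.
    """
    if x.params != y.params:
        raise ValueError("sketches built with different parameters")
    if x.hashes.size == 0 and y.hashes.size == 0:
        raise ValueError("Jaccard undefined: both sketches are empty")
    merged = np.union1d(x.hashes, y.hashes)[: x.params.s]
    shared = int(np.sum(np.isin(merged, x.hashes) & np.isin(merged, y.hashes)))
    return shared, shared / merged.size


def mash_distance(j: float, k: int) -> float:
    """Convert a Jaccard estimate to a per-base divergence estimate."""
    if not (0 <= j <= 1):
        raise ValueError(f"Jaccard estimate {j} outside [0, 1]")
    if j == 0:
        return 1.0
    d = -(1.0 / k) * np.log(2.0 * j / (1.0 + j))
    return float(min(max(d, 0.0), 1.0))


def mash_pair(x: Sketch, y: Sketch) -> DistanceEntry:
    shared, j = jaccard_estimate(x, y)
    return DistanceEntry(x.genome_id, y.genome_id, shared, j, mash_distance(j, x.params.k))


def distance_matrix(sketches: Sequence[Sketch]) -> DistanceMatrix:
    """All-pairs Mash distances between sketches (symmetric, zero diagonal)."""
    if len(sketches) < 2:
        raise ValueError("need at least two sketches")
    ids = [s.genome_id for s in sketches]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate genome_id among sketches")
    n = len(sketches)
    mat = np.zeros((n, n))
    for i in range(n):
        for j_ in range(i + 1, n):
            d = mash_pair(sketches[i], sketches[j_]).d
            mat[i, j_] = mat[j_, i] = d
    return DistanceMatrix(ids, mat)


def exact_jaccard(genome_a: GenomeRecord, genome_b: GenomeRecord, k: int) -> float:
    """Exact Jaccard index of the full canonical k-mer sets of two genomes."""
    a = np.unique(np.concatenate([_canonical_codes(c.sequence, k) for c in genome_a.contigs]))
    b = np.unique(np.concatenate([_canonical_codes(c.sequence, k) for c in genome_b.contigs]))
    if a.size == 0 and b.size == 0:
        raise ValueError("both k-mer sets empty")
    inter = np.intersect1d(a, b).size
    return inter / (a.size + b.size - inter)


# ---------------------------------------------------------------------------
# sketch files (JSON lines)
# ---------------------------------------------------------------------------


def save_sketches(sketches: Iterable[Sketch], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sk in sketches:
            fh.write(
                json.dumps(
                    {
                        "genome_id": sk.genome_id,
                        "k": sk.params.k,
                        "s": sk.params.s,
                        "seed": sk.params.hash_seed,
                        "total_kmers": sk.total_kmers,
                        "hashes": [int(h) for h in sk.hashes],
                    }
                )
                + "\n"
            )


def load_sketches(path: str | Path) -> list[Sketch]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            out.append(
                Sketch(
                    rec["genome_id"],
                    SketchParams(rec["k"], rec["s"], rec["seed"]),
                    np.array(rec["hashes"], dtype=np.uint64),
                    rec["total_kmers"],
                )
            )
    return out
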