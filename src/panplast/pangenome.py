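"""Partitioned pangenome graphs.

For a species cluster with at least ``min_genomes`` genomes (15 by default),
the pangenome is represented as a graph whose nodes are gene families and
whose edges carry genomic neighborhood information: w_ij is the number of
genomes in which genes of families i and j are immediate neighbors on a
contig.

Families are partitioned into persistent / shell / cloud by fitting a
K = 3 multivariate Bernoulli mixture on the binary family-by-genome
presence/absence matrix, smoothed by a Markov random field over the
neighborhood graph.  Inference is mean-field EM: the E-step multiplies each
family's mixture posterior by exp(beta * sum_j (w_ij / N) * r_jk), i.e.
neighboring families pull each other toward the same partition with
strength proportional to how often they are adjacent; the M-step is the
standard Bernoulli mixture update with epsilon clamped away from {0, 1}.
With beta = 0 this reduces exactly to EM on the plain mixture, whose
log-likelihood is non-decreasing per iteration - a testable limit.

Components are relabeled after fitting so that "persistent" is always the
component with the highest mean presence probability, then "shell", then
"cloud".  The exact (strict) core/variable split - families present in
every genome versus the rest - is computed separately and independently of
the model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import logsumexp

from panplast.io import GeneRecord

logger = logging.getLogger(__name__)

PARTITION_NAMES = ("persistent", "shell", "cloud")


@dataclass(frozen=True)
class PangenomeParams:
    """Partitioning parameters: cohort size rule, MRF coupling, EM controls."""

    min_genomes: int = 15
    K: int = 3
    beta: float = 0.5
    max_iter: int = 500
    tol: float = 1e-6
    eps_floor: float = 1e-3
    seed: int = 0
    random_init: bool = False

    def __post_init__(self) -> None:
        if self.min_genomes < 2:
            raise ValueError("min_genomes must be >= 2")
        if self.K != 3:
            raise ValueError("the partitioner is defined for K = 3")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


@dataclass
class PresenceAbsenceMatrix:
    """Binary family-by-genome occupancy: x[i, g] = 1 iff family i occurs in genome g."""

    families: list[str]
    genomes: list[str]
    x: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.uint8)
        if self.x.shape != (len(self.families), len(self.genomes)):
            raise ValueError("matrix shape mismatch")
        if not np.isin(self.x, (0, 1)).all():
            raise ValueError("matrix must be binary")
        if self.x.shape[0] and (self.x.sum(axis=1) == 0).any():
            raise ValueError("a family absent from every genome is not allowed")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.x, index=self.families, columns=self.genomes)


@dataclass
class PartitionModel:
    """Fitted Bernoulli-mixture/MRF parameters and the induced partition labels."""

    pi: np.ndarray  # (K,)
    eps: np.ndarray  # (K, N) presence probabilities per partition and genome
    responsibilities: np.ndarray  # (M, K), rows sum to 1
    labels: dict[str, str]  # family -> partition name
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False


def presence_absence(
    family_of: Mapping[str, str],
    genome_of: Mapping[str, str],
    min_genomes: int = 15,
    allow_fewer: bool = False,
) -> PresenceAbsenceMatrix:
    """Binarized family-by-genome matrix from a gene->family assignment.

    Paralogs collapse: two or more genes of one family in a genome still
    yield a single 1.  Refuses to build a pangenome from fewer than
    ``min_genomes`` genomes unless ``allow_fewer`` (the override is logged).
    """
    missing = [g for g in family_of if g not in genome_of]
    if missing:
        raise KeyError(f"genes without genome assignment: {missing[:5]}")
    genomes = sorted(set(genome_of[g] for g in family_of))
    if len(genomes) < min_genomes:
        if not allow_fewer:
            raise ValueError(
                f"{len(genomes)} genomes < required minimum of {min_genomes}; "
                "a pangenome needs at least that many genomes to be meaningful "
                "(pass allow_fewer=True to override)"
            )
        logger.warning(
            "building pangenome from only %d genomes (minimum %d overridden)",
            len(genomes),
            min_genomes,
        )
    families = sorted(set(family_of.values()))
    fidx = {f: i for i, f in enumerate(families)}
    gidx = {g: i for i, g in enumerate(genomes)}
    x = np.zeros((len(families), len(genomes)), dtype=np.uint8)
    for gene, fam in family_of.items():
        x[fidx[fam], gidx[genome_of[gene]]] = 1
    return PresenceAbsenceMatrix(families, genomes, x)


def build_pangenome_graph(
    gene_records: Iterable[GeneRecord],
    family_of: Mapping[str, str],
    circular_contigs: frozenset[tuple[str, str]] | set[tuple[str, str]] = frozenset(),
) -> nx.Graph:
    """Family-adjacency graph: edge weight = number of genomes where the two
    families have immediately neighboring genes.

    Genes are ordered by start coordinate per contig (ties by gene id); on a
    circular contig the last gene is also adjacent to the first.  Each genome
    contributes at most 1 to any edge weight, and tandem copies of one family
    produce no self-loop.
    """
    by_contig: dict[tuple[str, str], list[GeneRecord]] = {}
    for g in gene_records:
        if g.gene_id not in family_of:
            raise KeyError(f"gene {g.gene_id!r} has no family assignment")
        by_contig.setdefault((g.genome_id, g.contig_id), []).append(g)

    graph = nx.Graph()
    counts: dict[str, int] = {}
    per_genome_edges: dict[str, set[tuple[str, str]]] = {}
    for (genome_id, contig_id), genes in by_contig.items():
        genes.sort(key=lambda g: (g.start, g.gene_id))
        fams = [family_of[g.gene_id] for g in genes]
        for f in fams:
            counts[f] = counts.get(f, 0) + 1
        pairs = list(zip(fams, fams[1:]))
        if (genome_id, contig_id) in circular_contigs and len(fams) > 2:
            pairs.append((fams[-1], fams[0]))
        edges = per_genome_edges.setdefault(genome_id, set())
        for fa, fb in pairs:
            if fa == fb:
                continue  # tandem duplicates carry no neighborhood signal
            edges.add((min(fa, fb), max(fa, fb)))
    for fam, n in counts.items():
        graph.add_node(fam, n_genes=n)
    weights: dict[tuple[str, str], int] = {}
    for edges in per_genome_edges.values():
        for e in edges:
            weights[e] = weights.get(e, 0) + 1
    for (fa, fb), w in weights.items():
        graph.add_edge(fa, fb, weight=w)
    return graph


def strict_components(pa: PresenceAbsenceMatrix) -> tuple[set[str], set[str]]:
    """Exact core/variable split: core families occur in every genome."""
    full = pa.x.sum(axis=1) == len(pa.genomes)
    core = {f for f, is_core in zip(pa.families, full) if is_core}
    return core, set(pa.families) - core


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------


def _initial_eps(params: PangenomeParams, n_genomes: int) -> np.ndarray:
    if params.random_init:
        rng = np.random.default_rng(params.seed)
        eps = rng.uniform(0.05, 0.95, size=(params.K, n_genomes))
        return eps[np.argsort(-eps.mean(axis=1))]
    levels = np.array([0.9, 0.5, 0.1])
    return np.repeat(levels[:, None], n_genomes, axis=1)


def partition_em(
    pa: PresenceAbsenceMatrix,
    graph: nx.Graph | None,
    params: PangenomeParams = PangenomeParams(),
) -> PartitionModel:
    """Fit the smoothed Bernoulli mixture and label families.

    The objective trace records, per iteration, the mixture log-likelihood
    plus the MRF smoothness bonus beta * sum_ij (w_ij / N) <r_i, r_j>; with
    beta = 0 the trace is the plain log-likelihood.  Iteration stops when the
    largest responsibility change falls below ``tol`` or after ``max_iter``
    rounds.  An empty (or absent) graph reduces the model to an ordinary
    Bernoulli mixture.
    """
    M, N = pa.x.shape
    if M == 0:
        raise ValueError("empty presence/absence matrix")
    K = params.K
    X = pa.x.astype(float)

    # sparse neighbor weights, pre-scaled by beta / N
    rows, cols, vals = [], [], []
    if graph is not None and graph.number_of_edges() > 0:
        fidx = {f: i for i, f in enumerate(pa.families)}
        unknown = [f for f in graph.nodes if f not in fidx]
        if unknown:
            raise KeyError(f"graph families absent from matrix: {unknown[:5]}")
        for fa, fb, data in graph.edges(data=True):
            w = float(data.get("weight", 1.0)) * params.beta / N
            ia, ib = fidx[fa], fidx[fb]
            rows += [ia, ib]
            cols += [ib, ia]
            vals += [w, w]
    from scipy.sparse import coo_matrix

    W = coo_matrix((vals, (rows, cols)), shape=(M, M)).tocsr()

    eps = _initial_eps(params, N)
    pi = np.full(K, 1.0 / K)
    r = np.full((M, K), 1.0 / K)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, params.max_iter + 1):
        # E-step (mean field: neighbor term uses current responsibilities)
        log_eps = np.log(eps)
        log_1m = np.log1p(-eps)
        logB = X @ log_eps.T + (1.0 - X) @ log_1m.T  # (M, K)
        field_term = W @ r if W.nnz else 0.0
        logr = np.log(pi)[None, :] + logB + field_term
        norm = logsumexp(logr, axis=1, keepdims=True)
        r_new = np.exp(logr - norm)

        # penalized objective: mixture log-lik + smoothness bonus
        loglik = float(logsumexp(np.log(pi)[None, :] + logB, axis=1).sum())
        bonus = float((r_new * (W @ r_new)).sum()) / 2.0 if W.nnz else 0.0
        objective = loglik + bonus
        if not np.isfinite(objective):
            raise FloatingPointError(f"non-finite objective at iteration {it}")
        trace.append(objective)

        delta = float(np.max(np.abs(r_new - r)))
        r = r_new

        # M-step
        nk = r.sum(axis=0)
        pi = np.clip(nk / M, 1e-12, None)
        pi = pi / pi.sum()
        eps = (r.T @ X) / np.clip(nk[:, None], 1e-12, None)
        eps = np.clip(eps, params.eps_floor, 1.0 - params.eps_floor)

        if delta < params.tol:
            converged = True
            break

    # canonical order: persistent = highest mean presence probability
    order = np.argsort(-eps.mean(axis=1), kind="stable")
    pi, eps, r = pi[order], eps[order], r[:, order]
    # argmax takes the first maximum, i.e. ties resolve toward the
    # higher-mean-eps component thanks to the canonical ordering
    hard = np.argmax(r, axis=1)
    labels = {f: PARTITION_NAMES[k] for f, k in zip(pa.families, hard)}
    return PartitionModel(
        pi=pi,
        eps=eps,
        responsibilities=r,
        labels=labels,
        objective_trace=trace,
        n_iter=it,
        converged=converged,
    )


def pangenome_summary(
    model: PartitionModel,
    pa: PresenceAbsenceMatrix,
    family_sizes: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-partition family and gene counts.

    ``family_sizes`` maps family -> total gene count (paralogs included);
    when omitted, the number of genomes containing the family is used as the
    gene count (i.e. one gene per occurrence).
    """
    presence = dict(zip(pa.families, pa.x.sum(axis=1)))
    rows = []
    for name in PARTITION_NAMES:
        fams = [f for f in pa.families if model.labels[f] == name]
        n_genes = sum(
            (family_sizes[f] if family_sizes is not None else int(presence[f]))
            for f in fams
        )
        rows.append({"partition": name, "n_families": len(fams), "n_genes": n_genes})
    return pd.DataFrame(rows)
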