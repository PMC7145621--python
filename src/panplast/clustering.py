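"""Species delineation from genome distances.

Genomes passing a quality filter (completion >= 90%, contamination <= 5% by
default; boundary values are kept, only strictly worse genomes are removed)
become nodes of a similarity graph: an edge joins two genomes iff their
Mash distance d is <= 0.06 (the ~94% average-nucleotide-identity species
boundary), weighted by 1 - d.  Louvain community detection on this graph
yields species clusters, labeled ``SC1, SC2, ...`` by decreasing size.
Neighbor-joining trees summarize the structure within a selection of
genomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from panplast.io import GenomeRecord, QualityRecord, TreeNode
from panplast.sketch import DistanceMatrix


@dataclass(frozen=True)
class ClusteringParams:
    """Distance threshold and quality-filter thresholds for species clustering."""

    max_dist: float = 0.06
    min_completion: float = 90.0
    max_contamination: float = 5.0

    def __post_init__(self) -> None:
        if not (0 < self.max_dist < 1):
            raise ValueError("max_dist must be in (0, 1)")


def quality_filter(
    genome_ids: Iterable[str | GenomeRecord],
    quality_records: Iterable[QualityRecord],
    params: ClusteringParams = ClusteringParams(),
) -> list[str]:
    """Keep genomes with completion >= min_completion and contamination <= max_contamination.

    The removal rule is strict (contamination > threshold or completion <
    threshold removes a genome), so genomes sitting exactly on a boundary
    survive.  A genome without a quality record is an error, never silently
    kept or dropped.
    """
    quality = {q.genome_id: q for q in quality_records}
    kept = []
    for g in genome_ids:
        gid = g.genome_id if isinstance(g, GenomeRecord) else g
        q = quality.get(gid)
        if q is None:
            raise KeyError(f"no quality record for genome {gid!r}")
        if q.contamination > params.max_contamination or q.completion < params.min_completion:
            continue
        kept.append(gid)
    return kept


def build_species_graph(
    dist: DistanceMatrix,
    kept_ids: Sequence[str],
    params: ClusteringParams = ClusteringParams(),
) -> nx.Graph:
    """Build the thresholded similarity graph over quality-filtered genomes.

    Edge (a, b) exists iff d(a, b) <= max_dist, with weight 1 - d (an
    ANI-like similarity); pairs above the threshold are simply absent.
    """
    missing = set(kept_ids) - set(dist.ids)
    if missing:
        raise KeyError(f"genomes not in distance matrix: {sorted(missing)}")
    graph = nx.Graph()
    graph.add_nodes_from(kept_ids)
    idx = {g: i for i, g in enumerate(dist.ids)}
    ids = list(kept_ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            d = dist.values[idx[a], idx[b]]
            if d <= params.max_dist:
                graph.add_edge(a, b, weight=1.0 - d)
    return graph


def louvain_partition(graph: nx.Graph, seed: int = 0) -> dict[str, str]:
    """Louvain community detection; deterministic for a fixed seed.

    Communities are relabeled canonically (decreasing size, ties by the
    lexicographically smallest member) as ``SC1, SC2, ...``, so labels are
    stable under permutation of the input genomes.  Isolated genomes form
    singleton clusters.
    """
    if graph.number_of_nodes() == 0:
        return {}
    communities = nx.community.louvain_communities(
        graph, weight="weight", resolution=1.0, seed=seed
    )
    ordered = sorted(communities, key=lambda c: (-len(c), min(str(m) for m in c)))
    return {
        member: f"SC{rank}"
        for rank, comm in enumerate(ordered, start=1)
        for member in comm
    }


def partition_modularity(graph: nx.Graph, assignment: Mapping[str, str]) -> float:
    """Weighted modularity of a cluster assignment (resolution 1)."""
    groups: dict[str, set] = {}
    for node, label in assignment.items():
        groups.setdefault(label, set()).add(node)
    return nx.community.modularity(graph, list(groups.values()), weight="weight")


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------


def nj_tree(dist: DistanceMatrix, ids: Sequence[str] | None = None) -> TreeNode:
    """Classical Saitou-Nei neighbor joining on a distance matrix.

    Exact on additive matrices (the tree's path-length matrix reproduces the
    input).  A negative branch length is clamped to zero and its deficit is
    moved onto the sibling branch, preserving the pair's summed length.
    Returns an unrooted tree (trifurcating root for >= 3 taxa).
    """
    if ids is None:
        ids = dist.ids
    if len(ids) < 2:
        raise ValueError("neighbor joining needs at least 2 taxa")
    index = {g: i for i, g in enumerate(dist.ids)}
    sel = [index[g] for g in ids]
    D = dist.values[np.ix_(sel, sel)].astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=g) for g in ids]

    if len(nodes) == 2:
        half = D[0, 1] / 2.0
        nodes[0].length = half
        nodes[1].length = half
        return TreeNode(children=nodes)

    def clamp_pair(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        Q = (n - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        i, j = np.unravel_index(int(np.argmin(Q)), Q.shape)  # first min: deterministic
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (n - 2))
        lj = D[i, j] - li
        li, lj = clamp_pair(li, lj)
        a, b = nodes[i], nodes[j]
        a.length, b.length = li, lj
        new = TreeNode(children=[a, b])
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [x for x in range(n) if x not in (i, j)]
        D2 = np.zeros((n - 1, n - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D = D2
        nodes = [nodes[x] for x in keep] + [new]

    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    lengths = [
        0.5 * (d01 + d02 - d12),
        0.5 * (d01 + d12 - d02),
        0.5 * (d02 + d12 - d01),
    ]
    for node, ln in zip(nodes, lengths):
        node.length = max(ln, 0.0)
    return TreeNode(children=nodes)
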