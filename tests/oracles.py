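"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by exhaustive/naive means so they stay
independent of the code paths they check.
"""

from __future__ import annotations

import itertools
from fractions import Fraction

import networkx as nx
from Bio.Align import substitution_matrices

_BLOSUM62 = substitution_matrices.load("BLOSUM62")

GAP_OPEN = 11  # cost of a gap's first residue
GAP_EXTEND = 1  # cost of each further residue

NEG = float("-inf")


def gotoh_local_optima(a: str, b: str, max_paths: int = 100_000):
    """All co-optimal Smith-Waterman local alignments under affine gaps.

    A gap of length L costs GAP_OPEN + (L - 1) * GAP_EXTEND.  Returns
    (best score, set of (identity, coverage_a, coverage_b) over co-optimal
    alignments), with identity = matches / aligned columns (gap columns in
    the denominator) and coverage = aligned span / sequence length, both as
    Fractions for exact comparison.
    """
    n, m = len(a), len(b)
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            M[i][j] = max(
                0.0, max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s
            )
            Ix[i][j] = max(M[i - 1][j] - GAP_OPEN, Ix[i - 1][j] - GAP_EXTEND)
            Iy[i][j] = max(M[i][j - 1] - GAP_OPEN, Iy[i][j - 1] - GAP_EXTEND)
    best = max(M[i][j] for i in range(n + 1) for j in range(m + 1))
    if best <= 0:
        return 0.0, set()

    stats = set()
    paths = 0

    def walk(i, j, state, cols, idents, ei, ej):
        # walks backwards; (ei, ej) is the (exclusive) end of the alignment
        nonlocal paths
        if paths > max_paths:
            return
        if state == "M":
            val = M[i][j]
            s = _BLOSUM62[a[i - 1], b[j - 1]]
            prevs = []
            for st, mat in (("M", M), ("X", Ix), ("Y", Iy)):
                if mat[i - 1][j - 1] + s == val:
                    prevs.append(st)
            started = (
                max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]) + s <= 0
                and val == max(0.0, s)
            )
            new_cols = cols + 1
            new_idents = idents + (1 if a[i - 1] == b[j - 1] else 0)
            if val == s:  # local start here is co-optimal
                paths += 1
                stats.add(
                    (
                        Fraction(new_idents, new_cols),
                        Fraction(ei - (i - 1), n),
                        Fraction(ej - (j - 1), m),
                    )
                )
            for st in prevs:
                if st == "M" and M[i - 1][j - 1] <= 0 and val == s:
                    continue  # already counted as a start
                walk(i - 1, j - 1, st, new_cols, new_idents, ei, ej)
        elif state == "X":
            val = Ix[i][j]
            if M[i - 1][j] - GAP_OPEN == val:
                walk(i - 1, j, "M", cols + 1, idents, ei, ej)
            if Ix[i - 1][j] - GAP_EXTEND == val:
                walk(i - 1, j, "X", cols + 1, idents, ei, ej)
        else:
            val = Iy[i][j]
            if M[i][j - 1] - GAP_OPEN == val:
                walk(i, j - 1, "M", cols + 1, idents, ei, ej)
            if Iy[i][j - 1] - GAP_EXTEND == val:
                walk(i, j - 1, "Y", cols + 1, idents, ei, ej)

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            if M[i][j] == best:
                walk(i, j, "M", 0, 0, i, j)
    return best, stats


def exhaustive_rgp_windows(genes, scoring):
    """Greedy exhaustive reference for the RGP scan on one contig.

    Repeatedly selects the maximal-scoring contiguous gene window with
    non-persistent ends (ties: smallest end, then largest start, i.e. the
    shortest window ending first - a window never reaches back across a
    zero-crossing of the running score), removes its genes, and recurses on
    the flanks; selected windows are reported only if they meet the score
    and span rules.  Genes are (start, end, label) triples sorted by start.
    """
    scores = [scoring.gene_score(g[2]) for g in genes]

    def best_window(lo, hi):
        best = None
        for i in range(lo, hi):
            if genes[i][2] == "persistent":
                continue
            total = 0
            for j in range(i, hi):
                total += scores[j]
                if genes[j][2] == "persistent":
                    continue
                if (
                    best is None
                    or total > best[0]
                    or (total == best[0] and (j, -i) < (best[2], -best[1]))
                ):
                    best = (total, i, j)
        return best

    out = []

    def recurse(lo, hi):
        if lo >= hi:
            return
        win = best_window(lo, hi)
        if win is None or win[0] <= 0:
            return
        total, i, j = win
        span = genes[j][1] - genes[i][0]
        if total >= scoring.min_score and span > scoring.min_length:
            out.append((i, j, total))
        recurse(lo, i)
        recurse(j + 1, hi)

    recurse(0, len(genes))
    return sorted(out)


def exhaustive_best_modularity(graph: nx.Graph):
    """Maximum-modularity partition by enumerating all set partitions."""
    from sympy.utilities.iterables import multiset_partitions

    nodes = list(graph.nodes)
    best_q, best_p = NEG, None
    for parts in multiset_partitions(nodes):
        q = nx.community.modularity(graph, [set(p) for p in parts], weight="weight")
        if q > best_q:
            best_q, best_p = q, parts
    return best_q, [set(p) for p in best_p]


def exact_jaccard_strings(a: str, b: str, k: int) -> Fraction:
    """Exact Jaccard of full canonical k-mer sets, by direct string enumeration."""
    comp = str.maketrans("ACGT", "TGCA")

    def kmers(s):
        out = set()
        for i in range(len(s) - k + 1):
            w = s[i : i + k]
            if set(w) <= set("ACGT"):
                out.add(min(w, w.translate(comp)[::-1]))
        return out

    A, B = kmers(a), kmers(b)
    return Fraction(len(A & B), len(A | B))
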