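"""Independent oracles used by the test suite.

Everything here is implemented from first principles (plain-Python dynamic
programming, exhaustive enumeration, least-squares topology search) and
deliberately shares no code with the package paths it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def score_pair(x: str, y: str) -> float:
    if "X" in (x, y):
        return 0.0
    return float(_B62[x, y])


# ---------------------------------------------------------------------------
# Gotoh DP oracles (gap of length L costs open + L * extend)
# ---------------------------------------------------------------------------


def gotoh_global(a: str, b: str, open_: float, ext: float) -> float:
    n, m = len(a), len(b)
    NEG = -math.inf
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = -(open_ + i * ext)
    for j in range(1, m + 1):
        Iy[0][j] = -(open_ + j * ext)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = score_pair(a[i - 1], b[j - 1])
            M[i][j] = s + max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
            Ix[i][j] = max(M[i - 1][j] - (open_ + ext), Ix[i - 1][j] - ext)
            Iy[i][j] = max(M[i][j - 1] - (open_ + ext), Iy[i][j - 1] - ext)
    return max(M[n][m], Ix[n][m], Iy[n][m])


def gotoh_local(a: str, b: str, open_: float, ext: float) -> float:
    n, m = len(a), len(b)
    NEG = -math.inf
    best = 0.0
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iy = [[NEG] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = score_pair(a[i - 1], b[j - 1])
            M[i][j] = max(
                0.0,
                s + max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]),
            )
            Ix[i][j] = max(M[i - 1][j] - (open_ + ext), Ix[i - 1][j] - ext)
            Iy[i][j] = max(M[i][j - 1] - (open_ + ext), Iy[i][j - 1] - ext)
            best = max(best, M[i][j])
    return best


def enumerate_global_alignments(a: str, b: str):
    """Every global alignment of a and b as (row_a, row_b) gapped strings."""

    def rec(i, j):
        if i == len(a) and j == len(b):
            yield "", ""
            return
        if i < len(a) and j < len(b):
            for ra, rb in rec(i + 1, j + 1):
                yield a[i] + ra, b[j] + rb
        if i < len(a):
            for ra, rb in rec(i + 1, j):
                yield a[i] + ra, "-" + rb
        if j < len(b):
            for ra, rb in rec(i, j + 1):
                yield "-" + ra, b[j] + rb

    yield from rec(0, 0)


def score_alignment(row_a: str, row_b: str, open_: float, ext: float) -> float:
    """Affine-gap score of an explicit alignment (no gap-gap columns)."""
    total = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(row_a, row_b):
        if x == "-":
            total -= ext + (0.0 if in_gap_a else open_)
            in_gap_a, in_gap_b = True, False
        elif y == "-":
            total -= ext + (0.0 if in_gap_b else open_)
            in_gap_b, in_gap_a = True, False
        else:
            total += score_pair(x, y)
            in_gap_a = in_gap_b = False
    return total


# ---------------------------------------------------------------------------
# Random additive trees and the exhaustive least-squares topology oracle
# ---------------------------------------------------------------------------


def random_additive_tree(n_taxa: int, rng: np.random.Generator):
    """Random unrooted binary tree; returns (edges, lengths, leaf names).

    Built by sequential insertion of each new leaf into a random edge.
    Node ids: leaves are "L0".."L{n-1}", internal nodes "N*".
    """
    counter = itertools.count()
    edges = []

    def new_internal():
        return f"N{next(counter)}"

    c = new_internal()
    for k in range(3):
        edges.append([c, f"L{k}"])
    for k in range(3, n_taxa):
        e = edges[int(rng.integers(len(edges)))]
        u, v = e
        w = new_internal()
        edges.remove(e)
        edges.extend([[u, w], [w, v], [w, f"L{k}"]])
    lengths = {tuple(e): float(rng.uniform(0.05, 0.5)) for e in map(tuple, edges)}
    leaves = [f"L{k}" for k in range(n_taxa)]
    return [tuple(e) for e in edges], lengths, leaves


def _adjacency(edges):
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    return adj


def path_edges(edges, src, dst):
    adj = _adjacency(edges)
    stack = [(src, None, [])]
    while stack:
        node, prev, path = stack.pop()
        if node == dst:
            return path
        for nb in adj[node]:
            if nb != prev:
                e = (node, nb) if (node, nb) in set(edges) else (nb, node)
                stack.append((nb, node, path + [e]))
    raise ValueError("no path")


def tree_distances(edges, lengths, leaves) -> np.ndarray:
    n = len(leaves)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = sum(
                lengths[e] for e in path_edges(edges, leaves[i], leaves[j])
            )
    return d


def tree_splits(edges, leaves) -> set[frozenset]:
    """Non-trivial splits, normalized to the side without the first leaf."""
    leafset = frozenset(leaves)
    anchor = sorted(leaves)[0]
    adj = _adjacency(edges)
    out = set()
    for u, v in edges:
        # leaves on v's side when edge (u, v) removed
        seen, stack = {u, v}, [v]
        side = set()
        while stack:
            node = stack.pop()
            if node in leafset:
                side.add(node)
            for nb in adj[node]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        fs = frozenset(side)
        if 2 <= len(fs) <= len(leafset) - 2:
            out.add(leafset - fs if anchor in fs else fs)
    return out


def enumerate_topologies(leaves):
    """All unrooted binary topologies over the leaves (15 for 5 taxa)."""
    counter = itertools.count()

    def rec(current_edges, remaining):
        if not remaining:
            yield list(current_edges)
            return
        leaf = remaining[0]
        for e in list(current_edges):
            u, v = e
            w = f"T{next(counter)}"
            nxt = [x for x in current_edges if x != e]
            nxt.extend([(u, w), (w, v), (w, leaf)])
            yield from rec(nxt, remaining[1:])

    c = "T_root"
    base = [(c, leaves[0]), (c, leaves[1]), (c, leaves[2])]
    yield from rec(base, leaves[3:])


def least_squares_topology(d: np.ndarray, leaves) -> set[frozenset]:
    """Exhaustive search: the topology whose LS branch fit minimizes SSE."""
    pairs = list(itertools.combinations(range(len(leaves)), 2))
    best_sse, best_splits = math.inf, None
    for edges in enumerate_topologies(list(leaves)):
        edge_list = list(edges)
        A = np.zeros((len(pairs), len(edge_list)))
        for row, (i, j) in enumerate(pairs):
            on_path = set(path_edges(edge_list, leaves[i], leaves[j]))
            for col, e in enumerate(edge_list):
                if e in on_path:
                    A[row, col] = 1.0
        y = np.array([d[i, j] for i, j in pairs])
        w, *_ = np.linalg.lstsq(A, y, rcond=None)
        sse = float(((A @ w - y) ** 2).sum())
        if sse < best_sse - 1e-12:
            best_sse = sse
            best_splits = tree_splits(edge_list, list(leaves))
    return best_splits
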