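"""Spanning-tree backbone metrics of a functional connectivity matrix.

Network topology is summarised on the spanning tree over the *strongest*
connections (the convention of the MEG minimum-spanning-tree literature:
the maximum spanning tree of the PLV matrix, equivalently the minimum
spanning tree of 1 - PLV). Two scalar measures are used:

* diameter — hop count of the longest shortest path in the tree; the larger
  the diameter, the less integrated the network;
* leaf fraction — fraction of nodes with exactly one tree connection; a
  proxy for segregation / star-likeness.

Exact weight ties are broken lexicographically by edge index, making the
tree deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components

__all__ = [
    "SpanningTreeSummary",
    "maximum_spanning_tree",
    "tree_diameter",
    "leaf_fraction",
    "mst_summary",
]


@dataclass
class SpanningTreeSummary:
    """The tree's edges and its two topology metrics."""

    edges: list[tuple[int, int]]
    diameter: int
    leaf_fraction: float
    n_regions: int


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> bool:
        ri, rj = self.find(i), self.find(j)
        if ri == rj:
            return False
        self.parent[ri] = rj
        return True


def maximum_spanning_tree(weights: np.ndarray) -> list[tuple[int, int]]:
    """Kruskal spanning tree maximising total weight.

    ``weights`` is a symmetric non-negative matrix whose nonzero pattern must
    form a connected graph (a dense PLV matrix always does). Ties are broken
    by lexicographic (i, j) edge order. Disconnected input is rejected with
    the component partition in the message.
    """
    W = np.asarray(weights, dtype=float)
    n = W.shape[0]
    if W.shape != (n, n) or not np.allclose(W, W.T):
        raise ValueError("weights must be a symmetric square matrix")
    if np.any(W < 0):
        raise ValueError("weights must be non-negative")
    n_comp, labels = connected_components(W > 0, directed=False)
    if n_comp != 1:
        parts = [np.flatnonzero(labels == k).tolist() for k in range(n_comp)]
        raise ValueError(f"input graph is disconnected; components: {parts}")

    iu, ju = np.triu_indices(n, 1)
    present = W[iu, ju] > 0
    iu, ju, w = iu[present], ju[present], W[iu, ju][present]
    order = np.lexsort((ju, iu, -w))  # weight desc, then (i, j) asc
    uf = _UnionFind(n)
    edges: list[tuple[int, int]] = []
    for k in order:
        if uf.union(int(iu[k]), int(ju[k])):
            edges.append((int(iu[k]), int(ju[k])))
            if len(edges) == n - 1:
                break
    return edges


def _adjacency_lists(edges: list[tuple[int, int]], n: int) -> list[list[int]]:
    if len(edges) != n - 1:
        raise ValueError(f"a tree on {n} nodes has {n - 1} edges, got {len(edges)}")
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in edges:
        adj[i].append(j)
        adj[j].append(i)
    # connectivity check doubles as the acyclicity check given n-1 edges
    seen = {0}
    stack = [0]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    if len(seen) != n:
        raise ValueError("edge list does not form a spanning tree")
    return adj


def _bfs_farthest(adj: list[list[int]], start: int) -> tuple[int, int]:
    dist = {start: 0}
    frontier = [start]
    far, fdist = start, 0
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    if dist[v] > fdist:
                        far, fdist = v, dist[v]
                    nxt.append(v)
        frontier = nxt
    return far, fdist


def tree_diameter(edges: list[tuple[int, int]], n: int) -> int:
    """Longest shortest path in the tree, in hops (double BFS)."""
    adj = _adjacency_lists(edges, n)
    far, _ = _bfs_farthest(adj, 0)
    _, diameter = _bfs_farthest(adj, far)
    return diameter


def leaf_fraction(edges: list[tuple[int, int]], n: int) -> float:
    """Fraction of tree nodes with exactly one connection."""
    adj = _adjacency_lists(edges, n)
    return sum(1 for a in adj if len(a) == 1) / n


def mst_summary(weights: np.ndarray) -> SpanningTreeSummary:
    """Tree backbone of a connectivity matrix plus both scalar metrics."""
    n = weights.shape[0]
    edges = maximum_spanning_tree(weights)
    return SpanningTreeSummary(
        edges=edges,
        diameter=tree_diameter(edges, n),
        leaf_fraction=leaf_fraction(edges, n),
        n_regions=n,
    )
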