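"""Similarity graph, maximum spanning tree, and BFS encoding order.

Edge weight between two reads is the number of anchors they share — an
estimate of how much space encoding one against the other saves.  Weight-0
"chain" edges between consecutive read ids guarantee connectivity without
ever displacing an informative anchor edge in the maximum spanning tree.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Iterator, NamedTuple

from recoil.extsort import StructSerializer

ANCHOR_KIND = 0
CHAIN_KIND = 1

#: spill-file layout: u u32, v u32, weight u32, kind u8
EDGE_STRUCT = StructSerializer("<IIIB")


class SimilarityEdge(NamedTuple):
    u: int
    v: int  # u < v
    weight: int
    kind: int


@dataclass
class EncodingTree:
    """Rooted spanning tree plus its breadth-first read order.

    ``parent[i]`` is the parent read id (root maps to itself); ``bfs_order``
    lists read ids root-first; ``position[r]`` is read r's index in that
    order.  By construction parent BFS positions are non-decreasing along the
    BFS order, which is what lets encoder and decoder run as forward-only
    scans.
    """

    parent: list[int]
    root: int
    bfs_order: list[int]
    position: list[int]

    @property
    def n_reads(self) -> int:
        return len(self.parent)


def aggregate_edges(sorted_anchors: Iterable[tuple]) -> Iterator[SimilarityEdge]:
    """Collapse a lexicographically sorted anchor stream into weighted edges."""
    current: tuple[int, int] | None = None
    count = 0
    for anchor in sorted_anchors:
        pair = (anchor[0], anchor[1])
        if current is not None and pair < current:
            raise ValueError("anchor stream is not sorted")
        if pair != current:
            if current is not None:
                yield SimilarityEdge(current[0], current[1], count, ANCHOR_KIND)
            current = pair
            count = 0
        count += 1
    if current is not None:
        yield SimilarityEdge(current[0], current[1], count, ANCHOR_KIND)


def add_chain_edges(n_reads: int) -> Iterator[SimilarityEdge]:
    """Connectivity fallback: weight-0 edges (i, i+1) for every consecutive pair."""
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    for i in range(n_reads - 1):
        yield SimilarityEdge(i, i + 1, 0, CHAIN_KIND)


class _UnionFind:
    __slots__ = ("parent", "rank")

    def __init__(self, n: int):
        self.parent = list(range(n))
        self.rank = [0] * n

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1
        return True


def maximum_spanning_tree(
    edges: Iterable[SimilarityEdge | tuple], n_reads: int
) -> list[SimilarityEdge]:
    """Kruskal maximum spanning tree; ties broken by (weight desc, u asc, v asc).

    Only the union-find array is resident; the edge list is materialized for
    sorting (edge counts are bounded by the anchor cap, not the dataset size).
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    pool = [SimilarityEdge(*e) for e in edges]
    pool.sort(key=lambda e: (-e.weight, e.u, e.v))
    uf = _UnionFind(n_reads)
    tree: list[SimilarityEdge] = []
    for e in pool:
        if uf.union(e.u, e.v):
            tree.append(e)
            if len(tree) == n_reads - 1:
                break
    if len(tree) != n_reads - 1:
        raise ValueError("similarity graph is disconnected; chain edges missing?")
    return tree


def root_and_bfs(
    tree: Iterable[SimilarityEdge | tuple], n_reads: int, root: int = 0
) -> EncodingTree:
    """Orient a spanning tree away from ``root`` and compute its BFS order.

    Children are visited in ascending read id so archives are reproducible.
    """
    adjacency: list[list[int]] = [[] for _ in range(n_reads)]
    n_edges = 0
    for e in tree:
        u, v = e[0], e[1]
        adjacency[u].append(v)
        adjacency[v].append(u)
        n_edges += 1
    if n_edges != n_reads - 1:
        raise ValueError(f"expected {n_reads - 1} tree edges, got {n_edges}")
    for lst in adjacency:
        lst.sort()

    parent = [-1] * n_reads
    parent[root] = root
    order = [root]
    queue = deque([root])
    while queue:
        u = queue.popleft()
        for v in adjacency[u]:
            if parent[v] == -1:
                parent[v] = u
                order.append(v)
                queue.append(v)
    if len(order) != n_reads:
        raise ValueError("edges do not form a spanning tree")

    position = [0] * n_reads
    for pos, r in enumerate(order):
        position[r] = pos
    # parent positions must be non-decreasing along the BFS order
    last = 0
    for r in order[1:]:
        p = position[parent[r]]
        if p < last:
            raise AssertionError("BFS parent positions regressed")
        last = p
    return EncodingTree(parent=parent, root=root, bfs_order=order, position=position)
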