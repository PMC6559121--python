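"""Independent brute-force oracles used only by the test suite.

Each oracle was written before (and independently of) the implementation it
checks: union-find for connected components, exhaustive enumeration for
set-pair connectivity, closed-form/combinatorial hypergeometric tails, and a
recursive DFS enumerator for fixed-length simple paths.
"""

from __future__ import annotations

import itertools
from math import comb


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x, y):
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[rx] = ry


def components_oracle(nodes, edges):
    """Connected components via union-find; returns a list of frozensets."""
    uf = UnionFind(nodes)
    for a, b in edges:
        uf.union(a, b)
    groups = {}
    for n in nodes:
        groups.setdefault(uf.find(n), set()).add(n)
    return [frozenset(g) for g in groups.values()]


def bfs_distances_oracle(adjacency, source):
    """Plain queue-based BFS distances (no networkx)."""
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adjacency[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def connectivity_oracle(nodes, edges, a, b):
    """Exhaustive (overlap, direct interactions, common neighbors)."""
    edge_set = {frozenset(e) for e in edges}
    adjacency = {n: set() for n in nodes}
    for u, v in edges:
        adjacency[u].add(v)
        adjacency[v].add(u)
    overlap = len(a & b)
    direct = sum(
        1
        for e in edge_set
        if any(u in a and v in b for u, v in itertools.permutations(e, 2))
    )
    common = sum(1 for x in nodes if adjacency[x] & a and adjacency[x] & b)
    return overlap, direct, common


def hypergeom_tail_oracle(population, successes, draws, observed):
    """P(X >= observed) by direct combinatorial summation."""
    total = comb(population, draws)
    return (
        sum(
            comb(successes, i) * comb(population - successes, draws - i)
            for i in range(observed, min(successes, draws) + 1)
        )
        / total
    )


def hypergeom_tail_enumeration(population_items, success_items, draws, observed):
    """P(X >= observed) by literally enumerating every possible neighbor set."""
    success_items = set(success_items)
    hits = total = 0
    for subset in itertools.combinations(population_items, draws):
        total += 1
        if len(success_items.intersection(subset)) >= observed:
            hits += 1
    return hits / total


def simple_paths_oracle(adjacency, a, b, length):
    """All simple paths of exactly ``length`` edges from a to b, via DFS."""
    paths = []

    def dfs(node, path):
        if len(path) - 1 == length:
            if node == b:
                paths.append(tuple(path))
            return
        for nb in sorted(adjacency[node]):
            if nb not in path:
                dfs(nb, path + [nb])

    dfs(a, [a])
    return paths


def bridge_score_oracle(adjacency, a, b, candidate):
    """Weighted path-fraction score recomputed from the DFS enumerator."""
    score = 0.0
    for length, weight in ((2, 1.0), (3, 0.5), (4, 0.25)):
        paths = simple_paths_oracle(adjacency, a, b, length)
        if paths:
            containing = sum(1 for p in paths if candidate in p[1:-1])
            score += weight * containing / len(paths)
    return score
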