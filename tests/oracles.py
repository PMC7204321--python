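"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (pure-Python enumeration, no
networkx/scipy shortcuts) so it checks the package implementations by an
unrelated route.
"""

from __future__ import annotations

import itertools
from collections import deque
from math import comb


# ---------------------------------------------------------------------------
# graph centralities by explicit shortest-path enumeration
# ---------------------------------------------------------------------------


def _bfs_distances(adj: dict[str, set[str]], source: str) -> dict[str, int]:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def _all_shortest_paths(
    adj: dict[str, set[str]], source: str, target: str, dist: dict[str, int]
) -> list[tuple[str, ...]]:
    """Every shortest source->target path, by DFS along decreasing distance."""
    if target not in dist:
        return []
    paths: list[tuple[str, ...]] = []

    def extend(path: list[str]) -> None:
        head = path[-1]
        if head == source:
            paths.append(tuple(reversed(path)))
            return
        for w in adj[head]:
            if dist.get(w) == dist[head] - 1:
                extend(path + [w])

    extend([target])
    return paths


def brute_force_centralities(
    nodes: list[str], edges: list[tuple[str, str]]
) -> dict[str, tuple[int, float, float]]:
    """(degree, closeness, betweenness) per node by exhaustive enumeration.

    Closeness uses the reachable-component correction
    ((r-1)/sum_d) * ((r-1)/(N-1)); betweenness excludes endpoints, splits
    each pair's unit contribution equally over its shortest paths, and is
    normalized by (N-1)(N-2)/2.
    """
    adj: dict[str, set[str]] = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    n_total = len(nodes)
    degree = {n: len(adj[n]) for n in nodes}

    dists = {n: _bfs_distances(adj, n) for n in nodes}
    closeness = {}
    for n in nodes:
        reachable = len(dists[n])  # includes n itself
        total = sum(dists[n].values())
        if reachable <= 1 or total == 0 or n_total <= 1:
            closeness[n] = 0.0
        else:
            closeness[n] = ((reachable - 1) / total) * ((reachable - 1) / (n_total - 1))

    betweenness = {n: 0.0 for n in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = _all_shortest_paths(adj, s, t, dists[s])
        if not paths:
            continue
        for path in paths:
            for inner in path[1:-1]:
                betweenness[inner] += 1.0 / len(paths)
    if n_total > 2:
        scale = (n_total - 1) * (n_total - 2) / 2.0
        betweenness = {n: b / scale for n, b in betweenness.items()}
    return {n: (degree[n], closeness[n], betweenness[n]) for n in nodes}


# ---------------------------------------------------------------------------
# hypergeometric tail by combinatorial enumeration
# ---------------------------------------------------------------------------


def enumerate_hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) by enumerating every size-n draw from an N-item urn."""
    universe = list(range(N))
    marked = set(range(K))
    hits = sum(
        1
        for draw in itertools.combinations(universe, n)
        if len(marked.intersection(draw)) >= k
    )
    return hits / comb(N, n)


# ---------------------------------------------------------------------------
# textbook Benjamini-Hochberg step-up
# ---------------------------------------------------------------------------


def textbook_bh(pvalues: list[float]) -> list[float]:
    m = len(pvalues)
    indexed = sorted(range(m), key=lambda i: pvalues[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = indexed[rank - 1]
        running_min = min(running_min, pvalues[i] * m / rank)
        adjusted[i] = running_min
    return adjusted


# ---------------------------------------------------------------------------
# Tanimoto coefficient by direct elementwise evaluation
# ---------------------------------------------------------------------------


def direct_tanimoto(a: list[float], b: list[float]) -> float:
    dot = sum(x * y for x, y in zip(a, b))
    na = sum(x * x for x in a)
    nb = sum(y * y for y in b)
    return dot / (na + nb - dot)
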