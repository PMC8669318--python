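"""Shared fixtures and independent brute-force oracles.

The oracle functions here deliberately avoid the library paths they
check: shortest paths are enumerated with a hand-rolled BFS, triangles
by neighbor-pair scanning, k-cores by explicit peeling, and the
hypergeometric tail by exhaustive subset enumeration.
"""

from __future__ import annotations

import itertools
from collections import deque

import networkx as nx
import numpy as np
import pytest


# ---------------------------------------------------------------- fixtures


@pytest.fixture
def star5() -> nx.Graph:
    """Star: center 'C' with 4 leaves."""
    g = nx.Graph()
    g.add_edges_from(("C", f"L{i}") for i in range(1, 5))
    return g


@pytest.fixture
def path3() -> nx.Graph:
    g = nx.Graph()
    g.add_edges_from([("A", "B"), ("B", "C")])
    return g


@pytest.fixture
def cycle5() -> nx.Graph:
    g = nx.Graph()
    nodes = [f"N{i}" for i in range(5)]
    g.add_edges_from((nodes[i], nodes[(i + 1) % 5]) for i in range(5))
    return g


@pytest.fixture
def k4() -> nx.Graph:
    return nx.relabel_nodes(nx.complete_graph(4), {i: f"V{i}" for i in range(4)})


def random_graph(n: int, p: float, seed: int) -> nx.Graph:
    """Erdos–Renyi graph with string labels (independent of library labels)."""
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    names = [f"N{i:02d}" for i in range(n)]
    g.add_nodes_from(names)
    for a, b in itertools.combinations(names, 2):
        if rng.random() < p:
            g.add_edge(a, b)
    return g


# ----------------------------------------------------------------- oracles


def bfs_distances(g: nx.Graph, source) -> dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in g[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def oracle_betweenness(g: nx.Graph) -> dict:
    """Exhaustive shortest-path enumeration, normalized by (N-1)(N-2)/2."""
    n = g.number_of_nodes()
    nodes = list(g.nodes)
    score = {v: 0.0 for v in nodes}
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            paths = all_shortest_paths(g, s, t)
            if not paths:
                continue
            for v in nodes:
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                score[v] += through / len(paths)
    if n > 2:
        norm = (n - 1) * (n - 2) / 2
        score = {v: s / norm for v, s in score.items()}
    return score


def all_shortest_paths(g: nx.Graph, s, t) -> list[list]:
    """All geodesics from s to t by BFS layering + DFS back-tracing."""
    dist = bfs_distances(g, s)
    if t not in dist:
        return []
    paths = []

    def back(v, path):
        if v == s:
            paths.append(list(reversed(path + [s])))
            return
        for u in g[v]:
            if u in dist and dist[u] == dist[v] - 1:
                back(u, path + [v])

    back(t, [])
    return paths


def oracle_closeness(g: nx.Graph) -> dict:
    """(n_c - 1) / sum of BFS distances within each component."""
    out = {}
    for v in g:
        dist = bfs_distances(g, v)
        total = sum(dist.values())
        out[v] = (len(dist) - 1) / total if total > 0 else 0.0
    return out


def oracle_clustering(g: nx.Graph) -> dict:
    """2 m_i / (k_i (k_i - 1)) by enumerating neighbor pairs."""
    out = {}
    for v in g:
        nbrs = list(g[v])
        k = len(nbrs)
        if k < 2:
            out[v] = 0.0
            continue
        m = sum(1 for a, b in itertools.combinations(nbrs, 2) if g.has_edge(a, b))
        out[v] = 2 * m / (k * (k - 1))
    return out


def oracle_neighbor_connectivity(g: nx.Graph) -> dict:
    out = {}
    for v in g:
        nbrs = list(g[v])
        if nbrs:
            out[v] = sum(len(g[u]) for u in nbrs) / len(nbrs)
    return out


def oracle_core_numbers(g: nx.Graph) -> dict:
    """Iterative minimum-degree peeling, written from scratch."""
    h = g.copy()
    core = {}
    k = 0
    while h.number_of_nodes():
        while True:
            low = [v for v in h if h.degree(v) <= k]
            if not low:
                break
            for v in low:
                core[v] = k
                h.remove_node(v)
        k += 1
    return core


def oracle_hypergeom_tail(universe: int, term: int, draw: int, overlap: int) -> float:
    """P(X >= overlap) by exhaustive enumeration of all draws (universe <= 20)."""
    population = range(universe)
    successes = set(range(term))
    hits = 0
    total = 0
    for subset in itertools.combinations(population, draw):
        total += 1
        if len(successes.intersection(subset)) >= overlap:
            hits += 1
    return hits / total
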