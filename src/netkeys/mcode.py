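"""Molecular Complex Detection (MCODE) dense-module finding.

Three stages, following the classic seeded-expansion algorithm used to
pull protein complexes out of interaction networks:

1. *Vertex weighting* — each node is scored by the density of the
   highest k-core of its closed neighborhood times that core's k, so
   nodes sitting in locally dense regions get high weights.
2. *Complex prediction* — starting from the highest-weighted unvisited
   node (the seed), neighbors are admitted breadth-first while their
   weight exceeds ``seed_weight * (1 - node_score_cutoff)``, capped at
   ``max_depth`` hops from the seed.
3. *Post-processing* — complexes with no k-core (default k=2) are
   discarded; *haircut* iteratively strips members with fewer than two
   internal neighbors; optional *fluff* adds boundary nodes whose closed
   neighborhood is dense enough.

A complex's M-score is its internal density 2E/(n(n-1)) multiplied by
its size n, so an n-clique scores exactly n.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx

from .consensus import ConsensusNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "MCODEParams",
    "MCODEComplex",
    "core_numbers",
    "vertex_weights",
    "predict_complexes",
    "postprocess",
    "score_complex",
    "truncate_score",
    "select_modules",
    "run_mcode",
]


def _graph(net: ConsensusNetwork | nx.Graph) -> nx.Graph:
    return net.graph if isinstance(net, ConsensusNetwork) else net


@dataclass
class MCODEParams:
    node_score_cutoff: float = 0.2
    haircut: bool = True
    fluff: bool = False
    fluff_density_cutoff: float = 0.1
    k_core: int = 2
    max_depth: int = 100
    min_score: float = 4.0

    def __post_init__(self) -> None:
        if not 0 <= self.node_score_cutoff <= 1:
            raise ValueError("node_score_cutoff must be in [0, 1]")
        if not 0 <= self.fluff_density_cutoff <= 1:
            raise ValueError("fluff_density_cutoff must be in [0, 1]")
        if self.k_core < 2:
            raise ValueError("k_core must be >= 2")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")


@dataclass
class MCODEComplex:
    """A predicted complex: member set, seed node and density x size score."""

    members: set[str]
    seed: str
    edges: int = field(init=False)
    density: float = field(init=False)
    score: float = field(init=False)
    _graph: nx.Graph = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if self.seed not in self.members:
            raise ValueError("seed must be a member of the complex")
        sub = self._graph.subgraph(self.members)
        self.edges = sub.number_of_edges()
        n = len(self.members)
        self.density = 2 * self.edges / (n * (n - 1)) if n > 1 else 0.0
        self.score = self.density * n

    @property
    def n(self) -> int:
        return len(self.members)


def core_numbers(net: ConsensusNetwork | nx.Graph) -> dict[str, int]:
    """Highest k-core containing each node (iterative min-degree peeling)."""
    return dict(nx.core_number(_graph(net)))


def _density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 0.0
    return 2 * g.number_of_edges() / (n * (n - 1))


def vertex_weights(net: ConsensusNetwork | nx.Graph) -> dict[str, float]:
    """Local neighborhood-density weight of every node.

    For node v take the subgraph on v plus its neighbors, find its
    highest k-core, and set weight(v) = k_max * density(that core).
    Degree-0 nodes weigh 0.
    """
    g = _graph(net)
    weights: dict[str, float] = {}
    for v in g:
        nbrs = set(g[v])
        if not nbrs:
            weights[v] = 0.0
            continue
        closed = g.subgraph(nbrs | {v})
        cores = nx.core_number(closed)
        k_max = max(cores.values())
        core_sub = closed.subgraph([u for u, c in cores.items() if c == k_max])
        weights[v] = k_max * _density(core_sub)
    return weights


def predict_complexes(
    net: ConsensusNetwork | nx.Graph,
    weights: dict[str, float] | None = None,
    params: MCODEParams | None = None,
) -> list[MCODEComplex]:
    """Seeded breadth-first complex prediction (pre-post-processing).

    Seeds are taken in weight-descending, symbol-ascending order over
    unvisited nodes; an unvisited neighbor is admitted iff its weight is
    strictly greater than ``seed_weight * (1 - node_score_cutoff)``.
    Admitted nodes are marked visited, so complexes are disjoint.
    """
    g = _graph(net)
    params = params or MCODEParams()
    if weights is None:
        weights = vertex_weights(g)

    visited: set[str] = set()
    complexes: list[MCODEComplex] = []
    for seed in sorted(g.nodes, key=lambda v: (-weights[v], v)):
        if seed in visited:
            continue
        threshold = weights[seed] * (1 - params.node_score_cutoff)
        members = {seed}
        visited.add(seed)
        frontier = [seed]
        depth = 0
        while frontier and depth < params.max_depth:
            next_frontier = []
            for u in frontier:
                for w in sorted(g[u]):
                    if w in visited:
                        continue
                    if weights[w] > threshold:
                        visited.add(w)
                        members.add(w)
                        next_frontier.append(w)
            frontier = next_frontier
            depth += 1
        complexes.append(MCODEComplex(members=members, seed=seed, _graph=g))
    return complexes


def postprocess(
    complex_: MCODEComplex,
    net: ConsensusNetwork | nx.Graph,
    params: MCODEParams | None = None,
) -> MCODEComplex | None:
    """Apply the k-core filter, haircut and optional fluff; None = discard.

    A complex whose induced subgraph contains no ``k_core``-core is
    discarded.  Haircut runs to fixpoint, removing members with fewer
    than 2 internal neighbors (so it is idempotent).  Fluff then adds
    non-member neighbors whose closed-neighborhood density exceeds the
    fluff cutoff; fluffed complexes may overlap.
    """
    g = _graph(net)
    params = params or MCODEParams()
    members = set(complex_.members)

    sub = g.subgraph(members)
    cores = nx.core_number(sub)
    if not cores or max(cores.values()) < params.k_core:
        return None

    if params.haircut:
        sub = g.subgraph(members).copy()
        while True:
            stragglers = [v for v in sub if sub.degree(v) < 2]
            if not stragglers:
                break
            sub.remove_nodes_from(stragglers)
        members = set(sub.nodes)
        if len(members) <= 2:
            return None

    if params.fluff:
        boundary = {w for v in members for w in g[v]} - members
        for w in sorted(boundary):
            closed = g.subgraph(set(g[w]) | {w})
            if _density(closed) > params.fluff_density_cutoff:
                members.add(w)

    seed = complex_.seed if complex_.seed in members else min(members)
    return MCODEComplex(members=members, seed=seed, _graph=g)


def score_complex(n: int, edges: int) -> float:
    """M-score = density x size = (2 edges / (n (n-1))) * n, full precision."""
    if n < 2:
        raise ValueError("complex must have at least 2 nodes")
    if not 0 <= edges <= n * (n - 1) // 2:
        raise ValueError(f"impossible edge count {edges} for n={n}")
    return (2 * edges / (n * (n - 1))) * n


def truncate_score(score: float, decimals: int = 2) -> float:
    """Display convention: truncate (not round) to the given decimals."""
    factor = 10**decimals
    return math.floor(score * factor) / factor


def select_modules(
    complexes: list[MCODEComplex],
    min_score: float = 4.0,
    top_n: int | None = None,
) -> list[MCODEComplex]:
    """Keep complexes with score > min_score, best first.

    Ordering: score descending, then larger member count, then seed
    symbol; optionally truncated to the top_n best.
    """
    kept = [c for c in complexes if c.score > min_score]
    kept.sort(key=lambda c: (-c.score, -c.n, c.seed))
    if not kept:
        logger.warning("no complex exceeds min_score=%s", min_score)
    if top_n is not None:
        kept = kept[:top_n]
    return kept


def run_mcode(
    net: ConsensusNetwork | nx.Graph,
    params: MCODEParams | None = None,
    top_n: int | None = None,
) -> list[MCODEComplex]:
    """Full pipeline: weight, predict, post-process, score-select."""
    params = params or MCODEParams()
    g = _graph(net)
    weights = vertex_weights(g)
    raw = predict_complexes(g, weights, params)
    processed = [postprocess(c, g, params) for c in raw]
    return select_modules(
        [c for c in processed if c is not None], params.min_score, top_n
    )
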