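"""Hub / bottleneck selection and single-node knockout perturbation.

Hubs are the top fraction of nodes by degree, bottlenecks the top
fraction by betweenness centrality; their intersection — the
bottleneck-hubs (Bn-H) — are the candidates the centrality-lethality
rule marks as most structurally important.  Computational knockouts
remove one node at a time from the intact network and measure how the
betweenness landscape and component structure reorganize.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .consensus import ConsensusNetwork
from .topology import DegreeCurve, betweenness, degree_distribution

__all__ = [
    "RankedSelection",
    "KnockoutResult",
    "select_top_fraction",
    "identify_bottleneck_hubs",
    "knockout",
    "knockout_screen",
]


@dataclass
class RankedSelection:
    """Top-fraction hubs and bottlenecks with their overlap classes."""

    fraction: float
    count: int
    hubs: list[str]
    bottlenecks: list[str]
    bottleneck_hubs: set[str] = field(init=False)
    hub_only: set[str] = field(init=False)
    bottleneck_only: set[str] = field(init=False)

    def __post_init__(self) -> None:
        hub_set, bn_set = set(self.hubs), set(self.bottlenecks)
        self.bottleneck_hubs = hub_set & bn_set
        self.hub_only = hub_set - bn_set
        self.bottleneck_only = bn_set - hub_set

    def classes(self) -> pd.DataFrame:
        rows = []
        for rank, node in enumerate(self.hubs, 1):
            cls = "Bn-H" if node in self.bottleneck_hubs else "hub-only"
            rows.append((node, rank, "degree", cls))
        for rank, node in enumerate(self.bottlenecks, 1):
            cls = "Bn-H" if node in self.bottleneck_hubs else "bottleneck-only"
            rows.append((node, rank, "betweenness", cls))
        return pd.DataFrame(rows, columns=["node", "rank", "metric", "class"])


@dataclass
class KnockoutResult:
    """Perturbation summary for removing one node from the intact network."""

    removed: str
    n_components_delta: int
    edges_removed: int
    mean_abs_delta_CB: float
    max_abs_delta_CB: float
    degree_curve_after: DegreeCurve


def select_top_fraction(
    metrics: pd.DataFrame, key: str, q: float = 0.01
) -> list[str]:
    """Top floor(q*N) nodes by the given metric column.

    Ties at the boundary break by value descending, then symbol
    ascending, so the selection is deterministic.
    """
    if key not in {"degree", "betweenness"}:
        raise ValueError(f"key must be 'degree' or 'betweenness', got {key!r}")
    if not 0 < q < 1:
        raise ValueError("fraction q must be in (0, 1)")
    column = {"degree": "k", "betweenness": "C_B"}[key]
    count = math.floor(q * len(metrics))
    if count == 0:
        raise ValueError(
            f"fraction too small: floor({q} * {len(metrics)}) = 0 nodes"
        )
    ranked = sorted(metrics[column].items(), key=lambda kv: (-kv[1], kv[0]))
    return [node for node, _ in ranked[:count]]


def identify_bottleneck_hubs(
    hubs: list[str], bottlenecks: list[str], fraction: float = 0.01
) -> RankedSelection:
    """Intersect the hub and bottleneck lists into Bn-H / hub-only / bottleneck-only."""
    if not hubs or not bottlenecks:
        raise ValueError("hub and bottleneck lists must be non-empty")
    return RankedSelection(
        fraction=fraction, count=len(hubs), hubs=list(hubs), bottlenecks=list(bottlenecks)
    )


def knockout(
    net: ConsensusNetwork | nx.Graph,
    node: str,
    cb_before: dict[str, float] | None = None,
) -> KnockoutResult:
    """Remove one node, recompute betweenness and degree structure on the rest.

    Deltas are computed over surviving nodes only.  ``cb_before`` may be
    passed to amortize the intact-network betweenness across a screen.
    """
    g = net.graph if isinstance(net, ConsensusNetwork) else net
    if node not in g:
        raise KeyError(f"node not in network: {node!r}")
    if cb_before is None:
        cb_before = betweenness(g)
    components_before = nx.number_connected_components(g)
    degree = g.degree(node)

    remainder = g.copy()
    remainder.remove_node(node)
    if remainder.number_of_nodes() == 0:
        raise ValueError(f"removing {node!r} empties the network")
    cb_after = betweenness(remainder)
    deltas = [abs(cb_after[v] - cb_before[v]) for v in remainder.nodes]
    return KnockoutResult(
        removed=node,
        n_components_delta=nx.number_connected_components(remainder)
        - components_before,
        edges_removed=degree,
        mean_abs_delta_CB=float(sum(deltas) / len(deltas)),
        max_abs_delta_CB=float(max(deltas)),
        degree_curve_after=degree_distribution(remainder),
    )


def knockout_screen(
    net: ConsensusNetwork | nx.Graph, nodes: list[str]
) -> pd.DataFrame:
    """Independent single-node knockouts, ranked by mean |delta C_B| descending.

    Each knockout starts from the intact network (removals are not
    cumulative).  Returns one row per removed node.
    """
    g = net.graph if isinstance(net, ConsensusNetwork) else net
    if not nodes:
        return pd.DataFrame(
            columns=[
                "removed",
                "edges_removed",
                "n_components_delta",
                "mean_abs_delta_CB",
                "max_abs_delta_CB",
            ]
        )
    cb_before = betweenness(g)
    results = [knockout(g, node, cb_before=cb_before) for node in nodes]
    df = pd.DataFrame(
        {
            "removed": r.removed,
            "edges_removed": r.edges_removed,
            "n_components_delta": r.n_components_delta,
            "mean_abs_delta_CB": r.mean_abs_delta_CB,
            "max_abs_delta_CB": r.max_abs_delta_CB,
        }
        for r in results
    )
    return df.sort_values(
        ["mean_abs_delta_CB", "removed"], ascending=[False, True]
    ).reset_index(drop=True)
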