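"""Bottleneck-hub x module interaction-strength accounting.

The interaction strength between a bottleneck-hub and a module is the
number of consensus-network edges joining the hub to module members.  A
hub that is itself a module member contributes edges to *other* members
only.  Row totals over modules rank which hubs mediate the most module
crosstalk.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .consensus import ConsensusNetwork
from .mcode import MCODEComplex

__all__ = ["CrosstalkMatrix", "interaction_strength", "crosstalk_matrix", "common_connectors"]


def _graph(net: ConsensusNetwork | nx.Graph) -> nx.Graph:
    return net.graph if isinstance(net, ConsensusNetwork) else net


@dataclass
class CrosstalkMatrix:
    """Hub x module edge counts with row totals and membership flags."""

    counts: pd.DataFrame  # rows: hubs, columns: module ids, plus "total"
    membership: pd.DataFrame  # boolean, same shape minus total column

    @property
    def totals(self) -> pd.Series:
        return self.counts["total"]


def interaction_strength(
    net: ConsensusNetwork | nx.Graph, hub: str, module: MCODEComplex | set[str]
) -> int:
    """Edges in the full network between ``hub`` and module members (self excluded)."""
    g = _graph(net)
    if hub not in g:
        raise KeyError(f"hub not in network: {hub!r}")
    members = module.members if isinstance(module, MCODEComplex) else set(module)
    return sum(1 for m in members if m != hub and g.has_edge(hub, m))


def crosstalk_matrix(
    net: ConsensusNetwork | nx.Graph,
    bnhs: list[str],
    modules: list[MCODEComplex] | list[set[str]],
    module_ids: list[str] | None = None,
) -> CrosstalkMatrix:
    """Full Bn-H x module count matrix, rows ordered by total descending."""
    if not bnhs or not modules:
        raise ValueError("bnhs and modules must be non-empty")
    if module_ids is None:
        module_ids = [f"module_{i}" for i in range(1, len(modules) + 1)]
    member_sets = [
        m.members if isinstance(m, MCODEComplex) else set(m) for m in modules
    ]
    counts = pd.DataFrame(
        [
            [interaction_strength(net, hub, members) for members in member_sets]
            for hub in bnhs
        ],
        index=pd.Index(bnhs, name="bnh"),
        columns=module_ids,
    )
    counts["total"] = counts.sum(axis=1)
    counts = counts.sort_values(
        ["total", "bnh"], ascending=[False, True], kind="mergesort"
    )
    membership = pd.DataFrame(
        [[hub in members for members in member_sets] for hub in bnhs],
        index=pd.Index(bnhs, name="bnh"),
        columns=module_ids,
    ).loc[counts.index]
    return CrosstalkMatrix(counts=counts, membership=membership)


def common_connectors(
    net: ConsensusNetwork | nx.Graph, bnhs: list[str], min_links: int = 2
) -> pd.DataFrame:
    """Non-hub nodes adjacent to at least ``min_links`` of the given hubs.

    Convenience for spotting shared interaction partners that tie several
    bottleneck-hubs together; returns (node, n_links, linked hubs) sorted
    by n_links descending.
    """
    g = _graph(net)
    hub_set = set(bnhs)
    rows = []
    for v in g:
        if v in hub_set:
            continue
        linked = sorted(h for h in hub_set if g.has_edge(v, h))
        if len(linked) >= min_links:
            rows.append((v, len(linked), ",".join(linked)))
    df = pd.DataFrame(rows, columns=["node", "n_links", "linked_bnhs"])
    return df.sort_values(["n_links", "node"], ascending=[False, True]).reset_index(
        drop=True
    )
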