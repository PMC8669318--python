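"""Seed-gene handling and multi-source consensus network construction.

Interaction evidence for the same physical interaction is deposited
independently in several source databases (STRING, BioGRID, DIP, IntAct,
MINT, ...).  Requiring an edge to be reported by at least ``min_sources``
distinct databases filters single-database noise; the surviving simple
undirected graph is the *consensus network* on which all downstream
topology, module and crosstalk analysis runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "InteractionRecord",
    "ConsensusNetwork",
    "read_seed_genes",
    "read_source_edges",
    "build_consensus",
    "read_network_tsv",
    "write_network_tsv",
]


def normalize_symbol(token: str) -> str:
    """Canonical form of a gene symbol: stripped and upper-cased."""
    return token.strip().upper()


@dataclass
class GeneSet:
    """A de-duplicated, alias-resolved collection of gene symbols.

    ``symbols`` preserves first-seen order; ``alias_map`` records the
    alias -> canonical substitutions that were applied.
    """

    symbols: list[str]
    alias_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError("no seed genes")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("GeneSet symbols must be unique")

    def __len__(self) -> int:
        return len(self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in set(self.symbols)


@dataclass(frozen=True)
class InteractionRecord:
    """One reported interaction between two genes in one source database.

    The pair is unordered: records (A, B) and (B, A) describe the same
    interaction.  ``key`` gives the canonical sorted tuple.
    """

    gene_a: str
    gene_b: str
    source_id: str

    @property
    def key(self) -> tuple[str, str]:
        a, b = sorted((self.gene_a, self.gene_b))
        return (a, b)

    @property
    def is_self_loop(self) -> bool:
        return self.gene_a == self.gene_b


class ConsensusNetwork:
    """Simple undirected graph whose edges carry a source-support count.

    Thin wrapper over :class:`networkx.Graph`; the ``support`` edge
    attribute counts the distinct databases reporting that edge.
    """

    def __init__(self, graph: nx.Graph, min_sources: int):
        self.graph = graph
        self.min_sources = min_sources

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def support(self) -> dict[tuple[str, str], int]:
        return {
            tuple(sorted((u, v))): d["support"]
            for u, v, d in self.graph.edges(data=True)
        }

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"ConsensusNetwork(N={self.n_nodes}, E={self.n_edges}, "
            f"min_sources={self.min_sources})"
        )


def read_seed_genes(path: str | Path, alias_path: str | Path | None = None) -> GeneSet:
    """Read a one-symbol-per-line seed list, resolving aliases and duplicates.

    Parameters
    ----------
    path
        Plain-text file, one gene symbol per line; blank lines and lines
        starting with ``#`` are ignored.
    alias_path
        Optional two-column TSV ``alias<TAB>canonical``.  Every alias must
        map to exactly one canonical symbol and alias chains/cycles are
        rejected.

    Returns
    -------
    GeneSet with case-normalized symbols in first-seen order.
    """
    alias_map: dict[str, str] = {}
    if alias_path is not None:
        for lineno, line in enumerate(Path(alias_path).read_text().splitlines(), 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"alias file line {lineno}: expected 2 tab-separated columns"
                )
            alias = normalize_symbol(parts[0])
            canonical = normalize_symbol(parts[1])
            if alias == canonical:
                raise ValueError(f"alias cycle: {alias!r} maps to itself")
            if alias in alias_map and alias_map[alias] != canonical:
                raise ValueError(
                    f"conflicting alias: {alias!r} maps to both "
                    f"{alias_map[alias]!r} and {canonical!r}"
                )
            alias_map[alias] = canonical
        # a canonical symbol that is itself an alias would form a chain
        for alias, canonical in alias_map.items():
            if canonical in alias_map:
                raise ValueError(
                    f"alias chain: {alias!r} -> {canonical!r} -> "
                    f"{alias_map[canonical]!r}"
                )

    symbols: list[str] = []
    seen: set[str] = set()
    for line in Path(path).read_text().splitlines():
        token = line.strip()
        if not token or token.startswith("#"):
            continue
        symbol = normalize_symbol(token)
        symbol = alias_map.get(symbol, symbol)
        if symbol not in seen:
            seen.add(symbol)
            symbols.append(symbol)
    if not symbols:
        raise ValueError("no seed genes")
    return GeneSet(symbols=symbols, alias_map=alias_map)


def _parse_tsv_row(parts: Sequence[str]) -> tuple[str, str] | None:
    if len(parts) < 2:
        return None
    a, b = normalize_symbol(parts[0]), normalize_symbol(parts[1])
    if not a or not b:
        return None
    return a, b


def _parse_mitab_row(parts: Sequence[str]) -> tuple[str, str] | None:
    """Reduce the two PSI-MITAB interactor columns to bare gene symbols.

    Accepts ``db:ID`` prefixes (``uniprotkb:SOD1``) and keeps the part
    after the last colon.
    """
    if len(parts) < 2:
        return None
    symbols = []
    for column in parts[:2]:
        ident = column.split("|")[0].strip()
        if not ident or ident == "-":
            return None
        symbols.append(normalize_symbol(ident.rsplit(":", 1)[-1]))
    a, b = symbols
    if not a or not b:
        return None
    return a, b


def read_source_edges(
    path: str | Path, source_id: str, dialect: str = "tsv"
) -> list[InteractionRecord]:
    """Read one source database's edge table.

    ``dialect`` is ``"tsv"`` (columns geneA, geneB) or ``"mitab-min"``
    (PSI-MITAB 2.5 columns 1–2 reduced to gene symbols).  Malformed rows
    are skipped with a logged count; self-loop rows are retained and
    flagged so downstream consensus construction can drop them.
    """
    if dialect == "tsv":
        parser = _parse_tsv_row
    elif dialect == "mitab-min":
        parser = _parse_mitab_row
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")

    records: list[InteractionRecord] = []
    skipped = 0
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        pair = parser(line.split("\t"))
        if pair is None:
            skipped += 1
            continue
        records.append(InteractionRecord(pair[0], pair[1], source_id))
    if skipped:
        logger.warning("%s: skipped %d malformed rows", path, skipped)
    if not records:
        raise ValueError(f"{path}: zero parseable rows")
    return records


def build_consensus(
    records: Iterable[InteractionRecord], min_sources: int = 2
) -> ConsensusNetwork:
    """Build the consensus network from pooled multi-source records.

    An unordered pair becomes an edge iff it is reported by at least
    ``min_sources`` *distinct* sources.  Duplicate records within one
    source count once; self-loops are removed; nodes left with no edge
    are excluded.
    """
    if min_sources < 1:
        raise ValueError("min_sources must be >= 1")
    records = list(records)
    if not records:
        raise ValueError("no interaction records")

    sources_by_edge: dict[tuple[str, str], set[str]] = {}
    for rec in records:
        if rec.is_self_loop:
            continue
        sources_by_edge.setdefault(rec.key, set()).add(rec.source_id)

    graph = nx.Graph()
    for (a, b), sources in sources_by_edge.items():
        if len(sources) >= min_sources:
            graph.add_edge(a, b, support=len(sources))
    if graph.number_of_edges() == 0:
        raise ValueError("empty consensus network")
    return ConsensusNetwork(graph, min_sources)


def write_network_tsv(net: ConsensusNetwork, path: str | Path) -> None:
    """Write the consensus edge list as ``geneA<TAB>geneB<TAB>support``."""
    lines = ["geneA\tgeneB\tsupport"]
    for (a, b), support in sorted(net.support.items()):
        lines.append(f"{a}\t{b}\t{support}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_network_tsv(path: str | Path) -> ConsensusNetwork:
    """Read a consensus network written by :func:`write_network_tsv`."""
    graph = nx.Graph()
    for line in Path(path).read_text().splitlines()[1:]:
        if not line.strip():
            continue
        a, b, support = line.split("\t")
        graph.add_edge(a, b, support=int(support))
    if graph.number_of_edges() == 0:
        raise ValueError("empty consensus network")
    return ConsensusNetwork(graph, min_sources=1)


def write_graphml(net: ConsensusNetwork, path: str | Path) -> None:
    nx.write_graphml(net.graph, path)
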