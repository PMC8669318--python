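"""Seeded synthetic inputs with the statistical structure the pipeline assumes.

Four generators cover the pipeline's input surface:

* a multi-source interactome whose >= 2-source consensus equals a
  planted truth network (true edges are force-emitted into two distinct
  sources; decoys appear in exactly one, so recovery is exact);
* a hierarchical scale-free graph (preferential attachment with triad
  closure) giving a heavy-tailed P(k) and a decaying C(k);
* planted dense complexes on a sparse background, for module-recovery
  benchmarks;
* GMT term collections with one planted enriched term, and
  gene–disease–class tables with controlled class proportions.

Every generator is a pure function of its arguments and seed: the same
call produces byte-identical outputs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .consensus import ConsensusNetwork, InteractionRecord

__all__ = [
    "InteractomeSpec",
    "generate_multisource_interactome",
    "generate_hierarchical_scale_free",
    "generate_planted_complexes",
    "generate_annotations",
]


@dataclass
class InteractomeSpec:
    """Parameters of the multi-source interactome generator.

    Defaults give 5 sources over ~150 genes, mirroring the seed-list
    scale and five-database design of a disease interactome study, with
    moderate per-source re-emission and single-source decoy noise.
    """

    seed: int = 0
    n_genes: int = 150
    n_sources: int = 5
    true_edge_density: float = 0.04
    p_emit: float = 0.5  # extra-source emission beyond the 2 forced
    n_decoys: int = 200
    source_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_sources < 2:
            raise ValueError("need at least 2 sources")
        for p in (self.true_edge_density, self.p_emit):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if not self.source_ids:
            self.source_ids = [f"S{i + 1}" for i in range(self.n_sources)]


def _gene_names(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(1, n + 1)]


def generate_multisource_interactome(
    spec: InteractomeSpec, outdir: str | Path | None = None
) -> tuple[dict[str, list[InteractionRecord]], ConsensusNetwork]:
    """Per-source interaction records plus the planted truth network.

    Every true edge is emitted into 2 forced distinct sources and into
    each remaining source with probability ``p_emit``; each decoy edge
    (a non-true pair) appears in exactly one source.  Consequently
    ``build_consensus(..., min_sources=2)`` recovers exactly the truth.
    If ``outdir`` is given, one TSV per source is written there.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _gene_names(spec.n_genes)
    pairs = list(itertools.combinations(genes, 2))
    n_true = max(1, round(spec.true_edge_density * len(pairs)))
    order = rng.permutation(len(pairs))
    true_pairs = [pairs[i] for i in order[:n_true]]
    decoy_pool = [pairs[i] for i in order[n_true:]]
    n_decoys = min(spec.n_decoys, len(decoy_pool))
    decoy_pairs = decoy_pool[:n_decoys]

    truth = nx.Graph()
    by_source: dict[str, list[InteractionRecord]] = {s: [] for s in spec.source_ids}
    for a, b in true_pairs:
        truth.add_edge(a, b, support=2)
        forced = rng.choice(spec.n_sources, size=2, replace=False)
        emit = set(forced.tolist())
        for i in range(spec.n_sources):
            if i not in emit and rng.random() < spec.p_emit:
                emit.add(i)
        truth[a][b]["support"] = len(emit)
        for i in emit:
            # randomize record orientation: pairs are unordered
            if rng.random() < 0.5:
                a, b = b, a
            by_source[spec.source_ids[i]].append(
                InteractionRecord(a, b, spec.source_ids[i])
            )
            a, b = tuple(sorted((a, b)))
    for a, b in decoy_pairs:
        i = int(rng.integers(spec.n_sources))
        by_source[spec.source_ids[i]].append(
            InteractionRecord(a, b, spec.source_ids[i])
        )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for source, records in by_source.items():
            lines = [f"{r.gene_a}\t{r.gene_b}" for r in records]
            (outdir / f"{source}.tsv").write_text("\n".join(lines) + "\n")
    return by_source, ConsensusNetwork(truth, min_sources=2)


def generate_hierarchical_scale_free(
    n: int, m: int = 3, triad_prob: float = 0.8, seed: int = 0
) -> nx.Graph:
    """Growing network with preferential attachment and triad closure.

    Each new node makes ``m`` connections: the first by degree-
    proportional preferential attachment; each subsequent one, with
    probability ``triad_prob``, closes a triangle through a random
    neighbor of the previous target (otherwise preferential attachment
    again).  Triad closure yields a clustering curve C(k) that decays
    with k, the signature of hierarchical scale-free organization.
    With m=1 the result is a tree (no triangle can close).
    """
    if not n > m >= 1:
        raise ValueError("need n > m >= 1")
    if not 0 <= triad_prob <= 1:
        raise ValueError("triad_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    g = nx.complete_graph(m + 1)
    # repeated-nodes list: node i appears degree(i) times
    repeated = [v for v, d in g.degree() for _ in range(d)]
    for new in range(m + 1, n):
        targets: list[int] = []
        prev = None
        while len(targets) < m:
            if prev is not None and rng.random() < triad_prob:
                candidates = [u for u in g[prev] if u != new and u not in targets]
                if candidates:
                    choice = candidates[int(rng.integers(len(candidates)))]
                else:
                    choice = repeated[int(rng.integers(len(repeated)))]
            else:
                choice = repeated[int(rng.integers(len(repeated)))]
            if choice != new and choice not in targets:
                targets.append(choice)
                prev = choice
        for t in targets:
            g.add_edge(new, t)
            repeated.extend([new, t])
    return nx.relabel_nodes(g, {i: f"G{i + 1:04d}" for i in g.nodes})


def generate_planted_complexes(
    n_background: int,
    bg_density: float,
    complexes: list[tuple[int, float]],
    seed: int = 0,
) -> tuple[nx.Graph, dict[str, set[str]]]:
    """Dense blocks planted on a sparse Erdos–Renyi background.

    ``complexes`` is a list of (size, internal density); blocks occupy
    disjoint node ranges at the front of the node list.  Returns the
    graph and a plant map ``{"plant_1": members, ...}``.
    """
    if any(size < 3 for size, _ in complexes):
        raise ValueError("planted complex sizes must be >= 3")
    if sum(size for size, _ in complexes) > n_background:
        raise ValueError("planted blocks exceed the node budget")
    rng = np.random.default_rng(seed)
    genes = _gene_names(n_background)
    g = nx.Graph()
    g.add_nodes_from(genes)
    for a, b in itertools.combinations(genes, 2):
        if rng.random() < bg_density:
            g.add_edge(a, b)

    plant_map: dict[str, set[str]] = {}
    offset = 0
    for idx, (size, density) in enumerate(complexes, 1):
        members = genes[offset : offset + size]
        offset += size
        pairs = list(itertools.combinations(members, 2))
        n_internal = int(round(density * len(pairs)))
        # spanning cycle first so the plant is connected, then random fill
        chosen: set[tuple[str, str]] = set()
        for i in range(size):
            a, b = members[i], members[(i + 1) % size]
            chosen.add(tuple(sorted((a, b))))
        remaining = [p for p in pairs if p not in chosen]
        extra = max(0, n_internal - len(chosen))
        pick = rng.permutation(len(remaining))[:extra]
        chosen.update(remaining[i] for i in pick)
        g.add_edges_from(chosen)
        plant_map[f"plant_{idx}"] = set(members)
    return g, plant_map


def generate_annotations(
    genes: list[str],
    target_genes: set[str],
    n_terms: int = 20,
    term_size: int = 15,
    coverage: float = 0.8,
    classes: dict[str, float] | None = None,
    diseases_per_gene: int = 10,
    seed: int = 0,
    gmt_path: str | Path | None = None,
    disease_path: str | Path | None = None,
) -> tuple[dict[str, tuple[str, frozenset[str]]], list[tuple[str, str, str]]]:
    """Term collection with one planted enriched term, plus disease table.

    The planted term (``TERM_PLANTED``) contains ``coverage`` of the
    designated target genes, topped up with background genes to
    ``term_size``; the other terms are uniform random draws.  Each gene
    gets ``diseases_per_gene`` distinct diseases whose classes follow
    the ``classes`` proportion mapping exactly (largest-remainder
    apportionment), default 60% / 40% over two classes.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    universe = set(genes)
    target = sorted(set(target_genes) & universe)
    if not target:
        raise ValueError("target_genes must intersect the universe")
    n_from_target = int(round(coverage * len(target)))
    if n_from_target > term_size:
        raise ValueError("coverage infeasible for term_size")

    terms: dict[str, tuple[str, frozenset[str]]] = {}
    pick = rng.permutation(len(target))[:n_from_target]
    planted = {target[i] for i in pick}
    background = [g for g in genes if g not in planted]
    fill = rng.permutation(len(background))[: term_size - len(planted)]
    planted.update(background[i] for i in fill)
    terms["TERM_PLANTED"] = ("planted enriched term", frozenset(planted))
    for t in range(1, n_terms):
        draw = rng.permutation(len(genes))[:term_size]
        terms[f"TERM_{t:03d}"] = (
            f"background term {t}",
            frozenset(genes[i] for i in draw),
        )

    if classes is None:
        classes = {"Neoplasms": 0.6, "Nervous System Diseases": 0.4}
    if abs(sum(classes.values()) - 1.0) > 1e-9:
        raise ValueError("class proportions must sum to 1")
    # largest-remainder apportionment of diseases_per_gene over classes
    quotas = {c: p * diseases_per_gene for c, p in classes.items()}
    counts = {c: int(q) for c, q in quotas.items()}
    leftover = diseases_per_gene - sum(counts.values())
    for c in sorted(quotas, key=lambda c: quotas[c] - counts[c], reverse=True)[
        :leftover
    ]:
        counts[c] += 1
    records: list[tuple[str, str, str]] = []
    for gene in genes:
        disease_no = 0
        for cls, k in counts.items():
            for _ in range(k):
                disease_no += 1
                records.append((gene, f"{gene}_D{disease_no:02d}", cls))

    if gmt_path is not None:
        lines = [
            "\t".join([term_id, name, *sorted(members)])
            for term_id, (name, members) in terms.items()
        ]
        Path(gmt_path).write_text("\n".join(lines) + "\n")
    if disease_path is not None:
        lines = ["\t".join([g, d, c, "1.0"]) for g, d, c in records]
        Path(disease_path).write_text("\n".join(lines) + "\n")
    return terms, records
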