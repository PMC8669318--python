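# Methods

`netkeys` analyses disease-associated protein–protein interaction (PPI)
networks to prioritize key genes. The pipeline has six stages; each is a
library module with a matching CLI subcommand.

## Consensus network construction

Interaction evidence for the same physical interaction is deposited
independently in several databases. Given per-source edge tables (plain TSV or
a minimal PSI-MITAB 2.5 subset), an unordered gene pair becomes an edge of the
consensus network iff it is reported by at least `min_sources` **distinct**
sources (default 2). Conventions where the procedure is otherwise
underdetermined:

* symbols are normalized by stripping whitespace and upper-casing; alias
  resolution happens only through a user-supplied two-column map (no
  algorithmic aliasing) and rejects chains, cycles and conflicts;
* duplicate records within one source count once toward support;
* self-loops are removed before support counting (all downstream centralities
  assume a simple graph);
* nodes with no surviving edge are dropped, so every reported node
  participates in the network.

Consensus is monotone in `min_sources`: raising the threshold can only remove
edges.

## Topology and power-law regimes

Per node we compute degree `k`, clustering coefficient
`C = 2m / (k(k-1))` (0 for `k < 2`), neighborhood connectivity `CN`
(mean neighbor degree), betweenness `C_B`, closeness `C_C` and eigenvector
`C_E` centralities.

* Betweenness is normalized by `(N-1)(N-2)/2` with endpoints excluded, so
  values lie in [0, 1].
* Closeness uses the within-component form `(n_c - 1) / Σ_j d_ij`. A global-N
  numerator is unbounded and ill-defined on disconnected graphs, so the
  component-wise convention is used and noted here as a deliberate choice.
* Eigenvector centrality is the nonnegative, unit-L2 principal eigenvector of
  the adjacency matrix, computed by power iteration on `A + I` (the shift
  breaks the ±λ oscillation of bipartite components) to tolerance 1e-10
  within 1000 iterations, on the largest connected component; other nodes get
  0. Tests verify `‖Av − λv‖∞ < 1e-8` and agreement with a dense
  eigendecomposition.

Each statistic is then averaged over nodes sharing a degree (arithmetic means,
no log binning; `k < 2` nodes excluded from the C(k) curve), and
`fit_power_law` regresses `log10(value)` on `log10(k)` by ordinary least
squares, reporting the positive decay exponent (−slope), its standard error,
the Pearson correlation `r` of the log-transformed points, and the fit range.
Degree bins with zero or negative values are excluded. For empirical degree
distributions the optional `min_count` argument drops bins estimated from
fewer than that many nodes: the sparse high-degree tail (many degrees observed
exactly once) otherwise flattens the regression and biases the exponent low —
on the synthetic hierarchical scale-free generator the full-tail fit reads
~1.9 while the well-populated bins give ~2.6. Default is `min_count=1`
(no restriction), matching regression on the raw curve.

The degree-distribution exponent γ classifies the regime: γ < 2 hierarchical/
modular (module-dominated organization), 2 ≤ γ ≤ 3 scale-free with integrated
hubs, γ > 3 hub-independent. Clauset-style maximum-likelihood fitting with KS
cutoff selection is deliberately not the analysis path: these PPIN analyses
use regression-style fits on the averaged curves, which is what the acceptance
surface exercises.

## Bottleneck-hubs and knockouts

Hubs are the top `floor(q·N)` nodes by degree, bottlenecks the top `floor(q·N)`
by betweenness (default `q = 0.01`; `floor` rather than `ceil` so a 1949-node
network yields 19, not 20). Boundary ties break by value descending then
symbol ascending, making the selection deterministic. The intersection is the
bottleneck-hub (Bn-H) set; set differences give hub-only and bottleneck-only
nodes.

Knockouts are single-node and independent: each removes one node from the
intact network, recomputes betweenness and the degree distribution on the
remainder, and summarizes the perturbation as mean/max |ΔC_B| over surviving
nodes, the component-count change, and the number of incident edges removed
(= the node's intact degree). The perturbation summary statistics are this
package's own quantitative definitions — the underlying centrality-lethality
analyses report "significant changes" qualitatively without a threshold — so
the screen ranks nodes by mean |ΔC_B| and makes no significance call.

## MCODE module detection

The Molecular Complex Detection algorithm is implemented in its three stages:

1. **Vertex weighting.** For node *v*, take the subgraph on *v* plus its
   neighbors, find its highest k-core, and set
   `weight(v) = k_max × density(core subgraph)`.
2. **Complex prediction.** Seeds are unvisited nodes in weight-descending,
   symbol-ascending order. From a seed, neighbors are admitted breadth-first
   while unvisited and `weight > seed_weight × (1 − node_score_cutoff)`
   (strict inequality, the original tool's convention), capped at `max_depth`
   hops. Admitted nodes are marked visited, so complexes are disjoint.
3. **Post-processing.** Complexes with no `k_core`-core (default k=2) are
   discarded. *Haircut* removes members with fewer than two internal
   neighbors, iterated to fixpoint (single-pass vs. fixpoint is unspecified in
   the classic description; fixpoint is chosen so haircut is idempotent).
   Optional *fluff* adds boundary nodes whose closed-neighborhood density
   exceeds `fluff_density_cutoff`; fluff defaults **off** (the original tool's
   default), keeping modules disjoint.

Defaults: `node_score_cutoff=0.2`, `haircut=on`, `fluff=off`,
`fluff_density_cutoff=0.1`, `k_core=2`, `max_depth=100`.

The M-score is internal density × size, `(2E/(n(n−1)))·n`, kept at full
precision; display truncates (not rounds) to two decimals, which is the only
convention consistent with published two-decimal scores such as 4.375 → 4.37
and 4.693 → 4.69. Module selection keeps scores strictly above `min_score`
(default 4), ordered by score, then size, then seed symbol.

## Crosstalk accounting

The interaction strength between a Bn-H and a module is the number of edges in
the **full consensus network** between the hub and module members. A hub that
is itself a module member contributes edges to other members only
(self-exclusion): published per-module counts for member hubs are edge counts,
not membership markers, and this convention reproduces them. Row totals over
modules rank mediator hubs; `common_connectors` additionally lists non-hub
nodes adjacent to at least k of the chosen hubs.

## Annotation and disease classes

Over-representation uses the hypergeometric upper tail
`P(X ≥ overlap)` with the consensus-network node set as the default universe;
every term is intersected with the universe before testing. Multiple testing
uses Benjamini–Hochberg (`statsmodels`); the proprietary ordering-based g:SCS
correction of the original web service is deliberately replaced by this
documented standard procedure. Significance defaults to adjusted p ≤ 0.05.

Disease-class profiles report, per gene, 100 × (distinct associated diseases
in a class) / (distinct associated diseases); a disease tagged with several
classes (semicolon-separated in the input TSV) counts once in each class's
numerator, so rows may sum above 100. The module-level profile pools the
union of the module's (gene, disease) pairs. Both granularities are emitted
because published per-class percentages mix the two. An optional fourth score
column in the records table supports a minimum-association-score filter;
no score weighting beyond that filter is applied.

## Synthetic data

The generators produce the statistical structure each stage assumes, seeded
and byte-deterministic (every generator is a pure function of its arguments
and seed, with its own `numpy` Generator — no global random state):

* **Multi-source interactome** — defaults: 150 genes, 5 sources, true-edge
  density 0.04, extra-source emission probability 0.5, 200 single-source
  decoys. Five sources and a ~150-gene seed list mirror the design of
  multi-database disease-interactome studies; density 0.04 gives a sparse
  but connected-scale network of a few hundred true edges. Every true edge is
  force-emitted into two distinct sources, so the ≥2-source consensus equals
  the planted truth **exactly** — recovery is a construction guarantee, not a
  probabilistic outcome, which keeps the recovery tests sharp.
* **Hierarchical scale-free graphs** — growth with degree-proportional
  preferential attachment; after the first link each further link closes a
  triangle through a neighbor of the previous target with probability
  `triad_prob` (default 0.8). This yields a heavy-tailed P(k) and a C(k)
  that decays with k. With m=1 the graph is a tree.
* **Planted complexes** — disjoint node blocks wired at a stated internal
  density (a spanning cycle first, so plants are connected, then random fill)
  over an Erdős–Rényi background (default density 0.02 against plant
  densities ≥ 0.8, the separation regime where dense-module detection is
  expected to work).
* **Annotations** — one planted GMT term covering a stated fraction
  (default 0.8) of a designated gene subset plus random background terms, and
  a gene–disease table whose per-gene class proportions are apportioned
  exactly (largest remainder), so profile percentages are generator-controlled
  constants.

What the generators do **not** emulate: database-specific confidence-score
distributions, MITAB evidence codes, study-bias in annotation coverage, and
the size/degree correlations of real interactomes. Passing tests therefore
demonstrate algorithmic correctness under controlled structure, not
recovery performance on any particular real database snapshot — published
networks built from live database versions are not reproducible from a fixed
artifact, which is why printed worked-example tables (hub/bottleneck
rankings, module statistics, crosstalk counts) stand in as fixed inputs for
the selection, scoring and accounting logic.

## Problem sizes

Test and verification runs use desk-scale inputs chosen to exercise each
property: 50–150-gene interactomes, 100–150-node planted-complex graphs,
5000-node scale-free growth for exponent checks, and exhaustive brute-force
oracles on graphs of ≤ 20 nodes (≤ 10 for path-enumeration centrality
oracles, 200 random instances).

## Known limitations

* Betweenness recomputation per knockout is exact, not incremental; screens
  over thousands of nodes on large networks are O(nodes × N·E).
* Power-law exponents from OLS on raw curves are biased on sparse tails (see
  above); `min_count` mitigates but the regression approach is retained by
  design.
* Eigenvector centrality of components other than the largest is reported
  as 0 rather than computed per component.
* Confidence-score-based edge filtering (e.g. STRING combined scores) is out
  of scope; support counting is the only evidence filter.
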