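"""Topological statistics, degree-averaged curves and power-law regime fits.

Per-node statistics: degree ``k``, clustering coefficient ``C``,
neighborhood connectivity ``CN`` (mean neighbor degree), betweenness
``C_B``, closeness ``C_C`` and eigenvector ``C_E`` centralities.  Each
statistic is also averaged over nodes sharing a degree, producing curves
(P(k), C(k), CN(k), ...) whose log–log regression slope classifies the
network regime:

* exponent gamma < 2       -- hierarchical/modular organization
* 2 <= gamma <= 3          -- scale-free with integrated hubs
* gamma > 3                -- hub-independent, near-random behavior

Conventions: C = 0 for nodes of degree < 2; betweenness is normalized by
(N-1)(N-2)/2 so values lie in [0, 1]; closeness uses the within-component
form (n_c - 1) / sum of distances; eigenvector centrality is the
nonnegative, unit-L2-norm principal eigenvector of the adjacency matrix
of the largest connected component (other nodes get 0).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .consensus import ConsensusNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "DegreeCurve",
    "PowerLawFit",
    "degree_distribution",
    "clustering_coefficients",
    "neighborhood_connectivity",
    "betweenness",
    "closeness",
    "eigenvector",
    "compute_node_metrics",
    "degree_curves",
    "fit_power_law",
    "classify_regime",
]

METRIC_COLUMNS = ["k", "C", "CN", "C_B", "C_C", "C_E"]


def _graph(net: ConsensusNetwork | nx.Graph) -> nx.Graph:
    return net.graph if isinstance(net, ConsensusNetwork) else net


@dataclass
class DegreeCurve:
    """A statistic evaluated per degree value present in the graph.

    ``counts`` optionally records how many nodes contributed to each
    degree bin, so fits can exclude sparsely estimated tail bins.
    """

    degrees: np.ndarray
    values: np.ndarray
    name: str = ""
    counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.degrees = np.asarray(self.degrees, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.degrees) != len(self.values):
            raise ValueError("degrees and values must be equal length")
        if np.any(np.diff(self.degrees) <= 0):
            raise ValueError("degrees must be strictly increasing")
        if self.counts is not None:
            self.counts = np.asarray(self.counts, dtype=int)
            if len(self.counts) != len(self.degrees):
                raise ValueError("counts must match degrees in length")

    def __len__(self) -> int:
        return len(self.degrees)


@dataclass
class PowerLawFit:
    """OLS fit of log10(value) on log10(degree).

    ``exponent`` is the positive decay exponent (minus the fitted slope);
    ``r`` the Pearson correlation of the log-transformed points;
    ``stderr`` the standard error of the slope.
    """

    exponent: float
    stderr: float
    r: float
    n_points: int
    fit_range: tuple[int, int]


def degree_distribution(net: ConsensusNetwork | nx.Graph) -> DegreeCurve:
    """P(k) = N_k / N over the degrees present; values sum to 1."""
    g = _graph(net)
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    degs = np.array([d for _, d in g.degree()])
    ks, counts = np.unique(degs, return_counts=True)
    return DegreeCurve(ks, counts / len(degs), name="P(k)", counts=counts)


def clustering_coefficients(
    net: ConsensusNetwork | nx.Graph,
) -> tuple[dict[str, float], DegreeCurve]:
    """Per-node clustering C_i = 2 m_i / (k_i (k_i - 1)) and its C(k) curve.

    Nodes with k < 2 have C = 0 in the per-node output and are excluded
    from the degree-averaged curve (C is undefined there).
    """
    g = _graph(net)
    per_node = nx.clustering(g)
    per_node = {v: float(c) for v, c in per_node.items()}
    curve = _degree_average(g, per_node, min_degree=2, name="C(k)")
    return per_node, curve


def neighborhood_connectivity(
    net: ConsensusNetwork | nx.Graph,
) -> tuple[dict[str, float], DegreeCurve]:
    """Mean degree of each node's neighbors, per node and per degree.

    The degree-averaged curve CN(k) equals sum_q q P(q|k), the expected
    neighbor degree conditioned on the node's own degree.
    """
    g = _graph(net)
    per_node = {}
    for v in g:
        nbrs = list(g[v])
        if not nbrs:
            continue  # isolated: CN undefined, excluded
        per_node[v] = float(np.mean([g.degree(u) for u in nbrs]))
    curve = _degree_average(g, per_node, min_degree=1, name="CN(k)")
    return per_node, curve


def betweenness(net: ConsensusNetwork | nx.Graph) -> dict[str, float]:
    """Betweenness centrality normalized by (N-1)(N-2)/2, endpoints excluded."""
    g = _graph(net)
    return {v: float(b) for v, b in nx.betweenness_centrality(g, normalized=True).items()}


def closeness(net: ConsensusNetwork | nx.Graph) -> dict[str, float]:
    """Within-component closeness (n_c - 1) / sum_j d_ij; singletons get 0."""
    g = _graph(net)
    vals = nx.closeness_centrality(g, wf_improved=False)
    singletons = [v for v in g if g.degree(v) == 0]
    if singletons:
        warnings.warn(f"{len(singletons)} singleton nodes: closeness set to 0")
    return {v: float(c) for v, c in vals.items()}


def eigenvector(
    net: ConsensusNetwork | nx.Graph,
    tol: float = 1e-10,
    max_iter: int = 1000,
) -> dict[str, float]:
    """Principal adjacency eigenvector via shifted power iteration.

    Solves A v = lambda v on the largest connected component with
    nonnegative entries and unit L2 norm; iterating on (A + I) breaks the
    +/-lambda oscillation of bipartite components.  Nodes outside the
    largest component get 0 with a warning.
    """
    g = _graph(net)
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    components = list(nx.connected_components(g))
    giant = max(components, key=len)
    if len(components) > 1:
        warnings.warn(
            "graph is disconnected: eigenvector centrality computed on the "
            "largest component; other nodes set to 0"
        )
    sub = g.subgraph(giant)
    order = list(sub.nodes)
    a = nx.to_numpy_array(sub, nodelist=order)
    n = len(order)
    v = np.ones(n) / np.sqrt(n)
    for _ in range(max_iter):
        w = a @ v + v  # (A + I) v
        w_norm = np.linalg.norm(w)
        if w_norm == 0:
            break
        w /= w_norm
        if np.linalg.norm(w - v, ord=np.inf) < tol:
            v = w
            break
        v = w
    else:
        lam = float(v @ (a @ v))
        residual = float(np.linalg.norm(a @ v - lam * v, ord=np.inf))
        raise RuntimeError(
            f"eigenvector iteration did not converge: residual {residual:.3e}"
        )
    v = np.abs(v)
    v /= np.linalg.norm(v)
    result = {node: 0.0 for node in g}
    result.update({node: float(x) for node, x in zip(order, v)})
    return result


def compute_node_metrics(net: ConsensusNetwork | nx.Graph) -> pd.DataFrame:
    """All six per-node statistics as a DataFrame indexed by symbol.

    Columns: k, C, CN, C_B, C_C, C_E.
    """
    g = _graph(net)
    clustering, _ = clustering_coefficients(g)
    cn, _ = neighborhood_connectivity(g)
    df = pd.DataFrame(
        {
            "k": dict(g.degree()),
            "C": clustering,
            "CN": cn,
            "C_B": betweenness(g),
            "C_C": closeness(g),
            "C_E": eigenvector(g),
        }
    )
    df.index.name = "node"
    return df[METRIC_COLUMNS].fillna(0.0)


def _degree_average(
    g: nx.Graph, per_node: dict[str, float], min_degree: int, name: str
) -> DegreeCurve:
    by_degree: dict[int, list[float]] = {}
    for v, value in per_node.items():
        k = g.degree(v)
        if k >= min_degree:
            by_degree.setdefault(k, []).append(value)
    ks = sorted(by_degree)
    return DegreeCurve(
        np.array(ks),
        np.array([np.mean(by_degree[k]) for k in ks]),
        name=name,
        counts=np.array([len(by_degree[k]) for k in ks]),
    )


def degree_curves(
    net: ConsensusNetwork | nx.Graph, metrics: pd.DataFrame | None = None
) -> dict[str, DegreeCurve]:
    """P(k) plus degree-averaged curves for C, CN, C_B, C_C and C_E."""
    g = _graph(net)
    if metrics is None:
        metrics = compute_node_metrics(g)
    curves = {"P(k)": degree_distribution(g)}
    for column, min_k in [("C", 2), ("CN", 1), ("C_B", 1), ("C_C", 1), ("C_E", 1)]:
        per_node = metrics[column].to_dict()
        curves[column] = _degree_average(g, per_node, min_degree=min_k, name=column)
    return curves


def fit_power_law(
    curve: DegreeCurve, min_degree: int = 1, min_count: int = 1
) -> PowerLawFit:
    """Fit value ~ k^-exponent by OLS on log10–log10 axes.

    Only points with degree >= ``min_degree`` and strictly positive value
    enter the fit; at least 3 such points are required.  When the curve
    carries per-bin node counts, ``min_count`` drops degree bins
    estimated from fewer nodes: the sparse high-degree tail of an
    empirical P(k) (many degrees seen exactly once) otherwise flattens
    the regression and biases the exponent low.
    """
    mask = (curve.degrees >= min_degree) & (curve.values > 0)
    if min_count > 1 and curve.counts is not None:
        mask &= curve.counts >= min_count
    ks = curve.degrees[mask]
    vals = curve.values[mask]
    if len(ks) < 3:
        raise ValueError(
            f"power-law fit needs >= 3 usable points, got {len(ks)}"
        )
    x = np.log10(ks.astype(float))
    y = np.log10(vals)
    if np.allclose(y, y[0]):
        # constant curve: slope 0 exactly, correlation undefined -> 0
        return PowerLawFit(0.0, 0.0, 0.0, len(ks), (int(ks[0]), int(ks[-1])))
    fit = stats.linregress(x, y)
    return PowerLawFit(
        exponent=float(-fit.slope),
        stderr=float(fit.stderr),
        r=float(fit.rvalue),
        n_points=len(ks),
        fit_range=(int(ks[0]), int(ks[-1])),
    )


def classify_regime(gamma: float) -> str:
    """Regime label from the degree-distribution decay exponent."""
    if not np.isfinite(gamma):
        raise ValueError("gamma must be finite")
    if gamma < 2:
        return "hierarchical/modular"
    if gamma <= 3:
        return "scale-free (hub-integrated)"
    return "hub-independent"
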