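"""Published worked-example tables from a human ALS interactome study.

A 1949-node, 13087-edge consensus protein-interaction network built for
amyotrophic lateral sclerosis reported its top-1% rankings and module
statistics; those printed tables serve here as fixed reference inputs
for exercising the selection, scoring and crosstalk machinery without
re-deriving the (database-version-dependent) network itself.

Contents: the 19 highest-degree nodes (hubs) with degrees, the 19
highest-betweenness nodes (bottlenecks) with centralities, the
(n, edges) statistics of the five top-scoring MCODE modules, and the
17 bottleneck-hub x 5 module interaction-strength matrix.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "ALS_NETWORK_SIZE",
    "HUBS",
    "BOTTLENECKS",
    "MODULE_STATS",
    "CROSSTALK_COUNTS",
    "crosstalk_table",
]

#: (nodes, edges) of the published consensus network
ALS_NETWORK_SIZE = (1949, 13087)

#: top 1% by degree: symbol -> degree, rank order as printed
HUBS: dict[str, int] = {
    "TP53": 236,
    "SOD1": 211,
    "CDC5L": 186,
    "SNW1": 173,
    "VCP": 172,
    "AR": 171,
    "DLD": 155,
    "DISC1": 148,
    "NEK4": 138,
    "HSP90AA1": 128,
    "EGFR": 125,
    "DLST": 124,
    "PDHA1": 122,
    "ATXN1": 119,
    "HTT": 117,
    "SQSTM1": 117,
    "APP": 114,
    "PSEN1": 110,
    "EP300": 108,
}

#: top 1% by betweenness centrality: symbol -> C_B, rank order as printed
BOTTLENECKS: dict[str, float] = {
    "VCP": 0.06587026,
    "TP53": 0.06480069,
    "SOD1": 0.0560067,
    "AR": 0.05264571,
    "DISC1": 0.05158762,
    "ATXN1": 0.04441985,
    "SQSTM1": 0.03839771,
    "APP": 0.03540357,
    "CDC5L": 0.03374739,
    "PSEN1": 0.03306112,
    "EGFR": 0.03113805,
    "SNW1": 0.02913541,
    "HSP90AA1": 0.02680708,
    "HTT": 0.02414826,
    "DLD": 0.02369741,
    "PDHA1": 0.02203444,
    "NEK4": 0.02047508,
    "PARK7": 0.02043984,
    "MAPT": 0.01992754,
}

#: five top-scoring modules: module id -> (n nodes, internal edges)
MODULE_STATS: dict[int, tuple[int, int]] = {
    1: (11, 44),
    2: (41, 103),
    3: (15, 34),
    4: (76, 176),
    5: (65, 140),
}

#: bottleneck-hub -> per-module interaction strengths (modules 1..5)
CROSSTALK_COUNTS: dict[str, list[int]] = {
    "CDC5L": [3, 14, 2, 28, 13],
    "SNW1": [3, 13, 1, 26, 14],
    "TP53": [4, 9, 0, 22, 14],
    "NEK4": [0, 11, 0, 16, 9],
    "HSP90AA1": [1, 3, 0, 10, 15],
    "SOD1": [5, 4, 0, 5, 14],
    "EGFR": [1, 5, 0, 6, 13],
    "DLD": [4, 5, 0, 8, 8],
    "VCP": [5, 5, 0, 8, 5],
    "AR": [0, 4, 0, 6, 12],
    "PDHA1": [0, 3, 2, 5, 6],
    "ATXN1": [1, 4, 0, 2, 7],
    "PSEN1": [3, 4, 1, 5, 5],
    "DISC1": [0, 1, 0, 6, 4],
    "APP": [0, 3, 0, 5, 12],
    "SQSTM1": [1, 3, 0, 11, 5],
    "HTT": [4, 5, 0, 10, 13],
}


def crosstalk_table() -> pd.DataFrame:
    """Reference crosstalk counts as a DataFrame with a total column."""
    df = pd.DataFrame.from_dict(
        CROSSTALK_COUNTS,
        orient="index",
        columns=[f"module_{i}" for i in range(1, 6)],
    )
    df.index.name = "bnh"
    df["total"] = df.sum(axis=1)
    return df
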