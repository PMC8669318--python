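"""Over-representation analysis and disease-class profiling of modules.

Modules are tested against user-supplied term collections (GMT format,
e.g. Gene Ontology exports) with a hypergeometric upper-tail test and
Benjamini–Hochberg multiple-testing adjustment.  Disease-class profiles
summarize, per gene or per module, what percentage of associated
diseases fall in each disease class (e.g. MeSH categories).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "TermCollection",
    "read_gmt",
    "enrich",
    "read_disease_table",
    "disease_class_profile",
]


@dataclass
class TermCollection:
    """Named gene sets: term id -> (term name, genes)."""

    terms: dict[str, tuple[str, frozenset[str]]]
    namespace: str = ""

    def __len__(self) -> int:
        return len(self.terms)

    def genes(self, term_id: str) -> frozenset[str]:
        return self.terms[term_id][1]


def read_gmt(path: str | Path, namespace: str = "") -> TermCollection:
    """Parse a GMT file: ``term<TAB>description<TAB>gene1<TAB>gene2...``.

    Duplicate genes within a term collapse to a set; a line with fewer
    than 3 fields is an error naming the line.
    """
    terms: dict[str, tuple[str, frozenset[str]]] = {}
    lines = Path(path).read_text().splitlines()
    for lineno, line in enumerate(lines, 1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"GMT line {lineno}: expected >= 3 fields")
        term_id, name = parts[0], parts[1]
        genes = frozenset(g.strip().upper() for g in parts[2:] if g.strip())
        if not genes:
            raise ValueError(f"GMT line {lineno}: term {term_id!r} has no genes")
        if term_id in terms:
            raise ValueError(f"GMT line {lineno}: duplicate term id {term_id!r}")
        terms[term_id] = (name, genes)
    if not terms:
        raise ValueError(f"{path}: empty GMT file")
    return TermCollection(terms=terms, namespace=namespace)


def enrich(
    module_genes: set[str],
    terms: TermCollection,
    universe: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``module_genes`` in each term.

    Each term is intersected with the universe before testing.  The
    p-value is the upper tail P(X >= overlap) drawing ``len(module)``
    genes from ``len(universe)`` with ``len(term)`` successes;
    Benjamini–Hochberg adjusts across terms.  Rows sorted by adjusted p.
    """
    if not universe:
        raise ValueError("empty universe")
    if not module_genes:
        raise ValueError("empty module gene set")
    module = set(module_genes) & set(universe)
    if module != set(module_genes):
        logger.warning(
            "%d module genes outside the universe were dropped",
            len(set(module_genes)) - len(module),
        )
    if not module:
        raise ValueError("no module gene is in the universe")

    rows = []
    for term_id, (name, genes) in terms.terms.items():
        term_in_universe = genes & universe
        if not term_in_universe:
            continue
        overlap = len(module & term_in_universe)
        # P(X >= overlap), X ~ Hypergeom(M=|universe|, n=|term|, N=|module|)
        p = float(
            stats.hypergeom.sf(
                overlap - 1, len(universe), len(term_in_universe), len(module)
            )
        )
        rows.append(
            {
                "term_id": term_id,
                "term_name": name,
                "overlap": overlap,
                "module_size": len(module),
                "term_size": len(term_in_universe),
                "universe_size": len(universe),
                "p": min(p, 1.0),
            }
        )
    if not rows:
        raise ValueError("no term overlaps the universe")
    df = pd.DataFrame(rows)
    _, p_adj, _, _ = multipletests(df["p"], method="fdr_bh")
    df["p_adj"] = p_adj
    df["significant"] = df["p_adj"] <= alpha
    return df.sort_values(["p_adj", "p", "term_id"]).reset_index(drop=True)


def read_disease_table(path: str | Path, min_score: float | None = None) -> pd.DataFrame:
    """Read a gene–disease–class TSV: gene, disease id, class(es)[, score].

    Multiple classes for one disease are semicolon-separated.  If a
    4th score column is present and ``min_score`` given, rows below the
    threshold are dropped.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["gene", "disease", "disease_class", "score"],
        usecols=[0, 1, 2, 3],
        dtype={0: str, 1: str, 2: str},
        engine="python",
    )
    df["gene"] = df["gene"].str.strip().str.upper()
    if min_score is not None and df["score"].notna().any():
        df = df[df["score"].fillna(1.0) >= min_score]
    if df.empty:
        raise ValueError(f"{path}: no usable gene–disease records")
    return df.reset_index(drop=True)


def disease_class_profile(
    genes: set[str], records: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Percentage of associated diseases per class, per gene and pooled.

    For each gene: 100 * (distinct associated diseases in a class) /
    (distinct associated diseases).  A disease tagged with several
    classes counts once in each class's numerator, so rows may sum above
    100.  The pooled (module-level) profile uses the union of the
    module's (gene, disease) pairs.  Genes with no records get an all-NaN
    row with a warning.
    """
    if records.empty:
        raise ValueError("empty gene–disease table")
    genes = {g.strip().upper() for g in genes}
    sub = records[records["gene"].isin(genes)]
    if sub.empty:
        raise ValueError("no queried gene has disease records")

    def split_classes(value: str) -> list[str]:
        return [c.strip() for c in str(value).split(";") if c.strip()]

    all_classes = sorted(
        {c for value in sub["disease_class"] for c in split_classes(value)}
    )

    def profile(frame: pd.DataFrame) -> dict[str, float]:
        # class membership per distinct (gene, disease) pair
        classes_by_disease: dict[tuple[str, str], set[str]] = {}
        for gene, disease, value in zip(
            frame["gene"], frame["disease"], frame["disease_class"]
        ):
            classes_by_disease.setdefault((gene, disease), set()).update(
                split_classes(value)
            )
        total = len(classes_by_disease)
        return {
            cls: 100.0
            * sum(1 for cs in classes_by_disease.values() if cls in cs)
            / total
            for cls in all_classes
        }

    per_gene = pd.DataFrame(index=sorted(genes), columns=all_classes, dtype=float)
    per_gene.index.name = "gene"
    missing = []
    for gene in sorted(genes):
        frame = sub[sub["gene"] == gene]
        if frame.empty:
            missing.append(gene)
            continue
        for cls, pct in profile(frame).items():
            per_gene.loc[gene, cls] = pct
    if missing:
        logger.warning("genes without disease records: %s", ", ".join(missing))

    module_profile = pd.Series(profile(sub), name="module")
    return per_gene, module_profile
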