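"""Over-representation analysis against annotation term sets.

A query gene list is tested per term with the hypergeometric upper tail
(Fisher's one-sided test): with N universe genes, K of them in the term,
and a query of n genes of which k hit the term,

    p = sum_{i=k}^{min(K, n)} C(K, i) C(N-K, n-i) / C(N, n).

Significant terms (raw p below alpha, mirroring the screening rule of the
upstream workflow) are ranked ascending by p; adjusted p-values are
computed within each category and reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

__all__ = ["AnnotationCollection", "hypergeom_tail", "enrich", "read_annotations"]

CATEGORIES = ("BP", "CC", "MF", "pathway")


@dataclass
class AnnotationCollection:
    """term_id -> (term_name, category, gene set); unique ids, non-empty sets."""

    terms: dict[str, tuple[str, str, frozenset[str]]] = field(default_factory=dict)

    def add(self, term_id: str, term_name: str, category: str, genes) -> None:
        if term_id in self.terms:
            raise ValueError(f"duplicate term id {term_id}")
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        genes = frozenset(genes)
        if not genes:
            raise ValueError(f"term {term_id} has an empty gene set")
        self.terms[term_id] = (term_name, category, genes)

    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for _, _, genes in self.terms.values():
            out |= genes
        return out


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= k)."""
    if not (0 <= k <= min(K, n) and k <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric arguments k={k}, K={K}, n={n}, N={N}")
    # sf(k-1) = P(X >= k); scipy's parametrization is (M=N, n=K, N=n)
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    query,
    collection: AnnotationCollection,
    universe=None,
    alpha: float = 0.05,
    top_k: int = 15,
) -> pd.DataFrame:
    """Rank annotation terms over-represented in a query gene set.

    The universe defaults to all genes in the collection.  Query genes
    outside the universe are dropped with a warning.  One row per term with
    at least one query hit; BH adjustment within each category; rows with
    raw p < alpha retained, ranked ascending by p (ties: larger k, then
    term id), and truncated to ``top_k`` per category.
    """
    query = set(query)
    if universe is None:
        universe = collection.all_genes()
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    outside = query - universe
    if outside:
        warnings.warn(
            f"{len(outside)} query genes outside the universe were dropped", stacklevel=2
        )
    query &= universe
    N = len(universe)
    n = len(query)

    rows = []
    for term_id, (term_name, category, genes) in collection.terms.items():
        genes_in_universe = genes & universe
        K = len(genes_in_universe)
        k = len(genes_in_universe & query)
        if k < 1:
            continue
        p = hypergeom_tail(k, K, n, N)
        rows.append((term_id, term_name, category, k, K, n, N, k / n if n else 0.0, p))
    df = pd.DataFrame(
        rows,
        columns=["term_id", "term_name", "category", "k", "K", "n", "N", "gene_ratio", "p_value"],
    )
    if df.empty:
        df["adj_p"] = pd.Series(dtype=float)
        return df
    df["adj_p"] = 0.0
    for category in df["category"].unique():
        mask = df["category"] == category
        df.loc[mask, "adj_p"] = bh_adjust(df.loc[mask, "p_value"].to_numpy())
    df = df[df["p_value"] < alpha]
    df = df.sort_values(
        ["p_value", "k", "term_id"], ascending=[True, False, True], kind="mergesort"
    )
    df = df.groupby("category", group_keys=False, sort=False).head(top_k)
    return df.reset_index(drop=True)


def read_annotations(path) -> AnnotationCollection:
    """Annotation TSV: term_id, term_name, category, gene_id (one row per membership)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    collection = AnnotationCollection()
    for (term_id, term_name, category), group in df.groupby(
        ["term_id", "term_name", "category"], sort=True
    ):
        collection.add(term_id, term_name, category, group["gene_id"])
    return collection


def write_annotations(collection: AnnotationCollection, path) -> None:
    rows = [
        (term_id, name, category, gene)
        for term_id, (name, category, genes) in sorted(collection.terms.items())
        for gene in sorted(genes)
    ]
    pd.DataFrame(rows, columns=["term_id", "term_name", "category", "gene_id"]).to_csv(
        path, sep="\t", index=False
    )
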