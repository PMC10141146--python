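"""Hypergeometric over-representation analysis of gene sets against flat
GO/KEGG-style term annotations, with Benjamini-Hochberg correction.

The background defaults to all annotated-universe genes supplied by the
caller (in the pipeline: all genes with expression in at least one sample).
No term-graph propagation is performed; annotations are flat gene->term
sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from lncmolt.expression_de import bh_adjust


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    term_name: str
    N: int  # background size
    M: int  # background genes carrying the term
    n: int  # query size
    k: int  # query genes carrying the term
    p_value: float
    fdr: float = float("nan")

    @property
    def fold_enrichment(self) -> float:
        return (self.k / self.n) / (self.M / self.N)


def hypergeom_pvalue(N: int, M: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, M, n).

    N: population, M: successes in population, n: draws, k: observed
    successes. Computed via the survival function in log-stable form.
    """
    if not (0 <= M <= N and 0 <= n <= N and 0 <= k <= min(M, n)):
        raise ValueError(f"invalid hypergeometric parameters N={N} M={M} n={n} k={k}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, M, n))


def enrich(
    query_genes: set[str] | list[str],
    annotation: pd.DataFrame,
    background: set[str] | list[str],
) -> pd.DataFrame:
    """Term over-representation of ``query_genes`` within ``background``.

    ``annotation`` has columns gene_id, term_id, term_name. Genes absent from
    the annotation count toward N (and n) but belong to no term. One result
    row per term with k >= 1, BH-adjusted, sorted by p ascending.
    """
    background = set(background)
    query = set(query_genes) & background
    if set(query_genes) - background:
        raise ValueError("query genes must be a subset of the background")
    if not query:
        warnings.warn("empty query gene set; no enrichment computed", stacklevel=2)
        return _empty_table()
    ann = annotation[annotation["gene_id"].isin(background)]
    N, n = len(background), len(query)
    rows = []
    for (term_id, term_name), grp in ann.groupby(["term_id", "term_name"], sort=True):
        genes = set(grp["gene_id"])
        M = len(genes)
        k = len(genes & query)
        if k == 0:
            continue
        rows.append(
            EnrichmentResult(
                str(term_id), str(term_name), N, M, n, k, hypergeom_pvalue(N, M, n, k)
            )
        )
    if not rows:
        return _empty_table()
    df = pd.DataFrame(
        {
            "term_id": [r.term_id for r in rows],
            "term_name": [r.term_name for r in rows],
            "N": [r.N for r in rows],
            "M": [r.M for r in rows],
            "n": [r.n for r in rows],
            "k": [r.k for r in rows],
            "fold_enrichment": [r.fold_enrichment for r in rows],
            "p_value": [r.p_value for r in rows],
        }
    )
    df["fdr"] = bh_adjust(df["p_value"].to_numpy())
    return df.sort_values(["p_value", "term_id"], kind="stable").reset_index(drop=True)


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["term_id", "term_name", "N", "M", "n", "k", "fold_enrichment", "p_value", "fdr"]
    )
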