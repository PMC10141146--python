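"""cis/trans lncRNA target prediction and co-expression network construction.

cis targets: protein-coding genes whose spans overlap or lie within 10 kb
(boundary-inclusive) of the lncRNA locus span, either direction,
strand-agnostic. trans targets: coding genes whose log2(FPKM+1) expression
correlates with the lncRNA's across all samples with |r| strictly greater
than 0.95. The co-expression network joins differentially expressed lncRNAs
and mRNAs at the stricter |r| > 0.98 cutoff; hubs are the highest-degree
nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from lncmolt.genome_model import GenomeAnnotation, TranscriptModel, genomic_gap


@dataclass(frozen=True)
class TargetEdge:
    lncrna_id: str
    mrna_gene_id: str
    mode: str  # cis | trans | both
    r: float = float("nan")
    distance: float = float("nan")


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; NaN sentinel for zero-variance input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 samples")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        return float("nan")
    return float((xc * yc).sum() / denom)


def cis_targets(
    lnc: TranscriptModel, ref: GenomeAnnotation, window: int = 10_000
) -> list[TargetEdge]:
    """Coding genes within ``window`` bp of the lncRNA locus (inclusive)."""
    edges = []
    for g in ref.within(lnc.chrom, lnc.span, window):
        if not g.is_protein_coding:
            continue
        gap = genomic_gap(lnc.span, g.span)
        if gap <= window:
            edges.append(TargetEdge(lnc.transcript_id, g.gene_id, "cis", distance=gap))
    return sorted(edges, key=lambda e: (e.distance, e.mrna_gene_id))


def trans_targets(
    lnc_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    threshold: float = 0.95,
) -> list[TargetEdge]:
    """All lncRNA x coding-gene pairs with |Pearson r| strictly > threshold.

    Expression tables are transcripts/genes x samples over the same sample
    columns; the caller chooses the transform (log2(FPKM+1) by default in the
    pipeline). Zero-variance series are skipped with a warning.
    """
    if list(lnc_expr.columns) != list(mrna_expr.columns):
        raise ValueError("expression tables must share the same sample columns")
    edges = []
    n_skipped = 0
    lnc_arr = lnc_expr.to_numpy(dtype=float)
    mrna_arr = mrna_expr.to_numpy(dtype=float)
    # series that are flat to within float rounding carry no signal; their
    # "correlations" would be artifacts of last-ulp noise
    flat_tol = 1e-9
    lnc_sd = lnc_arr.std(axis=1)
    mrna_sd = mrna_arr.std(axis=1)
    lnc_sd = np.where(lnc_sd <= flat_tol, 0.0, lnc_sd)
    mrna_sd = np.where(mrna_sd <= flat_tol, 0.0, mrna_sd)
    n_skipped = int((lnc_sd == 0).sum() + (mrna_sd == 0).sum())
    if n_skipped:
        warnings.warn(
            f"skipped {n_skipped} zero-variance expression series", stacklevel=2
        )
    lnc_ok = lnc_sd > 0
    mrna_ok = mrna_sd > 0
    lz = (lnc_arr[lnc_ok] - lnc_arr[lnc_ok].mean(axis=1, keepdims=True)) / (
        lnc_sd[lnc_ok, None] * np.sqrt(lnc_arr.shape[1])
    )
    mz = (mrna_arr[mrna_ok] - mrna_arr[mrna_ok].mean(axis=1, keepdims=True)) / (
        mrna_sd[mrna_ok, None] * np.sqrt(mrna_arr.shape[1])
    )
    corr = lz @ mz.T
    lnc_ids = lnc_expr.index[lnc_ok]
    mrna_ids = mrna_expr.index[mrna_ok]
    hit_i, hit_j = np.nonzero(np.abs(corr) > threshold)
    for i, j in zip(hit_i, hit_j):
        edges.append(
            TargetEdge(str(lnc_ids[i]), str(mrna_ids[j]), "trans", r=float(corr[i, j]))
        )
    return edges


def combine_targets(
    cis_edges: list[TargetEdge], trans_edges: list[TargetEdge]
) -> list[TargetEdge]:
    """Merge cis and trans predictions; pairs found by both get mode ``both``."""
    cis_map = {(e.lncrna_id, e.mrna_gene_id): e for e in cis_edges}
    trans_map = {(e.lncrna_id, e.mrna_gene_id): e for e in trans_edges}
    out = []
    for key in sorted(set(cis_map) | set(trans_map)):
        c, t = cis_map.get(key), trans_map.get(key)
        if c and t:
            out.append(TargetEdge(key[0], key[1], "both", r=t.r, distance=c.distance))
        elif c:
            out.append(c)
        else:
            out.append(t)
    return out


def build_network(
    de_lnc_expr: pd.DataFrame,
    de_mrna_expr: pd.DataFrame,
    threshold: float = 0.98,
) -> nx.Graph:
    """Undirected lncRNA-mRNA co-expression graph at |r| strictly > threshold.

    Nodes carry a ``biotype`` attribute ("lncRNA" or "mRNA"); edges carry the
    Pearson coefficient ``r``. An empty DE set yields an empty graph.
    """
    g = nx.Graph()
    for nid in de_lnc_expr.index:
        g.add_node(str(nid), biotype="lncRNA")
    for nid in de_mrna_expr.index:
        g.add_node(str(nid), biotype="mRNA")
    if len(de_lnc_expr) and len(de_mrna_expr):
        for e in trans_targets(de_lnc_expr, de_mrna_expr, threshold=threshold):
            if e.lncrna_id != e.mrna_gene_id:
                g.add_edge(e.lncrna_id, e.mrna_gene_id, r=e.r)
    return g


def hub_nodes(network: nx.Graph, top_k: int = 20) -> list[tuple[str, int]]:
    """Nodes ranked by degree descending, ties broken by node id ascending."""
    ranked = sorted(network.degree(), key=lambda kv: (-kv[1], kv[0]))
    return [(str(n), int(d)) for n, d in ranked[:top_k]]


def edges_table(edges: list[TargetEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "lncrna_id": [e.lncrna_id for e in edges],
            "gene_id": [e.mrna_gene_id for e in edges],
            "mode": [e.mode for e in edges],
            "r": [e.r for e in edges],
            "distance": [e.distance for e in edges],
        }
    )


def mode_summary(edges: list[TargetEdge]) -> dict[str, dict[str, int]]:
    """Pair counts and unique target-gene counts per prediction mode."""
    out: dict[str, dict[str, int]] = {}
    for mode in ("cis", "trans", "both"):
        sub = [e for e in edges if e.mode == mode]
        out[mode] = {
            "pairs": len(sub),
            "unique_genes": len({e.mrna_gene_id for e in sub}),
        }
    return out
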