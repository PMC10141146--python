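"""Shared helpers for the test suite."""
from __future__ import annotations

import numpy as np
import pytest

from lncmolt.genome_model import (
    GeneModel,
    GenomeAnnotation,
    TranscriptModel,
    annotation_from_transcripts,
)


def make_tx(
    tid: str,
    exons: list[tuple[int, int]],
    strand: str = "+",
    chrom: str = "chr1",
    gene_id: str | None = None,
    biotype: str = "unknown",
) -> TranscriptModel:
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gene_id or f"g_{tid}",
        chrom=chrom,
        strand=strand,
        exons=exons,
        biotype=biotype,
    )


def make_gene(
    gid: str,
    exons: list[tuple[int, int]],
    strand: str = "+",
    chrom: str = "chr1",
    coding: bool = True,
) -> GeneModel:
    t = make_tx(f"tx_{gid}", exons, strand, chrom, gene_id=gid,
                biotype="coding" if coding else "unknown")
    return GeneModel(gene_id=gid, chrom=chrom, strand=strand,
                     transcripts=[t], is_protein_coding=coding)


@pytest.fixture
def simple_annotation() -> GenomeAnnotation:
    """Two coding genes on chr1: one '+' with two exons, one '-' downstream."""
    return GenomeAnnotation(
        [
            make_gene("geneA", [(1000, 1500), (2000, 2600)], "+"),
            make_gene("geneB", [(10_000, 10_800), (11_500, 12_000)], "-"),
        ]
    )


def random_transcript(
    rng: np.random.Generator,
    chrom: str = "chr1",
    lo: int = 0,
    hi: int = 5000,
    max_exons: int = 3,
) -> TranscriptModel:
    """A random small multi-exon transcript for property tests."""
    n_exons = int(rng.integers(1, max_exons + 1))
    cuts = np.sort(rng.choice(np.arange(lo, hi), size=2 * n_exons, replace=False))
    exons = [(int(cuts[2 * i]), int(cuts[2 * i + 1])) for i in range(n_exons)]
    exons = [(s, e) for s, e in exons if s < e]
    if not exons:
        exons = [(lo, lo + 100)]
    strand = "+" if rng.random() < 0.5 else "-"
    tid = f"rand{int(rng.integers(0, 10**9))}"
    return make_tx(tid, exons, strand, chrom)


def random_annotation(rng: np.random.Generator, n_genes: int = 3) -> GenomeAnnotation:
    txs = []
    for i in range(n_genes):
        t = random_transcript(rng)
        txs.append(
            TranscriptModel(
                transcript_id=f"ref_t{i}_{t.transcript_id}",
                gene_id=f"ref_g{i}",
                chrom=t.chrom,
                strand=t.strand,
                exons=t.exons,
                biotype="coding",
            )
        )
    return annotation_from_transcripts(txs)
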