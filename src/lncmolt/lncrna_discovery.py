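"""lncRNA identification and positional classification.

A transcript is called a lncRNA when it (i) is novel relative to the
reference annotation (class code in {u, i, j, x, c, e, o}), (ii) is longer
than 200 nt, and (iii) lacks coding potential by the intersection of two
independent predictors: an ORF-length rule (longest ORF < 300 nt by default)
and a hexamer log-odds score (< 0, i.e. more noncoding-like than
coding-like). Called lncRNAs are then classified by their position and
orientation relative to protein-coding genes into intergenic, intronic,
sense, antisense, bidirectional, or a residual "other" class.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from lncmolt.genome_model import (
    GeneModel,
    GenomeAnnotation,
    TranscriptModel,
    genomic_gap,
    intervals_overlap,
    reverse_complement,
    transcript_length,
    tss,
)

logger = logging.getLogger(__name__)

NOVEL_CLASS_CODES = frozenset({"u", "i", "j", "x", "c", "e", "o"})

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


# --------------------------------------------------------------------------
# Novelty class codes
# --------------------------------------------------------------------------

def _exonic_overlap(a: TranscriptModel, b: TranscriptModel) -> bool:
    return any(
        intervals_overlap(ea, eb) for ea in a.exons for eb in b.exons
    )


def _contained_in_exon_chain(novel: TranscriptModel, ref: TranscriptModel) -> bool:
    """Every novel exon lies within some exon of the reference transcript."""
    return all(
        any(rs <= ns and ne <= re for rs, re in ref.exons) for ns, ne in novel.exons
    )


def assign_class_code(novel: TranscriptModel, ref: GenomeAnnotation) -> str:
    """Assign a Cuffcompare-style novelty class code to a transcript.

    Precedence (first matching rule wins):

    ``=``  exon chain identical to a reference transcript (same strand);
    ``c``  contained within a same-strand reference transcript's exon chain;
    ``j``  shares at least one splice junction with a same-strand reference
           transcript but is not identical;
    ``e``  single-exon transcript with same-strand exonic overlap;
    ``o``  any other same-strand exonic overlap;
    ``x``  exonic overlap on the opposite strand;
    ``i``  entirely within an intron of a reference transcript;
    ``u``  no overlap with any reference gene span;
    ``p``  anything else (span overlap without exonic/intronic relation).
    """
    candidates = ref.overlapping(novel.chrom, novel.span)
    ref_ts = [t for g in candidates for t in g.transcripts]
    same = [t for t in ref_ts if t.strand == novel.strand]
    opposite = [t for t in ref_ts if t.strand != novel.strand]

    for t in same:
        if t.exons == novel.exons:
            return "="
    for t in same:
        if _contained_in_exon_chain(novel, t):
            return "c"
    junctions = novel.splice_junctions()
    if junctions:
        for t in same:
            if junctions & t.splice_junctions():
                return "j"
    same_exonic = any(_exonic_overlap(novel, t) for t in same)
    if same_exonic and len(novel.exons) == 1:
        return "e"
    if same_exonic:
        return "o"
    if any(_exonic_overlap(novel, t) for t in opposite):
        return "x"
    for t in ref_ts:
        if any(
            i_s <= novel.span[0] and novel.span[1] <= i_e for i_s, i_e in t.introns
        ):
            return "i"
    if not candidates:
        return "u"
    return "p"


# --------------------------------------------------------------------------
# ORF finding
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class OrfResult:
    """Longest ATG-to-stop open reading frame over all six frames.

    ``length`` counts start through stop codon inclusive (a multiple of 3);
    it is 0 iff no complete ORF exists. ``start_pos`` is 0-based on the
    strand scanned (i.e. on the reverse complement for strand "-").
    """

    length: int = 0
    frame: int = 0
    strand: str = "+"
    start_pos: int = 0


def _longest_orf_one_strand(seq: str) -> OrfResult:
    best = OrfResult()
    n = len(seq)
    for frame in range(3):
        start: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if start is None:
                if codon == "ATG":
                    start = pos
            elif codon in STOP_CODONS:
                length = pos + 3 - start
                if length > best.length:
                    best = OrfResult(length, frame, "+", start)
                start = None
    return best


def longest_orf(seq: str) -> OrfResult:
    """Longest complete ORF over three frames on both strands."""
    seq = seq.upper()
    if len(seq) < 6:
        return OrfResult()
    fwd = _longest_orf_one_strand(seq)
    rev = _longest_orf_one_strand(reverse_complement(seq))
    if rev.length > fwd.length:
        return OrfResult(rev.length, rev.frame, "-", rev.start_pos)
    return fwd


def orf_subsequence(seq: str, orf: OrfResult) -> str:
    """The ORF nucleotide sequence (on the coding strand)."""
    seq = seq.upper()
    if orf.length == 0:
        return ""
    scanned = seq if orf.strand == "+" else reverse_complement(seq)
    return scanned[orf.start_pos : orf.start_pos + orf.length]


# --------------------------------------------------------------------------
# Hexamer log-odds coding-potential score
# --------------------------------------------------------------------------

_BASES = "ACGT"
_HEXAMERS = None


def _all_hexamers() -> list[str]:
    global _HEXAMERS
    if _HEXAMERS is None:
        from itertools import product

        _HEXAMERS = ["".join(p) for p in product(_BASES, repeat=6)]
    return _HEXAMERS


def _hexamer_counts(seqs: list[str], in_orf: bool) -> dict[str, int]:
    counts: dict[str, int] = {}
    for seq in seqs:
        seq = seq.upper()
        if in_orf:
            orf = longest_orf(seq)
            region = orf_subsequence(seq, orf) if orf.length >= 6 else seq
        else:
            region = seq
        for i in range(0, len(region) - 5, 3):
            hexamer = region[i : i + 6]
            if all(b in _BASES for b in hexamer):
                counts[hexamer] = counts.get(hexamer, 0) + 1
    return counts


def train_hexamer_table(
    coding_seqs: list[str], noncoding_seqs: list[str]
) -> dict[str, float]:
    """Train per-hexamer log-odds (coding vs noncoding) with add-one smoothing.

    Hexamers are counted in-frame (step 3) within the longest ORF of each
    training sequence, matching how the score is later evaluated.
    """
    if not coding_seqs or not noncoding_seqs:
        raise ValueError("both coding and noncoding training sequences are required")
    cod = _hexamer_counts(coding_seqs, in_orf=True)
    non = _hexamer_counts(noncoding_seqs, in_orf=True)
    n_cod = sum(cod.values()) + 4096
    n_non = sum(non.values()) + 4096
    table: dict[str, float] = {}
    for h in _all_hexamers():
        p_c = (cod.get(h, 0) + 1) / n_cod
        p_n = (non.get(h, 0) + 1) / n_non
        table[h] = math.log(p_c / p_n)
    return table


def hexamer_score(seq: str, table: dict[str, float] | None) -> float:
    """Mean per-hexamer log-odds over sliding windows (step 3) in the longest
    ORF, or over the whole sequence if the transcript has no complete ORF.
    Higher scores are more coding-like."""
    if table is None:
        raise ValueError(
            "hexamer table missing: call train_hexamer_table on labelled "
            "coding/noncoding sequences first"
        )
    seq = seq.upper()
    orf = longest_orf(seq)
    region = orf_subsequence(seq, orf) if orf.length >= 6 else seq
    scores = [
        table[region[i : i + 6]]
        for i in range(0, len(region) - 5, 3)
        if all(b in _BASES for b in region[i : i + 6])
    ]
    if not scores:
        return 0.0
    return float(np.mean(scores))


# --------------------------------------------------------------------------
# The lncRNA call
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CodingPotentialCall:
    """Consensus of the two coding-potential predictors.

    Predictor A flags a transcript noncoding when its longest ORF is shorter
    than the cutoff; predictor B when its hexamer log-odds score is below 0.
    The consensus requires both (the intersection of no-coding-potential
    calls).
    """

    predictor_a_noncoding: bool
    predictor_b_noncoding: bool

    @property
    def consensus_noncoding(self) -> bool:
        return self.predictor_a_noncoding and self.predictor_b_noncoding


def call_lncrnas(
    transcripts: list[TranscriptModel],
    ref: GenomeAnnotation,
    sequences: dict[str, str],
    hexamer_table: dict[str, float],
    min_length: int = 200,
    orf_cutoff: int = 300,
) -> tuple[list[TranscriptModel], dict[str, CodingPotentialCall], dict[str, str]]:
    """Identify lncRNAs among assembled transcripts.

    Returns the retained lncRNA transcripts (biotype set to ``lncRNA``),
    per-transcript coding-potential calls, and per-transcript class codes.
    Retention rule: novel class code, length strictly greater than
    ``min_length`` nt, and consensus noncoding.
    """
    lncrnas: list[TranscriptModel] = []
    calls: dict[str, CodingPotentialCall] = {}
    codes: dict[str, str] = {}
    for t in transcripts:
        codes[t.transcript_id] = assign_class_code(t, ref)
        seq = sequences.get(t.transcript_id)
        if seq is None:
            logger.warning(
                "transcript %s has no sequence; excluded from coding-potential "
                "assessment",
                t.transcript_id,
            )
            continue
        call = CodingPotentialCall(
            predictor_a_noncoding=longest_orf(seq).length < orf_cutoff,
            predictor_b_noncoding=hexamer_score(seq, hexamer_table) < 0,
        )
        calls[t.transcript_id] = call
        if (
            codes[t.transcript_id] in NOVEL_CLASS_CODES
            and transcript_length(t) > min_length
            and call.consensus_noncoding
        ):
            lncrnas.append(
                TranscriptModel(
                    transcript_id=t.transcript_id,
                    gene_id=t.gene_id,
                    chrom=t.chrom,
                    strand=t.strand,
                    exons=list(t.exons),
                    biotype="lncRNA",
                )
            )
    return lncrnas, calls, codes


# --------------------------------------------------------------------------
# Positional classification
# --------------------------------------------------------------------------

POSITIONAL_CLASSES = ("intergenic", "intronic", "sense", "antisense", "bidirectional", "other")


@dataclass(frozen=True)
class PositionalClass:
    cls: str
    anchor_gene_id: str = ""
    distance: float = math.inf

    def __post_init__(self) -> None:
        if self.cls not in POSITIONAL_CLASSES:
            raise ValueError(f"unknown positional class {self.cls!r}")


def _exon_overlap_with_gene(lnc: TranscriptModel, gene: GeneModel) -> bool:
    return any(
        intervals_overlap(le, ge)
        for le in lnc.exons
        for ge in gene.exon_intervals()
    )


def _within_one_intron(lnc: TranscriptModel, gene: GeneModel) -> bool:
    s, e = lnc.span
    return any(i_s <= s and e <= i_e for i_s, i_e in gene.intron_intervals())


def _divergent(lnc: TranscriptModel, gene: GeneModel, window: int) -> bool:
    """Opposite strands, TSSs within ``window`` bp, transcribed apart."""
    if lnc.strand == gene.strand:
        return False
    lnc_tss = lnc.span[0] if lnc.strand == "+" else lnc.span[1]
    gene_tss = tss(gene)
    if abs(lnc_tss - gene_tss) > window:
        return False
    if gene.strand == "+":
        return lnc_tss <= gene_tss  # lncRNA runs leftward away from the gene
    return lnc_tss >= gene_tss


def classify_lncrna_position(
    lnc: TranscriptModel,
    ref: GenomeAnnotation,
    bidirectional_window: int = 1000,
) -> PositionalClass:
    """Classify a lncRNA by position relative to protein-coding genes.

    Precedence: intronic (all exons within one intron of a coding gene),
    sense (same-strand exonic overlap), antisense (opposite-strand exonic
    overlap), bidirectional (no overlap; divergent TSS within the window),
    intergenic (no span overlap with any coding gene and not bidirectional),
    other (span overlap only, e.g. straddling an exon/intron boundary
    without exonic overlap).

    The class assignment is deterministic: candidate genes are examined in
    gene_id order, so permuting the annotation never changes a call.
    """
    overlapping = [
        g for g in ref.overlapping(lnc.chrom, lnc.span) if g.is_protein_coding
    ]
    for g in overlapping:
        if _within_one_intron(lnc, g):
            return PositionalClass("intronic", g.gene_id, 0)
    for g in overlapping:
        if g.strand == lnc.strand and _exon_overlap_with_gene(lnc, g):
            return PositionalClass("sense", g.gene_id, 0)
    for g in overlapping:
        if g.strand != lnc.strand and _exon_overlap_with_gene(lnc, g):
            return PositionalClass("antisense", g.gene_id, 0)
    if not overlapping:
        near = [
            g
            for g in ref.within(lnc.chrom, lnc.span, bidirectional_window)
            if g.is_protein_coding
        ]
        for g in near:
            if _divergent(lnc, g, bidirectional_window):
                return PositionalClass(
                    "bidirectional", g.gene_id, genomic_gap(lnc.span, g.span)
                )
        nearest_gene, gap = _nearest_coding(lnc, ref)
        del nearest_gene
        return PositionalClass("intergenic", "", gap)
    # span overlap exists but no exonic/intronic relation
    return PositionalClass("other", overlapping[0].gene_id, 0)


def _nearest_coding(lnc: TranscriptModel, ref: GenomeAnnotation) -> tuple[GeneModel | None, float]:
    best: GeneModel | None = None
    best_gap = math.inf
    for g in ref.coding_genes():
        if g.chrom != lnc.chrom:
            continue
        gap = genomic_gap(lnc.span, g.span)
        if gap < best_gap:
            best, best_gap = g, gap
    return best, best_gap


def classify_all(
    lncrnas: list[TranscriptModel],
    ref: GenomeAnnotation,
    bidirectional_window: int = 1000,
) -> dict[str, PositionalClass]:
    return {
        t.transcript_id: classify_lncrna_position(t, ref, bidirectional_window)
        for t in lncrnas
    }
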