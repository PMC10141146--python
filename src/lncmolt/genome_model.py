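"""Core genomic data types, interval arithmetic, and GTF/FASTA/BED I/O.

Internal coordinates are 0-based half-open throughout; GTF I/O converts
to/from the 1-based inclusive convention of the format. Chromosome names are
matched by exact string equality (no "chr" prefix normalisation).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from intervaltree import IntervalTree

Interval = tuple[int, int]

VALID_STRANDS = frozenset({"+", "-"})
VALID_BIOTYPES = frozenset({"coding", "lncRNA", "unknown"})


class StrandError(ValueError):
    """Raised for transcripts with unknown strand when strict mode is on."""


@dataclass
class TranscriptModel:
    """A stranded, exon-structured transcript on one chromosome.

    Exons are 0-based half-open ``[start, end)`` intervals, sorted ascending
    and non-overlapping; every interval satisfies ``start < end``.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    biotype: str = "unknown"

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise StrandError(
                f"transcript {self.transcript_id!r}: strand must be '+' or '-', "
                f"got {self.strand!r}"
            )
        if self.biotype not in VALID_BIOTYPES:
            raise ValueError(f"unknown biotype {self.biotype!r}")
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id!r} has no exons")
        self.exons = [(int(s), int(e)) for s, e in self.exons]
        for s, e in self.exons:
            if s >= e:
                raise ValueError(
                    f"transcript {self.transcript_id!r}: invalid exon [{s},{e})"
                )
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(
                    f"transcript {self.transcript_id!r}: exons overlap or are unsorted"
                )

    @property
    def span(self) -> Interval:
        """Bounding interval of the exon union (the transcript locus)."""
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def introns(self) -> list[Interval]:
        return [
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]) if s2 > e1
        ]

    def splice_junctions(self) -> set[Interval]:
        """Intron (donor, acceptor) coordinate pairs."""
        return set(self.introns)


def transcript_length(t: TranscriptModel) -> int:
    """Total exonic length in nucleotides (sum of exon lengths)."""
    return sum(e - s for s, e in t.exons)


def genomic_gap(a: Interval, b: Interval) -> int:
    """Distance in bp between two intervals on the same chromosome.

    0 if the intervals overlap or touch, else the distance between the
    nearest ends.
    """
    if a[0] > b[0]:
        a, b = b, a
    return max(0, b[0] - a[1])


def genomic_gap_stranded(chrom_a: str, a: Interval, chrom_b: str, b: Interval) -> float:
    """Like :func:`genomic_gap` but infinite across chromosomes."""
    if chrom_a != chrom_b:
        return math.inf
    return genomic_gap(a, b)


def intervals_overlap(a: Interval, b: Interval) -> bool:
    return a[0] < b[1] and b[0] < a[1]


@dataclass
class GeneModel:
    """A gene locus: a set of transcripts sharing a gene_id, chrom and strand."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)
    is_protein_coding: bool = False

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise StrandError(f"gene {self.gene_id!r}: strand {self.strand!r}")

    @property
    def span(self) -> Interval:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id!r} has no transcripts")
        return (
            min(t.span[0] for t in self.transcripts),
            max(t.span[1] for t in self.transcripts),
        )

    def exon_intervals(self) -> list[Interval]:
        out: list[Interval] = []
        for t in self.transcripts:
            out.extend(t.exons)
        return sorted(out)

    def intron_intervals(self) -> list[Interval]:
        out: list[Interval] = []
        for t in self.transcripts:
            out.extend(t.introns)
        return sorted(out)


def tss(g: GeneModel) -> int:
    """Strand-aware transcription start site: 5' end of the gene span."""
    s, e = g.span
    return s if g.strand == "+" else e


class GenomeAnnotation:
    """Genes indexed by chromosome with interval-tree overlap queries."""

    def __init__(self, genes: Iterable[GeneModel]):
        self.genes: dict[str, GeneModel] = {}
        self._trees: dict[str, IntervalTree] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            self.genes[g.gene_id] = g
            s, e = g.span
            self._trees.setdefault(g.chrom, IntervalTree()).addi(s, e, g.gene_id)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes.values())

    def transcripts(self) -> Iterator[TranscriptModel]:
        for g in self:
            yield from g.transcripts

    def coding_genes(self) -> list[GeneModel]:
        return [g for g in self if g.is_protein_coding]

    def overlapping(self, chrom: str, interval: Interval) -> list[GeneModel]:
        """Genes whose spans intersect ``interval`` on ``chrom``."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = tree.overlap(interval[0], interval[1])
        return sorted((self.genes[h.data] for h in hits), key=lambda g: g.gene_id)

    def within(self, chrom: str, interval: Interval, window: int) -> list[GeneModel]:
        """Genes whose spans overlap or lie within ``window`` bp of ``interval``.

        Boundary-inclusive: a gene at a gap of exactly ``window`` bp is
        returned (the half-open expanded query must extend one extra base on
        each side to capture touching spans).
        """
        return self.overlapping(
            chrom, (max(0, interval[0] - window - 1), interval[1] + window + 1)
        )

    def nearest(self, chrom: str, interval: Interval) -> tuple[GeneModel | None, float]:
        """Nearest gene by span gap on the same chromosome (scan; desk-scale)."""
        best: GeneModel | None = None
        best_gap = math.inf
        for g in self:
            if g.chrom != chrom:
                continue
            gap = genomic_gap(interval, g.span)
            if gap < best_gap or (gap == best_gap and best and g.gene_id < best.gene_id):
                best, best_gap = g, gap
        return best, best_gap


# --------------------------------------------------------------------------
# GTF I/O (attribute keys: gene_id, transcript_id; exon features carry the
# structure; optional transcript_biotype attribute round-trips the biotype)
# --------------------------------------------------------------------------

_BIOTYPE_OUT = {"coding": "protein_coding", "lncRNA": "lncRNA", "unknown": "unknown"}
_BIOTYPE_IN = {v: k for k, v in _BIOTYPE_OUT.items()}


def _parse_attributes(attr_field: str) -> dict[str, str]:
    attrs: dict[str, str] = {}
    for part in attr_field.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gtf(path: str, strict_strand: bool = True) -> list[TranscriptModel]:
    """Read transcripts from a GTF file (exon features only are required).

    GTF 1-based inclusive coordinates are converted to internal 0-based
    half-open. Transcripts on strand "." are rejected (classification is
    strand-dependent) unless ``strict_strand`` is False, in which case they
    are excluded with a warning.
    """
    exons: dict[str, list[Interval]] = {}
    meta: dict[str, dict[str, str]] = {}
    skipped: set[str] = set()
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise ValueError(f"malformed GTF line: {line!r}")
            chrom, _, feature, start, end, _, strand, _, attr_field = f
            if feature != "exon":
                continue
            attrs = _parse_attributes(attr_field)
            tid = attrs.get("transcript_id")
            if tid is None:
                raise ValueError("exon feature without transcript_id")
            if strand not in VALID_STRANDS:
                if strict_strand:
                    raise StrandError(
                        f"transcript {tid!r} has strand {strand!r}; strand is "
                        "required for positional classification"
                    )
                skipped.add(tid)
                continue
            exons.setdefault(tid, []).append((int(start) - 1, int(end)))
            meta[tid] = {
                "gene_id": attrs.get("gene_id", ""),
                "chrom": chrom,
                "strand": strand,
                "biotype": _BIOTYPE_IN.get(attrs.get("transcript_biotype", ""), "unknown"),
            }
    if skipped:
        warnings.warn(f"excluded {len(skipped)} unstranded transcript(s)", stacklevel=2)
    out = []
    for tid in exons:
        m = meta[tid]
        out.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=m["gene_id"],
                chrom=m["chrom"],
                strand=m["strand"],
                exons=sorted(exons[tid]),
                biotype=m["biotype"],
            )
        )
    return out


def write_gtf(transcripts: Sequence[TranscriptModel], path: str, source: str = "lncmolt") -> None:
    """Write transcript + exon features; coordinates exported 1-based inclusive."""
    with open(path, "w") as fh:
        for t in transcripts:
            s, e = t.span
            attrs = (
                f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'transcript_biotype "{_BIOTYPE_OUT[t.biotype]}";'
            )
            fh.write(
                f"{t.chrom}\t{source}\ttranscript\t{s + 1}\t{e}\t.\t{t.strand}\t.\t{attrs}\n"
            )
            for i, (xs, xe) in enumerate(t.exons, start=1):
                fh.write(
                    f"{t.chrom}\t{source}\texon\t{xs + 1}\t{xe}\t.\t{t.strand}\t.\t"
                    f'{attrs} exon_number "{i}";\n'
                )


def annotation_from_transcripts(
    transcripts: Iterable[TranscriptModel],
    coding_gene_ids: Iterable[str] | None = None,
) -> GenomeAnnotation:
    """Group transcripts into genes by gene_id and build an annotation.

    A gene is flagged protein-coding if its id is in ``coding_gene_ids``, or,
    when that is None, if any of its transcripts has biotype "coding".
    """
    coding = set(coding_gene_ids) if coding_gene_ids is not None else None
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        gid = t.gene_id or t.transcript_id
        by_gene.setdefault(gid, []).append(t)
    genes = []
    for gid, ts in by_gene.items():
        if coding is not None:
            is_coding = gid in coding
        else:
            is_coding = any(t.biotype == "coding" for t in ts)
        genes.append(
            GeneModel(
                gene_id=gid,
                chrom=ts[0].chrom,
                strand=ts[0].strand,
                transcripts=ts,
                is_protein_coding=is_coding,
            )
        )
    return GenomeAnnotation(genes)


def read_fasta(path: str) -> dict[str, str]:
    """Read a FASTA file into an id -> uppercase sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(sequences: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def extract_transcript_sequence(t: TranscriptModel, genome: dict[str, str]) -> str:
    """Spliced transcript sequence; reverse-complemented for '-' strand."""
    chrom_seq = genome[t.chrom]
    seq = "".join(chrom_seq[s:e] for s, e in t.exons)
    if t.strand == "-":
        seq = reverse_complement(seq)
    return seq


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def write_bed6(records: Iterable[tuple[str, int, int, str, float, str]], path: str) -> None:
    """Write BED6 (0-based half-open, matching internal coordinates)."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in records:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score:g}\t{strand}\n")
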