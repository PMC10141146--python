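"""Synthetic study generator with planted ground truth.

Emits a complete synthetic molting study — reference annotation, genome and
transcript sequences, assembled novel transcripts, a 3-stage x 3-replicate
count matrix, term annotations and qPCR Ct tables — in which every quantity
the downstream stages estimate is planted and recorded:

* protein-coding genes with explicit ORFs (>= 300 nt, ATG-initiated, strongly
  codon-biased) and lncRNAs of every positional class whose sequences are
  ORF-poor by rejection sampling;
* negative-binomial counts with planted stage effects (log2 fold changes),
  planted temporal profiles, and planted correlated lncRNA-mRNA pairs;
* term annotations with planted over-represented terms;
* qPCR Ct values consistent with the planted fold changes.

In the default *noiseless* mode counts equal their expected values exactly
(integer by construction) and library depths are equal, so each stage of the
pipeline recovers the planted truth without error; this is the verification
regime. Setting ``noiseless=False`` draws gamma-Poisson (NB) counts with the
configured dispersion and library-size factors, the regime used for
statistical calibration. A high-abundance structural-RNA "filler" transcript
(emulating residual rRNA, the largest and most variable library component)
absorbs per-sample depth differences so that, in noiseless mode, column
totals are exactly equal and constitutively expressed genes have exactly
constant FPKM.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from lncmolt.genome_model import (
    GeneModel,
    GenomeAnnotation,
    TranscriptModel,
    genomic_gap,
    reverse_complement,
)
from lncmolt.lncrna_discovery import longest_orf
from lncmolt.temporal_profiles import enumerate_profiles

STAGES = ("PE", "DE", "AE")

LNCRNA_CLASSES = ("intergenic", "intronic", "sense", "antisense", "bidirectional")

# codon alphabet for planted coding sequences: strongly biased, stop-free
_CODING_CODONS = [
    "GCT", "GCC", "GAA", "GAG", "CTG", "CTC", "AAG", "AAA",
    "GAT", "GAC", "TTC", "TTT", "ATC", "ATT", "GGT", "GGC",
]

FILLER_ID = "rrna_filler"


class SizingError(ValueError):
    """Requested gene/lncRNA layout does not fit on the chromosomes."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    The defaults emulate the three-stage (PE/DE/AE), three-replicate design
    at desk scale: ~240 coding genes and ~90 lncRNAs whose positional-class
    proportions follow the observed mix (intergenic dominant, then antisense,
    sense, bidirectional, intronic). ``lfc_per_step`` is the planted log2
    fold change per unit profile step (4.0, comfortably above the |log2FC|
    >= 2 call threshold); ``nb_dispersion`` and ``library_size_range`` apply
    only when ``noiseless=False``.
    """

    seed: int = 0
    n_chromosomes: int = 3
    n_coding_genes: int = 240
    n_lncrna_per_class: dict[str, int] = field(
        default_factory=lambda: {
            "intergenic": 54,
            "antisense": 22,
            "sense": 9,
            "bidirectional": 4,
            "intronic": 2,
        }
    )
    n_decoy_identical: int = 5
    n_decoy_coding: int = 5
    n_samples_per_stage: int = 3
    de_fraction: float = 0.2
    lfc_per_step: float = 4.0
    profile_mix: dict[int, float] = field(
        default_factory=lambda: {
            0: 0.12, 1: 0.35, 2: 0.03, 3: 0.04, 4: 0.05, 5: 0.03, 6: 0.30, 7: 0.08,
        }
    )
    n_cis_pairs: int = 8
    n_trans_pairs: int = 8
    planted_pair_correlation: float = 1.0
    nb_dispersion: float = 0.05
    library_size_range: tuple[float, float] = (0.8, 1.2)
    noiseless: bool = True
    n_terms: int = 40
    n_enriched_terms: int = 2
    term_size_range: tuple[int, int] = (10, 40)
    enriched_de_fraction: float = 0.8
    enriched_bg_fraction: float = 0.02
    n_qpcr_genes: int = 6
    qpcr_noise_sd: float = 0.1
    qpcr_replicates: int = 3
    intergenic_gap_range: tuple[int, int] = (26_000, 32_000)
    cis_window: int = 10_000
    bidirectional_window: int = 1_000
    de_lfc_threshold: float = 2.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must lie in [0, 1]")
        if any(f < 0 or f > 1 for f in self.profile_mix.values()):
            raise ValueError("profile_mix fractions must lie in [0, 1]")
        if sum(self.profile_mix.values()) > 1.0 + 1e-9:
            raise ValueError("profile_mix must sum to <= 1")
        if any(v < 0 for v in self.n_lncrna_per_class.values()):
            raise ValueError("lncRNA counts must be >= 0")
        unknown = set(self.n_lncrna_per_class) - set(LNCRNA_CLASSES)
        if unknown:
            raise ValueError(f"unknown lncRNA classes {unknown}")
        if self.noiseless and not float(self.lfc_per_step).is_integer():
            raise ValueError(
                "noiseless mode requires an integer lfc_per_step so counts "
                "are exact"
            )
        if not 0.0 <= self.planted_pair_correlation <= 1.0:
            raise ValueError("planted_pair_correlation must lie in [0, 1]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")


@dataclass
class GroundTruth:
    """Planted truth for every downstream stage.

    ``trans_pairs`` lists all (DE lncRNA, DE coding gene) pairs planted on
    the same temporal profile: in the noiseless regime these, and only these,
    exceed the trans correlation threshold, because two transcripts on the
    same planted profile share their stage pattern exactly while distinct
    three-point profiles correlate at most ~0.87.
    """

    biotype: dict[str, str] = field(default_factory=dict)  # transcript -> coding|lncRNA
    positional_class: dict[str, str] = field(default_factory=dict)
    transcript_gene: dict[str, str] = field(default_factory=dict)
    true_lfc: dict[str, dict[str, float]] = field(default_factory=dict)  # comp -> tid -> lfc
    de_sets: dict[str, list[str]] = field(default_factory=dict)  # comp -> DE tids
    profile_id: dict[str, int] = field(default_factory=dict)  # DE tid -> profile
    cis_pairs: list[tuple[str, str, int]] = field(default_factory=list)  # lnc, gene, gap
    trans_pairs: list[tuple[str, str]] = field(default_factory=list)
    planted_pairs: list[tuple[str, str]] = field(default_factory=list)  # designated pairs
    enriched_terms: list[str] = field(default_factory=list)
    qpcr_fold: dict[str, dict[str, float]] = field(default_factory=dict)

    def de_transcripts(self, biotype: str | None = None) -> set[str]:
        tids = {t for tids in self.de_sets.values() for t in tids}
        if biotype is not None:
            tids = {t for t in tids if self.biotype.get(t) == biotype}
        return tids

    def de_genes(self) -> set[str]:
        return {
            self.transcript_gene[t]
            for t in self.de_transcripts("coding")
            if t in self.transcript_gene
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        gt = cls(**{k: d[k] for k in d if k in {f.name for f in dataclasses.fields(cls)}})
        gt.cis_pairs = [tuple(x) for x in gt.cis_pairs]
        gt.trans_pairs = [tuple(x) for x in gt.trans_pairs]
        gt.planted_pairs = [tuple(x) for x in gt.planted_pairs]
        gt.profile_id = {k: int(v) for k, v in gt.profile_id.items()}
        return gt


@dataclass
class SyntheticStudy:
    """In-memory bundle of everything the generator plants."""

    config: SimulationConfig
    reference: GenomeAnnotation
    novel: list[TranscriptModel]
    genome: dict[str, str]
    sequences: dict[str, str]  # transcript_id -> spliced sequence (ref + novel)
    truth: GroundTruth


# --------------------------------------------------------------------------
# sequence helpers
# --------------------------------------------------------------------------

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASE_ARR[rng.integers(0, 4, n)].tobytes().decode()


def _orf_poor_seq(rng: np.random.Generator, n: int, orf_cutoff: int = 300) -> str:
    for _ in range(200):
        s = _random_seq(rng, n)
        if longest_orf(s).length < orf_cutoff:
            return s
    raise RuntimeError("could not generate an ORF-poor sequence")


def _coding_mrna(rng: np.random.Generator) -> tuple[str, int]:
    """(mRNA sequence, 3'UTR length); CDS is ATG + biased codons + TAA."""
    utr5 = _orf_poor_seq(rng, int(rng.integers(80, 120)))
    n_codons = int(rng.integers(120, 240))
    cds = "ATG" + "".join(
        _CODING_CODONS[i] for i in rng.integers(0, len(_CODING_CODONS), n_codons)
    ) + "TAA"
    utr3 = _orf_poor_seq(rng, int(rng.integers(260, 400)))
    return utr5 + cds + utr3, len(utr3)


# --------------------------------------------------------------------------
# annotation generation
# --------------------------------------------------------------------------

@dataclass
class _PlacedGene:
    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    utr3: tuple[int, int]  # genomic interval of the 3'UTR
    mrna_len: int


def _place_gene(
    rng: np.random.Generator, gene_id: str, chrom: str, start: int
) -> tuple[_PlacedGene, str, int]:
    """Plan one gene starting at ``start``; returns (gene, mRNA, end)."""
    strand = "+" if rng.random() < 0.5 else "-"
    mrna, utr3_len = _coding_mrna(rng)
    total = len(mrna)
    # three exons; the exon holding the 3'UTR keeps a 60 nt CDS/UTR margin
    e_utr = utr3_len + 60
    e_first = int(rng.integers(250, 400))
    e_mid = total - e_first - e_utr
    if e_mid < 80:
        e_first = max(100, total - e_utr - 120)
        e_mid = total - e_first - e_utr
    lens = [e_first, e_mid, e_utr] if strand == "+" else [e_utr, e_mid, e_first]
    introns = [int(rng.integers(1800, 3500)) for _ in range(2)]
    exons = []
    pos = start
    for i, ln in enumerate(lens):
        exons.append((pos, pos + ln))
        pos += ln
        if i < 2:
            pos += introns[i]
    if strand == "+":
        utr3 = (exons[2][1] - utr3_len, exons[2][1])
    else:
        utr3 = (exons[0][0], exons[0][0] + utr3_len)
    return _PlacedGene(gene_id, chrom, strand, exons, utr3, total), mrna, pos


def generate_annotation(cfg: SimulationConfig) -> SyntheticStudy:
    """Generate the genome, reference annotation, and novel transcripts.

    Every planted lncRNA satisfies the geometric definition of its positional
    class by construction; lncRNA sequences are ORF-poor (< 300 nt) by
    rejection sampling; decoy novel transcripts exercise the novelty and
    coding-potential filters (exact copies of reference transcripts and
    novel coding isoforms with intact ORFs).
    """
    rng = np.random.default_rng(cfg.seed)
    truth = GroundTruth()

    n_lnc_gaps = cfg.n_lncrna_per_class.get("intergenic", 0) + cfg.n_cis_pairs
    per_chrom = int(np.ceil(cfg.n_coding_genes / cfg.n_chromosomes))
    if per_chrom - 1 < 1 or cfg.n_coding_genes < (
        cfg.n_lncrna_per_class.get("sense", 0)
        + cfg.n_lncrna_per_class.get("antisense", 0)
        + cfg.n_lncrna_per_class.get("intronic", 0)
        + cfg.n_lncrna_per_class.get("bidirectional", 0)
        + 2
    ):
        raise SizingError("too few coding genes to host the requested lncRNAs")
    if cfg.n_coding_genes - cfg.n_chromosomes < n_lnc_gaps:
        raise SizingError(
            f"{n_lnc_gaps} intergenic placements requested but only "
            f"{cfg.n_coding_genes - cfg.n_chromosomes} intergenic gaps exist"
        )

    # place genes chromosome by chromosome; record the gap after each gene
    genes: list[_PlacedGene] = []
    mrnas: dict[str, str] = {}
    gaps: dict[int, tuple[str, int, int]] = {}  # gene index -> (chrom, start, end)
    chrom_len: dict[str, int] = {}
    idx = 0
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        n_here = min(per_chrom, cfg.n_coding_genes - ci * per_chrom)
        cursor = 20_000
        for gi in range(n_here):
            gid = f"gene_{idx + 1:04d}"
            placed, mrna, end = _place_gene(rng, gid, chrom, cursor)
            genes.append(placed)
            mrnas[gid] = mrna
            gap = int(rng.integers(*cfg.intergenic_gap_range))
            if gi < n_here - 1:
                gaps[idx] = (chrom, end, end + gap)
            cursor = end + gap
            idx += 1
        chrom_len[chrom] = cursor + 5_000

    # genome background, then splice in the mRNA exon sequences
    genome_arr = {c: bytearray(_random_seq(rng, n), "ascii") for c, n in chrom_len.items()}

    def write_region(chrom: str, start: int, seq: str) -> None:
        genome_arr[chrom][start : start + len(seq)] = seq.encode()

    for g in genes:
        payload = mrnas[g.gene_id] if g.strand == "+" else reverse_complement(mrnas[g.gene_id])
        pos = 0
        for s, e in g.exons:
            write_region(g.chrom, s, payload[pos : pos + (e - s)])
            pos += e - s

    # ----- allocate hosts and gaps for the planted lncRNAs -----
    n_cls = dict(cfg.n_lncrna_per_class)
    plus_genes = [i for i, g in enumerate(genes) if g.strand == "+" and i in gaps]
    rng.shuffle(plus_genes)
    need_plus = n_cls.get("sense", 0) + n_cls.get("antisense", 0)
    if len(plus_genes) < need_plus:
        raise SizingError("not enough '+'-strand host genes for sense/antisense lncRNAs")
    sense_hosts = plus_genes[: n_cls.get("sense", 0)]
    antisense_hosts = plus_genes[n_cls.get("sense", 0) : need_plus]
    used_genes = set(sense_hosts) | set(antisense_hosts)
    used_gaps = set(sense_hosts) | set(antisense_hosts)  # their downstream gaps

    remaining = [i for i in range(len(genes)) if i not in used_genes]
    rng.shuffle(remaining)
    intronic_hosts, bidi_hosts = [], []
    for i in remaining:
        if len(intronic_hosts) < n_cls.get("intronic", 0):
            intronic_hosts.append(i)
            used_genes.add(i)
        elif len(bidi_hosts) < n_cls.get("bidirectional", 0):
            # bidirectional placement needs the gap on the gene's 5' side
            side = i - 1 if genes[i].strand == "+" else i
            if (
                side in gaps
                and side not in used_gaps
                and gaps[side][0] == genes[i].chrom
            ):
                bidi_hosts.append(i)
                used_genes.add(i)
                used_gaps.add(side)
    if len(intronic_hosts) < n_cls.get("intronic", 0) or len(bidi_hosts) < n_cls.get(
        "bidirectional", 0
    ):
        raise SizingError("could not allocate intronic/bidirectional host genes")

    free_gaps = [i for i in gaps if i not in used_gaps]
    rng.shuffle(free_gaps)
    n_gap_lnc = n_cls.get("intergenic", 0) + cfg.n_cis_pairs
    if len(free_gaps) < n_gap_lnc:
        raise SizingError("not enough intergenic gaps for intergenic/cis lncRNAs")
    cis_gaps = free_gaps[: cfg.n_cis_pairs]
    intergenic_gaps = free_gaps[cfg.n_cis_pairs : n_gap_lnc]

    # ----- build lncRNA transcripts -----
    novel: list[TranscriptModel] = []
    lnc_counter = 0

    def next_id() -> str:
        nonlocal lnc_counter
        lnc_counter += 1
        return f"asm_{lnc_counter:04d}"

    def add_lnc(
        chrom: str,
        exons: list[tuple[int, int]],
        strand: str,
        cls: str,
        free: tuple[int, int] | None,
    ) -> None:
        """Register a lncRNA; rewrite its free genomic region until ORF-poor."""
        tid = next_id()
        t = TranscriptModel(tid, "", chrom, strand, exons, biotype="lncRNA")
        for attempt in range(200):
            seq = "".join(
                genome_arr[chrom][s:e].decode() for s, e in exons
            )
            if strand == "-":
                seq = reverse_complement(seq)
            if longest_orf(seq).length < 300:
                break
            if free is None:
                raise RuntimeError("fixed lncRNA region is not ORF-poor")
            write_region(chrom, free[0], _random_seq(rng, free[1] - free[0]))
        else:
            raise RuntimeError("could not make lncRNA region ORF-poor")
        novel.append(t)
        truth.biotype[tid] = "lncRNA"
        truth.positional_class[tid] = cls

    # sense: single exon, same strand, overlapping the host 3'UTR and
    # extending past the gene end into the downstream gap
    for i in sense_hosts:
        g = genes[i]
        u_s, u_e = g.utr3
        exon = (u_e - 150, u_e + 250)
        add_lnc(g.chrom, [exon], "+", "sense", free=(u_e, u_e + 250))
    # antisense: like sense but on the opposite strand
    for i in antisense_hosts:
        g = genes[i]
        u_s, u_e = g.utr3
        exon = (u_e - 200, u_e + 200)
        add_lnc(g.chrom, [exon], "-", "antisense", free=(u_e, u_e + 200))
    # intronic: single exon strictly inside the first intron
    for i in intronic_hosts:
        g = genes[i]
        i_s, i_e = g.exons[0][1], g.exons[1][0]
        start = i_s + 300
        length = min(450, i_e - start - 300)
        exon = (start, start + length)
        strand = "+" if rng.random() < 0.5 else "-"
        add_lnc(g.chrom, [exon], strand, "intronic", free=exon)
    # bidirectional: divergent, TSS within the window of the host TSS
    for i in bidi_hosts:
        g = genes[i]
        span = (g.exons[0][0], g.exons[-1][1])
        if g.strand == "+":
            exon = (span[0] - 900, span[0] - 500)
            strand = "-"
        else:
            exon = (span[1] + 500, span[1] + 900)
            strand = "+"
        add_lnc(g.chrom, [exon], strand, "bidirectional", free=exon)
    # cis-planted intergenic: 2-8 kb downstream of a gene, > 10 kb from the next
    cis_lnc_ids: list[str] = []
    for gi in cis_gaps:
        chrom, g_s, g_e = gaps[gi]
        d = int(rng.integers(2000, 8000))
        length = int(rng.integers(300, 800))
        exon = (g_s + d, g_s + d + length)
        strand = "+" if rng.random() < 0.5 else "-"
        add_lnc(chrom, [exon], strand, "intergenic", free=exon)
        cis_lnc_ids.append(novel[-1].transcript_id)
    # plain intergenic: > 12 kb from both flanking genes (never a cis target)
    for gi in intergenic_gaps:
        chrom, g_s, g_e = gaps[gi]
        length = int(rng.integers(300, 1200))
        slack = (g_e - g_s) - 24_000 - length
        start = g_s + 12_000 + int(rng.integers(0, max(1, slack)))
        strand = "+" if rng.random() < 0.5 else "-"
        if rng.random() < 0.4 and length >= 500:
            mid = length // 2
            gap_i = 150
            exons = [
                (start, start + mid - gap_i // 2),
                (start + mid + gap_i // 2, start + length),
            ]
        else:
            exons = [(start, start + length)]
        add_lnc(chrom, exons, strand, "intergenic", free=(start, start + length))

    # ----- decoy novel transcripts -----
    host_pool = [i for i in range(len(genes)) if i not in used_genes]
    rng.shuffle(host_pool)
    for i in host_pool[: cfg.n_decoy_identical]:
        g = genes[i]
        tid = next_id()
        novel.append(TranscriptModel(tid, "", g.chrom, g.strand, list(g.exons)))
        truth.biotype[tid] = "coding"
    for i in host_pool[cfg.n_decoy_identical : cfg.n_decoy_identical + cfg.n_decoy_coding]:
        g = genes[i]
        exons = [list(e) for e in g.exons]
        exons[-1][1] += 100  # extended terminal exon: shares junctions, not identical
        tid = next_id()
        novel.append(
            TranscriptModel(tid, "", g.chrom, g.strand, [tuple(e) for e in exons])
        )
        truth.biotype[tid] = "coding"

    # ----- assemble reference annotation (coding genes + structural-RNA filler) -----
    ref_genes = []
    for g in genes:
        t = TranscriptModel(
            f"tx_{g.gene_id.split('_')[1]}", g.gene_id, g.chrom, g.strand,
            list(g.exons), biotype="coding",
        )
        ref_genes.append(
            GeneModel(g.gene_id, g.chrom, g.strand, [t], is_protein_coding=True)
        )
        truth.transcript_gene[t.transcript_id] = g.gene_id
        truth.biotype[t.transcript_id] = "coding"
    filler_t = TranscriptModel(FILLER_ID, FILLER_ID, "chr1", "+", [(1_000, 2_500)])
    ref_genes.append(GeneModel(FILLER_ID, "chr1", "+", [filler_t], is_protein_coding=False))
    reference = GenomeAnnotation(ref_genes)

    genome = {c: bytes(a).decode() for c, a in genome_arr.items()}

    # spliced sequences for every reference and novel transcript
    from lncmolt.genome_model import extract_transcript_sequence

    sequences: dict[str, str] = {}
    for g in reference:
        for t in g.transcripts:
            sequences[t.transcript_id] = extract_transcript_sequence(t, genome)
    for t in novel:
        sequences[t.transcript_id] = extract_transcript_sequence(t, genome)

    # cis ground truth: naive all-pairs scan of lncRNA loci vs coding genes
    for t in novel:
        if truth.biotype[t.transcript_id] != "lncRNA":
            continue
        for g in reference.coding_genes():
            if g.chrom != t.chrom:
                continue
            gap = genomic_gap(t.span, g.span)
            if gap <= cfg.cis_window:
                truth.cis_pairs.append((t.transcript_id, g.gene_id, int(gap)))
    truth.cis_pairs.sort()

    study = SyntheticStudy(cfg, reference, novel, genome, sequences, truth)
    study._cis_lnc_ids = cis_lnc_ids  # type: ignore[attr-defined]
    return study


# --------------------------------------------------------------------------
# count generation
# --------------------------------------------------------------------------

def _stage_template(pid: int) -> tuple[float, ...]:
    profiles = {p.profile_id: p.template for p in enumerate_profiles(3, 1)}
    return profiles[pid]


def generate_counts(
    cfg: SimulationConfig, study: SyntheticStudy
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Generate the transcripts x samples count matrix and the stage design.

    DE transcripts follow planted temporal profiles with log2 fold change
    ``lfc_per_step`` per unit profile step; planted pairs share a profile
    (their stage patterns are identical up to scale, inducing the planted
    correlation). In noiseless mode counts equal their integer expected
    values and the filler transcript tops every column up to a common total.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    truth = study.truth
    lam = cfg.lfc_per_step
    profiles = sorted(cfg.profile_mix)
    probs = np.array([cfg.profile_mix[p] for p in profiles], dtype=float)
    probs = probs / probs.sum()

    lnc_ids = [t.transcript_id for t in study.novel if truth.biotype[t.transcript_id] == "lncRNA"]
    decoy_ids = [t.transcript_id for t in study.novel if truth.biotype[t.transcript_id] == "coding"]
    coding_tx = [
        t.transcript_id
        for g in study.reference.coding_genes()
        for t in g.transcripts
    ]

    cis_lnc: list[str] = getattr(study, "_cis_lnc_ids", [])[: cfg.n_cis_pairs]

    # choose DE transcripts: designated cis lncRNAs and trans-pair members
    # first, then random fill to the configured DE fraction
    n_de_lnc = max(int(round(cfg.de_fraction * len(lnc_ids))), cfg.n_trans_pairs)
    n_de_cod = max(int(round(cfg.de_fraction * len(coding_tx))), cfg.n_trans_pairs)
    de_lnc = list(dict.fromkeys(cis_lnc))[:n_de_lnc]
    pool = [t for t in lnc_ids if t not in de_lnc]
    rng.shuffle(pool)
    de_lnc += pool[: n_de_lnc - len(de_lnc)]
    cod_pool = list(coding_tx)
    rng.shuffle(cod_pool)
    de_cod = cod_pool[:n_de_cod]

    # profiles: trans-pair members share one; everyone else draws from the mix
    pair_lnc = de_lnc[: cfg.n_trans_pairs]
    pair_cod = de_cod[: cfg.n_trans_pairs]
    for l, c in zip(pair_lnc, pair_cod):
        pid = int(rng.choice(profiles, p=probs))
        truth.profile_id[l] = pid
        truth.profile_id[c] = pid
        truth.planted_pairs.append((l, truth.transcript_gene[c]))
    for tid in de_lnc[cfg.n_trans_pairs :] + de_cod[cfg.n_trans_pairs :]:
        truth.profile_id[tid] = int(rng.choice(profiles, p=probs))

    de_all = set(de_lnc) | set(de_cod)

    # per-transcript expected counts per stage
    all_ids = coding_tx + lnc_ids + decoy_ids
    unit = 2 ** (int(lam) * 2) if cfg.noiseless else 1
    means = {}
    for tid in all_ids:
        if tid in de_all:
            base = unit * int(rng.integers(2, 8))
            tpl = _stage_template(truth.profile_id[tid])
            means[tid] = [base * 2.0 ** (lam * t) for t in tpl]
        else:
            lo = 30 if truth.biotype[tid] == "coding" else 20
            base = int(rng.integers(lo, 500))
            means[tid] = [float(base)] * 3

    # planted per-comparison log2 fold changes and DE sets
    comps = {"PEvsDE": (0, 1), "PEvsAE": (0, 2), "DEvsAE": (1, 2)}
    for comp, (a, b) in comps.items():
        truth.true_lfc[comp] = {}
        truth.de_sets[comp] = []
        for tid in all_ids:
            tpl = _stage_template(truth.profile_id[tid]) if tid in de_all else (0, 0, 0)
            lfc = lam * (tpl[b] - tpl[a])
            truth.true_lfc[comp][tid] = lfc
            if abs(lfc) >= cfg.de_lfc_threshold:
                truth.de_sets[comp].append(tid)
        truth.de_sets[comp].sort()

    n_rep = cfg.n_samples_per_stage
    samples = [f"{st}{r + 1}" for st in STAGES for r in range(n_rep)]
    design = {s: s[:2] for s in samples}
    stage_idx = {s: STAGES.index(design[s]) for s in samples}

    if cfg.noiseless:
        mat = np.array(
            [[int(means[tid][stage_idx[s]]) for s in samples] for tid in all_ids],
            dtype=np.int64,
        )
        totals = mat.sum(axis=0)
        target = int(totals.max()) + 10_000
        filler_row = target - totals
    else:
        lib = rng.uniform(*cfg.library_size_range, size=len(samples))
        # shared lognormal latent factor per planted pair induces the
        # across-sample correlation while preserving NB margins
        latent_sd = 1.2 * cfg.planted_pair_correlation
        pair_latent = {
            pair: np.exp(rng.normal(0.0, latent_sd, len(samples)) - latent_sd**2 / 2)
            for pair in range(len(pair_lnc))
        }
        pair_of = {}
        for k, (l, c) in enumerate(zip(pair_lnc, pair_cod)):
            pair_of[l] = k
            pair_of[c] = k
        rows = []
        for tid in all_ids:
            mu = np.array([means[tid][stage_idx[s]] for s in samples]) * lib
            if tid in pair_of and cfg.planted_pair_correlation > 0:
                mu = mu * pair_latent[pair_of[tid]]
            if cfg.nb_dispersion > 0:
                shape = 1.0 / cfg.nb_dispersion
                lam_draw = rng.gamma(shape, mu / shape)
            else:
                lam_draw = mu
            rows.append(rng.poisson(lam_draw))
        mat = np.array(rows, dtype=np.int64)
        filler_mu = mat.sum(axis=0).mean() * 0.15
        filler_row = rng.poisson(filler_mu * lib)

    counts = pd.DataFrame(mat, index=all_ids, columns=samples)
    counts.loc[FILLER_ID] = filler_row
    truth.biotype.setdefault(FILLER_ID, "unknown")

    # trans ground truth: DE lncRNA x DE coding-gene pairs on the same or
    # the mirror-image profile (templates t and -t correlate at exactly -1,
    # and the trans rule thresholds |r|)
    mirror = _mirror_profiles()
    truth.trans_pairs = sorted(
        {
            (l, truth.transcript_gene[c])
            for l in de_lnc
            for c in de_cod
            if truth.profile_id[l] == truth.profile_id[c]
            or mirror[truth.profile_id[l]] == truth.profile_id[c]
        }
    )
    return counts, design


def _mirror_profiles() -> dict[int, int]:
    """Map each profile id to the id of its sign-flipped template."""
    profs = enumerate_profiles(3, 1)
    by_template = {p.template: p.profile_id for p in profs}
    return {
        p.profile_id: by_template[tuple(-x for x in p.template)] for p in profs
    }


# --------------------------------------------------------------------------
# term annotation and qPCR
# --------------------------------------------------------------------------

def generate_term_annotation(
    cfg: SimulationConfig, study: SyntheticStudy
) -> pd.DataFrame:
    """Gene -> term table with planted over-represented terms.

    Enriched terms cover ``enriched_de_fraction`` of the DE coding genes plus
    ``enriched_bg_fraction`` of the others; background terms draw uniformly
    with sizes inside ``term_size_range``.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    truth = study.truth
    universe = sorted(g.gene_id for g in study.reference.coding_genes())
    de_genes = sorted(truth.de_genes())
    other = [g for g in universe if g not in set(de_genes)]
    rows = []
    for i in range(cfg.n_enriched_terms):
        term = f"TERM_E{i + 1:02d}"
        truth.enriched_terms.append(term)
        n_de = max(1, int(round(cfg.enriched_de_fraction * len(de_genes))))
        n_bg = max(0, int(round(cfg.enriched_bg_fraction * len(other))))
        members = list(rng.choice(de_genes, n_de, replace=False)) + list(
            rng.choice(other, n_bg, replace=False)
        )
        for g in members:
            rows.append((g, term, f"planted enriched process {i + 1}"))
    lo, hi = cfg.term_size_range
    for i in range(cfg.n_terms - cfg.n_enriched_terms):
        term = f"TERM_B{i + 1:03d}"
        size = int(rng.integers(lo, hi + 1))
        for g in rng.choice(universe, size, replace=False):
            rows.append((g, term, f"background process {i + 1}"))
    return pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name"])


def generate_qpcr(cfg: SimulationConfig, study: SyntheticStudy) -> pd.DataFrame:
    """Ct table consistent with the planted stage fold changes.

    Ct(target) = 20 + gene offset - log2(relative expression) + noise;
    Ct(reference) = 20 + noise. With zero noise 2^-ddCt inverts to the
    planted fold change exactly.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    truth = study.truth
    de_lnc = sorted(truth.de_transcripts("lncRNA"))
    chosen = de_lnc[: cfg.n_qpcr_genes]
    sd = 0.0 if cfg.noiseless else cfg.qpcr_noise_sd
    lam = cfg.lfc_per_step
    rows = []
    for tid in chosen:
        tpl = _stage_template(truth.profile_id[tid])
        offset = float(rng.uniform(0, 5))
        truth.qpcr_fold[tid] = {}
        for si, stage in enumerate(STAGES):
            rel = 2.0 ** (lam * tpl[si])
            truth.qpcr_fold[tid][stage] = rel
            for rep in range(1, cfg.qpcr_replicates + 1):
                rows.append(
                    {
                        "gene_id": tid,
                        "group": stage,
                        "replicate": rep,
                        "ct_target": 20.0 + offset - np.log2(rel) + rng.normal(0, sd),
                        "ct_reference": 20.0 + rng.normal(0, sd),
                    }
                )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# one-call study generation and file output
# --------------------------------------------------------------------------

def generate_study(cfg: SimulationConfig) -> tuple[SyntheticStudy, pd.DataFrame, dict[str, str], pd.DataFrame, pd.DataFrame]:
    """Generate annotation, counts, terms, and qPCR in dependency order."""
    study = generate_annotation(cfg)
    counts, design = generate_counts(cfg, study)
    terms = generate_term_annotation(cfg, study)
    qpcr = generate_qpcr(cfg, study)
    return study, counts, design, terms, qpcr


def write_study(cfg: SimulationConfig, outdir: str) -> dict[str, str]:
    """Generate a study and write all files; returns the path map.

    Outputs: reference.gtf, novel.gtf, genome.fa, transcripts.fa, counts.tsv,
    design.tsv, terms.tsv, qpcr.tsv, truth.json. Identical configs (including
    the seed) yield byte-identical files.
    """
    import os

    from lncmolt.genome_model import write_fasta, write_gtf

    os.makedirs(outdir, exist_ok=True)
    study, counts, design, terms, qpcr = generate_study(cfg)
    paths = {k: os.path.join(outdir, v) for k, v in {
        "reference": "reference.gtf",
        "novel": "novel.gtf",
        "genome": "genome.fa",
        "transcripts": "transcripts.fa",
        "counts": "counts.tsv",
        "design": "design.tsv",
        "terms": "terms.tsv",
        "qpcr": "qpcr.tsv",
        "truth": "truth.json",
    }.items()}
    ref_ts = [t for g in study.reference for t in g.transcripts]
    write_gtf(ref_ts, paths["reference"])
    write_gtf(study.novel, paths["novel"])
    write_fasta(study.genome, paths["genome"])
    write_fasta(study.sequences, paths["transcripts"])
    counts.to_csv(paths["counts"], sep="\t", index_label="transcript_id")
    pd.Series(design, name="stage").to_csv(
        paths["design"], sep="\t", index_label="sample_id"
    )
    terms.to_csv(paths["terms"], sep="\t", index=False)
    qpcr.to_csv(paths["qpcr"], sep="\t", index=False)
    study.truth.to_json(paths["truth"])
    return paths
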