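"""lncRNA identification: class codes, ORF finding, coding potential, positions."""
from __future__ import annotations

import numpy as np
import pytest

from lncmolt.genome_model import (
    GenomeAnnotation,
    annotation_from_transcripts,
    reverse_complement,
)
from lncmolt.lncrna_discovery import (
    NOVEL_CLASS_CODES,
    STOP_CODONS,
    CodingPotentialCall,
    assign_class_code,
    call_lncrnas,
    classify_lncrna_position,
    hexamer_score,
    longest_orf,
    orf_subsequence,
    train_hexamer_table,
)
from tests.conftest import make_gene, make_tx, random_annotation, random_transcript


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def oracle_class_code(novel, ref: GenomeAnnotation) -> str:
    """Naive re-derivation of the class-code precedence, no shared helpers."""

    def exonic(a_exons, b_exons):
        return any(s1 < e2 and s2 < e1 for s1, e1 in a_exons for s2, e2 in b_exons)

    ref_ts = [
        t
        for g in ref
        if g.chrom == novel.chrom
        and g.span[0] < novel.span[1]
        and novel.span[0] < g.span[1]
        for t in g.transcripts
    ]
    any_gene_overlap = bool(ref_ts)
    same = [t for t in ref_ts if t.strand == novel.strand]
    opp = [t for t in ref_ts if t.strand != novel.strand]
    if any(t.exons == novel.exons for t in same):
        return "="
    for t in same:
        if all(any(rs <= ns and ne <= re for rs, re in t.exons) for ns, ne in novel.exons):
            return "c"
    nj = {(e1, s2) for (_, e1), (s2, _) in zip(novel.exons, novel.exons[1:])}
    for t in same:
        tj = {(e1, s2) for (_, e1), (s2, _) in zip(t.exons, t.exons[1:])}
        if nj & tj:
            return "j"
    if any(exonic(novel.exons, t.exons) for t in same):
        return "e" if len(novel.exons) == 1 else "o"
    if any(exonic(novel.exons, t.exons) for t in opp):
        return "x"
    for t in ref_ts:
        introns = [(e1, s2) for (_, e1), (s2, _) in zip(t.exons, t.exons[1:])]
        if any(s <= novel.span[0] and novel.span[1] <= e for s, e in introns):
            return "i"
    return "u" if not any_gene_overlap else "p"


def oracle_longest_orf(seq: str) -> int:
    """Exhaustive ATG->first-stop scan over all 6 frames."""
    best = 0
    for s in (seq.upper(), reverse_complement(seq.upper())):
        for i in range(len(s) - 2):
            if s[i : i + 3] != "ATG":
                continue
            j = i + 3
            while j + 3 <= len(s):
                if s[j : j + 3] in STOP_CODONS:
                    best = max(best, j + 3 - i)
                    break
                j += 3
    return best


# ---------------------------------------------------------------------------
# Class codes
# ---------------------------------------------------------------------------

class TestClassCodes:
    @pytest.fixture
    def ref(self) -> GenomeAnnotation:
        return annotation_from_transcripts(
            [
                make_tx("ref1", [(1000, 1500), (2000, 2600)], "+", gene_id="gA",
                        biotype="coding"),
            ]
        )

    def test_identical_chain(self, ref):
        assert assign_class_code(make_tx("n", [(1000, 1500), (2000, 2600)], "+"), ref) == "="

    def test_contained(self, ref):
        assert assign_class_code(make_tx("n", [(1100, 1400)], "+"), ref) == "c"

    def test_shared_junction(self, ref):
        assert assign_class_code(make_tx("n", [(1200, 1500), (2000, 2900)], "+"), ref) == "j"

    def test_single_exon_overlap(self, ref):
        assert assign_class_code(make_tx("n", [(900, 1200)], "+"), ref) == "e"

    def test_multi_exon_overlap_no_junction(self, ref):
        assert assign_class_code(make_tx("n", [(900, 1200), (3000, 3200)], "+"), ref) == "o"

    def test_antisense_overlap(self, ref):
        assert assign_class_code(make_tx("n", [(1100, 1400)], "-"), ref) == "x"

    def test_intronic(self, ref):
        assert assign_class_code(make_tx("n", [(1600, 1900)], "+"), ref) == "i"
        assert assign_class_code(make_tx("n", [(1600, 1900)], "-"), ref) == "i"

    def test_intergenic(self, ref):
        assert assign_class_code(make_tx("n", [(5000, 5400)], "+"), ref) == "u"

    def test_precedence_identical_beats_junction(self, ref):
        # an identical chain also shares junctions; '=' must win
        n = make_tx("n", [(1000, 1500), (2000, 2600)], "+")
        assert assign_class_code(n, ref) == "="

    def test_matches_oracle_randomized(self):
        rng = np.random.default_rng(42)
        codes_seen = set()
        for _ in range(300):
            ref = random_annotation(rng, n_genes=int(rng.integers(1, 5)))
            novel = random_transcript(rng)
            got = assign_class_code(novel, ref)
            assert got == oracle_class_code(novel, ref)
            codes_seen.add(got)
        assert len(codes_seen) >= 5  # the random families exercise many codes


# ---------------------------------------------------------------------------
# ORF finding
# ---------------------------------------------------------------------------

class TestLongestOrf:
    def test_minimal_orf(self):
        assert longest_orf("ATGTAA").length == 6

    def test_no_stop_no_orf(self):
        # ATG with no in-frame stop: no complete ORF on the forward strand,
        # and the reverse complement contains none either
        assert longest_orf("ATGAAAAAA").length == 0

    def test_reverse_strand(self):
        seq = reverse_complement("ATGCCCTAA")
        r = longest_orf(seq)
        assert r.length == 9 and r.strand == "-"
        assert orf_subsequence(seq, r) == "ATGCCCTAA"

    def test_short_sequence(self):
        assert longest_orf("ATGTA").length == 0

    def test_matches_oracle_randomized(self):
        rng = np.random.default_rng(5)
        lengths_seen = set()
        for _ in range(300):
            n = int(rng.integers(6, 200))
            seq = "".join(rng.choice(list("ACGT"), n))
            got = longest_orf(seq).length
            assert got == oracle_longest_orf(seq)
            lengths_seen.add(got)
        assert 0 in lengths_seen and max(lengths_seen) > 20

    def test_orf_subsequence_translates(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            seq = "".join(rng.choice(list("ACGT"), 120))
            r = longest_orf(seq)
            sub = orf_subsequence(seq, r)
            if r.length:
                assert sub.startswith("ATG") and sub[-3:] in STOP_CODONS
                assert len(sub) == r.length and r.length % 3 == 0
                # no internal in-frame stops
                assert all(
                    sub[i : i + 3] not in STOP_CODONS for i in range(3, len(sub) - 3, 3)
                )


# ---------------------------------------------------------------------------
# Hexamer score
# ---------------------------------------------------------------------------

class TestHexamerScore:
    def test_separates_training_classes(self):
        rng = np.random.default_rng(1)
        codons = ["GCT", "GAA", "AAG", "CTG", "GAT", "TCT"]
        coding = [
            "ATG" + "".join(rng.choice(codons, 60)) + "TAA" for _ in range(30)
        ]
        noncoding = ["".join(rng.choice(list("ACGT"), 186)) for _ in range(30)]
        table = train_hexamer_table(coding, noncoding)
        cod_scores = [hexamer_score(s, table) for s in coding]
        non_scores = [hexamer_score(s, table) for s in noncoding]
        assert np.mean(cod_scores) > 0 > np.mean(non_scores)

    def test_missing_table_is_an_error(self):
        with pytest.raises(ValueError, match="hexamer table"):
            hexamer_score("ACGTACGTACGT", None)

    def test_empty_training_rejected(self):
        with pytest.raises(ValueError):
            train_hexamer_table([], ["ACGTAC"])


# ---------------------------------------------------------------------------
# The lncRNA call and positional classes
# ---------------------------------------------------------------------------

def _flat_table(value: float = -1.0) -> dict[str, float]:
    """A degenerate hexamer table scoring every sequence as noncoding."""
    from itertools import product

    return {"".join(p): value for p in product("ACGT", repeat=6)}


class TestCallLncrnas:
    @pytest.fixture
    def ref(self):
        return annotation_from_transcripts(
            [make_tx("ref1", [(50_000, 52_000)], "+", gene_id="gA", biotype="coding")]
        )

    def test_retention_rule(self, ref):
        rng = np.random.default_rng(2)

        def orf_poor(n):
            while True:
                s = "".join(rng.choice(list("ACGT"), n))
                if longest_orf(s).length < 300:
                    return s

        txs = [
            make_tx("len200", [(1000, 1200)]),  # length exactly 200: too short
            make_tx("len201", [(1000, 1201)]),  # length 201: long enough
            make_tx("known", [(50_000, 52_000)], "+"),  # class '=': not novel
        ]
        seqs = {t.transcript_id: orf_poor(sum(e - s for s, e in t.exons)) for t in txs}
        lncs, calls, codes = call_lncrnas(txs, ref, seqs, _flat_table())
        assert [t.transcript_id for t in lncs] == ["len201"]
        assert lncs[0].biotype == "lncRNA"
        assert codes["known"] == "="
        assert calls["len201"].consensus_noncoding

    def test_orf_cutoff_boundary(self, ref):
        # longest ORF exactly at the cutoff is called coding (strict <)
        core = "ATG" + "GCT" * 98 + "TAA"  # ORF length 300
        assert longest_orf(core).length == 300
        t = make_tx("t", [(1000, 1000 + len(core))])
        lncs, calls, _ = call_lncrnas([t], ref, {"t": core}, _flat_table())
        assert not calls["t"].predictor_a_noncoding and lncs == []

    def test_consensus_requires_both_predictors(self):
        assert not CodingPotentialCall(True, False).consensus_noncoding
        assert not CodingPotentialCall(False, True).consensus_noncoding
        assert CodingPotentialCall(True, True).consensus_noncoding

    def test_missing_sequence_excluded(self, ref, caplog):
        t = make_tx("noseq", [(1000, 1400)])
        with caplog.at_level("WARNING"):
            lncs, calls, codes = call_lncrnas([t], ref, {}, _flat_table())
        assert lncs == [] and "noseq" not in calls and codes["noseq"] == "u"
        assert any("no sequence" in r.message for r in caplog.records)


class TestPositionalClassification:
    @pytest.fixture
    def ref(self):
        return annotation_from_transcripts(
            [
                make_tx(
                    "refA",
                    [(10_000, 11_000), (15_000, 16_000)],
                    "+",
                    gene_id="gA",
                    biotype="coding",
                )
            ]
        )

    def _cls(self, ref, exons, strand):
        return classify_lncrna_position(make_tx("l", exons, strand), ref)

    def test_intronic_beats_overlap(self, ref):
        assert self._cls(ref, [(12_000, 13_000)], "+").cls == "intronic"
        assert self._cls(ref, [(12_000, 13_000)], "-").cls == "intronic"

    def test_sense_and_antisense(self, ref):
        assert self._cls(ref, [(10_500, 11_500)], "+").cls == "sense"
        assert self._cls(ref, [(10_500, 11_500)], "-").cls == "antisense"

    def test_bidirectional_window_boundary(self, ref):
        # gene TSS at 10_000 ('+'); divergent lncRNA on '-' with TSS <= 1000 bp away
        assert self._cls(ref, [(8_500, 9_000)], "-").cls == "bidirectional"
        # TSS exactly at the window edge still counts (<= window)
        assert self._cls(ref, [(8_000, 9_000)], "-").cls == "bidirectional"
        # one base beyond: plain intergenic
        assert self._cls(ref, [(8_000, 8_999)], "-").cls == "intergenic"

    def test_bidirectional_requires_divergence(self, ref):
        # same strand as the gene: never bidirectional
        assert self._cls(ref, [(8_500, 9_000)], "+").cls == "intergenic"
        # opposite strand but transcribed toward the gene (TSS at the far end)
        got = self._cls(ref, [(9_200, 9_800)], "-")
        assert got.cls == "bidirectional"  # TSS 9_800, within window, divergent

    def test_intergenic_has_empty_anchor(self, ref):
        got = self._cls(ref, [(100_000, 101_000)], "+")
        assert got.cls == "intergenic" and got.anchor_gene_id == ""

    def test_other_for_span_only_overlap(self, ref):
        # straddles intron/exon boundary region without exonic overlap:
        # span overlaps the gene span but exons fall in the intron...
        # (an exon fully inside the intron is intronic; build a span-only case
        # with one exon left of the gene and one inside the intron)
        got = self._cls(ref, [(9_000, 9_500), (12_000, 12_500)], "+")
        assert got.cls == "other"

    def test_noncoding_reference_genes_ignored(self):
        ref = annotation_from_transcripts(
            [make_tx("r", [(10_000, 12_000)], "+", gene_id="gN", biotype="unknown")]
        )
        got = classify_lncrna_position(make_tx("l", [(10_500, 11_000)], "+"), ref)
        assert got.cls == "intergenic"
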