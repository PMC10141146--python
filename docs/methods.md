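# Methods

This note records the statistical model, the decision rules with their exact
boundary semantics, the synthetic-data design, and the numerical choices.
Everything here is implemented in `src/lncmolt/` and exercised by the test
suite; the acceptance script (`scripts/acceptance.py`) reports the headline
quantities of a full run.

## Study design

Three molting stages — prior to ecdysis (PE), during ecdysis (DE), after
ecdysis (AE) — with three biological replicates each (nine samples). All
stage comparisons are PE vs DE, PE vs AE, and DE vs AE, with a positive
log2 fold change meaning higher expression in the second-named stage.

## lncRNA discovery

**Class codes.** Each assembled transcript is compared with the reference
annotation and assigned the first matching code in this precedence order:
`=` (identical exon chain, same strand), `c` (contained in a same-strand
exon chain), `j` (shares a splice junction, same strand), `e` (single-exon
same-strand exonic overlap), `o` (other same-strand exonic overlap), `x`
(opposite-strand exonic overlap), `i` (entirely within an intron), `u` (no
reference-gene span overlap), `p` (span overlap without exonic or intronic
relation). Codes `u i j x c e o` count as novel.

**Retention rule.** A transcript is called a lncRNA iff: novel class code
AND exonic length strictly greater than 200 nt AND consensus noncoding. The
consensus is the intersection of two predictors:

- *ORF length*: the longest complete ATG→stop ORF over three frames on both
  strands is strictly shorter than 300 nt (an ORF of exactly 300 nt is
  coding-like).
- *Hexamer usage*: the mean per-hexamer log-odds (coding vs noncoding),
  scored in frame (step 3) within the longest ORF (whole sequence if no ORF
  ≥ 6 nt exists), is below 0. The table is trained with add-one smoothing on
  the reference coding mRNAs versus shuffled copies of the same sequences;
  shuffling preserves base composition while destroying codon structure,
  which is the signal the score measures.

**Positional classes** (first match wins): *intronic* (the whole transcript
lies within one intron of a coding gene), *sense* / *antisense* (exonic
overlap on the same / opposite strand), *bidirectional* (no coding-gene
overlap; opposite strand; TSS within 1000 bp of a coding gene's TSS,
inclusive; transcribed divergently), *intergenic* (no coding-gene span
overlap and not bidirectional), *other* (span overlap without any exonic or
intronic relation, e.g. a multi-exon transcript straddling a gene end).
Candidate genes are examined in gene_id order, so the call never depends on
annotation ordering.

## Quantification and differential expression

**FPKM** = counts × 10⁹ / (exonic length × per-sample total counts), with
the total taken over *all* quantified transcripts (including structural
RNAs), so it reflects true library depth.

**Size factors**: DESeq-style median of ratios over transcripts with
positive counts in every sample, computed as exp(median(log ratio)).

**NB Wald test.** For each comparison, counts are divided by the size
factors; the per-transcript dispersion is the pooled within-group moment
estimate α̂ = max(0, (s² − μ̄)/μ̄²), shrunk 50/50 toward a log-log
least-squares trend of dispersion on mean. When fewer than 10 positive
estimates exist the trend falls back to the mean estimate over expressed
transcripts — zero estimates count as evidence of sub-Poisson variation
(this matters for the noise-free regime, where all estimates are exactly 0);
only with no expressed transcripts at all does it fall back to 0.1. The
Wald statistic is log2((mean_b + ½)/(mean_a + ½)) over its delta-method
standard error with NB variance μ + αμ², referred to a t distribution with
2(n_a + n_b − 2) effective degrees of freedom: the 50/50 shrink halves the
weight on the noisy per-transcript variance estimate, roughly doubling the
effective degrees of freedom of the pooled estimate. Null simulations
(gamma–Poisson, dispersion 0.05, 3 vs 3) give a mean type-I error of 0.050
at p < 0.05 under this reference (a plain normal reference is
anti-conservative at 0.089 and t with 4 df conservative at 0.022).

**DE call**: BH-adjusted FDR strictly below 0.05 AND |log2FC| ≥ 2
(inclusive). FDR is adjusted within each comparison.

## Temporal profiles

Model profiles are all cumulative templates over T ordered time points with
unit steps in {−c..+c}, flat excluded — (2c+1)^(T−1) − 1 templates; T = 3,
c = 1 gives 8, numbered lexicographically by their values after the first
(profile 0 = (0,−1,−2) … profile 7 = (0,1,2); {4,6,7} increasing, {0,1,3}
decreasing, 2 down-up, 5 up-down). A transcript's stage means (v0,v1,v2)
are normalised to (0, log2((v1+1)/(v0+1)), log2((v2+1)/(v0+1))) and assigned
to the template with the highest Pearson correlation (ties to the lowest
profile id). Filters: max/min fold of the pseudocount-stabilised raw values
below 2 or a flat normalised series (`low_range`), best correlation below
0.7 (`low_correlation`). Profile significance compares observed sizes with
the mean sizes over all 6 permutations of the stage columns (exhaustive for
T = 3) via a binomial upper tail, BH-adjusted across profiles.

## Targets, network, enrichment, qPCR

- **cis**: coding genes whose span lies within 10 kb of the lncRNA locus
  span, boundary-inclusive (a gap of exactly 10 000 bp qualifies), either
  side, strand-agnostic. Distance is the span gap (0 on overlap).
- **trans**: |Pearson r| strictly greater than 0.95 on log2(FPKM+1) across
  all nine samples, lncRNA × coding gene. Series that are constant to
  within float rounding (SD ≤ 1e−9) are skipped — correlations of
  last-ulp noise are meaningless.
- **network**: among DE lncRNAs and DE mRNAs only, edges at |r| strictly
  greater than 0.98; hubs are nodes ranked by degree (ties broken by id).
- **enrichment**: one-sided hypergeometric upper tail P(X ≥ k) via the
  survival function, flat term annotations, BH across terms; the background
  is the expressed coding-gene universe.
- **qPCR**: ΔCt = Ct(target) − Ct(reference); ΔΔCt against the calibrator
  group's *mean* ΔCt (replicates are unpaired); RQ = 2^−ΔΔCt. One-way ANOVA
  with Tukey HSD (studentized range) and a sweep-and-absorb compact letter
  display. When all groups have zero within-group variance the F test is
  undefined; groups are separated by exact means and flagged.

## Synthetic data and ground truth

The generator (`synthetic_data`) plants, per seed: ~240 three-exon coding
genes on 3 chromosomes with realistic mRNA structure (ORF-poor UTRs, a
CDS of biased stop-free codons); lncRNAs of every positional class
(intergenic, antisense, sense, bidirectional, intronic) whose sequences are
rejection-sampled to have no ORF ≥ 300 nt; coding decoys (exact exon-chain
copies, class `=`, and extended isoforms, class `j`, carrying full ORFs)
that the discovery stage must reject; cis pairs at 2–8 kb from a coding
gene; a DE program in which each DE transcript follows one of the 8
temporal templates with a log2 fold of 4 per unit step; flat term
annotations with two terms enriched in the DE coding genes; and a qPCR
table consistent with the planted folds.

**Noise-free regime (default).** Counts are the exact expected values:
the per-stage count is base × 2^(4·template value), with bases chosen as
multiples of 2^8 so every value is integer; library factors are 1; and a
structural-RNA filler transcript (`rrna_filler`, a non-protein-coding
reference gene) tops every sample up to a common column total. Consequences,
all exact rather than approximate:

- flat transcripts have identical FPKM in every sample (zero variance) and
  are skipped by the correlation stages;
- the correlation between two DE transcripts equals the correlation of
  their templates: +1 for the same profile, −1 for the mirror profile
  (sign-flipped template), at most ≈0.87 otherwise. The planted trans-target
  truth is therefore *combinatorial* — all (DE lncRNA, DE coding gene) pairs
  with the same or mirrored profile — computed without touching the
  pipeline's counts→FPKM→log2→Pearson path;
- the pipeline recovers the lncRNA call set, positional classes, DE sets,
  profile assignments, cis/trans/both partition, and the planted enriched
  terms exactly (verified across multiple seeds).

The filler varies across stages by construction, so the pipeline's DE input
is restricted to reference protein-coding transcripts plus called lncRNAs —
the standard practice of excluding structural RNAs before DE.

**Stochastic regime** (`noiseless=False` / `--stochastic`): gamma–Poisson
(negative binomial, var = μ + αμ², α = 0.05) counts, library sizes uniform
in (0.8, 1.2), and a shared log-normal latent factor for planted
lncRNA–mRNA pairs. This regime feeds the calibration studies (type-I error,
power, profile recovery under noise).

## Determinism

Every random choice flows from a single `numpy.random.default_rng(seed)`;
file outputs contain no timestamps and use sorted keys, so identical seeds
yield byte-identical studies, result tables, and reports.

## Limitations

- The NB test is a deliberately compact Wald test, not a full GLM: no
  per-gene IRLS fit, no Cook's distance outlier handling, no independent
  filtering. Its calibration is verified empirically for the 3 vs 3 design.
- The hexamer score and ORF rule are desk-scale stand-ins for full
  coding-potential suites (CPC/CNCI/Pfam); they are trained on the bundled
  reference, not on external curated sets.
- Profile significance uses stage-label permutations, which is exact only
  for the 3-point design.
- The generator plants one transcript per gene (plus decoy isoforms) and
  uniform 3-exon gene structure; it emulates the analysis contract, not
  genome biology.
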