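# Methods

## Data model

The atomic record is one variant observed in one sample with read-depth
evidence from a DNA assay (deep targeted sequencing of recurrently mutated
genes) and an RNA assay (whole-transcriptome sequencing). Variant allele
frequencies (VAFs) are always recomputed from depths, in percent, and never
trusted from input files; DNA and RNA calls are matched by
parsimony-normalised `(chrom, pos, ref, alt)` identity (shared prefix
trimmed before shared suffix, at least one base kept per allele) — exact
matching only, since different callers spell the same INDEL differently but
fuzzy matching would manufacture pairs. Region files follow BED (0-based,
half-open); variant positions are 1-based (VCF); conversion happens only at
the region-membership boundary. Strand is ignored throughout: variants are
genomic and strand-symmetric.

## Transcription classes and genotypes

A variant is **transcribed** when both assays show at least one alternate
read and the RNA locus is covered at or above the detection floor (default
10x); **DNA-exclusive** when RNA shows no alternate read at ≥ 4x RNA
coverage (enough to assert absence, a weaker requirement than detection);
**RNA-exclusive** when DNA shows no alternate read at ≥ 30x DNA coverage;
otherwise **unevaluable**. Keeping detection (10x) and absence (4x) floors
distinct separates "not transcribed" from "not assessable", which a single
threshold conflates.

Genotypes come from VAF bands: AB for VAF in [2, 75] percent (both edges
inclusive — deterministic tie-breaking), BB above, AA below. Comparing DNA
and RNA genotypes yields a conversion (AB→BB: mutant-abundant; AB→AA:
wild-type transcript only). Conversions are inadmissible for DNA VAF < 2%
and for BB→AA changes, which are biologically implausible and treated as
artefacts; BB→AB conversions are retained but are expected band-edge
artefacts of the arbitrary heterozygous definition.

## RNA depth-cutoff calibration

Transcribed variants are binned by RNA read depth (unit bins to a cap,
default 50, then one overflow bin). Within each bin the AB and BB
proportions are computed; the selected cutoff is the smallest depth *d*
such that |prop_AB − prop_BB| deviates from its value at *d* by at most
`tolerance` (default 0.02) across `window` (default 5) consecutive
evaluable bins. "Stabilised" is inherently a visual judgement; this rule is
one deterministic operationalisation, and both parameters are exposed. With
fewer than `window` evaluable bins, or no stable depth, the conventional
10x default is returned with an explicit flag. The rule is monotone:
tightening the tolerance never selects an earlier cutoff. SNVs and INDELs
should be summarised separately — INDEL counts per depth bin are usually
too sparse for the convergence argument to hold.

## Bias filters

All filters are evaluated for every variant (no short-circuiting), so the
report lists every reason a variant fails:

* depth floors (defaults 30x DNA, 10x RNA) and a minimum alternate-read
  count (2) in at least one assay;
* strand bias: two-sided Fisher's exact test on the ref/alt × fwd/rev
  table (all-zero table ⇒ p = 1);
* read-position bias: one-sample Kolmogorov–Smirnov test of alt-supporting
  read offsets against Uniform[0, read_length); fewer than 2 offsets is
  untestable (p = 1);
* mapping- and base-quality bias: Mann–Whitney rank test of alt- vs
  ref-supporting per-read qualities, auto-passing when the input dialect
  carries no per-read qualities;
* blacklists (RNA-editing sites, repeats, error-prone regions), intersected
  at the variant's anchor position only — deterministic and compatible with
  single-position blacklist files.

Bias tests fail a variant when p < 0.01 by default. All thresholds are
configuration, not constants: the mechanism is the deliverable and
study-specific values can be substituted.

## The WAI regression

For variant *i*, `expected_i = dna_vaf_i × rna_total_depth_i / 100`. The
weighted allelic imbalance of a group (gene, or mutation type) is the OLS
slope β of observed RNA alternate depth on expected depth, with an
intercept and dummy-coded categorical covariates (mutation type for
gene-wise fits, gene for type-wise fits, plus cohort for pooled
multi-cohort fits; constant covariate columns drop out, so a single-cohort
pooled fit reproduces the plain gene-wise fit exactly). The test is against
β = 1, not 0 — only that reading makes "WAI = 1 ⇒ no imbalance" coherent.
Regressing counts rather than VAFs implicitly weights variants by
coverage.

Modelling set: DNA-heterozygous (AB) recurrent mutations that are
transcribed or DNA-exclusive and admissible as conversions, passing all
filters; homozygous and RNA-exclusive variants are excluded; SNVs and
INDELs are modelled separately; groups need ≥ 5 variants; each mutation
pair is one independent row even for multiple mutations per patient per
gene. Groups whose expected depths take fewer than two distinct values are
reported as degenerate (WAI undefined, flagged) rather than fitted.

Inference is a nonparametric case-resampling bootstrap within the group
(default B = 2000): resampling is encoded as multinomial row weights so all
B weighted least-squares solves are one batched linear-algebra call;
singular replicates (a dummy level absent from a resample) are redrawn with
a bounded number of rounds and any shortfall is reported. Confidence
intervals are percentile; the p-value for H0: β = 1 is
`2·min(#{β* ≤ 1}+1, #{β* ≥ 1}+1)/(B+1)`, capped at 1. The percentile
method makes the fewest distributional assumptions; its far tail
(p ≲ 0.01) is mildly anti-conservative at group sizes of a few hundred
with heavy-tailed depth leverage (measured ≈ 1.2% below 0.01 under the
null), while the 5% level is calibrated (≈ 5–6% measured). Bootstrap
results are reproducible bit-for-bit given (seed, B); per-group seeds are
spawned from the analysis seed over the sorted group labels, so results do
not depend on row order.

p-values are Benjamini–Hochberg adjusted within one family per (analysis,
variant class) across its groups, matching per-table reporting granularity.
A group's direction tag (mutant- vs wild-type-abundant) is set only when
the adjusted p is below 0.05.

### SNP negative control

The same machinery runs on common SNPs in samples without recurrent
mutations in the target genes, on the minor-allele scale: when the DNA VAF
exceeds 50% the minor allele is REF, so the expected depth uses 100 − VAF
and the observed count is `rna_total − rna_alt`. Germline SNPs have no
allele-specific mechanism tied to somatic mutation, so their true WAI is 1;
with five genes tested and BH adjustment, an exactly calibrated test is
expected to show a spurious gene in about 5% of cohorts (the Simes
equality), so occasional single-gene flags in the negative control are the
expected false-positive rate, not a defect.

## Synthetic cohort generator

The generator emulates the paired-cohort structure so truth is known:

* depths: negative binomial, DNA mean 542 / dispersion 8, RNA mean 85 /
  dispersion 5 (deep amplicon panel vs whole-transcriptome coverage),
  clipped below at the assay floors (30x / 10x) so evaluability is never
  the limiting factor unless configured otherwise;
* DNA VAF: Beta(2, 3) scaled to [2, 75] percent — subclonal, median ≈ 30%;
* `dna_alt ~ Binomial(dna_total, vaf/100)`; the RNA allele-sampling
  probability is `min(1, true_wai × recorded_vaf/100)` where
  `recorded_vaf = dna_alt/dna_total`. Conditioning on the *recorded* VAF
  (the regressor the model sees) makes the regression estimand exactly the
  generative factor; conditioning on the latent VAF instead would introduce
  errors-in-variables attenuation (≈ 1% at 542x) and an inflated type-I
  error. Probabilities clamped at 1 are counted and reported as a warning —
  configurations where clamping is frequent (large factor × high VAF) have
  a different estimand by construction;
* non-transcription: with probability 0.04 the mutant allele produces no
  RNA alternate reads (the ~4% DNA-exclusive fraction seen in practice);
* RNA-exclusive decoys at 15 per sample (error-dominated false positives,
  anchored at well-covered DNA loci);
* common SNPs at true WAI 1, population MAF ~ Normal(50%, 5%), planted in
  mutation-free samples, heterozygous/homozygous by Hardy–Weinberg;
* `sampling_noise=False` replaces every binomial draw by its rounded
  expectation, making genotype-conversion counts exactly predictable.

Default gene panel: eleven recurrently mutated AML genes with modest
imbalance factors in [0.73, 1.4] (mutant-abundant, balanced and
wild-type-abundant examples; two INDEL-dominated genes), reflecting the
small-but-significant effects this analysis targets.

What the generator does *not* emulate: read-level artefacts (alignment,
duplicates, strand and position biases are exercised only through planted
evidence columns), RNA-editing biochemistry, copy-number alterations,
imprinting, and correlated noise between variants of one sample. Passing
tests therefore demonstrate the correctness of the statistical machinery
under the stated generative model, not robustness to every failure mode of
real sequencing data.

## Problem sizes and numerical choices

Test and verification runs use groups of 200 mutations (100 groups for CI
coverage, 200 for type-I), a 10,000-mutation cohort for classifier
recovery, B = 1000–2000 bootstrap replicates, and 20 replicate cohorts for
the SNP control — sizes at which the measured quantities are stable while a
full verification run stays in the minutes range. Exact-recovery fixtures
use integer-valued observed = k × expected grids so the slope is recovered
to numerical precision (asserted at 1e-9). Band edges, cutoff stability,
tie-breaks and degenerate-group handling are all deterministic; every
stochastic path takes an explicit seed.

## Known limitations

* The per-variant bias filters need evidence columns (strand counts,
  offsets, qualities) that sites-only VCFs lack; absent evidence
  auto-passes, so filtering strength depends on the input dialect.
* INDEL normalisation is reference-free; representations that require
  reference-context left-shifting will not unify.
* The percentile bootstrap's far tail is slightly anti-conservative at
  moderate group sizes (see above); studies screening many groups at
  stringent adjusted thresholds may prefer larger groups or more
  conservative inference.
* Locus coverage for variants seen in only one assay is not recoverable
  from sites-only VCFs and is recorded as 0; depth-floor filters then
  remove such rows unless a consolidated table supplies true locus depths.
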