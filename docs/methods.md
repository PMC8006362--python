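# Methods

## Problem setting

A somatic SNV acquired after fertilization is carried by a clone of cells;
in bulk sequencing of a tissue it appears at a variant allele fraction
(VAF) equal to half the fraction of cells carrying it — between ~0.005 and
~0.28 for variants of early development, against 0.5 for a germline
heterozygote. Callers run with elevated ploidy recover such low-fraction
alleles but emit candidate lists dominated by germline SNPs and artifacts;
the toolkit's job is principled post-hoc filtering, orthogonal validation,
and biological interpretation of the survivors.

## Filter cascade

All verdicts are PASS/FAIL/NA per filter per candidate; records are never
deleted during evaluation (hard filtering is a write-time switch), so the
full verdict matrix is available for post-hoc analyses.

* **Ploidy rule** — advisory caller setting `max(2, round(0.2 × coverage))`,
  i.e. about five reads per modelled haplotype (ploidy 50 at 250×).
  Rounds to nearest and clamps at diploid; the rule's source states only
  the 20% proportionality.
* **Germline het test** — exact two-sided binomial test of alt/depth
  against p = 0.5, minimum-likelihood two-sidedness (sum of outcome
  probabilities no larger than the observed one); a candidate with
  p > 10⁻⁶ is labelled germline. At 250× this flags > 99% of true hets
  while the exact mislabel probability for a mosaic stays below 10⁻⁴ up to
  VAF ≈ 0.24; at the extreme 0.28 edge of the mosaic range it rises to
  ~1%, an inherent limit of separating a 0.28-VAF clone from a
  heterozygote at this depth.
* **Strand bias** — two tests, failing on either at α = 0.05: exact
  binomial evenness of alt reads across strands, and Fisher's exact test
  on the ref/alt × fwd/rev table. Zero alt reads gives NA.
* **Panel of normals** — a site fails when its alternate allele fraction
  exceeds 0.05 in more than 5 panel samples (zero-depth panel samples are
  not counted either way). The module is panel-agnostic: the same rule
  serves a 2504-sample population panel or a smaller cohort.
* **Hard thresholds** — popAF > 0.001; < 5 supporting reads; CN > 2.5;
  counts taken at MQ/BQ ≥ 20 (recorded on the counts object). The CN
  cutoff is nominally a "scrutinize CNV regions" step; the numeric 2.5
  rule is adopted from the discovery-pipeline practice and is
  configurable.
* **Multiallelic** — fails when "other"-allele reads exceed
  max(2, 0.02 × depth). The intent is a single dominant third allele; the
  pileup exchange format carries only an aggregate other-read count, so
  the threshold is applied to that aggregate (conservative, since a
  dominant third base is the usual failure mode).
* **Context filters** — indel within ±5 bp, homopolymer run of ≥ 5 bases
  (configurable; no canonical run length exists) within 2 bp, repeat-track
  membership, another candidate within 100 bp, and an optional depth
  outlier rule (|z| > 3, off by default as it belongs to the extended
  rather than core filter set).
* **VAF denominator** is the full quality-filtered depth including
  other-allele reads — the conservative pileup-style convention.

## Amplicon validation

Read pairs are merged over their overlap; discordant bases become N at
quality 0 and are excluded from every frequency numerator and denominator.
Concordant positions keep the higher of the two qualities. The error model
collects, per substitution type X>Y, the per-site mismatch frequency at
non-candidate positions and stores the 95th percentile as a noise cutoff.
The percentile is nearest-rank (the ⌈0.95 n⌉-th order statistic): exact,
deterministic, and checkable against a sorted list. A type with no
observations falls back to the pooled global cutoff.

Classification order: depth < 200 → NED ("read not enough"); case
AF > 0.40 → germline; then false-positive triggers — control AF > 0.01,
no significant case excess (Skellam p ≥ 0.05), case AF within the
substitution type's noise cutoff, or case AF < 0.005 — any of which
rejects; otherwise the site validates. All triggered reasons are kept. The
0.005 floor is applied both here and during discordance resolution.

**Skellam test.** The control count is scaled to the case depth
(k′ = k·n_case/n_ctrl) and the difference k_case − k′ is referred, under
the null of equal fractions, to a Skellam distribution with both Poisson
means at the pooled average (k_case + k′)/2; the p-value is the upper tail
at ⌈D⌉ on the integer support. The exact parameterization of the published
test is not stated; this choice is explicit and swappable, and an exact
conditional binomial test (case count binomial in the total at
n_case/(n_case+n_ctrl)) is provided as an independent cross-check — the
two agree in ordering on > 95% of random configurations. α = 0.05, the
conventional level, as no level is published for this test.

**Discordance resolution** across experiments: unanimity stands; else
overlap-consensus experiments win if they agree among themselves; else
invalidation rules fire in a fixed order (4-haplotype state, amplicon
VAF < 0.005, < 3 reads in every WGS replicate, flagged
indel/homopolymer/CNV context), then the germline rule (VAF near 0.5 plus
a 2-haplotype state), then NED. The source enumerates these rules without
an order; the order here is the one that never lets weaker evidence
overrule stronger.

## Orthogonal evidence

**Linked reads.** With alternate reads confined to one haplotype, the site
is germline if they are > 90% of that haplotype's reads (strict
inequality, as published) and mosaic otherwise ("third haplotype").
Alternate reads on both haplotypes (≥ 2 each; the guard against single
stray reads is this module's own) indicate sequencing error ("four
haplotypes"). No assigned alternate reads → no information.

**Single cells.** MDA propagates a first-round polymerase error into one
strand of one allele, an expected alternate fraction of 1/8. The genotype
test is a one-sided binomial likelihood ratio of p = 0.125 + θ against
p = 0.125, floored at zero and referred to upper-tail χ²₁. The printed
form of the statistic has an ambiguous sign; the standard one-sided LRT is
implemented, which is what the χ²₁ reference requires. θ is the
kernel-smoothed local haplotype balance minus 0.125, floored at 0
(allelic loss is not modelled); the kernel is Gaussian with sd = 10 kb
(the published optimum is a size, not a shape) over phased het SNPs
within 5 bandwidths, and a locus with no informative het SNP falls back
to θ = 0.375 (balanced, p = 0.5). Under the null
(alt ~ Binomial(100, 0.125)) the test's empirical size at α = 0.05 is
≤ 0.06 — slightly conservative-to-nominal given discreteness.

Site-level flags (PASS: some cell rejects the null at α = 0.05; LOWQUAL:
every alt-bearing cell below 10× at the locus; ARTIF: alt reads present
but no rejection; NOFLAG: no alt reads) are this package's explicit
definitions; the upstream genotyper's are unpublished. The support
category boundary (alt reads in ≥ 4 cells) is as published.

## Naive Bayes consolidation

Four categorical feature groups (PON ≤ 5 / > 5; linked-read
PASS/FAIL/NOINFO; single-cell support NONE/LT4/GE4; single-cell flag
PASS/LOWQUAL/ARTIF/NOFLAG), each likelihood estimated with pseudocount 1
per category. The denominator adds the group's category count (Laplace
smoothing), which is the unique choice that keeps each table normalized
per class given the published pseudocount. The posterior is the displayed
two-class ratio, computed in log space; LOOCV refits on n−1 sites per
fold, with a prior-only prediction (and a counter) for degenerate folds.
Decision threshold 0.5 by default; the operating point behind the
published headline metrics is not stated and those metrics require the
original 400-site feature table, so they are not reproduced here.

## Lineage reconstruction

A clade marker's VAF in a tissue is half the clade's cell fraction, so
sister-lineage markers satisfy VAF₁ + VAF₂ = 0.5 per sample. Pair score =
mean per-sample |VAF₁ + VAF₂ − 0.5| (the √2 diagonal-projection constant
is dropped; ranking is invariant to it), pairwise-complete over samples,
ranked ascending. Pair significance is a two-sided Welch t-test of the
pair's per-sample distances against the pooled distances of the other
pairs — an explicit stand-in, as the published "< 0.05" test is unnamed.
SNVs cluster under Canberra distance (sensitive across the two decades of
VAF magnitude involved) with average linkage; cells cluster under Jaccard
distance on present-marker sets, where presence means ≥ 1 supporting read
and cells with no present marker are excluded. Missing VAFs are imputed
as 0 for clustering (complete vectors needed) but excluded from pair
scoring (imputation would fabricate complementarity).

Tree assembly renders the published manual procedure as an algorithm: cut
the SNV dendrogram into groups (largest cut height whose groups each span
≤ 0.05 VAF per sample, configurable), order groups by mean VAF descending,
attach each group under the deepest placed group whose cells contain all
of its carrier cells, and report containment violations instead of
resolving them silently.

## Synthetic data

The generators emit the exact table schemas the readers consume, and every
dataset regenerates bit-identically from (seed, parameters).

* **Bulk cohorts**: 35% mosaic (VAF uniform in 0.005–0.28), 25% germline
  het (VAF 0.5), 40% error sites (VAF ≈ 10⁻³, half strand-asymmetric) at
  250× fixed depth, sites 10 kb apart, substitution types drawn with C>T
  and G>A upweighted 2× to echo the deamination-heavy somatic spectrum.
  The class mix mirrors caller candidate lists in which false positives
  outnumber true mosaics.
* **Mixing designs**: expected VAF = Σᵢ propᵢ·genotypeᵢ/2 with binomial
  sampling; a germline het private to a 10% contributor simulates a
  0.05-VAF mosaic.
* **Amplicon libraries**: case ~ Binomial(10⁴, AF + e_type),
  control ~ Binomial(10⁴, e_type), e = 10⁻³ by default per type, plus 30
  background sites per substitution type so the error profile has
  structure to estimate.
* **Single cells**: 12 cells assigned to lineage paths by clade fraction;
  carried variants sampled at a per-(site, cell) Beta(10, 10) haplotype
  balance (MDA skews allelic representation), artifacts at exactly 0.125,
  10% locus dropout, and phased het SNPs nearby that reflect the same
  balance — the signal the kernel estimator is meant to recover.
* **Lineage panels**: per-sample L1 fraction uniform in (0.2, 0.8) with L2
  complementary, three markers per lineage, VAF = fraction/2 observed
  through binomial sampling at 250×.

What the simulators do **not** model: alignment and mappability error,
read-position and base-quality structure, PCR duplicates, CNV-induced VAF
shifts, contamination, or correlated errors across sites. Passing
closed-loop tests therefore demonstrates the statistics and bookkeeping
are correct under the stated generative assumptions, not that real-data
performance matches the published figures, which depend on external
caller behaviour and terabyte-scale datasets.

## Numerical and scale choices

Exact tests come from scipy (binomtest's minimum-likelihood two-sided
definition matches the one specified here; Fisher via the hypergeometric);
brute-force enumeration oracles in the test suite verify both across all
configurations to depth 25. Ties in allele ranking break by base order
A<C<G<T. Zero depth is an undefined VAF, never 0. The end-to-end suite
uses 1000-site cohorts at 250×, the LR calibration 10⁴ null replicates,
and lineage recovery 100 seeded panels of 8 samples — sizes at which the
measured properties (≥ 90% mid-VAF mosaic retention, ≥ 99%
germline/error removal, ≥ 95/100 sister-pair recovery, mean top-pair VAF
sum within 0.5 ± 0.02) are stable.

## Known limitations

MosaicForecast-style machine-learning rescoring participates only as a
pluggable score-table hook; copy number arrives as an annotation, never
computed from reads; BAM/CRAM pileup generation is out of scope (counts
come in as tables); the single-cell flag definitions and the lineage pair
test are explicit stand-ins for unpublished choices, as noted above.
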