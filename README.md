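# mosaictk

Detection and interpretation of **somatic mosaic SNVs** — variants acquired
post-zygotically and present in only a fraction of an individual's cells —
from bulk short-read sequencing of non-cancerous tissue. Mosaic variants sit
at variant allele fractions (VAF) from ~0.005 to ~0.28, far below the 0.5 of
a germline heterozygote, so candidate lists from standard callers are
dominated by germline SNPs, sequencing artifacts and alignment errors.
`mosaictk` implements, as a reusable library plus a thin CLI:

* **The best-practices filter cascade** for post-caller cleanup: a
  coverage-to-ploidy rule for the upstream caller (ploidy = 0.2 × coverage),
  accessibility masking, population allele frequency screening (> 0.001 →
  germline), an exact binomial test against the VAF ≈ 0.5 germline
  expectation (retain when *p* < 10⁻⁶), a ≥ 5 supporting-read rule at
  MQ/BQ ≥ 20, copy-number (CN > 2.5) and multiallelic checks, strand-bias
  tests (binomial evenness + Fisher's exact ref/alt imbalance), and a
  **panel-of-normals** filter failing sites with alternate allele fraction
  > 0.05 in more than 5 unrelated samples. Every filter records a
  PASS/FAIL/NA verdict; nothing is silently dropped.
* **Amplicon validation statistics**: overlap consensus merging of read
  pairs (discordant bases → N), an empirical per-substitution-type error
  model (95th-percentile noise cutoffs from background positions), a
  Skellam test for case-vs-control alternate count excess, and site
  classification into TRUE_MOSAIC / FALSE_POSITIVE / GERMLINE / NED.
* **Orthogonal evidence**: linked-read 2/3/4-haplotype classification
  (germline SNP / true mosaic / sequencing artifact) and a single-cell
  likelihood-ratio genotype test against the MDA-artifact null
  *p* = 0.125, with kernel-smoothed allelic balance (Gaussian, 10 kb):
  −2 log[f(X; 0.125)/f(X; 0.125 + θ)] ~ χ²₁.
* **Naive Bayes consolidation** of PON, linked-read and single-cell
  features into a validation posterior Pr(B | S), with pseudocount-1
  smoothing and leave-one-out cross-validation metrics.
* **Lineage reconstruction**: markers of the two earliest embryonic sister
  lineages are anti-correlated across tissues with VAF₁ + VAF₂ ≈ 0.5;
  the toolkit clusters SNVs by VAF profile (average linkage, Canberra),
  clusters cells by shared genotypes (Jaccard), ranks SNV pairs by mean
  |VAF₁ + VAF₂ − 0.5|, and assembles a nested lineage tree.
* **Seeded simulators** for every input above, with planted truth, so the
  whole pipeline is testable closed-loop.

## Worked example

```python
from mosaictk import CandidateSNV, run_cascade, sim_bulk_pileups

pileups, truth = sim_bulk_pileups(n_sites=300, coverage=250, seed=1)
candidates = [CandidateSNV(site=s, counts=c) for s, c in pileups.items()]
annotated, summary = run_cascade(candidates)
print(summary["n_surviving"], "/", summary["n_candidates"])
```

Running `python examples/filter_candidates.py` prints:

```
advisory caller ploidy for 250x data: 50

95/300 candidates survive all filters
failures per filter:
  het_germline    75
  read_support    127
  strand_bias     13
mosaic        planted 105  surviving  95
germline_het  planted  75  surviving   0
error         planted 120  surviving   0
```

All 75 planted germline heterozygotes fail the binomial het test, all 120
error sites fail read support and/or strand bias, and the mosaics lost are
those whose VAF puts them under the five-read floor at 250×. The other
scripts in `examples/` walk through amplicon validation, single-cell
genotyping, evidence consolidation and lineage reconstruction the same
way.

The CLI mirrors the library:

```bash
mosaictk simulate bulk --seed 3 --out sim/
mosaictk filter --vcf cands.vcf --pileup sim/pileup.tsv --out filtered
mosaictk lineage --vafs vafs.tsv --out lineage_out
```

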