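"""Run the best-practices filter cascade on a simulated 250x candidate cohort.

Generates a caller-like candidate list (mosaic SNVs, germline het SNPs and
error sites with known truth), applies every filter, and reports how many
of each planted class survive.
"""
from mosaictk import CandidateSNV, ploidy_for_coverage, run_cascade, sim_bulk_pileups

pileups, truth = sim_bulk_pileups(n_sites=300, coverage=250, seed=1)
print(f"advisory caller ploidy for 250x data: {ploidy_for_coverage(250)}")

candidates = [CandidateSNV(site=s, counts=c) for s, c in pileups.items()]
annotated, summary = run_cascade(candidates)

print(f"\n{summary['n_surviving']}/{summary['n_candidates']} candidates survive all filters")
print("failures per filter:")
for name, n in sorted(summary["fail_counts"].items()):
    if n:
        print(f"  {name:15s} {n}")

by_class = truth.table.set_index("pos")["class"]
survivors = [c for c in annotated if c.passes]
for cls in ("mosaic", "germline_het", "error"):
    total = (by_class == cls).sum()
    kept = sum(by_class[c.site.pos] == cls for c in survivors)
    print(f"{cls:13s} planted {total:3d}  surviving {kept:3d}")
# Surviving germline/error counts should be ~0; surviving mosaics are the
# planted variants with enough supporting reads at their VAF.
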