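"""Distinguish true mosaic variants from MDA artifacts in single cells.

A first-round multiple-displacement-amplification error propagates to an
expected alternate-read fraction of 1/8. The likelihood-ratio test
contrasts that null against the locally estimated allelic balance.
"""
from mosaictk import (
    HaplotypeEvidence,
    PhasedHetSNP,
    SingleCellCall,
    classify_haplotype_state,
    estimate_allelic_balance,
    summarize_single_cell_support,
)

# Local allelic balance from phased het SNPs within ~10 kb of the locus
hets = [PhasedHetSNP(99_000, 22, 18), PhasedHetSNP(103_000, 19, 21)]
ab = estimate_allelic_balance(hets, position=100_000, target_haplotype=1)
print(f"smoothed balance {ab.balance:.3f}, theta {ab.theta:.3f}")

for label, alt, depth in [("true variant", 14, 30), ("MDA artifact", 4, 30)]:
    call = SingleCellCall.from_counts("cell1", alt, depth, ab.theta)
    print(f"{label:13s} {alt}/{depth} alt -> LR {call.lr_stat:6.2f}  p {call.p_value:.2e}")

calls = [SingleCellCall.from_counts(f"c{i}", x, 30, ab.theta)
         for i, x in enumerate([14, 12, 0, 0, 3])]
support, flag = summarize_single_cell_support(calls)
print(f"site summary: support {support.value}, flag {flag.value}")

# Linked-read haplotype states for the same kinds of site:
for label, ev in [
    ("mosaic (minor allele, one haplotype)", HaplotypeEvidence(5, 40, 0, 38)),
    ("germline (whole haplotype)", HaplotypeEvidence(38, 40, 0, 39)),
    ("artifact (both haplotypes)", HaplotypeEvidence(4, 40, 5, 38)),
]:
    print(f"{label}: {classify_haplotype_state(ev).value}")
# A variant at ~half the reads of a balanced locus rejects the 0.125 null;
# reads at ~1/8 do not.
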