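"""Orthogonal evidence for candidate mosaic SNVs.

Two independent data types can separate a true mosaic variant from both
germline SNPs and sequencing/amplification artifacts:

* Linked-read (barcoded short-read) haplotype assignments. A germline
  heterozygous SNP occupies one full parental haplotype ("2 haplotypes");
  a true mosaic SNV appears as a minor allele on exactly one haplotype
  ("3 haplotypes"); alternate reads on both haplotypes ("4 haplotypes")
  can only come from recurrent sequencing error.

* Single-cell whole-genome data amplified by multiple displacement
  amplification (MDA). A polymerase error in the first round of MDA is
  copied into one of the two strands of one of the two alleles, so the
  expected alternate-read fraction of such an artifact is 1/8 = 0.125. A
  likelihood-ratio test contrasts that null against a true variant at the
  locally estimated allelic balance (0.125 + theta), with the statistic
  referred to a chi-square distribution with one degree of freedom.
"""
from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

MDA_ARTIFACT_P = 0.125  # expected alt fraction of a first-round MDA artifact


class HaplotypeClass(enum.Enum):
    GERMLINE_2HAP = "GERMLINE_2HAP"
    MOSAIC_3HAP = "MOSAIC_3HAP"
    ARTIFACT_4HAP = "ARTIFACT_4HAP"
    NO_INFO = "NO_INFO"


@dataclass(frozen=True)
class HaplotypeEvidence:
    """Haplotype-assigned read counts at one site in linked-read data."""

    hap1_alt: int
    hap1_total: int
    hap2_alt: int
    hap2_total: int
    unassigned_alt: int = 0
    unassigned_total: int = 0

    def __post_init__(self) -> None:
        if self.hap1_alt > self.hap1_total or self.hap2_alt > self.hap2_total:
            raise ValueError("alt reads exceed total on a haplotype")
        if min(self.hap1_alt, self.hap1_total, self.hap2_alt, self.hap2_total) < 0:
            raise ValueError("negative read count")


def classify_haplotype_state(
    ev: HaplotypeEvidence,
    germline_fraction: float = 0.9,
    min_alt_per_hap: int = 2,
) -> HaplotypeClass:
    """Assign the 2/3/4-haplotype state from haplotype-resolved counts.

    No haplotype-assigned alternate reads gives NO_INFO. Alternate reads
    on both haplotypes (at least ``min_alt_per_hap`` each, guarding
    against single stray reads) give ARTIFACT_4HAP. Otherwise the alt is
    confined to one haplotype: if it makes up more than
    ``germline_fraction`` of that haplotype's reads it is a germline SNP
    (GERMLINE_2HAP), else a mosaic candidate (MOSAIC_3HAP).
    """
    if ev.hap1_alt + ev.hap2_alt == 0:
        return HaplotypeClass.NO_INFO
    if ev.hap1_alt >= min_alt_per_hap and ev.hap2_alt >= min_alt_per_hap:
        return HaplotypeClass.ARTIFACT_4HAP
    if ev.hap1_alt >= ev.hap2_alt:
        alt, total = ev.hap1_alt, ev.hap1_total
    else:
        alt, total = ev.hap2_alt, ev.hap2_total
    if total > 0 and alt / total > germline_fraction:
        return HaplotypeClass.GERMLINE_2HAP
    return HaplotypeClass.MOSAIC_3HAP


@dataclass(frozen=True)
class PhasedHetSNP:
    """Reads over a phased germline het SNP in one cell."""

    pos: int
    hap1_reads: int
    hap2_reads: int

    @property
    def total(self) -> int:
        return self.hap1_reads + self.hap2_reads


@dataclass
class AllelicBalance:
    """Kernel-smoothed local haplotype balance around a locus."""

    balance: float  # smoothed fraction of reads from the target haplotype
    theta: float    # excess over the MDA-artifact null, floored at 0
    n_snps: int


def estimate_allelic_balance(
    het_snps: Sequence[PhasedHetSNP],
    position: int,
    target_haplotype: int = 1,
    bandwidth: float = 10_000.0,
) -> Optional[AllelicBalance]:
    """Estimate local allelic balance by Gaussian kernel smoothing.

    Averages, over phased het SNPs within 5 bandwidths of ``position``,
    the per-SNP fraction of reads from the target haplotype, weighted by a
    Gaussian kernel (sd = ``bandwidth``, default 10 kb). theta is the
    excess of that balance over the MDA-artifact fraction 0.125, floored
    at zero. Returns None when no informative SNP is in range; callers
    then fall back to theta = 0.375 (an alternate allele fraction of 0.5).
    """
    if target_haplotype not in (1, 2):
        raise ValueError("target_haplotype must be 1 or 2")
    weights, fractions = [], []
    for snp in het_snps:
        if snp.total == 0 or abs(snp.pos - position) > 5 * bandwidth:
            continue
        reads = snp.hap1_reads if target_haplotype == 1 else snp.hap2_reads
        fractions.append(reads / snp.total)
        weights.append(math.exp(-((snp.pos - position) ** 2) / (2 * bandwidth**2)))
    if not weights:
        return None
    b = float(np.average(fractions, weights=weights))
    return AllelicBalance(balance=b, theta=max(b - MDA_ARTIFACT_P, 0.0), n_snps=len(weights))


def lr_genotype_test(x_alt: int, depth: int, theta: float) -> tuple[float, float]:
    """One-sided binomial likelihood-ratio test against the MDA null.

    Null: alt reads ~ Binomial(depth, 0.125). Alternative: Binomial(depth,
    0.125 + theta) with theta >= 0 estimated from local allelic balance.
    The statistic 2*(l_alt - l_null) is floored at zero (evidence must
    favour the mosaic hypothesis) and referred to the upper tail of
    chi-square with 1 df.
    """
    if depth <= 0 or not 0 <= x_alt <= depth:
        raise ValueError("need 0 <= x_alt <= depth with depth > 0")
    p_alt = MDA_ARTIFACT_P + theta
    if not 0 <= p_alt <= 1 or theta < 0:
        raise ValueError(f"invalid alternate proportion 0.125 + {theta}")
    ll_null = stats.binom.logpmf(x_alt, depth, MDA_ARTIFACT_P)
    ll_alt = stats.binom.logpmf(x_alt, depth, p_alt)
    lr = max(0.0, 2.0 * float(ll_alt - ll_null))
    return lr, float(stats.chi2.sf(lr, df=1))


class SingleCellFlag(enum.Enum):
    PASS = "PASS"        # at least one cell rejects the artifact null
    LOWQUAL = "LOWQUAL"  # alt-bearing cells all under-covered
    ARTIF = "ARTIF"      # alt reads present but consistent with MDA artifact
    NOFLAG = "NOFLAG"    # no alternate reads in any cell


class SupportCategory(enum.Enum):
    NONE = "NONE"  # no cell with alternate reads
    LT4 = "LT4"    # alternate reads in 1-3 cells
    GE4 = "GE4"    # alternate reads in >= 4 cells


@dataclass
class SingleCellCall:
    """Genotyping result for one site in one cell."""

    cell: str
    x_alt: int
    depth: int
    theta: float
    lr_stat: float
    p_value: float

    @classmethod
    def from_counts(cls, cell: str, x_alt: int, depth: int, theta: float) -> "SingleCellCall":
        lr, p = lr_genotype_test(x_alt, depth, theta)
        return cls(cell, x_alt, depth, theta, lr, p)


def summarize_single_cell_support(
    calls: Sequence[SingleCellCall],
    alpha: float = 0.05,
    min_depth: int = 10,
) -> tuple[SupportCategory, SingleCellFlag]:
    """Site-level summary over the genotyped cells.

    Support category counts cells with any alternate reads (NONE / LT4 /
    GE4 at the published >=4-cell boundary). The flag is NOFLAG without
    any alternate reads; LOWQUAL when every alt-bearing cell is below
    ``min_depth``; PASS when at least one cell rejects the MDA-artifact
    null at ``alpha``; ARTIF when alt reads exist but no cell rejects.
    """
    if len(calls) == 0:
        raise ValueError("need at least one cell")
    alt_cells = [c for c in calls if c.x_alt > 0]
    if not alt_cells:
        return SupportCategory.NONE, SingleCellFlag.NOFLAG
    category = SupportCategory.GE4 if len(alt_cells) >= 4 else SupportCategory.LT4
    if all(c.depth < min_depth for c in alt_cells):
        return category, SingleCellFlag.LOWQUAL
    if any(c.p_value < alpha for c in alt_cells):
        return category, SingleCellFlag.PASS
    return category, SingleCellFlag.ARTIF
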