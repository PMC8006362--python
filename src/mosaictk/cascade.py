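"""The best-practices post-caller filtering cascade for mosaic SNVs.

Bulk short-read callers run at high ploidy emit large candidate lists that
are dominated by germline heterozygous SNPs, systematic sequencing
artifacts and alignment errors. This module applies the consensus
filtering workflow to such candidate lists: genome accessibility masking,
population-frequency screening, an exact binomial test against the VAF≈0.5
germline expectation, minimum read support, copy-number sanity checks, a
panel-of-normals (PON) recurrence filter, strand-bias tests, and a set of
sequence-context filters (indel proximity, homopolymers, repeats, call
clusters, depth outliers).

Every filter records a PASS/FAIL/NA verdict on the candidate rather than
deleting it, so the full verdict matrix is available for post-hoc
analysis; hard filtering happens only at write time.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .io import IntervalTrack, in_track
from .types import CandidateSNV, GenomicSite, StrandCounts, Verdict


@dataclass
class CascadeConfig:
    """Thresholds of the filtering cascade.

    Defaults follow the published best-practices recommendations: quality
    cutoffs of 20 for mapping and base quality, at least five independent
    supporting reads, a population allele frequency ceiling of 0.001, a
    germline binomial-test p-value cutoff of 1e-6, a copy-number ceiling
    of 2.5, and a PON rule flagging sites with alternate allele fraction
    > 0.05 in more than 5 panel samples.
    """

    mq_min: int = 20
    bq_min: int = 20
    min_alt_reads: int = 5
    popaf_max: float = 0.001
    het_p_cutoff: float = 1e-6
    cn_max: float = 2.5
    pon_af_threshold: float = 0.05
    pon_max_samples: int = 5
    pon_min_depth: int = 1
    strand_alpha: float = 0.05
    indel_window: int = 5          # bp either side of the site
    cluster_window: int = 100      # bp between neighbouring candidates
    homopolymer_min_run: int = 5   # run length counted as a homopolymer
    homopolymer_margin: int = 2    # bp between site and run
    depth_z_max: float = 3.0
    multiallelic_min_other: int = 2
    multiallelic_other_frac: float = 0.02
    mosaicforecast_min_score: float = 0.5
    # per-filter enable switches
    enable_accessibility: bool = True
    enable_popaf: bool = True
    enable_het_test: bool = True
    enable_read_support: bool = True
    enable_copy_number: bool = True
    enable_multiallelic: bool = True
    enable_pon: bool = True
    enable_strand_bias: bool = True
    enable_context: bool = True
    enable_cluster: bool = True
    enable_depth_outlier: bool = False  # extended filter, not in the core list
    enable_replicates: bool = False
    enable_mosaicforecast: bool = False


@dataclass
class PonSummary:
    """Per-site panel-of-normals recurrence counts."""

    n_samples_total: int
    n_samples_exceeding: dict[GenomicSite, int] = field(default_factory=dict)
    fractions: dict[GenomicSite, list[float]] = field(default_factory=dict)

    def count(self, site: GenomicSite) -> Optional[int]:
        return self.n_samples_exceeding.get(site)


@dataclass
class CascadeResources:
    """External annotation bundles consumed by the cascade.

    Any resource may be None, in which case the corresponding filter
    records NA verdicts and the run summary carries a warning.
    """

    accessible_track: Optional[IntervalTrack] = None
    indel_track: Optional[IntervalTrack] = None
    repeat_track: Optional[IntervalTrack] = None
    popaf: Optional[Mapping[GenomicSite, float]] = None
    pon: Optional[PonSummary] = None
    copy_number: Optional[Mapping[GenomicSite, float]] = None
    reference_windows: Optional[Mapping[GenomicSite, str]] = None
    mosaicforecast_scores: Optional[Mapping[GenomicSite, float]] = None


def ploidy_for_coverage(coverage: float) -> int:
    """Advisory caller ploidy: 20% of the fold-coverage, at least diploid.

    High-ploidy genotyping lets the caller entertain low-fraction alleles;
    20% of coverage corresponds to roughly five reads per modelled
    haplotype (e.g. ploidy 50 for 250x whole-genome data).
    """
    if coverage <= 0:
        raise ValueError(f"coverage must be positive, got {coverage}")
    return max(2, round(0.2 * coverage))


def test_het_binomial(alt: int, depth: int, p0: float = 0.5) -> float:
    """Exact two-sided binomial p-value of ``alt`` successes in ``depth`` at p0.

    Two-sidedness is the minimum-likelihood definition: the sum of
    probabilities of all outcomes no more likely than the observed one.
    Candidates with p above the cascade cutoff are consistent with a
    germline heterozygous VAF of 0.5 and are labelled GERMLINE.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not 0 <= alt <= depth:
        raise ValueError("alt must lie in [0, depth]")
    return stats.binomtest(alt, depth, p0, alternative="two-sided").pvalue


def test_strand_bias(counts: StrandCounts) -> tuple[Optional[float], Optional[float]]:
    """Strand evenness and ref/alt strand imbalance p-values.

    Evenness: exact two-sided binomial test of the alt forward count
    against a fair strand split. Imbalance: two-sided Fisher exact test of
    the 2x2 table [[ref_fwd, ref_rev], [alt_fwd, alt_rev]]. With zero alt
    reads neither test is informative and (None, None) is returned.
    """
    n_alt = counts.alt_fwd + counts.alt_rev
    if n_alt == 0:
        return None, None
    p_even = stats.binomtest(counts.alt_fwd, n_alt, 0.5, alternative="two-sided").pvalue
    table = [[counts.ref_fwd, counts.ref_rev], [counts.alt_fwd, counts.alt_rev]]
    p_imb = stats.fisher_exact(table, alternative="two-sided")[1]
    return p_even, p_imb


def build_pon(
    per_sample_counts: Mapping[str, Mapping[GenomicSite, tuple[int, int]]],
    af_threshold: float = 0.05,
    min_depth: int = 1,
    keep_fractions: bool = False,
) -> PonSummary:
    """Summarize a panel of normals into per-site recurrence counts.

    A panel sample counts toward a site when its depth reaches
    ``min_depth`` and its alternate allele fraction exceeds
    ``af_threshold``. Zero-depth samples are not counted either way.
    """
    if not per_sample_counts:
        raise ValueError("panel of normals requires at least one sample")
    summary = PonSummary(n_samples_total=len(per_sample_counts))
    for counts in per_sample_counts.values():
        for site, (alt, depth) in counts.items():
            summary.n_samples_exceeding.setdefault(site, 0)
            if depth >= min_depth and depth > 0:
                af = alt / depth
                if keep_fractions:
                    summary.fractions.setdefault(site, []).append(af)
                if af > af_threshold:
                    summary.n_samples_exceeding[site] += 1
    return summary


def apply_pon(site: GenomicSite, pon: PonSummary, cfg: CascadeConfig) -> Verdict:
    """FAIL a site seen above the panel allele-fraction threshold in more
    than ``pon_max_samples`` unrelated samples (recurrent artifact)."""
    n = pon.count(site)
    if n is None:
        return Verdict.NA
    return Verdict.FAIL if n > cfg.pon_max_samples else Verdict.PASS


def replicate_concordance(
    vafs_by_replicate: Sequence[float],
    min_vaf: float = 0.01,
    min_replicates: int = 3,
) -> bool:
    """True when the variant exceeds ``min_vaf`` in at least
    ``min_replicates`` replicate datasets (strict inequality on VAF)."""
    if len(vafs_by_replicate) == 0:
        raise ValueError("need at least one replicate VAF")
    return sum(v > min_vaf for v in vafs_by_replicate) >= min_replicates


def context_flags(
    site: GenomicSite,
    reference_window: Optional[str],
    indel_track: Optional[IntervalTrack],
    repeat_track: Optional[IntervalTrack],
    neighbor_sites: Sequence[GenomicSite],
    cfg: CascadeConfig,
    depth: Optional[int] = None,
    depth_stats: Optional[tuple[float, float]] = None,
) -> dict[str, Optional[bool]]:
    """Sequence-context flags for one site.

    ``reference_window`` is centred on the site (odd length). A flag value
    of None means the needed resource was unavailable.
    """
    flags: dict[str, Optional[bool]] = {}

    if indel_track is None:
        flags["near_indel"] = None
    else:
        hit = False
        tree = indel_track.trees.get(site.chrom)
        if tree is not None:
            lo = max(0, site.pos - 1 - cfg.indel_window)
            hi = site.pos + cfg.indel_window
            hit = bool(tree.overlap(lo, hi))
        flags["near_indel"] = hit

    if reference_window is None:
        flags["near_homopolymer"] = None
    else:
        flags["near_homopolymer"] = _near_homopolymer(
            reference_window, cfg.homopolymer_min_run, cfg.homopolymer_margin
        )

    if repeat_track is None:
        flags["in_repeat"] = None
    else:
        flags["in_repeat"] = in_track(site, repeat_track)

    flags["clustered"] = any(
        other.chrom == site.chrom and other != site and abs(other.pos - site.pos) <= cfg.cluster_window
        for other in neighbor_sites
    )

    if depth is None or depth_stats is None or depth_stats[1] == 0:
        flags["depth_outlier"] = None
    else:
        mean, sd = depth_stats
        flags["depth_outlier"] = abs(depth - mean) / sd > cfg.depth_z_max
    return flags


def _near_homopolymer(window: str, min_run: int, margin: int) -> bool:
    """A homopolymer run of >= min_run whose span comes within ``margin``
    bases of the window centre."""
    center = len(window) // 2
    run_start = 0
    for i in range(1, len(window) + 1):
        if i == len(window) or window[i] != window[run_start]:
            run_len = i - run_start
            if run_len >= min_run and window[run_start] in "ACGT":
                if run_start - margin <= center <= i - 1 + margin:
                    return True
            run_start = i
    return False


def filter_site(
    cand: CandidateSNV,
    cfg: CascadeConfig,
    resources: CascadeResources,
) -> CandidateSNV:
    """Evaluate the per-site (context-free) cascade filters on one candidate.

    Sets verdicts: accessibility, popaf, het_germline, read_support,
    copy_number, multiallelic, strand_bias, pon, mosaicforecast and
    replicates where enabled. Missing annotations give NA, never FAIL.
    """
    v = cand.verdicts
    site = cand.site
    counts = cand.counts

    if cfg.enable_accessibility:
        if resources.accessible_track is None:
            v["accessibility"] = Verdict.NA
        else:
            v["accessibility"] = (
                Verdict.PASS if in_track(site, resources.accessible_track) else Verdict.FAIL
            )

    if cfg.enable_popaf:
        af = cand.annotations.popaf
        if af is None and resources.popaf is not None:
            af = resources.popaf.get(site, 0.0)
        if af is None:
            v["popaf"] = Verdict.NA
        else:
            v["popaf"] = Verdict.FAIL if af > cfg.popaf_max else Verdict.PASS

    if cfg.enable_het_test:
        if counts is None or counts.depth == 0:
            v["het_germline"] = Verdict.NA
        else:
            p = test_het_binomial(counts.alt, counts.depth)
            v["het_germline"] = Verdict.FAIL if p > cfg.het_p_cutoff else Verdict.PASS

    if cfg.enable_read_support:
        if counts is None:
            v["read_support"] = Verdict.NA
        else:
            v["read_support"] = Verdict.FAIL if counts.alt < cfg.min_alt_reads else Verdict.PASS

    if cfg.enable_copy_number:
        cn = cand.annotations.copy_number
        if cn is None and resources.copy_number is not None:
            cn = resources.copy_number.get(site)
        if cn is None:
            v["copy_number"] = Verdict.NA
        else:
            v["copy_number"] = Verdict.FAIL if cn > cfg.cn_max else Verdict.PASS

    if cfg.enable_multiallelic:
        if counts is None or counts.depth == 0:
            v["multiallelic"] = Verdict.NA
        else:
            cutoff = max(cfg.multiallelic_min_other, cfg.multiallelic_other_frac * counts.depth)
            v["multiallelic"] = Verdict.FAIL if counts.other > cutoff else Verdict.PASS

    if cfg.enable_strand_bias:
        if counts is None:
            v["strand_bias"] = Verdict.NA
        else:
            p_even, p_imb = test_strand_bias(counts)
            if p_even is None:
                v["strand_bias"] = Verdict.NA
            else:
                biased = p_even < cfg.strand_alpha or p_imb < cfg.strand_alpha
                v["strand_bias"] = Verdict.FAIL if biased else Verdict.PASS

    if cfg.enable_pon:
        if resources.pon is None:
            v["pon"] = Verdict.NA
        else:
            v["pon"] = apply_pon(site, resources.pon, cfg)

    if cfg.enable_replicates:
        vafs = cand.annotations.replicate_vafs
        if vafs is None:
            v["replicates"] = Verdict.NA
        else:
            v["replicates"] = Verdict.PASS if replicate_concordance(vafs) else Verdict.FAIL

    if cfg.enable_mosaicforecast:
        scores = resources.mosaicforecast_scores
        if scores is None or site not in scores:
            v["mosaicforecast"] = Verdict.NA
        else:
            ok = scores[site] >= cfg.mosaicforecast_min_score
            v["mosaicforecast"] = Verdict.PASS if ok else Verdict.FAIL

    return cand


def run_cascade(
    candidates: Sequence[CandidateSNV],
    cfg: Optional[CascadeConfig] = None,
    resources: Optional[CascadeResources] = None,
) -> tuple[list[CandidateSNV], dict]:
    """Apply every enabled filter to every candidate; never short-circuits.

    Returns the annotated candidates (same order as given) and a summary
    with per-filter failure counts, survivor count, and warnings for
    resources that were absent. Verdicts depend only on the candidate set,
    not on its order.
    """
    cfg = cfg or CascadeConfig()
    resources = resources or CascadeResources()
    candidates = list(candidates)
    all_sites = [c.site for c in candidates]

    depth_stats: Optional[tuple[float, float]] = None
    if cfg.enable_depth_outlier:
        depths = [c.counts.depth for c in candidates if c.counts is not None]
        if len(depths) >= 2:
            depth_stats = (float(np.mean(depths)), float(np.std(depths, ddof=1)))

    for cand in candidates:
        filter_site(cand, cfg, resources)
        if cfg.enable_context or cfg.enable_cluster or cfg.enable_depth_outlier:
            window = None
            if resources.reference_windows is not None:
                window = resources.reference_windows.get(cand.site)
            flags = context_flags(
                cand.site, window, resources.indel_track, resources.repeat_track,
                all_sites, cfg,
                depth=cand.counts.depth if cand.counts else None,
                depth_stats=depth_stats,
            )
            ann = cand.annotations
            ann.near_indel, ann.near_homopolymer = flags["near_indel"], flags["near_homopolymer"]
            ann.in_repeat, ann.clustered = flags["in_repeat"], flags["clustered"]
            ann.depth_outlier = flags["depth_outlier"]
            if cfg.enable_context:
                for name in ("near_indel", "near_homopolymer", "in_repeat"):
                    val = flags[name]
                    cand.verdicts[name] = (
                        Verdict.NA if val is None else (Verdict.FAIL if val else Verdict.PASS)
                    )
            if cfg.enable_cluster:
                cand.verdicts["clustered"] = Verdict.FAIL if flags["clustered"] else Verdict.PASS
            if cfg.enable_depth_outlier:
                val = flags["depth_outlier"]
                cand.verdicts["depth_outlier"] = (
                    Verdict.NA if val is None else (Verdict.FAIL if val else Verdict.PASS)
                )

    filter_names = sorted({name for c in candidates for name in c.verdicts})
    fail_counts = {
        name: sum(c.verdicts.get(name) is Verdict.FAIL for c in candidates)
        for name in filter_names
    }
    warnings_ = []
    for attr, label in [
        ("accessible_track", "accessibility mask"), ("popaf", "population AF table"),
        ("pon", "panel of normals"), ("copy_number", "copy-number track"),
    ]:
        if getattr(resources, attr) is None:
            warnings_.append(f"{label} absent: corresponding verdicts are NA")
    summary = {
        "n_candidates": len(candidates),
        "n_surviving": sum(c.passes for c in candidates),
        "fail_counts": fail_counts,
        "warnings": warnings_,
    }
    return candidates, summary
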