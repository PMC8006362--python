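"""Deep amplicon-sequencing validation of candidate mosaic SNVs.

Targeted PCR amplicons sequenced to ~10^4x depth can confirm or refute a
candidate down to sub-percent allele fractions, provided the amplicon's
own error floor is known. This module implements the validation pipeline:

* overlap consensus merging of read pairs (discordant bases masked to N),
* an empirical per-substitution-type error model built from consensus
  pileups at non-candidate positions (95th-percentile noise cutoffs),
* a Skellam test comparing case vs control alternate counts,
* site classification into TRUE_MOSAIC / FALSE_POSITIVE / GERMLINE / NED,
* and resolution of discordant validation outcomes across experiments.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from scipy import stats

from .types import GenomicSite, ValidationStatus

SUBSTITUTION_TYPES = tuple(
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
)

BASES = "ACGT"


# ---------------------------------------------------------------------------
# Read-pair overlap consensus
# ---------------------------------------------------------------------------

@dataclass
class MergedRead:
    """Consensus of an overlapping read pair.

    Discordant overlap positions carry base N with quality 0 and a False
    concordance flag; everywhere else the flag is True.
    """

    sequence: str
    qualities: list[int]
    concordant: list[bool]


def merge_overlapping_pair(
    read1: tuple[str, Sequence[int]],
    read2: tuple[str, Sequence[int]],
    overlap_offset: int,
) -> MergedRead:
    """Merge a read pair whose second read starts ``overlap_offset`` bases
    into the first.

    Concordant overlap positions keep the base with the higher of the two
    qualities; discordant positions become N with quality zero.
    Non-overlapping prefix/suffix bases pass through unchanged.
    """
    seq1, q1 = read1
    seq2, q2 = read2
    if len(seq1) != len(q1) or len(seq2) != len(q2):
        raise ValueError("sequence and quality lengths differ")
    if overlap_offset < 0 or overlap_offset >= len(seq1):
        raise ValueError(f"offset {overlap_offset} outside read1")
    overlap_len = min(len(seq1) - overlap_offset, len(seq2))
    if overlap_len < 1:
        raise ValueError("reads do not overlap at this offset")

    seq, quals, conc = list(seq1[:overlap_offset]), list(q1[:overlap_offset]), \
        [True] * overlap_offset
    for i in range(overlap_len):
        b1, b2 = seq1[overlap_offset + i], seq2[i]
        if b1 == b2:
            seq.append(b1)
            quals.append(max(q1[overlap_offset + i], q2[i]))
            conc.append(True)
        else:
            seq.append("N")
            quals.append(0)
            conc.append(False)
    seq += list(seq2[overlap_len:])
    quals += list(q2[overlap_len:])
    conc += [True] * (len(seq2) - overlap_len)
    return MergedRead("".join(seq), quals, conc)


# ---------------------------------------------------------------------------
# Empirical error profile
# ---------------------------------------------------------------------------

def nearest_rank_percentile(values: Sequence[float], pct: float = 95.0) -> float:
    """Nearest-rank percentile: the ceil(pct/100 * n)-th order statistic."""
    if len(values) == 0:
        raise ValueError("empty sample")
    s = sorted(values)
    rank = math.ceil(pct / 100.0 * len(s))
    return s[max(rank, 1) - 1]


@dataclass
class ErrorProfile:
    """Per-substitution-type noise distributions from consensus pileups.

    ``rates[t]`` holds the per-site mismatch ("second allele") frequencies
    observed for substitution type t at non-candidate positions;
    ``cutoff(t)`` is the 95th-percentile (nearest-rank) noise level used
    as the minimum believable allele fraction for that base change.
    """

    rates: dict[str, list[float]] = field(default_factory=dict)
    percentile: float = 95.0

    def cutoff(self, subst: str) -> Optional[float]:
        obs = self.rates.get(subst)
        if not obs:
            return None
        return nearest_rank_percentile(obs, self.percentile)

    def global_cutoff(self) -> Optional[float]:
        pooled = [r for obs in self.rates.values() for r in obs]
        if not pooled:
            return None
        return nearest_rank_percentile(pooled, self.percentile)

    def cutoff_or_global(self, subst: str) -> Optional[float]:
        c = self.cutoff(subst)
        return c if c is not None else self.global_cutoff()


def build_error_profile(
    consensus_pileups: Iterable[tuple[str, Mapping[str, int]]],
    percentile: float = 95.0,
) -> ErrorProfile:
    """Build the noise model from per-site base counts at non-candidate sites.

    Each pileup is ``(ref_base, counts)`` where counts maps A/C/G/T (and
    optionally N) to read counts from merged consensus reads. N bases are
    excluded from both numerator and denominator. For a site with
    reference X, every alternate base Y contributes one observation of the
    X>Y mismatch frequency.
    """
    profile = ErrorProfile(percentile=percentile)
    for ref, counts in consensus_pileups:
        if ref not in BASES:
            continue
        total = sum(counts.get(b, 0) for b in BASES)
        if total == 0:
            continue
        for alt in BASES:
            if alt == ref:
                continue
            profile.rates.setdefault(f"{ref}>{alt}", []).append(counts.get(alt, 0) / total)
    return profile


def allele_rank_frequencies(base_counts: Mapping[str, int]) -> tuple[float, float]:
    """Fractions of the 2nd and 3rd most frequent bases at a site.

    Ties are broken by base order A<C<G<T so the result is deterministic.
    """
    total = sum(base_counts.get(b, 0) for b in BASES)
    if total == 0:
        raise ValueError("zero depth")
    ranked = sorted(BASES, key=lambda b: (-base_counts.get(b, 0), b))
    return base_counts.get(ranked[1], 0) / total, base_counts.get(ranked[2], 0) / total


# ---------------------------------------------------------------------------
# Case/control tests
# ---------------------------------------------------------------------------

def skellam_test(k_case: int, n_case: int, k_ctrl: int, n_ctrl: int) -> float:
    """Upper-tail Skellam p-value for excess alternate reads in the case.

    The control count is scaled to the case depth (k' = k_ctrl *
    n_case/n_ctrl) and the difference D = k_case - k' is modelled, under
    the null of equal allele fractions, as the difference of two Poisson
    counts with common mean (k_case + k')/2. Returns P(D_null >= D).
    """
    if n_case <= 0 or n_ctrl <= 0:
        raise ValueError("depths must be positive")
    k_scaled = k_ctrl * n_case / n_ctrl
    d = k_case - k_scaled
    mu = (k_case + k_scaled) / 2.0
    if mu == 0:
        return 1.0  # no alternate evidence anywhere: no excess
    # P(X >= ceil(d)) on the integer Skellam support
    return float(stats.skellam.sf(math.ceil(d) - 1, mu, mu))


def conditional_binomial_test(k_case: int, n_case: int, k_ctrl: int, n_ctrl: int) -> float:
    """Exact one-sided case/control comparison used as a cross-check.

    Conditional on the total alternate count, the case count is binomial
    with success probability n_case/(n_case+n_ctrl) under the null;
    returns the upper-tail p-value.
    """
    if n_case <= 0 or n_ctrl <= 0:
        raise ValueError("depths must be positive")
    total = k_case + k_ctrl
    if total == 0:
        return 1.0
    p = n_case / (n_case + n_ctrl)
    return float(stats.binom.sf(k_case - 1, total, p))


# ---------------------------------------------------------------------------
# Site classification
# ---------------------------------------------------------------------------

@dataclass
class AmpliconConfig:
    """Classification thresholds for amplicon validation."""

    min_depth: int = 200          # below this: NED ("read not enough")
    germline_af: float = 0.40     # above this: germline SNP
    control_af_max: float = 0.01  # control allele fraction hard cutoff
    skellam_alpha: float = 0.05
    min_af: float = 0.005         # amplicon VAF floor for a believable call
    error_percentile: float = 95.0


@dataclass
class AmpliconSiteData:
    """Case and control amplicon counts for one candidate site."""

    site: GenomicSite
    case_alt: int
    case_depth: int
    ctrl_alt: Optional[int] = None
    ctrl_depth: Optional[int] = None
    overlap_consensus: bool = True
    base_counts: Optional[Mapping[str, int]] = None

    @property
    def case_af(self) -> float:
        return self.case_alt / self.case_depth if self.case_depth else float("nan")

    @property
    def ctrl_af(self) -> Optional[float]:
        if self.ctrl_depth is None or self.ctrl_alt is None or self.ctrl_depth == 0:
            return None
        return self.ctrl_alt / self.ctrl_depth


def classify_amplicon_site(
    data: AmpliconSiteData,
    profile: ErrorProfile,
    cfg: Optional[AmpliconConfig] = None,
) -> tuple[ValidationStatus, list[str]]:
    """Classify one candidate from its amplicon counts.

    Decision order: insufficient depth -> NED; near-0.5 allele fraction ->
    GERMLINE; any false-positive criterion (control contamination, no
    significant case excess by the Skellam test, allele fraction within
    the substitution-type noise floor, or below the 0.005 VAF floor) ->
    FALSE_POSITIVE; otherwise TRUE_MOSAIC. All triggered reasons are
    returned; missing control data disables the control checks and is
    itself recorded as a reason.
    """
    cfg = cfg or AmpliconConfig()
    reasons: list[str] = []

    if data.case_depth < cfg.min_depth:
        return ValidationStatus.NED, ["read not enough"]

    af = data.case_af
    if af > cfg.germline_af:
        return ValidationStatus.GERMLINE, [f"case AF {af:.3f} > {cfg.germline_af}"]

    is_fp = False
    if data.ctrl_depth is None or data.ctrl_alt is None:
        reasons.append("no control data: control checks skipped")
    else:
        ctrl_af = data.ctrl_af
        if ctrl_af is not None and ctrl_af > cfg.control_af_max:
            is_fp = True
            reasons.append(f"control AF {ctrl_af:.4f} > {cfg.control_af_max}")
        p = skellam_test(data.case_alt, data.case_depth, data.ctrl_alt, data.ctrl_depth)
        if p >= cfg.skellam_alpha:
            is_fp = True
            reasons.append(f"Skellam p {p:.3g} >= {cfg.skellam_alpha}")

    cutoff = profile.cutoff_or_global(data.site.substitution)
    if cutoff is not None and af <= cutoff:
        is_fp = True
        reasons.append(f"case AF {af:.4f} <= error cutoff {cutoff:.4f} for {data.site.substitution}")
    elif cutoff is None:
        reasons.append("no error-profile cutoff available")

    if af < cfg.min_af:
        is_fp = True
        reasons.append(f"case AF {af:.4f} < floor {cfg.min_af}")

    if is_fp:
        return ValidationStatus.FALSE_POSITIVE, reasons
    return ValidationStatus.TRUE_MOSAIC, reasons


# ---------------------------------------------------------------------------
# Discordance resolution across experiments
# ---------------------------------------------------------------------------

@dataclass
class ConsolidationEvidence:
    """Orthogonal evidence consulted when validation experiments disagree."""

    haplotype_class: Optional[str] = None      # HaplotypeClass name, if available
    amplicon_vaf: Optional[float] = None
    wgs_replicate_alt_reads: Optional[Sequence[int]] = None
    context_flagged: Optional[bool] = None     # near indel/homopolymer/CNV
    bulk_vaf: Optional[float] = None


def resolve_discordant(
    statuses: Sequence[tuple[ValidationStatus, dict]],
    evidence: Optional[ConsolidationEvidence] = None,
    cfg: Optional[AmpliconConfig] = None,
) -> ValidationStatus:
    """Resolve conflicting validation outcomes for one site.

    Precedence: (1) unanimous statuses stand; (2) experiments with
    overlapping end reads (``meta['overlap_consensus']``) are more
    reliable — their unanimous status stands; (3) invalidation rules:
    a 4-haplotype linked-read state, an amplicon VAF below 0.005, fewer
    than 3 supporting reads in every WGS replicate, or a flagged
    indel/homopolymer/CNV context each force FALSE_POSITIVE; (4) a
    near-0.5 VAF together with a 2-haplotype state means GERMLINE;
    (5) otherwise NED.
    """
    if len(statuses) == 0:
        raise ValueError("need at least one validation status")
    cfg = cfg or AmpliconConfig()
    evidence = evidence or ConsolidationEvidence()

    unique = {s for s, _ in statuses}
    if len(unique) == 1:
        return unique.pop()

    overlap = {s for s, meta in statuses if meta.get("overlap_consensus")}
    if len(overlap) == 1:
        return overlap.pop()

    if evidence.haplotype_class == "ARTIFACT_4HAP":
        return ValidationStatus.FALSE_POSITIVE
    if evidence.amplicon_vaf is not None and evidence.amplicon_vaf < cfg.min_af:
        return ValidationStatus.FALSE_POSITIVE
    reps = evidence.wgs_replicate_alt_reads
    if reps is not None and len(reps) > 0 and all(r < 3 for r in reps):
        return ValidationStatus.FALSE_POSITIVE
    if evidence.context_flagged:
        return ValidationStatus.FALSE_POSITIVE

    vaf = evidence.bulk_vaf if evidence.bulk_vaf is not None else evidence.amplicon_vaf
    if (
        vaf is not None
        and vaf > cfg.germline_af
        and evidence.haplotype_class == "GERMLINE_2HAP"
    ):
        return ValidationStatus.GERMLINE

    return ValidationStatus.NED
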