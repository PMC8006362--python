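"""Shared domain types for the mosaic-SNV toolkit.

Conventions: variant positions are 1-based (VCF); interval tracks are
0-based half-open (BED). Conversions happen only at I/O boundaries.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

_BASES = frozenset("ACGT")


class ValidationStatus(enum.Enum):
    """Outcome of an orthogonal validation experiment for one site."""

    TRUE_MOSAIC = "TRUE_MOSAIC"
    FALSE_POSITIVE = "FALSE_POSITIVE"
    GERMLINE = "GERMLINE"
    NED = "NED"  # not enough data


class Verdict(enum.Enum):
    """Per-filter state of a candidate. NA means the filter could not run."""

    PASS = "PASS"
    FAIL = "FAIL"
    NA = "NA"


@dataclass(frozen=True, order=True)
class GenomicSite:
    """A single-nucleotide variant locus: chromosome, 1-based position, ref>alt."""

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(f"ref/alt must be single bases A/C/G/T: {self.ref}>{self.alt}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def substitution(self) -> str:
        """Substitution type label, e.g. 'C>T'. Twelve possible values."""
        return f"{self.ref}>{self.alt}"

    def __str__(self) -> str:
        return f"{self.chrom}:{self.pos} {self.ref}>{self.alt}"


@dataclass(frozen=True)
class StrandCounts:
    """Strand-resolved, quality-filtered read counts at a site.

    Counts reflect non-duplicate reads passing the mapping/base quality
    cutoffs recorded in ``mq_min``/``bq_min``. ``other`` counts reads
    supporting neither the ref nor the alt allele; ``depth`` is the total
    of all retained reads and always equals the sum of the five counts.
    """

    ref_fwd: int
    ref_rev: int
    alt_fwd: int
    alt_rev: int
    other: int = 0
    mq_min: int = 20
    bq_min: int = 20

    def __post_init__(self) -> None:
        for name in ("ref_fwd", "ref_rev", "alt_fwd", "alt_rev", "other"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def depth(self) -> int:
        return self.ref_fwd + self.ref_rev + self.alt_fwd + self.alt_rev + self.other

    @property
    def alt(self) -> int:
        return self.alt_fwd + self.alt_rev

    @property
    def ref(self) -> int:
        return self.ref_fwd + self.ref_rev


def compute_vaf(counts: StrandCounts) -> float:
    """Variant allele fraction: alt reads over total retained depth.

    Raises
    ------
    ValueError
        If depth is zero; a zero-depth site has an undefined VAF, which is
        deliberately not conflated with VAF 0.
    """
    if counts.depth == 0:
        raise ValueError("VAF undefined at zero depth")
    return counts.alt / counts.depth


@dataclass
class Annotations:
    """Optional per-site context used by the filter cascade.

    ``None`` for any field means the annotation was unavailable, in which
    case the corresponding filter records an NA verdict rather than a guess.
    """

    popaf: Optional[float] = None          # population allele frequency
    copy_number: Optional[float] = None    # local copy-number estimate
    near_indel: Optional[bool] = None
    near_homopolymer: Optional[bool] = None
    in_repeat: Optional[bool] = None
    clustered: Optional[bool] = None
    depth_outlier: Optional[bool] = None
    replicate_vafs: Optional[list[float]] = None


@dataclass
class CandidateSNV:
    """One candidate mosaic SNV with counts, annotations and filter verdicts."""

    site: GenomicSite
    counts: Optional[StrandCounts] = None
    annotations: Annotations = field(default_factory=Annotations)
    verdicts: dict[str, Verdict] = field(default_factory=dict)

    @property
    def vaf(self) -> Optional[float]:
        if self.counts is None or self.counts.depth == 0:
            return None
        return compute_vaf(self.counts)

    def failed_filters(self) -> list[str]:
        return sorted(k for k, v in self.verdicts.items() if v is Verdict.FAIL)

    @property
    def passes(self) -> bool:
        """True when no evaluated filter failed."""
        return not any(v is Verdict.FAIL for v in self.verdicts.values())
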