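"""Seeded simulators for every input the toolkit consumes.

Each generator emulates the study conditions of deep bulk sequencing of
non-cancerous tissue: mosaic SNVs at variant allele fractions from 0.005
to 0.28, germline heterozygous SNPs at VAF ~0.5, binomial read sampling
at 75-250x coverage, per-substitution sequencing error with a C>T excess,
MDA first-round artifacts with an expected alternate fraction of 0.125 in
single cells, and two sister embryonic lineages whose cell fractions sum
to one across tissues. All randomness flows through a single integer
seed, so any dataset is bit-identical under regeneration.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .amplicon import SUBSTITUTION_TYPES, AmpliconSiteData
from .evidence import MDA_ARTIFACT_P, PhasedHetSNP
from .types import GenomicSite, StrandCounts

BASES = "ACGT"


@dataclass
class SyntheticTruth:
    """Planted ground truth emitted alongside every simulated dataset."""

    table: pd.DataFrame
    seed: int
    params: dict = field(default_factory=dict)


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _random_substitution(rng: np.random.Generator, ct_weight: float) -> tuple[str, str]:
    """Draw a substitution type; C>T (and its complement G>A) upweighted to
    mirror the deamination-dominated somatic spectrum."""
    weights = np.array(
        [ct_weight if t in ("C>T", "G>A") else 1.0 for t in SUBSTITUTION_TYPES]
    )
    t = rng.choice(len(SUBSTITUTION_TYPES), p=weights / weights.sum())
    ref, alt = SUBSTITUTION_TYPES[t].split(">")
    return ref, alt


# ---------------------------------------------------------------------------
# Bulk pileups
# ---------------------------------------------------------------------------

def sim_bulk_pileups(
    n_sites: int = 300,
    mosaic_fraction: float = 0.35,
    germline_fraction: float = 0.25,
    mosaic_vaf_range: tuple[float, float] = (0.005, 0.28),
    coverage: int = 250,
    error_rate: float = 1e-3,
    strand_bias_fraction: float = 0.5,
    ct_weight: float = 2.0,
    site_spacing: int = 10_000,
    seed: int = 0,
) -> tuple[dict[GenomicSite, StrandCounts], SyntheticTruth]:
    """Simulate a caller candidate list as strand-resolved pileup counts.

    Sites are planted every ``site_spacing`` bp on one chromosome; each is
    a mosaic SNV (VAF uniform in ``mosaic_vaf_range``), a germline het SNP
    (VAF 0.5) or a sequencing-error site (VAF ~ ``error_rate``). A
    ``strand_bias_fraction`` of error sites place all alternate reads on
    one strand, mimicking systematic strand artifacts. Alt counts are
    binomial at fixed ``coverage``.
    """
    lo, hi = mosaic_vaf_range
    if not (0 < lo < hi < 0.5):
        raise ValueError("mosaic VAF range must satisfy 0 < lo < hi < 0.5")
    if mosaic_fraction + germline_fraction > 1:
        raise ValueError("class fractions exceed 1")
    rng = _rng(seed)
    n_mosaic = round(n_sites * mosaic_fraction)
    n_germ = round(n_sites * germline_fraction)
    classes = ["mosaic"] * n_mosaic + ["germline_het"] * n_germ
    classes += ["error"] * (n_sites - len(classes))
    rng.shuffle(classes)

    pileups: dict[GenomicSite, StrandCounts] = {}
    rows = []
    for i, cls in enumerate(classes):
        ref, alt = _random_substitution(rng, ct_weight)
        site = GenomicSite("chr1", (i + 1) * site_spacing, ref, alt)
        if cls == "mosaic":
            vaf = float(rng.uniform(lo, hi))
        elif cls == "germline_het":
            vaf = 0.5
        else:
            vaf = error_rate
        n_alt = int(rng.binomial(coverage, vaf))
        n_ref = coverage - n_alt
        strand_biased = cls == "error" and rng.random() < strand_bias_fraction
        if strand_biased:
            alt_fwd = n_alt if rng.random() < 0.5 else 0
        else:
            alt_fwd = int(rng.binomial(n_alt, 0.5)) if n_alt else 0
        ref_fwd = int(rng.binomial(n_ref, 0.5)) if n_ref else 0
        pileups[site] = StrandCounts(
            ref_fwd, n_ref - ref_fwd, alt_fwd, n_alt - alt_fwd, 0
        )
        rows.append(
            {
                "chrom": site.chrom, "pos": site.pos, "ref": ref, "alt": alt,
                "class": cls, "true_vaf": vaf, "strand_biased": strand_biased,
            }
        )
    truth = SyntheticTruth(
        table=pd.DataFrame(rows),
        seed=seed,
        params={
            "n_sites": n_sites, "coverage": coverage, "error_rate": error_rate,
            "mosaic_vaf_range": mosaic_vaf_range, "site_spacing": site_spacing,
            "span_bp": n_sites * site_spacing,
        },
    )
    return pileups, truth


# ---------------------------------------------------------------------------
# DNA mixing experiment
# ---------------------------------------------------------------------------

@dataclass
class MixDesign:
    """Design of a cell-line DNA mixing experiment.

    ``genotypes`` is a sites x individuals matrix of alternate allele copy
    numbers in {0, 1, 2}; ``proportions`` are the mixing fractions of the
    individuals (summing to 1). Private germline SNPs diluted by mixing
    act as proxies for mosaic SNVs of known VAF.
    """

    genotypes: np.ndarray
    proportions: np.ndarray
    coverage: int = 100
    error_rate: float = 1e-3
    sites: Optional[Sequence[GenomicSite]] = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes)
        self.proportions = np.asarray(self.proportions, dtype=float)
        if np.any(self.proportions < 0) or abs(self.proportions.sum() - 1) > 1e-9:
            raise ValueError("mixing proportions must be >= 0 and sum to 1")
        if self.genotypes.shape[1] != len(self.proportions):
            raise ValueError("genotype columns must match proportions")


def sim_mixing(design: MixDesign, seed: int = 0) -> tuple[dict[GenomicSite, StrandCounts], SyntheticTruth]:
    """Simulate pileups for a mixing design.

    The expected VAF at a site is sum_i prop_i * genotype_i / 2; observed
    alternate counts are binomial at the design coverage after folding in
    the per-base error rate (errors add alt reads at ref-dominated sites
    and remove them at alt-dominated ones).
    """
    rng = _rng(seed)
    exp_vaf = design.genotypes @ design.proportions / 2.0
    sites = list(design.sites) if design.sites is not None else [
        GenomicSite("chr1", (i + 1) * 1000, "A", "G") for i in range(len(exp_vaf))
    ]
    pileups: dict[GenomicSite, StrandCounts] = {}
    rows = []
    for site, vaf in zip(sites, exp_vaf):
        p_eff = vaf * (1 - design.error_rate) + (1 - vaf) * design.error_rate / 3
        n_alt = int(rng.binomial(design.coverage, p_eff))
        n_ref = design.coverage - n_alt
        alt_fwd = int(rng.binomial(n_alt, 0.5)) if n_alt else 0
        ref_fwd = int(rng.binomial(n_ref, 0.5)) if n_ref else 0
        pileups[site] = StrandCounts(ref_fwd, n_ref - ref_fwd, alt_fwd, n_alt - alt_fwd)
        rows.append({"chrom": site.chrom, "pos": site.pos, "expected_vaf": float(vaf)})
    truth = SyntheticTruth(
        pd.DataFrame(rows), seed,
        {"coverage": design.coverage, "error_rate": design.error_rate,
         "proportions": design.proportions.tolist()},
    )
    return pileups, truth


# ---------------------------------------------------------------------------
# Amplicon libraries
# ---------------------------------------------------------------------------

def sim_amplicon_library(
    sites_with_afs: Sequence[tuple[GenomicSite, float]],
    depth: int = 10_000,
    per_type_error_rates: Optional[Mapping[str, float]] = None,
    default_error_rate: float = 1e-3,
    n_background_per_type: int = 30,
    control: bool = True,
    seed: int = 0,
) -> tuple[list[AmpliconSiteData], list[tuple[str, dict[str, int]]], SyntheticTruth]:
    """Simulate deep amplicon counts for candidate sites plus background.

    Case alternate counts are Binomial(depth, AF + error); control counts
    (the unrelated reference individual) are Binomial(depth, error).
    Background (non-candidate) consensus pileups are emitted per
    substitution type so an error profile can be estimated downstream.
    """
    rng = _rng(seed)
    err = {t: default_error_rate for t in SUBSTITUTION_TYPES}
    if per_type_error_rates:
        err.update(per_type_error_rates)

    data: list[AmpliconSiteData] = []
    rows = []
    for site, af in sites_with_afs:
        e = err[site.substitution]
        if af + e > 1:
            raise ValueError(f"AF + error > 1 at {site}")
        case_alt = int(rng.binomial(depth, af + e))
        ctrl_alt = int(rng.binomial(depth, e)) if control else None
        data.append(
            AmpliconSiteData(
                site=site, case_alt=case_alt, case_depth=depth,
                ctrl_alt=ctrl_alt, ctrl_depth=depth if control else None,
            )
        )
        rows.append({"chrom": site.chrom, "pos": site.pos, "true_af": af,
                     "substitution": site.substitution})

    background: list[tuple[str, dict[str, int]]] = []
    for t in SUBSTITUTION_TYPES:
        ref, alt = t.split(">")
        for _ in range(n_background_per_type):
            k = int(rng.binomial(depth, err[t]))
            background.append((ref, {ref: depth - k, alt: k}))

    truth = SyntheticTruth(
        pd.DataFrame(rows), seed,
        {"depth": depth, "error_rates": err, "n_background_per_type": n_background_per_type},
    )
    return data, background, truth


# ---------------------------------------------------------------------------
# Single cells
# ---------------------------------------------------------------------------

@dataclass
class CladeSpec:
    """A lineage clade: its name, parent (None for a root), the fraction of
    all cells belonging to it, and its marker SNV ids."""

    name: str
    fraction: float
    markers: list[str]
    parent: Optional[str] = None


@dataclass
class SingleCellDataset:
    """Per-cell counts and phased het SNPs from the single-cell simulator."""

    alt: pd.DataFrame     # sites x cells alternate read counts
    depth: pd.DataFrame   # sites x cells total depth
    het_snps: dict[tuple[str, str], list[PhasedHetSNP]]  # (site, cell) -> SNPs
    cell_paths: dict[str, list[str]]  # cell -> clade names on its lineage path


def sim_single_cells(
    clades: Sequence[CladeSpec],
    n_cells: int = 12,
    mean_depth: float = 30.0,
    artifact_sites: int = 5,
    dropout_rate: float = 0.1,
    imbalance_concentration: float = 20.0,
    n_het_snps: int = 3,
    het_snp_depth: int = 40,
    seed: int = 0,
) -> tuple[SingleCellDataset, SyntheticTruth]:
    """Simulate single-cell counts under MDA amplification.

    Cells are assigned to leaf lineage paths according to the clade
    fractions. A variant carried by a cell yields alternate reads at the
    cell's local haplotype balance, drawn per (site, cell) from a
    symmetric Beta around 0.5 with the given concentration (MDA skews
    allelic representation). Artifact sites place alternate reads at the
    first-round MDA error fraction 0.125 in a random subset of cells.
    Dropout zeroes depth. Phased het SNPs near each site reflect the same
    local balance, which is what the kernel-smoothing estimator recovers.
    """
    rng = _rng(seed)
    by_name = {c.name: c for c in clades}
    roots = [c for c in clades if c.parent is None]
    if abs(sum(c.fraction for c in roots) - 1) > 1e-9:
        raise ValueError("root clade fractions must sum to 1")
    for c in clades:
        if c.parent is not None and c.fraction > by_name[c.parent].fraction + 1e-9:
            raise ValueError(f"sub-clade {c.name} larger than its parent")

    # leaves and their path fractions
    children: dict[str, list[CladeSpec]] = {}
    for c in clades:
        if c.parent is not None:
            children.setdefault(c.parent, []).append(c)

    def paths(clade: CladeSpec) -> list[tuple[list[str], float]]:
        kids = children.get(clade.name, [])
        if not kids:
            return [([clade.name], clade.fraction)]
        out = []
        used = 0.0
        for k in kids:
            for path, frac in paths(k):
                out.append(([clade.name] + path, frac))
                used += frac if len(path) == 1 else 0
        remainder = clade.fraction - sum(k.fraction for k in kids)
        if remainder > 1e-9:
            out.append(([clade.name], remainder))
        return out

    leaf_paths: list[tuple[list[str], float]] = []
    for r in roots:
        leaf_paths.extend(paths(r))
    fracs = np.array([f for _, f in leaf_paths])
    fracs = fracs / fracs.sum()
    assignments = rng.choice(len(leaf_paths), size=n_cells, p=fracs)

    cells = [f"cell{i + 1}" for i in range(n_cells)]
    cell_paths = {cell: leaf_paths[a][0] for cell, a in zip(cells, assignments)}

    site_ids = [m for c in clades for m in c.markers]
    site_clade = {m: c.name for c in clades for m in c.markers}
    art_ids = [f"artifact{i + 1}" for i in range(artifact_sites)]
    all_ids = site_ids + art_ids
    art_cells = {a: set(rng.choice(cells, size=max(1, n_cells // 4), replace=False))
                 for a in art_ids}

    alt = pd.DataFrame(0, index=all_ids, columns=cells, dtype=int)
    depth = pd.DataFrame(0, index=all_ids, columns=cells, dtype=int)
    het_snps: dict[tuple[str, str], list[PhasedHetSNP]] = {}
    rows = []
    k = imbalance_concentration
    positions = {sid: (i + 1) * 1_000_000 for i, sid in enumerate(all_ids)}
    for sid in all_ids:
        for cell in cells:
            d = int(rng.poisson(mean_depth))
            if rng.random() < dropout_rate:
                d = 0
            balance = float(rng.beta(k * 0.5, k * 0.5))
            carried = sid in site_clade and site_clade[sid] in cell_paths[cell]
            is_artifact = sid in art_ids and cell in art_cells[sid]
            if carried:
                p = balance
            elif is_artifact:
                p = MDA_ARTIFACT_P
            else:
                p = 0.0
            x = int(rng.binomial(d, p)) if d else 0
            alt.loc[sid, cell] = x
            depth.loc[sid, cell] = d
            snps = [
                PhasedHetSNP(
                    pos=positions[sid] + int(rng.integers(-5000, 5000)),
                    hap1_reads=int(rng.binomial(het_snp_depth, balance)),
                    hap2_reads=0,
                )
                for _ in range(n_het_snps)
            ]
            het_snps[(sid, cell)] = [
                PhasedHetSNP(s.pos, s.hap1_reads, het_snp_depth - s.hap1_reads) for s in snps
            ]
            rows.append({"site": sid, "cell": cell, "carried": carried,
                         "artifact": is_artifact, "balance": balance, "depth": d})

    truth = SyntheticTruth(
        pd.DataFrame(rows), seed,
        {"n_cells": n_cells, "mean_depth": mean_depth, "dropout_rate": dropout_rate,
         "clades": [(c.name, c.parent, c.fraction, list(c.markers)) for c in clades],
         "cell_paths": cell_paths},
    )
    return SingleCellDataset(alt, depth, het_snps, cell_paths), truth


# ---------------------------------------------------------------------------
# Multi-tissue lineage VAF matrices
# ---------------------------------------------------------------------------

def sim_lineage_vafs(
    n_samples: int = 10,
    markers_per_clade: int = 3,
    coverage: int = 250,
    fraction_range: tuple[float, float] = (0.2, 0.8),
    subclade_ratio: Optional[float] = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Simulate bulk VAFs of markers of two sister embryonic lineages.

    In each tissue sample the L1 cell fraction f is uniform in
    ``fraction_range`` and L2 takes the complement 1 - f, so marker VAFs
    are f/2 and (1-f)/2 and any (L1 marker, L2 marker) pair sums to 0.5
    in expectation. Optional sub-clades carry ``subclade_ratio`` of their
    parent's fraction. Observed VAFs come from binomial sampling at the
    given coverage.
    """
    if n_samples < 2:
        raise ValueError("need at least two samples")
    rng = _rng(seed)
    samples = [f"sample{i + 1}" for i in range(n_samples)]
    f_l1 = rng.uniform(*fraction_range, size=n_samples)

    marker_fraction: dict[str, np.ndarray] = {}
    marker_clade: dict[str, str] = {}
    for m in range(markers_per_clade):
        marker_fraction[f"L1_m{m + 1}"] = f_l1
        marker_clade[f"L1_m{m + 1}"] = "L1"
        marker_fraction[f"L2_m{m + 1}"] = 1 - f_l1
        marker_clade[f"L2_m{m + 1}"] = "L2"
    if subclade_ratio is not None:
        if not 0 < subclade_ratio <= 1:
            raise ValueError("subclade_ratio must lie in (0, 1]")
        marker_fraction["L1.1_m1"] = f_l1 * subclade_ratio
        marker_clade["L1.1_m1"] = "L1.1"

    vafs = pd.DataFrame(index=list(marker_fraction), columns=samples, dtype=float)
    for mid, fr in marker_fraction.items():
        true_vaf = fr / 2.0
        vafs.loc[mid] = rng.binomial(coverage, true_vaf) / coverage

    sister_pairs = {
        (a, b) if a < b else (b, a)
        for a in marker_clade for b in marker_clade
        if marker_clade[a] == "L1" and marker_clade[b] == "L2"
    }
    truth = SyntheticTruth(
        pd.DataFrame(
            {"marker": list(marker_clade), "clade": list(marker_clade.values())}
        ),
        seed,
        {"n_samples": n_samples, "coverage": coverage,
         "l1_fractions": f_l1.tolist(), "sister_pairs": sorted(sister_pairs)},
    )
    return vafs, truth


# ---------------------------------------------------------------------------
# Sensitivity evaluation
# ---------------------------------------------------------------------------

def evaluate_calls(
    called_sites: set,
    truth: SyntheticTruth,
    vaf_bins: Sequence[float] = (0.0, 0.01, 0.02, 0.05, 0.1, 0.2, 0.3, 0.5),
) -> pd.DataFrame:
    """Per-VAF-bin sensitivity of a call set against planted truth.

    Sensitivity per bin is the fraction of planted mosaic sites in the bin
    that were called, with a 95% Clopper-Pearson interval; false calls are
    reported per megabase of simulated territory when the truth records a
    span. Sites are keyed as (chrom, pos).
    """
    t = truth.table
    if len(t) == 0:
        raise ValueError("empty truth table")
    mosaics = t[t["class"] == "mosaic"] if "class" in t.columns else t
    rows = []
    for lo, hi in itertools.pairwise(vaf_bins):
        vaf_col = "true_vaf" if "true_vaf" in mosaics.columns else "expected_vaf"
        in_bin = mosaics[(mosaics[vaf_col] > lo) & (mosaics[vaf_col] <= hi)]
        n = len(in_bin)
        det = sum(
            (r.chrom, r.pos) in called_sites for r in in_bin.itertuples(index=False)
        )
        if n:
            ci_lo = stats.beta.ppf(0.025, det, n - det + 1) if det > 0 else 0.0
            ci_hi = stats.beta.ppf(0.975, det + 1, n - det) if det < n else 1.0
        else:
            ci_lo = ci_hi = float("nan")
        rows.append(
            {"vaf_lo": lo, "vaf_hi": hi, "n_planted": n, "n_detected": det,
             "sensitivity": det / n if n else float("nan"),
             "ci_low": ci_lo, "ci_high": ci_hi}
        )
    out = pd.DataFrame(rows)
    span = truth.params.get("span_bp")
    if span and "class" in t.columns:
        planted = {(r.chrom, r.pos) for r in t.itertuples(index=False)}
        mosaic_keys = {(r.chrom, r.pos) for r in mosaics.itertuples(index=False)}
        fp = sum(1 for s in called_sites if s in planted and s not in mosaic_keys)
        out.attrs["false_calls_per_mb"] = fp / (span / 1e6)
    return out
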