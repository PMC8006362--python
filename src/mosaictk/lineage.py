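"""Early developmental lineage reconstruction from mosaic SNVs.

A mosaic SNV acquired in an early cell division marks every descendant
cell, so its variant allele fraction in a bulk tissue equals half the
fraction of cells descending from the mutated lineage. Markers of the two
earliest sister lineages (L1/L2) are therefore anti-correlated across
tissues, with VAF_L1 + VAF_L2 ~= 0.5 in every sample. This module
clusters SNVs by their VAF profiles (average linkage, Canberra distance),
clusters single cells by shared genotypes (Jaccard distance), ranks SNV
pairs by their fit to the VAF1 + VAF2 = 0.5 diagonal, and assembles a
nested lineage tree from marker containment among cells.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

logger = logging.getLogger(__name__)

# VafMatrix: DataFrame with SNV ids as the index and sample ids as columns,
# entries in [0, 1] or NaN for missing.
# PresenceMatrix: boolean DataFrame, SNV ids x cell ids.


def build_presence_matrix(
    per_cell_alt: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Binarize per-(SNV, cell) alternate read counts into presence calls.

    An SNV is present in a cell when at least one supporting read was
    found. Cells carrying none of the SNVs are dropped and reported, as
    they contribute no genotype information.
    """
    presence = per_cell_alt.fillna(0).astype(int) >= 1
    excluded = [c for c in presence.columns if not presence[c].any()]
    if excluded:
        logger.info("excluding cells with no SNV support: %s", excluded)
    return presence.drop(columns=excluded), excluded


def cluster_snvs_by_vaf(vafs: pd.DataFrame, method: str = "average"):
    """Hierarchical clustering of SNVs by their cross-tissue VAF profiles.

    Average linkage on Canberra distance, d(u,v) = sum |u_k - v_k| /
    (|u_k| + |v_k|) with 0/0 terms contributing nothing; small absolute
    VAF differences at low VAF weigh as much as large ones at high VAF,
    which suits lineage markers spanning two orders of magnitude.
    Missing entries are imputed as 0. Returns a scipy linkage matrix.
    """
    if len(vafs) < 2:
        raise ValueError("need at least two SNVs to cluster")
    x = vafs.fillna(0.0).to_numpy(dtype=float)
    return hierarchy.linkage(x, method=method, metric="canberra")


def cluster_cells_by_genotype(presence: pd.DataFrame, method: str = "average"):
    """Hierarchical clustering of cells by shared mosaic genotypes.

    Jaccard distance (1 - intersection/union of present-SNV sets) under
    average linkage; two cells with identical (possibly empty) genotypes
    are at distance 0. Returns a scipy linkage matrix over the columns.
    """
    if presence.shape[1] < 2:
        raise ValueError("need at least two cells to cluster")
    x = presence.to_numpy(dtype=bool).T
    return hierarchy.linkage(x, method=method, metric="jaccard")


@dataclass(frozen=True)
class PairScore:
    """Fit of one SNV pair to the sister-lineage diagonal VAF1+VAF2=0.5."""

    snv_i: str
    snv_j: str
    score: float                  # mean |VAF_i + VAF_j - 0.5|; lower is better
    per_sample_sums: tuple[float, ...]
    n_samples: int
    p_value: float = float("nan")

    @property
    def mean_vaf_sum(self) -> float:
        return float(np.mean(self.per_sample_sums))


def score_lineage_pairs(
    vafs: pd.DataFrame,
    target_sum: float = 0.5,
    compute_pvalues: bool = True,
) -> list[PairScore]:
    """Rank SNV pairs by anti-correlation across samples.

    For each pair, over the samples where both VAFs are observed, the
    score is the mean distance of (VAF_i, VAF_j) from the line
    VAF_i + VAF_j = target_sum, measured as |VAF_i + VAF_j - target_sum|.
    Pairs are returned sorted ascending by score. Each pair's p-value is
    a two-sided Welch t-test of its per-sample distances against the
    pooled distances of all other pairs (a stand-in for an unspecified
    published test). Pairs sharing fewer than two samples are skipped.
    """
    if vafs.shape[1] < 2:
        raise ValueError("pair scoring needs at least two samples")
    ids = list(vafs.index)
    dists: dict[tuple[str, str], np.ndarray] = {}
    scores: list[PairScore] = []
    for i, j in itertools.combinations(range(len(ids)), 2):
        vi, vj = vafs.iloc[i], vafs.iloc[j]
        both = vi.notna() & vj.notna()
        if both.sum() < 2:
            logger.warning("pair (%s, %s) skipped: <2 common samples", ids[i], ids[j])
            continue
        sums = (vi[both] + vj[both]).to_numpy(dtype=float)
        d = np.abs(sums - target_sum)
        dists[(ids[i], ids[j])] = d
        scores.append(
            PairScore(ids[i], ids[j], float(d.mean()), tuple(sums), int(both.sum()))
        )
    if compute_pvalues and len(scores) > 1:
        rescored = []
        for ps in scores:
            own = dists[(ps.snv_i, ps.snv_j)]
            others = np.concatenate(
                [v for k, v in dists.items() if k != (ps.snv_i, ps.snv_j)]
            )
            p = stats.ttest_ind(own, others, equal_var=False).pvalue
            rescored.append(
                PairScore(ps.snv_i, ps.snv_j, ps.score, ps.per_sample_sums, ps.n_samples, float(p))
            )
        scores = rescored
    return sorted(scores, key=lambda s: (s.score, s.snv_i, s.snv_j))


@dataclass
class Clade:
    """One node of the reconstructed lineage tree."""

    markers: list[str]
    cells: set[str] = field(default_factory=set)
    mean_vaf: float = 0.0
    children: list["Clade"] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "markers": list(self.markers),
            "cells": sorted(self.cells),
            "mean_vaf": round(self.mean_vaf, 4),
            "children": [c.to_dict() for c in self.children],
        }

    def to_newick(self) -> str:
        label = "|".join(self.markers) or "root"
        if not self.children:
            return label
        return "(" + ",".join(c.to_newick() for c in self.children) + ")" + label


@dataclass
class LineageTree:
    roots: list[Clade]
    violations: list[str] = field(default_factory=list)
    excluded_cells: list[str] = field(default_factory=list)

    def to_newick(self) -> str:
        if len(self.roots) == 1:
            return self.roots[0].to_newick() + ";"
        return "(" + ",".join(r.to_newick() for r in self.roots) + ");"


def cut_snv_groups(
    linkage_matrix,
    vafs: pd.DataFrame,
    max_within_range: float = 0.05,
) -> list[list[str]]:
    """Cut the SNV dendrogram into marker groups.

    Chooses the largest cut height at which every resulting group has a
    per-sample VAF range no larger than ``max_within_range``; falls back
    to singletons when no merge satisfies the constraint.
    """
    ids = list(vafs.index)
    heights = sorted(set(linkage_matrix[:, 2])) if len(linkage_matrix) else []
    best = [[i] for i in ids]
    for h in heights:
        labels = hierarchy.fcluster(linkage_matrix, t=h + 1e-12, criterion="distance")
        groups = {}
        for snv, lab in zip(ids, labels):
            groups.setdefault(lab, []).append(snv)
        ok = all(
            (vafs.loc[g].max() - vafs.loc[g].min()).max() <= max_within_range
            for g in groups.values()
            if len(g) > 1
        )
        if ok:
            best = list(groups.values())
    return best


def reconstruct_tree(
    snv_linkage,
    presence: pd.DataFrame,
    vafs: pd.DataFrame,
    max_within_range: float = 0.05,
) -> LineageTree:
    """Assemble a lineage tree from marker groups, cells and VAFs.

    Marker groups (dendrogram cut) are ordered by mean VAF descending —
    earlier lineages carry higher VAFs — and each group is attached below
    the deepest already-placed group whose cell set contains all cells
    carrying the group's markers; groups with no consistent parent become
    roots. Cells end up attached to the deepest clade whose markers they
    carry. Containment conflicts (a group's cells straddling two placed
    clades) are reported as violations rather than silently resolved.
    """
    groups = cut_snv_groups(snv_linkage, vafs, max_within_range)
    clades: list[Clade] = []
    for markers in groups:
        cells = {
            cell
            for cell in presence.columns
            if presence.loc[[m for m in markers if m in presence.index], cell].any()
        }
        mean_vaf = float(vafs.loc[markers].mean(axis=1).mean())
        clades.append(Clade(markers=sorted(markers), cells=cells, mean_vaf=mean_vaf))
    clades.sort(key=lambda c: -c.mean_vaf)

    tree = LineageTree(roots=[])
    placed: list[Clade] = []
    for clade in clades:
        candidates = [p for p in placed if clade.cells and clade.cells <= p.cells]
        if candidates:
            parent = min(candidates, key=lambda p: len(p.cells))
            parent.children.append(clade)
        else:
            overlapping = [p for p in tree.roots if clade.cells & p.cells]
            if overlapping and any(clade.cells - p.cells for p in overlapping):
                tree.violations.append(
                    f"markers {clade.markers}: cells straddle existing clades"
                )
            tree.roots.append(clade)
        placed.append(clade)
    return tree
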