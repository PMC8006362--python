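"""Naive Bayes consolidation of validation evidence.

Each candidate site carries one categorical feature per evidence source:
its panel-of-normals recurrence (alternate reads in <=5 vs >5 panel
samples), its linked-read haplotype outcome (PASS / FAIL / NOINFO), its
single-cell support (no alt reads / <4 cells / >=4 cells) and its
single-cell genotyper flag (PASS / LOWQUAL / ARTIF / NOFLAG). Absence of
information is always an explicit category, never a missing value.

Writing B = 1 for a site that passes validation and S for its feature
set, the classifier computes

    Pr(B | S) = prod_s Pr(s|B) Pr(B) /
                [prod_s Pr(s|B=0) Pr(B=0) + prod_s Pr(s|B=1) Pr(B=1)]

with conditional likelihoods estimated from labelled training sites under
a pseudocount of 1 per category (Laplace smoothing over each feature
group, which keeps every per-group likelihood table normalized).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .evidence import HaplotypeClass, SingleCellFlag, SupportCategory

# Feature groups and their category alphabets
FEATURE_GROUPS: dict[str, tuple[str, ...]] = {
    "pon": ("LE5", "GT5"),
    "tenx": ("PASS", "FAIL", "NOINFO"),
    "sc_support": ("NONE", "LT4", "GE4"),
    "sc_flag": ("PASS", "LOWQUAL", "ARTIF", "NOFLAG"),
}

FeatureVector = dict[str, str]


def featurize(
    pon_n_samples: Optional[int],
    haplotype_class: Optional[HaplotypeClass],
    sc_support: Optional[SupportCategory],
    sc_flag: Optional[SingleCellFlag],
    pon_max_samples: int = 5,
) -> FeatureVector:
    """Map raw evidence for one site onto the classifier's categories.

    A PON count above ``pon_max_samples`` becomes GT5 (recurrent in the
    panel). The linked-read outcome is PASS for the mosaic-compatible
    3-haplotype state, FAIL for germline or artifact states, NOINFO
    without assigned alternate reads. Missing evidence maps to the
    explicit no-information categories.
    """
    fv: FeatureVector = {}
    if pon_n_samples is None:
        fv["pon"] = "LE5"  # unobserved in the panel: no recurrence evidence
    else:
        fv["pon"] = "GT5" if pon_n_samples > pon_max_samples else "LE5"

    if haplotype_class is None or haplotype_class is HaplotypeClass.NO_INFO:
        fv["tenx"] = "NOINFO"
    elif haplotype_class is HaplotypeClass.MOSAIC_3HAP:
        fv["tenx"] = "PASS"
    else:
        fv["tenx"] = "FAIL"

    fv["sc_support"] = (sc_support or SupportCategory.NONE).value
    fv["sc_flag"] = (sc_flag or SingleCellFlag.NOFLAG).value
    return fv


@dataclass
class NBModel:
    """Fitted naive Bayes model over categorical feature groups."""

    prior_pass: float
    prior_fail: float
    # likelihoods[group][category] = (Pr(cat | fail), Pr(cat | pass))
    likelihoods: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)
    groups: Mapping[str, tuple[str, ...]] = field(default_factory=lambda: dict(FEATURE_GROUPS))


def nb_fit(
    features: Sequence[FeatureVector],
    labels: Sequence[bool],
    groups: Optional[Mapping[str, Sequence[str]]] = None,
    pseudocount: float = 1.0,
) -> NBModel:
    """Fit priors and per-group conditional likelihood tables.

    Pr(category | class) = (count + pseudocount) / (n_class + pseudocount
    * n_categories_in_group), so each group's table sums to one per class.
    Labels are True for sites that passed validation.
    """
    if len(features) != len(labels):
        raise ValueError("features and labels length mismatch")
    groups = {k: tuple(v) for k, v in (groups or FEATURE_GROUPS).items()}
    n_pass = sum(labels)
    n_fail = len(labels) - n_pass
    if n_pass == 0 or n_fail == 0:
        raise ValueError("training data must contain both classes")

    model = NBModel(
        prior_pass=n_pass / len(labels),
        prior_fail=n_fail / len(labels),
        groups=groups,
    )
    for group, cats in groups.items():
        table: dict[str, tuple[float, float]] = {}
        for cat in cats:
            c_fail = sum(1 for fv, y in zip(features, labels) if not y and fv[group] == cat)
            c_pass = sum(1 for fv, y in zip(features, labels) if y and fv[group] == cat)
            table[cat] = (
                (c_fail + pseudocount) / (n_fail + pseudocount * len(cats)),
                (c_pass + pseudocount) / (n_pass + pseudocount * len(cats)),
            )
        model.likelihoods[group] = table
    return model


def nb_posterior(model: NBModel, fv: FeatureVector) -> float:
    """Posterior probability that the site passes validation, in (0, 1).

    Computed in log space; unknown categories raise rather than being
    silently smoothed at predict time.
    """
    log_fail = math.log(model.prior_fail)
    log_pass = math.log(model.prior_pass)
    for group in model.groups:
        cat = fv[group]
        try:
            p_fail, p_pass = model.likelihoods[group][cat]
        except KeyError as exc:
            raise ValueError(f"unknown category {cat!r} for group {group!r}") from exc
        log_fail += math.log(p_fail)
        log_pass += math.log(p_pass)
    m = max(log_fail, log_pass)
    return math.exp(log_pass - m) / (math.exp(log_pass - m) + math.exp(log_fail - m))


@dataclass
class LoocvResult:
    precision: float
    sensitivity: float
    specificity: float
    posteriors: list[float]
    n_prior_only_folds: int = 0


def loocv_metrics(
    features: Sequence[FeatureVector],
    labels: Sequence[bool],
    threshold: float = 0.5,
    groups: Optional[Mapping[str, Sequence[str]]] = None,
) -> LoocvResult:
    """Leave-one-out cross-validated precision/sensitivity/specificity.

    Each site is predicted from a model fitted on the other n-1; a fold
    whose training data collapses to a single class is predicted from the
    class proportions alone (with a counter recording how often). The
    positive class is "passes validation".
    """
    n = len(features)
    if n < 2:
        raise ValueError("need at least two sites")
    posteriors: list[float] = []
    n_prior_only = 0
    for i in range(n):
        train_f = [fv for j, fv in enumerate(features) if j != i]
        train_y = [y for j, y in enumerate(labels) if j != i]
        try:
            model = nb_fit(train_f, train_y, groups=groups)
            posteriors.append(nb_posterior(model, features[i]))
        except ValueError:
            n_prior_only += 1
            posteriors.append(sum(train_y) / len(train_y))

    tp = sum(1 for p, y in zip(posteriors, labels) if p >= threshold and y)
    fp = sum(1 for p, y in zip(posteriors, labels) if p >= threshold and not y)
    fn = sum(1 for p, y in zip(posteriors, labels) if p < threshold and y)
    tn = sum(1 for p, y in zip(posteriors, labels) if p < threshold and not y)
    precision = tp / (tp + fp) if tp + fp else float("nan")
    sensitivity = tp / (tp + fn) if tp + fn else float("nan")
    specificity = tn / (tn + fp) if tn + fp else float("nan")
    return LoocvResult(precision, sensitivity, specificity, posteriors, n_prior_only)
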