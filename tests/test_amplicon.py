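"""Amplicon validation: consensus merge, error profile, Skellam, classification."""
import itertools

import numpy as np
import pytest

from mosaictk import (
    AmpliconConfig,
    AmpliconSiteData,
    GenomicSite,
    ValidationStatus,
    allele_rank_frequencies,
    build_error_profile,
    classify_amplicon_site,
    conditional_binomial_test,
    merge_overlapping_pair,
    nearest_rank_percentile,
    resolve_discordant,
    skellam_test,
)
from mosaictk.amplicon import ConsolidationEvidence, ErrorProfile


class TestMergeOverlappingPair:
    def test_discordant_base_becomes_n_quality_zero(self):
        merged = merge_overlapping_pair(("ACGT", [30, 30, 30, 30]), ("ACGA", [20, 20, 20, 35]), 0)
        assert merged.sequence == "ACGN"
        assert merged.qualities[3] == 0
        assert merged.concordant == [True, True, True, False]

    def test_concordant_keeps_higher_quality(self):
        merged = merge_overlapping_pair(("AC", [10, 40]), ("AC", [30, 20]), 0)
        assert merged.qualities == [30, 40]

    def test_partial_overlap_passes_through_tails(self):
        merged = merge_overlapping_pair(("AAACC", [30] * 5), ("CCGGG", [20] * 5), 3)
        assert merged.sequence == "AAACCGGG"
        assert merged.concordant == [True] * 8

    def test_zero_overlap_rejected(self):
        with pytest.raises(ValueError):
            merge_overlapping_pair(("ACGT", [30] * 4), ("ACGT", [30] * 4), 4)


def oracle_percentile(values, pct=95.0):
    """Smallest value whose empirical CDF reaches pct/100."""
    s = sorted(values)
    n = len(s)
    for x in s:
        if sum(v <= x for v in s) / n >= pct / 100.0:
            return x
    return s[-1]


class TestErrorProfile:
    def test_nearest_rank_examples(self):
        assert nearest_rank_percentile([0.001] * 19 + [0.01]) == 0.001
        assert nearest_rank_percentile([0.0] * 5) == 0.0
        assert nearest_rank_percentile([0.004]) == 0.004

    def test_nearest_rank_matches_cdf_oracle(self):
        rng = np.random.default_rng(0)
        for n in list(range(1, 30)) + [50, 99, 100]:
            vals = rng.beta(1, 500, size=n).tolist()
            assert nearest_rank_percentile(vals) == oracle_percentile(vals)

    def test_build_profile_per_type(self):
        pileups = [("C", {"C": 990, "T": 10})] * 19 + [("C", {"C": 900, "T": 100})]
        profile = build_error_profile(pileups)
        assert profile.cutoff("C>T") == pytest.approx(0.01)
        assert profile.cutoff("C>A") == pytest.approx(0.0)
        assert profile.cutoff("A>T") is None  # no A-reference sites observed

    def test_n_bases_excluded_from_denominator(self):
        profile = build_error_profile([("C", {"C": 90, "T": 10, "N": 900})])
        assert profile.cutoff("C>T") == pytest.approx(0.1)

    def test_global_cutoff_fallback(self):
        profile = build_error_profile([("C", {"C": 99, "T": 1})])
        assert profile.cutoff_or_global("A>G") == profile.global_cutoff()


class TestAlleleRanks:
    def test_basic_ranking(self):
        assert allele_rank_frequencies({"A": 90, "T": 8, "C": 2, "G": 0}) == (0.08, 0.02)

    def test_single_allele(self):
        assert allele_rank_frequencies({"A": 100}) == (0.0, 0.0)

    def test_tie_broken_by_base_order(self):
        second, third = allele_rank_frequencies({"A": 90, "T": 5, "C": 5})
        assert second == pytest.approx(0.05)  # C sorts before T on ties
        assert third == pytest.approx(0.05)

    def test_zero_depth_rejected(self):
        with pytest.raises(ValueError):
            allele_rank_frequencies({})


class TestSkellam:
    def test_case_excess_is_significant(self):
        assert skellam_test(30, 10_000, 0, 10_000) < 1e-6

    def test_symmetric_null_is_not(self):
        assert skellam_test(5, 1000, 5, 1000) >= 0.5

    def test_no_case_alt_reads(self):
        assert skellam_test(0, 1000, 10, 1000) > 0.9
        assert skellam_test(0, 1000, 0, 1000) == 1.0

    def test_monotone_in_case_count(self):
        ps = [skellam_test(k, 5000, 5, 5000) for k in range(0, 60, 3)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_ordering_agrees_with_conditional_binomial(self):
        """Both tests should rank random case/control configurations identically."""
        rng = np.random.default_rng(1)
        configs = []
        for _ in range(200):
            n1, n2 = int(rng.integers(500, 5000)), int(rng.integers(500, 5000))
            k1, k2 = int(rng.integers(0, 40)), int(rng.integers(0, 40))
            configs.append((k1, n1, k2, n2))
        sk = [skellam_test(*c) for c in configs]
        cb = [conditional_binomial_test(*c) for c in configs]
        # Spearman-style concordance: orderings agree for the vast majority of pairs
        concordant = discordant = 0
        for (i, j) in itertools.combinations(range(len(configs)), 2):
            a, b = sk[i] - sk[j], cb[i] - cb[j]
            if a * b > 0:
                concordant += 1
            elif a * b < 0:
                discordant += 1
        assert concordant / (concordant + discordant) > 0.95


class TestClassifyAmpliconSite:
    @pytest.fixture
    def profile(self):
        p = ErrorProfile()
        for t in ("G>A", "C>T", "A>T"):
            p.rates[t] = [0.001] * 20
        return p

    def _data(self, case_alt, case_depth=10_000, ctrl_alt=0, ctrl_depth=10_000):
        return AmpliconSiteData(
            site=GenomicSite("chr19", 9_493_288, "G", "A"),
            case_alt=case_alt, case_depth=case_depth,
            ctrl_alt=ctrl_alt, ctrl_depth=ctrl_depth,
        )

    def test_low_depth_is_ned(self, profile):
        status, reasons = classify_amplicon_site(self._data(10, case_depth=150), profile)
        assert status is ValidationStatus.NED
        assert reasons == ["read not enough"]

    def test_depth_boundary(self, profile):
        status, _ = classify_amplicon_site(self._data(10, case_depth=200), profile)
        assert status is not ValidationStatus.NED

    def test_high_af_is_germline(self, profile):
        status, _ = classify_amplicon_site(self._data(4500), profile)
        assert status is ValidationStatus.GERMLINE

    def test_contaminated_control_is_false_positive(self, profile):
        status, reasons = classify_amplicon_site(self._data(300, ctrl_alt=200), profile)
        assert status is ValidationStatus.FALSE_POSITIVE
        assert any("control AF" in r for r in reasons)

    def test_af_within_error_floor_is_false_positive(self, profile):
        status, reasons = classify_amplicon_site(self._data(8), profile)
        assert status is ValidationStatus.FALSE_POSITIVE

    def test_clean_mosaic_is_true(self, profile):
        status, _ = classify_amplicon_site(self._data(200), profile)  # AF 0.02
        assert status is ValidationStatus.TRUE_MOSAIC

    def test_af_floor_boundary(self, profile):
        # AF 0.004 < 0.005 floor even though above the error cutoff
        status, reasons = classify_amplicon_site(self._data(40), profile)
        assert status is ValidationStatus.FALSE_POSITIVE
        assert any("floor" in r for r in reasons)

    def test_missing_control_noted(self, profile):
        data = AmpliconSiteData(
            site=GenomicSite("chr1", 1, "G", "A"), case_alt=200, case_depth=10_000
        )
        status, reasons = classify_amplicon_site(data, profile)
        assert status is ValidationStatus.TRUE_MOSAIC
        assert any("no control" in r for r in reasons)


class TestResolveDiscordant:
    TM, FP = ValidationStatus.TRUE_MOSAIC, ValidationStatus.FALSE_POSITIVE

    def test_unanimous_statuses_stand(self):
        assert resolve_discordant([(self.TM, {}), (self.TM, {})]) is self.TM

    def test_overlap_consensus_experiments_preferred(self):
        statuses = [(self.TM, {"overlap_consensus": True}),
                    (self.FP, {"overlap_consensus": False})]
        assert resolve_discordant(statuses) is self.TM

    def test_four_haplotype_evidence_invalidates(self):
        statuses = [(self.TM, {}), (self.FP, {})]
        ev = ConsolidationEvidence(haplotype_class="ARTIFACT_4HAP")
        assert resolve_discordant(statuses, ev) is self.FP

    def test_low_amplicon_vaf_invalidates(self):
        statuses = [(self.TM, {}), (self.FP, {})]
        ev = ConsolidationEvidence(amplicon_vaf=0.003)
        assert resolve_discordant(statuses, ev) is self.FP

    def test_weak_wgs_support_invalidates(self):
        ev = ConsolidationEvidence(wgs_replicate_alt_reads=[2, 1, 0])
        assert resolve_discordant([(self.TM, {}), (self.FP, {})], ev) is self.FP

    def test_germline_by_vaf_and_two_haplotypes(self):
        ev = ConsolidationEvidence(bulk_vaf=0.49, haplotype_class="GERMLINE_2HAP")
        out = resolve_discordant([(self.TM, {}), (ValidationStatus.GERMLINE, {})], ev)
        assert out is ValidationStatus.GERMLINE

    def test_unresolvable_is_ned(self):
        assert resolve_discordant([(self.TM, {}), (self.FP, {})]) is ValidationStatus.NED

    def test_permutation_invariant_and_idempotent(self):
        ev = ConsolidationEvidence(amplicon_vaf=0.002)
        statuses = [(self.TM, {"overlap_consensus": False}), (self.FP, {}),
                    (ValidationStatus.NED, {})]
        results = {
            resolve_discordant(list(perm), ev)
            for perm in itertools.permutations(statuses)
        }
        assert len(results) == 1
        resolved = results.pop()
        assert resolve_discordant([(resolved, {})], ev) is resolved

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            resolve_discordant([])
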