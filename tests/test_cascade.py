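"""Filter cascade: statistical tests, threshold rules, PON, orchestration."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mosaictk import (
    CandidateSNV,
    CascadeConfig,
    CascadeResources,
    GenomicSite,
    IntervalTrack,
    StrandCounts,
    Verdict,
    apply_pon,
    build_pon,
    context_flags,
    filter_site,
    ploidy_for_coverage,
    replicate_concordance,
    run_cascade,
)
from mosaictk import test_het_binomial as het_binomial_pvalue
from mosaictk import test_strand_bias as strand_bias_pvalues
from mosaictk.cascade import PonSummary

from conftest import exact_binom_two_sided, exact_fisher_two_sided


class TestPloidyRule:
    @pytest.mark.parametrize("coverage,expected", [(250, 50), (100, 20), (5, 2), (2, 2)])
    def test_twenty_percent_rule_with_diploid_floor(self, coverage, expected):
        assert ploidy_for_coverage(coverage) == expected

    def test_nonpositive_coverage_rejected(self):
        with pytest.raises(ValueError):
            ploidy_for_coverage(0)


class TestHetBinomial:
    def test_balanced_counts_give_p_one(self):
        assert het_binomial_pvalue(125, 250) == pytest.approx(1.0)
        assert het_binomial_pvalue(1, 1) == pytest.approx(1.0)

    def test_low_vaf_rejects_het_hypothesis(self):
        assert het_binomial_pvalue(10, 250) < 1e-6

    @given(st.integers(1, 25), st.data())
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration_oracle(self, depth, data):
        alt = data.draw(st.integers(0, depth))
        p = het_binomial_pvalue(alt, depth)
        assert p == pytest.approx(exact_binom_two_sided(alt, depth), rel=1e-9)


class TestStrandBias:
    def test_one_sided_alt_reads_fail_evenness(self):
        p_even, _ = strand_bias_pvalues(StrandCounts(50, 50, 8, 0))
        assert p_even == pytest.approx(2 * 0.5**8)

    def test_symmetric_table_passes_imbalance(self):
        _, p_imb = strand_bias_pvalues(StrandCounts(50, 50, 5, 5))
        assert p_imb == pytest.approx(1.0)

    def test_asymmetric_alt_fails_imbalance(self):
        _, p_imb = strand_bias_pvalues(StrandCounts(100, 100, 10, 0))
        assert p_imb < 0.05

    def test_no_alt_reads_gives_na(self):
        assert strand_bias_pvalues(StrandCounts(50, 50, 0, 0)) == (None, None)

    @given(st.integers(0, 25), st.data())
    @settings(max_examples=200, deadline=None)
    def test_matches_oracles_small_depth(self, total, data):
        rf = data.draw(st.integers(0, total))
        rr = data.draw(st.integers(0, total - rf))
        af = data.draw(st.integers(0, total - rf - rr))
        ar = total - rf - rr - af
        if af + ar == 0:
            return
        p_even, p_imb = strand_bias_pvalues(StrandCounts(rf, rr, af, ar))
        assert p_even == pytest.approx(exact_binom_two_sided(af, af + ar), rel=1e-9)
        assert p_imb == pytest.approx(exact_fisher_two_sided(rf, rr, af, ar), rel=1e-7)


class TestPon:
    def _panel(self, n_exceeding, n_total=20, depth=30):
        sites = {GenomicSite("chr1", 100, "A", "T"): None}
        panel = {}
        for i in range(n_total):
            alt = 3 if i < n_exceeding else 0  # 3/30 = 0.1 > 0.05
            panel[f"s{i}"] = {GenomicSite("chr1", 100, "A", "T"): (alt, depth)}
        return panel

    @pytest.mark.parametrize("n,verdict", [(6, Verdict.FAIL), (5, Verdict.PASS), (0, Verdict.PASS)])
    def test_more_than_five_samples_fails(self, n, verdict):
        pon = build_pon(self._panel(n))
        site = GenomicSite("chr1", 100, "A", "T")
        assert pon.count(site) == n
        assert apply_pon(site, pon, CascadeConfig()) is verdict

    def test_zero_depth_samples_not_counted(self):
        site = GenomicSite("chr1", 100, "A", "T")
        panel = {"a": {site: (5, 0)}, "b": {site: (3, 30)}}
        assert build_pon(panel).count(site) == 1

    def test_af_at_threshold_not_counted(self):
        site = GenomicSite("chr1", 100, "A", "T")
        # exactly 0.05 is not "greater than 0.05"
        panel = {"a": {site: (5, 100)}, "b": {site: (6, 100)}}
        assert build_pon(panel).count(site) == 1

    def test_absent_site_gives_na(self):
        pon = build_pon(self._panel(0))
        other = GenomicSite("chr2", 5, "C", "G")
        assert apply_pon(other, pon, CascadeConfig()) is Verdict.NA

    def test_monotone_in_recurrence(self):
        cfg = CascadeConfig()
        site = GenomicSite("chr1", 100, "A", "T")
        verdicts = []
        for n in range(12):
            pon = PonSummary(n_samples_total=12, n_samples_exceeding={site: n})
            verdicts.append(apply_pon(site, pon, cfg))
        # once FAIL, always FAIL as recurrence grows
        first_fail = verdicts.index(Verdict.FAIL)
        assert all(v is Verdict.FAIL for v in verdicts[first_fail:])

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            build_pon({})


class TestReplicateConcordance:
    @pytest.mark.parametrize(
        "vafs,expected",
        [
            ([0.02, 0.015, 0.012, 0.003], True),
            ([0.02, 0.015], False),
            ([0.011, 0.010, 0.012], False),  # 0.010 is not > 0.01
        ],
    )
    def test_three_replicates_above_one_percent(self, vafs, expected):
        assert replicate_concordance(vafs) is expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            replicate_concordance([])


class TestFilterSite:
    def _cand(self, alt=25, depth=250, **ann):
        from mosaictk.types import Annotations

        ref = depth - alt
        return CandidateSNV(
            site=GenomicSite("chr1", 1000, "A", "T"),
            counts=StrandCounts(ref - ref // 2, ref // 2, alt - alt // 2, alt // 2),
            annotations=Annotations(**ann),
        )

    def test_read_support_boundary(self):
        cfg, res = CascadeConfig(), CascadeResources()
        assert filter_site(self._cand(alt=4), cfg, res).verdicts["read_support"] is Verdict.FAIL
        assert filter_site(self._cand(alt=5), cfg, res).verdicts["read_support"] is Verdict.PASS

    def test_popaf_boundary(self):
        cfg, res = CascadeConfig(), CascadeResources()
        assert filter_site(self._cand(popaf=0.002), cfg, res).verdicts["popaf"] is Verdict.FAIL
        assert filter_site(self._cand(popaf=0.001), cfg, res).verdicts["popaf"] is Verdict.PASS

    def test_copy_number_boundary(self):
        cfg, res = CascadeConfig(), CascadeResources()
        assert filter_site(self._cand(copy_number=2.6), cfg, res).verdicts["copy_number"] is Verdict.FAIL
        assert filter_site(self._cand(copy_number=2.5), cfg, res).verdicts["copy_number"] is Verdict.PASS

    def test_missing_annotations_are_na_not_fail(self):
        verdicts = filter_site(self._cand(), CascadeConfig(), CascadeResources()).verdicts
        assert verdicts["popaf"] is Verdict.NA
        assert verdicts["copy_number"] is Verdict.NA
        assert verdicts["pon"] is Verdict.NA


class TestContextFlags:
    def test_indel_window(self):
        cfg = CascadeConfig()
        site = GenomicSite("chr1", 1000, "A", "T")
        near = IntervalTrack.from_intervals([("chr1", 1003, 1004)])  # pos+4
        far = IntervalTrack.from_intervals([("chr1", 1005 + cfg.indel_window, 1006 + cfg.indel_window)])
        assert context_flags(site, None, near, None, [], cfg)["near_indel"]
        assert not context_flags(site, None, far, None, [], cfg)["near_indel"]

    def test_homopolymer_detection(self):
        cfg = CascadeConfig()
        site = GenomicSite("chr1", 1000, "A", "T")
        # run of 6 Ts ending 2 bp before the centre base
        window = "ACGTACGTTTTTTGCACGTACGTAC"
        flags = context_flags(site, window, None, None, [], cfg)
        assert flags["near_homopolymer"]
        # alternating STR context has no homopolymer run
        flags2 = context_flags(site, "CTCACTCTCTCTCTCTCACTCTCTC", None, None, [], cfg)
        assert not flags2["near_homopolymer"]

    def test_missing_window_gives_na(self):
        site = GenomicSite("chr1", 1000, "A", "T")
        assert context_flags(site, None, None, None, [], CascadeConfig())["near_homopolymer"] is None

    @pytest.mark.parametrize("gap,expected", [(99, True), (100, True), (101, False)])
    def test_cluster_window(self, gap, expected):
        cfg = CascadeConfig()
        a = GenomicSite("chr1", 1000, "A", "T")
        b = GenomicSite("chr1", 1000 + gap, "C", "G")
        assert context_flags(a, None, None, None, [a, b], cfg)["clustered"] is expected
        assert context_flags(b, None, None, None, [a, b], cfg)["clustered"] is expected


class TestRunCascade:
    def test_planted_het_fails_het_test_only(self):
        cand = CandidateSNV(
            site=GenomicSite("chr1", 1000, "A", "T"),
            counts=StrandCounts(63, 62, 63, 62),
        )
        annotated, _ = run_cascade([cand])
        assert annotated[0].verdicts["het_germline"] is Verdict.FAIL
        assert annotated[0].verdicts["read_support"] is Verdict.PASS

    def test_clean_mosaic_survives(self, clean_mosaic_counts):
        cand = CandidateSNV(site=GenomicSite("chr1", 1000, "A", "T"), counts=clean_mosaic_counts)
        annotated, summary = run_cascade([cand])
        assert annotated[0].passes
        assert summary["n_surviving"] == 1

    def test_empty_input(self):
        annotated, summary = run_cascade([])
        assert annotated == [] and summary["n_candidates"] == 0

    def test_verdicts_order_independent(self, bulk_cohort):
        candidates, _ = bulk_cohort
        subset = [CandidateSNV(site=c.site, counts=c.counts) for c in candidates[:40]]
        fwd, _ = run_cascade(subset)
        rev_in = [CandidateSNV(site=c.site, counts=c.counts) for c in reversed(candidates[:40])]
        rev, _ = run_cascade(rev_in)
        by_site = {c.site: c.verdicts for c in rev}
        for c in fwd:
            assert c.verdicts == by_site[c.site]

    def test_absent_resources_warn_na(self, clean_mosaic_counts):
        cand = CandidateSNV(site=GenomicSite("chr1", 1000, "A", "T"), counts=clean_mosaic_counts)
        _, summary = run_cascade([cand])
        assert summary["warnings"]  # PON, popAF, mask, CN all absent
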