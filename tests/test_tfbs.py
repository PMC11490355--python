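"""Active TFBS, context-adjusted O/E machinery, profiles and heatmap."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mosaicstats import (
    ActiveSiteConfig,
    IntervalTrack,
    VariantRecord,
    active_tfbs,
    annotate_context,
    annulus_oe_profile,
    case_control_binomial,
    expected_count,
    genome_context_rates,
    multi_track_heatmap,
    oe_poisson_test,
    rate_profile_case_control,
)
from mosaicstats._contexts import census_contexts, encode_seq
from mosaicstats.tfbs import nearest_distance, per_sample_oe


def v(sample, pos, ref, alt, chrom="chr1"):
    return VariantRecord(sample_id=sample, chrom=chrom, pos=pos, ref=ref,
                         alt=alt, alt_reads=10, total_reads=100)


class TestActiveTfbs:
    def tracks(self, scores):
        n = len(scores)
        starts = np.arange(n) * 100 + 1
        frame = pd.DataFrame({"chrom": "chr1", "start": starts,
                              "end": starts + 19})
        tfbs = IntervalTrack("tfbs", frame)
        dhs = IntervalTrack("dhs", frame.assign(score=scores))
        return tfbs, dhs

    def test_quantile_zero_keeps_all(self):
        tfbs, dhs = self.tracks(np.arange(10.0))
        mids = active_tfbs(tfbs, dhs, ActiveSiteConfig(dhs_quantile=0.0))
        assert len(mids) == 10

    def test_top_decile_of_distinct_scores(self, rng):
        scores = rng.permutation(np.arange(100.0))
        tfbs, dhs = self.tracks(scores)
        mids = active_tfbs(tfbs, dhs, ActiveSiteConfig(dhs_quantile=0.90))
        assert len(mids) == 10

    def test_midpoint_floor_rule(self):
        frame = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [119]})
        tfbs = IntervalTrack("tfbs", frame)
        dhs = IntervalTrack("dhs", frame.assign(score=[5.0]))
        mids = active_tfbs(tfbs, dhs, ActiveSiteConfig(dhs_quantile=0.0))
        assert mids["pos"].tolist() == [109]

    def test_no_survivors_errors(self):
        tfbs, dhs = self.tracks(np.zeros(4))
        cfg = ActiveSiteConfig(dhs_quantile=0.99)
        frame = tfbs.frame.iloc[:0]
        with pytest.raises(ValueError):
            active_tfbs(IntervalTrack("t", frame),
                        IntervalTrack("d", frame.assign(score=[])), cfg)


class TestContextRates:
    def test_homopolymer_direct_ratio(self):
        seq = "T" * 100
        ref = {"chr1": seq}
        cs = {"s1": [v("s1", p, "T", "G") for p in (10, 20, 30)]}
        annotate_context(cs, ref)
        table = genome_context_rates(cs, ref)
        frame = table.to_frame().set_index("channel")
        assert frame.loc["T[T>G]T", "count"] == 3
        assert frame.loc["T[T>G]T", "census"] == 98
        assert frame.loc["T[T>G]T", "rate"] == pytest.approx(3 / 98)

    def test_counts_conserved(self, enriched_cohort):
        table = genome_context_rates(enriched_cohort["callset"],
                                     enriched_cohort["reference"])
        n = sum(len(r) for r in enriched_cohort["callset"].values())
        assert table.counts.sum() == n

    def test_census_matches_bruteforce_50kb(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=50_000))
        fast = census_contexts(encode_seq(seq))
        from mosaicstats._contexts import collapse_context, context32_index
        brute = np.zeros(32, dtype=int)
        for i in range(1, len(seq) - 1):
            tri = seq[i - 1: i + 2]
            ctx, _ = collapse_context(tri, tri[1], "A" if tri[1] != "A" else "C")
            brute[context32_index(ctx)] += 1
        assert np.array_equal(fast, brute)


class TestExpectedCount:
    def test_whole_genome_identity(self, enriched_cohort):
        ref = enriched_cohort["reference"]
        cs = enriched_cohort["callset"]
        table = genome_context_rates(cs, ref)
        L = len(ref["chr1"])
        E = expected_count(np.ones(L, dtype=bool), table, ref, "all")
        n = sum(len(r) for r in cs.values())
        assert E == pytest.approx(n, rel=1e-12)

    def test_half_genome_proportionality(self, null_cohort):
        ref = null_cohort["reference"]
        cs = null_cohort["callset"]
        table = genome_context_rates(cs, ref)
        L = len(ref["chr1"])
        mask = np.zeros(L, dtype=bool)
        mask[::2] = True  # alternating half: composition-matched subset
        E = expected_count(mask, table, ref, "all")
        n = sum(len(r) for r in cs.values())
        assert E == pytest.approx(n / 2, rel=0.02)

    def test_class_without_sites_is_zero(self):
        ref = {"chr1": "C" * 50}  # no T/A sites
        cs = {"s1": [v("s1", 10, "C", "A")]}
        annotate_context(cs, ref)
        table = genome_context_rates(cs, ref)
        E = expected_count(np.ones(50, dtype=bool), table, ref, "T>G")
        assert E == 0.0

    def test_zero_region_rejected(self, null_cohort):
        ref = null_cohort["reference"]
        table = genome_context_rates(null_cohort["callset"], ref)
        with pytest.raises(ValueError):
            expected_count(np.zeros(len(ref["chr1"]), dtype=bool), table, ref)


class TestOEPoisson:
    def test_printed_promoter_cpg_example(self):
        res = oe_poisson_test(2, 0.083)
        assert res.ratio == pytest.approx(24.096, abs=0.001)
        assert res.p_one_sided == pytest.approx(0.00326, abs=0.0001)
        assert res.ci_low == pytest.approx(2.92, abs=0.01)
        assert res.ci_high == pytest.approx(87.0, abs=0.1)

    def test_zero_observed(self):
        res = oe_poisson_test(0, 3.0)
        assert res.ratio == 0.0 and res.p_one_sided == 1.0 and res.ci_low == 0.0

    def test_minlike_two_sided_le_double(self):
        a = oe_poisson_test(7, 2.0, two_sided_method="double_tail")
        b = oe_poisson_test(7, 2.0, two_sided_method="minlike")
        assert b.p_two_sided <= a.p_two_sided + 1e-12

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            oe_poisson_test(2, 0.0)

    def test_ci_coverage(self, rng):
        """Exact CI covers the true ratio in >= 93% of Poisson simulations."""
        for E in (0.5, 1.0, 10.0):
            cover = 0
            n = 400
            for O in rng.poisson(E, size=n):
                res = oe_poisson_test(int(O), E)
                cover += res.ci_low <= 1.0 <= res.ci_high
            assert cover / n >= 0.93


class TestNearestDistance:
    def test_signed_and_tie_rule(self):
        mids = np.array([800, 1000])
        assert nearest_distance(np.array([950]), mids)[0] == -50
        assert nearest_distance(np.array([900]), mids)[0] == 100

    def test_matches_bruteforce(self, rng):
        mids = np.sort(rng.choice(np.arange(1, 10_000), 20, replace=False))
        pos = rng.integers(1, 10_000, 100)
        fast = nearest_distance(pos, mids)
        for p, d in zip(pos, fast):
            assert abs(d) == np.min(np.abs(p - mids))


class TestAnnulus:
    def test_differencing_arithmetic(self, enriched_cohort):
        ref = enriched_cohort["reference"]
        cs = enriched_cohort["callset"]
        truth = enriched_cohort["truth"]
        mids = pd.DataFrame({"chrom": "chr1", "pos": truth.active_midpoints})
        rates = genome_context_rates(cs, ref)
        res = annulus_oe_profile(cs, mids, rates, ref, breaks=[50, 100, 1000])
        # conservation: annulus observations sum to the outermost window count
        pos = np.array([r.pos for recs in cs.values() for r in recs])
        within = np.abs(nearest_distance(pos, np.array(truth.active_midpoints))) <= 1000
        assert sum(r.observed for r in res) == int(within.sum())

    def test_breaks_must_increase(self, enriched_cohort):
        ref = enriched_cohort["reference"]
        cs = enriched_cohort["callset"]
        rates = genome_context_rates(cs, ref)
        mids = pd.DataFrame({"chrom": ["chr1"], "pos": [100]})
        with pytest.raises(ValueError):
            annulus_oe_profile(cs, mids, rates, ref, breaks=[100, 50])

    def test_planted_tg_enrichment_recovered(self, enriched_cohort):
        """The planted 25x T>G fold shows up only inside the halfwidth."""
        ref = enriched_cohort["reference"]
        truth = enriched_cohort["truth"]
        cases = {s: r for s, r in enriched_cohort["callset"].items()
                 if s.startswith("case")}
        rates = genome_context_rates(cases, ref)
        mids = pd.DataFrame({"chrom": "chr1", "pos": truth.active_midpoints})
        inner, outer = annulus_oe_profile(cases, mids, rates, ref,
                                          breaks=[100, 2000],
                                          class_filter="T>G")
        assert inner.ratio > 5
        assert inner.p_one_sided < 0.01
        # planted fold within the inner annulus CI
        assert inner.ci_low <= truth.enrich_tg * 1.5 and inner.ratio < truth.enrich_tg * 3
        assert outer.ci_low <= 2.0

    def test_cpg_enrichment_recovered(self, enriched_cohort):
        ref = enriched_cohort["reference"]
        truth = enriched_cohort["truth"]
        cases = {s: r for s, r in enriched_cohort["callset"].items()
                 if s.startswith("case")}
        rates = genome_context_rates(cases, ref)
        mids = pd.DataFrame({"chrom": "chr1", "pos": truth.active_midpoints})
        inner, _ = annulus_oe_profile(cases, mids, rates, ref,
                                      breaks=[100, 2000],
                                      class_filter="CpG>GpG")
        assert inner.ratio > 2


class TestRateProfile:
    def test_null_rate_ratio_near_one(self, null_cohort):
        ref = null_cohort["reference"]
        truth = null_cohort["truth"]
        cs = null_cohort["callset"]
        cases = {s: r for s, r in cs.items() if s.startswith("case")}
        ctrls = {s: r for s, r in cs.items() if s.startswith("ctrl")}
        mids = pd.DataFrame({"chrom": "chr1", "pos": truth.active_midpoints})
        prof = rate_profile_case_control(cases, ctrls, mids, ref,
                                         halfwidth=10_000, binwidth=2_000)
        pooled = prof.pooled.iloc[0]
        assert pooled["ci_low"] <= 1.0 <= pooled["ci_high"]
        assert len(prof.frame) == 10

    def test_planted_case_excess_detected(self, enriched_cohort):
        ref = enriched_cohort["reference"]
        truth = enriched_cohort["truth"]
        cs = enriched_cohort["callset"]
        cases = {s: r for s, r in cs.items() if s.startswith("case")}
        ctrls = {s: r for s, r in cs.items() if s.startswith("ctrl")}
        mids = pd.DataFrame({"chrom": "chr1", "pos": truth.active_midpoints})
        prof = rate_profile_case_control(cases, ctrls, mids, ref,
                                         pooled_halfwidth=1_000)
        pooled = prof.pooled.iloc[0]
        assert pooled["rate_ratio"] > 1.5

    def test_duplicating_samples_leaves_rr_invariant(self, null_cohort):
        ref = null_cohort["reference"]
        truth = null_cohort["truth"]
        cs = null_cohort["callset"]
        cases = {s: r for s, r in cs.items() if s.startswith("case")}
        ctrls = {s: r for s, r in cs.items() if s.startswith("ctrl")}
        mids = pd.DataFrame({"chrom": "chr1", "pos": truth.active_midpoints})
        base = rate_profile_case_control(cases, ctrls, mids, ref)
        dup_cases = dict(cases, **{s + "_dup": r for s, r in cases.items()})
        dup_ctrls = dict(ctrls, **{s + "_dup": r for s, r in ctrls.items()})
        dup = rate_profile_case_control(dup_cases, dup_ctrls, mids, ref)
        assert dup.pooled.iloc[0]["rate_ratio"] == pytest.approx(
            base.pooled.iloc[0]["rate_ratio"], rel=1e-12)

    def test_empty_group_rejected(self, null_cohort):
        with pytest.raises(ValueError):
            rate_profile_case_control({}, {"a": []},
                                      pd.DataFrame({"chrom": [], "pos": []}),
                                      null_cohort["reference"])


class TestCaseControlBinomial:
    def test_equal_rates_closed_form(self):
        res = case_control_binomial(5, 0, 1.0, 1.0)
        assert res.p_lower == pytest.approx(0.5 ** 5)

    def test_all_in_controls_full_tail(self):
        assert case_control_binomial(0, 7, 1.0, 1.0).p_lower == 1.0

    def test_unequal_expectations(self):
        res = case_control_binomial(3, 1, 3.0, 1.0)
        assert res.p_lower == pytest.approx(stats.binom.cdf(1, 4, 0.25))
        assert res.p_lower == pytest.approx(0.7383, abs=1e-4)

    def test_degenerate_flagged(self):
        res = case_control_binomial(0, 0, 1.0, 1.0)
        assert res.p_lower == 1.0 and res.flagged


class TestHeatmap:
    def test_single_cell_bh_identity(self, enriched_cohort):
        ref = enriched_cohort["reference"]
        cs = enriched_cohort["callset"]
        tracks = enriched_cohort["tracks"]
        rates = genome_context_rates(cs, ref)
        grid = multi_track_heatmap(cs, tracks["tfbs"], {"dhs": tracks["dhs"]},
                                   rates, ref, quantiles=(0.9,),
                                   class_filter="T>G")
        assert len(grid) == 1
        assert grid["p_adj"].iloc[0] == pytest.approx(grid["p"].iloc[0])

    def test_planted_cell_flagged(self, enriched_cohort):
        ref = enriched_cohort["reference"]
        cs = {s: r for s, r in enriched_cohort["callset"].items()
              if s.startswith("case")}
        tracks = enriched_cohort["tracks"]
        rates = genome_context_rates(cs, ref)
        grid = multi_track_heatmap(cs, tracks["tfbs"], {"dhs": tracks["dhs"]},
                                   rates, ref, quantiles=(0.5, 0.9),
                                   class_filter="T>G")
        assert grid.loc[grid["quantile"] == 0.9, "significant"].iloc[0]

    def test_per_sample_oe_consistent(self, enriched_cohort):
        ref = enriched_cohort["reference"]
        cs = enriched_cohort["callset"]
        truth = enriched_cohort["truth"]
        mids = pd.DataFrame({"chrom": "chr1", "pos": truth.active_midpoints})
        rates = {s: genome_context_rates({s: r}, ref) for s, r in cs.items()}
        table = per_sample_oe(cs, mids, rates, ref, window=100,
                              class_filter="T>G")
        assert len(table) == len(cs)
        # case samples carry the planted signal; their mean O/E exceeds controls'
        cases = table[table["sample_id"].str.startswith("case")]["ratio"]
        ctrls = table[table["sample_id"].str.startswith("ctrl")]["ratio"]
        assert cases.fillna(0).mean() > ctrls.fillna(0).mean()
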