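"""Call-set IO, mosaic filtering, context annotation and distances."""

import numpy as np
import pandas as pd
import pytest

from mosaicstats import (
    FilterParams,
    IntervalTrack,
    VariantRecord,
    annotate_context,
    apply_mosaic_filters,
    callset_to_frame,
    distance_to_feature,
    overlap_counts,
    read_callset,
    spectrum_96,
)
from mosaicstats.variants import write_callset_tsv


def rec(pos, ref, alt, alt_reads=20, total=200, sample="s1", pop_af=None):
    return VariantRecord(sample_id=sample, chrom="chr1", pos=pos, ref=ref,
                         alt=alt, alt_reads=alt_reads, total_reads=total,
                         pop_af=pop_af)


class TestRecord:
    def test_vaf_derived_from_reads(self):
        assert rec(100, "T", "G", 5, 100).vaf == pytest.approx(0.05)

    def test_rejects_non_snv(self):
        with pytest.raises(ValueError):
            rec(100, "T", "T")


class TestFilters:
    def test_removal_reasons_in_fixed_order(self):
        cs = {"s1": [
            rec(1000, "T", "G", 90, 200),            # vaf 0.45 -> vaf_max
            rec(2000, "T", "G", 8, 24),              # p vs 0.5 ~ 0.15 -> germline_p
            rec(3000, "T", "G", 20, 200, pop_af=0.01),  # pop_af
            rec(4000, "T", "G", 3, 200),             # min_reads
            rec(5000, "T", "G", 20, 200),            # kept
        ]}
        kept, removed = apply_mosaic_filters(cs, FilterParams())
        assert [r.pos for r in kept["s1"]] == [5000]
        assert removed.set_index("pos")["reason"].to_dict() == {
            1000: "vaf_max", 2000: "germline_p", 3000: "pop_af", 4000: "min_reads"}

    def test_first_failing_rule_wins(self):
        # vaf 0.45 also fails the pop-af screen, but vaf_max is checked first
        cs = {"s1": [rec(1, "T", "G", 90, 200, pop_af=0.5)]}
        _, removed = apply_mosaic_filters(cs)
        assert removed["reason"].tolist() == ["vaf_max"]

    def test_idempotent(self):
        cs = {"s1": [rec(1000 + i, "T", "G", 20, 200) for i in range(5)]}
        kept, _ = apply_mosaic_filters(cs)
        kept2, removed2 = apply_mosaic_filters(kept)
        assert removed2.empty
        assert [r.pos for r in kept2["s1"]] == [r.pos for r in kept["s1"]]

    def test_missing_pop_af_treated_as_novel(self):
        cs = {"s1": [rec(1, "T", "G", 20, 200, pop_af=None)]}
        kept, _ = apply_mosaic_filters(cs)
        assert len(kept["s1"]) == 1

    def test_zero_total_reads_errors(self):
        r = rec(1, "T", "G", 20, 200)
        r.total_reads = 0
        with pytest.raises(ValueError):
            apply_mosaic_filters({"s1": [r]})


class TestAnnotation:
    def test_direct_readoff_with_cpg(self):
        ref = {"chr1": "AACGT"}
        cs = {"s1": [rec(3, "C", "A")]}
        annotate_context(cs, ref)
        r = cs["s1"][0]
        assert (r.context, r.context_pyr, r.substitution, r.is_cpg) == \
            ("ACG", "ACG", "C>A", True)

    def test_purine_strand_collapse(self):
        ref = {"chr1": "ACGTA"}
        cs = {"s1": [rec(3, "G", "T")]}
        annotate_context(cs, ref)
        r = cs["s1"][0]
        assert (r.context, r.context_pyr, r.substitution) == ("CGT", "ACG", "C>A")
        assert r.is_cpg  # the G sits in a CG dinucleotide on the forward strand

    def test_reference_mismatch_raises(self):
        with pytest.raises(ValueError, match="chr1:3"):
            annotate_context({"s1": [rec(3, "T", "G")]}, {"chr1": "AACGT"})

    def test_edge_position_raises(self):
        with pytest.raises(ValueError):
            annotate_context({"s1": [rec(1, "A", "G")]}, {"chr1": "AACGT"})


class TestSpectrum:
    def test_single_mutation_single_channel(self):
        cs = annotate_context({"s1": [rec(3, "C", "A")]}, {"chr1": "AACGT"})
        sp = spectrum_96(cs)
        assert sp.sum() == 1 and sp["A[C>A]G"] == 1

    def test_additive_over_callsets(self, enriched_cohort):
        cs = enriched_cohort["callset"]
        sids = list(cs)
        half1 = {s: cs[s] for s in sids[:len(sids) // 2]}
        half2 = {s: cs[s] for s in sids[len(sids) // 2:]}
        assert (spectrum_96(half1) + spectrum_96(half2)).equals(spectrum_96(cs))

    def test_sum_equals_record_count(self, enriched_cohort):
        cs = enriched_cohort["callset"]
        assert spectrum_96(cs).sum() == sum(len(v) for v in cs.values())

    def test_unannotated_raises(self):
        with pytest.raises(ValueError):
            spectrum_96({"s1": [rec(3, "C", "A")]})


class TestOverlap:
    def test_boundary_inclusive(self):
        t = IntervalTrack("prom", pd.DataFrame(
            {"chrom": ["chr1"], "start": [47500], "end": [49999]}))
        cs = {"s1": [rec(47500, "T", "G"), rec(50000, "T", "G")]}
        total, per_sample, _ = overlap_counts(cs, t)
        assert total == 1 and per_sample["s1"] == 1

    def test_census_merged_union(self):
        t = IntervalTrack("x", pd.DataFrame(
            {"chrom": ["chr1", "chr1"], "start": [2, 4], "end": [5, 8]}))
        ref = {"chr1": "TTTTTTTTTT"}
        _, _, census = overlap_counts({}, t, reference=ref)
        assert census == 7  # union [2,8]

    def test_census_base_subset(self):
        t = IntervalTrack("x", pd.DataFrame(
            {"chrom": ["chr1"], "start": [1], "end": [8]}))
        _, _, census = overlap_counts({}, t, reference={"chr1": "TATTGCCA"},
                                      base_subset="TA")
        assert census == 5

    def test_absent_chromosome_raises(self):
        t = IntervalTrack("x", pd.DataFrame(
            {"chrom": ["chrX"], "start": [1], "end": [5]}))
        with pytest.raises(KeyError):
            overlap_counts({}, t, reference={"chr1": "ACGT"})


class TestDistance:
    def midpoints(self, *pos):
        return pd.DataFrame({"chrom": "chr1", "pos": list(pos)})

    def test_signed_distance(self):
        cs = {"s1": [rec(950, "T", "G")]}
        distance_to_feature(cs, self.midpoints(1000))
        assert cs["s1"][0].dist_tfbs == -50

    def test_tie_breaks_to_smaller_midpoint(self):
        cs = {"s1": [rec(900, "T", "G")]}
        distance_to_feature(cs, self.midpoints(800, 1000))
        assert cs["s1"][0].dist_tfbs == 100  # assigned to 800

    def test_matches_bruteforce(self, rng):
        mids = np.sort(rng.choice(np.arange(1, 100_000), size=50, replace=False))
        pos = rng.integers(1, 100_000, size=200)
        cs = {"s1": [rec(int(p), "T", "G") for p in pos]}
        distance_to_feature(cs, self.midpoints(*mids))
        for r in cs["s1"]:
            dists = r.pos - mids
            best = dists[np.argmin(np.abs(dists))]
            assert abs(r.dist_tfbs) == abs(best)

    def test_contig_without_midpoints_flagged(self):
        cs = {"s1": [rec(100, "T", "G")]}
        with pytest.warns(UserWarning, match="no midpoints"):
            distance_to_feature(cs, pd.DataFrame({"chrom": ["chr2"], "pos": [5]}))
        assert cs["s1"][0].dist_tfbs is None


class TestIO:
    def test_tsv_roundtrip(self, tmp_path):
        cs = {"s1": [rec(100, "T", "G"), rec(200, "C", "A")],
              "s2": [rec(150, "G", "T", sample="s2")]}
        p = tmp_path / "calls.tsv"
        write_callset_tsv(cs, p)
        back = read_callset(p)
        assert {s: [(r.pos, r.ref, r.alt, r.alt_reads) for r in recs]
                for s, recs in back.items()} == \
               {s: [(r.pos, r.ref, r.alt, r.alt_reads) for r in recs]
                for s, recs in cs.items()}

    def test_vcf_and_tsv_dialects_agree(self, tmp_path):
        vcf = tmp_path / "s1.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=DP,Number=1,Type=Integer,Description="d">\n'
            '##INFO=<ID=AD,Number=2,Type=Integer,Description="a">\n'
            "##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "chr1\t100\t.\tT\tG\t.\tPASS\tDP=100;AD=95,5\n")
        tsv = tmp_path / "calls.tsv"
        pd.DataFrame([{"sample_id": "s1", "chrom": "chr1", "pos": 100,
                       "ref": "T", "alt": "G", "alt_reads": 5,
                       "total_reads": 100}]).to_csv(tsv, sep="\t", index=False)
        a = read_callset(vcf)["s1"][0]
        b = read_callset(tsv)["s1"][0]
        assert (a.pos, a.ref, a.alt, a.alt_reads, a.total_reads, a.vaf) == \
               (b.pos, b.ref, b.alt, b.alt_reads, b.total_reads, b.vaf)

    def test_indel_rows_skipped(self, tmp_path):
        tsv = tmp_path / "calls.tsv"
        pd.DataFrame([
            {"sample_id": "s1", "chrom": "chr1", "pos": 100, "ref": "T",
             "alt": "G", "alt_reads": 5, "total_reads": 100},
            {"sample_id": "s1", "chrom": "chr1", "pos": 200, "ref": "TA",
             "alt": "T", "alt_reads": 5, "total_reads": 100},
        ]).to_csv(tsv, sep="\t", index=False)
        cs = read_callset(tsv)
        assert [r.pos for r in cs["s1"]] == [100]

    def test_frame_flattening(self):
        cs = {"s1": [rec(100, "T", "G")]}
        frame = callset_to_frame(cs)
        assert frame.loc[0, ["chrom", "pos", "ref", "alt"]].tolist() == \
            ["chr1", 100, "T", "G"]
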