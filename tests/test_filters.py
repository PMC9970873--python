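"""Filter cascade tests: hard-filter boundaries on both sides of every quoted
threshold, trio subtraction recovery, splice-window and population-frequency
rules."""

import pytest

from somapipe.filters import (
    VariantRecord,
    aggregate_splice_predictions,
    classify_panel_quality,
    classify_population_frequency,
    exclude_panel_somatic_snv,
    filter_germline,
    reportable,
    splice_window_annotate,
    trio_subtract,
    wgs_somatic_filter,
)
from somapipe.intervals import GenomicInterval


def record(**kw):
    base = dict(chrom="chr1", pos=100, ref="C", alt="T")
    base.update(kw)
    return VariantRecord(**base)


class TestGermlineHardFilters:
    @pytest.mark.parametrize(
        "vclass,metric,failing,passing",
        [
            ("substitution", "QD", 1.999, 2.0),
            ("substitution", "FS", 60.001, 60.0),
            ("substitution", "MQ", 39.999, 40.0),
            ("substitution", "MQRankSum", -12.501, -12.5),
            ("substitution", "ReadPosRankSum", -8.001, -8.0),
            ("substitution", "SOR", 30.001, 30.0),
            ("indel", "QD", 1.999, 2.0),
            ("indel", "FS", 200.001, 200.0),
            ("indel", "ReadPosRankSum", -20.001, -20.0),
            ("indel", "SOR", 10.001, 10.0),
        ],
    )
    def test_each_threshold_both_sides(self, vclass, metric, failing, passing):
        bad = record(variant_class=vclass, caller_metrics={metric: failing})
        good = record(variant_class=vclass, caller_metrics={metric: passing})
        v_bad, v_good = filter_germline(bad), filter_germline(good)
        assert not v_bad.kept and any(metric in r for r in v_bad.reasons)
        assert v_good.kept

    def test_missing_metric_skips_rule(self):
        assert filter_germline(record(caller_metrics={})).kept

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError):
            filter_germline(record(), "structural")

    def test_indel_not_subject_to_mq_rule(self):
        assert filter_germline(record(variant_class="indel", caller_metrics={"MQ": 10.0})).kept


class TestPanelSomaticExclusion:
    def ok(self):
        return dict(tumor_alt_depth=20, tumor_ref_depth=80,
                    normal_alt_depth=0, normal_ref_depth=100)

    @pytest.mark.parametrize(
        "override,excluded",
        [
            ({"tumor_alt_depth": 9}, True),
            ({"tumor_alt_depth": 10}, False),
            ({"normal_alt_depth": 3}, True),
            ({"normal_alt_depth": 2}, False),
        ],
    )
    def test_depth_rules_both_sides(self, override, excluded):
        v = exclude_panel_somatic_snv(record(**{**self.ok(), **override}))
        assert v.kept is not excluded

    def test_low_germline_ref_with_low_vaf_is_conjunctive(self):
        # both conditions must hold to exclude
        both = record(tumor_alt_depth=10, tumor_ref_depth=1990,
                      normal_alt_depth=0, normal_ref_depth=50)
        assert both.tumor_vaf == pytest.approx(0.005)
        assert not exclude_panel_somatic_snv(both).kept
        low_vaf_only = record(tumor_alt_depth=10, tumor_ref_depth=1990,
                              normal_alt_depth=0, normal_ref_depth=51)
        assert exclude_panel_somatic_snv(low_vaf_only).kept

    def test_pon_frequency_boundary(self):
        r = record(**self.ok())
        assert not exclude_panel_somatic_snv(r, {r.key: 0.01}).kept
        assert exclude_panel_somatic_snv(r, {r.key: 0.009}).kept

    def test_caller_pass_overrides_low_depth_in_both(self):
        r_fail = record(tumor_alt_depth=8, tumor_ref_depth=1,
                        normal_alt_depth=0, normal_ref_depth=8, caller_pass=False)
        r_pass = record(tumor_alt_depth=8, tumor_ref_depth=1,
                        normal_alt_depth=0, normal_ref_depth=8, caller_pass=True)
        v_fail = exclude_panel_somatic_snv(r_fail)
        v_pass = exclude_panel_somatic_snv(r_pass)
        assert "low_depth_both_samples" in v_fail.reasons
        assert "low_depth_both_samples" not in v_pass.reasons


class TestQualityAndReporting:
    def test_high_quality_substitution_boundaries(self):
        high = record(tumor_alt_depth=4, tumor_ref_depth=56, normal_alt_depth=0,
                      normal_ref_depth=55, tumor_vaf=0.06, caller_pass=True)
        assert classify_panel_quality(high) == "high"
        low_vaf = record(tumor_alt_depth=4, tumor_ref_depth=96, normal_ref_depth=55,
                         normal_alt_depth=0, tumor_vaf=0.04, caller_pass=True)
        assert classify_panel_quality(low_vaf) == "low"
        depth49 = record(tumor_alt_depth=3, tumor_ref_depth=46, normal_alt_depth=0,
                         normal_ref_depth=55, tumor_vaf=0.06, caller_pass=True)
        assert classify_panel_quality(depth49) == "low"
        no_pass = record(tumor_alt_depth=4, tumor_ref_depth=56, normal_alt_depth=0,
                         normal_ref_depth=55, tumor_vaf=0.06, caller_pass=False)
        assert classify_panel_quality(no_pass) == "low"

    @pytest.mark.parametrize(
        "alt_t,ref_n,alt_n,vaf,expect",
        [
            (11, 51, 2, 0.12, "high"),
            (10, 51, 2, 0.12, "low"),   # needs >10 alt reads in tumor
            (11, 50, 2, 0.12, "low"),   # needs >50 ref reads in normal
            (11, 51, 3, 0.12, "low"),   # needs <=2 alt reads in normal
            (11, 51, 2, 0.099, "low"),  # needs VAF >= 10%
        ],
    )
    def test_high_quality_indel_boundaries(self, alt_t, ref_n, alt_n, vaf, expect):
        r = record(variant_class="indel", tumor_alt_depth=alt_t, tumor_ref_depth=90,
                   normal_alt_depth=alt_n, normal_ref_depth=ref_n, tumor_vaf=vaf)
        assert classify_panel_quality(r) == expect

    @pytest.mark.parametrize(
        "vclass,vaf,expect",
        [
            ("substitution", 0.05, True),
            ("substitution", 0.0499, False),
            ("indel", 0.10, True),
            ("indel", 0.08, False),
        ],
    )
    def test_reporting_thresholds_inclusive(self, vclass, vaf, expect):
        assert reportable(record(variant_class=vclass, tumor_vaf=vaf)) is expect

    def test_actionable_exception_reports_below_threshold(self):
        r = record(tumor_vaf=0.02, actionable_flag=True, actionable_exception=True)
        assert reportable(r)
        no_exc = record(tumor_vaf=0.02, actionable_flag=True)
        assert not reportable(no_exc)


class TestWgsSomaticFilter:
    def deep(self, **locus):
        return record(tumor_alt_depth=10, tumor_ref_depth=40, normal_alt_depth=0,
                      normal_ref_depth=40, locus_metrics=locus)

    def test_two_of_four_mapping_flags_required(self):
        two = self.deep(unique_mapping_fraction=0.69, dust=60.1)
        assert not wgs_somatic_filter(two).kept
        one = self.deep(dust=60.1)
        assert wgs_somatic_filter(one).kept

    def test_dust_threshold_both_sides(self):
        at = self.deep(unique_mapping_fraction=0.69, dust=60.0)  # 60 does not fire
        assert wgs_somatic_filter(at).kept
        above = self.deep(unique_mapping_fraction=0.69, dust=60.001)
        assert not wgs_somatic_filter(above).kept

    def test_unique_mapping_threshold_both_sides(self):
        at = self.deep(unique_mapping_fraction=0.70, dust=61)
        assert wgs_somatic_filter(at).kept
        below = self.deep(unique_mapping_fraction=0.699, dust=61)
        assert not wgs_somatic_filter(below).kept

    def test_normal_support_and_depth_rules(self):
        supported = record(tumor_alt_depth=10, tumor_ref_depth=40,
                           normal_alt_depth=1, normal_ref_depth=40)
        assert "variant_reads_in_normal" in wgs_somatic_filter(supported).reasons
        shallow = record(tumor_alt_depth=2, tumor_ref_depth=7, normal_alt_depth=0,
                         normal_ref_depth=40)
        assert "tumor_depth<10" in wgs_somatic_filter(shallow).reasons
        boundary = record(tumor_alt_depth=2, tumor_ref_depth=8, normal_alt_depth=0,
                          normal_ref_depth=10)
        assert wgs_somatic_filter(boundary).kept

    def test_pon_membership_removes(self):
        r = self.deep()
        assert not wgs_somatic_filter(r, pon_set={r.key}).kept


class TestTrioSubtraction:
    def test_intersection_is_somatic_and_singletons_inherited(self):
        a = [("chr1", 1, "A", "T"), ("chr1", 2, "C", "G")]
        b = [("chr1", 2, "C", "G"), ("chr1", 3, "G", "A")]
        out = trio_subtract(a, b)
        assert [k for k in map(tuple, out["somatic"])] == [("chr1", 2, "C", "G")]
        assert out["inherited_paternal"] == [("chr1", 1, "A", "T")]
        assert out["inherited_maternal"] == [("chr1", 3, "G", "A")]

    def test_commutative_and_empty(self):
        a = [("chr1", 1, "A", "T")]
        b = [("chr1", 1, "A", "T")]
        assert trio_subtract(a, b)["somatic"] == trio_subtract(b, a)["somatic"]
        assert trio_subtract([], [])["somatic"] == []

    def test_recovers_planted_somatic_set_exactly(self, config):
        from somapipe.simulate import make_trio_and_tumor

        trio = make_trio_and_tumor(config)
        out = trio_subtract(trio["tumor_vs_mother"], trio["tumor_vs_father"])
        assert {v.key for v in out["somatic"]} == trio["truth"].true_somatic_variants


class TestAnnotationRules:
    @pytest.mark.parametrize(
        "freq,expect",
        [
            (0.06, "benign"),
            (0.0501, "benign"),
            (0.05, "likely_benign"),
            (0.03, "likely_benign"),
            (0.0201, "likely_benign"),
            (0.02, "not_classified_by_frequency"),
            (0.001, "not_classified_by_frequency"),
            (None, "not_classified_by_frequency"),
        ],
    )
    def test_population_frequency_bands(self, freq, expect):
        assert classify_population_frequency(freq) == expect

    @pytest.mark.parametrize(
        "vclass,offset,in_window",
        [
            ("substitution", 10, True),
            ("substitution", 11, False),
            ("indel", 20, True),
            ("indel", 21, False),
            ("indel", 15, True),
        ],
    )
    def test_splice_window_boundaries(self, vclass, offset, in_window):
        exons = [GenomicInterval("chr1", 100, 200)]
        r = record(pos=200 + offset - 1, variant_class=vclass)  # offset bases into intron
        ann = splice_window_annotate(r, exons)
        assert ann["distance"] == offset
        assert ann["in_window"] is in_window

    def test_exonic_variant_distance_zero(self):
        ann = splice_window_annotate(record(pos=150), [GenomicInterval("chr1", 100, 200)])
        assert ann == {"in_window": True, "distance": 0}

    @pytest.mark.parametrize(
        "scores,expect",
        [
            ([40, 35, 31, 0], True),    # three programs above 30%
            ([40, 35, 24, 0], False),   # only two above 30%, sum 99 < 100
            ([60, 45], True),           # combined score reaches 100%
            ([60, 39], False),
            ([20, 20, 20, 20], False),  # neither branch (sum 80)
        ],
    )
    def test_splice_prediction_aggregation(self, scores, expect):
        assert aggregate_splice_predictions(scores) is expect
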