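"""Molecular subtype assignment: tier hierarchy, AML-MR, report phases."""

import pytest

from leukotype.classify import (
    assign_report_phase,
    classify_case,
    evaluate_aml_mr,
    evaluate_case,
    is_complex_karyotype,
)
from leukotype.fixtures import _case, _fusion_event, _stub_variant, category_cohort
from leukotype.genome import gene_regions
from leukotype.iscn import parse_iscn
from leukotype.models import (
    Breakpoint,
    CNVKind,
    CNVSegment,
    CytoLesion,
    Frame,
    LesionKind,
    ReportPhase,
    RuleConfig,
    StructuralEvent,
    SubtypeCategory,
)


@pytest.fixture(scope="module")
def cfg():
    return RuleConfig()


def _classify(case, rules, cfg):
    return classify_case(case, rules, evaluate_case(case, cfg), cfg)


class TestComplexKaryotype:
    def test_three_unrelated_abnormalities_is_complex(self, cfg):
        k = parse_iscn("47,XX,add(3)(q21),del(13)(q12q22),+mar[20]")
        assert is_complex_karyotype(k, cfg)

    def test_normal_karyotype_is_not(self, cfg):
        assert not is_complex_karyotype(parse_iscn("46,XX"), cfg)

    def test_two_abnormalities_below_threshold(self, cfg):
        assert not is_complex_karyotype(parse_iscn("45,XY,-7,del(5)(q13q33)"), cfg)


class TestAmlMr:
    def test_monosomy_7_matches(self, cfg, rules):
        lesion = CytoLesion(kind=LesionKind.MONOSOMY, chrom="7", raw="-7")
        flag, matched = evaluate_aml_mr([lesion], [], [], rules, cfg)
        assert flag and matched == ["cyto:mono7/7q-"]

    def test_wgs_only_11q_deletion_matches(self, cfg, rules):
        # a 25 Mb deletion on 11q seen only by sequencing
        seg = CNVSegment(
            case_id="X", chrom="chr11", start=95_000_000, end=120_000_000,
            kind=CNVKind.LOSS, scale_class=None,
        )
        from leukotype.rules import classify_cnv_event

        flag, matched = evaluate_aml_mr([], [classify_cnv_event(seg, cfg)], [], rules, cfg)
        assert flag and matched == ["cnv:11q-"]

    def test_trisomy_8_alone_does_not_match(self, cfg, rules):
        lesion = CytoLesion(kind=LesionKind.TRISOMY, chrom="8", raw="+8")
        flag, _ = evaluate_aml_mr([lesion], [], [], rules, cfg)
        assert not flag

    def test_mr_gene_mutation_matches(self, cfg, rules):
        v = _stub_variant("X", "RUNX1")
        flag, matched = evaluate_aml_mr([], [], [v], rules, cfg)
        assert flag and matched == ["mut:RUNX1"]


class TestTierHierarchy:
    def test_who_fusion_wins(self, cfg, rules):
        case = _case("X", svs=[_fusion_event("X", "RUNX1::RUNX1T1")])
        out = _classify(case, rules, cfg)
        assert out.category is SubtypeCategory.WHO_FUSION
        assert out.defining_lesion == "RUNX1::RUNX1T1"

    def test_npm1_with_complex_karyotype_is_who_mutation_not_aml_mr(self, cfg, rules):
        case = _case(
            "X",
            variants=[_stub_variant("X", "NPM1")],
            karyotype=parse_iscn("47,XX,add(3)(q21),del(13)(q12q22),+mar[20]"),
        )
        out = _classify(case, rules, cfg)
        assert out.category is SubtypeCategory.WHO_MUTATION
        assert "NPM1" in out.defining_lesion

    def test_7q_deletion_alone_is_aml_mr(self, cfg, rules):
        case = _case(
            "X",
            cnvs=[CNVSegment(case_id="X", chrom="chr7", start=62_000_000, end=110_000_000, kind=CNVKind.LOSS)],
        )
        out = _classify(case, rules, cfg)
        assert out.category is SubtypeCategory.AML_MR

    def test_no_reportable_lesion_is_nos_with_null_driver(self, cfg, rules):
        out = _classify(_case("X"), rules, cfg)
        assert out.category is SubtypeCategory.NOS and out.defining_lesion is None

    def test_two_driver_fusions_pick_who_pattern_and_keep_secondary(self, cfg, rules):
        # a core-binding-factor fusion co-occurring with a kinase fusion
        kit = StructuralEvent(
            case_id="X",
            breakpoint_a=Breakpoint(chrom="chr9", pos=121_100_000),
            breakpoint_b=Breakpoint(chrom="chr4", pos=54_658_000),
            gene_a="CNTRL",
            gene_b="KIT",
            exon_junction=(20, 10),
            frame=Frame.IN_FRAME,
        ).canonical()
        case = _case("X", svs=[_fusion_event("X", "CBFB::MYH11"), kit])
        out = _classify(case, rules, cfg)
        assert out.category is SubtypeCategory.WHO_FUSION
        assert out.defining_lesion == "CBFB::MYH11"
        assert "CNTRL::KIT" in out.secondary_drivers

    def test_ds_aml_outranks_fusion(self, cfg, rules):
        case = _case(
            "X",
            down_syndrome=True,
            variants=[_stub_variant("X", "GATA1")],
            svs=[_fusion_event("X", "CBFB::MYH11")],
        )
        out = _classify(case, rules, cfg)
        assert out.category is SubtypeCategory.DS_AML
        assert "CBFB::MYH11" in out.secondary_drivers

    def test_biallelic_tp53_requires_second_hit(self, cfg, rules):
        single = _case("X", variants=[_stub_variant("X", "TP53")])
        assert _classify(single, rules, cfg).category is not SubtypeCategory.WHO_MUTATION
        second = single.model_copy(
            update={
                "cnvs": [
                    CNVSegment(case_id="X", chrom="chr17", start=1_000_000, end=20_000_000, kind=CNVKind.LOSS)
                ]
            }
        )
        out = _classify(second, rules, cfg)
        assert out.category is SubtypeCategory.WHO_MUTATION and "TP53" in out.defining_lesion

    def test_removing_defining_lesion_never_promotes(self, cfg, rules):
        """Deleting the defining lesion re-classifies to a lower tier or NOS."""
        order = list(SubtypeCategory)
        cohort = [c for c in category_cohort() if c.svs or c.variants]
        for case in cohort[:40]:
            before = _classify(case, rules, cfg)
            stripped = case.model_copy(update={"svs": [], "variants": []})
            after = _classify(stripped, rules, cfg)
            assert order.index(after.category) >= order.index(before.category)

    def test_every_case_gets_exactly_one_category(self, cfg, rules):
        cats = [_classify(c, rules, cfg).category for c in category_cohort()]
        assert len(cats) == 153 and all(isinstance(c, SubtypeCategory) for c in cats)


class TestReportPhase:
    @pytest.mark.parametrize(
        "kind,phase",
        [
            ("who_fusion", ReportPhase.PHASE1_DAY7),
            ("ls_cnv", ReportPhase.PHASE1_DAY7),
            ("rare_novel_fusion", ReportPhase.PHASE2_DAY14),
            ("cooperating_variant", ReportPhase.PHASE2_DAY14),
            ("germline", ReportPhase.PHASE3_DAY21),
        ],
    )
    def test_phase_mapping(self, kind, phase):
        assert assign_report_phase(kind) is phase

    def test_unknown_kind_is_an_error(self):
        with pytest.raises(ValueError, match="unknown finding kind"):
            assign_report_phase("prognostic_vibe")
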