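"""Evidence rules: reportability, CNV scale classes, ITD/PTD, SV mechanism."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leukotype.genome import gene_regions
from leukotype.models import (
    Breakpoint,
    CNVKind,
    CNVSegment,
    EventClass,
    Frame,
    ITDEvidence,
    ITDStrength,
    Mechanism,
    Origin,
    Pathogenicity,
    ReportStatus,
    RuleConfig,
    StructuralEvent,
)
from leukotype.rules import (
    ITD_WEAK_BOTH,
    ITD_WTS_ONLY,
    SUB50KB_REVIEW,
    VAF_PASS,
    WTS_RESCUE,
    assess_snv_reportability,
    call_kmt2a_ptd,
    classify_cnv_event,
    classify_sv_mechanism,
    combine_itd_evidence,
    filter_germline_findings,
    normalize_variant,
)

S = ITDStrength


# ---------------------------------------------------------------------------
# SNV/indel reportability
# ---------------------------------------------------------------------------


class TestSnvReportability:
    def test_wgs_vaf_at_floor_is_reportable(self, cfg, variant_factory):
        d = assess_snv_reportability(variant_factory(wgs=0.06), cfg)
        assert d.status is ReportStatus.REPORTABLE and VAF_PASS in d.rationale_codes

    def test_subclonal_driver_rescued_by_high_rna_vaf(self, cfg, variant_factory):
        v = variant_factory(is_aml_driver=True, wgs=0.03, wts=0.30)
        d = assess_snv_reportability(v, cfg)
        assert d.status is ReportStatus.REPORTABLE and WTS_RESCUE in d.rationale_codes

    def test_subclonal_non_driver_is_not_rescued_by_wes(self, cfg, variant_factory):
        v = variant_factory(wgs=0.031, wes=0.07)
        assert assess_snv_reportability(v, cfg).status is ReportStatus.NOT_REPORTABLE

    def test_rescue_threshold_is_strict(self, cfg, variant_factory):
        v = variant_factory(is_aml_driver=True, wgs=0.03, wts=0.25)
        assert assess_snv_reportability(v, cfg).status is ReportStatus.NOT_REPORTABLE

    def test_vus_never_reportable(self, cfg, variant_factory):
        v = variant_factory(pathogenicity=Pathogenicity.VUS, wgs=0.40)
        assert assess_snv_reportability(v, cfg).status is ReportStatus.NOT_REPORTABLE

    def test_insufficient_wgs_evidence_blocks_vaf_branch(self, cfg, variant_factory):
        v = variant_factory(wgs="insufficient", wts=0.10)
        assert assess_snv_reportability(v, cfg).status is ReportStatus.NOT_REPORTABLE

    def test_missing_pathogenicity_is_an_error(self, cfg, variant_factory):
        v = variant_factory(pathogenicity=None, wgs=0.40)
        with pytest.raises(ValueError, match="pathogenicity"):
            assess_snv_reportability(v, cfg)

    @settings(max_examples=60, deadline=None)
    @given(
        low=st.floats(0.0, 1.0, allow_nan=False),
        bump=st.floats(0.0, 1.0, allow_nan=False),
        driver=st.booleans(),
    )
    def test_reportability_monotone_in_wgs_vaf(self, cfg, low, bump, driver):
        """Raising the WGS VAF can never flip reportable -> not reportable."""
        from conftest import make_variant

        high = min(1.0, low + bump)
        d_low = assess_snv_reportability(make_variant(is_aml_driver=driver, wgs=low), cfg)
        d_high = assess_snv_reportability(make_variant(is_aml_driver=driver, wgs=high), cfg)
        if d_low.status is ReportStatus.REPORTABLE:
            assert d_high.status is ReportStatus.REPORTABLE


class TestGermlineFilter:
    def test_keeps_plp_in_panel_gene(self, cfg, variant_factory):
        v = variant_factory(gene="RUNX1", origin=Origin.GERMLINE, wgs=0.5)
        assert filter_germline_findings([v], cfg) == [v]

    @pytest.mark.parametrize(
        "gene,patho",
        [("RUNX1", Pathogenicity.VUS), ("MYCN", Pathogenicity.P)],
        ids=["vus_in_panel_gene", "pathogenic_outside_panel"],
    )
    def test_drops_non_reportable_findings(self, cfg, variant_factory, gene, patho):
        v = variant_factory(gene=gene, origin=Origin.GERMLINE, pathogenicity=patho, wgs=0.5)
        assert filter_germline_findings([v], cfg) == []

    def test_empty_panel_is_a_configuration_error(self, variant_factory):
        with pytest.raises(ValueError, match="germline_gene_list"):
            filter_germline_findings([variant_factory(origin=Origin.GERMLINE)], RuleConfig())


# ---------------------------------------------------------------------------
# CNV scale classes
# ---------------------------------------------------------------------------


def _seg(size_bp, kind=CNVKind.LOSS, chrom="chr11"):
    return CNVSegment(case_id="X", chrom=chrom, start=1_000_000, end=1_000_000 + size_bp - 1, kind=kind)


class TestCnvScaleClasses:
    def test_small_intragenic_loss_is_focal_with_review_flag(self, cfg):
        out = classify_cnv_event(_seg(7_200), cfg)
        assert out.scale_class.value == "focal" and SUB50KB_REVIEW in out.flags

    def test_exactly_5mb_is_large_scale(self, cfg):
        assert classify_cnv_event(_seg(5_000_000), cfg).scale_class.value == "large_scale"

    def test_cnloh_below_10mb_is_sub_threshold(self, cfg):
        assert classify_cnv_event(_seg(9_000_000, CNVKind.CNLOH), cfg).scale_class.value == "sub_threshold"

    def test_cnloh_at_10mb_is_large_scale(self, cfg):
        assert classify_cnv_event(_seg(10_000_000, CNVKind.CNLOH), cfg).scale_class.value == "large_scale"

    @settings(max_examples=60, deadline=None)
    @given(size=st.integers(1, 300_000_000), gain=st.booleans())
    def test_every_gain_or_loss_lands_in_exactly_one_class(self, cfg, size, gain):
        out = classify_cnv_event(_seg(size, CNVKind.GAIN if gain else CNVKind.LOSS), cfg)
        assert out.scale_class.value in ("focal", "large_scale")
        assert (out.scale_class.value == "focal") == (size < cfg.focal_cnv_max_bp)


# ---------------------------------------------------------------------------
# FLT3-ITD combiner
# ---------------------------------------------------------------------------

# Hand-written 16-entry oracle over the WGS x WTS strength grid.
_ITD_ORACLE = {
    (S.STRONG, S.STRONG): ReportStatus.REPORTABLE,
    (S.STRONG, S.WEAK): ReportStatus.REPORTABLE,
    (S.STRONG, S.NONE): ReportStatus.REPORTABLE,
    (S.STRONG, S.INSUFFICIENT_COVERAGE): ReportStatus.REPORTABLE,
    (S.WEAK, S.STRONG): ReportStatus.BORDERLINE,
    (S.NONE, S.STRONG): ReportStatus.BORDERLINE,
    (S.INSUFFICIENT_COVERAGE, S.STRONG): ReportStatus.BORDERLINE,
    (S.WEAK, S.WEAK): ReportStatus.BORDERLINE,
    (S.WEAK, S.NONE): ReportStatus.NOT_REPORTABLE,
    (S.WEAK, S.INSUFFICIENT_COVERAGE): ReportStatus.NOT_REPORTABLE,
    (S.NONE, S.WEAK): ReportStatus.NOT_REPORTABLE,
    (S.NONE, S.NONE): ReportStatus.NOT_REPORTABLE,
    (S.NONE, S.INSUFFICIENT_COVERAGE): ReportStatus.NOT_REPORTABLE,
    (S.INSUFFICIENT_COVERAGE, S.WEAK): ReportStatus.NOT_REPORTABLE,
    (S.INSUFFICIENT_COVERAGE, S.NONE): ReportStatus.NOT_REPORTABLE,
    (S.INSUFFICIENT_COVERAGE, S.INSUFFICIENT_COVERAGE): ReportStatus.NOT_REPORTABLE,
}


class TestItdCombiner:
    @pytest.mark.parametrize("wgs,wts", list(itertools.product(S, S)))
    def test_full_grid_matches_oracle(self, wgs, wts):
        e = ITDEvidence(case_id="X", wgs_strength=wgs, wts_strength=wts)
        assert combine_itd_evidence(e).status is _ITD_ORACLE[(wgs, wts)]

    def test_wts_only_and_weak_both_get_distinct_rationales(self):
        d1 = combine_itd_evidence(ITDEvidence(case_id="X", wgs_strength=S.NONE, wts_strength=S.STRONG))
        d2 = combine_itd_evidence(ITDEvidence(case_id="X", wgs_strength=S.WEAK, wts_strength=S.WEAK))
        assert ITD_WTS_ONLY in d1.rationale_codes and ITD_WEAK_BOTH in d2.rationale_codes

    def test_pcr_only_subclonal_itd_not_reportable_by_sequencing(self):
        e = ITDEvidence(case_id="SJ030286", wgs_strength=S.NONE, wts_strength=S.NONE, pcr_ratio=0.02)
        assert combine_itd_evidence(e).status is ReportStatus.NOT_REPORTABLE


# ---------------------------------------------------------------------------
# KMT2A-PTD
# ---------------------------------------------------------------------------


def _kmt2a_gain(size=20_000):
    chrom, start, _ = gene_regions()["KMT2A"]
    return CNVSegment(
        case_id="X", chrom=chrom, start=start + 1_000, end=start + 1_000 + size - 1,
        kind=CNVKind.GAIN, gene="KMT2A",
    )


def _kmt2a_junction(donor=8, acceptor=2, frame=Frame.IN_FRAME):
    chrom, start, _ = gene_regions()["KMT2A"]
    return StructuralEvent(
        case_id="X",
        breakpoint_a=Breakpoint(chrom=chrom, pos=start + 30_000),
        breakpoint_b=Breakpoint(chrom=chrom, pos=start + 50_000),
        gene_a="KMT2A",
        gene_b="KMT2A",
        exon_junction=(donor, acceptor),
        frame=frame,
    )


class TestKmt2aPtd:
    def test_gain_with_exon8_to_exon2_junction_is_reportable(self, cfg):
        calls = call_kmt2a_ptd([_kmt2a_gain()], [_kmt2a_junction(8, 2)], cfg)
        assert len(calls) == 1
        event, decision = calls[0]
        assert event.event_class is EventClass.PTD
        assert decision.status is ReportStatus.REPORTABLE

    def test_gain_without_junction_is_borderline(self, cfg):
        calls = call_kmt2a_ptd([_kmt2a_gain()], [], cfg)
        (event, decision), = calls
        assert decision.status is ReportStatus.BORDERLINE

    def test_junction_outside_exon_pattern_does_not_support(self, cfg):
        calls = call_kmt2a_ptd([_kmt2a_gain()], [_kmt2a_junction(5, 2)], cfg)
        (_, decision), = calls
        assert decision.status is ReportStatus.BORDERLINE

    def test_junction_without_gain_emits_nothing(self, cfg):
        assert call_kmt2a_ptd([], [_kmt2a_junction(8, 2)], cfg) == []

    def test_large_gain_is_not_a_ptd(self, cfg):
        assert call_kmt2a_ptd([_kmt2a_gain(size=80_000)], [_kmt2a_junction(8, 2)], cfg) == []


# ---------------------------------------------------------------------------
# SV mechanism
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def oncogenes():
    return {g: r for g, r in gene_regions().items() if g in ("MECOM", "BCL11B")}


def _sv(chrom_a, pos_a, chrom_b, pos_b, frame=Frame.UNKNOWN, junction=None):
    return StructuralEvent(
        case_id="X",
        breakpoint_a=Breakpoint(chrom=chrom_a, pos=pos_a),
        breakpoint_b=Breakpoint(chrom=chrom_b, pos=pos_b),
        gene_a="A",
        gene_b="B",
        frame=frame,
        exon_junction=junction,
    )


class TestSvMechanism:
    def test_in_frame_exon_junction_is_a_fusion_oncogene(self, cfg, oncogenes):
        sv = _sv("chr1", 100, "chr2", 200, frame=Frame.IN_FRAME, junction=(5, 2))
        assert classify_sv_mechanism(sv, oncogenes, cfg).mechanism is Mechanism.IN_FRAME_FUSION

    def test_breakpoint_upstream_of_oncogene_is_hijack_candidate(self, cfg, oncogenes):
        chrom, start, _ = gene_regions()["MECOM"]
        out = classify_sv_mechanism(_sv(chrom, start - 100_000, "chr3", 128_482_000), oncogenes, cfg)
        assert out.mechanism is Mechanism.ENHANCER_HIJACK_CANDIDATE
        assert out.hijack_target == "MECOM"

    def test_breakpoint_beyond_window_is_other(self, cfg, oncogenes):
        chrom, start, _ = gene_regions()["MECOM"]
        out = classify_sv_mechanism(_sv(chrom, start - 600_000, "chr2", 45_000_000), oncogenes, cfg)
        assert out.mechanism is Mechanism.OTHER

    def test_breakpoint_inside_coding_span_is_not_a_hijack(self, cfg, oncogenes):
        chrom, start, end = gene_regions()["MECOM"]
        out = classify_sv_mechanism(_sv(chrom, (start + end) // 2, "chr2", 45_000_000), oncogenes, cfg)
        assert out.mechanism is Mechanism.OTHER

    def test_in_frame_wins_regardless_of_window(self, oncogenes):
        # even with a huge window, an exon junction means chimeric fusion
        wide = RuleConfig(enhancer_window_bp=50_000_000)
        chrom, start, _ = gene_regions()["MECOM"]
        sv = _sv(chrom, start - 10_000, "chr2", 45_000_000, frame=Frame.IN_FRAME, junction=(3, 2))
        assert classify_sv_mechanism(sv, {"MECOM": gene_regions()["MECOM"]}, wide).mechanism is Mechanism.IN_FRAME_FUSION

    def test_empty_gene_model_is_an_error(self, cfg):
        with pytest.raises(ValueError, match="gene model"):
            classify_sv_mechanism(_sv("chr1", 1, "chr2", 2), {}, cfg)


# ---------------------------------------------------------------------------
# Indel normalization
# ---------------------------------------------------------------------------


class TestNormalizeVariant:
    def test_minimal_representation_trims_shared_bases(self):
        # CTG->CTGTG insertion written with redundant context
        assert normalize_variant(100, "CTG", "CTGTG") == (100, "C", "CTG")

    def test_left_alignment_through_repeat_tract(self):
        # reference ...A C T G T G T G A...: a TG deletion anywhere in the
        # repeat left-aligns to the same spelling
        seq = "ACTGTGTGA"  # 1-based; TG-repeat spans positions 3-8
        fetch = lambda pos: seq[pos - 1]  # noqa: E731
        spelled_right = normalize_variant(6, "GTG", "G", sequence=fetch)  # del bases 7-8
        spelled_mid = normalize_variant(3, "TGT", "T", sequence=fetch)  # del bases 4-5
        assert spelled_right == spelled_mid == (2, "CTG", "C")

    def test_snv_passthrough(self):
        assert normalize_variant(50, "A", "G") == (50, "A", "G")

    def test_empty_allele_rejected(self):
        with pytest.raises(ValueError):
            normalize_variant(10, "", "A")
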