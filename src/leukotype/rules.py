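"""Reportability and event-calling rules for integrated WGS+WTS evidence.

This module implements the clinical decision logic applied to each raw
call set before classification:

* somatic SNV/indel reportability — WGS VAF floor with a transcriptome
  "rescue" branch for AML drivers highly expressed in RNA;
* germline panel filtering (P/LP in a configured predisposition list);
* CNV scale classes (focal < 5 Mb, large-scale >= 5 Mb, cnLOH >= 10 Mb)
  with a sub-50 kb intragenic-review flag;
* FLT3-ITD evidence combination across WGS and WTS;
* KMT2A partial tandem duplication calling from an intragenic gain plus
  an in-frame exon 7/8 -> exon 2/3/4 chimeric junction;
* structural-variant mechanism assignment (chimeric in-frame fusion
  oncogene vs. enhancer-hijack candidate vs. other).

All decisions return :class:`~leukotype.models.ReportDecision` objects
carrying short rationale codes so downstream reports can be audited.
"""

from __future__ import annotations

from typing import Callable, Iterable, Mapping, Optional

from .models import (
    INSUFFICIENT,
    Breakpoint,
    CNVKind,
    CNVSegment,
    EventClass,
    Frame,
    ITDEvidence,
    ITDStrength,
    Mechanism,
    Origin,
    Platform,
    ReportDecision,
    ReportStatus,
    RuleConfig,
    ScaleClass,
    StructuralEvent,
    VariantCall,
)

# Rationale codes
VAF_PASS = "VAF_PASS"
WTS_RESCUE = "WTS_RESCUE"
VAF_BELOW = "VAF_BELOW"
NOT_SOMATIC = "NOT_SOMATIC"
NOT_PLP = "NOT_PLP"
ITD_BOTH_STRONG = "ITD_BOTH_STRONG"
ITD_WGS_STRONG = "ITD_WGS_STRONG"
ITD_WTS_ONLY = "ITD_WTS_ONLY"
ITD_WEAK_BOTH = "ITD_WEAK_BOTH"
ITD_NO_EVIDENCE = "ITD_NO_EVIDENCE"
PTD_JUNCTION_SUPPORTED = "PTD_JUNCTION_SUPPORTED"
PTD_NO_JUNCTION = "PTD_NO_JUNCTION"
SUB50KB_REVIEW = "SUB50KB_INTRAGENIC_REVIEW"

# KMT2A-PTD chimeric junction pattern: a duplicated 3' exon spliced back
# upstream of an early 5' exon.
PTD_DONOR_EXONS = frozenset({7, 8})
PTD_ACCEPTOR_EXONS = frozenset({2, 3, 4})


# ---------------------------------------------------------------------------
# Indel normalization
# ---------------------------------------------------------------------------


def normalize_variant(
    pos: int,
    ref: str,
    alt: str,
    sequence: Optional[Callable[[int], str]] = None,
) -> tuple[int, str, str]:
    """Reduce a variant to its minimal, left-most representation.

    Trailing then leading shared bases are trimmed (minimal form); when
    ``sequence`` — a callable returning the reference base at a 1-based
    position — is supplied, pure insertions/deletions are additionally
    shifted left through repeat tracts (left alignment). Complex indels
    written against different anchors otherwise defeat exact-key
    matching between call sets.
    """
    if not ref or not alt:
        raise ValueError("ref and alt must be non-empty allele strings")
    ref, alt = ref.upper(), alt.upper()

    # trim shared suffix; when an allele empties, extend both to the left
    # from the reference (this is what shifts indels through repeats)
    while ref[-1] == alt[-1] and not (len(ref) == 1 and len(alt) == 1):
        if (len(ref) == 1 or len(alt) == 1) and (sequence is None or pos <= 1):
            break
        ref, alt = ref[:-1], alt[:-1]
        if not ref or not alt:
            prev = sequence(pos - 1).upper()  # type: ignore[misc]
            ref, alt, pos = prev + ref, prev + alt, pos - 1

    # trim shared prefix
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1

    return pos, ref, alt


# ---------------------------------------------------------------------------
# SNV/indel reportability
# ---------------------------------------------------------------------------


def assess_snv_reportability(v: VariantCall, cfg: RuleConfig) -> ReportDecision:
    """Decide whether a somatic small variant is valid for reporting.

    Reportable iff the variant is somatic P/LP and either (a) its WGS
    VAF meets the floor (default >= 5%), or (b) it is an annotated AML
    driver whose WTS VAF strictly exceeds the rescue threshold (default
    25%) — the transcriptome rescue branch for subclonal drivers with
    high allele-specific expression. WES evidence never rescues.
    """
    if v.pathogenicity is None:
        raise ValueError(f"variant {v.gene} {v.chrom}:{v.pos} has no pathogenicity call")
    if v.origin is not Origin.SOMATIC:
        return ReportDecision(status=ReportStatus.NOT_REPORTABLE, rationale_codes=[NOT_SOMATIC])
    if not v.pathogenicity.is_plp:
        return ReportDecision(status=ReportStatus.NOT_REPORTABLE, rationale_codes=[NOT_PLP])

    wgs_vaf = v.vaf(Platform.WGS)
    if wgs_vaf is not None and wgs_vaf != INSUFFICIENT and float(wgs_vaf) >= cfg.wgs_vaf_min:
        return ReportDecision(status=ReportStatus.REPORTABLE, rationale_codes=[VAF_PASS])

    wts_vaf = v.vaf(Platform.WTS)
    if (
        v.is_aml_driver
        and wts_vaf is not None
        and wts_vaf != INSUFFICIENT
        and float(wts_vaf) > cfg.wts_rescue_vaf
    ):
        return ReportDecision(status=ReportStatus.REPORTABLE, rationale_codes=[WTS_RESCUE])

    return ReportDecision(status=ReportStatus.NOT_REPORTABLE, rationale_codes=[VAF_BELOW])


def filter_germline_findings(
    variants: Iterable[VariantCall], cfg: RuleConfig
) -> list[VariantCall]:
    """Keep germline P/LP variants in the configured predisposition panel.

    The panel content (genes predisposing to cancer and/or bone-marrow
    failure) is site-specific configuration, so an empty gene list is a
    configuration error rather than "report nothing".
    """
    if not cfg.germline_gene_list:
        raise ValueError("germline_gene_list is empty; configure the predisposition panel")
    return [
        v
        for v in variants
        if v.origin is Origin.GERMLINE
        and v.pathogenicity is not None
        and v.pathogenicity.is_plp
        and v.gene in cfg.germline_gene_list
    ]


# ---------------------------------------------------------------------------
# CNV scale classes
# ---------------------------------------------------------------------------


def classify_cnv_event(seg: CNVSegment, cfg: RuleConfig) -> CNVSegment:
    """Assign a scale class to a copy-number / cnLOH segment.

    Gains and losses split at the focal/large-scale boundary (strictly
    below 5 Mb is focal); cnLOH only counts once it reaches 10 Mb.
    Focal events under 50 kb get an extra review flag: they are
    typically intragenic/exonic and warrant exon-level inspection.
    """
    if seg.size_bp <= 0:
        raise ValueError(f"segment has non-positive size: {seg.start}-{seg.end}")
    flags = list(seg.flags)
    if seg.kind is CNVKind.CNLOH:
        scale = (
            ScaleClass.LARGE_SCALE
            if seg.size_bp >= cfg.cnloh_min_bp
            else ScaleClass.SUB_THRESHOLD
        )
    else:
        if seg.size_bp < cfg.focal_cnv_max_bp:
            scale = ScaleClass.FOCAL
            if seg.size_bp < cfg.sub50kb_bp and SUB50KB_REVIEW not in flags:
                flags.append(SUB50KB_REVIEW)
        else:
            scale = ScaleClass.LARGE_SCALE
    return seg.model_copy(update={"scale_class": scale, "flags": flags})


# ---------------------------------------------------------------------------
# FLT3-ITD evidence combination
# ---------------------------------------------------------------------------

_S = ITDStrength


def combine_itd_evidence(e: ITDEvidence) -> ReportDecision:
    """Combine WGS and WTS internal-tandem-duplication evidence.

    Decision table (total over the 4x4 strength grid):

    * strong WGS  -> reportable, whatever WTS shows (including
      insufficient RNA coverage over the duplicated exons);
    * strong WTS with weak/no/insufficient WGS -> borderline — real ITDs
      surface this way when the DNA evidence is thin, but orthogonal
      confirmation (PCR fragment analysis) is required;
    * weak on both platforms -> borderline for the same reason;
    * anything else (at most one weak signal) -> not reportable by
      sequencing. A PCR-only subclonal ITD lands here.
    """
    wgs, wts = e.wgs_strength, e.wts_strength
    if wgs is _S.STRONG:
        code = ITD_BOTH_STRONG if wts is _S.STRONG else ITD_WGS_STRONG
        return ReportDecision(status=ReportStatus.REPORTABLE, rationale_codes=[code])
    if wts is _S.STRONG:
        return ReportDecision(status=ReportStatus.BORDERLINE, rationale_codes=[ITD_WTS_ONLY])
    if wgs is _S.WEAK and wts is _S.WEAK:
        return ReportDecision(status=ReportStatus.BORDERLINE, rationale_codes=[ITD_WEAK_BOTH])
    return ReportDecision(status=ReportStatus.NOT_REPORTABLE, rationale_codes=[ITD_NO_EVIDENCE])


# ---------------------------------------------------------------------------
# KMT2A-PTD
# ---------------------------------------------------------------------------


def _is_ptd_junction(sv: StructuralEvent, gene: str) -> bool:
    if sv.gene_a != gene or sv.gene_b != gene:
        return False
    if sv.frame is not Frame.IN_FRAME or sv.exon_junction is None:
        return False
    donor, acceptor = sv.exon_junction
    return donor in PTD_DONOR_EXONS and acceptor in PTD_ACCEPTOR_EXONS


def call_kmt2a_ptd(
    segs: Iterable[CNVSegment],
    junctions: Iterable[StructuralEvent],
    cfg: RuleConfig,
    gene: str = "KMT2A",
) -> list[tuple[StructuralEvent, ReportDecision]]:
    """Call partial tandem duplications from DNA gains + RNA junctions.

    A PTD is emitted for each sub-50 kb intragenic gain in ``gene``.
    When an in-frame chimeric junction splicing a duplicated exon 7/8
    back upstream of exon 2/3/4 corroborates it, the call is reportable;
    a gain without junction support is emitted as borderline — RNA
    coverage over the duplication may simply be insufficient.

    Junctions lacking exon annotation cannot be evaluated and are
    skipped.
    """
    usable = [
        j
        for j in junctions
        if j.exon_junction is not None or not (j.gene_a == gene and j.gene_b == gene)
    ]
    out: list[tuple[StructuralEvent, ReportDecision]] = []
    for seg in segs:
        if seg.gene != gene or seg.kind is not CNVKind.GAIN:
            continue
        if seg.size_bp >= cfg.sub50kb_bp:
            continue
        supported = [j for j in usable if j.case_id == seg.case_id and _is_ptd_junction(j, gene)]
        if supported:
            template = supported[0]
            event = template.model_copy(update={"event_class": EventClass.PTD})
            decision = ReportDecision(
                status=ReportStatus.REPORTABLE, rationale_codes=[PTD_JUNCTION_SUPPORTED]
            )
        else:
            event = StructuralEvent(
                case_id=seg.case_id,
                breakpoint_a=Breakpoint(chrom=seg.chrom, pos=seg.start),
                breakpoint_b=Breakpoint(chrom=seg.chrom, pos=seg.end),
                gene_a=gene,
                gene_b=gene,
                event_class=EventClass.PTD,
                frame=Frame.UNKNOWN,
            )
            decision = ReportDecision(
                status=ReportStatus.BORDERLINE, rationale_codes=[PTD_NO_JUNCTION]
            )
        out.append((event, decision))
    return out


# ---------------------------------------------------------------------------
# SV mechanism classification
# ---------------------------------------------------------------------------


def _near_but_outside(
    bp_chrom: str, bp_pos: int, region: tuple[str, int, int], window: int
) -> bool:
    chrom, start, end = region
    if bp_chrom != chrom:
        return False
    if start <= bp_pos <= end:
        return False
    return (start - window) <= bp_pos <= (end + window)


def classify_sv_mechanism(
    sv: StructuralEvent,
    oncogene_regions: Mapping[str, tuple[str, int, int]],
    cfg: RuleConfig,
) -> StructuralEvent:
    """Infer how a rearrangement acts: chimeric fusion vs enhancer hijack.

    An in-frame exon-exon junction always means a fusion oncogene. A
    breakpoint landing *outside* an oncogene's coding span but within
    the configured window of it (default 500 kb per side), with the
    partner breakpoint bringing in foreign sequence, marks an
    enhancer-hijack candidate — the rearrangement is predicted to
    activate the intact oncogene rather than produce a chimeric
    protein. Candidates must later be confirmed or refuted against
    expression data.
    """
    if not oncogene_regions:
        raise ValueError("oncogene_regions is empty: gene model required")

    if sv.frame is Frame.IN_FRAME and sv.exon_junction is not None:
        return sv.model_copy(update={"mechanism": Mechanism.IN_FRAME_FUSION})

    window = cfg.enhancer_window_bp
    # when several oncogenes qualify (clustered loci), attribute the
    # candidate to the nearest one
    best: Optional[tuple[int, str]] = None
    for target, region in oncogene_regions.items():
        for near_bp, far_bp in (
            (sv.breakpoint_a, sv.breakpoint_b),
            (sv.breakpoint_b, sv.breakpoint_a),
        ):
            if not _near_but_outside(near_bp.chrom, near_bp.pos, region, window):
                continue
            chrom, start, end = region
            # the partner side must be foreign: other chromosome, or well
            # outside the oncogene neighbourhood on the same one
            foreign = far_bp.chrom != chrom or not (
                (start - window) <= far_bp.pos <= (end + window)
            )
            if not foreign:
                continue
            distance = min(abs(near_bp.pos - start), abs(near_bp.pos - end))
            if best is None or (distance, target) < best:
                best = (distance, target)
    if best is not None:
        return sv.model_copy(
            update={
                "mechanism": Mechanism.ENHANCER_HIJACK_CANDIDATE,
                "hijack_target": best[1],
            }
        )
    return sv.model_copy(update={"mechanism": Mechanism.OTHER})
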