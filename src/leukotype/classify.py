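"""Molecular subtype assignment for pediatric AML.

Each case's evidence bundle is reduced to a single
:class:`~leukotype.models.MolecularSubtype` through a fixed-priority
tier hierarchy:

1. Down-syndrome AML (pathogenic GATA1 variant in a DS patient);
2. AML class-defining gene fusions / rearrangements (WHO), including
   *confirmed* enhancer hijacks of WHO-listed oncogenes;
3. AML class-defining gene mutations (NPM1, bZIP CEBPA, biallelic TP53);
4. newly proposed / recently recognized class-defining lesions;
5. myelodysplasia-related AML (AML-MR) — qualifying gene mutations or
   cytogenetic lesions in the absence of any tier 1-4 driver;
6. rare or novel in-frame fusions;
7. not otherwise specified (NOS) — no defining lesion.

The first matching tier wins; remaining reportable drivers are recorded
as secondary (cooperating) lesions. Within a tier, ties break by the
order of the pattern list, then alphabetically by 5' partner, so the
outcome is deterministic. Pattern content lives in an editable YAML
data file (``leukotype/data/classification_rules.yaml``), so newly
recognized markers are adopted by a data update, not a code change.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import yaml
from pydantic import BaseModel, Field

from . import genome
from .expression import (
    OverexpressionCall,
    build_reference,
    overexpression_call,
    validate_enhancer_hijack,
)
from .models import (
    CaseProfile,
    CNVKind,
    CNVSegment,
    CytoLesion,
    EventClass,
    Frame,
    HijackValidation,
    ITDEvidence,
    KaryotypeRecord,
    LesionKind,
    Mechanism,
    MolecularSubtype,
    Origin,
    ReportDecision,
    ReportPhase,
    ReportStatus,
    RuleConfig,
    ScaleClass,
    StructuralEvent,
    SubtypeCategory,
    VariantCall,
)
from .rules import (
    assess_snv_reportability,
    call_kmt2a_ptd,
    classify_cnv_event,
    classify_sv_mechanism,
    combine_itd_evidence,
)


class ClassificationRules(BaseModel):
    """Pattern sets defining the classification tiers (see module docs)."""

    version: int = 1
    who_fusions: list[str] = Field(default_factory=list)
    who_mutations: list[str] = Field(default_factory=list)
    proposed_class_fusions: list[str] = Field(default_factory=list)
    proposed_class_mutations: list[str] = Field(default_factory=list)
    aml_mr_genes: list[str] = Field(default_factory=list)
    aml_mr_cyto: list[str] = Field(default_factory=list)


def load_classification_rules(path: Union[str, Path, None] = None) -> ClassificationRules:
    """Load tier patterns from YAML; defaults to the packaged rule file."""
    if path is None:
        text = resources.files("leukotype.data").joinpath("classification_rules.yaml").read_text()
    else:
        text = Path(path).read_text()
    return ClassificationRules.model_validate(yaml.safe_load(text))


# ---------------------------------------------------------------------------
# Pattern matching
# ---------------------------------------------------------------------------


def _fusion_pattern_index(
    patterns: Sequence[str], sv: StructuralEvent, validation: Optional[HijackValidation]
) -> Optional[int]:
    """Index of the first pattern the event matches, else None.

    Enhancer-hijack candidates match only ``GENE-r`` patterns for their
    predicted target, and only when not refuted by expression.
    """
    if sv.mechanism is Mechanism.ENHANCER_HIJACK_CANDIDATE:
        if validation is HijackValidation.REFUTED:
            return None
        target = sv.hijack_target
        for i, p in enumerate(patterns):
            if p.endswith("-r") and p[:-2] == target:
                return i
        return None
    name_a, name_b = sv.gene_a, sv.gene_b
    for i, p in enumerate(patterns):
        if p.endswith("-r"):
            if p[:-2] in (name_a, name_b):
                return i
        elif "::" in p:
            left, right = p.split("::", 1)
            ok_left = left == "*" or left == name_a
            ok_right = right == "*" or right == name_b
            if ok_left and ok_right:
                return i
    return None


def _driver_eligible(sv: StructuralEvent, validation: Optional[HijackValidation]) -> bool:
    if sv.event_class not in (EventClass.FUSION, EventClass.OTHER_SV):
        return False
    if sv.mechanism is Mechanism.IN_FRAME_FUSION:
        return True
    if sv.mechanism is Mechanism.ENHANCER_HIJACK_CANDIDATE:
        return validation is not HijackValidation.REFUTED
    return False


def _sv_label(sv: StructuralEvent, validation: Optional[HijackValidation]) -> str:
    if sv.mechanism is Mechanism.ENHANCER_HIJACK_CANDIDATE:
        suffix = " (confirmed)" if validation is HijackValidation.CONFIRMED else ""
        return f"{sv.hijack_target}-r enhancer hijack{suffix}"
    return sv.fusion_name()


# ---------------------------------------------------------------------------
# Karyotype / AML-MR evaluation
# ---------------------------------------------------------------------------


def is_complex_karyotype(k: Optional[KaryotypeRecord], cfg: RuleConfig) -> bool:
    """>= 3 distinct clonal abnormalities (standard complex-karyotype rule)."""
    if k is None:
        return False
    return k.n_abnormalities >= cfg.complex_karyotype_min


_MR_ARM_PATTERNS = {
    ("5", "q"): "5q-",
    ("7", "q"): "mono7/7q-",
    ("11", "q"): "11q-",
    ("12", "p"): "12p-",
    ("17", "p"): "17p-",
}


def _chrom_num(chrom: str) -> str:
    return chrom[3:] if chrom.startswith("chr") else chrom


def _lesion_mr_pattern(lesion: CytoLesion) -> Optional[str]:
    num = _chrom_num(lesion.chrom)
    if lesion.kind is LesionKind.MONOSOMY and num == "7":
        return "mono7/7q-"
    if lesion.kind is LesionKind.DELETION and lesion.arm_or_band:
        return _MR_ARM_PATTERNS.get((num, lesion.arm_or_band[0]))
    if lesion.kind is LesionKind.ISOCHROMOSOME and num == "17" and lesion.arm_or_band.startswith("q"):
        return "i(17q)"
    return None


def _cnv_mr_pattern(seg: CNVSegment) -> Optional[str]:
    if seg.kind is not CNVKind.LOSS or seg.scale_class is not ScaleClass.LARGE_SCALE:
        return None
    num = _chrom_num(seg.chrom)
    if num == "7" and genome.is_whole_chromosome(seg.chrom, seg.start, seg.end):
        return "mono7/7q-"
    arm = seg.arm or genome.arm_of(seg.chrom, seg.start, seg.end)
    if arm is None:
        return None
    for a in ("p", "q"):
        if a in arm and (num, a) in _MR_ARM_PATTERNS:
            return _MR_ARM_PATTERNS[(num, a)]
    return None


def evaluate_aml_mr(
    lesions: Iterable[CytoLesion],
    cnvs: Iterable[CNVSegment],
    muts: Iterable[VariantCall],
    rules: ClassificationRules,
    cfg: RuleConfig,
) -> tuple[bool, list[str]]:
    """Does the case carry myelodysplasia-related defining evidence?

    Cytogenetic lesions and large-scale WGS losses are mapped onto the
    arm-level lesion patterns (5q-, -7/7q-, 11q-, 12p-, 17p-, i(17q));
    a karyotype with >= ``complex_karyotype_min`` clonal abnormalities
    matches ``complex``; mutations match the MR gene list. Returns the
    flag and the matched evidence descriptors.
    """
    allowed = set(rules.aml_mr_cyto)
    matched: list[str] = []

    clonal = [l for l in lesions if l.clonal]
    for lesion in clonal:
        pat = _lesion_mr_pattern(lesion)
        if pat is not None and pat in allowed and f"cyto:{pat}" not in matched:
            matched.append(f"cyto:{pat}")
    if "complex" in allowed and len(clonal) >= cfg.complex_karyotype_min:
        matched.append("cyto:complex")

    for seg in cnvs:
        pat = _cnv_mr_pattern(seg)
        if pat is not None and pat in allowed and f"cnv:{pat}" not in matched:
            matched.append(f"cnv:{pat}")

    mr_genes = set(rules.aml_mr_genes)
    for v in muts:
        if (
            v.origin is Origin.SOMATIC
            and v.pathogenicity is not None
            and v.pathogenicity.is_plp
            and v.gene in mr_genes
        ):
            matched.append(f"mut:{v.gene}")

    return (bool(matched), matched)


# ---------------------------------------------------------------------------
# Evidence orchestration
# ---------------------------------------------------------------------------


@dataclass
class CaseEvidence:
    """Pre-computed rule outcomes for one case, consumed by classify_case."""

    variant_decisions: list[tuple[VariantCall, ReportDecision]] = field(default_factory=list)
    svs: list[StructuralEvent] = field(default_factory=list)
    hijack_validation: dict[int, HijackValidation] = field(default_factory=dict)
    hijack_calls: dict[int, OverexpressionCall] = field(default_factory=dict)
    itd_decisions: list[tuple[ITDEvidence, ReportDecision]] = field(default_factory=list)
    ptd_calls: list[tuple[StructuralEvent, ReportDecision]] = field(default_factory=list)
    cnvs: list[CNVSegment] = field(default_factory=list)

    def reportable_variants(self) -> list[VariantCall]:
        return [v for v, d in self.variant_decisions if d.status is ReportStatus.REPORTABLE]


def evaluate_case(
    profile: CaseProfile,
    cfg: Optional[RuleConfig] = None,
    oncogene_regions: Optional[dict[str, tuple[str, int, int]]] = None,
    reference_profiles: Sequence = (),
    all_svs: Iterable[StructuralEvent] = (),
) -> CaseEvidence:
    """Run every evidence rule for one case.

    ``reference_profiles`` (expression profiles of other cases) enables
    enhancer-hijack validation; without them candidates stay unvalidated
    and remain classification-eligible on DNA evidence alone.
    ``all_svs`` lets the expression reference exclude rearranged cases.
    """
    cfg = cfg or RuleConfig()
    regions = oncogene_regions if oncogene_regions is not None else genome.gene_regions()
    ev = CaseEvidence()

    for v in profile.variants:
        if v.origin is Origin.SOMATIC:
            ev.variant_decisions.append((v, assess_snv_reportability(v, cfg)))

    ev.cnvs = [classify_cnv_event(seg, cfg) for seg in profile.cnvs]

    for sv in profile.svs:
        if sv.event_class is EventClass.ITD:
            continue
        ev.svs.append(classify_sv_mechanism(sv, regions, cfg))

    if reference_profiles and profile.expression is not None:
        for i, sv in enumerate(ev.svs):
            if sv.mechanism is not Mechanism.ENHANCER_HIJACK_CANDIDATE:
                continue
            gene = sv.hijack_target
            reference = build_reference(gene, reference_profiles, all_svs)
            reference = [p for p in reference if p.case_id != profile.case_id and p.get(gene) is not None]
            if not reference or profile.expression.get(gene) is None:
                continue
            call = overexpression_call(gene, profile.expression, reference, cfg)
            ev.hijack_calls[i] = call
            ev.hijack_validation[i] = validate_enhancer_hijack(sv, call)

    ev.itd_decisions = [(e, combine_itd_evidence(e)) for e in profile.itds]
    ev.ptd_calls = call_kmt2a_ptd(ev.cnvs, ev.svs, cfg)
    return ev


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def _match_mutation_pattern(pattern: str, variants: list[VariantCall], evidence: CaseEvidence) -> Optional[str]:
    """Match one who/proposed mutation pattern against reportable variants.

    ``GENE`` or ``GENE-qualifier`` patterns match on the gene symbol;
    ``TP53-biallelic`` additionally demands a second hit: another TP53
    variant, a large-scale 17p loss, or cnLOH over 17p.
    """
    gene = pattern.split("-", 1)[0]
    hits = [v for v in variants if v.gene == gene]
    if not hits:
        return None
    if pattern == "TP53-biallelic":
        if len(hits) >= 2:
            return "TP53 biallelic (two variants)"
        second = _has_17p_second_hit(evidence.cnvs)
        return f"TP53 biallelic (variant + {second})" if second else None
    return f"{gene} mutation"


def _has_17p_second_hit(cnvs: Iterable[CNVSegment]) -> Optional[str]:
    tp53_chrom, tp53_start, tp53_end = genome.gene_regions()["TP53"]
    for seg in cnvs:
        if genome.normalize_chrom(seg.chrom) != tp53_chrom:
            continue
        overlaps_tp53 = seg.start <= tp53_end and seg.end >= tp53_start
        arm = seg.arm or genome.arm_of(seg.chrom, seg.start, seg.end)
        on_17p = overlaps_tp53 or (arm is not None and "p" in arm)
        if not on_17p:
            continue
        if seg.kind is CNVKind.LOSS and seg.scale_class in (ScaleClass.LARGE_SCALE, ScaleClass.FOCAL):
            return "17p loss"
        if seg.kind is CNVKind.CNLOH and overlaps_tp53:
            return "17p cnLOH"
    return None


def _best_fusion(
    patterns: Sequence[str], evidence: CaseEvidence
) -> Optional[tuple[int, StructuralEvent]]:
    """Lowest (pattern index, 5' partner) eligible fusion, or None."""
    best: Optional[tuple[tuple[int, str, str], int, StructuralEvent]] = None
    for i, sv in enumerate(evidence.svs):
        validation = evidence.hijack_validation.get(i)
        if not _driver_eligible(sv, validation):
            continue
        idx = _fusion_pattern_index(patterns, sv, validation)
        if idx is None:
            continue
        key = (idx, sv.gene_a, sv.gene_b)
        if best is None or key < best[0]:
            best = (key, i, sv)
    if best is None:
        return None
    return best[1], best[2]


def classify_case(
    profile: CaseProfile,
    rules: ClassificationRules,
    evidence: CaseEvidence,
    cfg: Optional[RuleConfig] = None,
) -> MolecularSubtype:
    """Assign the molecular subtype (see module docstring for the tiers).

    Deterministic and total: every case maps to exactly one category,
    and ``category == NOS`` iff no defining lesion was found.
    """
    cfg = cfg or RuleConfig()
    reportable = evidence.reportable_variants()
    defining: Optional[str] = None
    category: Optional[SubtypeCategory] = None
    defining_sv_index: Optional[int] = None

    # Tier 1: Down-syndrome AML
    if profile.down_syndrome:
        gata1 = [v for v in reportable if v.gene == "GATA1"]
        if gata1:
            category, defining = SubtypeCategory.DS_AML, "GATA1 mutation"

    # Tier 2: WHO class-defining fusion / rearrangement
    if category is None:
        hit = _best_fusion(rules.who_fusions, evidence)
        if hit is not None:
            defining_sv_index, sv = hit
            category = SubtypeCategory.WHO_FUSION
            defining = _sv_label(sv, evidence.hijack_validation.get(defining_sv_index))

    # Tier 3: WHO class-defining mutation
    if category is None:
        for pattern in rules.who_mutations:
            label = _match_mutation_pattern(pattern, reportable, evidence)
            if label is not None:
                category, defining = SubtypeCategory.WHO_MUTATION, label
                break

    # Tier 4: proposed class-defining lesion (fusion patterns, then mutations)
    if category is None:
        hit = _best_fusion(rules.proposed_class_fusions, evidence)
        if hit is not None:
            defining_sv_index, sv = hit
            category = SubtypeCategory.PROPOSED_CLASS
            defining = _sv_label(sv, evidence.hijack_validation.get(defining_sv_index))
        else:
            for pattern in rules.proposed_class_mutations:
                label = _match_mutation_pattern(pattern, reportable, evidence)
                if label is not None:
                    category, defining = SubtypeCategory.PROPOSED_CLASS, label
                    break

    # Tier 5: AML-MR in the absence of any other known or potential
    # driver — a driver-eligible fusion of any rarity pre-empts it
    if category is None:
        any_driver_sv = any(
            _driver_eligible(sv, evidence.hijack_validation.get(i))
            for i, sv in enumerate(evidence.svs)
        )
        if not any_driver_sv:
            lesions = profile.karyotype.lesions if profile.karyotype else []
            mr_flag, mr_matched = evaluate_aml_mr(lesions, evidence.cnvs, reportable, rules, cfg)
            if mr_flag:
                category, defining = SubtypeCategory.AML_MR, mr_matched[0]

    # Tier 6: rare / novel in-frame fusion
    if category is None:
        candidates = []
        for i, sv in enumerate(evidence.svs):
            validation = evidence.hijack_validation.get(i)
            if _driver_eligible(sv, validation):
                candidates.append((sv.gene_a, sv.gene_b, i, sv))
        if candidates:
            candidates.sort(key=lambda t: (t[0], t[1]))
            _, _, defining_sv_index, sv = candidates[0]
            category = SubtypeCategory.RARE_NOVEL_FUSION
            defining = _sv_label(sv, evidence.hijack_validation.get(defining_sv_index))

    if category is None:
        category = SubtypeCategory.NOS

    # Secondary (cooperating) drivers: everything reportable that did not define
    secondary: list[str] = []
    for i, sv in enumerate(evidence.svs):
        if i == defining_sv_index:
            continue
        validation = evidence.hijack_validation.get(i)
        if _driver_eligible(sv, validation):
            secondary.append(_sv_label(sv, validation))
    for e, d in evidence.itd_decisions:
        if d.status is ReportStatus.REPORTABLE:
            secondary.append(f"{e.gene}-ITD")
    for ptd, d in evidence.ptd_calls:
        if d.status is ReportStatus.REPORTABLE:
            secondary.append(f"{ptd.gene_a}-PTD")
    for v in reportable:
        label = f"{v.gene} mutation"
        if defining is not None and defining.startswith(v.gene):
            continue
        if v.is_aml_driver and label not in secondary:
            secondary.append(label)

    phase = _phase_for_category(category)
    return MolecularSubtype(
        case_id=profile.case_id,
        category=category,
        defining_lesion=defining,
        secondary_drivers=secondary,
        report_phase=phase,
    )


def _phase_for_category(category: SubtypeCategory) -> Optional[ReportPhase]:
    if category in (
        SubtypeCategory.WHO_FUSION,
        SubtypeCategory.WHO_MUTATION,
        SubtypeCategory.PROPOSED_CLASS,
        SubtypeCategory.DS_AML,
        SubtypeCategory.AML_MR,
    ):
        return ReportPhase.PHASE1_DAY7
    if category is SubtypeCategory.RARE_NOVEL_FUSION:
        return ReportPhase.PHASE2_DAY14
    return None


# Findings eligible for phased reporting, by kind.
_PHASE_BY_FINDING = {
    "who_fusion": ReportPhase.PHASE1_DAY7,
    "proposed_fusion": ReportPhase.PHASE1_DAY7,
    "driver_mutation": ReportPhase.PHASE1_DAY7,
    "ls_cnv": ReportPhase.PHASE1_DAY7,
    "rare_novel_fusion": ReportPhase.PHASE2_DAY14,
    "cooperating_variant": ReportPhase.PHASE2_DAY14,
    "focal_cnv": ReportPhase.PHASE2_DAY14,
    "itd": ReportPhase.PHASE2_DAY14,
    "germline": ReportPhase.PHASE3_DAY21,
}


def assign_report_phase(finding_kind: str) -> ReportPhase:
    """Phase under the three-stage reporting workflow.

    Class-defining drivers and large-scale CNVs go out in the rapid
    tumor report (day 7); rare/novel fusions and cooperating somatic
    variants follow in the integrated report (day 14); germline
    findings wait for the paired tumor-normal report (day 21).
    """
    try:
        return _PHASE_BY_FINDING[finding_kind]
    except KeyError:
        raise ValueError(
            f"unknown finding kind {finding_kind!r}; expected one of "
            f"{sorted(_PHASE_BY_FINDING)}"
        ) from None
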