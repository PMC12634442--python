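"""Domain model for integrated WGS+WTS (iWGS-WTS) leukemia genomics.

The types here are shared by every stage of the pipeline: evidence
reportability rules, expression integration, molecular classification,
cross-platform concordance and the cohort simulator.

Conventions
-----------
* Variant allele fractions (VAFs) are fractions in ``[0, 1]`` everywhere
  inside the package; percentages appear only at I/O boundaries.
* Genomic coordinates are 1-based inclusive (VCF/SEG convention); BEDPE
  input is converted from 0-based half-open on read.
* A platform that *lacked sufficient evidence* is recorded as the string
  ``"insufficient"`` — deliberately distinct from a VAF of ``0.0``, which
  means the platform looked and saw nothing.

Models are intentionally permissive at construction time: domain
invariants are checked by :func:`validate_case_profile`, which reports
violations as data rather than raising, so that malformed clinical input
can be linted and triaged instead of aborting a run.
"""

from __future__ import annotations

import enum
from typing import Literal, Optional, Union

from pydantic import BaseModel, ConfigDict, Field

INSUFFICIENT = "insufficient"

VafValue = Union[float, Literal["insufficient"]]


class _Model(BaseModel):
    model_config = ConfigDict(validate_assignment=False, extra="forbid")


# ---------------------------------------------------------------------------
# Enumerations
# ---------------------------------------------------------------------------


class Origin(str, enum.Enum):
    SOMATIC = "somatic"
    GERMLINE = "germline"


class Pathogenicity(str, enum.Enum):
    P = "P"
    LP = "LP"
    VUS = "VUS"
    B_LB = "B/LB"

    @property
    def is_plp(self) -> bool:
        return self in (Pathogenicity.P, Pathogenicity.LP)


class Platform(str, enum.Enum):
    CYTOGENETICS = "cytogenetics"
    FISH = "fish"
    PANEL = "panel"
    WGS = "wgs"
    WES = "wes"
    WTS = "wts"


class Frame(str, enum.Enum):
    IN_FRAME = "in_frame"
    OUT_OF_FRAME = "out_of_frame"
    NON_CODING = "non_coding"
    UNKNOWN = "unknown"


class EventClass(str, enum.Enum):
    FUSION = "fusion"
    ITD = "itd"
    PTD = "ptd"
    OTHER_SV = "other_sv"


class Mechanism(str, enum.Enum):
    IN_FRAME_FUSION = "in_frame_fusion"
    ENHANCER_HIJACK_CANDIDATE = "enhancer_hijack_candidate"
    OTHER = "other"


class FusionCategory(str, enum.Enum):
    WHO_DEFINING = "who_defining"
    PROPOSED_CLASS_DEFINING = "proposed_class_defining"
    RARE_NOVEL = "rare_novel"
    NON_DRIVER = "non_driver"


class ITDStrength(str, enum.Enum):
    STRONG = "strong"
    WEAK = "weak"
    NONE = "none"
    INSUFFICIENT_COVERAGE = "insufficient_coverage"


class CNVKind(str, enum.Enum):
    GAIN = "gain"
    LOSS = "loss"
    CNLOH = "cnloh"


class ScaleClass(str, enum.Enum):
    FOCAL = "focal"
    LARGE_SCALE = "large_scale"
    SUB_THRESHOLD = "sub_threshold"


class LesionKind(str, enum.Enum):
    MONOSOMY = "monosomy"
    TRISOMY = "trisomy"
    DELETION = "deletion"
    ADDITION = "addition"
    TRANSLOCATION = "translocation"
    ISOCHROMOSOME = "isochromosome"
    MARKER = "marker"
    OTHER = "other"


class DiseaseContext(str, enum.Enum):
    DE_NOVO = "de_novo"
    POST_CYTOTOXIC = "post_cytotoxic"
    RELAPSE = "relapse"


class ReportStatus(str, enum.Enum):
    REPORTABLE = "reportable"
    BORDERLINE = "borderline"
    NOT_REPORTABLE = "not_reportable"


class SubtypeCategory(str, enum.Enum):
    WHO_FUSION = "who_fusion"
    WHO_MUTATION = "who_mutation"
    PROPOSED_CLASS = "proposed_class"
    AML_MR = "aml_mr"
    DS_AML = "ds_aml"
    RARE_NOVEL_FUSION = "rare_novel_fusion"
    NOS = "nos"


class ReportPhase(str, enum.Enum):
    PHASE1_DAY7 = "phase1_day7"
    PHASE2_DAY14 = "phase2_day14"
    PHASE3_DAY21 = "phase3_day21"


class HijackValidation(str, enum.Enum):
    CONFIRMED = "confirmed"
    REFUTED = "refuted"


class ASECall(str, enum.Enum):
    MUTANT_ASE = "mutant_ase"
    BALANCED = "balanced"
    WILDTYPE_ASE = "wildtype_ase"


# ---------------------------------------------------------------------------
# Evidence records
# ---------------------------------------------------------------------------


class VariantCall(_Model):
    """One small variant (SNV/indel) with per-platform VAF evidence."""

    case_id: str
    gene: str
    chrom: str
    pos: int
    ref: str
    alt: str
    origin: Origin
    pathogenicity: Optional[Pathogenicity] = None
    is_aml_driver: bool = False
    vaf_by_platform: dict[Platform, VafValue] = Field(default_factory=dict)

    def vaf(self, platform: Platform) -> Optional[VafValue]:
        return self.vaf_by_platform.get(platform)

    def key(self) -> tuple[str, str, int, str, str]:
        """Identity key used for cross-platform matching."""
        return (self.case_id, self.chrom, self.pos, self.ref, self.alt)


class Breakpoint(_Model):
    chrom: str
    pos: int
    strand: Literal["+", "-"] = "+"

    def sort_key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


class StructuralEvent(_Model):
    """A breakpoint pair: fusion, ITD/PTD, or other structural variant.

    ``mechanism`` and ``hijack_target`` are assigned by the evidence rules,
    not by the caller that parsed the event.
    """

    case_id: str
    breakpoint_a: Breakpoint
    breakpoint_b: Breakpoint
    gene_a: str = "intergenic"
    gene_b: str = "intergenic"
    exon_junction: Optional[tuple[int, int]] = None
    frame: Frame = Frame.UNKNOWN
    event_class: EventClass = EventClass.FUSION
    mechanism: Optional[Mechanism] = None
    fusion_category: Optional[FusionCategory] = None
    hijack_target: Optional[str] = None

    def canonical(self) -> "StructuralEvent":
        """Return the event with breakpoints in lexicographic order.

        Only the breakpoint pair is reordered; ``gene_a``/``gene_b``
        keep the biological 5'/3' fusion orientation.
        """
        if self.breakpoint_a.sort_key() <= self.breakpoint_b.sort_key():
            return self
        return self.model_copy(
            update={
                "breakpoint_a": self.breakpoint_b,
                "breakpoint_b": self.breakpoint_a,
            }
        )

    @property
    def partners(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)

    def fusion_name(self) -> str:
        return f"{self.gene_a}::{self.gene_b}"


class ITDEvidence(_Model):
    """Internal tandem duplication evidence observed on two platforms.

    ``pcr_ratio`` carries the orthogonal PCR fragment-analysis ratio of
    ITD to wild-type allele, when available.
    """

    case_id: str
    gene: str = "FLT3"
    wgs_strength: ITDStrength
    wts_strength: ITDStrength
    pcr_ratio: Optional[float] = None


class CNVSegment(_Model):
    """Copy-number or copy-neutral LOH segment (1-based inclusive)."""

    case_id: str
    chrom: str
    start: int
    end: int
    kind: CNVKind
    clone_fraction: float = 1.0
    gene: Optional[str] = None
    arm: Optional[str] = None
    scale_class: Optional[ScaleClass] = None
    sv_supported: bool = False
    flags: list[str] = Field(default_factory=list)

    @property
    def size_bp(self) -> int:
        return self.end - self.start + 1


class CytoLesion(_Model):
    kind: LesionKind
    chrom: str = ""
    arm_or_band: str = ""
    partner_chrom: Optional[str] = None
    partner_band: Optional[str] = None
    size_mb: Optional[float] = None
    clonal: bool = True
    raw: str = ""


class KaryotypeRecord(_Model):
    iscn: str
    lesions: list[CytoLesion] = Field(default_factory=list)
    metaphases_total: Optional[int] = None
    metaphases_abnormal: Optional[int] = None

    @property
    def n_abnormalities(self) -> int:
        return sum(1 for lesion in self.lesions if lesion.clonal)


class ExpressionProfile(_Model):
    """Normalized gene abundances (non-negative, linear scale) for one case."""

    case_id: str
    values: dict[str, float] = Field(default_factory=dict)
    cohort_id: str = "default"

    def get(self, gene: str) -> Optional[float]:
        return self.values.get(gene)


class CaseProfile(_Model):
    """Per-case evidence bundle: the unit the classifier consumes."""

    case_id: str
    sex: Literal["M", "F", "U"] = "U"
    age_years: Optional[float] = None
    disease_context: DiseaseContext = DiseaseContext.DE_NOVO
    down_syndrome: bool = False
    blast_percent: Optional[float] = None
    variants: list[VariantCall] = Field(default_factory=list)
    svs: list[StructuralEvent] = Field(default_factory=list)
    itds: list[ITDEvidence] = Field(default_factory=list)
    cnvs: list[CNVSegment] = Field(default_factory=list)
    karyotype: Optional[KaryotypeRecord] = None
    expression: Optional[ExpressionProfile] = None


# ---------------------------------------------------------------------------
# Rule configuration and decisions
# ---------------------------------------------------------------------------


class RuleConfig(_Model):
    """Thresholds governing reportability and event calling.

    Defaults encode the clinical rule set: WGS VAF >= 5% for somatic
    P/LP reporting, WTS rescue of AML drivers at VAF strictly > 25%,
    focal vs large-scale CNV split at 5 Mb, cnLOH floor at 10 Mb,
    sub-50 kb intragenic review flag, a 500 kb enhancer-hijack search
    window per side, ~9 Mb G-band visibility at 400-band resolution and
    a 30-40% clone-fraction floor for karyotype/WGS subclonal detection.
    """

    wgs_vaf_min: float = 0.05
    wts_rescue_vaf: float = 0.25  # strict >
    focal_cnv_max_bp: int = 5_000_000  # strict <
    ls_cnv_min_bp: int = 5_000_000
    cnloh_min_bp: int = 10_000_000
    sub50kb_bp: int = 50_000
    enhancer_window_bp: int = 500_000
    cyto_visible_min_bp: int = 9_000_000
    subclonal_cnv_min_fraction: float = 0.35
    complex_karyotype_min: int = 3
    overexpression_z: float = 2.0
    ase_skew_threshold: float = 0.30
    germline_gene_list: frozenset[str] = frozenset()


class ReportDecision(_Model):
    status: ReportStatus
    rationale_codes: list[str] = Field(default_factory=list)

    @property
    def is_reportable(self) -> bool:
        return self.status == ReportStatus.REPORTABLE


class MolecularSubtype(_Model):
    case_id: str
    category: SubtypeCategory
    defining_lesion: Optional[str] = None
    secondary_drivers: list[str] = Field(default_factory=list)
    report_phase: Optional[ReportPhase] = None


# ---------------------------------------------------------------------------
# Platform sensitivity + concordance containers
# ---------------------------------------------------------------------------


class PlatformModel(_Model):
    """Sensitivity parameters governing what a simulated platform observes."""

    platform: Platform
    min_cnv_bp: int = 0
    min_clone_fraction: float = 0.0
    vaf_floor: float = 0.0
    cryptic_miss_prob: dict[str, float] = Field(default_factory=dict)
    purity: float = 1.0
    read_depth: int = 60


class ConcordanceStats(_Model):
    r: float
    slope: float
    intercept: float = 0.0
    n_pairs: int


class ConcordanceRow(_Model):
    category: str
    both: int
    only_a: int
    only_b: int = 0

    @property
    def total(self) -> int:
        # Table-1 convention: total counts truth events (both + missed-by-B);
        # events seen only by B are listed but not part of the total.
        return self.both + self.only_a

    @property
    def pct_missed_b(self) -> float:
        return 100.0 * self.only_a / self.total if self.total else 0.0


class ConcordanceTable(_Model):
    rows: list[ConcordanceRow] = Field(default_factory=list)

    def total_row(self) -> ConcordanceRow:
        return ConcordanceRow(
            category="Total",
            both=sum(r.both for r in self.rows),
            only_a=sum(r.only_a for r in self.rows),
            only_b=sum(r.only_b for r in self.rows),
        )

    def row(self, category: str) -> ConcordanceRow:
        for r in self.rows:
            if r.category == category:
                return r
        raise KeyError(category)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


def _check_vafs(v: VariantCall, where: str, out: list[str]) -> None:
    if not v.vaf_by_platform:
        out.append(f"{where}.vaf_by_platform: at least one platform must have evidence")
    for platform, vaf in v.vaf_by_platform.items():
        if vaf == INSUFFICIENT:
            continue
        if not (0.0 <= float(vaf) <= 1.0):
            out.append(
                f"{where}.vaf_by_platform[{platform.value}]: VAF {vaf} outside [0, 1]"
            )


def validate_case_profile(profile: CaseProfile) -> list[str]:
    """Check every domain invariant of a case bundle.

    Returns an empty list iff the profile is internally consistent; each
    violation is a human-readable descriptor naming the field and the
    rule it breaks. Violations are data, not exceptions, so a whole
    cohort can be linted in one pass.
    """
    out: list[str] = []
    if profile.blast_percent is not None and not (0.0 <= profile.blast_percent <= 100.0):
        out.append(f"blast_percent: {profile.blast_percent} outside [0, 100]")

    for i, v in enumerate(profile.variants):
        where = f"variants[{i}]"
        if v.pos < 1:
            out.append(f"{where}.pos: {v.pos} < 1 (coordinates are 1-based)")
        if v.ref == v.alt:
            out.append(f"{where}: ref == alt ({v.ref!r})")
        _check_vafs(v, where, out)

    for i, sv in enumerate(profile.svs):
        where = f"svs[{i}]"
        if sv.breakpoint_a.sort_key() > sv.breakpoint_b.sort_key():
            out.append(f"{where}: breakpoints not in canonical lexicographic order")
        if sv.event_class in (EventClass.ITD, EventClass.PTD) and sv.gene_a != sv.gene_b:
            out.append(
                f"{where}: {sv.event_class.value} event must be intragenic "
                f"(gene_a={sv.gene_a!r} != gene_b={sv.gene_b!r})"
            )
        for bp_name, bp in (("breakpoint_a", sv.breakpoint_a), ("breakpoint_b", sv.breakpoint_b)):
            if bp.pos < 1:
                out.append(f"{where}.{bp_name}.pos: {bp.pos} < 1")

    for i, seg in enumerate(profile.cnvs):
        where = f"cnvs[{i}]"
        if seg.end < seg.start:
            out.append(f"{where}: end {seg.end} < start {seg.start}")
        if not (0.0 <= seg.clone_fraction <= 1.0):
            out.append(f"{where}.clone_fraction: {seg.clone_fraction} outside [0, 1]")
        if seg.start < 1:
            out.append(f"{where}.start: {seg.start} < 1")

    if profile.karyotype is not None:
        k = profile.karyotype
        if (
            k.metaphases_total is not None
            and k.metaphases_abnormal is not None
            and k.metaphases_abnormal > k.metaphases_total
        ):
            out.append(
                "karyotype: metaphases_abnormal "
                f"{k.metaphases_abnormal} > metaphases_total {k.metaphases_total}"
            )

    if profile.expression is not None:
        for gene, value in profile.expression.values.items():
            if value < 0:
                out.append(f"expression.values[{gene}]: {value} < 0")

    return out
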