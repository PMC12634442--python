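"""Seedable synthetic cohort generator with per-platform observation models.

The generator emits *truth* case bundles whose statistical structure
matches the study conditions the pipeline assumes — a ~150-case
pediatric AML cohort with the published subtype frequencies, blast
counts centred near the published median, per-subtype defining lesions,
and cooperating lesions at the published rates — and then degrades the
truth through platform sensitivity models:

* **cytogenetics** sees copy-number changes only at band resolution
  (>= ~9 Mb) and adequate clone fraction, and misses each fusion type
  with its published cryptic-miss probability;
* **WGS** applies a VAF floor with binomial read-sampling jitter at the
  configured depth, and loses subclonal CNVs once
  ``clone_fraction x purity`` drops below the detectability floor;
* **WTS** sees chimeric fusion transcripts (with a small miss rate) but
  never enhancer-hijack rearrangements, which leave no fusion
  transcript.

Identical ``(config, seed)`` pairs produce identical cohorts.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .fixtures import (
    _PROPOSED_MIX,
    _RARE_NOVEL_MIX,
    _WHO_FUSION_MIX,
    FUSION_DETECTION_ROWS,
    _fusion_event,
    _hijack_event,
    _monosomy7_karyotype,
    _stub_variant,
)
from .genome import chromosome_table, gene_regions
from .models import (
    Breakpoint,
    CaseProfile,
    CNVKind,
    CNVSegment,
    EventClass,
    ExpressionProfile,
    Frame,
    ITDEvidence,
    ITDStrength,
    Mechanism,
    Platform,
    PlatformModel,
    StructuralEvent,
    SubtypeCategory,
    VariantCall,
)

_HIJACK_GENES = ("MECOM", "HOXA13", "HOXA10", "BCL11B", "TLX3", "NKX2-5")
_EXPR_BASELINE = {"MECOM": 4.0, "HOXA13": 2.0, "HOXA10": 3.0, "BCL11B": 6.0, "TLX3": 1.0, "NKX2-5": 1.0}
# chromosomes safe for cooperating losses: none of their arms define AML-MR
_SAFE_LOSS_CHROMS = ("chr3", "chr9", "chr13", "chr14", "chr16", "chr18", "chr20")
_COOPERATING_GENES = ("KIT", "FLT3", "CBL")


def default_cryptic_miss_prob() -> dict[str, float]:
    """Per-fusion cytogenetic miss probabilities from the published
    detection table (missed-only / total truth events)."""
    out: dict[str, float] = {}
    for name, both, only in FUSION_DETECTION_ROWS:
        out[name] = only / (both + only)
    return out


def default_platform_models() -> dict[Platform, PlatformModel]:
    miss = default_cryptic_miss_prob()
    wts_miss = {name: 0.02 for name in miss}
    wts_miss["MECOM-r"] = 1.0  # enhancer hijacks leave no fusion transcript
    return {
        Platform.CYTOGENETICS: PlatformModel(
            platform=Platform.CYTOGENETICS,
            min_cnv_bp=9_000_000,
            min_clone_fraction=0.35,
            cryptic_miss_prob=miss,
        ),
        Platform.WGS: PlatformModel(
            platform=Platform.WGS,
            min_cnv_bp=0,
            min_clone_fraction=0.35,
            vaf_floor=0.05,
            read_depth=60,
        ),
        Platform.WTS: PlatformModel(
            platform=Platform.WTS,
            vaf_floor=0.05,
            read_depth=60,
            cryptic_miss_prob=wts_miss,
        ),
    }


def _default_weights() -> dict[str, float]:
    # published subtype breakdown of the 153-case cohort
    counts = {
        "who_fusion": 86,
        "who_mutation": 26,
        "proposed_class": 21,
        "aml_mr": 5,
        "rare_novel_fusion": 6,
        "nos": 4,
        "ds_aml": 5,
    }
    total = sum(counts.values())
    return {k: v / total for k, v in counts.items()}


class CohortConfig(BaseModel):
    """Study conditions for the simulator (defaults follow the cohort
    the analysis was designed around)."""

    model_config = ConfigDict(extra="forbid")

    n_cases: int = 153
    subtype_weights: dict[str, float] = Field(default_factory=_default_weights)
    seed: int = 0
    blast_mean: float = 63.0
    blast_sd: float = 20.0
    blast_range: tuple[float, float] = (5.0, 96.0)
    driver_vaf_range: tuple[float, float] = (0.20, 0.50)
    itd_case_rate: float = 18 / 153
    cooperating_variant_rate: float = 0.6
    lscnv_case_rate: float = 83 / 153
    expression_log_sd: float = 0.5
    hijack_shift_sd: float = 4.0  # target oncogene shift, in log-scale SDs
    read_depth: int = 60


def _check_weights(weights: dict[str, float]) -> None:
    total = sum(weights.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"subtype weights sum to {total}, expected 1.0")
    if any(not (0.0 <= w <= 1.0) for w in weights.values()):
        raise ValueError("subtype weights must lie in [0, 1]")


def _pick(rng: np.random.Generator, mix: Sequence[tuple[str, int]]) -> str:
    names = [m[0] for m in mix]
    weights = np.array([m[1] for m in mix], dtype=float)
    return names[rng.choice(len(names), p=weights / weights.sum())]


def _expression(rng: np.random.Generator, cfg: CohortConfig, shifted: Optional[str], case_id: str) -> ExpressionProfile:
    values = {}
    for g in _HIJACK_GENES:
        mu = np.log(_EXPR_BASELINE[g])
        if g == shifted:
            mu += cfg.hijack_shift_sd * cfg.expression_log_sd
        values[g] = float(np.exp(rng.normal(mu, cfg.expression_log_sd)))
    return ExpressionProfile(case_id=case_id, values=values)


def _random_vaf(rng: np.random.Generator, cfg: CohortConfig) -> float:
    lo, hi = cfg.driver_vaf_range
    # 4-decimal precision matches the bundle writers, so truth cohorts
    # round-trip through files byte-exactly
    return round(float(rng.uniform(lo, hi)), 4)


def _random_lscnv(rng: np.random.Generator, case_id: str) -> CNVSegment:
    gain = rng.random() < 0.6
    chroms = list(chromosome_table()) if gain else list(_SAFE_LOSS_CHROMS)
    chrom = chroms[rng.integers(len(chroms))]
    length = chromosome_table()[chrom]["length"]
    size = int(rng.uniform(5_000_000, min(80_000_000, length * 0.6)))
    start = int(rng.integers(1, max(2, length - size)))
    return CNVSegment(
        case_id=case_id,
        chrom=chrom,
        start=start,
        end=start + size - 1,
        kind=CNVKind.GAIN if gain else CNVKind.LOSS,
        clone_fraction=float(rng.uniform(0.25, 1.0)),
        sv_supported=bool(rng.random() < 0.5),
    )


def _truth_case(rng: np.random.Generator, cfg: CohortConfig, case_id: str, subtype: str) -> CaseProfile:
    svs: list[StructuralEvent] = []
    variants: list[VariantCall] = []
    cnvs: list[CNVSegment] = []
    itds: list[ITDEvidence] = []
    karyotype = None
    down_syndrome = False
    hijack_target: Optional[str] = None

    if subtype == "who_fusion":
        name = _pick(rng, _WHO_FUSION_MIX)
        if name == "MECOM-hijack":
            svs.append(_hijack_event(case_id, "MECOM", int(rng.integers(-300_000, 150_000)) or -3_800, "chr3", 128_482_000))
            hijack_target = "MECOM"
        elif name == "KMT2A::SEPT6":
            chrom, start, _ = gene_regions()["KMT2A"]
            svs.append(
                StructuralEvent(
                    case_id=case_id,
                    breakpoint_a=Breakpoint(chrom=chrom, pos=start + 20_000),
                    breakpoint_b=Breakpoint(chrom="chrX", pos=119_743_000),
                    gene_a="KMT2A",
                    gene_b="SEPT6",
                    exon_junction=(9, 2),
                    frame=Frame.IN_FRAME,
                ).canonical()
            )
        else:
            svs.append(_fusion_event(case_id, name))
    elif subtype == "who_mutation":
        gene = ("NPM1", "CEBPA", "TP53")[rng.integers(3)]
        variants.append(_stub_variant(case_id, gene, vaf=_random_vaf(rng, cfg)))
        if gene == "TP53":
            variants.append(_stub_variant(case_id, gene, pos_shift=150, vaf=_random_vaf(rng, cfg)))
    elif subtype == "proposed_class":
        svs.append(_fusion_event(case_id, _pick(rng, _PROPOSED_MIX)))
    elif subtype == "aml_mr":
        if rng.random() < 0.5:
            karyotype = _monosomy7_karyotype()
        else:
            cnvs.append(
                CNVSegment(
                    case_id=case_id, chrom="chr7", start=62_000_000, end=110_000_000,
                    kind=CNVKind.LOSS, clone_fraction=float(rng.uniform(0.5, 1.0)),
                )
            )
    elif subtype == "rare_novel_fusion":
        svs.append(_fusion_event(case_id, _pick(rng, _RARE_NOVEL_MIX)))
    elif subtype == "ds_aml":
        down_syndrome = True
        variants.append(_stub_variant(case_id, "GATA1", vaf=_random_vaf(rng, cfg)))
    elif subtype == "nos":
        pass
    else:
        raise ValueError(f"unknown subtype {subtype!r}")

    if rng.random() < cfg.itd_case_rate:
        strata = [
            (15, ITDStrength.STRONG, ITDStrength.STRONG),
            (2, ITDStrength.STRONG, ITDStrength.INSUFFICIENT_COVERAGE),
            (10, ITDStrength.WEAK, ITDStrength.STRONG),
            (1, ITDStrength.WEAK, ITDStrength.WEAK),
        ]
        weights = np.array([s[0] for s in strata], dtype=float)
        _, wgs_s, wts_s = strata[rng.choice(len(strata), p=weights / weights.sum())]
        itds.append(ITDEvidence(case_id=case_id, gene="FLT3", wgs_strength=wgs_s, wts_strength=wts_s))
    if rng.random() < cfg.cooperating_variant_rate:
        gene = _COOPERATING_GENES[rng.integers(len(_COOPERATING_GENES))]
        variants.append(_stub_variant(case_id, gene, pos_shift=int(rng.integers(1000, 5000)), vaf=_random_vaf(rng, cfg)))
    if rng.random() < cfg.lscnv_case_rate:
        for _ in range(1 + rng.poisson(1.0)):
            cnvs.append(_random_lscnv(rng, case_id))

    blast = float(np.clip(rng.normal(cfg.blast_mean, cfg.blast_sd), *cfg.blast_range))
    return CaseProfile(
        case_id=case_id,
        sex="F" if rng.random() < 0.5 else "M",
        age_years=float(np.clip(rng.normal(11.0, 5.0), 0.1, 22.0)),
        down_syndrome=down_syndrome,
        blast_percent=round(blast, 1),
        variants=variants,
        svs=svs,
        itds=itds,
        cnvs=cnvs,
        karyotype=karyotype,
        expression=_expression(rng, cfg, hijack_target, case_id),
    )


def generate_cohort(cfg: CohortConfig) -> list[CaseProfile]:
    """Draw a truth cohort: reproducible for a given (config, seed)."""
    _check_weights(cfg.subtype_weights)
    rng = np.random.default_rng(cfg.seed)
    names = sorted(cfg.subtype_weights)
    probs = np.array([cfg.subtype_weights[n] for n in names])
    cases = []
    for i in range(cfg.n_cases):
        subtype = names[rng.choice(len(names), p=probs)]
        cases.append(_truth_case(rng, cfg, f"SIM{i + 1:04d}", subtype))
    return cases


# ---------------------------------------------------------------------------
# Platform observation
# ---------------------------------------------------------------------------


def _fusion_key(sv: StructuralEvent) -> str:
    if sv.mechanism is Mechanism.ENHANCER_HIJACK_CANDIDATE or (
        sv.gene_a == "intergenic" and sv.gene_b == "intergenic"
    ):
        return "MECOM-r"  # hijack events are keyed as rearrangements
    return sv.fusion_name()


def observe_with_platform(
    truth: CaseProfile, model: PlatformModel, seed: int
) -> CaseProfile:
    """Degrade a truth bundle into what one platform would report.

    Sequencing platforms re-observe each variant's VAF as a binomial
    draw at the configured depth over ``true VAF x purity`` and drop
    variants whose underlying VAF sits below the floor. CNVs are
    dropped below the platform's size or clone-fraction floors (scaled
    by purity for sequencing). Fusions are dropped with the platform's
    per-type cryptic-miss probability.
    """
    rng = np.random.default_rng(seed)
    is_sequencing = model.platform in (Platform.WGS, Platform.WES, Platform.WTS, Platform.PANEL)

    variants: list[VariantCall] = []
    if is_sequencing:
        for v in truth.variants:
            base = v.vaf(Platform.WGS)
            if base is None or base == "insufficient":
                continue
            underlying = float(base) * model.purity
            if underlying < model.vaf_floor:
                continue
            depth = max(1, model.read_depth)
            observed = round(float(rng.binomial(depth, min(underlying, 1.0)) / depth), 4)
            variants.append(v.model_copy(update={"vaf_by_platform": {model.platform: observed}}))

    cnvs: list[CNVSegment] = []
    for seg in truth.cnvs:
        if seg.size_bp < model.min_cnv_bp:
            continue
        effective = seg.clone_fraction * (model.purity if is_sequencing else 1.0)
        if effective < model.min_clone_fraction:
            continue
        cnvs.append(seg)

    svs: list[StructuralEvent] = []
    for sv in truth.svs:
        miss = model.cryptic_miss_prob.get(_fusion_key(sv), 0.0)
        if rng.random() >= miss:
            svs.append(sv)

    return truth.model_copy(
        update={"variants": variants, "cnvs": cnvs, "svs": svs, "expression": None, "karyotype": None}
    )


def dilution_series(
    truth_cnvs: Iterable[CNVSegment],
    purities: Sequence[float],
    model: PlatformModel,
    seed: int = 0,
) -> dict[float, float]:
    """Detected fraction of large-scale CNVs at each tumor purity.

    Emulates a cell-line dilution experiment: at purity ``p`` a segment
    is detected iff ``clone_fraction x p`` clears the platform's
    clone-fraction floor. Detection is therefore monotone nonincreasing
    as purity falls.
    """
    segs = list(truth_cnvs)
    if not segs:
        raise ValueError("empty truth CNV set")
    out: dict[float, float] = {}
    for p in purities:
        if not (0.0 < p <= 1.0):
            raise ValueError(f"purity {p} outside (0, 1]")
        detected = sum(1 for s in segs if s.clone_fraction * p >= model.min_clone_fraction)
        out[p] = detected / len(segs)
    return out
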