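"""Case-bundle I/O: VCF / BEDPE / SEG / expression TSV + JSON manifest.

A case bundle is a JSON manifest referencing one file per evidence
stream, plus inline fields for evidence without a standard text format
(ITD calls, the ISCN karyotype string). The simulator writes the same
formats this module reads, so generated cohorts feed the pipeline
unmodified and round-trip exactly.

Format conventions
------------------
* **VCF** (small variants): one file per case; platforms are VCF
  samples; per-sample FORMAT ``AF`` carries the VAF (4-decimal
  precision) and FORMAT ``NS=1`` marks *insufficient evidence*, which
  is distinct from an absent sample entry (platform not assayed) and
  from ``AF=0``. INFO carries gene, origin, pathogenicity and driver
  annotations. Multi-allelic records are split on read and alleles are
  reduced to minimal representation.
* **BEDPE** (structural events): 0-based half-open breakpoint
  intervals, converted to 1-based internal positions on read; extra
  columns carry partner genes, exon junction, frame and event class.
* **SEG-style TSV** (CNV/cnLOH): headered, 1-based inclusive segments
  with copy-state kind and clone fraction.
* **Expression TSV**: one row per gene; one column per case.

Readers reject malformed coordinates with errors naming the file, line
and rule rather than silently coercing.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
from cyvcf2 import VCF
from pydantic import BaseModel, Field

from .iscn import parse_iscn
from .models import (
    Breakpoint,
    CaseProfile,
    CNVKind,
    CNVSegment,
    DiseaseContext,
    EventClass,
    ExpressionProfile,
    Frame,
    FusionCategory,
    ITDEvidence,
    Mechanism,
    Origin,
    Pathogenicity,
    Platform,
    ScaleClass,
    StructuralEvent,
    VariantCall,
)
from .rules import normalize_variant

VAF_DECIMALS = 4

_PLATFORM_ORDER = [
    Platform.WGS,
    Platform.WES,
    Platform.WTS,
    Platform.PANEL,
    Platform.CYTOGENETICS,
    Platform.FISH,
]

_BEDPE_COLUMNS = [
    "chrom1", "start1", "end1", "chrom2", "start2", "end2",
    "name", "score", "strand1", "strand2",
    "gene_a", "gene_b", "exon_a", "exon_b", "frame", "event_class",
    "mechanism", "hijack_target", "fusion_category",
]

_SEG_COLUMNS = [
    "ID", "chrom", "loc.start", "loc.end", "kind",
    "clone_fraction", "gene", "arm", "sv_supported", "scale_class", "flags",
]


class BundleFormatError(ValueError):
    """Raised when a bundle file violates its format contract."""


class CaseBundleManifest(BaseModel):
    """JSON manifest tying one case's evidence files together."""

    case_id: str
    sex: str = "U"
    age_years: Optional[float] = None
    disease_context: DiseaseContext = DiseaseContext.DE_NOVO
    down_syndrome: bool = False
    blast_percent: Optional[float] = None
    variants_vcf: Optional[str] = None
    svs_bedpe: Optional[str] = None
    cnvs_seg: Optional[str] = None
    expression_tsv: Optional[str] = None
    karyotype_iscn: Optional[str] = None
    itds: list[ITDEvidence] = Field(default_factory=list)


def _fmt_opt(value) -> str:
    return "." if value is None else str(value)


def _parse_opt(token: str) -> Optional[str]:
    return None if token in (".", "", "nan") else token


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def write_vcf(variants: Sequence[VariantCall], path: Union[str, Path]) -> None:
    """Write one case's small variants as an uncompressed VCF."""
    path = Path(path)
    platforms = [
        p for p in _PLATFORM_ORDER if any(p in v.vaf_by_platform for v in variants)
    ] or [Platform.WGS]
    chroms = sorted({v.chrom for v in variants})
    lines = [
        "##fileformat=VCFv4.2",
        "##source=leukotype",
        *[f"##contig=<ID={c}>" for c in chroms],
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=ORIGIN,Number=1,Type=String,Description="somatic or germline">',
        '##INFO=<ID=PATHO,Number=1,Type=String,Description="Pathogenicity tier">',
        '##INFO=<ID=DRIVER,Number=0,Type=Flag,Description="Annotated AML driver">',
        '##FORMAT=<ID=AF,Number=1,Type=Float,Description="Variant allele fraction">',
        '##FORMAT=<ID=NS,Number=1,Type=Integer,Description="1 if evidence insufficient">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(p.value.upper() for p in platforms),
    ]
    for v in variants:  # input order preserved for exact round-trips
        info = [f"GENE={v.gene}", f"ORIGIN={v.origin.value}"]
        if v.pathogenicity is not None:
            info.append(f"PATHO={v.pathogenicity.value}")
        if v.is_aml_driver:
            info.append("DRIVER")
        entries = []
        for p in platforms:
            vaf = v.vaf_by_platform.get(p)
            if vaf is None:
                entries.append(".:.")
            elif vaf == "insufficient":
                entries.append(".:1")
            else:
                entries.append(f"{float(vaf):.{VAF_DECIMALS}f}:0")
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\t.\t"
            + ";".join(info)
            + "\tAF:NS\t"
            + "\t".join(entries)
        )
    path.write_text("\n".join(lines) + "\n")


def read_vcf(path: Union[str, Path], case_id: str) -> list[VariantCall]:
    """Read a case VCF back into variant calls.

    Multi-allelic records are split (each allele inherits the record's
    per-sample VAFs) and alleles reduced to minimal representation.
    """
    path = Path(path)
    vcf = VCF(str(path))
    platforms = [Platform(s.lower()) for s in vcf.samples]
    out: list[VariantCall] = []
    def _fmt(rec, tag):
        try:
            return rec.format(tag)
        except KeyError:  # tag absent from header
            return None

    for rec in vcf:
        af = _fmt(rec, "AF")
        ns = _fmt(rec, "NS")
        ad = _fmt(rec, "AD")
        vafs: dict[Platform, Union[float, str]] = {}
        for i, p in enumerate(platforms):
            ns_i = int(ns[i][0]) if ns is not None else 0
            if ns_i == 1:
                vafs[p] = "insufficient"
                continue
            af_i = float(af[i][0]) if af is not None else math.nan
            if math.isnan(af_i) and ad is not None:
                # fall back to allelic depths: alt / (ref + alt)
                ref_d, alt_d = int(ad[i][0]), int(ad[i][1])
                if ref_d >= 0 and alt_d >= 0 and ref_d + alt_d > 0:
                    af_i = alt_d / (ref_d + alt_d)
            if not math.isnan(af_i):
                vafs[p] = round(af_i, VAF_DECIMALS)
        gene = rec.INFO.get("GENE") or "unknown"
        origin = Origin(rec.INFO.get("ORIGIN") or "somatic")
        patho = rec.INFO.get("PATHO")
        for alt in rec.ALT:
            pos, ref, alt_n = normalize_variant(rec.POS, rec.REF, alt)
            out.append(
                VariantCall(
                    case_id=case_id,
                    gene=gene,
                    chrom=rec.CHROM,
                    pos=pos,
                    ref=ref,
                    alt=alt_n,
                    origin=origin,
                    pathogenicity=Pathogenicity(patho) if patho else None,
                    is_aml_driver=rec.INFO.get("DRIVER") is not None,
                    vaf_by_platform=dict(vafs),
                )
            )
    vcf.close()
    return out


# ---------------------------------------------------------------------------
# BEDPE
# ---------------------------------------------------------------------------


def write_bedpe(events: Sequence[StructuralEvent], path: Union[str, Path]) -> None:
    path = Path(path)
    rows = ["#" + "\t".join(_BEDPE_COLUMNS)]
    for i, sv in enumerate(events):
        a, b = sv.breakpoint_a, sv.breakpoint_b
        exon_a, exon_b = sv.exon_junction if sv.exon_junction else (None, None)
        rows.append(
            "\t".join(
                str(x)
                for x in [
                    a.chrom, a.pos - 1, a.pos, b.chrom, b.pos - 1, b.pos,
                    f"{sv.case_id}_sv{i}", ".", a.strand, b.strand,
                    sv.gene_a, sv.gene_b, _fmt_opt(exon_a), _fmt_opt(exon_b),
                    sv.frame.value, sv.event_class.value,
                    _fmt_opt(sv.mechanism.value if sv.mechanism else None),
                    _fmt_opt(sv.hijack_target),
                    _fmt_opt(sv.fusion_category.value if sv.fusion_category else None),
                ]
            )
        )
    path.write_text("\n".join(rows) + "\n")


def read_bedpe(path: Union[str, Path], case_id: str) -> list[StructuralEvent]:
    path = Path(path)
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", names=_BEDPE_COLUMNS, dtype=str, header=None
        )
    except pd.errors.EmptyDataError:
        return []
    out: list[StructuralEvent] = []
    for idx, row in df.iterrows():
        line = idx + 2  # 1-based, after header
        try:
            s1, e1, s2, e2 = (int(row[k]) for k in ("start1", "end1", "start2", "end2"))
        except ValueError as exc:
            raise BundleFormatError(f"{path}:{line}: non-integer breakpoint coordinate") from exc
        for s, e, which in ((s1, e1, "1"), (s2, e2, "2")):
            if s < 0:
                raise BundleFormatError(f"{path}:{line}: start{which} {s} < 0 (BEDPE is 0-based)")
            if e < s:
                raise BundleFormatError(f"{path}:{line}: end{which} {e} < start{which} {s}")
        exon_a, exon_b = _parse_opt(row["exon_a"]), _parse_opt(row["exon_b"])
        out.append(
            StructuralEvent(
                case_id=case_id,
                breakpoint_a=Breakpoint(chrom=row["chrom1"], pos=s1 + 1, strand=row["strand1"]),
                breakpoint_b=Breakpoint(chrom=row["chrom2"], pos=s2 + 1, strand=row["strand2"]),
                gene_a=row["gene_a"],
                gene_b=row["gene_b"],
                exon_junction=(int(exon_a), int(exon_b)) if exon_a and exon_b else None,
                frame=Frame(row["frame"]),
                event_class=EventClass(row["event_class"]),
                mechanism=Mechanism(m) if (m := _parse_opt(row["mechanism"])) else None,
                hijack_target=_parse_opt(row["hijack_target"]),
                fusion_category=(
                    FusionCategory(f) if (f := _parse_opt(row["fusion_category"])) else None
                ),
            )
        )
    return out


# ---------------------------------------------------------------------------
# SEG
# ---------------------------------------------------------------------------


def write_seg(segments: Sequence[CNVSegment], path: Union[str, Path]) -> None:
    path = Path(path)
    rows = ["\t".join(_SEG_COLUMNS)]
    for seg in segments:
        rows.append(
            "\t".join(
                str(x)
                for x in [
                    seg.case_id, seg.chrom, seg.start, seg.end, seg.kind.value,
                    seg.clone_fraction, _fmt_opt(seg.gene), _fmt_opt(seg.arm),
                    int(seg.sv_supported),
                    _fmt_opt(seg.scale_class.value if seg.scale_class else None),
                    ",".join(seg.flags) if seg.flags else ".",
                ]
            )
        )
    path.write_text("\n".join(rows) + "\n")


def read_seg(path: Union[str, Path], case_id: Optional[str] = None) -> list[CNVSegment]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != _SEG_COLUMNS:
        raise BundleFormatError(f"{path}:1: unexpected SEG header {list(df.columns)}")
    out: list[CNVSegment] = []
    for idx, row in df.iterrows():
        line = idx + 2
        try:
            start, end = int(row["loc.start"]), int(row["loc.end"])
        except ValueError as exc:
            raise BundleFormatError(f"{path}:{line}: non-integer segment coordinate") from exc
        if start < 1:
            raise BundleFormatError(f"{path}:{line}: start {start} < 1 (SEG is 1-based)")
        if end < start:
            raise BundleFormatError(f"{path}:{line}: end {end} < start {start}")
        flags = _parse_opt(row["flags"])
        out.append(
            CNVSegment(
                case_id=case_id or row["ID"],
                chrom=row["chrom"],
                start=start,
                end=end,
                kind=CNVKind(row["kind"]),
                clone_fraction=float(row["clone_fraction"]),
                gene=_parse_opt(row["gene"]),
                arm=_parse_opt(row["arm"]),
                sv_supported=bool(int(row["sv_supported"])),
                scale_class=None,
                flags=flags.split(",") if flags else [],
            )
        )
        sc = _parse_opt(row["scale_class"])
        if sc:
            out[-1] = out[-1].model_copy(update={"scale_class": ScaleClass(sc)})
    return out


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def write_expression(profile: ExpressionProfile, path: Union[str, Path]) -> None:
    path = Path(path)
    lines = [f"gene\t{profile.case_id}"]
    for gene in sorted(profile.values):
        lines.append(f"{gene}\t{profile.values[gene]!r}")
    path.write_text("\n".join(lines) + "\n")


def read_expression(path: Union[str, Path]) -> ExpressionProfile:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    if df.columns[0] != "gene" or len(df.columns) != 2:
        raise BundleFormatError(f"{path}:1: expected columns 'gene\\t<case_id>'")
    case_id = df.columns[1]
    values = {str(g): float(v) for g, v in zip(df["gene"], df[case_id])}
    for gene, v in values.items():
        if v < 0:
            raise BundleFormatError(f"{path}: negative abundance for {gene}")
    return ExpressionProfile(case_id=case_id, values=values)


def write_expression_matrix(
    profiles: Sequence[ExpressionProfile], path: Union[str, Path]
) -> None:
    """Cohort-level matrix: one row per gene, one column per case."""
    genes = sorted({g for p in profiles for g in p.values})
    df = pd.DataFrame(
        {p.case_id: [p.values.get(g, 0.0) for g in genes] for p in profiles},
        index=pd.Index(genes, name="gene"),
    )
    df.to_csv(path, sep="\t")


def read_expression_matrix(path: Union[str, Path]) -> list[ExpressionProfile]:
    df = pd.read_csv(path, sep="\t", index_col="gene", float_precision="round_trip")
    return [
        ExpressionProfile(case_id=str(c), values={str(g): float(v) for g, v in df[c].items()})
        for c in df.columns
    ]


# ---------------------------------------------------------------------------
# Bundles
# ---------------------------------------------------------------------------


def write_case_bundle(profile: CaseProfile, outdir: Union[str, Path]) -> Path:
    """Write one case's evidence files + manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cid = profile.case_id
    manifest = CaseBundleManifest(
        case_id=cid,
        sex=profile.sex,
        age_years=profile.age_years,
        disease_context=profile.disease_context,
        down_syndrome=profile.down_syndrome,
        blast_percent=profile.blast_percent,
        karyotype_iscn=profile.karyotype.iscn if profile.karyotype else None,
        itds=profile.itds,
    )
    if profile.variants:
        manifest.variants_vcf = f"{cid}.vcf"
        write_vcf(profile.variants, outdir / manifest.variants_vcf)
    if profile.svs:
        manifest.svs_bedpe = f"{cid}.bedpe"
        write_bedpe(profile.svs, outdir / manifest.svs_bedpe)
    if profile.cnvs:
        manifest.cnvs_seg = f"{cid}.seg"
        write_seg(profile.cnvs, outdir / manifest.cnvs_seg)
    if profile.expression is not None:
        manifest.expression_tsv = f"{cid}.expr.tsv"
        write_expression(profile.expression, outdir / manifest.expression_tsv)
    manifest_path = outdir / f"{cid}.manifest.json"
    manifest_path.write_text(
        json.dumps(manifest.model_dump(mode="json"), indent=1, sort_keys=True) + "\n"
    )
    return manifest_path


def load_case_bundle(manifest_path: Union[str, Path]) -> CaseProfile:
    """Load and validate a case bundle from its manifest."""
    manifest_path = Path(manifest_path)
    manifest = CaseBundleManifest.model_validate_json(manifest_path.read_text())
    base = manifest_path.parent

    def _resolve(rel: Optional[str]) -> Optional[Path]:
        if rel is None:
            return None
        p = base / rel
        if not p.exists():
            raise BundleFormatError(f"{manifest_path}: referenced file missing: {rel}")
        return p

    vcf_path = _resolve(manifest.variants_vcf)
    bedpe_path = _resolve(manifest.svs_bedpe)
    seg_path = _resolve(manifest.cnvs_seg)
    expr_path = _resolve(manifest.expression_tsv)

    return CaseProfile(
        case_id=manifest.case_id,
        sex=manifest.sex,
        age_years=manifest.age_years,
        disease_context=manifest.disease_context,
        down_syndrome=manifest.down_syndrome,
        blast_percent=manifest.blast_percent,
        variants=read_vcf(vcf_path, manifest.case_id) if vcf_path else [],
        svs=read_bedpe(bedpe_path, manifest.case_id) if bedpe_path else [],
        itds=list(manifest.itds),
        cnvs=read_seg(seg_path, manifest.case_id) if seg_path else [],
        karyotype=parse_iscn(manifest.karyotype_iscn) if manifest.karyotype_iscn else None,
        expression=read_expression(expr_path) if expr_path else None,
    )


def write_cohort(cases: Sequence[CaseProfile], outdir: Union[str, Path]) -> Path:
    """Write a cohort of bundles plus a top-level index; returns its path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifests = [write_case_bundle(c, outdir).name for c in cases]
    index = outdir / "cohort.json"
    index.write_text(json.dumps({"cases": manifests}, indent=1, sort_keys=True) + "\n")
    return index


def load_cohort(index_path: Union[str, Path]) -> list[CaseProfile]:
    index_path = Path(index_path)
    index = json.loads(index_path.read_text())
    return [load_case_bundle(index_path.parent / m) for m in index["cases"]]
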