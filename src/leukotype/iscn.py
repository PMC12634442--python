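"""Parser for a working subset of ISCN karyotype nomenclature.

Clinical karyotype strings are heterogeneous; downstream comparison only
needs the lesion classes that define myelodysplasia-related AML and the
abnormality count, so this parser supports an explicit grammar subset:

* modal chromosome number and sex chromosomes (``46,XX``);
* numerical changes ``-7`` / ``+8``;
* ``del(7)(q22q36)``, ``add(12)(p13)``, ``t(5;14)(q35;q32)``,
  ``i(17)(q10)``, ``+mar`` / ``mar``;
* clones separated by ``/`` with metaphase counts in brackets, and
  ``idem``/``sl`` stemline references.

Anything else becomes a lesion of kind ``other`` with a logged warning
rather than a parse failure. The modal section must parse; a string
without a leading chromosome count is rejected.
"""

from __future__ import annotations

import logging
import re
from typing import Optional

from .models import CytoLesion, KaryotypeRecord, LesionKind

logger = logging.getLogger(__name__)

_COUNT_RE = re.compile(r"\[(\d+)\]\s*$")
_MODAL_RE = re.compile(r"^\d+(?:[~-]\d+)?$")
_SEX_RE = re.compile(r"^[XY]+$")
_NUMERICAL_RE = re.compile(r"^([+-])(\d+|X|Y)$")
_DEL_RE = re.compile(r"^del\((\d+|X|Y)\)\(([^)]+)\)$")
_ADD_RE = re.compile(r"^add\((\d+|X|Y)\)\(([^)]+)\)$")
_TRANS_RE = re.compile(r"^t\((\d+|X|Y);(\d+|X|Y)\)\(([^;)]+);([^)]+)\)$")
_ISO_RE = re.compile(r"^i\((\d+|X|Y)\)\(([^)]+)\)$")


def _parse_token(token: str) -> Optional[CytoLesion]:
    """One abnormality token -> lesion, or None for non-lesion tokens."""
    if _MODAL_RE.match(token) or _SEX_RE.match(token):
        return None
    m = _NUMERICAL_RE.match(token)
    if m:
        kind = LesionKind.MONOSOMY if m.group(1) == "-" else LesionKind.TRISOMY
        return CytoLesion(kind=kind, chrom=m.group(2), raw=token)
    m = _DEL_RE.match(token)
    if m:
        return CytoLesion(kind=LesionKind.DELETION, chrom=m.group(1), arm_or_band=m.group(2), raw=token)
    m = _ADD_RE.match(token)
    if m:
        return CytoLesion(kind=LesionKind.ADDITION, chrom=m.group(1), arm_or_band=m.group(2), raw=token)
    m = _TRANS_RE.match(token)
    if m:
        return CytoLesion(
            kind=LesionKind.TRANSLOCATION,
            chrom=m.group(1),
            arm_or_band=m.group(3),
            partner_chrom=m.group(2),
            partner_band=m.group(4),
            raw=token,
        )
    m = _ISO_RE.match(token)
    if m:
        return CytoLesion(kind=LesionKind.ISOCHROMOSOME, chrom=m.group(1), arm_or_band=m.group(2), raw=token)
    if token in ("mar", "+mar") or re.match(r"^\+?\d*mar$", token):
        return CytoLesion(kind=LesionKind.MARKER, raw=token)
    logger.warning("unsupported ISCN token %r; recorded as kind=other", token)
    return CytoLesion(kind=LesionKind.OTHER, raw=token)


def parse_iscn(iscn: str) -> KaryotypeRecord:
    """Parse a karyotype string into a lesion-level record.

    Lesions are pooled across clones (``idem``/``sl`` inherit the
    stemline), deduplicated by token; metaphase counts sum over clones,
    with the abnormal tally covering clones carrying any lesion.
    """
    if not iscn or not iscn.strip():
        raise ValueError("empty ISCN string")

    lesions: list[CytoLesion] = []
    seen_tokens: set[str] = set()
    stem_lesions: list[CytoLesion] = []
    total = 0
    abnormal = 0
    any_counts = False

    for clone_idx, clone in enumerate(iscn.strip().split("/")):
        clone = clone.strip()
        count = None
        m = _COUNT_RE.search(clone)
        if m:
            count = int(m.group(1))
            any_counts = True
            clone = clone[: m.start()].strip()
        fields = [f.strip() for f in clone.split(",") if f.strip()]
        if clone_idx == 0:
            if not fields or not _MODAL_RE.match(fields[0]):
                raise ValueError(f"unparseable modal section in ISCN string: {iscn!r}")
        clone_lesions: list[CytoLesion] = []
        for field in fields:
            if field in ("idem", "sl"):
                clone_lesions.extend(stem_lesions)
                continue
            lesion = _parse_token(field)
            if lesion is not None:
                clone_lesions.append(lesion)
        if clone_idx == 0:
            stem_lesions = list(clone_lesions)
        for lesion in clone_lesions:
            if lesion.raw not in seen_tokens:
                seen_tokens.add(lesion.raw)
                lesions.append(lesion)
        if count is not None:
            total += count
            if clone_lesions:
                abnormal += count

    return KaryotypeRecord(
        iscn=iscn.strip(),
        lesions=lesions,
        metaphases_total=total if any_counts else None,
        metaphases_abnormal=abnormal if any_counts else None,
    )


def _lesion_token(lesion: CytoLesion) -> str:
    if lesion.kind is LesionKind.MONOSOMY:
        return f"-{lesion.chrom}"
    if lesion.kind is LesionKind.TRISOMY:
        return f"+{lesion.chrom}"
    if lesion.kind is LesionKind.DELETION:
        return f"del({lesion.chrom})({lesion.arm_or_band})"
    if lesion.kind is LesionKind.ADDITION:
        return f"add({lesion.chrom})({lesion.arm_or_band})"
    if lesion.kind is LesionKind.TRANSLOCATION:
        return (
            f"t({lesion.chrom};{lesion.partner_chrom})"
            f"({lesion.arm_or_band};{lesion.partner_band})"
        )
    if lesion.kind is LesionKind.ISOCHROMOSOME:
        return f"i({lesion.chrom})({lesion.arm_or_band})"
    if lesion.kind is LesionKind.MARKER:
        return "+mar"
    return lesion.raw


def to_iscn(record: KaryotypeRecord, modal: int = 46, sex: str = "XX") -> str:
    """Canonical single-clone string for the record's lesions.

    Inverse of :func:`parse_iscn` on the supported grammar subset (the
    original clone structure is not reconstructed).
    """
    tokens = [str(modal), sex] + [_lesion_token(l) for l in record.lesions]
    suffix = f"[{record.metaphases_total}]" if record.metaphases_total else ""
    return ",".join(tokens) + suffix
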