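"""Transcriptome-derived decisions.

Whole-transcriptome sequencing contributes three kinds of evidence that
DNA alone cannot provide:

* **oncogene overexpression** — an enhancer relocated next to an intact
  oncogene (e.g. MECOM, HOXA cluster genes) leaves no chimeric
  transcript, but drives ectopic expression measurable against a
  reference of cases without a rearrangement of that gene;
* **enhancer-hijack validation** — a DNA-predicted hijack candidate is
  confirmed when the target is overexpressed and refuted when it is
  not; refuted candidates must never drive classification;
* **allele-specific expression (ASE)** — a large skew between DNA and
  RNA VAF (e.g. 35% in genomic DNA vs 97% in RNA) indicates selective
  expression of one allele, which can upgrade the interpretation of a
  monoallelic variant.

Overexpression is operationalized as a z-score on the log1p scale
against a reference set that excludes structurally rearranged cases.
"""

from __future__ import annotations

import math
from typing import Iterable, Optional, Sequence

from pydantic import BaseModel

from .models import (
    ASECall,
    ExpressionProfile,
    HijackValidation,
    Mechanism,
    RuleConfig,
    StructuralEvent,
)


class OverexpressionCall(BaseModel):
    gene: str
    case_value: float
    reference_mean: float  # log1p scale
    reference_sd: float
    reference_n: int
    z_score: float
    overexpressed: bool


def build_reference(
    gene: str,
    profiles: Iterable[ExpressionProfile],
    svs: Iterable[StructuralEvent] = (),
) -> list[ExpressionProfile]:
    """Reference profiles for ``gene``: cases without any structural event
    touching it (as partner or hijack target), to avoid contaminating the
    null distribution with rearranged cases."""
    rearranged = {
        sv.case_id
        for sv in svs
        if gene in (sv.gene_a, sv.gene_b) or sv.hijack_target == gene
    }
    return [p for p in profiles if p.case_id not in rearranged]


def overexpression_call(
    gene: str,
    profile: ExpressionProfile,
    reference: Sequence[ExpressionProfile],
    cfg: Optional[RuleConfig] = None,
) -> OverexpressionCall:
    """Score a case's expression of ``gene`` against a reference cohort.

    The z-score is computed on the log1p scale, which makes the call
    invariant to uniform multiplicative rescaling of all profiles
    (library-size style factors shift every log value equally).
    """
    cfg = cfg or RuleConfig()
    if not reference:
        raise ValueError("reference cohort is empty")
    case_value = profile.get(gene)
    if case_value is None:
        raise KeyError(f"gene {gene!r} absent from case profile {profile.case_id}")
    ref_values = []
    for p in reference:
        v = p.get(gene)
        if v is None:
            raise KeyError(f"gene {gene!r} absent from reference profile {p.case_id}")
        ref_values.append(math.log1p(v))
    n = len(ref_values)
    mean = sum(ref_values) / n
    var = sum((x - mean) ** 2 for x in ref_values) / (n - 1) if n > 1 else 0.0
    sd = math.sqrt(var)
    if sd == 0.0:
        raise ValueError(
            f"reference expression of {gene!r} has zero variance; "
            "enlarge or diversify the reference cohort"
        )
    z = (math.log1p(case_value) - mean) / sd
    return OverexpressionCall(
        gene=gene,
        case_value=case_value,
        reference_mean=mean,
        reference_sd=sd,
        reference_n=n,
        z_score=z,
        overexpressed=z >= cfg.overexpression_z,
    )


def validate_enhancer_hijack(
    sv: StructuralEvent, call: OverexpressionCall
) -> HijackValidation:
    """Confirm or refute a DNA-predicted enhancer-hijack candidate.

    Confirmed iff the candidate's target oncogene is overexpressed;
    a candidate whose target shows expression comparable to
    non-rearranged cases is refuted and excluded from the set of
    class-defining drivers.
    """
    if sv.mechanism is not Mechanism.ENHANCER_HIJACK_CANDIDATE:
        raise ValueError("event is not an enhancer-hijack candidate")
    if sv.hijack_target != call.gene:
        raise ValueError(
            f"expression call targets {call.gene!r} but the candidate's "
            f"predicted oncogene is {sv.hijack_target!r}"
        )
    return HijackValidation.CONFIRMED if call.overexpressed else HijackValidation.REFUTED


def allele_specific_expression(
    dna_vaf: float, rna_vaf: float, skew_threshold: float = 0.30
) -> ASECall:
    """Call allele-specific expression from a DNA/RNA VAF pair.

    ``mutant_ase`` when RNA exceeds DNA by at least the skew threshold
    (mutant allele preferentially expressed), ``wildtype_ase`` for the
    symmetric case, ``balanced`` otherwise.
    """
    for name, value in (("dna_vaf", dna_vaf), ("rna_vaf", rna_vaf)):
        if not (0.0 <= value <= 1.0):
            raise ValueError(f"{name} {value} outside [0, 1]")
    if rna_vaf - dna_vaf >= skew_threshold:
        return ASECall.MUTANT_ASE
    if dna_vaf - rna_vaf >= skew_threshold:
        return ASECall.WILDTYPE_ASE
    return ASECall.BALANCED
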