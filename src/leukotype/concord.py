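"""Cross-platform concordance statistics.

Quantifies how well two assays agree: exact-key variant matching, VAF
correlation/regression between platforms, per-category detection tables
(truth established by the integrated DNA+RNA analysis vs. what a second
platform saw), overall agreement rates, and cohort-level diagnostic
yield under a given modality.

Counting convention for detection tables: the "total" column counts
truth events (seen by both, plus missed by the comparison platform);
events reported only by the comparison platform are tallied separately
in ``only_b`` and do not inflate the total.
"""

from __future__ import annotations

from typing import Callable, Iterable, Optional, Sequence

import pandas as pd
from scipy import stats

from .models import (
    ConcordanceRow,
    ConcordanceStats,
    ConcordanceTable,
    MolecularSubtype,
    VariantCall,
)


def match_variant_sets(
    a: Sequence[VariantCall], b: Sequence[VariantCall]
) -> tuple[list[VariantCall], list[VariantCall], list[VariantCall]]:
    """Partition two call sets by exact key (case, chrom, pos, ref, alt).

    Callers must normalize indels first (see
    :func:`leukotype.rules.normalize_variant`); two spellings of the
    same indel otherwise count as discordant. Duplicate keys within one
    set are an input error.
    """
    keys_a = [v.key() for v in a]
    keys_b = [v.key() for v in b]
    for name, keys in (("a", keys_a), ("b", keys_b)):
        if len(set(keys)) != len(keys):
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise ValueError(f"duplicate variant key in set {name}: {dup}")
    set_b = set(keys_b)
    set_a = set(keys_a)
    both = [v for v in a if v.key() in set_b]
    only_a = [v for v in a if v.key() not in set_b]
    only_b = [v for v in b if v.key() not in set_a]
    return both, only_a, only_b


def vaf_concordance(pairs: Sequence[tuple[float, float]]) -> ConcordanceStats:
    """Pearson r and ordinary-least-squares slope of platform B on A."""
    if len(pairs) < 3:
        raise ValueError(f"need at least 3 VAF pairs, got {len(pairs)}")
    x = [p[0] for p in pairs]
    y = [p[1] for p in pairs]
    if len(set(x)) == 1 or len(set(y)) == 1:
        raise ValueError("VAF vector is constant; concordance undefined")
    fit = stats.linregress(x, y)
    return ConcordanceStats(
        r=float(fit.rvalue), slope=float(fit.slope), intercept=float(fit.intercept), n_pairs=len(pairs)
    )


def agreement_rate(both: int, only_a: int, only_b: int) -> int:
    """Percentage agreement 100*both/(both+only_a+only_b), nearest integer."""
    for name, n in (("both", both), ("only_a", only_a), ("only_b", only_b)):
        if n < 0:
            raise ValueError(f"{name} must be non-negative, got {n}")
    denom = both + only_a + only_b
    if denom == 0:
        raise ValueError("agreement rate undefined for all-zero counts")
    return round(100.0 * both / denom)


def detection_table(
    truth: Iterable[tuple[str, bool]],
    extra_b: Optional[dict[str, int]] = None,
) -> ConcordanceTable:
    """Per-category detection table from (category, observed_by_b) pairs.

    ``truth`` enumerates events established by the reference analysis;
    the boolean says whether the comparison platform also saw it.
    ``extra_b`` optionally carries per-category counts reported only by
    the comparison platform (kept out of the total, per convention).
    Categories keep first-appearance order.
    """
    order: list[str] = []
    counts: dict[str, list[int]] = {}
    for category, seen_by_b in truth:
        if category not in counts:
            counts[category] = [0, 0]
            order.append(category)
        counts[category][0 if seen_by_b else 1] += 1
    extra_b = extra_b or {}
    for category in extra_b:
        if category not in counts:
            counts[category] = [0, 0]
            order.append(category)
    rows = [
        ConcordanceRow(
            category=c,
            both=counts[c][0],
            only_a=counts[c][1],
            only_b=extra_b.get(c, 0),
        )
        for c in order
    ]
    return ConcordanceTable(rows=rows)


def table_to_frame(table: ConcordanceTable, include_total: bool = True) -> pd.DataFrame:
    """Render a detection table as a DataFrame mirroring the clinical layout."""
    rows = list(table.rows)
    if include_total:
        rows.append(table.total_row())
    return pd.DataFrame(
        {
            "category": [r.category for r in rows],
            "both": [r.both for r in rows],
            "only_a": [r.only_a for r in rows],
            "only_b": [r.only_b for r in rows],
            "total": [r.total for r in rows],
            "pct_missed_b": [round(r.pct_missed_b) for r in rows],
        }
    )


def diagnostic_yield(
    cohort: Sequence[MolecularSubtype],
    modality_detectable: Optional[Callable[[MolecularSubtype], bool]] = None,
    decimals: int = 1,
) -> float:
    """Fraction of cases (as %) whose defining lesion the modality finds.

    With no predicate, computes the yield of the integrated analysis
    itself: a case counts as diagnosed iff its defining lesion is
    non-null. Reported to one decimal (the headline resolution).
    """
    if not cohort:
        raise ValueError("empty cohort")
    if modality_detectable is None:
        modality_detectable = lambda s: True  # noqa: E731
    hits = sum(
        1 for s in cohort if s.defining_lesion is not None and modality_detectable(s)
    )
    return round(100.0 * hits / len(cohort), decimals)
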