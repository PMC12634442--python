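"""Lightweight genome annotation: gene loci and chromosome arms.

Backed by small packaged tables of approximate GRCh38 coordinates.
Everything downstream works at locus or arm resolution (enhancer
windows of hundreds of kb, band-level karyotype comparison), so
approximate spans are adequate and keep the package self-contained.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources
from typing import Optional

GeneRegion = tuple[str, int, int]  # (chrom, start, end), 1-based inclusive


def _load_json(name: str) -> dict:
    with resources.files("leukotype.data").joinpath(name).open() as fh:
        data = json.load(fh)
    data.pop("_comment", None)
    return data


@lru_cache(maxsize=1)
def gene_regions() -> dict[str, GeneRegion]:
    """Locus spans for the genes the rule engine and fixtures reference."""
    return {g: (c, int(s), int(e)) for g, (c, s, e) in _load_json("gene_regions.json").items()}


@lru_cache(maxsize=1)
def chromosome_table() -> dict[str, dict[str, int]]:
    return _load_json("chromosomes.json")


def normalize_chrom(chrom: str) -> str:
    c = chrom if chrom.startswith("chr") else f"chr{chrom}"
    return c


def arm_of(chrom: str, start: int, end: int) -> Optional[str]:
    """Arm label for a segment: 'p', 'q', or 'pq' when it spans the
    centromere substantially (>25% of the segment on each side).

    Returns None for chromosomes absent from the packaged table.
    """
    info = chromosome_table().get(normalize_chrom(chrom))
    if info is None:
        return None
    cen = info["centromere"]
    if end <= cen:
        return "p"
    if start >= cen:
        return "q"
    size = end - start + 1
    p_part = cen - start
    q_part = end - cen
    if p_part / size > 0.25 and q_part / size > 0.25:
        return "pq"
    return "p" if p_part >= q_part else "q"


def is_whole_chromosome(chrom: str, start: int, end: int, min_fraction: float = 0.8) -> bool:
    """True when a segment covers most of the chromosome (numerical change)."""
    info = chromosome_table().get(normalize_chrom(chrom))
    if info is None:
        return False
    return (end - start + 1) / info["length"] >= min_fraction
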