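"""PET ligation taxonomy and the pipeline's threshold parameters.

A nonredundant PET is one of three things. Both tags on one chromosome with
a 5'-to-5' span under 8 kb: a self-ligation PET, the two ends of a single
ChIP fragment and hence a proxy for protein-binding evidence. Both tags on
one chromosome with span of 8 kb or more: an inter-ligation PET, the two
ends of different fragments held in one chromatin complex — the raw
evidence of a chromatin contact. Tags on different chromosomes: a trans
PET, reported as high-order topology signal but never clustered into loops.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .align import RawPET

SELF_LIGATION_SPAN = 8_000
ANCHOR_EXTENSION = 500
MIN_PET_COUNT = 4
MAX_LOOP_SPAN = 1_000_000
MIN_MAPQ = 31


@dataclass
class PipelineParams:
    """All thresholds of the processing pipeline, config-exposed.

    ``self_ligation_span``: same-chromosome PETs with 5'-to-5' span strictly
    below this are self-ligation ("fewer than 8 kb"); the boundary value
    itself is inter-ligation. ``min_mapq`` is the smallest retained mapping
    quality (31, i.e. strictly greater than 30).
    """

    self_ligation_span: int = SELF_LIGATION_SPAN
    anchor_extension: int = ANCHOR_EXTENSION
    min_pet_count: int = MIN_PET_COUNT
    max_loop_span: int = MAX_LOOP_SPAN
    min_mapq: int = MIN_MAPQ
    max_mismatches: int = 2
    min_overlap: int = 10
    min_tag_len: int = 18
    default_tag_len: int = 50
    coverage_bin: int = 100
    contact_bin: int = 25_000
    promoter_window: int = 2_000
    seed_k: int = 12

    def __post_init__(self) -> None:
        for name in (
            "self_ligation_span", "min_pet_count", "max_loop_span",
            "min_mapq", "coverage_bin", "contact_bin",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.anchor_extension < 0:
            raise ValueError("anchor_extension must be >= 0")
        if self.max_loop_span <= self.self_ligation_span:
            raise ValueError("max_loop_span must exceed self_ligation_span")


CATEGORIES = ("self_ligation", "inter_ligation", "trans")


@dataclass(frozen=True)
class PET:
    """A classified, canonically ordered paired-end tag."""

    raw: RawPET
    category: str

    @property
    def tag1(self):
        return self.raw.tag1

    @property
    def tag2(self):
        return self.raw.tag2

    @property
    def span(self):
        """5'-to-5' genomic span; None for trans PETs."""
        if self.tag1.chrom != self.tag2.chrom:
            return None
        return abs(self.tag2.pos5 - self.tag1.pos5)


def classify(pet: RawPET, params: PipelineParams) -> PET:
    if pet.tag1.chrom != pet.tag2.chrom:
        return PET(pet, "trans")
    span = abs(pet.tag2.pos5 - pet.tag1.pos5)
    if span < params.self_ligation_span:
        return PET(pet, "self_ligation")
    return PET(pet, "inter_ligation")


def partition(
    pets: Iterable[RawPET], params: PipelineParams
) -> tuple[dict[str, list[PET]], list[tuple[str, object]]]:
    """Split PETs into the three disjoint classes, with a summary table."""
    parts: dict[str, list[PET]] = {cat: [] for cat in CATEGORIES}
    for raw in pets:
        pet = classify(raw, params)
        parts[pet.category].append(pet)
    total = sum(len(v) for v in parts.values())
    summary: list[tuple[str, object]] = [("total_pets", total)]
    for cat in CATEGORIES:
        n = len(parts[cat])
        summary.append((f"{cat}_count", n))
        summary.append((f"{cat}_fraction", round(n / total, 4) if total else 0.0))
    return parts, summary


def write_pets_tsv(pets: Iterable[PET], path: str) -> None:
    """7-column PET TSV: chrom1,pos1,strand1,chrom2,pos2,strand2,read_id."""
    with open(path, "w") as fh:
        for pet in pets:
            t1, t2 = pet.tag1, pet.tag2
            fh.write(
                f"{t1.chrom}\t{t1.pos5}\t{t1.strand}\t"
                f"{t2.chrom}\t{t2.pos5}\t{t2.strand}\t{pet.raw.read_id}\n"
            )
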