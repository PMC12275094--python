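"""Tag mapping and PCR-duplicate removal.

Two routes produce AlignedTag coordinates: a built-in exact/unique matcher
(a deterministic surrogate adequate for synthetic genomes) and an adapter
consuming SAM output from an external aligner such as bwa-mem. Either way,
only pairs whose two tags both map uniquely with sufficient mapping quality
become PETs, and PCR duplicates are removed at PET level by the 5'
coordinate signature of both tags — the same coordinate semantics Picard
MarkDuplicates applies to read pairs.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

from .formats_io import AlignedTag
from .linker import TagPair, reverse_complement


@dataclass
class ReferenceIndex:
    """Exact-match index: k-mer seed table over the + strand of each chrom."""

    genome: dict[str, str]
    k: int = 12
    seeds: dict[str, list[tuple[str, int]]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.seeds:
            table: dict[str, list[tuple[str, int]]] = defaultdict(list)
            for chrom, seq in self.genome.items():
                for i in range(len(seq) - self.k + 1):
                    table[seq[i : i + self.k]].append((chrom, i))
            self.seeds = dict(table)

    @property
    def sizes(self) -> dict[str, int]:
        return {chrom: len(seq) for chrom, seq in self.genome.items()}

    def occurrences(self, query: str) -> list[tuple[str, int]]:
        """All exact + strand occurrences of query, seeded by its first k-mer."""
        hits: list[tuple[str, int]] = []
        for chrom, pos in self.seeds.get(query[: self.k], ()):
            if self.genome[chrom].startswith(query, pos):
                hits.append((chrom, pos))
        return hits


@dataclass
class MappingCounters:
    mapped: int = 0
    unmapped: int = 0
    multimapped: int = 0
    too_short: int = 0


def map_exact(
    tag_seq: str,
    index: ReferenceIndex,
    read_id: str = "",
    counters: Optional[MappingCounters] = None,
) -> Optional[AlignedTag]:
    """Map a tag requiring a single exact occurrence genome-wide.

    Both strands are searched; exactly one occurrence yields an AlignedTag
    with mapq 60 and pos5 at the 5'-most base of the matched strand. Zero or
    multiple occurrences return None (counted unmapped / multimapped).
    """
    if len(tag_seq) < index.k:
        if counters is not None:
            counters.too_short += 1
        return None
    fwd = index.occurrences(tag_seq)
    rev = index.occurrences(reverse_complement(tag_seq))
    total = len(fwd) + len(rev)
    if total == 0:
        if counters is not None:
            counters.unmapped += 1
        return None
    if total > 1:
        if counters is not None:
            counters.multimapped += 1
        return None
    if counters is not None:
        counters.mapped += 1
    span = len(tag_seq)
    if fwd:
        chrom, pos = fwd[0]
        return AlignedTag(read_id, chrom, pos, "+", span, mapq=60)
    chrom, pos = rev[0]
    return AlignedTag(read_id, chrom, pos + span - 1, "-", span, mapq=60)


def map_tag_pairs(
    pairs: Iterable[TagPair],
    index: ReferenceIndex,
    counters: Optional[MappingCounters] = None,
) -> Iterator[tuple[AlignedTag, AlignedTag]]:
    """Map both tags of each pair; pairs with either tag unresolved drop out."""
    for pair in pairs:
        t1 = map_exact(pair.tag1.sequence, index, pair.read_id, counters)
        t2 = map_exact(pair.tag2.sequence, index, pair.read_id, counters)
        if t1 is not None and t2 is not None:
            yield t1, t2


# ---------------------------------------------------------------------------
# PET assembly and deduplication
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RawPET:
    """Canonically ordered pair of mapped tags (pre-classification)."""

    tag1: AlignedTag
    tag2: AlignedTag

    @property
    def read_id(self) -> str:
        return self.tag1.read_id

    def signature(self):
        return (
            (self.tag1.chrom, self.tag1.pos5, self.tag1.strand),
            (self.tag2.chrom, self.tag2.pos5, self.tag2.strand),
        )


def _canonical(t1: AlignedTag, t2: AlignedTag) -> tuple[AlignedTag, AlignedTag]:
    if (t1.chrom, t1.pos5) <= (t2.chrom, t2.pos5):
        return t1, t2
    return t2, t1


def pair_tags(
    tag_pairs: Iterable[tuple[Optional[AlignedTag], Optional[AlignedTag]]],
    dropped: Optional[Counter] = None,
) -> Iterator[RawPET]:
    """Turn mapped tag pairs into canonically ordered PETs.

    Pairs with either tag missing are dropped and counted. Identical
    coordinates on both tags are allowed (degenerate span-0 PET).
    """
    for t1, t2 in tag_pairs:
        if t1 is None or t2 is None:
            if dropped is not None:
                dropped["unpaired"] += 1
            continue
        a, b = _canonical(t1, t2)
        yield RawPET(a, b)


def dedup(pets: Iterable[RawPET]) -> tuple[list[RawPET], int]:
    """Remove PCR duplicates by the (chrom, pos5, strand) x 2 signature.

    The first-seen PET per signature survives; output is sorted by tag
    coordinates for determinism. Returns (survivors, n_duplicates).
    """
    seen: dict[tuple, RawPET] = {}
    n_dup = 0
    for pet in pets:
        sig = pet.signature()
        if sig in seen:
            n_dup += 1
        else:
            seen[sig] = pet
    survivors = sorted(
        seen.values(),
        key=lambda p: (
            p.tag1.chrom, p.tag1.pos5, p.tag1.strand,
            p.tag2.chrom, p.tag2.pos5, p.tag2.strand,
        ),
    )
    return survivors, n_dup
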