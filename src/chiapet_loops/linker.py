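"""Bridge-linker detection and read splitting.

In situ ChIA-PET joins the two DNA fragments of a proximity-ligation product
through a biotinylated double-stranded bridge linker. In base-called reads
the biotinylated dT is reported as a plain T, so the forward strand of the
linker reads CGCGATATCTTATCTGACT (19 nt) and the reverse strand
GTCAGATAAGATATCGCGT. A read may contain the linker in any of four
orientations (either strand, either direction), possibly truncated at the
read's 3' end. The sequence 5' of the junction is the genomic tag; pairs
without a linker in either mate are discarded, mirroring the rule that only
PETs with bridge linkers enter downstream analysis.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .formats_io import SequenceRecord

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

BRIDGE_FORWARD = "CGCGATATCTTATCTGACT"
BRIDGE_REVERSE = "GTCAGATAAGATATCGCGT"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class BridgeLinker:
    """The bridge-linker query set and its matching tolerance."""

    forward_seq: str = BRIDGE_FORWARD
    reverse_seq: str = BRIDGE_REVERSE
    max_mismatches: int = 2
    min_overlap: int = 10

    def __post_init__(self) -> None:
        if not self.forward_seq or not self.reverse_seq:
            raise ValueError("linker sequences must be non-empty")
        if not 0 <= self.max_mismatches < len(self.forward_seq) / 2:
            raise ValueError("max_mismatches must be in [0, linker_len/2)")

    def queries(self) -> list[tuple[str, str]]:
        """(orientation, sequence) in tie-break priority order."""
        return [
            ("forward", self.forward_seq),
            ("reverse", self.reverse_seq),
            ("forward_rc", reverse_complement(self.forward_seq)),
            ("reverse_rc", reverse_complement(self.reverse_seq)),
        ]


@dataclass(frozen=True)
class LinkerHit:
    read_index: int  # 1 or 2: which mate
    offset: int  # 0-based start of the match in the read
    orientation: str  # forward | reverse | forward_rc | reverse_rc
    mismatches: int
    match_len: int  # linker_len for internal hits, shorter for 3' partials


@dataclass
class TagPair:
    read_id: str
    tag1: SequenceRecord
    tag2: SequenceRecord
    provenance: tuple[str, str]  # per tag: "split" (5' of hit) or "whole"


@dataclass
class LinkerCounters:
    pairs_in: int = 0
    pairs_with_linker: int = 0
    rejected: Counter = field(default_factory=Counter)
    orientations: Counter = field(default_factory=Counter)


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def scan_linker(
    read_seq: str, linker: BridgeLinker
) -> Optional[LinkerHit]:
    """Best linker hit in a read, or None.

    All four query orientations are scanned at every offset. Full internal
    matches tolerate up to ``max_mismatches`` substitutions; a 3'-terminal
    partial match of length L >= ``min_overlap`` (prefix of the query running
    off the read end) tolerates floor(max_mismatches * L / linker_len).
    The winner has the fewest mismatches, ties broken by smaller offset,
    then by query priority forward > reverse > forward_rc > reverse_rc.
    """
    n = len(read_seq)
    if n == 0:
        raise ValueError("read_seq must be non-empty")
    read = _encode(read_seq)
    best: Optional[tuple[int, int, int, LinkerHit]] = None  # sort key + hit
    for prio, (orientation, query) in enumerate(linker.queries()):
        m = len(query)
        q = _encode(query)
        # full internal matches, all offsets at once
        if n >= m:
            windows = np.lib.stride_tricks.sliding_window_view(read, m)
            mm = (windows != q).sum(axis=1)
            ok = np.flatnonzero(mm <= linker.max_mismatches)
            for off in ok:
                key = (int(mm[off]), int(off), prio)
                if best is None or key < best[:3]:
                    best = (*key, LinkerHit(0, int(off), orientation, int(mm[off]), m))
        # 3'-terminal partials: query prefix of length L hangs off the read end
        lo = max(linker.min_overlap, 1)
        for L in range(min(m - 1, n), lo - 1, -1):
            off = n - L
            mm_part = int((read[off:] != q[:L]).sum())
            if mm_part <= (linker.max_mismatches * L) // m:
                key = (mm_part, off, prio)
                if best is None or key < best[:3]:
                    best = (*key, LinkerHit(0, off, orientation, mm_part, L))
    return best[3] if best is not None else None


def split_pair(
    mate1: SequenceRecord,
    mate2: SequenceRecord,
    linker: BridgeLinker,
    min_tag_len: int = 18,
    counters: Optional[LinkerCounters] = None,
):
    """Split a mate pair at the bridge junction into a TagPair.

    The tag taken from each mate is the sequence 5' of its linker hit; a
    mate without a hit contributes its whole sequence. Pairs with a hit in
    neither mate are rejected ("no_linker"); a resulting tag shorter than
    ``min_tag_len`` rejects the pair ("short_tag"). Returns a TagPair or a
    rejection-reason string.
    """
    if counters is not None:
        counters.pairs_in += 1
    hit1 = scan_linker(mate1.sequence, linker)
    hit2 = scan_linker(mate2.sequence, linker)
    if hit1 is None and hit2 is None:
        if counters is not None:
            counters.rejected["no_linker"] += 1
        return "no_linker"

    def cut(rec: SequenceRecord, hit: Optional[LinkerHit]) -> SequenceRecord:
        if hit is None:
            return rec
        qual = rec.qualities[: hit.offset] if rec.qualities else None
        return SequenceRecord(rec.id, rec.sequence[: hit.offset], qual)

    tag1, tag2 = cut(mate1, hit1), cut(mate2, hit2)
    if len(tag1) < min_tag_len or len(tag2) < min_tag_len:
        if counters is not None:
            counters.rejected["short_tag"] += 1
        return "short_tag"
    if counters is not None:
        counters.pairs_with_linker += 1
        for hit in (hit1, hit2):
            if hit is not None:
                counters.orientations[hit.orientation] += 1
    from .formats_io import strip_mate_suffix

    return TagPair(
        read_id=strip_mate_suffix(mate1.id),
        tag1=tag1,
        tag2=tag2,
        provenance=(
            "split" if hit1 is not None else "whole",
            "split" if hit2 is not None else "whole",
        ),
    )


def linker_report(counters: LinkerCounters) -> list[tuple[str, object]]:
    """Per-library linker statistics as (key, value) rows."""
    rows: list[tuple[str, object]] = [
        ("pairs_in", counters.pairs_in),
        ("pairs_with_linker", counters.pairs_with_linker),
        (
            "linker_rate",
            round(counters.pairs_with_linker / counters.pairs_in, 4)
            if counters.pairs_in
            else 0.0,
        ),
    ]
    for reason in sorted(counters.rejected):
        rows.append((f"rejected_{reason}", counters.rejected[reason]))
    for orient in ("forward", "reverse", "forward_rc", "reverse_rc"):
        rows.append((f"orientation_{orient}", counters.orientations[orient]))
    return rows


def write_report(rows: list[tuple[str, object]], path: str) -> None:
    with open(path, "w") as fh:
        for key, value in rows:
            fh.write(f"{key}\t{value}\n")
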