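"""Readers and writers for the standard formats the pipeline touches.

Every interval held in memory is 0-based half-open. BED and BEDPE already use
that convention and pass through unchanged; SAM's 1-based POS is converted by
-1 at the single point where alignments are read. FASTQ and SAM parsing go
through pysam, which handles gzip transparently.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import pysam


class FormatError(ValueError):
    """Malformed input file; message carries the offending record or line."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A chromosome span, 0-based half-open: covers bases [start, end)."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (half-open semantics)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class SequenceRecord:
    """One sequenced read: id, uppercase DNA, optional phred qualities."""

    id: str
    sequence: str
    qualities: Optional[str] = None

    def __post_init__(self) -> None:
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise FormatError(
                f"record {self.id!r}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.qualities)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignedTag:
    """A mapped tag: 5'-most reference coordinate on its strand, 0-based.

    For a + tag ``pos5`` is the leftmost aligned base; for a - tag it is the
    rightmost aligned base. The occupied reference interval is recovered via
    :meth:`occupied`.
    """

    read_id: str
    chrom: str
    pos5: int
    strand: str
    aln_span: int
    mapq: int = 60

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not 0 <= self.mapq <= 255:
            raise ValueError(f"mapq {self.mapq} outside [0, 255]")
        if self.aln_span < 1:
            raise ValueError(f"aln_span must be >= 1, got {self.aln_span}")

    def occupied(self) -> GenomicInterval:
        """Reference interval covered by the tag, strand-resolved."""
        if self.strand == "+":
            return GenomicInterval(self.chrom, self.pos5, self.pos5 + self.aln_span)
        return GenomicInterval(
            self.chrom, max(0, self.pos5 - self.aln_span + 1), self.pos5 + 1
        )


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

_MATE_SUFFIXES = ("/1", "/2")


def strip_mate_suffix(read_id: str) -> str:
    """Canonical read name: drop whitespace tail and trailing /1 or /2."""
    base = read_id.split()[0] if read_id else read_id
    if base.endswith(_MATE_SUFFIXES):
        base = base[:-2]
    return base


def _fastq_records(path: str) -> Iterator[SequenceRecord]:
    with pysam.FastxFile(path) as fh:
        for entry in fh:
            yield SequenceRecord(entry.name, entry.sequence.upper(), entry.quality)


def read_fastq(path1: str, path2: str) -> Iterator[tuple[SequenceRecord, SequenceRecord]]:
    """Stream synchronized mate pairs from two FASTQ files (gzip allowed).

    Mate ids must match after suffix stripping; a mismatch or unequal record
    counts is fatal, naming the 1-based index of the offending record.
    """
    it1, it2 = _fastq_records(path1), _fastq_records(path2)
    index = 0
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        index += 1
        if r1 is None and r2 is None:
            return
        if r1 is None or r2 is None:
            raise FormatError(
                f"mate files out of sync: record {index} present in only one file"
            )
        id1, id2 = strip_mate_suffix(r1.id), strip_mate_suffix(r2.id)
        if id1 != id2:
            raise FormatError(
                f"mate id mismatch at record {index}: {r1.id!r} vs {r2.id!r}"
            )
        yield r1, r2


def write_fastq(records: Sequence[SequenceRecord], path: str) -> None:
    with open(path, "w") as fh:
        for rec in records:
            qual = rec.qualities if rec.qualities is not None else "I" * len(rec)
            fh.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str) -> dict[str, str]:
    """Load a FASTA file into an ordered {name: uppercase sequence} dict."""
    genome: dict[str, str] = {}
    with pysam.FastxFile(path) as fh:
        for entry in fh:
            genome[entry.name] = entry.sequence.upper()
    return genome


def write_fasta(genome: dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------

def read_bed(path: str) -> list[GenomicInterval]:
    """Read BED3+ intervals; track/browser/# lines skipped, name kept."""
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: expected >= 3 columns")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            name = fields[3] if len(fields) > 3 else ""
            intervals.append(GenomicInterval(chrom, start, end, name))
    return intervals


def write_bed(intervals: Sequence[GenomicInterval], path: str) -> None:
    with open(path, "w") as fh:
        for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name:
                cols.append(iv.name)
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# BEDPE (10 columns; score column carries the PET count)
# ---------------------------------------------------------------------------

@dataclass
class BedpeRecord:
    anchor1: GenomicInterval
    anchor2: GenomicInterval
    name: str
    score: int
    extra: list[str] = field(default_factory=list)


def write_bedpe(records: Sequence, path: str) -> None:
    """Write 10-column BEDPE; objects need anchor1/anchor2/score attributes.

    Output is deterministically sorted by (chrom1, start1, start2) and names
    are reassigned cluster_1.. in that order unless the record carries one.
    """
    ordered = sorted(
        records,
        key=lambda r: (
            r.anchor1.chrom,
            r.anchor1.start,
            r.anchor2.chrom,
            r.anchor2.start,
        ),
    )
    with open(path, "w") as fh:
        for i, rec in enumerate(ordered, start=1):
            a1, a2 = rec.anchor1, rec.anchor2
            name = getattr(rec, "name", "") or f"cluster_{i}"
            extra = list(getattr(rec, "extra", []) or [])
            cols = [
                a1.chrom, str(a1.start), str(a1.end),
                a2.chrom, str(a2.start), str(a2.end),
                name, str(rec.score), ".", ".",
            ] + extra
            fh.write("\t".join(cols) + "\n")


def read_bedpe(path: str) -> list[BedpeRecord]:
    records: list[BedpeRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 8:
                raise FormatError(f"{path}:{lineno}: expected >= 8 BEDPE columns")
            records.append(
                BedpeRecord(
                    anchor1=GenomicInterval(f[0], int(f[1]), int(f[2])),
                    anchor2=GenomicInterval(f[3], int(f[4]), int(f[5])),
                    name=f[6],
                    score=int(f[7]),
                    extra=f[10:],
                )
            )
    return records


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def read_sam_pairs(
    path: str, min_mapq: int = 31
) -> Iterator[tuple[AlignedTag, AlignedTag]]:
    """Stream mate pairs of AlignedTags from a SAM/BAM file.

    Secondary and supplementary records are ignored; mates are paired by
    read name (buffered, so name-sorted input is not required). Only pairs
    where both mates are mapped with mapq >= ``min_mapq`` are yielded.
    Orphan mates are counted on the generator's ``orphans`` attribute after
    exhaustion rather than raising.
    """
    pending: dict[str, AlignedTag] = {}
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode, check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            strand = "-" if aln.is_reverse else "+"
            span = aln.reference_length or (aln.query_length or 1)
            pos5 = aln.reference_end - 1 if aln.is_reverse else aln.reference_start
            tag = AlignedTag(
                read_id=strip_mate_suffix(aln.query_name),
                chrom=aln.reference_name,
                pos5=pos5,
                strand=strand,
                aln_span=span,
                mapq=aln.mapping_quality,
            )
            mate = pending.pop(tag.read_id, None)
            if mate is None:
                pending[tag.read_id] = tag
            elif mate.mapq >= min_mapq and tag.mapq >= min_mapq:
                yield mate, tag
    read_sam_pairs.orphans = len(pending)  # type: ignore[attr-defined]


# ---------------------------------------------------------------------------
# bedGraph / chrom.sizes helpers
# ---------------------------------------------------------------------------

def write_chrom_sizes(sizes: dict[str, int], path: str) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


def read_chrom_sizes(path: str) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, size = line.split()[:2]
                sizes[chrom] = int(size)
    return sizes


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
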