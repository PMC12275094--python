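"""RNAPII binding-coverage track and raw binned contact matrix.

All uniquely mapped, nonredundant tags — self-ligation and inter-ligation
alike — contribute to binding coverage: a bin counts the tag intervals that
overlap it. Intra-chromosomal inter-ligation PETs (clusters and singletons
both) populate a raw upper-triangular contact matrix keyed by the bins of
the two 5' positions. Counts are raw; normalization is left to external
tools.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .classify import PET
from .formats_io import GenomicInterval


@dataclass
class CoverageTrack:
    bin_size: int
    chrom_sizes: dict[str, int]
    bins: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, length in self.chrom_sizes.items():
            if chrom not in self.bins:
                n = -(-length // self.bin_size)  # ceil division
                self.bins[chrom] = np.zeros(n, dtype=np.int64)

    def add_interval(self, iv: GenomicInterval) -> None:
        arr = self.bins[iv.chrom]
        first = iv.start // self.bin_size
        last = (iv.end - 1) // self.bin_size  # end exclusive
        arr[first : min(last, len(arr) - 1) + 1] += 1


def coverage(
    pets: Iterable[PET], bin_size: int, chrom_sizes: dict[str, int]
) -> CoverageTrack:
    """Per-bin tag coverage over all PET categories; each tag counts once
    in every bin its occupied interval overlaps."""
    track = CoverageTrack(bin_size, chrom_sizes)
    for pet in pets:
        for tag in (pet.tag1, pet.tag2):
            track.add_interval(tag.occupied())
    return track


def write_bedgraph(track: CoverageTrack, path: str) -> None:
    """bedGraph with zero bins suppressed and equal adjacent bins merged."""
    with open(path, "w") as fh:
        for chrom in sorted(track.bins):
            arr = track.bins[chrom]
            length = track.chrom_sizes[chrom]
            nz = np.flatnonzero(arr)
            if len(nz) == 0:
                continue
            run_start, run_val = int(nz[0]), int(arr[nz[0]])
            prev = int(nz[0])
            for b in nz[1:]:
                b = int(b)
                if b == prev + 1 and int(arr[b]) == run_val:
                    prev = b
                    continue
                fh.write(
                    f"{chrom}\t{run_start * track.bin_size}\t"
                    f"{min((prev + 1) * track.bin_size, length)}\t{run_val}\n"
                )
                run_start, run_val, prev = b, int(arr[b]), b
            fh.write(
                f"{chrom}\t{run_start * track.bin_size}\t"
                f"{min((prev + 1) * track.bin_size, length)}\t{run_val}\n"
            )


@dataclass
class ContactMatrix:
    bin_size: int
    counts: dict[str, Counter] = field(default_factory=dict)  # chrom -> {(i,j): n}

    @property
    def total(self) -> int:
        return sum(sum(c.values()) for c in self.counts.values())


def contact_matrix(inter_pets: Sequence[PET], bin_size: int) -> ContactMatrix:
    """Raw COO contact matrix from intra-chromosomal inter-ligation PETs.

    Each PET increments the (bin(tag1.pos5), bin(tag2.pos5)) triplet with
    i <= j enforced; total mass equals the number of contributing PETs.
    """
    matrix = ContactMatrix(bin_size)
    for pet in inter_pets:
        if pet.tag1.chrom != pet.tag2.chrom:
            continue
        i = pet.tag1.pos5 // bin_size
        j = pet.tag2.pos5 // bin_size
        if i > j:
            i, j = j, i
        matrix.counts.setdefault(pet.tag1.chrom, Counter())[(i, j)] += 1
    return matrix


def write_contacts(matrix: ContactMatrix, path: str) -> None:
    """Text COO: one header per chromosome, then bin_i bin_j count rows."""
    with open(path, "w") as fh:
        for chrom in sorted(matrix.counts):
            fh.write(f"# chrom={chrom} bin={matrix.bin_size}\n")
            for (i, j), n in sorted(matrix.counts[chrom].items()):
                fh.write(f"{i}\t{j}\t{n}\n")


def read_contacts_total(path: str) -> int:
    total = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#") and line.strip():
                total += int(line.split("\t")[2])
    return total
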