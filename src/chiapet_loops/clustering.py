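"""PET clustering by both-anchor overlap after 500-bp end extension.

Each intra-chromosomal inter-ligation PET occupies two reference intervals
(one per tag). For merging, both intervals are extended by the anchor
extension (default 500 bp) in each direction; two PETs are linked when
their extended left intervals overlap AND their extended right intervals
overlap, and clusters are the connected components of that link graph.
Reported cluster anchors are the min-start/max-end hulls of the members'
UNEXTENDED occupied intervals, keeping anchors tight for downstream peak
overlap. Clusters of size one are singletons — retained as Hi-C-like
topology signal but not loop candidates on their own.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .classify import PET, PipelineParams
from .formats_io import AlignedTag, GenomicInterval


@dataclass
class PETCluster:
    anchor1: GenomicInterval
    anchor2: GenomicInterval
    pet_count: int
    member_ids: list[str]
    name: str = ""

    @property
    def is_singleton(self) -> bool:
        return self.pet_count == 1

    @property
    def score(self) -> int:  # BEDPE score column
        return self.pet_count

    @property
    def anchor_distance(self) -> float:
        return abs(self.anchor2.midpoint - self.anchor1.midpoint)


def extend(
    interval: GenomicInterval, extension: int, chrom_length: Optional[int] = None
) -> GenomicInterval:
    """Widen an interval by ``extension`` bp per side, clipped at [0, length)."""
    start = max(0, interval.start - extension)
    end = interval.end + extension
    if chrom_length is not None:
        end = min(end, chrom_length)
    return GenomicInterval(interval.chrom, start, end, interval.name)


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def _pet_intervals(
    pet: PET, extension: int, sizes: Optional[dict[str, int]]
) -> tuple[GenomicInterval, GenomicInterval, GenomicInterval, GenomicInterval]:
    """(left, right, left_ext, right_ext) occupied intervals of a PET."""
    a = pet.tag1.occupied()
    b = pet.tag2.occupied()
    if (a.start, a.end) > (b.start, b.end):
        a, b = b, a
    length = sizes.get(a.chrom) if sizes else None
    return a, b, extend(a, extension, length), extend(b, extension, length)


def cluster_pets(
    inter_pets: Sequence[PET],
    params: PipelineParams,
    chrom_sizes: Optional[dict[str, int]] = None,
) -> list[PETCluster]:
    """Group inter-ligation PETs into clusters by transitive both-anchor overlap.

    All PETs must be intra-chromosomal; the input may mix chromosomes, which
    are clustered independently. Output is deterministically ordered by
    (chrom, anchor1.start, anchor2.start).
    """
    for pet in inter_pets:
        if pet.tag1.chrom != pet.tag2.chrom:
            raise ValueError(
                f"trans PET {pet.raw.read_id!r} cannot be clustered"
            )
    by_chrom: dict[str, list[PET]] = {}
    for pet in inter_pets:
        by_chrom.setdefault(pet.tag1.chrom, []).append(pet)

    clusters: list[PETCluster] = []
    for chrom in sorted(by_chrom):
        clusters.extend(
            _cluster_one_chrom(by_chrom[chrom], params, chrom_sizes)
        )
    clusters.sort(key=lambda c: (c.anchor1.chrom, c.anchor1.start, c.anchor2.start))
    for i, cluster in enumerate(clusters, start=1):
        cluster.name = f"cluster_{i}"
    return clusters


def _cluster_one_chrom(
    pets: list[PET],
    params: PipelineParams,
    chrom_sizes: Optional[dict[str, int]],
) -> list[PETCluster]:
    n = len(pets)
    ivs = [_pet_intervals(p, params.anchor_extension, chrom_sizes) for p in pets]
    # sweep over extended left intervals sorted by start; only pairs whose
    # left extensions overlap are tested for right-anchor overlap
    order = sorted(range(n), key=lambda i: ivs[i][2].start)
    starts = np.array([ivs[i][2].start for i in order])
    uf = _UnionFind(n)
    for rank, i in enumerate(order):
        left_i, right_i = ivs[i][2], ivs[i][3]
        # candidates: later-starting lefts that begin before left_i ends
        hi = int(np.searchsorted(starts, left_i.end, side="left"))
        for j_rank in range(rank + 1, hi):
            j = order[j_rank]
            if ivs[j][3].start < right_i.end and right_i.start < ivs[j][3].end:
                uf.union(i, j)

    members: dict[int, list[int]] = {}
    for i in range(n):
        members.setdefault(uf.find(i), []).append(i)

    clusters = []
    for idxs in members.values():
        lefts = [ivs[i][0] for i in idxs]
        rights = [ivs[i][1] for i in idxs]
        chrom = lefts[0].chrom
        anchor1 = GenomicInterval(
            chrom, min(iv.start for iv in lefts), max(iv.end for iv in lefts)
        )
        anchor2 = GenomicInterval(
            chrom, min(iv.start for iv in rights), max(iv.end for iv in rights)
        )
        if (anchor1.start, anchor1.end) > (anchor2.start, anchor2.end):
            anchor1, anchor2 = anchor2, anchor1
        clusters.append(
            PETCluster(
                anchor1=anchor1,
                anchor2=anchor2,
                pet_count=len(idxs),
                member_ids=sorted(pets[i].raw.read_id for i in idxs),
            )
        )
    return clusters


def cluster_summary(clusters: Sequence[PETCluster]) -> dict[str, object]:
    """PET-count histogram, singleton fraction, and span quantiles."""
    if not clusters:
        return {"histogram": {}, "singleton_fraction": 0.0, "span_quantiles": {}}
    hist = Counter(c.pet_count for c in clusters)
    spans = np.array([c.anchor_distance for c in clusters])
    qs = np.quantile(spans, [0.25, 0.5, 0.75])
    return {
        "histogram": dict(sorted(hist.items())),
        "singleton_fraction": round(
            sum(1 for c in clusters if c.is_singleton) / len(clusters), 4
        ),
        "span_quantiles": {"q25": float(qs[0]), "q50": float(qs[1]), "q75": float(qs[2])},
    }


def pets_from_tsv(path: str, params: PipelineParams) -> list[PET]:
    """Rehydrate inter-ligation PETs from the 7-column TSV.

    Alignment spans are not stored in the TSV, so each tag is assumed to
    occupy ``params.default_tag_len`` bp from its 5' position.
    """
    from .align import RawPET
    from .classify import classify

    pets = []
    with open(path) as fh:
        for line in fh:
            c1, p1, s1, c2, p2, s2, rid = line.rstrip("\n").split("\t")
            t1 = AlignedTag(rid, c1, int(p1), s1, params.default_tag_len)
            t2 = AlignedTag(rid, c2, int(p2), s2, params.default_tag_len)
            pets.append(classify(RawPET(t1, t2), params))
    return pets
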