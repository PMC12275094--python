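"""Loop calling: the three cluster filters, plus promoter/enhancer annotation.

A PET cluster is promoted to an RNAPII-mediated chromatin loop when, in
order: (1) its PET count is at least 4 (clusters with counts less than four
are removed); (2) H3K27ac appears on both anchors, i.e. each anchor overlaps
at least one peak by >= 1 bp; (3) the genomic distance between the two
anchors — taken midpoint to midpoint — is under 1 Mb. Anchors are then
classed against a TSS annotation (promoter within +/- 2 kb of a TSS,
enhancer if on an H3K27ac peak, otherwise other), which yields
promoter-enhancer loop classes and per-gene connectivity degrees.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

from intervaltree import IntervalTree

from .classify import PipelineParams
from .clustering import PETCluster
from .formats_io import FormatError, GenomicInterval


@dataclass
class Loop:
    cluster: PETCluster
    anchor1_class: str = "other"
    anchor2_class: str = "other"
    genes: list[str] = field(default_factory=list)
    annotated: bool = False

    @property
    def anchor1(self) -> GenomicInterval:
        return self.cluster.anchor1

    @property
    def anchor2(self) -> GenomicInterval:
        return self.cluster.anchor2

    @property
    def score(self) -> int:
        return self.cluster.pet_count

    @property
    def name(self) -> str:
        return self.cluster.name

    @property
    def anchor_distance(self) -> float:
        return self.cluster.anchor_distance

    @property
    def loop_class(self) -> str:
        return f"{self.anchor1_class}-{self.anchor2_class}"

    @property
    def extra(self) -> list[str]:
        # annotation columns appear only once annotate_loops has run
        if not self.annotated:
            return []
        return [self.loop_class, ",".join(self.genes) or "."]


def build_peak_index(peaks: Sequence[GenomicInterval]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for peak in peaks:
        trees[peak.chrom][peak.start : peak.end] = peak
    return dict(trees)


def _on_peak(anchor: GenomicInterval, trees: dict[str, IntervalTree]) -> bool:
    tree = trees.get(anchor.chrom)
    return bool(tree is not None and tree.overlap(anchor.start, anchor.end))


def filter_loops(
    clusters: Sequence[PETCluster],
    h3k27ac_peaks: Sequence[GenomicInterval],
    params: PipelineParams,
) -> tuple[list[Loop], Counter]:
    """Apply the three loop filters in order with per-filter rejection counts.

    Returns (loops, rejections) where rejections counts the first filter
    each rejected cluster failed: ``pet_count``, ``no_peak_on_anchor``, or
    ``distance``. Kept + rejected == input cluster count.
    """
    trees = build_peak_index(h3k27ac_peaks)
    loops: list[Loop] = []
    rejections: Counter = Counter()
    for cluster in clusters:
        if cluster.pet_count < params.min_pet_count:
            rejections["pet_count"] += 1
            continue
        if not (_on_peak(cluster.anchor1, trees) and _on_peak(cluster.anchor2, trees)):
            rejections["no_peak_on_anchor"] += 1
            continue
        if cluster.anchor_distance >= params.max_loop_span:
            rejections["distance"] += 1
            continue
        loops.append(Loop(cluster))
    return loops, rejections


def annotate_loops(
    loops: Sequence[Loop],
    tss: Sequence[GenomicInterval],
    h3k27ac_peaks: Sequence[GenomicInterval],
    params: PipelineParams,
) -> dict[str, int]:
    """Class each anchor as promoter / enhancer / other, in place.

    A promoter window spans ``promoter_window`` bp on each side of a named
    TSS; an anchor overlapping one is a promoter anchor and collects the
    gene name. Otherwise an anchor on an H3K27ac peak is an enhancer anchor.
    Returns the per-gene loop degree: the number of distinct distal anchors
    connected to each gene's promoter.
    """
    for t in tss:
        if not t.name:
            raise FormatError("TSS annotation requires a name column")
    w = params.promoter_window
    prom_trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for t in tss:
        prom_trees[t.chrom][max(0, t.start - w) : t.end + w] = t.name
    peak_trees = build_peak_index(h3k27ac_peaks)

    def classify_anchor(anchor: GenomicInterval) -> tuple[str, list[str]]:
        tree = prom_trees.get(anchor.chrom)
        if tree is not None:
            hits = tree.overlap(anchor.start, anchor.end)
            if hits:
                return "promoter", sorted({h.data for h in hits})
        if _on_peak(anchor, peak_trees):
            return "enhancer", []
        return "other", []

    degree: dict[str, set[tuple[str, int, int]]] = defaultdict(set)
    for loop in loops:
        cls1, genes1 = classify_anchor(loop.anchor1)
        cls2, genes2 = classify_anchor(loop.anchor2)
        loop.anchor1_class, loop.anchor2_class = cls1, cls2
        loop.genes = sorted({*genes1, *genes2})
        loop.annotated = True
        a1 = (loop.anchor1.chrom, loop.anchor1.start, loop.anchor1.end)
        a2 = (loop.anchor2.chrom, loop.anchor2.start, loop.anchor2.end)
        for gene in genes1:
            degree[gene].add(a2)
        for gene in genes2:
            degree[gene].add(a1)
    return {gene: len(anchors) for gene, anchors in sorted(degree.items())}


def compare_conditions(
    loops_a: Sequence[Loop], loops_b: Sequence[Loop], slack: int = 500
) -> dict[str, int]:
    """Presence/absence comparison of two loop sets.

    Loops match when both anchor midpoints agree within ``slack`` bp on the
    same chromosome; matching is one-to-one greedy by total midpoint
    distance. Returns counts of shared / a_only / b_only loops.
    """

    def key(loop: Loop):
        return loop.anchor1.chrom, loop.anchor1.midpoint, loop.anchor2.midpoint

    candidates = []
    for i, la in enumerate(loops_a):
        ca, ma1, ma2 = key(la)
        for j, lb in enumerate(loops_b):
            cb, mb1, mb2 = key(lb)
            if ca == cb and abs(ma1 - mb1) <= slack and abs(ma2 - mb2) <= slack:
                candidates.append((abs(ma1 - mb1) + abs(ma2 - mb2), i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    shared = 0
    for _, i, j in candidates:
        if i not in used_a and j not in used_b:
            used_a.add(i)
            used_b.add(j)
            shared += 1
    return {
        "shared": shared,
        "a_only": len(loops_a) - shared,
        "b_only": len(loops_b) - shared,
    }


def write_rejections(rejections: Counter, kept: int, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"kept\t{kept}\n")
        for reason in ("pet_count", "no_peak_on_anchor", "distance"):
            fh.write(f"rejected_{reason}\t{rejections[reason]}\n")


def write_gene_degrees(degrees: dict[str, int], path: str) -> None:
    with open(path, "w") as fh:
        for gene, deg in degrees.items():
            fh.write(f"{gene}\t{deg}\n")
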