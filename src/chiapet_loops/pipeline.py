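"""End-to-end orchestration: linker -> align -> classify -> cluster ->
filter/annotate -> coverage/contacts, with a JSON run manifest.

Every stage writes its artifact under the output directory and appends a
manifest entry carrying the parameter values and the stage's counts, so a
rerun with identical inputs and configuration is byte-identical and the
manifest's conservation chain (pairs in >= pairs with linker >= mapped PETs
>= nonredundant PETs == self + inter + trans) can be checked mechanically.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Optional

from . import align as align_mod
from . import clustering as clustering_mod
from . import loops as loops_mod
from .classify import CATEGORIES, PipelineParams
from .classify import classify as classify_pet
from .classify import partition, write_pets_tsv
from .coverage import contact_matrix, coverage, write_bedgraph, write_contacts
from .formats_io import (
    GenomicInterval,
    ensure_dir,
    read_bed,
    read_bedpe,
    read_fasta,
    read_fastq,
    read_sam_pairs,
    write_bed,
    write_bedpe,
)
from .linker import BridgeLinker, LinkerCounters, linker_report, split_pair, write_report


@dataclass
class RunConfig:
    fq1: str
    fq2: str
    out_dir: str
    genome_fasta: Optional[str] = None  # built-in matcher route
    sam: Optional[str] = None  # external-aligner route
    peaks_bed: Optional[str] = None
    tss_bed: Optional[str] = None
    params: PipelineParams = field(default_factory=PipelineParams)

    def validate(self) -> None:
        required = [self.fq1, self.fq2]
        if self.genome_fasta is None and self.sam is None:
            raise ValueError("need either genome_fasta (builtin) or sam input")
        for path in required + [
            p for p in (self.genome_fasta, self.sam, self.peaks_bed, self.tss_bed)
            if p is not None
        ]:
            if not os.path.exists(path):
                raise FileNotFoundError(f"input path does not exist: {path}")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunResult:
    manifest: dict
    loops: list
    clusters: list
    parts: dict
    out_dir: str


def run_all(config: RunConfig) -> RunResult:
    """Execute every pipeline stage; returns the manifest and key objects."""
    config.validate()
    out = ensure_dir(config.out_dir)
    params = config.params
    manifest: dict = {
        "params": vars(params).copy(),
        "inputs": {
            name: {"path": path, "sha256": _sha256(path)}
            for name, path in (
                ("fq1", config.fq1), ("fq2", config.fq2),
                ("genome", config.genome_fasta), ("sam", config.sam),
                ("peaks", config.peaks_bed), ("tss", config.tss_bed),
            )
            if path is not None
        },
        "stages": [],
    }

    # stage 1: linker detection and splitting
    linker = BridgeLinker(
        max_mismatches=params.max_mismatches, min_overlap=params.min_overlap
    )
    counters = LinkerCounters()
    tag_pairs = []
    for m1, m2 in read_fastq(config.fq1, config.fq2):
        result = split_pair(m1, m2, linker, params.min_tag_len, counters)
        if not isinstance(result, str):
            tag_pairs.append(result)
    write_report(linker_report(counters), os.path.join(out, "linker_report.tsv"))
    manifest["stages"].append(
        {
            "stage": "linker",
            "pairs_in": counters.pairs_in,
            "pairs_with_linker": counters.pairs_with_linker,
            "rejected": dict(counters.rejected),
        }
    )

    # stage 2: mapping + PET assembly + dedup
    if config.genome_fasta is not None:
        genome = read_fasta(config.genome_fasta)
        index = align_mod.ReferenceIndex(genome, k=params.seed_k)
        chrom_sizes = index.sizes
        map_counters = align_mod.MappingCounters()
        mapped = list(align_mod.map_tag_pairs(tag_pairs, index, map_counters))
        map_stats = vars(map_counters).copy()
    else:
        mapped = list(read_sam_pairs(config.sam, params.min_mapq))
        chrom_sizes = {}
        map_stats = {"mapped_pairs": len(mapped)}
    pets = list(align_mod.pair_tags(mapped))
    nonredundant, n_dup = align_mod.dedup(pets)
    write_pets_tsv(
        (classify_pet(p, params) for p in nonredundant),
        os.path.join(out, "pets_nonredundant.tsv"),
    )
    manifest["stages"].append(
        {
            "stage": "align",
            **map_stats,
            "mapped_pets": len(pets),
            "duplicates_removed": n_dup,
            "nonredundant_pets": len(nonredundant),
        }
    )

    # stage 3: classification
    parts, summary = partition(nonredundant, params)
    with open(os.path.join(out, "pet_classes.tsv"), "w") as fh:
        for key, value in summary:
            fh.write(f"{key}\t{value}\n")
    for cat, pet_list in parts.items():
        write_pets_tsv(pet_list, os.path.join(out, f"pets_{cat}.tsv"))
    manifest["stages"].append(
        {"stage": "classify", **{f"{c}_count": len(parts[c]) for c in parts}}
    )

    # stage 4: clustering
    inter = parts["inter_ligation"]
    clusters = clustering_mod.cluster_pets(inter, params, chrom_sizes or None)
    non_singleton = [c for c in clusters if not c.is_singleton]
    singletons = [c for c in clusters if c.is_singleton]
    write_bedpe(non_singleton, os.path.join(out, "clusters.bedpe"))
    write_bedpe(singletons, os.path.join(out, "singletons.bedpe"))
    manifest["stages"].append(
        {
            "stage": "cluster",
            "n_clusters": len(non_singleton),
            "n_singletons": len(singletons),
            "sum_pet_counts": sum(c.pet_count for c in clusters),
        }
    )

    # stage 5: loop filtering and annotation
    peaks = read_bed(config.peaks_bed) if config.peaks_bed else []
    called_loops, rejections = loops_mod.filter_loops(clusters, peaks, params)
    degrees: dict[str, int] = {}
    if config.tss_bed:
        tss = read_bed(config.tss_bed)
        degrees = loops_mod.annotate_loops(called_loops, tss, peaks, params)
        loops_mod.write_gene_degrees(degrees, os.path.join(out, "gene_degrees.tsv"))
    write_bedpe(called_loops, os.path.join(out, "loops.bedpe"))
    loops_mod.write_rejections(
        rejections, len(called_loops), os.path.join(out, "loop_rejections.tsv")
    )
    manifest["stages"].append(
        {
            "stage": "loops",
            "n_loops": len(called_loops),
            "rejections": dict(rejections),
        }
    )

    # stage 6: coverage + contacts
    all_pets = [p for cat in CATEGORIES for p in parts[cat]]
    if chrom_sizes:
        track = coverage(all_pets, params.coverage_bin, chrom_sizes)
        write_bedgraph(track, os.path.join(out, "coverage.bedgraph"))
    matrix = contact_matrix(inter, params.contact_bin)
    write_contacts(matrix, os.path.join(out, "contacts.coo.tsv"))
    manifest["stages"].append(
        {"stage": "coverage_contacts", "contact_mass": matrix.total}
    )

    manifest_path = os.path.join(out, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return RunResult(manifest, called_loops, clusters, parts, out)


def check_conservation(manifest: dict) -> list[str]:
    """Violations of the manifest's count conservation chain (empty = OK)."""
    stages = {s["stage"]: s for s in manifest["stages"]}
    link, aln, cls = stages["linker"], stages["align"], stages["classify"]
    violations = []
    if not link["pairs_in"] >= link["pairs_with_linker"]:
        violations.append("pairs_in < pairs_with_linker")
    if not link["pairs_with_linker"] >= aln["mapped_pets"]:
        violations.append("pairs_with_linker < mapped_pets")
    if not aln["mapped_pets"] >= aln["nonredundant_pets"]:
        violations.append("mapped_pets < nonredundant_pets")
    class_sum = sum(
        cls[f"{c}_count"] for c in ("self_ligation", "inter_ligation", "trans")
    )
    if aln["nonredundant_pets"] != class_sum:
        violations.append("nonredundant_pets != self + inter + trans")
    clu = stages["cluster"]
    if clu["sum_pet_counts"] != cls["inter_ligation_count"]:
        violations.append("sum of cluster pet_counts != inter-ligation PETs")
    return violations


def validate_outputs(
    loops_bedpe: str,
    params: PipelineParams,
    peaks: list[GenomicInterval],
) -> tuple[bool, list[str]]:
    """Independent naive re-check of the three loop filters on a BEDPE file.

    Deliberately avoids the pipeline's own filter code: peak overlap is a
    linear scan, distance a direct midpoint computation. Returns (ok,
    failure messages naming the violated filter and record).
    """
    failures: list[str] = []
    for rec in read_bedpe(loops_bedpe):
        if rec.score < params.min_pet_count:
            failures.append(
                f"{rec.name}: pet_count filter violated (count {rec.score})"
            )
        for label, anchor in (("anchor1", rec.anchor1), ("anchor2", rec.anchor2)):
            hit = any(
                p.chrom == anchor.chrom
                and p.start < anchor.end
                and anchor.start < p.end
                for p in peaks
            )
            if not hit:
                failures.append(
                    f"{rec.name}: H3K27ac filter violated ({label} off-peak)"
                )
        dist = abs(rec.anchor2.midpoint - rec.anchor1.midpoint)
        if dist >= params.max_loop_span:
            failures.append(
                f"{rec.name}: distance filter violated ({dist:.0f} bp)"
            )
    return not failures, failures
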