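"""Synthetic ChIA-PET library generator with ground truth.

Emulates what the wet-lab protocol hands to the sequencer: dual-crosslinked,
restriction-digested chromatin fragments proximity-ligated through the
biotinylated bridge linker and sequenced as paired-end reads. Each simulated
mate concatenates tag-proximal genomic sequence, the bridge linker in a
random orientation, and carry-over sequence from the partner fragment, then
truncates to the read length. The generator plants loops (PETs whose two
tags fall in two distant anchors), self-ligation products (both tags from
one sub-8-kb fragment), trans-chromosomal and random intra-chromosomal
noise, and exact-copy PCR duplicates, recording a truth label for every
read pair so each downstream stage can be scored.

It does not model fragment-size distributions from the restriction digest,
base-quality decay, or polymerase error spectra; per-base errors are i.i.d.
substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .formats_io import (
    GenomicInterval,
    SequenceRecord,
    write_bed,
    write_bedpe,
    write_chrom_sizes,
    write_fasta,
    write_fastq,
)
from .linker import BRIDGE_FORWARD, BRIDGE_REVERSE, reverse_complement

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    gc_fraction: float = 0.42
    n_loops: int = 10
    anchor_width: int = 500
    loop_span_min: int = 20_000
    loop_span_max: int = 500_000
    pets_per_loop_mean: float = 6.0
    pets_per_loop_dispersion: float = 0.0  # 0 -> exactly the mean per loop
    self_ligation_fraction: float = 0.30
    trans_noise_fraction: float = 0.05
    random_intra_noise_fraction: float = 0.05
    duplicate_rate: float = 0.10
    read_length: int = 150
    min_tag_len: int = 18
    error_rate: float = 0.0
    one_sided_fraction: float = 0.05
    peak_fraction: float = 1.0  # fraction of loop anchors covered by truth peaks
    peak_margin: int = 250
    min_anchor_separation: int = 5_000

    def __post_init__(self) -> None:
        fracs = (
            self.self_ligation_fraction,
            self.trans_noise_fraction,
            self.random_intra_noise_fraction,
        )
        if any(not 0.0 <= f <= 1.0 for f in fracs) or sum(fracs) > 1.0:
            raise ValueError("noise fractions must lie in [0,1] and sum to <= 1")
        if not 0.0 <= self.duplicate_rate <= 1.0:
            raise ValueError("duplicate_rate must lie in [0,1]")
        if self.loop_span_max <= self.loop_span_min:
            raise ValueError("loop_span_max must exceed loop_span_min")


@dataclass
class TruthLoop:
    loop_id: str
    anchor1: GenomicInterval
    anchor2: GenomicInterval
    pet_count: int

    @property
    def score(self) -> int:
        return self.pet_count

    @property
    def name(self) -> str:
        return self.loop_id


@dataclass
class TruthRead:
    read_id: str
    label: str  # loop_<i> | self | trans | intra_noise
    is_duplicate: bool
    tag1: tuple[str, int, str]  # chrom, pos5, strand
    tag2: tuple[str, int, str]


@dataclass
class TruthSet:
    loops: list[TruthLoop] = field(default_factory=list)
    peaks: list[GenomicInterval] = field(default_factory=list)
    reads: list[TruthRead] = field(default_factory=list)

    def label_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for read in self.reads:
            key = "loop" if read.label.startswith("loop_") else read.label
            counts[key] = counts.get(key, 0) + 1
        return counts


def simulate_genome(config: SimulationConfig, rng: np.random.Generator) -> dict[str, str]:
    """I.i.d. random genome at the configured GC fraction; deterministic per seed."""
    gc = config.gc_fraction
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    genome = {}
    for i in range(config.n_chroms):
        draws = rng.choice(_BASES, size=config.chrom_length, p=probs)
        genome[f"chr{i + 1}"] = draws.tobytes().decode("ascii")
    return genome


class _LibraryBuilder:
    def __init__(self, config: SimulationConfig, genome: dict[str, str],
                 rng: np.random.Generator) -> None:
        self.cfg = config
        self.genome = genome
        self.chroms = list(genome)
        self.rng = rng
        self.linker_len = len(BRIDGE_FORWARD)
        # reads crossing a junction see the A-tail, then either linker strand
        self.junction_seqs = ["A" + BRIDGE_FORWARD, "A" + BRIDGE_REVERSE]
        self.reads1: list[SequenceRecord] = []
        self.reads2: list[SequenceRecord] = []
        self.truth = TruthSet()
        self._counter = 0

    # -- geometry ----------------------------------------------------------

    def _segment(self, chrom: str, pos5: int, strand: str, length: int) -> str:
        seq = self.genome[chrom]
        if strand == "+":
            return seq[pos5 : pos5 + length]
        lo = max(0, pos5 - length + 1)
        return reverse_complement(seq[lo : pos5 + 1])

    def _draw_tag(self, anchor: GenomicInterval) -> tuple[int, str]:
        pos5 = int(self.rng.integers(anchor.start, anchor.end))
        strand = "+" if self.rng.random() < 0.5 else "-"
        return pos5, strand

    def _place_anchors(self) -> list[tuple[str, GenomicInterval, GenomicInterval]]:
        """Non-overlapping, well-separated loop anchor pairs; fatal after retries."""
        cfg = self.cfg
        placed: list[tuple[str, GenomicInterval, GenomicInterval]] = []
        occupied: dict[str, list[GenomicInterval]] = {c: [] for c in self.chroms}
        margin = cfg.read_length  # keep tags clear of chromosome edges
        for _ in range(cfg.n_loops):
            for attempt in range(1000):
                chrom = self.chroms[int(self.rng.integers(len(self.chroms)))]
                span = int(self.rng.integers(cfg.loop_span_min, cfg.loop_span_max + 1))
                hi = len(self.genome[chrom]) - span - cfg.anchor_width - margin
                if hi <= margin:
                    continue
                s1 = int(self.rng.integers(margin, hi))
                a1 = GenomicInterval(chrom, s1, s1 + cfg.anchor_width)
                a2 = GenomicInterval(chrom, s1 + span, s1 + span + cfg.anchor_width)
                if a1.end + 2 * cfg.anchor_width >= a2.start:
                    continue
                sep = cfg.min_anchor_separation
                clash = any(
                    new.start - sep < old.end and old.start < new.end + sep
                    for old in occupied[chrom]
                    for new in (a1, a2)
                )
                if clash:
                    continue
                occupied[chrom].extend([a1, a2])
                placed.append((chrom, a1, a2))
                break
            else:
                raise RuntimeError(
                    "could not place non-overlapping loop anchors; "
                    "genome too small for the requested loops"
                )
        return placed

    # -- read emission -----------------------------------------------------

    def _apply_errors(self, seq: str) -> str:
        rate = self.cfg.error_rate
        if rate <= 0:
            return seq
        arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        hits = np.flatnonzero(self.rng.random(len(arr)) < rate)
        for i in hits:
            choices = _BASES[_BASES != arr[i]]
            arr[i] = choices[int(self.rng.integers(len(choices)))]
        return arr.tobytes().decode("ascii")

    def _build_mate(self, chrom: str, pos5: int, strand: str, tag_len: int,
                    partner: tuple[str, int, str], with_linker: bool) -> str:
        cfg = self.cfg
        tag = self._segment(chrom, pos5, strand, tag_len)
        if not with_linker:
            read = self._segment(chrom, pos5, strand, cfg.read_length)
        else:
            linker = self.junction_seqs[int(self.rng.integers(2))]
            need = cfg.read_length - len(tag) - len(linker)
            carry = ""
            if need > 0:
                pc, pp, ps = partner
                carry = self._segment(pc, pp, "-" if ps == "+" else "+", need)
            read = (tag + linker + carry)[: cfg.read_length]
        if len(read) < cfg.read_length:
            read = read + "A" * (cfg.read_length - len(read))
        return self._apply_errors(read)

    def _emit_pet(self, label: str, tag1: tuple[str, int, str],
                  tag2: tuple[str, int, str]) -> None:
        cfg = self.cfg
        rid = f"sim_{self._counter}"
        self._counter += 1
        lo, hi = cfg.min_tag_len, cfg.read_length - self.linker_len - 1
        len1 = int(self.rng.integers(lo, hi + 1))
        len2 = int(self.rng.integers(lo, hi + 1))
        one_sided = self.rng.random() < cfg.one_sided_fraction
        seq1 = self._build_mate(*tag1, len1, tag2, with_linker=True)
        seq2 = self._build_mate(*tag2, len2, tag1, with_linker=not one_sided)
        self.reads1.append(SequenceRecord(f"{rid}/1", seq1))
        self.reads2.append(SequenceRecord(f"{rid}/2", seq2))
        self.truth.reads.append(TruthRead(rid, label, False, tag1, tag2))
        if self.rng.random() < cfg.duplicate_rate:
            dup_id = f"sim_{self._counter}"
            self._counter += 1
            self.reads1.append(SequenceRecord(f"{dup_id}/1", seq1))
            self.reads2.append(SequenceRecord(f"{dup_id}/2", seq2))
            self.truth.reads.append(TruthRead(dup_id, label, True, tag1, tag2))

    def _pets_for_loop(self) -> int:
        cfg = self.cfg
        if cfg.pets_per_loop_dispersion <= 0:
            return int(round(cfg.pets_per_loop_mean))
        return max(1, int(self.rng.poisson(cfg.pets_per_loop_mean)))

    # -- library assembly --------------------------------------------------

    def build(self) -> None:
        cfg = self.cfg
        anchors = self._place_anchors()
        n_loop_pets = 0
        for i, (chrom, a1, a2) in enumerate(anchors):
            count = self._pets_for_loop()
            self.truth.loops.append(TruthLoop(f"loop_{i}", a1, a2, count))
            for _ in range(count):
                p1, s1 = self._draw_tag(a1)
                p2, s2 = self._draw_tag(a2)
                self._emit_pet(f"loop_{i}", (chrom, p1, s1), (chrom, p2, s2))
            n_loop_pets += count

        signal_frac = 1.0 - (
            cfg.self_ligation_fraction
            + cfg.trans_noise_fraction
            + cfg.random_intra_noise_fraction
        )
        total = n_loop_pets / signal_frac if signal_frac > 0 else n_loop_pets
        n_self = int(round(total * cfg.self_ligation_fraction))
        n_trans = int(round(total * cfg.trans_noise_fraction))
        n_intra = int(round(total * cfg.random_intra_noise_fraction))
        margin = cfg.read_length

        for _ in range(n_self):
            chrom = self.chroms[int(self.rng.integers(len(self.chroms)))]
            size = len(self.genome[chrom])
            span = int(self.rng.integers(100, 7_000))
            p = int(self.rng.integers(margin, size - span - margin))
            self._emit_pet("self", (chrom, p, "+"), (chrom, p + span, "-"))

        for _ in range(n_trans):
            if len(self.chroms) < 2:
                break
            c1, c2 = self.rng.choice(len(self.chroms), size=2, replace=False)
            chrom1, chrom2 = self.chroms[int(c1)], self.chroms[int(c2)]
            p1 = int(self.rng.integers(margin, len(self.genome[chrom1]) - margin))
            p2 = int(self.rng.integers(margin, len(self.genome[chrom2]) - margin))
            s1 = "+" if self.rng.random() < 0.5 else "-"
            s2 = "+" if self.rng.random() < 0.5 else "-"
            self._emit_pet("trans", (chrom1, p1, s1), (chrom2, p2, s2))

        for _ in range(n_intra):
            chrom = self.chroms[int(self.rng.integers(len(self.chroms)))]
            size = len(self.genome[chrom])
            p1 = int(self.rng.integers(margin, size - margin))
            p2 = int(self.rng.integers(margin, size - margin))
            s1 = "+" if self.rng.random() < 0.5 else "-"
            s2 = "+" if self.rng.random() < 0.5 else "-"
            self._emit_pet("intra_noise", (chrom, p1, s1), (chrom, p2, s2))

        # truth H3K27ac peaks: anchor intervals +/- margin for a subset of anchors
        all_anchors = [iv for _, a1, a2 in anchors for iv in (a1, a2)]
        n_covered = int(round(cfg.peak_fraction * len(all_anchors)))
        covered_idx = self.rng.choice(
            len(all_anchors), size=n_covered, replace=False
        ) if all_anchors else []
        for idx in sorted(int(i) for i in np.atleast_1d(covered_idx)):
            iv = all_anchors[idx]
            self.truth.peaks.append(
                GenomicInterval(
                    iv.chrom,
                    max(0, iv.start - cfg.peak_margin),
                    iv.end + cfg.peak_margin,
                    name=f"peak_{idx}",
                )
            )


def simulate_library(
    config: SimulationConfig, genome: dict[str, str], rng: np.random.Generator
) -> tuple[list[SequenceRecord], list[SequenceRecord], TruthSet]:
    """Generate the paired reads and the ground truth for one library."""
    builder = _LibraryBuilder(config, genome, rng)
    builder.build()
    return builder.reads1, builder.reads2, builder.truth


def write_library(
    out_dir: str,
    genome: dict[str, str],
    reads1: list[SequenceRecord],
    reads2: list[SequenceRecord],
    truth: TruthSet,
) -> dict[str, str]:
    """Materialize genome.fa, chrom.sizes, FASTQ pair, and truth files."""
    import os

    paths = {
        "genome": os.path.join(out_dir, "genome.fa"),
        "sizes": os.path.join(out_dir, "chrom.sizes"),
        "fq1": os.path.join(out_dir, "reads_1.fq"),
        "fq2": os.path.join(out_dir, "reads_2.fq"),
        "truth_loops": os.path.join(out_dir, "truth_loops.bedpe"),
        "truth_peaks": os.path.join(out_dir, "truth_peaks.bed"),
        "truth_reads": os.path.join(out_dir, "truth_reads.tsv"),
    }
    os.makedirs(out_dir, exist_ok=True)
    write_fasta(genome, paths["genome"])
    write_chrom_sizes({c: len(s) for c, s in genome.items()}, paths["sizes"])
    write_fastq(reads1, paths["fq1"])
    write_fastq(reads2, paths["fq2"])
    write_bedpe(truth.loops, paths["truth_loops"])
    write_bed(truth.peaks, paths["truth_peaks"])
    with open(paths["truth_reads"], "w") as fh:
        fh.write("read_id\tlabel\tis_duplicate\ttag1\ttag2\n")
        for read in truth.reads:
            t1 = "{}:{}:{}".format(*read.tag1)
            t2 = "{}:{}:{}".format(*read.tag2)
            fh.write(
                f"{read.read_id}\t{read.label}\t{int(read.is_duplicate)}\t{t1}\t{t2}\n"
            )
    return paths


def score_recovery(
    called: list, truth_loops: list[TruthLoop], slack: int = 500
) -> dict[str, float]:
    """Precision/recall/F1 of called loops against the planted truth.

    A truth loop is recovered when a called loop places both anchor
    midpoints within ``slack`` bp of the truth midpoints; matching is
    one-to-one greedy by total midpoint distance. Precision on an empty
    called set is defined as 1.0.
    """
    pairs = []
    for i, c in enumerate(called):
        for j, t in enumerate(truth_loops):
            if c.anchor1.chrom != t.anchor1.chrom:
                continue
            d1 = abs(c.anchor1.midpoint - t.anchor1.midpoint)
            d2 = abs(c.anchor2.midpoint - t.anchor2.midpoint)
            if d1 <= slack and d2 <= slack:
                pairs.append((d1 + d2, i, j))
    pairs.sort()
    used_c: set[int] = set()
    used_t: set[int] = set()
    matches: list[tuple[int, int]] = []
    for _, i, j in pairs:
        if i not in used_c and j not in used_t:
            used_c.add(i)
            used_t.add(j)
            matches.append((i, j))
    n_match = len(matches)
    precision = n_match / len(called) if called else 1.0
    recall = n_match / len(truth_loops) if truth_loops else 1.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall > 0
        else 0.0
    )
    return {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "n_called": len(called),
        "n_truth": len(truth_loops),
        "n_matched": n_match,
    }


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
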