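# Methods

## The processing model

RNAPII in situ ChIA-PET captures pairs of genomic loci held together in one
chromatin complex by RNA polymerase II. Restriction-digested, A-tailed
chromatin fragments are proximity-ligated through a biotinylated
double-stranded bridge linker (forward strand `CGCGATATCTTATCTGACT`, the
biotinylated dT base-called as plain T; reverse strand
`GTCAGATAAGATATCGCGT`), so a sequenced read that crosses a ligation
junction contains linker sequence. The pipeline turns paired-end reads into
chromatin loops in six deterministic stages:

1. **Linker detection and splitting.** Each mate is scanned for the linker
   in all four orientations (both strands and their reverse complements).
   The genomic tag is the sequence 5' of the best hit; pairs with a hit in
   neither mate are discarded. A pair with a hit in only one mate is kept,
   using the other mate whole.
2. **Mapping.** Tags become reference coordinates either through a built-in
   exact/unique matcher (for synthetic genomes) or by consuming SAM output
   from an external aligner such as bwa-mem, keeping only tags with mapping
   quality of at least 31 (strictly greater than 30).
3. **PET assembly and duplicate removal.** The two tags of a pair form a
   PET, canonically ordered by (chromosome, 5' position). PCR duplicates
   are PETs whose (chromosome, 5' position, strand) signatures agree on
   both tags; the first-seen PET survives.
4. **Ligation classification.** Same chromosome, 5'-to-5' span < 8 kb:
   self-ligation (two ends of one ChIP fragment, the protein-binding
   proxy). Same chromosome, span >= 8 kb: inter-ligation (a chromatin
   contact). Different chromosomes: trans. The boundary span of exactly
   8,000 bp is inter-ligation, because "under 8 kb" defines self-ligation
   strictly and the complement inherits the boundary.
5. **Clustering.** Both occupied intervals of each intra-chromosomal
   inter-ligation PET are extended by 500 bp per side; PETs whose extended
   intervals overlap (>= 1 bp, half-open semantics) at BOTH ends are
   linked, and clusters are the connected components of the link graph.
   Merging is transitive rather than seed-greedy because connected
   components are the only order-independent closure of pairwise
   overlap. Reported anchors are the min-start/max-end hulls of the
   members' UNEXTENDED intervals — extension is a merging device, not a
   coordinate change — which keeps anchors tight for peak overlap.
   Single-member clusters are singletons: retained as Hi-C-like topology
   signal and counted in the contact matrix, but not loops by themselves.
6. **Loop filtering.** In order: clusters with PET count < 4 are removed;
   both anchors must overlap an H3K27ac peak by >= 1 bp; the
   midpoint-to-midpoint anchor distance must be < 1 Mb. Surviving clusters
   are the called loops. The filters commute in outcome; the order only
   affects per-filter rejection counts.

Coverage and contacts are exported for visualization: every nonredundant
tag (all three classes) contributes its occupied interval to a binned
binding-coverage track (bedGraph, zero bins suppressed), and every
intra-chromosomal inter-ligation PET increments one upper-triangular
(bin_i, bin_j) contact count (raw counts; normalization is deliberately
left to external tools).

## Parameters

| parameter | default | meaning |
|---|---|---|
| `self_ligation_span` | 8,000 bp | strict upper bound for self-ligation |
| `anchor_extension` | 500 bp | per-side extension used only for merging |
| `min_pet_count` | 4 | minimum PETs per cluster to call a loop |
| `max_loop_span` | 1,000,000 bp | strict upper bound on anchor midpoint distance |
| `min_mapq` | 31 | smallest retained mapping quality (> 30) |
| `max_mismatches` | 2 | substitutions tolerated in a full linker match |
| `min_overlap` | 10 nt | shortest 3'-terminal partial linker match |
| `min_tag_len` | 18 nt | shortest usable genomic tag |
| `default_tag_len` | 50 bp | assumed tag span when rehydrating PETs from TSV |
| `coverage_bin` / `contact_bin` | 100 bp / 25 kb | export resolutions |
| `promoter_window` | 2,000 bp | per-side window around a TSS |

The 8 kb / 500 bp / 4 / 1 Mb / >30 values are the pipeline's defining
thresholds; the linker-matching tolerances, tag-length floor, promoter
window, and export bins are conventional choices, config-exposed because no
single value is canonical.

### Linker matching details

A full internal match tolerates up to `max_mismatches` substitutions. A
3'-terminal partial match of length L >= `min_overlap` (query prefix
running off the read end) tolerates `floor(max_mismatches * L /
linker_len)`. The best hit has the fewest mismatches; ties go to the
smaller offset, then to query priority forward > reverse > forward_rc >
reverse_rc. One degeneracy is worth knowing: because ligation follows
A-tailing, `"A" + forward_strand` is exactly the reverse complement of the
reverse strand shifted one base left. A forward linker preceded by an A
therefore also matches `reverse_rc` one base earlier with zero mismatches,
and the offset-first tie-break selects that earlier hit. This is the
biologically correct junction position — the A-tail is not genomic — so
trimming at it returns the exact genomic tag.

When one read contains several linker copies (concatemers), the tag is the
sequence 5' of the winning hit; with equal mismatch counts that is the
first copy. A later copy with strictly fewer mismatches outranks an
earlier, noisier one — the junction with the best evidence wins.

### Built-in matcher

The built-in mapper indexes every k-mer (k = 12) of the reference forward
strand and reports a tag only when it has exactly one exact occurrence
genome-wide across both strands (mapq 60). It is a deterministic,
oracle-checkable stand-in adequate for random synthetic genomes, where an
18+ nt tag is essentially always unique; it tolerates no mismatches, so
reads carrying simulated sequencing errors in the tag go uncounted
(`unmapped`). Real libraries should use the SAM route.

## The simulator

The generator emulates the sequencer-facing product of the protocol:
junction reads are `tag + "A" + linker-strand + carry-over`, truncated to
the read length (150 bp), with the junction offset drawn uniformly in
[`min_tag_len`, `read_length` − linker length − 1]. Defaults describe a
small but realistically composed library: 10 planted loops with 500-bp
anchors separated by 20–500 kb on a 2 × 1 Mb random genome (GC 0.42,
roughly mammalian), 6 PETs per loop, and noise as library fractions —
self-ligation 0.30, trans 0.05, random intra-chromosomal 0.05 — plus a
PCR duplicate rate of 0.10 (exact byte copies) and a 0.05 fraction of
pairs whose second mate lacks a linker (exercising the one-sided split
policy). Truth H3K27ac peaks are anchor intervals ±250 bp for a
configurable fraction of anchors, so loops with an uncovered anchor are
planted negatives for the peak filter.

What it does not model: restriction-fragment size distributions (tag
positions are uniform within anchors), base-quality decay, non-uniform PCR
amplification, chromatin-state-dependent contact frequencies, and genome
repeat structure. Passing tests therefore demonstrate the correctness of
the processing logic under known ground truth, not performance on real
tissue libraries, where mappability and noise structure are harder.

Recovery scoring matches called to truth loops one-to-one (greedy by total
anchor-midpoint distance, both midpoints within the slack); precision on an
empty called set is defined as 1.0.

## Numerical and degenerate-input choices

- All in-memory intervals are 0-based half-open; BED/BEDPE pass through
  unchanged and SAM POS is converted by −1 at the single reading point.
  Abutting intervals do not overlap.
- Anchor distance uses midpoints: symmetric and stable when an anchor hull
  widens as members join.
- A PET with identical tag coordinates (span 0) is legal and classifies as
  self-ligation.
- Extension intervals clip at 0 and at the chromosome length when known.
- Cluster output order, BEDPE record order, and dedup survivor order are
  fully sorted, so reruns are byte-identical.
- The clustering sweep only tests right-anchor overlap for pairs whose
  extended left intervals overlap (sorted sweep), which is equivalent to
  the full O(n²) test; the equivalence is asserted against a brute-force
  union-find oracle in the tests.

## Problem sizes used in the shipped checks

The test suite and the reproduction script run the simulator at desk
scale: 2 × 1 Mb genomes, 10 loops, 30–120 read pairs per library, 1,000
reads for the linker oracle, 100 instances of up to 200 PETs for the
clustering oracle, and 10⁵ PETs for deduplication. These sizes exercise
every code path and keep a full run in well under a minute per library;
the pipeline itself is linear in reads apart from the O(genome) k-mer
index and the clustering sweep.

## Known limitations

- The built-in matcher's exact-uniqueness rule under-maps error-bearing
  reads and is unsuitable for repetitive genomes.
- Strand-orientation refinements of self-ligation calling (convergent /
  divergent tests) are not implemented; classification is span-only.
- No statistical significance model for clusters: loops are filtered by
  count, peaks, and distance only.
- Contact matrices are raw; no balancing or distance normalization.
- Trans PETs are reported and counted but never clustered or called as
  loops.
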