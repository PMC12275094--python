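import random

import pytest
from hypothesis import given, settings, strategies as st

from chiapet_loops import (
    BRIDGE_FORWARD,
    BRIDGE_REVERSE,
    BridgeLinker,
    LinkerCounters,
    linker_report,
    reverse_complement,
    scan_linker,
    split_pair,
)
from chiapet_loops.formats_io import SequenceRecord

from .oracles import brute_force_linker_scan

LINKER = BridgeLinker()


def random_read(rng, n=150):
    return "".join(rng.choice("ACGT") for _ in range(n))


def mutate(rng, seq, k):
    pos = rng.sample(range(len(seq)), k)
    out = list(seq)
    for p in pos:
        out[p] = rng.choice([b for b in "ACGT" if b != out[p]])
    return "".join(out)


class TestScanLinker:
    def test_planted_forward_linker_found_at_offset(self):
        # flank must not end in A: the A-tailed duplex makes "A" + forward
        # equal to reverse_rc shifted one base left, a legitimate earlier hit
        read = "TTTTT" + BRIDGE_FORWARD + "GGGGG"
        hit = scan_linker(read, LINKER)
        assert (hit.offset, hit.orientation, hit.mismatches) == (5, "forward", 0)

    def test_a_tailing_degeneracy_prefers_earlier_offset(self):
        # preceded by A, the reverse-strand reverse-complement matches one
        # base earlier with 0 mismatches; smaller offset wins the tie
        read = "TTTTA" + BRIDGE_FORWARD + "GGGGG"
        hit = scan_linker(read, LINKER)
        assert (hit.offset, hit.orientation, hit.mismatches) == (4, "reverse_rc", 0)

    @pytest.mark.parametrize(
        "orientation,query",
        [
            ("forward", BRIDGE_FORWARD),
            ("reverse", BRIDGE_REVERSE),
            ("forward_rc", reverse_complement(BRIDGE_FORWARD)),
            ("reverse_rc", reverse_complement(BRIDGE_REVERSE)),
        ],
    )
    def test_all_four_orientations_detected(self, orientation, query):
        read = "T" * 40 + query + "G" * 40
        hit = scan_linker(read, LINKER)
        assert hit is not None
        assert hit.offset == 40
        assert hit.mismatches == 0

    def test_single_substitution_reported(self):
        rng = random.Random(5)
        read = "T" * 30 + mutate(rng, BRIDGE_FORWARD, 1) + "T" * 30
        hit = scan_linker(read, LINKER)
        assert hit.mismatches == 1

    def test_three_prime_partial_needs_min_overlap(self):
        prefix12 = BRIDGE_FORWARD[:12]  # 12 >= min_overlap: detectable
        read = "C" * 100 + prefix12
        hit = scan_linker(read, LINKER)
        assert hit is not None and hit.offset == 100 and hit.match_len == 12
        prefix8 = BRIDGE_FORWARD[:8]  # below min_overlap: invisible
        assert scan_linker("C" * 100 + prefix8, LINKER) is None

    def test_agrees_with_exhaustive_scan_on_random_reads(self):
        rng = random.Random(42)
        for trial in range(300):
            read = random_read(rng)
            if trial % 3 == 0:  # plant a mutated linker at a random offset
                query = rng.choice(
                    [BRIDGE_FORWARD, BRIDGE_REVERSE,
                     reverse_complement(BRIDGE_FORWARD),
                     reverse_complement(BRIDGE_REVERSE)]
                )
                planted = mutate(rng, query, rng.randint(0, 2))
                off = rng.randint(0, len(read) - len(planted))
                read = read[:off] + planted + read[off + len(planted):]
            hit = scan_linker(read, LINKER)
            expected = brute_force_linker_scan(read, LINKER)
            if expected is None:
                assert hit is None
            else:
                assert hit is not None
                assert (hit.offset, hit.orientation, hit.mismatches,
                        hit.match_len) == expected

    def test_monotone_in_max_mismatches(self):
        rng = random.Random(7)
        reads = []
        for _ in range(100):
            read = random_read(rng)
            planted = mutate(rng, BRIDGE_FORWARD, rng.randint(0, 4))
            off = rng.randint(0, len(read) - len(planted))
            reads.append(read[:off] + planted + read[off + len(planted):])
        hits_per_level = []
        for mm in range(0, 5):
            linker = BridgeLinker(max_mismatches=mm)
            hits_per_level.append(
                sum(scan_linker(r, linker) is not None for r in reads)
            )
        assert hits_per_level == sorted(hits_per_level)

    def test_empty_read_rejected(self):
        with pytest.raises(ValueError):
            scan_linker("", LINKER)


def pair(seq1, seq2, rid="p"):
    return (SequenceRecord(f"{rid}/1", seq1, "I" * len(seq1)),
            SequenceRecord(f"{rid}/2", seq2, "I" * len(seq2)))


class TestSplitPair:
    def test_two_sided_split_keeps_five_prime_tags(self):
        rng = random.Random(1)
        # tags end in C so the A-tailing degeneracy cannot shift the junction
        tag_a = random_read(rng, 39) + "C"
        tag_b = random_read(rng, 39) + "C"
        m1, m2 = pair(tag_a + BRIDGE_FORWARD + random_read(rng, 30),
                      tag_b + BRIDGE_REVERSE + random_read(rng, 30))
        result = split_pair(m1, m2, LINKER, min_tag_len=18)
        assert result.tag1.sequence == tag_a
        assert result.tag2.sequence == tag_b
        assert result.provenance == ("split", "split")
        assert len(result.tag1.qualities) == 40

    def test_one_sided_hit_keeps_whole_other_mate(self):
        rng = random.Random(2)
        tag_a = random_read(rng, 50)
        whole = random_read(rng, 150)
        m1, m2 = pair(tag_a + BRIDGE_FORWARD + random_read(rng, 20), whole)
        result = split_pair(m1, m2, LINKER, min_tag_len=18)
        assert result.tag1.sequence == tag_a
        assert result.tag2.sequence == whole
        assert result.provenance == ("split", "whole")

    def test_no_linker_in_either_mate_rejected(self):
        rng = random.Random(9)
        counters = LinkerCounters()
        m1, m2 = pair(random_read(rng), random_read(rng))
        assert split_pair(m1, m2, LINKER, 18, counters) == "no_linker"
        assert counters.rejected["no_linker"] == 1

    def test_short_tag_rejected(self):
        rng = random.Random(4)
        m1, m2 = pair("ACGTACGTAC" + BRIDGE_FORWARD + random_read(rng, 100),
                      random_read(rng, 60) + BRIDGE_REVERSE)
        assert split_pair(m1, m2, LINKER, min_tag_len=18) == "short_tag"


class TestLinkerReport:
    def test_zero_pairs_all_zero(self):
        rows = dict(linker_report(LinkerCounters()))
        assert rows["pairs_in"] == 0
        assert rows["linker_rate"] == 0.0

    def test_linker_rate_row(self):
        counters = LinkerCounters(pairs_in=100, pairs_with_linker=90)
        assert dict(linker_report(counters))["linker_rate"] == 0.90

    def test_composition_counts_from_known_mixture(self):
        rng = random.Random(12)
        counters = LinkerCounters()
        # 7 clean pairs, 2 linker-less, 1 short-tag
        for i in range(7):
            m1, m2 = pair(random_read(rng, 40) + BRIDGE_FORWARD + random_read(rng, 40),
                          random_read(rng, 40) + BRIDGE_REVERSE, rid=f"ok{i}")
            split_pair(m1, m2, LINKER, 18, counters)
        for i in range(2):
            split_pair(*pair(random_read(rng), random_read(rng), rid=f"no{i}"),
                       LINKER, 18, counters)
        split_pair(*pair("ACGT" + BRIDGE_FORWARD + random_read(rng, 100),
                         random_read(rng), rid="short"), LINKER, 18, counters)
        rows = dict(linker_report(counters))
        assert rows["pairs_in"] == 10
        assert rows["pairs_with_linker"] == 7
        assert rows["rejected_no_linker"] == 2
        assert rows["rejected_short_tag"] == 1


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=1, max_size=200))
def test_scan_is_deterministic_and_within_bounds(read):
    hit1 = scan_linker(read, LINKER)
    hit2 = scan_linker(read, LINKER)
    assert hit1 == hit2
    if hit1 is not None:
        assert 0 <= hit1.offset <= len(read)
        assert hit1.offset + hit1.match_len <= len(read)
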