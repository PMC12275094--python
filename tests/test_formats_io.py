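import pytest

from chiapet_loops import (
    FormatError,
    GenomicInterval,
    read_bed,
    read_bedpe,
    read_fastq,
    read_sam_pairs,
    write_bed,
    write_bedpe,
)
from chiapet_loops.clustering import PETCluster
from chiapet_loops.formats_io import strip_mate_suffix, write_fastq, SequenceRecord


def write_lines(path, lines):
    path.write_text("\n".join(lines) + "\n")
    return str(path)


class TestFastq:
    def test_pairs_stream_in_order_with_qualities(self, tmp_path):
        fq1 = write_lines(tmp_path / "r1.fq", ["@r1/1", "ACGT", "+", "IIII"])
        fq2 = write_lines(tmp_path / "r2.fq", ["@r1/2", "TTTT", "+", "IIII"])
        pairs = list(read_fastq(fq1, fq2))
        assert len(pairs) == 1
        m1, m2 = pairs[0]
        assert (m1.sequence, m2.sequence) == ("ACGT", "TTTT")
        assert m1.qualities == "IIII"

    def test_empty_files_give_empty_stream(self, tmp_path):
        fq1 = tmp_path / "a.fq"
        fq2 = tmp_path / "b.fq"
        fq1.write_text("")
        fq2.write_text("")
        assert list(read_fastq(str(fq1), str(fq2))) == []

    def test_mismatched_mate_counts_name_offending_record(self, tmp_path):
        lines1 = []
        lines2 = []
        for i in range(10):
            lines1 += [f"@r{i}/1", "ACGT", "+", "IIII"]
            if i < 9:
                lines2 += [f"@r{i}/2", "ACGT", "+", "IIII"]
        fq1 = write_lines(tmp_path / "r1.fq", lines1)
        fq2 = write_lines(tmp_path / "r2.fq", lines2)
        with pytest.raises(FormatError, match="record 10"):
            list(read_fastq(fq1, fq2))

    def test_mate_id_mismatch_is_fatal(self, tmp_path):
        fq1 = write_lines(tmp_path / "r1.fq", ["@a/1", "ACGT", "+", "IIII"])
        fq2 = write_lines(tmp_path / "r2.fq", ["@b/2", "ACGT", "+", "IIII"])
        with pytest.raises(FormatError, match="mismatch at record 1"):
            list(read_fastq(fq1, fq2))

    @pytest.mark.parametrize(
        "raw,expected",
        [("r1/1", "r1"), ("r1/2", "r1"), ("r1 1:N:0", "r1"), ("r1", "r1")],
    )
    def test_mate_suffix_stripping(self, raw, expected):
        assert strip_mate_suffix(raw) == expected


class TestBed:
    def test_basic_parse_and_comment_skip(self, tmp_path):
        bed = write_lines(
            tmp_path / "x.bed",
            ["# comment", "track name=x", "chr1\t100\t200", "chr2\t5\t10\tpeakA"],
        )
        ivs = read_bed(bed)
        assert ivs[0] == GenomicInterval("chr1", 100, 200)
        assert ivs[1].name == "peakA"

    def test_inverted_coordinates_fatal_with_line_number(self, tmp_path):
        bed = write_lines(tmp_path / "x.bed", ["chr1\t100\t200", "chr1\t200\t100"])
        with pytest.raises(FormatError, match=":2"):
            read_bed(bed)

    def test_roundtrip_bit_exact(self, tmp_path):
        ivs = [GenomicInterval("chr2", 7, 99, "a"), GenomicInterval("chr1", 0, 5)]
        path = tmp_path / "rt.bed"
        write_bed(ivs, str(path))
        assert set(read_bed(str(path))) == set(ivs)


class TestBedpe:
    def test_ten_column_layout_and_score(self, tmp_path):
        cluster = PETCluster(
            GenomicInterval("chr1", 100, 250),
            GenomicInterval("chr1", 5000, 5200),
            pet_count=6,
            member_ids=[],
        )
        path = tmp_path / "c.bedpe"
        write_bedpe([cluster], str(path))
        line = path.read_text().strip()
        assert line == "chr1\t100\t250\tchr1\t5000\t5200\tcluster_1\t6\t.\t."

    def test_sorted_by_start1_then_start2(self, tmp_path):
        clusters = [
            PETCluster(GenomicInterval("chr1", 100, 200),
                       GenomicInterval("chr1", 9000, 9100), 4, []),
            PETCluster(GenomicInterval("chr1", 100, 200),
                       GenomicInterval("chr1", 8000, 8100), 5, []),
        ]
        path = tmp_path / "c.bedpe"
        write_bedpe(clusters, str(path))
        records = read_bedpe(str(path))
        assert [r.anchor2.start for r in records] == [8000, 9000]

    def test_empty_list_gives_empty_file(self, tmp_path):
        path = tmp_path / "c.bedpe"
        write_bedpe([], str(path))
        assert path.read_text() == ""

    def test_roundtrip_coordinates(self, tmp_path):
        cluster = PETCluster(
            GenomicInterval("chr3", 17, 93),
            GenomicInterval("chr3", 10001, 10777),
            pet_count=9,
            member_ids=[],
        )
        path = tmp_path / "rt.bedpe"
        write_bedpe([cluster], str(path))
        rec = read_bedpe(str(path))[0]
        assert (rec.anchor1, rec.anchor2, rec.score) == (
            cluster.anchor1, cluster.anchor2, 9
        )


SAM_HEADER = ["@HD\tVN:1.6", "@SQ\tSN:chr1\tLN:100000"]


def sam_line(name, flag, pos, mapq, cigar="50M"):
    return (
        f"{name}\t{flag}\t chr1\t{pos}\t{mapq}\t{cigar}\t*\t0\t0\t"
        f"{'A' * 50}\t{'I' * 50}"
    ).replace(" ", "")


class TestSamPairs:
    def make_sam(self, tmp_path, lines):
        path = tmp_path / "x.sam"
        path.write_text("\n".join(SAM_HEADER + lines) + "\n")
        return str(path)

    def test_mapq_threshold_is_strictly_greater_than_30(self, tmp_path):
        sam = self.make_sam(
            tmp_path,
            [
                sam_line("keep", 0, 1001, 31), sam_line("keep", 16, 2001, 60),
                sam_line("drop", 0, 1001, 30), sam_line("drop", 16, 2001, 60),
            ],
        )
        pairs = list(read_sam_pairs(sam, min_mapq=31))
        assert [p[0].read_id for p in pairs] == ["keep"]

    def test_pos5_conversion_per_strand(self, tmp_path):
        # SAM POS 1001 (1-based) -> 1000; reverse mate spans [2000, 2050) so
        # its 5'-most base sits at 2049
        sam = self.make_sam(
            tmp_path,
            [sam_line("r", 0, 1001, 60), sam_line("r", 16, 2001, 60)],
        )
        fwd, rev = list(read_sam_pairs(sam))[0]
        assert (fwd.pos5, fwd.strand) == (1000, "+")
        assert (rev.pos5, rev.strand) == (2049, "-")

    def test_secondary_records_ignored(self, tmp_path):
        sam = self.make_sam(
            tmp_path,
            [
                sam_line("r", 0, 1001, 60),
                sam_line("r", 256, 5001, 60),  # secondary copy of mate 1
                sam_line("r", 16, 2001, 60),
            ],
        )
        pairs = list(read_sam_pairs(sam))
        assert len(pairs) == 1
        assert {t.pos5 for t in pairs[0]} == {1000, 2049}


def test_fastq_writer_reader_roundtrip(tmp_path):
    recs = [SequenceRecord("x/1", "ACGTN", "IIIII")]
    path = tmp_path / "w.fq"
    write_fastq(recs, str(path))
    with open(path) as fh:
        assert fh.read() == "@x/1\nACGTN\n+\nIIIII\n"
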