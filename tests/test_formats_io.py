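"""I/O layer: coordinate conventions, loaders, and event-table round trips."""

import pytest

from tepool.formats_io import (
    AbsenceEvent,
    GenomicInterval,
    InsertionEvent,
    load_te_annotation,
    load_te_library,
    read_alignments,
    read_events,
    write_events,
    write_events_bed,
    revcomp,
)

from conftest import write_bam


class TestGenomicInterval:
    def test_rejects_degenerate_intervals(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)

    def test_overlap_and_intersection(self):
        a = GenomicInterval("chr1", 100, 600)
        b = GenomicInterval("chr1", 400, 900)
        c = GenomicInterval("chr1", 700, 900)
        assert a.overlaps(b) and not a.overlaps(c)
        inter = a.intersection(b)
        assert (inter.start, inter.end) == (400, 600)
        assert a.intersection(c) is None

    def test_junction_slots_are_inclusive_of_both_ends(self):
        iv = GenomicInterval("chr1", 100, 200)
        assert iv.contains_junction(100)
        assert iv.contains_junction(200)
        assert not iv.contains_junction(201)


class TestReadAlignments:
    def test_pair_count_and_clip_parsing(self, tmp_path):
        seq = "A" * 90
        recs = []
        for i, (s1, s2) in enumerate([(1000, 1400), (2000, 2400)]):
            recs.append(dict(name=f"p{i}", flag=0x1 | 0x40, contig="chr1",
                             start=s1, cigar="90M", seq=seq,
                             mate_contig="chr1", mate_start=s2))
            recs.append(dict(name=f"p{i}", flag=0x1 | 0x80 | 0x10, contig="chr1",
                             start=s2, cigar="10S80M", seq=seq,
                             mate_contig="chr1", mate_start=s1))
        bam = write_bam(tmp_path / "two_pairs.bam", recs)
        reads = list(read_alignments(bam))
        assert len(reads) == 4
        clipped = [r for r in reads if r.clip_left]
        assert len(clipped) == 2
        assert clipped[0].clip_left == 10
        assert clipped[0].end - clipped[0].start == 80
        assert clipped[0].clip_left_seq == seq[:10]

    def test_empty_region_yields_nothing(self, tmp_path):
        bam = write_bam(
            tmp_path / "one.bam",
            [dict(name="r", flag=0, contig="chr1", start=100,
                  cigar="90M", seq="C" * 90)],
        )
        region = GenomicInterval("chr1", 50_000, 60_000)
        assert list(read_alignments(bam, region=region)) == []

    def test_region_partition_covers_all_reads(self, tmp_path):
        recs = [
            dict(name=f"r{i}", flag=0, contig="chr1", start=s,
                 cigar="90M", seq="G" * 90)
            for i, s in enumerate(range(0, 9000, 450))
        ]
        bam = write_bam(tmp_path / "many.bam", recs)
        whole = {(r.name, r.start) for r in read_alignments(bam)}
        # assign each read to the region containing its start
        parts = []
        for lo in range(0, 10_000, 2_000):
            region = GenomicInterval("chr1", lo, lo + 2_000)
            parts.append(
                {(r.name, r.start) for r in read_alignments(bam, region=region)
                 if lo <= r.start < lo + 2_000}
            )
        assert set.union(*parts) == whole
        assert sum(len(p) for p in parts) == len(whole)


class TestLibraryLoading:
    def test_loads_records_with_tokenized_names(self, tmp_path):
        fa = tmp_path / "lib.fa"
        fa.write_text(
            ">pogo description text\nACGTACGTACGTACGTACGT\n"
            ">roo\nacgtacgtacgtacgtacgt\n"
            ">jockey extra\nTTTTACGTACGTACGTACGT\n"
        )
        lib = load_te_library(fa)
        assert len(lib) == 3
        assert "pogo" in lib and "jockey" in lib
        # lowercase input is normalized
        assert lib["roo"] == "ACGTACGTACGTACGTACGT"

    def test_duplicate_names_and_empty_file_error(self, tmp_path):
        dup = tmp_path / "dup.fa"
        dup.write_text(">a\nACGT\n>a\nACGT\n")
        with pytest.raises(ValueError):
            load_te_library(dup)
        empty = tmp_path / "empty.fa"
        empty.write_text("")
        with pytest.raises(ValueError):
            load_te_library(empty)


class TestAnnotationLoading:
    def test_repeatmasker_coordinates_convert_to_half_open(self, tmp_path):
        out = tmp_path / "rm.out"
        out.write_text(
            "  SW  perc perc perc  query     begin  end  left  strand matrix\n"
            "score div. del. ins.  sequence\n"
            "\n"
            " 463  10.3  0.0  0.0  chr2L     1001   1500  (0)   +  roo  LTR/Pao  1 500 (0) 1\n"
        )
        ann = load_te_annotation(out, dialect="repeatmasker_out")
        copy = ann.copies[0]
        assert (copy.interval.start, copy.interval.end) == (1000, 1500)
        assert copy.family == "roo"

    def test_bed_taken_as_is_and_overlaps_retained(self, tmp_path):
        bed = tmp_path / "te.bed"
        bed.write_text(
            "chr2L\t999\t1500\troo\n"
            "chr2L\t1200\t1600\tjockey\n"
        )
        ann = load_te_annotation(bed, dialect="bed")
        assert len(ann) == 2
        assert ann.copies[0].interval.start == 999
        assert len(ann.overlapping("chr2L", 1300, 1400)) == 2

    def test_unparseable_line_names_line_number(self, tmp_path):
        bad = tmp_path / "bad.bed"
        bad.write_text("chr1\t100\t200\tok\nchr1\tnotanumber\t300\tbad\n")
        with pytest.raises(ValueError, match=":2:"):
            load_te_annotation(bad, dialect="bed")

    def test_containment_requires_full_overlap(self, tmp_path):
        bed = tmp_path / "te.bed"
        bed.write_text("chr1\t1000\t2000\troo\n")
        ann = load_te_annotation(bed, dialect="bed")
        assert len(ann.contained_in("chr1", 900, 2100)) == 1
        assert ann.contained_in("chr1", 1100, 2100) == []


class TestEventTables:
    def _events(self):
        return [
            InsertionEvent(
                contig="chr1", family="roo", strand="+",
                interval=GenomicInterval("chr1", 1000, 1200),
                junction_plus=1105, junction_minus=1100,
                junction_resolution="base", support_sides="both",
                T=3, R=1, frequency=3 / 4,
            ),
            InsertionEvent(
                contig="chr1", family="jockey", strand="-",
                interval=GenomicInterval("chr1", 1000, 1150),
                junction_resolution="interval", support_sides="left_only",
                T=2, R=0, frequency=1.0,
            ),
            AbsenceEvent(
                contig="chr1", family="pogo", strand="+",
                interval=GenomicInterval("chr1", 5000, 7000),
                copy_ids=("pogo#3",), junction_plus=5000, junction_minus=7000,
                junction_resolution="annotated", T=5, R=5, frequency=0.5,
            ),
        ]

    def test_round_trip_preserves_fields(self, tmp_path):
        path = tmp_path / "events.tsv"
        write_events(self._events(), path, header_comments=["#config=x"])
        back = read_events(path)
        assert len(back) == 3
        by_family = {e.family: e for e in back}
        assert by_family["roo"].junction_plus == 1105
        assert by_family["roo"].frequency == pytest.approx(0.75)
        assert by_family["pogo"].copy_ids == ("pogo#3",)
        assert by_family["jockey"].junction_plus is None
        # sort: same start -> family order jockey before roo
        assert [e.family for e in back] == ["jockey", "roo", "pogo"]

    def test_frequency_formatting_and_empty_table(self, tmp_path):
        path = tmp_path / "events.tsv"
        write_events(self._events()[:1], path)
        line = path.read_text().splitlines()[1]
        assert "0.750000" in line
        write_events([], path)
        assert len(path.read_text().splitlines()) == 1  # header only
        assert read_events(path) == []

    def test_bed_export_scores_frequency(self, tmp_path):
        path = tmp_path / "events.bed"
        write_events_bed(self._events(), path)
        lines = path.read_text().splitlines()
        assert len(lines) == 3
        fields = lines[1].split("\t")  # roo row (jockey sorts first)
        assert fields[3] == "roo"
        assert fields[4] == "750"


def test_revcomp_involution():
    s = "ACGTNacgt".upper()
    assert revcomp(revcomp(s)) == s
    assert revcomp("ACGTN") == "NACGT"
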