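"""Coordinate model, projection geometry and format round-trips."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from m6akit import (
    FragmentLibrary,
    FragmentRecord,
    GenomeSequence,
    TranscriptModel,
    project_fragment,
    read_annotation,
    read_fragments,
    read_table,
    write_annotation,
    write_coverage,
    write_fragments,
    write_genome,
    write_table,
)
from m6akit.io import read_coverage, read_genome
from m6akit.models import reverse_complement


@pytest.fixture
def two_exon():
    # exons 1..100 and 201..300 (GFF convention), CDS 51..250
    return TranscriptModel("t1", "chr1", "+", [(0, 100), (200, 300)],
                           cds_span=(50, 250))


class TestTranscriptModel:
    def test_single_exon_coordinates(self):
        t = TranscriptModel("t", "chr1", "+", [(0, 300)])
        assert t.spliced_length == 300

    def test_two_exon_spliced_length(self, two_exon):
        assert two_exon.spliced_length == 200

    def test_stop_codon_projection_through_exon_map(self, two_exon):
        # last CDS base is genomic 249, transcript position 149
        assert two_exon.stop_codon_tpos == 149

    def test_minus_strand_stop(self):
        t = TranscriptModel("t", "chr1", "-", [(0, 300)], cds_span=(50, 250))
        assert t.stop_codon_tpos == t.genomic_to_transcript(50)

    @pytest.mark.parametrize("exons", [[(10, 10)], [(0, 50), (40, 90)]])
    def test_invalid_exons_rejected(self, exons):
        with pytest.raises(ValueError):
            TranscriptModel("t", "chr1", "+", exons)

    def test_transcript_to_genomic_roundtrip(self, two_exon):
        for tpos in range(two_exon.spliced_length):
            g = two_exon.transcript_to_genomic(tpos)
            assert two_exon.genomic_to_transcript(g) == tpos


class TestProjection:
    def test_plain_overlap(self):
        t = TranscriptModel("t", "chr1", "+", [(0, 300)])
        assert project_fragment(FragmentRecord("chr1", 0, 50), t) == (0, 50)

    def test_intron_spanning_fragment(self, two_exon):
        assert project_fragment(FragmentRecord("chr1", 90, 210), two_exon) == (90, 110)

    def test_minus_strand_reversal(self):
        t = TranscriptModel("t", "chr1", "-", [(0, 300)])
        assert project_fragment(FragmentRecord("chr1", 0, 50), t) == (250, 300)

    def test_no_overlap_is_none(self, two_exon):
        assert project_fragment(FragmentRecord("chr1", 120, 180), two_exon) is None

    @given(st.data())
    def test_projected_length_never_exceeds_fragment(self, data):
        start = data.draw(st.integers(0, 400))
        length = data.draw(st.integers(1, 200))
        t = TranscriptModel("t", "chr1",
                            data.draw(st.sampled_from("+-")),
                            [(0, 100), (150, 300), (320, 500)])
        res = project_fragment(FragmentRecord("chr1", start, start + length), t)
        if res is not None:
            assert 0 < res[1] - res[0] <= length

    @given(st.integers(0, 80), st.integers(1, 20))
    def test_fully_exonic_fragment_conserves_length(self, start, length):
        t = TranscriptModel("t", "chr1", "+", [(0, 100), (150, 300)])
        res = project_fragment(FragmentRecord("chr1", start, start + length), t)
        assert res[1] - res[0] == length

    def test_minus_strand_matches_revcomp_layout(self):
        # projecting on '-' then reversing coordinates equals projecting the
        # mirrored layout on '+'
        L = 300
        t_minus = TranscriptModel("t", "chr1", "-", [(0, L)])
        t_plus = TranscriptModel("t", "chr1", "+", [(0, L)])
        frag = FragmentRecord("chr1", 40, 90)
        mirrored = FragmentRecord("chr1", L - 90, L - 40)
        a = project_fragment(frag, t_minus)
        b = project_fragment(mirrored, t_plus)
        assert a == b


class TestAnnotationIO:
    def test_gff3_round_trip(self, two_exon, tmp_path):
        other = TranscriptModel("t2", "chr1", "-", [(400, 700)], biotype="rRNA")
        path = tmp_path / "a.gff3"
        write_annotation([two_exon, other], str(path))
        models = {m.transcript_id: m for m in read_annotation(str(path))}
        assert models["t1"].exons == two_exon.exons
        assert models["t1"].cds_span == two_exon.cds_span
        assert models["t2"].strand == "-"
        assert models["t2"].biotype == "rRNA"

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.gff3"
        path.write_text("##gff-version 3\nchr1\tx\tgene\tnot\tenough\n")
        with pytest.raises(ValueError, match="line 2"):
            read_annotation(str(path))


class TestFragmentIO:
    def test_empty_bed(self, tmp_path):
        path = tmp_path / "e.bed"
        path.write_text("")
        lib = read_fragments(str(path), "leaves", 1, "m6A")
        assert lib.total_mapped == 0 and lib.fragments == []

    def test_three_records(self, tmp_path):
        path = tmp_path / "f.bed"
        path.write_text("chr1\t0\t100\nchr1\t50\t150\nchr2\t5\t10\n")
        lib = read_fragments(str(path), "roots", 2, "mRNA")
        assert lib.total_mapped == 3

    def test_inverted_interval_rejected(self, tmp_path):
        path = tmp_path / "g.bed"
        path.write_text("chr1\t100\t90\n")
        with pytest.raises(ValueError):
            read_fragments(str(path), "leaves", 1, "m6A")

    def test_bed_round_trip(self, tmp_path):
        lib = FragmentLibrary("leaves", 1, "m6A", [
            FragmentRecord("chr1", 5, 80), FragmentRecord("chr1", 0, 100)])
        path = tmp_path / "rt.bed"
        write_fragments(lib, str(path))
        back = read_fragments(str(path), "leaves", 1, "m6A")
        assert sorted((f.start, f.end) for f in back.fragments) == [(0, 100), (5, 80)]


class TestCoverageAndTables:
    def test_single_fragment_coverage(self, tmp_path):
        lib = FragmentLibrary("leaves", 1, "m6A", [FragmentRecord("chr1", 0, 100)])
        path = tmp_path / "c.bg"
        write_coverage([lib], str(path))
        df = read_coverage(str(path))
        assert df.values.tolist() == [["chr1", 0, 100, 1]]

    def test_overlapping_fragments_step_function(self, tmp_path):
        lib = FragmentLibrary("leaves", 1, "m6A", [
            FragmentRecord("chr1", 0, 100), FragmentRecord("chr1", 50, 150)])
        path = tmp_path / "c.bg"
        write_coverage([lib], str(path))
        df = read_coverage(str(path))
        assert df["depth"].tolist() == [1, 2, 1]
        assert df["start"].tolist() == [0, 50, 100]

    def test_table_round_trip(self, tmp_path):
        df = pd.DataFrame({
            "transcript_id": ["b", "a"], "fpkm": [1.25, 3.5], "m6a_count": [3, 0]})
        path = tmp_path / "t.tsv"
        write_table(df, str(path))
        back = read_table(str(path))
        assert back["transcript_id"].tolist() == ["a", "b"]  # deterministic order
        assert back.set_index("transcript_id")["fpkm"]["b"] == 1.25

    def test_genome_round_trip(self, tmp_path):
        g = GenomeSequence({"chr1": "ACGTACGTNN", "chr2": "TTTT"})
        path = tmp_path / "g.fa"
        write_genome(g, str(path))
        back = read_genome(str(path))
        assert back.fetch("chr1", 0, 10) == "ACGTACGTNN"
        assert back.fetch("chr2", 0, 4, strand="-") == "AAAA"


def test_reverse_complement():
    assert reverse_complement("AACGT") == "ACGTT"
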