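"""Transcript coordinate arithmetic: HGVS parsing, c<->g conversion against
an exhaustive enumeration oracle, codon indexing and sequence extraction."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from conftest import enumerate_coordinate_table, random_transcript
from pseudoexon.genemodel import (
    CodingPosition,
    CoordinateError,
    HgvsParseError,
    TranscriptModel,
    c_to_g,
    codon_index,
    extract_sequence,
    format_cpos,
    g_to_c,
    parse_cpos,
    read_bed12,
    read_gff3,
    write_bed12,
    write_gff3,
)


class TestParseCpos:
    @pytest.mark.parametrize(
        "text, base, offset",
        [
            ("c.531+1482", 531, 1482),
            ("c.532", 532, 0),
            ("c.101-50", 101, -50),
            ("c. 531 + 1482", 531, 1482),  # whitespace tolerated
        ],
    )
    def test_examples(self, text, base, offset):
        p = parse_cpos(text)
        assert (p.base, p.offset) == (base, offset)

    @pytest.mark.parametrize(
        "bad", ["c.0", "c.10+0", "c.-5", "g.100", "c.12++3", "c.", "531+1482"]
    )
    def test_malformed(self, bad):
        with pytest.raises(HgvsParseError):
            parse_cpos(bad)

    @given(
        base=st.integers(1, 10_000),
        offset=st.integers(-5_000, 5_000),
    )
    def test_format_parse_roundtrip(self, base, offset):
        p = CodingPosition(base, offset)
        assert parse_cpos(format_cpos(p)) == p
        assert " " not in format_cpos(p)

    def test_transcript_order(self):
        order = [
            parse_cpos(s)
            for s in ["c.100", "c.100+1", "c.100+999", "c.101-999", "c.101-1", "c.101"]
        ]
        assert order == sorted(order)


class TestToyGeneConversion:
    @pytest.mark.parametrize(
        "cpos, g",
        [("c.1", 101), ("c.100", 200), ("c.100+1", 201), ("c.100+50", 250),
         ("c.101-1", 300), ("c.101", 301), ("c.300", 600)],
    )
    def test_c_to_g(self, toyg1, cpos, g):
        assert c_to_g(toyg1, parse_cpos(cpos)) == g

    @pytest.mark.parametrize(
        "g, cpos",
        [(250, "c.100+50"), (301, "c.101"), (101, "c.1"),
         (251, "c.101-50"), (201, "c.100+1")],
    )
    def test_g_to_c(self, toyg1, g, cpos):
        assert format_cpos(g_to_c(toyg1, g)) == cpos

    def test_offset_walks_past_intron(self, toyg1):
        with pytest.raises(CoordinateError):
            c_to_g(toyg1, parse_cpos("c.100+101"))

    def test_base_beyond_cds(self, toyg1):
        with pytest.raises(CoordinateError):
            c_to_g(toyg1, parse_cpos("c.301"))

    def test_offset_from_internal_base_rejected(self, toyg1):
        with pytest.raises(CoordinateError):
            c_to_g(toyg1, parse_cpos("c.50+3"))

    def test_g_outside_span(self, toyg1):
        with pytest.raises(CoordinateError):
            g_to_c(toyg1, 50)
        with pytest.raises(CoordinateError):
            g_to_c(toyg1, 601)


class TestEnumerationOracle:
    """c_to_g and g_to_c agree with the exhaustive position walk and are
    mutually inverse, on random transcripts of both strands."""

    @pytest.mark.parametrize("seed", range(25))
    def test_conversions_match_oracle(self, seed):
        tm = random_transcript(seed)
        table = enumerate_coordinate_table(tm)
        for (base, offset), g in table.items():
            p = CodingPosition(base, offset)
            assert c_to_g(tm, p) == g, f"{tm.transcript_id} {format_cpos(p)}"
            assert g_to_c(tm, g) == p, f"{tm.transcript_id} g.{g}"

    @pytest.mark.parametrize("seed", range(25))
    def test_midpoint_balance(self, seed):
        """Per intron, '+'- and '-'-assigned position counts differ by <= 1."""
        tm = random_transcript(seed)
        table = enumerate_coordinate_table(tm)
        for i, length in enumerate(tm.intron_lengths_transcript_order()):
            plus = sum(1 for (b, o) in table if o > 0 and _intron_of(tm, b, o) == i)
            minus = sum(1 for (b, o) in table if o < 0 and _intron_of(tm, b, o) == i)
            assert plus + minus == length
            assert abs(plus - minus) <= 1


def _intron_of(tm: TranscriptModel, base: int, offset: int) -> int:
    spans = tm.exon_transcript_spans()
    t = tm.cds_start_c + base - 1
    for i in range(tm.n_introns):
        if offset > 0 and t == spans[i][1]:
            return i
        if offset < 0 and t == spans[i + 1][0]:
            return i
    return -1


class TestCodonIndex:
    @pytest.mark.parametrize("base, idx", [(532, 178), (1, 1), (531, 177), (3, 1), (4, 2)])
    def test_examples(self, base, idx):
        assert codon_index(CodingPosition(base)) == idx

    @given(k=st.integers(1, 4000))
    def test_exact_multiples_and_monotone(self, k):
        assert codon_index(CodingPosition(3 * k)) == k
        assert codon_index(CodingPosition(3 * k + 1)) == k + 1

    def test_intronic_rejected(self):
        with pytest.raises(CoordinateError):
            codon_index(CodingPosition(531, 1482))


class TestExtractSequence:
    def test_first_codon(self, toyg1):
        chrom = toyg1.sequence_source["chrT"]
        assert extract_sequence(toyg1, parse_cpos("c.1"), parse_cpos("c.3")) == chrom[100:103]

    def test_span_length_equals_inclusive_span(self, toyg1):
        s = extract_sequence(toyg1, parse_cpos("c.100+10"), parse_cpos("c.100+65"))
        assert len(s) == 56

    def test_minus_strand_reverse_complement(self):
        from Bio.Seq import Seq

        plus = random_transcript(3, strand="+")
        spans_plus = extract_sequence(plus, parse_cpos("c.1"), parse_cpos("c.5"))
        minus = random_transcript(3, strand="-")
        got = extract_sequence(minus, parse_cpos("c.1"), parse_cpos("c.5"))
        # first 5 CDS bases read in transcript sense; on '-' they are the
        # reverse complement of the corresponding plus-strand genomic slice
        g1, g2 = c_to_g(minus, parse_cpos("c.1")), c_to_g(minus, parse_cpos("c.5"))
        raw = minus.sequence_source["chrR"][min(g1, g2) - 1 : max(g1, g2)]
        assert got == str(Seq(raw).reverse_complement())
        assert len(got) == len(spans_plus) == 5

    @pytest.mark.parametrize("seed", range(8))
    def test_length_invariant_both_strands(self, seed):
        tm = random_transcript(seed)
        table = enumerate_coordinate_table(tm)
        keys = sorted(CodingPosition(b, o) for b, o in table)
        a, b = keys[1], keys[len(keys) // 2]
        span = abs(c_to_g(tm, b) - c_to_g(tm, a)) + 1
        assert len(extract_sequence(tm, a, b)) == span

    def test_missing_sequence_source(self, toyg1):
        bare = TranscriptModel("X", "chrT", "+", toyg1.exons, 1, 300)
        from pseudoexon.genemodel import GeneModelError

        with pytest.raises(GeneModelError):
            extract_sequence(bare, parse_cpos("c.1"), parse_cpos("c.3"))

    def test_inverted_span(self, toyg1):
        with pytest.raises(CoordinateError):
            extract_sequence(toyg1, parse_cpos("c.10"), parse_cpos("c.5"))


class TestModelInvariants:
    def test_overlapping_exons_rejected(self):
        from pseudoexon.genemodel import GeneModelError

        with pytest.raises(GeneModelError):
            TranscriptModel("B", "c", "+", [(1, 10), (5, 20)], 1, 10)
        with pytest.raises(GeneModelError):
            TranscriptModel("B", "c", "+", [(10, 5)], 1, 3)
        with pytest.raises(GeneModelError):
            TranscriptModel("B", "c", "+", [(1, 10)], 1, 11)  # CDS too long


class TestGeneModelIO:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_gff3_roundtrip(self, tmp_path, seed):
        tm = random_transcript(seed)
        path = tmp_path / "m.gff3"
        write_gff3([tm], str(path))
        (back,) = read_gff3(str(path))
        assert back.exons == list(tm.exons)
        assert back.strand == tm.strand
        assert (back.cds_start_c, back.cds_end_c) == (tm.cds_start_c, tm.cds_end_c)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_bed12_roundtrip(self, tmp_path, seed):
        tm = random_transcript(seed)
        path = tmp_path / "m.bed"
        write_bed12([tm], str(path))
        (back,) = read_bed12(str(path))
        assert back.exons == list(tm.exons)
        assert (back.cds_start_c, back.cds_end_c) == (tm.cds_start_c, tm.cds_end_c)
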