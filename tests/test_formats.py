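import pytest

from oysterlsu.formats import (
    CircularGenome,
    CoordinateError,
    FormatError,
    GeneFeature,
    SecondaryStructure,
    read_ct,
    read_dotbracket,
    read_fasta,
    read_gff3,
    reverse_complement,
    to_dotbracket,
    transcribe,
    write_ct,
    write_fasta,
    write_gff3,
)


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">x\nACGT\n")
        assert read_fasta(p) == [("x", "ACGT")]

    def test_lowercase_uppercased(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">x\nacgt\n>y\ntTgG\n")
        assert read_fasta(p) == [("x", "ACGT"), ("y", "TTGG")]

    def test_illegal_char_names_position(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">x\nACZT\n")
        with pytest.raises(FormatError, match="position 3"):
            read_fasta(p)

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">x\nACGT\n>x\nACGT\n")
        with pytest.raises(FormatError, match="x"):
            read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text("")
        with pytest.raises(FormatError):
            read_fasta(p)

    def test_alphabet_normalization(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">x\nACGU\n")
        assert read_fasta(p, alphabet="dna") == [("x", "ACGT")]
        assert read_fasta(p, alphabet="rna") == [("x", "ACGU")]

    def test_roundtrip(self, tmp_path):
        p = tmp_path / "a.fasta"
        records = [("a", "ACGT" * 40), ("b", "TTTT")]
        write_fasta(records, p)
        assert read_fasta(p) == records


class TestGenomeCoordinates:
    def test_origin_spanning_feature_length(self):
        # positions 95..100 plus 1..5 on a 100-nt circle
        g = CircularGenome("g", "ACGT" * 25, is_circular=True)
        f = GeneFeature("wrap", 95, 5)
        assert f.length(len(g)) == 11

    def test_wrap_extract_matches_concatenation(self):
        g = CircularGenome("g", "ACGTACGTAC", is_circular=True)
        assert g.extract(9, 2) == g.sequence[8:] + g.sequence[:2]

    def test_wrap_on_linear_rejected(self):
        g = CircularGenome("g", "ACGTACGTAC", is_circular=False)
        with pytest.raises(CoordinateError):
            g.extract(9, 2)

    def test_minus_strand_extract(self):
        g = CircularGenome("g", "AACCGGTTAA")
        assert g.extract(3, 6, strand="-") == reverse_complement("CCGG")


class TestGff3:
    def _genome(self, n=100):
        return CircularGenome("chr", "A" * n, is_circular=True)

    def test_basic_line(self, tmp_path):
        p = tmp_path / "f.gff3"
        p.write_text("chr\t.\tgene\t10\t20\t.\t+\t.\tID=g1\n")
        feats = read_gff3(p, self._genome())
        assert (feats[0].start, feats[0].end, feats[0].strand) == (10, 20, "+")

    def test_column_count_violation(self, tmp_path):
        p = tmp_path / "f.gff3"
        p.write_text("chr\tgene\t10\t20\n")
        with pytest.raises(FormatError, match="9"):
            read_gff3(p, self._genome())

    def test_origin_spanning_feature_accepted_on_circle(self, tmp_path):
        p = tmp_path / "f.gff3"
        p.write_text("chr\t.\tgene\t95\t5\t.\t+\t.\tID=w\n")
        feats = read_gff3(p, self._genome(100))
        assert feats[0].length(100) == 11

    def test_out_of_range_coordinate_rejected(self, tmp_path):
        p = tmp_path / "f.gff3"
        p.write_text("chr\t.\tgene\t10\t200\t.\t+\t.\tID=g1\n")
        with pytest.raises(CoordinateError):
            read_gff3(p, self._genome(100))

    def test_write_read_roundtrip(self, tmp_path):
        g = CircularGenome(
            "chr", "A" * 50,
            features=(GeneFeature("t1", 5, 10, "+", "tRNA"),
                      GeneFeature("r1", 20, 40, "-", "rRNA_fragment")),
        )
        p = tmp_path / "f.gff3"
        write_gff3(g, p)
        feats = read_gff3(p, g)
        assert [(f.name, f.start, f.end, f.strand, f.kind) for f in feats] == [
            ("t1", 5, 10, "+", "tRNA"), ("r1", 20, 40, "-", "rRNA_fragment")
        ]


class TestDotBracket:
    def test_nested(self):
        s = read_dotbracket("((..))")
        assert s.pairs == {(1, 6), (2, 5)}
        assert not s.pseudoknot

    def test_unpaired(self):
        assert read_dotbracket("......").pairs == frozenset()

    def test_pseudoknot_layer(self):
        s = read_dotbracket("([)]")
        assert s.pairs == {(1, 3), (2, 4)}
        assert s.pseudoknot

    def test_unmatched_bracket_names_position(self):
        with pytest.raises(FormatError, match="position 1"):
            read_dotbracket("(()")
        with pytest.raises(FormatError, match="position 2"):
            read_dotbracket(".)..")

    def test_dotbracket_roundtrip(self):
        for text in ["((..))", "......", "(((...)))..((.))", "([)]"]:
            assert to_dotbracket(read_dotbracket(text)) == text


class TestCt:
    def test_roundtrip_identity(self, tmp_path):
        s = read_dotbracket("((..))", sequence="GGAACC")
        p = tmp_path / "s.ct"
        write_ct(s, p)
        back = read_ct(p)
        assert back.pairs == s.pairs
        assert back.sequence == s.sequence

    def test_empty_structure_roundtrip(self, tmp_path):
        s = SecondaryStructure(sequence="ACGU")
        p = tmp_path / "s.ct"
        write_ct(s, p)
        assert read_ct(p).pairs == frozenset()

    def test_inconsistent_pairing_names_rows(self, tmp_path):
        p = tmp_path / "bad.ct"
        p.write_text(
            "3\tbad\n"
            "1\tG\t0\t2\t3\t1\n"
            "2\tA\t1\t3\t0\t2\n"
            "3\tC\t2\t0\t2\t3\n"  # 3 pairs 2, but 2 pairs 0
        )
        with pytest.raises(FormatError, match="inconsistent"):
            read_ct(p)


class TestStructureInvariants:
    def test_position_in_two_pairs_rejected(self):
        with pytest.raises(FormatError):
            SecondaryStructure(sequence="ACGUA", pairs={(1, 5), (2, 5)})

    def test_crossing_requires_flag(self):
        with pytest.raises(FormatError):
            SecondaryStructure(sequence="ACGU", pairs={(1, 3), (2, 4)})
        s = SecondaryStructure(sequence="ACGU", pairs={(1, 3), (2, 4)},
                               pseudoknot=True)
        assert s.partner(1) == 3

    def test_transcribe_roundtrip(self):
        assert transcribe("ACGT") == "ACGU"
        assert reverse_complement("ACGT") == "ACGT"[::-1].translate(
            str.maketrans("ACGT", "TGCA")
        )
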