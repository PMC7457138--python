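import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from asorf.seqio import (
    Genome,
    GeneFeature,
    ParseError,
    TABLE11,
    read_fasta,
    read_features,
    read_matrix,
    reverse_complement,
    translate,
    write_fasta,
    write_gff3,
)

dna = st.text(alphabet="ACGTN", max_size=200)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

class TestFasta:
    def test_case_normalization_and_u_to_t(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">c1\nacgu\n")
        assert read_fasta(p) == {"c1": "ACGT"}

    def test_multi_record_and_id_token(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">c1 some description\nAC\nGT\n>c2\nTT\n")
        assert read_fasta(p) == {"c1": "ACGT", "c2": "TT"}

    def test_empty_file_warns_and_returns_empty(self, tmp_path, caplog):
        p = tmp_path / "empty.fa"
        p.write_text("")
        with caplog.at_level("WARNING"):
            assert read_fasta(p) == {}
        assert "empty" in caplog.text

    def test_sequence_before_header_names_line(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text("ACGT\n>c1\nACGT\n")
        with pytest.raises(ParseError, match=":1:"):
            read_fasta(p)

    def test_roundtrip(self, tmp_path):
        seqs = {"c1": "ACGT" * 40, "c2": "N" * 10}
        p = tmp_path / "rt.fa"
        write_fasta(p, seqs)
        assert read_fasta(p) == seqs


# ---------------------------------------------------------------------------
# features
# ---------------------------------------------------------------------------

class TestFeatures:
    def test_gff3_field_mapping(self, tmp_path):
        p = tmp_path / "a.gff"
        p.write_text("##gff-version 3\nc1\t.\tCDS\t7\t15\t.\t-\t.\tID=g1\n")
        feats = read_features(p, "gff3")
        assert feats == [GeneFeature("g1", "c1", 7, 15, "-", "CDS")]

    def test_gff3_unknown_type_becomes_other(self, tmp_path):
        p = tmp_path / "a.gff"
        p.write_text("c1\t.\tpseudogene\t1\t9\t.\t+\t.\tID=p1\n")
        assert read_features(p, "gff3")[0].kind == "other"

    def test_feature_table_trna_kind(self, tmp_path):
        p = tmp_path / "ft.txt"
        p.write_text(
            "# feature\tclass\tassembly\tgenomic_accession\tstart\tend\tstrand\tlocus_tag\n"
            "tRNA\t.\t.\tc1\t5\t80\t+\tt0001\n"
        )
        feats = read_features(p, "ncbi_feature_table")
        assert feats == [GeneFeature("t0001", "c1", 5, 80, "+", "tRNA")]

    def test_start_after_end_rejected_with_warning(self, tmp_path, caplog):
        p = tmp_path / "a.gff"
        p.write_text("c1\t.\tCDS\t15\t7\t.\t+\t.\tID=g1\n")
        with caplog.at_level("WARNING"):
            assert read_features(p, "gff3") == []

    def test_unknown_dialect(self, tmp_path):
        p = tmp_path / "a.gff"
        p.write_text("")
        with pytest.raises(ValueError, match="dialect"):
            read_features(p, "bed")

    def test_feature_beyond_contig_rejected_at_genome_assembly(self):
        with pytest.raises(ValueError, match="exceeds contig"):
            Genome("g", {"c1": "ACGTACGT"},
                   [GeneFeature("f", "c1", 3, 100, "+", "CDS")])

    def test_gff3_roundtrip(self, tmp_path):
        feats = [
            GeneFeature("g1", "c1", 7, 15, "-", "CDS"),
            GeneFeature("r1", "c1", 20, 120, "+", "rRNA"),
            GeneFeature("t1", "c2", 3, 80, "+", "tRNA"),
        ]
        p = tmp_path / "rt.gff"
        write_gff3(p, feats)
        assert read_features(p, "gff3") == feats


# ---------------------------------------------------------------------------
# reverse complement / translation
# ---------------------------------------------------------------------------

class TestSequenceOps:
    @pytest.mark.parametrize("seq,expected", [
        ("ATGC", "GCAT"), ("", ""), ("AAAN", "NTTT"),
    ])
    def test_reverse_complement_examples(self, seq, expected):
        assert reverse_complement(seq) == expected

    def test_reverse_complement_rejects_iupac(self):
        with pytest.raises(ValueError, match="R"):
            reverse_complement("ACGR")

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(dna)
    def test_reverse_complement_involution_and_length(self, s):
        rc = reverse_complement(s)
        assert len(rc) == len(s)
        assert reverse_complement(rc) == s

    @pytest.mark.parametrize("seq,strip,expected", [
        ("ATGAAATAA", True, "MK"),
        ("ATGTGAAAA", True, "M*K"),
        ("ATGNNN", False, "MX"),
    ])
    def test_translate_examples(self, seq, strip, expected):
        assert translate(seq, TABLE11, strip_terminal_stop=strip) == expected

    def test_translate_length_error(self):
        with pytest.raises(ValueError, match="divisible by 3"):
            translate("ATGA")

    def test_table11_stops(self):
        assert TABLE11.stop_codons == {"TAA", "TAG", "TGA"}
        assert len(TABLE11.codon_to_aa) == 64

    def test_antisense_translation_matches_codonwise_oracle(self, rng):
        """translate(reverse_complement(s)) == oracle that complements and
        reverses codon-by-codon explicitly."""
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for _ in range(20):
            s = "".join(rng.choice(list("ACGT"), size=300))
            oracle = "".join(
                TABLE11.codon_to_aa["".join(comp[b] for b in reversed(s[i:i+3]))]
                for i in range(len(s) - 3, -1, -3)
            )
            assert translate(reverse_complement(s)) == oracle


# ---------------------------------------------------------------------------
# substitution matrices
# ---------------------------------------------------------------------------

class TestMatrix:
    def test_blosum62_spot_checks_from_file(self, blosum62_file):
        m = read_matrix(blosum62_file)
        assert m.score("A", "A") == 4
        assert m.score("C", "C") == 9
        assert m.score("W", "W") == 11
        assert m.score("W", "F") == 1
        assert m.score("R", "S") == -1

    def test_symmetry(self, blosum62_file):
        m = read_matrix(blosum62_file)
        for a in m.alphabet:
            for b in m.alphabet:
                assert m.score(a, b) == m.score(b, a)

    def test_missing_pair_names_residues(self, matrix):
        with pytest.raises(KeyError, match="'J'"):
            matrix.score("J", "A")

    def test_asymmetric_file_rejected(self, tmp_path):
        p = tmp_path / "bad.mat"
        p.write_text("  A B\nA 1 2\nB 3 1\n")
        with pytest.raises(ParseError, match="asymmetric"):
            read_matrix(p)


def test_genome_flags_cds_not_divisible_by_3(caplog):
    with caplog.at_level("WARNING"):
        Genome("g", {"c1": "ACGTACGTAC"},
               [GeneFeature("f", "c1", 1, 10, "+", "CDS")])
    assert "not divisible by 3" in caplog.text
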