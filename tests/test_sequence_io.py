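import numpy as np
import pytest

from srnatarget.sequence_io import (AlphabetError, AnnotatedReplicon,
                                    AnnotationError, FastaParseError,
                                    GeneRecord, NucleotideSequence,
                                    extract_window, read_annotation, read_fasta)

from conftest import random_rna


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadFasta:
    def test_transcribes_dna_and_preserves_order(self, tmp_path):
        p = write(tmp_path, "a.fa", ">s\nACGT\n>b\nUUU\n")
        recs = read_fasta(p)
        assert [(r.name, r.residues) for r in recs] == [("s", "ACGU"), ("b", "UUU")]

    def test_strict_alphabet_rejects_ambiguity(self, tmp_path):
        p = write(tmp_path, "a.fa", ">s\nACGN\n")
        with pytest.raises(AlphabetError, match="N"):
            read_fasta(p)
        # permissive mode maps codes deterministically instead
        assert read_fasta(p, strict_alphabet=False)[0].residues == "ACGA"

    @pytest.mark.parametrize("text,msg", [
        (">a\n>b\nACG\n", "no sequence"),
        ("ACGT\n", "before any header"),
        (">only\n\n", "no sequence"),
    ])
    def test_malformed_files_name_the_line(self, tmp_path, text, msg):
        p = write(tmp_path, "bad.fa", text)
        with pytest.raises(FastaParseError, match=msg):
            read_fasta(p)


class TestReadAnnotation:
    def test_table_row_maps_fields(self, tmp_path):
        p = write(tmp_path, "t.tsv", "g1 thrL + 10 57 leader peptide\n")
        (rec,) = read_annotation(p, dialect="table")
        assert rec == GeneRecord("g1", "thrL", "+", 10, 57, "leader peptide")

    def test_gff3_cds_and_minus_strand_storage(self, tmp_path):
        gff = ("##gff-version 3\n"
               "chr\tx\tCDS\t100\t150\t.\t-\t0\tID=g2;gene=abc;product=p\n")
        (rec,) = read_annotation(write(tmp_path, "a.gff3", gff), dialect="gff3")
        # minus-strand coordinates are stored start <= end, genome sense
        assert (rec.strand, rec.cds_start, rec.cds_end) == ("-", 100, 150)

    def test_start_after_end_is_rejected(self, tmp_path):
        gff = "chr\tx\tCDS\t90\t50\t.\t+\t0\tID=g3\n"
        with pytest.raises(AnnotationError, match="g3"):
            read_annotation(write(tmp_path, "a.gff3", gff), dialect="gff3")

    def test_out_of_range_gene_rejected_by_replicon(self):
        seq = NucleotideSequence("ACGU" * 10)
        with pytest.raises(AnnotationError, match="g9"):
            AnnotatedReplicon(seq, [GeneRecord("g9", "g9", "+", 30, 60)])


def _replicon(seq: str, genes):
    return AnnotatedReplicon(NucleotideSequence(seq), genes)


class TestExtractWindow:
    def test_plus_strand_coordinates(self):
        seq = random_rna(np.random.default_rng(0), 300)
        rep = _replicon(seq, [GeneRecord("g", "g", "+", 101, 200)])
        win = extract_window(rep, rep.genes[0], offset_up=3, offset_down=3)
        assert win.genomic_interval == (98, 103, "+")
        assert win.window_seq.residues == seq[97:103]
        assert not win.truncated
        # position offset_up+1 is the first base of the start codon
        assert win.window_seq.residues[3] == seq[100]

    def test_minus_strand_is_reverse_complement(self):
        seq = random_rna(np.random.default_rng(1), 300)
        rep = _replicon(seq, [GeneRecord("g", "g", "-", 101, 200)])
        win = extract_window(rep, rep.genes[0], offset_up=3, offset_down=3)
        assert win.genomic_interval == (198, 203, "-")
        expect = NucleotideSequence(seq[197:203]).reverse_complement().residues
        assert win.window_seq.residues == expect

    def test_truncation_at_linear_boundary(self):
        seq = random_rna(np.random.default_rng(2), 120)
        rep = _replicon(seq, [GeneRecord("g", "g", "+", 10, 100)])
        win = extract_window(rep, rep.genes[0], offset_up=80, offset_down=20)
        assert win.truncated and win.offset_up == 9
        assert len(win.window_seq) == 9 + 20

    def test_circular_wraparound(self):
        seq = random_rna(np.random.default_rng(3), 120)
        rep = _replicon(seq, [GeneRecord("g", "g", "+", 10, 100)])
        win = extract_window(rep, rep.genes[0], offset_up=20, offset_down=5,
                             circular=True)
        assert not win.truncated
        assert win.window_seq.residues == (seq[-11:] + seq[:14])

    def test_planted_roundtrip_and_strand_symmetry(self):
        # a window planted verbatim is recovered exactly on both strands,
        # and reverse-complementing the whole replicon with flipped
        # coordinates yields the identical window sequence
        rng = np.random.default_rng(4)
        planted = random_rna(rng, 30)
        seq = random_rna(rng, 100) + planted + random_rna(rng, 100)
        start = 101 + 20  # window -20..+10 covers the planted block
        rep = _replicon(seq, [GeneRecord("g", "g", "+", start, start + 50)])
        win = extract_window(rep, rep.genes[0], offset_up=20, offset_down=10)
        assert win.window_seq.residues == planted

        n = len(seq)
        rc = NucleotideSequence(seq).reverse_complement().residues
        flipped = GeneRecord("g", "g", "-", n - (start + 50) + 1, n - start + 1)
        rep_rc = _replicon(rc, [flipped])
        win_rc = extract_window(rep_rc, flipped, offset_up=20, offset_down=10)
        assert win_rc.window_seq.residues == planted

    def test_relative_position_skips_zero(self):
        rep = _replicon(random_rna(np.random.default_rng(5), 200),
                        [GeneRecord("g", "g", "+", 101, 150)])
        win = extract_window(rep, rep.genes[0], offset_up=5, offset_down=5)
        rels = [win.relative_position(k) for k in range(1, 11)]
        assert rels == [-5, -4, -3, -2, -1, 1, 2, 3, 4, 5]
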