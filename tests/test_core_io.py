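"""Format readers/writers: coordinate conventions, validation, round trips."""

import numpy as np
import pytest

from ltrkit.core_io import (
    CytosineCall,
    GenomicInterval,
    Genome,
    derive_context,
    read_counts,
    read_cx_report,
    read_elements_gff3,
    read_fasta,
    read_gff3_genes,
    read_repeat_hits,
    write_counts,
    write_cx_report,
    write_elements_gff3,
    write_repeat_hits,
)


class TestGenomicInterval:
    def test_rejects_degenerate_and_negative(self):
        with pytest.raises(ValueError):
            GenomicInterval("s", 5, 5)
        with pytest.raises(ValueError):
            GenomicInterval("s", -1, 5)
        with pytest.raises(ValueError):
            GenomicInterval("s", 0, 5, "x")

    def test_overlap_and_distance(self):
        a = GenomicInterval("s", 0, 10)
        b = GenomicInterval("s", 10, 20)
        c = GenomicInterval("s", 5, 15)
        assert not a.overlaps(b) and a.overlaps(c)
        assert a.distance(b) == 0
        assert a.distance(GenomicInterval("s", 15, 20)) == 5


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">s1\nACGT\n")
        g = read_fasta(p)
        assert g.sequences == {"s1": "ACGT"}

    def test_multiline_and_ambiguity(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nAC\nGT\n>b\nNN\n")
        g = read_fasta(p)
        assert g["a"] == "ACGT" and g["b"] == "NN"

    def test_duplicate_id_error(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nAC\n>a\nGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta(p)

    def test_empty_file_error(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text("")
        with pytest.raises(ValueError):
            read_fasta(p)

    def test_softmask_bitmap(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nACgtA\n")
        g = read_fasta(p)
        assert g["a"] == "ACGTA"
        assert g.masks["a"].tolist() == [False, False, True, True, False]


GFF = """##gff-version 3
chr1\t.\tgene\t101\t200\t.\t{strand}\t.\tID=g1
chr1\t.\tmRNA\t101\t200\t.\t{strand}\t.\tID=m1;Parent=g1
chr1\t.\texon\t101\t140\t.\t{strand}\t.\tID=e1;Parent=m1
chr1\t.\texon\t161\t200\t.\t{strand}\t.\tID=e2;Parent=m1
"""


class TestGeneGff3:
    def test_plus_strand_conversion(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(GFF.format(strand="+"))
        (gene,) = read_gff3_genes(p)
        assert (gene.interval.start, gene.interval.end) == (100, 200)
        assert gene.tss == 100 and gene.tts == 199
        (intron,) = gene.introns
        assert (intron.start, intron.end) == (140, 160)

    def test_minus_strand_tss(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(GFF.format(strand="-"))
        (gene,) = read_gff3_genes(p)
        assert gene.tss == 199 and gene.tts == 100

    def test_longest_mrna_is_canonical(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\t.\tgene\t1\t800\t.\t+\t.\tID=g1\n"
            "chr1\t.\tmRNA\t1\t500\t.\t+\t.\tID=m_short;Parent=g1\n"
            "chr1\t.\texon\t1\t500\t.\t+\t.\tID=es;Parent=m_short\n"
            "chr1\t.\tmRNA\t1\t800\t.\t+\t.\tID=m_long;Parent=g1\n"
            "chr1\t.\texon\t1\t800\t.\t+\t.\tID=el;Parent=m_long\n"
        )
        (gene,) = read_gff3_genes(p)
        assert gene.mrna_id == "m_long"
        assert gene.exons[0].length == 800

    def test_exon_outside_mrna_is_error(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(
            "##gff-version 3\n"
            "chr1\t.\tgene\t1\t500\t.\t+\t.\tID=g1\n"
            "chr1\t.\tmRNA\t1\t500\t.\t+\t.\tID=m1;Parent=g1\n"
            "chr1\t.\texon\t1\t600\t.\t+\t.\tID=e1;Parent=m1\n"
        )
        with pytest.raises(ValueError, match="outside"):
            read_gff3_genes(p)


class TestContextDerivation:
    @pytest.mark.parametrize(
        "seq,pos,strand,expected",
        [
            ("ACGA", 1, "+", "CG"),
            ("ACAGA", 1, "+", "CHG"),
            ("ACAAA", 1, "+", "CHH"),
            ("ACGA", 2, "-", "CG"),     # G at 2, C at 1
            ("CAGAA", 2, "-", "CHG"),
            ("TTGAA", 2, "-", "CHH"),
            ("ACGA", 0, "+", None),     # not a C
            ("AC", 1, "+", None),       # runs off the end
        ],
    )
    def test_examples(self, seq, pos, strand, expected):
        assert derive_context(seq, pos, strand) == expected


class TestCxReport:
    def test_parse_and_convert(self, tmp_path):
        genome = Genome({"chr1": "AAAACGAAAA"})
        p = tmp_path / "cx.txt"
        p.write_text("chr1\t5\t+\t3\t1\tCG\tCGA\n")
        (call,) = read_cx_report(p, genome)
        assert call.pos == 4 and call.context == "CG"
        assert (call.meth_count, call.unmeth_count) == (3, 1)

    def test_context_contradiction_names_position(self, tmp_path):
        genome = Genome({"chr1": "AAAACAGAAA"})  # pos 4 is CHG, not CHH
        p = tmp_path / "cx.txt"
        p.write_text("chr1\t5\t+\t3\t1\tCHH\tCAG\n")
        with pytest.raises(ValueError, match="chr1:5"):
            read_cx_report(p, genome)

    def test_zero_coverage_retained(self, tmp_path):
        genome = Genome({"chr1": "AAAACGAAAA"})
        p = tmp_path / "cx.txt"
        p.write_text("chr1\t5\t+\t0\t0\tCG\tCGA\n")
        (call,) = read_cx_report(p, genome)
        assert call.coverage == 0

    def test_round_trip(self, tmp_path, small_sim):
        p = tmp_path / "cx.txt"
        subset = small_sim.cx_calls[:500]
        write_cx_report(subset, small_sim.genome, p)
        back = read_cx_report(p, small_sim.genome)
        assert back == subset


class TestElementsGff3:
    def test_round_trip_identity(self, tmp_path, small_elements):
        p = tmp_path / "el.gff3"
        write_elements_gff3(small_elements, p)
        back = read_elements_gff3(p)
        assert back == small_elements

    def test_feature_line_count(self, tmp_path, small_elements):
        p = tmp_path / "el.gff3"
        write_elements_gff3(small_elements[:1], p)
        lines = [l for l in p.read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == 5  # parent + 2 LTRs + 2 TSDs

    def test_tsd_children_omitted_without_tsd(self, tmp_path, small_elements):
        import copy

        el = copy.deepcopy(small_elements[0])
        el.tsd = None
        p = tmp_path / "el.gff3"
        write_elements_gff3([el], p)
        text = p.read_text()
        assert "target_site_duplication" not in text
        assert text.count("long_terminal_repeat") == 2


class TestRepeatHits:
    def test_tsv_round_trip(self, tmp_path, small_sim):
        p = tmp_path / "hits.tsv"
        write_repeat_hits(small_sim.repeat_hits, p)
        back = read_repeat_hits(p)
        assert len(back) == len(small_sim.repeat_hits)
        for a, b in zip(back, small_sim.repeat_hits):
            assert a.interval == b.interval
            assert a.consensus_id == b.consensus_id
            assert a.identity == pytest.approx(b.identity, abs=1e-4)

    def test_classic_out_dialect(self, tmp_path):
        p = tmp_path / "rm.out"
        p.write_text(
            "   SW   perc perc perc  query     position in query    matching"
            "  repeat         position in repeat\n"
            "score   div. del. ins.  sequence  begin end   (left)   repeat"
            "  class/family   begin end (left) ID\n"
            "\n"
            "  225   8.0  0.0  0.0  chr1      1001  2000 (8000) +"
            "  consA  LTR/Copia  1 1000 (0) 1\n"
        )
        (hit,) = read_repeat_hits(p)
        assert hit.interval.start == 1000 and hit.interval.end == 2000
        assert hit.consensus_id == "consA"
        assert hit.identity == pytest.approx(0.92)
        assert (hit.consensus_start, hit.consensus_end) == (0, 1000)


class TestCounts:
    def test_round_trip_and_validation(self, tmp_path, small_sim):
        p = tmp_path / "c.tsv"
        write_counts(small_sim.counts, p)
        back = read_counts(p)
        assert (back == small_sim.counts).all().all()

    def test_duplicate_feature_error(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("feature_id\trep1\nx\t1\nx\t2\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_counts(p)


def test_bed6_export(tmp_path, small_elements):
    from ltrkit.core_io import write_elements_bed

    p = tmp_path / "el.bed"
    write_elements_bed(small_elements, p)
    lines = p.read_text().splitlines()
    assert len(lines) == len(small_elements)
    f = lines[0].split("\t")
    el = small_elements[0]
    assert f[0] == el.element_interval.seq_id
    assert (int(f[1]), int(f[2])) == (el.element_interval.start,
                                      el.element_interval.end)
    assert f[3] == el.element_id and f[5] == "."
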