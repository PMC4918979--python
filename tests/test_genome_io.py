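"""Coordinate conventions, gene models and file round trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bivalent_smad.genome_io import (
    Annotation, GeneModel, GenomicInterval, ParseError, ReadSet,
    ValidationError, mapping_summary, read_annotation, read_bedgraph,
    read_reads_bed, read_samples, write_annotation, write_bed,
    write_bedgraph, write_reads_bed)
from conftest import make_gene


class TestGenomicInterval:
    @pytest.mark.parametrize("start,end", [(-1, 5), (5, 5), (9, 3)])
    def test_rejects_degenerate_coordinates(self, start, end):
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", start, end)

    def test_rejects_empty_chrom_and_bad_strand(self):
        with pytest.raises(ValidationError):
            GenomicInterval("", 0, 10)
        with pytest.raises(ValidationError):
            GenomicInterval("chr1", 0, 10, "x")


class TestGeneModel:
    def test_tss_is_first_transcribed_base(self):
        plus = make_gene("p", "chr1", 100, [(0, 50), (80, 20)], "+")
        minus = make_gene("m", "chr1", 100, [(0, 50), (80, 20)], "-")
        assert plus.tss == 100
        assert minus.tss == 199
        assert plus.interval.start <= plus.tss < plus.interval.end
        assert minus.interval.start <= minus.tss < minus.interval.end

    def test_first_intron_follows_transcription_order(self):
        plus = make_gene("p", "chr1", 1_000, [(0, 100), (200, 100)], "+")
        assert (plus.first_intron.start, plus.first_intron.end) == (1_100,
                                                                    1_200)
        minus = make_gene("m", "chr1", 1_000, [(0, 100), (200, 100)], "-")
        # '-' strand: exon at 1200-1300 is exon 1, so the same gap is the
        # first intron seen from the other side
        assert (minus.first_intron.start, minus.first_intron.end) == (1_100,
                                                                      1_200)

    def test_single_exon_gene_has_no_intron(self):
        g = make_gene("s", "chr1", 500, [(0, 300)], "+")
        assert g.first_intron is None

    def test_strandless_gene_rejected(self):
        with pytest.raises(ValidationError):
            make_gene("g", "chr1", 0, [(0, 100)], ".")

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValidationError):
            make_gene("g", "chr1", 0, [(0, 100), (50, 100)], "+")

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.tuples(st.integers(0, 50), st.integers(1, 30)),
                    min_size=2, max_size=6),
           st.sampled_from(["+", "-"]))
    def test_first_intron_matches_bruteforce_sorter(self, raw, strand):
        # build disjoint blocks from (gap, length) pairs
        blocks, pos = [], 0
        for gap, ln in raw:
            pos += gap + 1
            blocks.append((pos, ln))
            pos += ln
        g = make_gene("g", "chr1", 10_000, blocks, strand)
        genomic = sorted(blocks)
        if strand == "+":
            lo = 10_000 + genomic[0][0] + genomic[0][1]
            hi = 10_000 + genomic[1][0]
        else:
            lo = 10_000 + genomic[-2][0] + genomic[-2][1]
            hi = 10_000 + genomic[-1][0]
        assert (g.first_intron.start, g.first_intron.end) == (lo, hi)


class TestAnnotationIO:
    def test_gff3_one_based_to_internal_zero_based(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(
            "##gff-version 3\n"
            "##sequence-region chr1 1 5000\n"
            "chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tID=g1\n"
            "chr1\tsrc\texon\t1001\t1200\t.\t+\t.\tID=g1.e1;Parent=g1\n"
            "chr1\tsrc\texon\t1501\t2000\t.\t+\t.\tID=g1.e2;Parent=g1\n")
        ann = read_annotation(p)
        g = ann.genes["g1"]
        assert g.interval.start == 1_000 and g.interval.end == 2_000
        assert g.exons[0].start == 1_000
        assert (g.first_intron.start, g.first_intron.end) == (1_200, 1_500)
        assert ann.chrom_sizes["chr1"] == 5_000

    def test_gff3_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text("##gff-version 3\nchr1\tsrc\tgene\tnope\t10\t.\t+\t.\t"
                     "ID=g\n")
        with pytest.raises(ParseError, match="line 2"):
            read_annotation(p)

    def test_gff3_gene_without_exons_rejected(self, tmp_path):
        p = tmp_path / "noexon.gff3"
        p.write_text("##gff-version 3\n"
                     "chr1\tsrc\tgene\t100\t200\t.\t+\t.\tID=g1\n")
        with pytest.raises(ValidationError, match="zero exon"):
            read_annotation(p)

    def test_bed12_block_arithmetic(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t1000\t1300\tg1\t0\t+\t1000\t1300\t0\t2\t"
                     "100,100\t0,200\n")
        ann = read_annotation(p, fmt="bed12")
        intron = ann.genes["g1"].first_intron
        assert (intron.start, intron.end) == (1_100, 1_200)

    @pytest.mark.parametrize("fmt", ["gff3", "bed12"])
    def test_round_trip_is_identity(self, tmp_path, tiny_annotation, fmt):
        p = tmp_path / f"rt.{fmt}"
        write_annotation(tiny_annotation, p, fmt=fmt)
        back = read_annotation(p, fmt=fmt,
                               chrom_sizes=tiny_annotation.chrom_sizes)
        assert set(back.genes) == set(tiny_annotation.genes)
        for gid, g in tiny_annotation.genes.items():
            b = back.genes[gid]
            assert b.interval == g.interval
            assert b.exons == g.exons


class TestReadIO:
    def test_header_metadata_and_counts(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("#sample_id=s1\n#antibody=H3K4me3\n"
                     "#condition=TGFb_plus\n#total_sequenced=5\n"
                     "chr1\t0\t50\tr\t0\t+\n"
                     "chr1\t100\t150\tr\t0\t-\n"
                     "chr1\t200\t250\tr\t0\t.\n")
        rs = read_reads_bed(p)
        assert rs.mapped == 3 and rs.total_sequenced == 5
        assert rs.antibody == "H3K4me3" and rs.condition == "TGFb_plus"

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "e.bed"
        p.write_text("#sample_id=empty\n#total_sequenced=10\n")
        rs = read_reads_bed(p)
        assert rs.mapped == 0 and rs.total_sequenced == 10

    def test_inverted_interval_rejected(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t50\t40\n")
        with pytest.raises(ValidationError, match="line 1"):
            read_reads_bed(p)

    def test_reads_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        reads = tuple(
            GenomicInterval("chr1", int(s), int(s) + 50)
            for s in rng.integers(0, 10_000, 10))
        rs = ReadSet("s", "Smad2/3", "TGFb_plus", reads, 20)
        p = tmp_path / "rt.bed"
        write_reads_bed(rs, p)
        back = read_reads_bed(p)
        assert back.reads == rs.reads
        assert (back.antibody, back.condition,
                back.total_sequenced) == ("Smad2/3", "TGFb_plus", 20)

    def test_sample_sheet_overrides_header(self, tmp_path):
        bed = tmp_path / "s.bed"
        bed.write_text("#antibody=input\nchr1\t0\t50\n")
        (tmp_path / "samples.yaml").write_text(
            "- {sample_id: s1, path: s.bed, antibody: H3K27me3, "
            "condition: TGFb_minus}\n")
        samples = read_samples(tmp_path / "samples.yaml")
        assert ("H3K27me3", "TGFb_minus") in samples


class TestMappingSummary:
    def test_reported_library_summary(self):
        assert mapping_summary(mapped=10_837_516,
                               total_sequenced=15_108_905) == 71.7

    @pytest.mark.parametrize("mapped,total,expect",
                             [(1000, 1000, 100.0), (1, 3, 33.3)])
    def test_simple_fractions(self, mapped, total, expect):
        assert mapping_summary(mapped=mapped,
                               total_sequenced=total) == expect

    def test_zero_total_is_undefined(self):
        with pytest.raises(ValidationError):
            mapping_summary(mapped=0, total_sequenced=0)


class TestTrackIO:
    def test_bed_write_empty_and_intervals(self, tmp_path):
        p = tmp_path / "x.bed"
        write_bed([], p)
        assert p.read_text() == ""
        write_bed([GenomicInterval("chr1", 5, 10)], p)
        assert p.read_text().startswith("chr1\t5\t10")

    def test_bedgraph_round_trip(self, tmp_path):
        from bivalent_smad.peak_calling import SignalTrack
        track = SignalTrack(
            bin_size=100,
            counts={"chr1": np.array([5, 0, 2]), "chr2": np.array([1])},
            library_size=8)
        p = tmp_path / "t.bedGraph"
        write_bedgraph(track, p)
        assert "chr1\t0\t100\t5" in p.read_text().splitlines()[0]
        back = read_bedgraph(p)
        assert back.bin_size == 100
        np.testing.assert_array_equal(back.counts["chr1"],
                                      track.counts["chr1"])
        assert back.library_size == 8


def test_annotation_rejects_gene_past_chromosome_end():
    g = make_gene("g", "chr1", 0, [(0, 100)], "+")
    with pytest.raises(ValidationError):
        Annotation({"g": g}, {"chr1": 50})
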