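import numpy as np
import pytest

from helpers import gene_bounds, perbase_region_masks, random_toy_gtf, regionset_masks
from pacscope.annotation import (
    GtfParseError,
    build_all_regions,
    build_downstream_regions,
    build_intron_regions,
    build_utr3_regions,
    load_annotation,
    read_regions_bed,
    write_regions_bed,
    RegionSet,
)
from pacscope.intervals import Interval


class TestLoadAnnotation:
    def test_retained_intron_transcript_dropped(self, toy_annotation):
        assert "G1.t1" in toy_annotation.transcripts
        assert "G1.t2" not in toy_annotation.transcripts

    def test_coordinates_converted_to_half_open(self, toy_annotation):
        # GTF exon 1..400 (1-based inclusive) -> [0, 400)
        exon = toy_annotation.transcripts["G1.t1"].exons[0]
        assert (exon.start, exon.end) == (0, 400)

    def test_non_coding_biotype_excluded(self, toy_annotation):
        assert "G3" not in toy_annotation.genes
        assert "G1" in toy_annotation.genes and "G2" in toy_annotation.genes

    def test_malformed_line_names_line_number(self, tmp_path):
        bad = tmp_path / "bad.gtf"
        bad.write_text('chr1\tx\tgene\t1\t100\t.\t+\t.\tgene_id "G";\nchr1\tbroken line\n')
        with pytest.raises(GtfParseError, match="line 2"):
            load_annotation(bad)

    def test_orphan_transcript_rejected(self, tmp_path):
        orphan = tmp_path / "orphan.gtf"
        orphan.write_text(
            'chr1\tx\ttranscript\t1\t100\t.\t+\t.\tgene_id "NOPE"; transcript_id "T";\n'
        )
        with pytest.raises(GtfParseError, match="unknown gene"):
            load_annotation(orphan)


class TestUtr3Regions:
    def test_plus_strand_extension(self, toy_annotation):
        rs = build_utr3_regions(toy_annotation, extension_nt=300)
        # annotated [1500, 2000) extended 3' (rightward) by 300
        assert rs.regions["G1"] == [Interval("chr1", 1500, 2300, "+")]

    def test_minus_strand_extension_goes_left(self, toy_annotation):
        rs = build_utr3_regions(toy_annotation, extension_nt=300)
        # annotated [5000, 5500) on minus strand extends leftward
        assert rs.regions["G2"] == [Interval("chr1", 4700, 5500, "-")]

    def test_extension_clipped_at_chromosome_start(self, toy_annotation):
        rs = build_utr3_regions(toy_annotation, extension_nt=6000)
        assert rs.regions["G2"][0].start == 0

    def test_gene_without_utr3_absent(self, tmp_path):
        gtf = tmp_path / "noutr.gtf"
        gtf.write_text(
            'chr1\tx\tgene\t1\t100\t.\t+\t.\tgene_id "G"; gene_biotype "protein_coding";\n'
            'chr1\tx\ttranscript\t1\t100\t.\t+\t.\tgene_id "G"; transcript_id "T";\n'
            'chr1\tx\texon\t1\t100\t.\t+\t.\tgene_id "G"; transcript_id "T";\n'
        )
        rs = build_utr3_regions(load_annotation(gtf))
        assert rs.regions == {}


class TestIntronRegions:
    def test_worked_example_perbase(self, tmp_path):
        # gene [0,1000), CDS [100,400)+[500,700), extended utr3 [700,1300)
        gtf = tmp_path / "g.gtf"
        gtf.write_text(
            'chr1\tx\tgene\t1\t1000\t.\t+\t.\tgene_id "G"; gene_biotype "protein_coding";\n'
            'chr1\tx\ttranscript\t1\t1000\t.\t+\t.\tgene_id "G"; transcript_id "T";\n'
            'chr1\tx\texon\t1\t1000\t.\t+\t.\tgene_id "G"; transcript_id "T";\n'
            'chr1\tx\tCDS\t101\t400\t.\t+\t.\tgene_id "G"; transcript_id "T";\n'
            'chr1\tx\tCDS\t501\t700\t.\t+\t.\tgene_id "G"; transcript_id "T";\n'
            'chr1\tx\tthree_prime_utr\t701\t1000\t.\t+\t.\tgene_id "G"; transcript_id "T";\n'
        )
        ann = load_annotation(gtf)
        utr3 = build_utr3_regions(ann, extension_nt=300)
        intron = build_intron_regions(ann, utr3)
        # per-base oracle over positions 0..999
        keep = np.ones(1000, bool)
        keep[100:400] = False
        keep[500:700] = False
        keep[700:1000] = False  # extended utr3 within the span
        got = np.zeros(1000, bool)
        for iv in intron.regions["G"]:
            got[iv.start : iv.end] = True
        assert np.array_equal(got, keep)
        assert [(i.start, i.end) for i in intron.regions["G"]] == [(0, 100), (400, 500)]

    def test_gene_without_cds_is_span_minus_utr3(self, tmp_path):
        gtf = tmp_path / "g.gtf"
        gtf.write_text(
            'chr1\tx\tgene\t1\t1000\t.\t+\t.\tgene_id "G"; gene_biotype "protein_coding";\n'
            'chr1\tx\ttranscript\t1\t1000\t.\t+\t.\tgene_id "G"; transcript_id "T";\n'
            'chr1\tx\texon\t1\t1000\t.\t+\t.\tgene_id "G"; transcript_id "T";\n'
            'chr1\tx\tthree_prime_utr\t601\t1000\t.\t+\t.\tgene_id "G"; transcript_id "T";\n'
        )
        ann = load_annotation(gtf)
        intron = build_intron_regions(ann, build_utr3_regions(ann))
        assert [(i.start, i.end) for i in intron.regions["G"]] == [(0, 600)]


class TestDownstreamRegions:
    def test_isolated_gene_window_minus_own_extended_utr(self, toy_annotation):
        utr3 = build_utr3_regions(toy_annotation)
        down = build_downstream_regions(toy_annotation, utr3)
        # G1 ends at 2000; own extended utr3 runs to 2300
        assert down.regions["G1"] == [Interval("chr1", 2300, 12000, "+")]

    def test_same_strand_neighbor_exon_subtracted(self, tmp_path):
        lines = [
            'chr1\tx\tgene\t1\t2000\t.\t+\t.\tgene_id "A"; gene_biotype "protein_coding";',
            'chr1\tx\ttranscript\t1\t2000\t.\t+\t.\tgene_id "A"; transcript_id "A.t";',
            'chr1\tx\texon\t1\t2000\t.\t+\t.\tgene_id "A"; transcript_id "A.t";',
            'chr1\tx\tthree_prime_utr\t1901\t2000\t.\t+\t.\tgene_id "A"; transcript_id "A.t";',
            'chr1\tx\tgene\t2501\t2600\t.\t{s}\t.\tgene_id "B"; gene_biotype "protein_coding";',
            'chr1\tx\ttranscript\t2501\t2600\t.\t{s}\t.\tgene_id "B"; transcript_id "B.t";',
            'chr1\tx\texon\t2501\t2600\t.\t{s}\t.\tgene_id "B"; transcript_id "B.t";',
        ]
        for strand, expect_hole in (("+", True), ("-", False)):
            gtf = tmp_path / f"n{strand_id(strand)}.gtf"
            gtf.write_text("\n".join(lines).format(s=strand) + "\n")
            ann = load_annotation(gtf)
            down = build_downstream_regions(ann, build_utr3_regions(ann))
            covered = {
                p for iv in down.regions["A"] for p in range(iv.start, iv.end)
            }
            assert (2550 not in covered) is expect_hole

    def test_perbase_oracle_on_random_annotations(self, rng):
        gtf_text, chrom_len = random_toy_gtf(rng, n_genes=15)
        import tempfile, os

        with tempfile.NamedTemporaryFile("w", suffix=".gtf", delete=False) as fh:
            fh.write(gtf_text)
        try:
            ann = load_annotation(fh.name)
        finally:
            os.unlink(fh.name)
        lens = {"chr1": chrom_len}
        regions = build_all_regions(ann, 300, 10000, lens)
        oracle = perbase_region_masks(ann, chrom_len, 300, 10000)
        bounds = gene_bounds(ann, chrom_len, 300, 10000)
        for cls in ("utr3", "cds", "intron", "downstream10k"):
            got = regionset_masks(regions[cls], bounds)
            assert set(got) == set(oracle[cls]), cls
            for gid in got:
                assert np.array_equal(got[gid], oracle[cls][gid]), (cls, gid)


def strand_id(s):
    return "plus" if s == "+" else "minus"


class TestBedRoundTrip:
    def test_write_read_identity(self, toy_annotation, tmp_path):
        rs = build_utr3_regions(toy_annotation)
        path = tmp_path / "utr3.bed"
        write_regions_bed(rs, path)
        back = read_regions_bed(path)
        assert back.region_class == rs.region_class
        assert back.regions == rs.regions
        first = path.read_text().splitlines()
        assert first[0].startswith("#")
        assert first[1].split("\t")[3] == "G1|utr3"  # sorted by position

    def test_empty_regionset_round_trips(self, tmp_path):
        rs = RegionSet("cds", {})
        path = tmp_path / "empty.bed"
        write_regions_bed(rs, path)
        back = read_regions_bed(path)
        assert back.region_class == "cds"
        assert back.regions == {}
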