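"""Genome model: coordinate conventions, feature partition, round trips."""

import numpy as np
import pytest

from peakscape import (
    ChromSizes,
    FeatureMap,
    Gene,
    GenomeAnnotation,
    Interval,
    build_feature_map,
    promoter_interval,
    read_annotation,
    read_chrom_sizes,
)
from peakscape.errors import AnnotationError, FormatError

from conftest import brute_force_class, mirror_annotation


class TestChromSizes:
    def test_read_simple(self, tmp_path):
        p = tmp_path / "g.sizes"
        p.write_text("chr1\t9000\nchr2\t500\n")
        sizes = read_chrom_sizes(p)
        assert sizes["chr1"] == 9000 and sizes.names == ["chr1", "chr2"]
        assert sizes.total_length == 9500

    def test_empty_file_is_valid(self, tmp_path):
        p = tmp_path / "g.sizes"
        p.write_text("")
        assert len(read_chrom_sizes(p)) == 0

    @pytest.mark.parametrize("content", ["chr1\t-5\n", "chr1\t0\n", "chr1\tabc\n",
                                         "chr1\n", "chr1\t10\nchr1\t20\n"])
    def test_malformed_rejected(self, tmp_path, content):
        p = tmp_path / "g.sizes"
        p.write_text(content)
        with pytest.raises(FormatError):
            read_chrom_sizes(p)


class TestReadAnnotation:
    def test_gtf_coordinate_conversion(self, tmp_path):
        # GTF is 1-based closed: [1001, 2000] -> internal [1000, 2000)
        p = tmp_path / "a.gtf"
        p.write_text('chr1\tsrc\texon\t1001\t2000\t.\t+\t.\tgene_id "g1";\n')
        ann = read_annotation(p, ChromSizes([("chr1", 9000)]))
        g = ann.genes[0]
        assert (g.body.start, g.body.end) == (1000, 2000)

    def test_intron_derivation(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(
            'chr1\tsrc\texon\t1001\t1200\t.\t+\t.\tgene_id "g1";\n'
            'chr1\tsrc\texon\t1501\t2000\t.\t+\t.\tgene_id "g1";\n'
        )
        ann = read_annotation(p, ChromSizes([("chr1", 9000)]))
        assert ann.genes[0].introns() == [(1200, 1500)]

    def test_unknown_chromosome_rejected(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text('chrX\tsrc\texon\t100\t200\t.\t+\t.\tgene_id "g1";\n')
        with pytest.raises(AnnotationError):
            read_annotation(p, ChromSizes([("chr1", 9000)]))

    def test_isoform_exons_unioned(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(
            'chr1\tsrc\texon\t101\t300\t.\t+\t.\tgene_id "g1";\n'
            'chr1\tsrc\texon\t201\t400\t.\t+\t.\tgene_id "g1";\n'
            'chr1\tsrc\texon\t601\t700\t.\t+\t.\tgene_id "g1";\n'
        )
        ann = read_annotation(p, ChromSizes([("chr1", 9000)]))
        assert ann.genes[0].exons == [(100, 400), (600, 700)]

    def test_refflat_native_coordinates(self, tmp_path):
        p = tmp_path / "a.refflat"
        p.write_text("g1\tnm1\tchr1\t+\t1000\t2000\t1100\t1900\t2\t1000,1500,\t1200,2000,\n")
        ann = read_annotation(p, ChromSizes([("chr1", 9000)]), dialect="refflat")
        g = ann.genes[0]
        assert (g.body.start, g.body.end) == (1000, 2000)
        assert g.exons == [(1000, 1200), (1500, 2000)]
        assert (g.cds_start, g.cds_end) == (1100, 1900)

    def test_exon_outside_body_rejected(self):
        with pytest.raises(AnnotationError):
            Gene(id="g", body=Interval("chr1", 100, 200, "+"), exons=[(150, 300)])


class TestPromoterInterval:
    def test_plus_strand_upstream_window(self):
        g = Gene(id="g", body=Interval("chr1", 10_000, 12_000, "+"),
                 exons=[(10_000, 12_000)])
        prom = promoter_interval(g, 5000, ChromSizes([("chr1", 30_000)]))
        assert (prom.start, prom.end) == (5000, 10_000)

    def test_minus_strand_mirror(self):
        g = Gene(id="g", body=Interval("chr1", 10_000, 20_000, "-"),
                 exons=[(10_000, 20_000)])
        prom = promoter_interval(g, 5000, ChromSizes([("chr1", 30_000)]))
        assert (prom.start, prom.end) == (20_000, 25_000)

    def test_clipped_at_chromosome_start(self):
        g = Gene(id="g", body=Interval("chr1", 2000, 4000, "+"),
                 exons=[(2000, 4000)])
        prom = promoter_interval(g, 5000, ChromSizes([("chr1", 30_000)]))
        assert (prom.start, prom.end) == (0, 2000)

    def test_empty_window_at_edge(self):
        g = Gene(id="g", body=Interval("chr1", 0, 1000, "+"), exons=[(0, 1000)])
        assert promoter_interval(g, 5000, ChromSizes([("chr1", 30_000)])) is None


class TestFeatureMap:
    def test_partition_conserves_genome_length(self, two_gene_annotation,
                                               two_gene_feature_map):
        lengths = two_gene_feature_map.class_lengths()
        assert sum(lengths.values()) == two_gene_annotation.chrom_sizes.total_length

    def test_no_cds_means_no_utr(self, small_sizes):
        g = Gene(id="g", body=Interval("chr1", 1000, 3000, "+"),
                 exons=[(1000, 1500), (2500, 3000)])
        fm = build_feature_map(GenomeAnnotation([g], small_sizes), 500)
        lengths = fm.class_lengths()
        assert lengths["utr5"] == 0 and lengths["utr3"] == 0
        assert lengths["exon"] == 1000 and lengths["intron"] == 1000

    def test_agrees_with_brute_force_on_fixture(self, two_gene_annotation,
                                                two_gene_feature_map):
        rng = np.random.default_rng(7)
        for chrom, L in two_gene_annotation.chrom_sizes.items():
            pos = rng.integers(0, L, size=400)
            got = [two_gene_feature_map.class_name_at(chrom, int(p)) for p in pos]
            want = [brute_force_class(two_gene_annotation, 5000, chrom, int(p))
                    for p in pos]
            assert got == want

    def test_overlapping_genes_follow_precedence(self, small_sizes):
        # gY's exon inside gX's intron; every base gets exactly one class
        gx = Gene(id="gX", body=Interval("chr1", 1000, 9000, "+"),
                  exons=[(1000, 1500), (8500, 9000)])
        gy = Gene(id="gY", body=Interval("chr1", 3000, 4000, "+"),
                  exons=[(3000, 4000)])
        ann = GenomeAnnotation([gx, gy], small_sizes)
        fm = build_feature_map(ann, 500)
        for pos in range(0, 10_000, 13):
            assert fm.class_name_at("chr1", pos) == brute_force_class(ann, 500, "chr1", pos)
        assert fm.class_name_at("chr1", 3500) == "exon"  # exon beats host intron

    def test_gene_body_never_promoter(self, small_sizes):
        # gB starts inside the 5 kb window downstream-gene promoter would claim
        ga = Gene(id="gA", body=Interval("chr1", 10_000, 12_000, "+"),
                  exons=[(10_000, 12_000)])
        gb = Gene(id="gB", body=Interval("chr1", 6_000, 9_000, "+"),
                  exons=[(6_000, 9_000)])
        fm = build_feature_map(GenomeAnnotation([ga, gb], small_sizes), 5000)
        # base inside gB's body, also in gA's promoter window: body wins
        assert fm.class_name_at("chr1", 8_000) == "exon"

    def test_bed_round_trip(self, tmp_path, two_gene_feature_map, small_sizes):
        path = tmp_path / "features.bed"
        two_gene_feature_map.to_bed(path)
        back = FeatureMap.from_bed(path, small_sizes, promoter_window=5000)
        for chrom, L in small_sizes.items():
            pos = np.arange(0, L, 97)
            np.testing.assert_array_equal(
                two_gene_feature_map.class_at(chrom, pos), back.class_at(chrom, pos))

    def test_strand_mirror_symmetry(self, two_gene_annotation):
        fm = build_feature_map(two_gene_annotation, 5000)
        mirrored = build_feature_map(mirror_annotation(two_gene_annotation), 5000)
        for chrom, L in two_gene_annotation.chrom_sizes.items():
            pos = np.arange(0, L, 31)
            np.testing.assert_array_equal(
                fm.class_at(chrom, pos), mirrored.class_at(chrom, L - 1 - pos))

    def test_empty_genome_rejected(self):
        ann = GenomeAnnotation([], ChromSizes([]))
        with pytest.raises(Exception):
            build_feature_map(ann, 5000)
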