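"""Coverage tracks and metagene profiles (TSS and length-scaled features)."""

import numpy as np
import pytest

from peakscape import (
    ChromSizes,
    CoverageTrack,
    Gene,
    GenomeAnnotation,
    Interval,
    gene_feature_intervals,
    read_bedgraph,
    scaled_feature_profile,
    tss_profile,
)
from peakscape.errors import FormatError
from test_peaks import make_peakset

from conftest import mirror_annotation


@pytest.fixture
def sizes():
    return ChromSizes([("chr1", 30_000)])


def centered_gene(sizes, strand="+"):
    g = Gene(id="g", body=Interval("chr1", 12_000, 18_000, strand),
             exons=[(12_000, 18_000)])
    return GenomeAnnotation([g], sizes)


class TestReadBedgraph:
    def test_constant_track(self, tmp_path, sizes):
        p = tmp_path / "cov.bedgraph"
        p.write_text("chr1\t0\t30000\t2.0\n")
        track = read_bedgraph(p, sizes)
        assert track.genome_mean() == pytest.approx(2.0)
        assert (track.per_base("chr1", 100, 200) == 2.0).all()

    def test_gaps_are_zero(self, tmp_path, sizes):
        p = tmp_path / "cov.bedgraph"
        p.write_text("chr1\t1000\t2000\t3.0\n")
        track = read_bedgraph(p, sizes)
        assert track.per_base("chr1", 0, 1000).sum() == 0
        assert track.genome_mean() == pytest.approx(3000 / 30_000)

    def test_missing_chromosome_all_zero(self, tmp_path):
        sizes = ChromSizes([("chr1", 1000), ("chr2", 1000)])
        p = tmp_path / "cov.bedgraph"
        p.write_text("chr1\t0\t1000\t1.0\n")
        track = read_bedgraph(p, sizes)
        assert track.per_base("chr2", 0, 1000).sum() == 0

    @pytest.mark.parametrize("content", [
        "chr1\t0\t100\t1.0\nchr1\t50\t150\t1.0\n",   # overlap
        "chr1\t0\t100\t-1.0\n",                        # negative
        "chr1\t29000\t31000\t1.0\n",                   # beyond end
        "chrX\t0\t100\t1.0\n",                         # unknown chromosome
    ])
    def test_malformed_rejected(self, tmp_path, sizes, content):
        p = tmp_path / "cov.bedgraph"
        p.write_text(content)
        with pytest.raises(FormatError):
            read_bedgraph(p, sizes)

    def test_unsorted_input_accepted(self, tmp_path, sizes):
        p = tmp_path / "cov.bedgraph"
        p.write_text("chr1\t200\t300\t2.0\nchr1\t0\t100\t1.0\n")
        track = read_bedgraph(p, sizes)
        assert track.per_base("chr1", 0, 100)[0] == 1.0
        assert track.per_base("chr1", 200, 300)[0] == 2.0


class TestTssProfile:
    def test_constant_coverage_flat_profile(self, sizes):
        track = CoverageTrack.constant(sizes, 7.0)
        prof = tss_profile(track, centered_gene(sizes), flank_bp=2000, n_bins=40)
        np.testing.assert_allclose(prof.values, 1.0)

    def test_spike_at_tss_peaks_center(self, sizes):
        ann = centered_gene(sizes)
        tss = ann.genes[0].tss
        segs = {"chr1": (np.array([0, tss, tss + 1], dtype=np.int64),
                         np.array([0.0, 1000.0, 0.0]))}
        track = CoverageTrack(sizes, segs)
        prof = tss_profile(track, ann, flank_bp=2000, n_bins=40)
        # TSS base is the first base of the downstream-half center bin
        assert prof.values.argmax() == 20

    def test_minus_strand_mirror_identical(self, sizes):
        ann = centered_gene(sizes)
        rng = np.random.default_rng(3)
        breaks = np.arange(0, 30_000, 100, dtype=np.int64)
        vals = rng.uniform(0, 5, breaks.size)
        track = CoverageTrack(sizes, {"chr1": (breaks, vals)})
        prof_fwd = tss_profile(track, ann, 2000, 40)

        mirrored_ann = mirror_annotation(ann)
        mirror_vals = vals[::-1]  # value of base 29999-p equals value of p
        # rebuild mirrored piecewise track at 100 bp resolution
        track_m = CoverageTrack(sizes, {"chr1": (breaks, mirror_vals)})
        prof_rev = tss_profile(track_m, mirrored_ann, 2000, 40)
        np.testing.assert_allclose(prof_fwd.values, prof_rev.values, rtol=1e-12)

    def test_out_of_bounds_gene_skipped(self, sizes):
        g_edge = Gene(id="edge", body=Interval("chr1", 500, 2500, "+"),
                      exons=[(500, 2500)])
        g_ok = centered_gene(sizes).genes[0]
        ann = GenomeAnnotation([g_edge, g_ok], sizes)
        prof = tss_profile(CoverageTrack.constant(sizes, 1.0), ann, 2000, 40)
        assert prof.n_features == 1 and prof.n_skipped == 1

    def test_zero_coverage_rejected(self, sizes):
        with pytest.raises(ValueError):
            tss_profile(CoverageTrack.constant(sizes, 0.0),
                        centered_gene(sizes), 2000, 40)

    def test_scale_invariance(self, sizes):
        ann = centered_gene(sizes)
        rng = np.random.default_rng(4)
        breaks = np.arange(0, 30_000, 250, dtype=np.int64)
        vals = rng.uniform(0.1, 5, breaks.size)
        t1 = CoverageTrack(sizes, {"chr1": (breaks, vals)})
        t2 = CoverageTrack(sizes, {"chr1": (breaks, vals * 13.0)})
        p1 = tss_profile(t1, ann, 2000, 40)
        p2 = tss_profile(t2, ann, 2000, 40)
        np.testing.assert_allclose(p1.values, p2.values, rtol=1e-12)


class TestScaledFeatureProfile:
    def test_linear_ramp_closed_form(self, sizes):
        # coverage rises linearly 0..1 over a 100 bp exon; 10 slices of 10 bp
        # have means 0.05, 0.15, ..., 0.95 before genome-mean normalization
        exon = Interval("chr1", 1000, 1100, "+")
        breaks = np.arange(0, 30_000, dtype=np.int64)
        vals = np.zeros(30_000)
        vals[1000:1100] = np.arange(100) / 100.0
        track = CoverageTrack(sizes, {"chr1": (breaks, vals)})
        prof = scaled_feature_profile(track, [exon], n_bins=10, min_length_bp=50)
        gmean = track.genome_mean()
        # discrete ramp: slice i covers values (10i..10i+9)/100, mean 0.1*i+0.045
        expect = (np.arange(10) / 10 + 0.045) / gmean
        np.testing.assert_allclose(prof.values, expect, rtol=1e-9)

    def test_constant_coverage_flat(self, sizes):
        track = CoverageTrack.constant(sizes, 3.0)
        prof = scaled_feature_profile(track, [Interval("chr1", 0, 500, "+")],
                                      n_bins=10, min_length_bp=50)
        np.testing.assert_allclose(prof.values, 1.0)

    def test_minus_strand_reverses(self, sizes):
        breaks = np.arange(0, 30_000, dtype=np.int64)
        vals = np.zeros(30_000)
        vals[1000:1100] = np.arange(100)
        track = CoverageTrack(sizes, {"chr1": (breaks, vals)})
        fwd = scaled_feature_profile(track, [Interval("chr1", 1000, 1100, "+")],
                                     n_bins=10, min_length_bp=50)
        rev = scaled_feature_profile(track, [Interval("chr1", 1000, 1100, "-")],
                                     n_bins=10, min_length_bp=50)
        np.testing.assert_allclose(fwd.values, rev.values[::-1], rtol=1e-12)

    def test_all_features_too_short_rejected(self, sizes):
        track = CoverageTrack.constant(sizes, 1.0)
        with pytest.raises(ValueError):
            scaled_feature_profile(track, [Interval("chr1", 0, 40, "+")],
                                   n_bins=10, min_length_bp=1000)

    def test_duplicated_feature_shifts_average_by_weight(self, sizes):
        track = CoverageTrack(sizes, {"chr1": (
            np.array([0, 1000, 2000, 3000, 4000], dtype=np.int64),
            np.array([0.0, 4.0, 0.0, 8.0, 0.0]))})
        f1 = Interval("chr1", 1000, 2000, "+")
        f2 = Interval("chr1", 3000, 4000, "+")
        p1 = scaled_feature_profile(track, [f1], 10, 100).values
        p2 = scaled_feature_profile(track, [f2], 10, 100).values
        both = scaled_feature_profile(track, [f1, f2, f2], 10, 100).values
        np.testing.assert_allclose(both, (p1 + 2 * p2) / 3, rtol=1e-12)


class TestPeakDensityTrack:
    def test_union_binary_track(self, sizes):
        ps = make_peakset([("chr1", 100, 300), ("chr1", 200, 400),
                           ("chr1", 1000, 1100)])
        track = CoverageTrack.from_peaks(ps, sizes)
        assert (track.per_base("chr1", 100, 400) == 1.0).all()
        assert track.per_base("chr1", 400, 1000).sum() == 0
        assert track.genome_mean() == pytest.approx((300 + 100) / 30_000)

    def test_exon_feature_extraction(self, two_gene_annotation):
        exons = gene_feature_intervals(two_gene_annotation, "exon")
        introns = gene_feature_intervals(two_gene_annotation, "intron")
        assert len(exons) == 6 and len(introns) == 3
        assert all(iv.strand in "+-" for iv in exons)
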