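"""Shared fixtures: tiny hand-constructed genomes and simulated substrates."""

import numpy as np
import pytest

from peakscape import (
    ChromSizes,
    Gene,
    GenomeAnnotation,
    GenomeSpec,
    Interval,
    build_feature_map,
    simulate_genome,
)


@pytest.fixture
def small_sizes():
    return ChromSizes([("chr1", 30_000), ("chr2", 20_000)])


@pytest.fixture
def two_gene_annotation(small_sizes):
    """Two genes on chr1 (one per strand, one with CDS), one on chr2."""
    g1 = Gene(
        id="gA",
        body=Interval("chr1", 10_000, 14_000, "+"),
        exons=[(10_000, 10_500), (11_000, 11_800), (13_000, 14_000)],
        cds_start=10_200,
        cds_end=13_500,
    )
    g2 = Gene(
        id="gB",
        body=Interval("chr1", 20_000, 23_000, "-"),
        exons=[(20_000, 20_600), (22_000, 23_000)],
    )
    g3 = Gene(
        id="gC",
        body=Interval("chr2", 5_000, 8_000, "+"),
        exons=[(5_000, 8_000)],
    )
    return GenomeAnnotation([g1, g2, g3], small_sizes)


@pytest.fixture
def two_gene_feature_map(two_gene_annotation):
    return build_feature_map(two_gene_annotation, promoter_window=5000)


@pytest.fixture(scope="session")
def toy_genome():
    """Session-wide simulated genome: 10 x 100 kb chromosomes, 100 genes."""
    sizes, annotation, truth = simulate_genome(GenomeSpec(), seed=20_001)
    return sizes, annotation


@pytest.fixture(scope="session")
def toy_feature_map(toy_genome):
    _, annotation = toy_genome
    return build_feature_map(annotation, promoter_window=5000)


def brute_force_class(annotation, promoter_window, chrom, pos):
    """Independent per-base classifier used as an oracle for FeatureMap.

    Walks every gene and applies the precedence
    exon > utr5 > utr3 > intron > promoter > intergenic directly.
    """
    best = "intergenic"
    rank = {"intergenic": 0, "promoter": 1, "intron": 2,
            "utr3": 3, "utr5": 4, "exon": 5}
    for g in annotation.genes:
        if g.chrom != chrom:
            continue
        label = None
        in_exon = any(s <= pos < e for s, e in g.exons)
        if in_exon:
            has_cds = (g.cds_start is not None and g.cds_end is not None
                       and g.cds_start < g.cds_end)
            if not has_cds or g.cds_start <= pos < g.cds_end:
                label = "exon"
            elif pos < g.cds_start:
                label = "utr5" if g.strand == "+" else "utr3"
            else:
                label = "utr3" if g.strand == "+" else "utr5"
        elif g.body.start <= pos < g.body.end:
            label = "intron"
        else:
            if g.strand == "+":
                lo, hi = g.body.start - promoter_window, g.body.start
            else:
                lo, hi = g.body.end, g.body.end + promoter_window
            if lo <= pos < hi:
                label = "promoter"
        if label is not None and rank[label] > rank[best]:
            best = label
    return best


def mirror_annotation(annotation):
    """Reverse all coordinates and strands: the oracle for mirror symmetry."""
    sizes = annotation.chrom_sizes
    genes = []
    for g in annotation.genes:
        L = sizes[g.chrom]
        body = Interval(g.chrom, L - g.body.end, L - g.body.start,
                        "-" if g.strand == "+" else "+")
        exons = [(L - e, L - s) for s, e in g.exons]
        cds_start = cds_end = None
        if g.cds_start is not None and g.cds_end is not None:
            cds_start, cds_end = L - g.cds_end, L - g.cds_start
        genes.append(Gene(id=g.id, body=body, exons=exons,
                          cds_start=cds_start, cds_end=cds_end))
    return GenomeAnnotation(genes, sizes)
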