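"""Seeded generators for toy genomes, peak sets and expression matrices.

Every generator is a pure function of its spec and seed: repeated calls with
the same arguments return identical objects (and byte-identical files when
written).  Each call also returns a :class:`TruthRecord` holding the planted
parameters — target feature class per peak, planted DE genes and folds,
co-occupancy probabilities — sufficient to compute every downstream expected
statistic without peeking into generator internals.

The default genome is deliberately modest: 10 chromosomes of 100 kb (1 Mb
total) with ~100 non-overlapping multi-exon genes, which gives every feature
class a non-trivial base fraction while keeping whole-pipeline runs fast.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cooccurrence import BinGrid, occupancy
from .errors import PeakscapeError
from .genome import (ChromSizes, FeatureMap, Gene, GenomeAnnotation, Interval,
                     build_feature_map, FEATURE_CLASSES)
from .peaks import PEAK_COLUMNS, PeakSet


@dataclass
class TruthRecord:
    """Planted ground truth serialized alongside every generated dataset."""

    kind: str
    seed: int
    params: dict = field(default_factory=dict)
    data: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=_jsonable)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthRecord":
        with open(path) as fh:
            return cls(**json.load(fh))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serializable: {type(obj)}")


@dataclass
class GenomeSpec:
    """Toy genome shape: chromosomes plus non-overlapping multi-exon genes.

    Exon counts are geometric (minimum 1); exon and intron lengths are
    log-normal, roughly 200 bp exons and 800 bp introns, echoing compact
    vertebrate gene architecture at toy scale.
    """

    n_chromosomes: int = 10
    chrom_length: int = 100_000
    n_genes: int = 100
    mean_exons: float = 4.0
    exon_meanlog: float = np.log(200.0)
    exon_sdlog: float = 0.5
    intron_meanlog: float = np.log(800.0)
    intron_sdlog: float = 0.6
    min_exon: int = 30
    min_intron: int = 60
    strand_prob: float = 0.5
    cds_prob: float = 0.8
    max_placement_retries: int = 200


def simulate_genome(spec: GenomeSpec, seed: int = 0
                    ) -> tuple[ChromSizes, GenomeAnnotation, TruthRecord]:
    """Generate a toy genome with non-overlapping genes.

    Genes are placed by rejection sampling; if a gene cannot be placed within
    ``max_placement_retries`` attempts a :class:`PeakscapeError` is raised.
    """
    rng = np.random.default_rng(seed)
    chrom_sizes = ChromSizes(
        [(f"chr{i + 1}", spec.chrom_length) for i in range(spec.n_chromosomes)])
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    genes: list[Gene] = []
    for gi in range(spec.n_genes):
        n_exons = max(1, int(rng.geometric(1.0 / spec.mean_exons)))
        exon_lens = np.maximum(
            spec.min_exon,
            rng.lognormal(spec.exon_meanlog, spec.exon_sdlog, n_exons).astype(int))
        intron_lens = np.maximum(
            spec.min_intron,
            rng.lognormal(spec.intron_meanlog, spec.intron_sdlog,
                          max(0, n_exons - 1)).astype(int))
        glen = int(exon_lens.sum() + intron_lens.sum())
        strand = "+" if rng.random() < spec.strand_prob else "-"
        for _ in range(spec.max_placement_retries):
            chrom = f"chr{rng.integers(spec.n_chromosomes) + 1}"
            limit = chrom_sizes[chrom] - glen
            if limit <= 0:
                continue
            start = int(rng.integers(limit + 1))
            end = start + glen
            if all(e <= start or s >= end for s, e in placed[chrom]):
                break
        else:
            raise PeakscapeError(
                f"could not place gene {gi} of length {glen} after "
                f"{spec.max_placement_retries} retries")
        placed[chrom].append((start, end))
        exons = []
        pos = start
        for j, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if j < len(intron_lens):
                pos += int(intron_lens[j])
        cds_start = cds_end = None
        if rng.random() < spec.cds_prob:
            first_s, first_e = exons[0]
            last_s, last_e = exons[-1]
            cds_start = first_s + int(rng.integers((first_e - first_s) // 2 + 1))
            cds_end = last_e - int(rng.integers((last_e - last_s) // 2 + 1))
            if cds_start >= cds_end:
                cds_start = cds_end = None
        genes.append(Gene(
            id=f"gene{gi + 1}",
            body=Interval(chrom, start, end, strand),
            exons=exons,
            cds_start=cds_start,
            cds_end=cds_end,
        ))
    annotation = GenomeAnnotation(genes, chrom_sizes)
    truth = TruthRecord(
        kind="genome", seed=seed, params=asdict(spec),
        data={"n_genes": len(genes),
              "gene_ids": [g.id for g in genes]})
    return chrom_sizes, annotation, truth


@dataclass
class PeakSpec:
    """Peak placement propensities per feature class plus a length model.

    The anchor base of each peak lands in class c with probability
    proportional to ``propensity[c] * base_fraction[c]``; equal propensities
    therefore reproduce the genomic base composition, and a propensity of 4
    on exons emulates a four-fold exon preference.
    """

    n_peaks: int = 500
    propensities: dict = field(
        default_factory=lambda: {c: 1.0 for c in FEATURE_CLASSES})
    length_meanlog: float = np.log(300.0)
    length_sdlog: float = 0.4
    min_length: int = 50


def simulate_peaks(annotation: GenomeAnnotation, spec: PeakSpec, seed: int = 0,
                   feature_map: FeatureMap | None = None,
                   promoter_window: int = 5000) -> tuple[PeakSet, TruthRecord]:
    """Place peaks with per-feature-class propensities; truth holds each
    peak's target class.  Peaks carry MACS-style -10*log10(p) scores drawn
    uniformly in [30, 100] so significance filtering is exercised."""
    if feature_map is None:
        feature_map = build_feature_map(annotation, promoter_window)
    rng = np.random.default_rng(seed)
    fractions = feature_map.class_fractions()
    weights = np.array([spec.propensities.get(c, 0.0) * fractions[c]
                        for c in FEATURE_CLASSES])
    for c in FEATURE_CLASSES:
        if spec.propensities.get(c, 0.0) > 0 and fractions[c] == 0:
            raise PeakscapeError(f"class {c!r} has propensity > 0 but no bases")
    if weights.sum() <= 0:
        raise PeakscapeError("all effective class weights are zero")
    probs = weights / weights.sum()

    # per-class interval tables for uniform base sampling within a class
    class_ivs = {}
    for c in FEATURE_CLASSES:
        ivs = feature_map.intervals(c)
        if ivs:
            lens = np.array([len(iv) for iv in ivs], dtype=np.int64)
            class_ivs[c] = (ivs, np.cumsum(lens), int(lens.sum()))

    rows = []
    anchor_classes = []
    chrom_sizes = annotation.chrom_sizes
    class_draws = rng.choice(len(FEATURE_CLASSES), size=spec.n_peaks, p=probs)
    for ci in class_draws:
        cls = FEATURE_CLASSES[ci]
        ivs, cum, total = class_ivs[cls]
        offset = int(rng.integers(total))
        j = int(np.searchsorted(cum, offset, side="right"))
        iv = ivs[j]
        anchor = iv.start + offset - (int(cum[j - 1]) if j else 0)
        length = max(spec.min_length,
                     int(rng.lognormal(spec.length_meanlog, spec.length_sdlog)))
        length = min(length, chrom_sizes[iv.chrom])
        start = min(max(anchor - length // 2, 0), chrom_sizes[iv.chrom] - length)
        rows.append({
            "chrom": iv.chrom, "start": start, "end": start + length,
            "summit": anchor - start, "score": float(rng.uniform(5, 30)),
            "neg_log10_p": float(rng.uniform(30, 100)),
        })
        anchor_classes.append(cls)
    peakset = PeakSet(pd.DataFrame(rows, columns=PEAK_COLUMNS), name="simulated")
    truth = TruthRecord(
        kind="peaks", seed=seed,
        params={"n_peaks": spec.n_peaks, "propensities": dict(spec.propensities)},
        data={"anchor_classes": anchor_classes,
              "class_fractions": fractions})
    return peakset, truth


def simulate_cooccurring_peaks(base_peakset: PeakSet, grid: BinGrid,
                               p_given: float = 0.8, p_background: float = 0.1,
                               seed: int = 0, peak_length: int = 200
                               ) -> tuple[PeakSet, TruthRecord]:
    """Spawn a partner peak set with bin-level conditional co-occupancy.

    Each bin occupied by the base set receives a partner peak with
    probability ``p_given``; every other bin with ``p_background``.  Partner
    peaks are placed entirely inside their bin.
    """
    if not (0 <= p_background <= p_given <= 1):
        raise ValueError("require 0 <= p_background <= p_given <= 1")
    rng = np.random.default_rng(seed)
    occ = occupancy(base_peakset, grid)
    spawn_p = np.where(occ, p_given, p_background)
    spawn = rng.random(grid.n_bins) < spawn_p
    rows = []
    for iv, hit in zip(grid.intervals(), spawn):
        if not hit:
            continue
        plen = min(peak_length, len(iv))
        start = iv.start + int(rng.integers(len(iv) - plen + 1))
        rows.append({"chrom": iv.chrom, "start": start, "end": start + plen,
                     "summit": np.nan, "score": np.nan,
                     "neg_log10_p": float(rng.uniform(30, 100))})
    peakset = PeakSet(pd.DataFrame(rows, columns=PEAK_COLUMNS), name="partner")
    truth = TruthRecord(
        kind="cooccurring_peaks", seed=seed,
        params={"p_given": p_given, "p_background": p_background,
                "peak_length": peak_length},
        data={"n_base_occupied": int(occ.sum()),
              "n_partner_peaks": len(rows)})
    return peakset, truth


@dataclass
class ExpressionSpec:
    """Duplicate-design expression matrix with planted fold changes.

    A fraction of genes sits under the detection floor (signals below 45 in
    all samples); among the remaining expressed genes a planted subset gets a
    multiplicative fold change (half up, half down by default) in group B.
    Noise is multiplicative log-normal with the given coefficient of
    variation.
    """

    n_genes: int = 2000
    baseline_meanlog: float = np.log(500.0)
    baseline_sdlog: float = 1.0
    min_expressed: float = 60.0
    floor_fraction: float = 0.2
    floor_low: float = 5.0
    floor_high: float = 40.0
    n_de: int = 100
    fold: float = 2.0
    up_fraction: float = 0.5
    noise_cv: float = 0.10
    n_replicates: int = 2
    group_a: str = "WT"
    group_b: str = "KO"


def simulate_expression(spec: ExpressionSpec, seed: int = 0):
    """Generate the matrix and truth: planted DE genes, directions, floor set."""
    from .expression import ExpressionMatrix  # local import: avoid cycle at import time

    rng = np.random.default_rng(seed)
    n = spec.n_genes
    genes = [f"gene{i + 1}" for i in range(n)]
    n_floor = int(round(spec.floor_fraction * n))
    idx = rng.permutation(n)
    floor_idx = idx[:n_floor]
    expressed_idx = idx[n_floor:]
    if spec.n_de > expressed_idx.size:
        raise ValueError("more planted DE genes than expressed genes")
    de_idx = expressed_idx[:spec.n_de]
    n_up = int(round(spec.up_fraction * spec.n_de))

    baseline = np.maximum(
        spec.min_expressed,
        rng.lognormal(spec.baseline_meanlog, spec.baseline_sdlog, n))
    baseline[floor_idx] = rng.uniform(spec.floor_low, spec.floor_high, n_floor)

    fold = np.ones(n)
    fold[de_idx[:n_up]] = spec.fold
    fold[de_idx[n_up:]] = 1.0 / spec.fold

    sdlog = np.sqrt(np.log1p(spec.noise_cv ** 2))
    columns = {}
    for r in range(spec.n_replicates):
        noise = np.exp(rng.normal(0.0, sdlog, n)) if sdlog > 0 else np.ones(n)
        columns[f"{spec.group_a}_{r + 1}"] = baseline * noise
    for r in range(spec.n_replicates):
        noise = np.exp(rng.normal(0.0, sdlog, n)) if sdlog > 0 else np.ones(n)
        columns[f"{spec.group_b}_{r + 1}"] = baseline * fold * noise

    data = pd.DataFrame(columns, index=pd.Index(genes, name="gene_id"))
    groups = {f"{spec.group_a}_{r + 1}": spec.group_a for r in range(spec.n_replicates)}
    groups |= {f"{spec.group_b}_{r + 1}": spec.group_b for r in range(spec.n_replicates)}
    matrix = ExpressionMatrix(data, groups)
    truth = TruthRecord(
        kind="expression", seed=seed, params=asdict(spec),
        data={
            "de_up": [genes[i] for i in de_idx[:n_up]],
            "de_down": [genes[i] for i in de_idx[n_up:]],
            "floor_genes": [genes[i] for i in floor_idx],
        })
    return matrix, truth
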