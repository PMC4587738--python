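"""End-to-end orchestration: annotate -> enrich -> metagene -> cooccur ->
associate -> de-call -> overlap from a single config, with a run manifest.

Stages run in dependency order; only stages whose inputs are configured are
executed.  The manifest records the resolved config, SHA-256 checksums of all
inputs, per-stage wall times and warnings, so identical (inputs, config,
seed) reruns are reproducible and auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from ._version import __version__
from .cooccurrence import CooccurrenceTest, make_bins, occupancy
from .enrichment import PeakFeatureEnrichment
from .errors import PipelineError
from .expression import DEParams, DifferentialExpression, bound_gene_overlap, read_expression
from .genome import build_feature_map, read_annotation, read_chrom_sizes
from .metagene import (CoverageTrack, gene_feature_intervals, read_bedgraph,
                       scaled_feature_profile, tss_profile)
from .peaks import associate_genes, filter_peaks, read_peaks

logger = logging.getLogger(__name__)

ALL_STAGES = ("annotate", "associate", "enrich", "metagene", "cooccur", "de", "overlap")


@dataclass
class RunConfig:
    """Resolved pipeline configuration; defaults match the analysis defaults
    used throughout the package (5 kb promoters, 3000 bp bins, floor 45,
    1.5/2.5 fold tiers, peak p thresholds 0.01 and 0.001)."""

    chrom_sizes: str
    annotation: str
    out_dir: str
    annotation_dialect: str = "gtf"
    peaks: str | None = None
    peaks_dialect: str = "bed"
    partner_peaks: list[str] = field(default_factory=list)
    coverage: str | None = None
    expression: str | None = None
    expression_groups: dict = field(default_factory=dict)
    de_group_a: str = "WT"
    de_group_b: str = "KO"
    promoter_window: int = 5000
    bin_width: int = 3000
    n_permutations: int = 10_000
    seed: int = 0
    de_floor: float = 45.0
    de_tiers: tuple = (1.5, 2.5)
    peak_p_thresholds: tuple = (0.01, 0.001)
    tss_flank: int = 5000
    tss_bins: int = 100
    feature_bins: int = 50

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise PipelineError(f"invalid config: {exc}") from exc

    def input_paths(self) -> dict[str, str]:
        paths = {"chrom_sizes": self.chrom_sizes, "annotation": self.annotation}
        if self.peaks:
            paths["peaks"] = self.peaks
        for i, p in enumerate(self.partner_peaks):
            paths[f"partner_peaks_{i}"] = p
        if self.coverage:
            paths["coverage"] = self.coverage
        if self.expression:
            paths["expression"] = self.expression
        return paths


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Execute the configured stages; returns (and writes) the run manifest.

    Pre-flight validation checks every referenced input path before any
    stage runs; a missing file aborts naming the path.  ``stages`` allows
    partial reruns (dependencies are recomputed in memory, outputs only
    written for requested stages).
    """
    stages = list(stages) if stages is not None else list(ALL_STAGES)
    for s in stages:
        if s not in ALL_STAGES:
            raise PipelineError(f"unknown stage {s!r}")
    inputs = config.input_paths()
    for label, path in inputs.items():
        if not Path(path).is_file():
            raise PipelineError(f"missing input file for {label}: {path}")

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "peakscape_version": __version__,
        "config": asdict(config),
        "input_checksums": {k: _sha256(v) for k, v in inputs.items()},
        "stages": {},
        "warnings": [],
    }

    chrom_sizes = read_chrom_sizes(config.chrom_sizes)
    annotation = read_annotation(config.annotation, chrom_sizes,
                                 dialect=config.annotation_dialect)
    peakset = None
    if config.peaks:
        peakset = read_peaks(config.peaks, dialect=config.peaks_dialect)

    def stage(name):
        def deco(fn):
            if name in stages:
                t0 = time.perf_counter()
                outputs = fn()
                manifest["stages"][name] = {
                    "outputs": outputs,
                    "seconds": round(time.perf_counter() - t0, 4),
                }
                logger.info("stage %s done in %.2fs", name,
                            manifest["stages"][name]["seconds"])
            return fn
        return deco

    feature_map = build_feature_map(annotation, config.promoter_window)

    @stage("annotate")
    def _annotate():
        path = out_dir / "features.bed"
        feature_map.to_bed(path)
        return [str(path)]

    de_results = None
    if config.expression and ("de" in stages or "overlap" in stages):
        matrix = read_expression(config.expression, config.expression_groups)
        model = DifferentialExpression(
            matrix, config.de_group_a, config.de_group_b,
            DEParams(floor=config.de_floor,
                     fold_thresholds=tuple(config.de_tiers)))
        de_results = model.fit()

    associations = {}
    if peakset is not None:

        @stage("associate")
        def _associate():
            out = []
            for max_p in config.peak_p_thresholds:
                kept = filter_peaks(peakset, max_p)
                assoc = associate_genes(kept, annotation, config.promoter_window)
                associations[max_p] = assoc
                path = out_dir / f"associated_genes_p{max_p:g}.tsv"
                assoc.to_frame(annotation.gene_ids()).to_csv(path, sep="\t", index=False)
                out.append(str(path))
            return out

        @stage("enrich")
        def _enrich():
            model = PeakFeatureEnrichment(peakset, feature_map)
            res = model.fit(config.n_permutations, config.seed)
            tsv = out_dir / "enrichment.tsv"
            res.table.to_csv(tsv, sep="\t", index_label="feature_class")
            grid = make_bins(chrom_sizes, config.bin_width)
            hyp = model.hypergeometric_test(grid)
            meta = out_dir / "enrichment.json"
            with open(meta, "w") as fh:
                json.dump({
                    "n_permutations": res.n_permutations,
                    "seed": res.seed,
                    "n_peaks": res.n_peaks,
                    "epsilon": res.epsilon,
                    "hypergeometric_p": hyp.to_dict(),
                }, fh, indent=2)
            return [str(tsv), str(meta)]

        @stage("cooccur")
        def _cooccur():
            if not config.partner_peaks:
                return []
            grid = make_bins(chrom_sizes, config.bin_width)
            occ_a = occupancy(peakset, grid)
            rows = []
            m = len(config.partner_peaks)
            for partner_path in config.partner_peaks:
                partner = read_peaks(partner_path, dialect="bed")
                res = CooccurrenceTest(occ_a, occupancy(partner, grid),
                                       n_comparisons=m).fit()
                rows.append({
                    "partner": Path(partner_path).name, "N": res.N, "K": res.K,
                    "n": res.n, "k": res.k, "fold": res.fold,
                    "p_raw": res.p_raw, "p_bonferroni": res.p_bonferroni,
                })
            import pandas as pd
            path = out_dir / "cooccurrence.tsv"
            pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
            return [str(path)]

    if "metagene" in stages and (config.coverage or peakset is not None):

        @stage("metagene")
        def _metagene():
            if config.coverage:
                track = read_bedgraph(config.coverage, chrom_sizes)
            else:
                track = CoverageTrack.from_peaks(peakset, chrom_sizes)
                manifest["warnings"].append(
                    "metagene computed from peak density (no coverage input)")
            out = []
            prof = tss_profile(track, annotation, config.tss_flank, config.tss_bins)
            path = out_dir / "metagene_tss.tsv"
            prof.to_tsv(path)
            out.append(str(path))
            for kind in ("exon", "intron"):
                feats = gene_feature_intervals(annotation, kind)
                try:
                    prof = scaled_feature_profile(track, feats, config.feature_bins)
                except ValueError as exc:
                    manifest["warnings"].append(f"metagene {kind}: {exc}")
                    continue
                path = out_dir / f"metagene_{kind}.tsv"
                prof.to_tsv(path)
                out.append(str(path))
            return out

    if de_results is not None:

        @stage("de")
        def _de():
            path = out_dir / "de_calls.tsv"
            de_results.to_tsv(path)
            return [str(path)]

        if peakset is not None:

            @stage("overlap")
            def _overlap():
                matrix_genes = set(de_results.table.index)
                universe = sorted(matrix_genes & set(annotation.gene_ids()))
                if not universe:
                    manifest["warnings"].append(
                        "overlap: annotation and expression share no genes")
                    return []
                de_genes = de_results.genes_at(config.de_tiers[0]) & set(universe)
                report = {}
                for max_p in config.peak_p_thresholds:
                    assoc = associations.get(max_p)
                    if assoc is None:
                        assoc = associate_genes(filter_peaks(peakset, max_p),
                                                annotation, config.promoter_window)
                    for category, genes in (("body", assoc.body_genes),
                                            ("promoter", assoc.promoter_genes)):
                        res = bound_gene_overlap(genes & set(universe), de_genes, universe)
                        report[f"{category}_p{max_p:g}"] = {
                            "universe": res.universe_size, "bound": res.n_bound,
                            "de": res.n_de, "intersection": res.n_intersection,
                            "p_value": res.p_value,
                        }
                path = out_dir / "overlap.json"
                with open(path, "w") as fh:
                    json.dump(report, fh, indent=2)
                return [str(path)]

    manifest_path = out_dir / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    manifest["manifest_path"] = str(manifest_path)
    return manifest
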