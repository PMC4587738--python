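"""Peak-call ingestion, significance filtering and peak-to-gene association.

Peaks come from a MACS 1.4 peak table or a BED file.  The gene-association
rules are the ones used throughout the analyses: a peak is associated with a
gene when it overlaps the gene body by at least one base, and with a promoter
when it overlaps the window 5 kb upstream of the TSS.  Any-overlap (not full
containment) is the default; ``mode="containment"`` is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import FormatError
from .genome import ChromSizes, GenomeAnnotation, Interval, promoter_interval

logger = logging.getLogger(__name__)

PEAK_COLUMNS = ["chrom", "start", "end", "summit", "score", "neg_log10_p"]


@dataclass(frozen=True)
class Peak:
    """A single peak; ``summit`` is a bp offset within the interval."""

    interval: Interval
    summit: int | None = None
    score: float | None = None
    neg_log10_p: float | None = None

    def __post_init__(self):
        if self.summit is not None and not (0 <= self.summit < len(self.interval)):
            raise ValueError("summit offset outside peak interval")
        if self.neg_log10_p is not None and self.neg_log10_p < 0:
            raise ValueError("neg_log10_p must be >= 0")

    @property
    def pvalue(self) -> float | None:
        """MACS convention: the table stores -10*log10(p)."""
        if self.neg_log10_p is None:
            return None
        return 10.0 ** (-self.neg_log10_p / 10.0)


class PeakSet:
    """An ordered set of peaks backed by a DataFrame sorted by (chrom, start).

    Missing summit/score/p-value are NaN in the frame.  The anchor of a peak
    -- the single base used to assign it a feature class -- is its summit when
    present, else its midpoint.
    """

    def __init__(self, df: pd.DataFrame, name: str = "peaks"):
        missing = set(PEAK_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"peak frame missing columns: {sorted(missing)}")
        df = df[PEAK_COLUMNS].copy()
        df = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
        if ((df["end"] <= df["start"]) | (df["start"] < 0)).any():
            raise ValueError("peak with end <= start or negative start")
        self.df = df
        self.name = name

    @classmethod
    def from_peaks(cls, peaks: Iterable[Peak], name: str = "peaks") -> "PeakSet":
        rows = [
            {
                "chrom": p.interval.chrom,
                "start": p.interval.start,
                "end": p.interval.end,
                "summit": np.nan if p.summit is None else p.summit,
                "score": np.nan if p.score is None else p.score,
                "neg_log10_p": np.nan if p.neg_log10_p is None else p.neg_log10_p,
            }
            for p in peaks
        ]
        df = pd.DataFrame(rows, columns=PEAK_COLUMNS)
        return cls(df, name=name)

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self):
        for row in self.df.itertuples(index=False):
            yield Peak(
                Interval(row.chrom, int(row.start), int(row.end)),
                summit=None if pd.isna(row.summit) else int(row.summit),
                score=None if pd.isna(row.score) else float(row.score),
                neg_log10_p=None if pd.isna(row.neg_log10_p) else float(row.neg_log10_p),
            )

    @property
    def chroms(self) -> list[str]:
        return list(dict.fromkeys(self.df["chrom"]))

    def pvalues(self) -> np.ndarray:
        """Peak-level p-values, NaN where absent."""
        return 10.0 ** (-self.df["neg_log10_p"].to_numpy(dtype=float) / 10.0)

    def anchors(self) -> np.ndarray:
        """Absolute anchor base per peak: summit if present, else midpoint."""
        starts = self.df["start"].to_numpy(np.int64)
        ends = self.df["end"].to_numpy(np.int64)
        summit = self.df["summit"].to_numpy(float)
        mid = (starts + ends) // 2
        anchors = np.where(np.isnan(summit), mid, starts + np.nan_to_num(summit))
        return anchors.astype(np.int64)

    def validate_chroms(self, chrom_sizes: ChromSizes) -> None:
        for chrom, grp in self.df.groupby("chrom", sort=False):
            if chrom not in chrom_sizes:
                raise ValueError(f"peak on unknown chromosome {chrom!r}")
            if int(grp["end"].max()) > chrom_sizes[chrom]:
                raise ValueError(f"peak beyond end of chromosome {chrom}")

    def to_macs_table(self, path: str | Path) -> None:
        """Write a MACS 1.4 style peak table (1-based starts, summit offset).

        Peaks without a summit get their midpoint offset; peaks without a
        p-value get -10*log10(p) = 0 (p = 1).
        """
        with open(path, "w") as fh:
            fh.write("chr\tstart\tend\tlength\tsummit\ttags\t"
                     "-10*log10(pvalue)\tfold_enrichment\n")
            for row in self.df.itertuples(index=False):
                length = row.end - row.start
                summit = int(row.summit) if not pd.isna(row.summit) else length // 2
                nlp = 0.0 if pd.isna(row.neg_log10_p) else row.neg_log10_p
                score = 0.0 if pd.isna(row.score) else row.score
                fh.write(f"{row.chrom}\t{row.start + 1}\t{row.end}\t{length}\t"
                         f"{summit}\t10\t{nlp:.5f}\t{score:.5f}\n")

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for i, row in enumerate(self.df.itertuples(index=False)):
                score = 0.0 if pd.isna(row.score) else row.score
                fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{self.name}_{i}\t{score:g}\t.\n")

    def __repr__(self) -> str:
        return f"PeakSet({self.name!r}, {len(self)} peaks)"


def read_peaks(path: str | Path, dialect: str = "bed", name: str | None = None) -> PeakSet:
    """Read peaks from a MACS 1.4 table (``dialect="macs14_table"``) or BED3+.

    MACS coordinates are 1-based starts and are converted to 0-based
    half-open; the summit column is the offset from the peak start and the
    seventh column is -10*log10(p) stored as reported.
    """
    if name is None:
        name = Path(path).stem
    if dialect == "macs14_table":
        rows = _read_macs14(path)
    elif dialect == "bed":
        rows = _read_bed(path)
    else:
        raise ValueError(f"unknown peak dialect {dialect!r}")
    df = pd.DataFrame(rows, columns=PEAK_COLUMNS)
    try:
        return PeakSet(df, name=name)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def _read_macs14(path: str | Path) -> list[dict]:
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if f[0] == "chr" and not f[1].lstrip("-").isdigit():
                continue  # header
            if len(f) < 8:
                raise FormatError(f"{path}:{lineno}: expected >=8 MACS columns, got {len(f)}")
            try:
                chrom = f[0]
                start = int(f[1]) - 1  # MACS start is 1-based
                end = int(f[2])
                summit = int(f[4])
                neg_log10_p = float(f[6])
                fold = float(f[7])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: malformed MACS row") from None
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end <= start")
            if not (0 <= summit < end - start):
                raise FormatError(f"{path}:{lineno}: summit offset outside peak")
            if neg_log10_p < 0:
                raise FormatError(f"{path}:{lineno}: negative -10*log10(p)")
            rows.append({"chrom": chrom, "start": start, "end": end,
                         "summit": summit, "score": fold, "neg_log10_p": neg_log10_p})
    return rows


def _read_bed(path: str | Path) -> list[dict]:
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise FormatError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(f[1]), int(f[2])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: malformed BED row") from None
            if end <= start:
                raise FormatError(f"{path}:{lineno}: end <= start")
            score = np.nan
            if len(f) >= 5:
                try:
                    score = float(f[4])
                except ValueError:
                    pass
            rows.append({"chrom": f[0], "start": start, "end": end,
                         "summit": np.nan, "score": score, "neg_log10_p": np.nan})
    return rows


def filter_peaks(peakset: PeakSet, max_p: float) -> PeakSet:
    """Keep peaks with peak-level p strictly below ``max_p``.

    The thresholds used in practice are the mild 0.01 and the stringent
    0.001; the resulting sets are nested.  ``max_p >= 1`` keeps everything
    (p-values never exceed 1); every peak must carry a p-value.
    """
    p = peakset.pvalues()
    if np.isnan(p).any():
        raise ValueError("filter_peaks requires a p-value on every peak")
    kept = peakset.df[p < max_p]
    return PeakSet(kept.reset_index(drop=True), name=peakset.name)


@dataclass
class GeneAssociation:
    """Gene ids with at least one peak in the body / in the promoter window."""

    body_genes: set[str] = field(default_factory=set)
    promoter_genes: set[str] = field(default_factory=set)

    def to_frame(self, gene_ids: Iterable[str]) -> pd.DataFrame:
        ids = list(gene_ids)
        return pd.DataFrame({
            "gene_id": ids,
            "body_bound": [g in self.body_genes for g in ids],
            "promoter_bound": [g in self.promoter_genes for g in ids],
        })


def _any_overlap(starts: np.ndarray, ends: np.ndarray, s: int, e: int) -> bool:
    hi = np.searchsorted(starts, e, side="left")
    return bool((ends[:hi] > s).any())


def _any_contained(starts: np.ndarray, ends: np.ndarray, s: int, e: int) -> bool:
    hi = np.searchsorted(starts, e, side="right")
    lo = np.searchsorted(starts, s, side="left")
    return bool((ends[lo:hi] <= e).any())


def associate_genes(peakset: PeakSet, annotation: GenomeAnnotation,
                    promoter_window: int = 5000, mode: str = "overlap") -> GeneAssociation:
    """Associate peaks with genes and promoters.

    A gene is body-associated when >=1 peak overlaps its body by >=1 bp, and
    promoter-associated when >=1 peak overlaps the ``promoter_window`` bases
    upstream of its TSS.  A peak may hit several genes and both categories.
    Peaks on chromosomes absent from the annotation contribute nothing (a
    warning is logged once per chromosome).
    """
    if mode not in ("overlap", "containment"):
        raise ValueError(f"unknown association mode {mode!r}")
    hit = _any_overlap if mode == "overlap" else _any_contained
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, grp in peakset.df.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy(np.int64)
        by_chrom[chrom] = (starts, grp["end"].to_numpy(np.int64))
        if chrom not in annotation.chrom_sizes:
            logger.warning("peaks on chromosome %r absent from annotation; ignored", chrom)
    assoc = GeneAssociation()
    for gene in annotation.genes:
        arrays = by_chrom.get(gene.chrom)
        if arrays is None:
            continue
        starts, ends = arrays
        if hit(starts, ends, gene.body.start, gene.body.end):
            assoc.body_genes.add(gene.id)
        prom = promoter_interval(gene, promoter_window, annotation.chrom_sizes)
        if prom is not None and hit(starts, ends, prom.start, prom.end):
            assoc.promoter_genes.add(gene.id)
    return assoc
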