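"""Average coverage profiles: TSS-centered windows and length-scaled features.

Coverage is a piecewise-constant non-negative track per chromosome (bedGraph
in; gaps are zero).  Profiles are strand-oriented (minus-strand windows are
reversed so position runs 5'->3'), normalized by the genome-wide mean
coverage so a uniform track profiles flat at 1.0, and averaged unweighted
over features.  Normalizing by the global mean rather than per-feature means
preserves depletion: a gene class that is genuinely depleted stays below 1
in the average.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import FormatError
from .genome import ChromSizes, GenomeAnnotation, Interval
from .peaks import PeakSet


class CoverageTrack:
    """Piecewise-constant coverage over every chromosome.

    Stored per chromosome as segment start positions (beginning at 0) and a
    value per segment; segments tile the chromosome.
    """

    def __init__(self, chrom_sizes: ChromSizes,
                 segments: dict[str, tuple[np.ndarray, np.ndarray]]):
        self.chrom_sizes = chrom_sizes
        self._segments = {}
        for chrom in chrom_sizes:
            breaks, values = segments.get(
                chrom, (np.array([0], dtype=np.int64), np.array([0.0])))
            if breaks[0] != 0:
                raise ValueError(f"{chrom}: segments must start at 0")
            if (np.asarray(values) < 0).any():
                raise ValueError(f"{chrom}: negative coverage")
            self._segments[chrom] = (np.asarray(breaks, dtype=np.int64),
                                     np.asarray(values, dtype=float))

    @classmethod
    def constant(cls, chrom_sizes: ChromSizes, value: float) -> "CoverageTrack":
        return cls(chrom_sizes, {
            c: (np.array([0], dtype=np.int64), np.array([float(value)]))
            for c in chrom_sizes
        })

    @classmethod
    def from_peaks(cls, peakset: PeakSet, chrom_sizes: ChromSizes) -> "CoverageTrack":
        """Binary 0/1 track over the union of the peaks."""
        segments = {}
        for chrom, grp in peakset.df.groupby("chrom", sort=False):
            length = chrom_sizes[chrom]
            merged: list[list[int]] = []
            for s, e in sorted(zip(grp["start"].to_numpy(np.int64),
                                   grp["end"].to_numpy(np.int64))):
                s, e = int(s), min(int(e), length)
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            segments[chrom] = _tile_segments(
                [(s, e, 1.0) for s, e in merged], length)
        return cls(chrom_sizes, segments)

    def genome_mean(self) -> float:
        total, weight = 0.0, 0
        for chrom in self.chrom_sizes:
            breaks, values = self._segments[chrom]
            length = self.chrom_sizes[chrom]
            seg_len = np.diff(np.append(breaks, length))
            total += float((values * seg_len).sum())
            weight += length
        return total / weight

    def per_base(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Dense per-base coverage over [start, end)."""
        length = self.chrom_sizes[chrom]
        if not (0 <= start < end <= length):
            raise ValueError(f"window [{start}, {end}) outside {chrom} [0, {length})")
        breaks, values = self._segments[chrom]
        ends = np.append(breaks[1:], length)
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(breaks, end, side="left")
        out = np.empty(end - start, dtype=float)
        pos = start
        for s, e, v in zip(breaks[lo:hi], ends[lo:hi], values[lo:hi]):
            seg_end = min(e, end)
            out[pos - start:seg_end - start] = v
            pos = seg_end
        return out


def _tile_segments(covered: list[tuple[int, int, float]],
                   length: int) -> tuple[np.ndarray, np.ndarray]:
    """Turn sorted non-overlapping (start, end, value) runs into a tiling
    (breaks, values) pair, filling gaps with zero and merging equal runs."""
    breaks: list[int] = []
    values: list[float] = []

    def emit(pos: int, value: float) -> None:
        if values and values[-1] == value:
            return
        breaks.append(pos)
        values.append(value)

    pos = 0
    for s, e, v in covered:
        if s > pos:
            emit(pos, 0.0)
        emit(s, v)
        pos = e
    if pos < length:
        emit(pos, 0.0)
    if not breaks:
        breaks, values = [0], [0.0]
    return np.array(breaks, dtype=np.int64), np.array(values, dtype=float)


def read_bedgraph(path: str | Path, chrom_sizes: ChromSizes) -> CoverageTrack:
    """Read a bedGraph file into a tiling coverage track.

    Input may be unsorted; bases not covered by any line get coverage 0.
    Overlapping intervals, negative values, or intervals beyond the
    chromosome end are format errors.
    """
    per_chrom: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split()
            if len(f) < 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            try:
                chrom, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
            except ValueError:
                raise FormatError(f"{path}:{lineno}: malformed bedGraph row") from None
            if chrom not in chrom_sizes:
                raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            if not (0 <= start < end <= chrom_sizes[chrom]):
                raise FormatError(f"{path}:{lineno}: interval outside chromosome")
            if value < 0:
                raise FormatError(f"{path}:{lineno}: negative coverage")
            per_chrom.setdefault(chrom, []).append((start, end, value))
    segments = {}
    for chrom, rows in per_chrom.items():
        rows.sort()
        pos = 0
        for s, e, _ in rows:
            if s < pos:
                raise FormatError(f"{path}: overlapping intervals on {chrom} at {s}")
            pos = e
        segments[chrom] = _tile_segments(rows, chrom_sizes[chrom])
    return CoverageTrack(chrom_sizes, segments)


@dataclass
class MetageneProfile:
    """Mean normalized coverage per bin over many aligned features."""

    mode: str  # "tss" or "scaled_feature"
    positions: np.ndarray  # bp offsets from TSS, or relative positions in (0, 1)
    values: np.ndarray
    n_features: int
    n_skipped: int = 0

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("position\tmean_normalized_coverage\n")
            for x, y in zip(self.positions, self.values):
                fh.write(f"{x:g}\t{y:.6g}\n")

    def plot(self, ax=None, label: str | None = None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 3))
        ax.plot(self.positions, self.values, label=label)
        ax.set_xlabel("distance from TSS (bp)" if self.mode == "tss"
                      else "relative position (5'→3')")
        ax.set_ylabel("mean coverage / genome mean")
        if label:
            ax.legend()
        return ax


def tss_profile(track: CoverageTrack, annotation: GenomeAnnotation,
                flank_bp: int = 5000, n_bins: int = 100) -> MetageneProfile:
    """Average coverage in [TSS - flank, TSS + flank), strand-oriented.

    Genes whose window would leave the chromosome are skipped and counted in
    ``n_skipped``.  ``2 * flank_bp`` must be divisible by ``n_bins``.
    """
    if flank_bp <= 0:
        raise ValueError("flank_bp must be positive")
    if n_bins % 2 != 0 or (2 * flank_bp) % n_bins != 0:
        raise ValueError("n_bins must be even and divide 2*flank_bp")
    gmean = track.genome_mean()
    if gmean == 0:
        raise ValueError("genome-wide mean coverage is zero")
    width = 2 * flank_bp // n_bins
    acc = np.zeros(n_bins)
    used = skipped = 0
    for gene in annotation.genes:
        if gene.strand == "+":
            lo, hi = gene.tss - flank_bp, gene.tss + flank_bp
        else:
            # exact strand-mirror of the + window under coordinate reversal
            lo, hi = gene.tss - flank_bp + 1, gene.tss + flank_bp + 1
        if lo < 0 or hi > annotation.chrom_sizes[gene.chrom]:
            skipped += 1
            continue
        window = track.per_base(gene.chrom, lo, hi)
        if gene.strand == "-":
            window = window[::-1]
        acc += window.reshape(n_bins, width).mean(axis=1)
        used += 1
    if used == 0:
        raise ValueError("no gene window fits inside its chromosome")
    centers = (np.arange(n_bins) + 0.5) * width - flank_bp
    return MetageneProfile("tss", centers, acc / used / gmean, used, skipped)


def scaled_feature_profile(track: CoverageTrack, features: Sequence[Interval],
                           n_bins: int = 50, min_length_bp: int | None = None) -> MetageneProfile:
    """Average coverage within length-scaled features (e.g. introns, exons).

    Each feature is cut into ``n_bins`` near-equal slices (5'->3' by strand),
    the mean coverage per slice is normalized by the genome mean, and slices
    are averaged unweighted across features.  Features shorter than
    ``min_length_bp`` (default ``2 * n_bins``) are skipped.
    """
    if min_length_bp is None:
        min_length_bp = 2 * n_bins
    gmean = track.genome_mean()
    if gmean == 0:
        raise ValueError("genome-wide mean coverage is zero")
    acc = np.zeros(n_bins)
    used = skipped = 0
    for iv in features:
        length = len(iv)
        if length < min_length_bp:
            skipped += 1
            continue
        arr = track.per_base(iv.chrom, iv.start, iv.end)
        if iv.strand == "-":
            arr = arr[::-1]
        bounds = (np.arange(n_bins + 1) * length) // n_bins
        sums = np.add.reduceat(arr, bounds[:-1])
        acc += sums / np.diff(bounds)
        used += 1
    if used == 0:
        raise ValueError(f"all features shorter than min_length_bp={min_length_bp}")
    centers = (np.arange(n_bins) + 0.5) / n_bins
    return MetageneProfile("scaled_feature", centers, acc / used / gmean, used, skipped)


def gene_feature_intervals(annotation: GenomeAnnotation, kind: str) -> list[Interval]:
    """All exon or intron intervals of the annotation, stranded."""
    if kind not in ("exon", "intron"):
        raise ValueError("kind must be 'exon' or 'intron'")
    out = []
    for g in annotation.genes:
        pairs = g.exons if kind == "exon" else g.introns()
        out.extend(Interval(g.chrom, s, e, g.strand) for s, e in pairs)
    return out
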