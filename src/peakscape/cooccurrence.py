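"""Genome binning and the hypergeometric co-occurrence test between peak sets.

The genome is tiled with non-intersecting fixed-width bins (3000 bp by
default); a bin is *occupied* by a peak set when at least one peak overlaps it
by at least one base.  Co-occurrence between two sets is then an urn problem:
with N bins of which K are occupied by set A, drawing the n bins occupied by
set B, the probability of seeing at least k jointly occupied bins is the
upper tail of Hypergeometric(N, K, n).  When a panel of partner sets is
tested against the same reference set, the p-values are Bonferroni-corrected
by the panel size.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
from scipy import stats

from .errors import PeakscapeError
from .genome import ChromSizes, Interval
from .peaks import PeakSet


class BinGrid:
    """Fixed-width tiling of every chromosome, with global bin indexing.

    Bins are anchored at coordinate 0 on each chromosome; the last bin of a
    chromosome may be truncated but is kept, so bin lengths always sum to the
    genome length.
    """

    def __init__(self, chrom_sizes: ChromSizes, width: int = 3000):
        if width <= 0:
            raise ValueError("bin width must be positive")
        if len(chrom_sizes) == 0:
            raise PeakscapeError("cannot bin an empty genome")
        self.chrom_sizes = chrom_sizes
        self.width = int(width)
        self._n_bins = {c: -(-chrom_sizes[c] // width) for c in chrom_sizes}
        offsets = np.cumsum([0] + [self._n_bins[c] for c in chrom_sizes])
        self._offset = {c: int(o) for c, o in zip(chrom_sizes, offsets)}
        self.n_bins = int(offsets[-1])

    def n_bins_of(self, chrom: str) -> int:
        return self._n_bins[chrom]

    def offset_of(self, chrom: str) -> int:
        return self._offset[chrom]

    def bin_index(self, chrom: str, positions) -> np.ndarray:
        """Global bin index for 0-based positions on ``chrom`` (vectorized)."""
        positions = np.asarray(positions, dtype=np.int64)
        if positions.size and (positions.min() < 0 or positions.max() >= self.chrom_sizes[chrom]):
            raise ValueError(f"position outside chromosome {chrom}")
        return self._offset[chrom] + positions // self.width

    def intervals(self) -> Iterator[Interval]:
        for chrom in self.chrom_sizes:
            length = self.chrom_sizes[chrom]
            for k in range(self._n_bins[chrom]):
                yield Interval(chrom, k * self.width, min((k + 1) * self.width, length))

    def midpoints(self) -> tuple[list[str], np.ndarray]:
        """Chromosome and midpoint base of every bin, in global bin order."""
        chroms: list[str] = []
        mids = np.empty(self.n_bins, dtype=np.int64)
        i = 0
        for chrom in self.chrom_sizes:
            length = self.chrom_sizes[chrom]
            n = self._n_bins[chrom]
            starts = np.arange(n, dtype=np.int64) * self.width
            ends = np.minimum(starts + self.width, length)
            mids[i:i + n] = (starts + ends) // 2
            chroms.extend([chrom] * n)
            i += n
        return chroms, mids

    def total_binned_length(self) -> int:
        return sum(self.chrom_sizes[c] for c in self.chrom_sizes)

    def __repr__(self) -> str:
        return f"BinGrid(width={self.width}, n_bins={self.n_bins})"


def make_bins(chrom_sizes: ChromSizes, width: int = 3000) -> BinGrid:
    """Tile the genome into non-intersecting bins of ``width`` bases."""
    return BinGrid(chrom_sizes, width)


def occupancy(peakset: PeakSet, grid: BinGrid) -> np.ndarray:
    """Boolean occupancy per bin: True iff >=1 peak overlaps the bin."""
    occ = np.zeros(grid.n_bins, dtype=bool)
    w = grid.width
    for chrom, grp in peakset.df.groupby("chrom", sort=False):
        if chrom not in grid.chrom_sizes:
            continue
        off = grid.offset_of(chrom)
        n = grid.n_bins_of(chrom)
        first = grp["start"].to_numpy(np.int64) // w
        last = (grp["end"].to_numpy(np.int64) - 1) // w
        np.clip(first, 0, n - 1, out=first)
        np.clip(last, 0, n - 1, out=last)
        delta = np.zeros(n + 1, dtype=np.int64)
        np.add.at(delta, first, 1)
        np.add.at(delta, last + 1, -1)
        occ[off:off + n] = np.cumsum(delta[:-1]) > 0
    return occ


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k), X ~ HG(N, K, n).

    Stable in log space via scipy's survival function; exact degenerate
    cases (k = 0, K = N) return 1.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError("require 0 <= K, n <= N")
    if not (0 <= k <= min(K, n)):
        raise ValueError("require 0 <= k <= min(K, n)")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class CooccurrenceResults:
    """Bin co-occupancy contingency margins and the hypergeometric test."""

    N: int
    K: int
    n: int
    k: int
    n_comparisons: int

    def __post_init__(self):
        if self.k > min(self.K, self.n):
            raise ValueError("jointly occupied bins exceed a margin")

    @property
    def p_raw(self) -> float:
        return hypergeom_upper(self.N, self.K, self.n, self.k)

    @property
    def p_bonferroni(self) -> float:
        return min(1.0, self.p_raw * self.n_comparisons)

    @property
    def fold(self) -> float:
        """Observed joint density over the independence expectation."""
        if self.K == 0 or self.n == 0:
            return float("nan")
        return (self.k / self.N) / ((self.K / self.N) * (self.n / self.N))

    def summary(self) -> str:
        lines = [
            "Bin co-occurrence (upper-tail hypergeometric)",
            f"  total bins N        : {self.N}",
            f"  occupied by A (K)   : {self.K}",
            f"  occupied by B (n)   : {self.n}",
            f"  jointly occupied (k): {self.k}",
            f"  fold over expected  : {self.fold:.3f}",
            f"  p (raw)             : {self.p_raw:.3g}",
            f"  p (Bonferroni x{self.n_comparisons})  : {self.p_bonferroni:.3g}",
        ]
        return "\n".join(lines)


class CooccurrenceTest:
    """Model object for co-occupancy of two peak sets on a shared bin grid.

    Built either from occupancy vectors or from two :class:`PeakSet` objects
    plus a grid.  ``restrict_universe=True`` limits N to bins occupied by at
    least one of the two sets instead of all genome bins (the default, more
    conservative universe).
    """

    def __init__(self, occ_a: np.ndarray, occ_b: np.ndarray,
                 n_comparisons: int = 1, restrict_universe: bool = False):
        occ_a = np.asarray(occ_a, dtype=bool)
        occ_b = np.asarray(occ_b, dtype=bool)
        if occ_a.shape != occ_b.shape:
            raise ValueError("occupancy vectors differ in length")
        if n_comparisons < 1:
            raise ValueError("n_comparisons must be >= 1")
        self.occ_a = occ_a
        self.occ_b = occ_b
        self.n_comparisons = int(n_comparisons)
        self.restrict_universe = restrict_universe

    @classmethod
    def from_peaksets(cls, peaks_a: PeakSet, peaks_b: PeakSet, grid: BinGrid,
                      n_comparisons: int = 1, restrict_universe: bool = False) -> "CooccurrenceTest":
        return cls(occupancy(peaks_a, grid), occupancy(peaks_b, grid),
                   n_comparisons=n_comparisons, restrict_universe=restrict_universe)

    def fit(self) -> CooccurrenceResults:
        a, b = self.occ_a, self.occ_b
        if self.restrict_universe:
            keep = a | b
            a, b = a[keep], b[keep]
        return CooccurrenceResults(
            N=int(a.size),
            K=int(a.sum()),
            n=int(b.sum()),
            k=int((a & b).sum()),
            n_comparisons=self.n_comparisons,
        )


def cooccurrence_test(occ_a: np.ndarray, occ_b: np.ndarray,
                      n_comparisons: int = 1) -> CooccurrenceResults:
    """Functional wrapper: fit a :class:`CooccurrenceTest` in one call."""
    return CooccurrenceTest(occ_a, occ_b, n_comparisons=n_comparisons).fit()
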