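"""Replicate-consistent fold-change differential expression and set overlap.

The caller reproduces a microarray-style scheme for duplicate designs:

* detection floor — a gene is testable only if its signal exceeds the
  background floor (default 45, strict ``>``) in at least one of the compared
  samples;
* pairwise consistency — every replicate-by-replicate ratio between the two
  groups must agree in direction (all > 1 for "up", all < 1 for "down");
  genes with mixed directions are excluded as inconsistent;
* tiered fold thresholds — the summary fold (geometric mean of the pairwise
  ratios, or of their reciprocals for "down") is compared against ordered
  tiers, 1.5 and 2.5 by default; tier sets are nested by construction.

Also here: the r² concordance between two fold-change panels (e.g. qRT-PCR
validation against the array), and the hypergeometric overlap between a
bound-gene set and a differentially expressed set over a shared universe.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cooccurrence import hypergeom_upper
from .errors import FormatError


@dataclass
class DEParams:
    """Detection floor and ordered fold-change tiers."""

    floor: float = 45.0
    fold_thresholds: tuple[float, ...] = (1.5, 2.5)
    #: "pairwise" (all replicate-by-replicate ratios) or "mean" (group means)
    comparison: str = "pairwise"

    def __post_init__(self):
        if self.floor < 0:
            raise ValueError("floor must be >= 0")
        tiers = tuple(self.fold_thresholds)
        if any(t <= 1 for t in tiers) or list(tiers) != sorted(set(tiers)):
            raise ValueError("fold thresholds must be strictly increasing and > 1")
        if self.comparison not in ("pairwise", "mean"):
            raise ValueError("comparison must be 'pairwise' or 'mean'")
        self.fold_thresholds = tiers


class ExpressionMatrix:
    """Normalized gene x sample signal matrix with a sample -> group map."""

    def __init__(self, data: pd.DataFrame, groups: Mapping[str, str]):
        if data.isna().any().any():
            raise ValueError("expression matrix contains missing cells")
        if data.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if (data.to_numpy() < 0).any():
            raise ValueError("negative expression signal")
        unknown = set(groups) - set(data.columns)
        if unknown:
            raise ValueError(f"group map names unknown samples: {sorted(unknown)}")
        self.data = data.astype(float)
        self.groups = dict(groups)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    def samples_in(self, group: str) -> list[str]:
        out = [s for s, g in self.groups.items() if g == group]
        if not out:
            raise ValueError(f"no samples in group {group!r}")
        return out

    def __repr__(self) -> str:
        return f"ExpressionMatrix({self.data.shape[0]} genes x {self.data.shape[1]} samples)"


def read_expression(path: str | Path, groups: Mapping[str, str]) -> ExpressionMatrix:
    """Read a TSV expression matrix (first column = gene id, header row)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        return ExpressionMatrix(df, groups)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


@dataclass
class DEResults:
    """Per-gene differential-expression calls.

    ``table`` columns: direction (up/down/none), fold (summary fold >= 1 for
    called directions), tier (highest threshold passed, NaN if none), reason
    (pass / floor / inconsistent / below_threshold).
    """

    table: pd.DataFrame
    params: DEParams
    group_a: str
    group_b: str

    def genes_at(self, tier: float) -> set[str]:
        """Genes with a consistent direction and summary fold >= tier."""
        t = self.table
        return set(t.index[(t["direction"] != "none") & (t["fold"] >= tier)])

    def counts(self) -> pd.Series:
        return pd.Series(
            {t: len(self.genes_at(t)) for t in self.params.fold_thresholds},
            name="n_genes",
        )

    def summary(self) -> str:
        n = len(self.table)
        lines = [
            f"Differential expression: {self.group_b} vs {self.group_a} "
            f"({n} genes, floor>{self.params.floor:g}, "
            f"{self.params.comparison} comparisons)",
        ]
        for t in self.params.fold_thresholds:
            genes = self.genes_at(t)
            up = sum(self.table.loc[g, "direction"] == "up" for g in genes)
            lines.append(f"  fold >= {t:g}: {len(genes)} genes ({up} up, {len(genes) - up} down)")
        reasons = self.table["reason"].value_counts()
        lines.append("  exclusions: " + ", ".join(f"{k}={v}" for k, v in reasons.items()
                                                  if k != "pass"))
        return "\n".join(lines)

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="gene_id")


class DifferentialExpression:
    """Model object: tiered fold-change DE between two sample groups."""

    def __init__(self, matrix: ExpressionMatrix, group_a: str, group_b: str,
                 params: DEParams | None = None):
        self.matrix = matrix
        self.group_a = group_a
        self.group_b = group_b
        self.params = params or DEParams()
        self.samples_a = matrix.samples_in(group_a)
        self.samples_b = matrix.samples_in(group_b)

    def fit(self) -> DEResults:
        p = self.params
        a = self.matrix.data[self.samples_a].to_numpy()
        b = self.matrix.data[self.samples_b].to_numpy()
        genes = self.matrix.genes

        directions, folds, tiers, reasons = [], [], [], []
        for i in range(len(genes)):
            av, bv = a[i], b[i]
            if not ((av > p.floor).any() or (bv > p.floor).any()):
                directions.append("none")
                folds.append(np.nan)
                tiers.append(np.nan)
                reasons.append("floor")
                continue
            if p.comparison == "pairwise":
                ratios = np.array([_ratio(y, x) for x, y in itertools.product(av, bv)])
            else:
                ratios = np.array([_ratio(bv.mean(), av.mean())])
            if np.isnan(ratios).any():
                direction = "none"
            elif (ratios > 1).all():
                direction = "up"
            elif (ratios < 1).all():
                direction = "down"
            else:
                direction = "none"
            if direction == "none":
                directions.append("none")
                folds.append(np.nan)
                tiers.append(np.nan)
                reasons.append("inconsistent")
                continue
            with np.errstate(divide="ignore"):
                logs = np.log(ratios if direction == "up" else 1.0 / ratios)
            fold = float(np.exp(logs.mean())) if np.isfinite(logs).all() else float("inf")
            passed = [t for t in p.fold_thresholds if fold >= t]
            directions.append(direction)
            folds.append(fold)
            tiers.append(passed[-1] if passed else np.nan)
            reasons.append("pass" if passed else "below_threshold")

        table = pd.DataFrame(
            {"direction": directions, "fold": folds, "tier": tiers, "reason": reasons},
            index=pd.Index(genes, name="gene_id"),
        )
        return DEResults(table, p, self.group_a, self.group_b)


def _ratio(num: float, den: float) -> float:
    """b/a ratio with explicit zero handling; 0/0 is undefined (NaN)."""
    if den == 0 and num == 0:
        return float("nan")
    if den == 0:
        return float("inf")
    return num / den


def call_de(matrix: ExpressionMatrix, group_a: str, group_b: str,
            params: DEParams | None = None) -> DEResults:
    """Functional wrapper around :class:`DifferentialExpression`."""
    return DifferentialExpression(matrix, group_a, group_b, params).fit()


def concordance_r2(fold_changes_a: Sequence[float], fold_changes_b: Sequence[float],
                   log2_scale: bool = True) -> float:
    """Squared Pearson correlation between two fold-change panels.

    Equivalent to the r² of an ordinary least-squares trendline.  Computed on
    log2 fold changes by default (set ``log2_scale=False`` for the raw
    scale); requires >= 3 pairs and non-degenerate variance.
    """
    x = np.asarray(fold_changes_a, dtype=float)
    y = np.asarray(fold_changes_b, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("fold-change vectors must be 1-D and equally long")
    if x.size < 3:
        raise ValueError("need at least 3 paired fold changes")
    if log2_scale:
        if (x <= 0).any() or (y <= 0).any():
            raise ValueError("log2 scale requires positive fold changes")
        x, y = np.log2(x), np.log2(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a fold-change vector")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


@dataclass
class OverlapResult:
    """Hypergeometric overlap of a bound-gene set with a DE-gene set."""

    universe_size: int
    n_bound: int
    n_de: int
    n_intersection: int

    @property
    def p_value(self) -> float:
        return hypergeom_upper(self.universe_size, self.n_bound,
                               self.n_de, self.n_intersection)

    def summary(self) -> str:
        return (
            f"Bound x DE gene overlap: |universe|={self.universe_size}, "
            f"|bound|={self.n_bound}, |DE|={self.n_de}, "
            f"|intersection|={self.n_intersection}, "
            f"hypergeometric p={self.p_value:.3g}"
        )


def bound_gene_overlap(bound_genes: Iterable[str], de_genes: Iterable[str],
                       universe: Iterable[str]) -> OverlapResult:
    """Upper-tail hypergeometric overlap test over an explicit gene universe."""
    universe = set(universe)
    bound = set(bound_genes)
    de = set(de_genes)
    if not universe:
        raise ValueError("empty gene universe")
    if not bound <= universe or not de <= universe:
        raise ValueError("bound/DE sets must be subsets of the universe")
    return OverlapResult(
        universe_size=len(universe),
        n_bound=len(bound),
        n_de=len(de),
        n_intersection=len(bound & de),
    )
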