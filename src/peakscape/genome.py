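"""Genome coordinate system, annotation ingestion and the feature-class partition.

All coordinates are internally 0-based, half-open ``[start, end)``.  GTF input
(1-based, closed) is converted on read; refFlat and BED are native.

The central derived object is the :class:`FeatureMap`: a disjoint partition of
every base of the genome into six classes -- promoter, 5'UTR, exon, 3'UTR,
intron, intergenic -- with a fixed precedence resolving overlaps
(CDS-exon > utr5 > utr3 > intron > promoter > intergenic).  Gene-body bases are
therefore never counted as promoter, and the promoter of one gene may be
overridden by the body of another.  The promoter is the window immediately
upstream of the transcription start site (default 5 kb), strand-aware and
clipped to the chromosome.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np

from .errors import AnnotationError, FormatError

#: Feature classes in paint order: later entries take precedence when bases
#: would belong to several classes.
FEATURE_CLASSES = ("intergenic", "promoter", "intron", "utr3", "utr5", "exon")
CLASS_CODE = {name: code for code, name in enumerate(FEATURE_CLASSES)}

STRANDS = ("+", "-", ".")


class ChromSizes:
    """Ordered chromosome name -> length (bp) mapping."""

    def __init__(self, sizes: Mapping[str, int] | Sequence[tuple[str, int]]):
        items = list(sizes.items()) if isinstance(sizes, Mapping) else list(sizes)
        names = [n for n, _ in items]
        if len(set(names)) != len(names):
            raise FormatError("duplicate chromosome names")
        for name, length in items:
            if not isinstance(length, (int, np.integer)) or length <= 0:
                raise FormatError(f"chromosome {name!r}: length must be a positive integer, got {length!r}")
        self._sizes: dict[str, int] = {n: int(l) for n, l in items}

    def __getitem__(self, name: str) -> int:
        return self._sizes[name]

    def __contains__(self, name: str) -> bool:
        return name in self._sizes

    def __iter__(self) -> Iterator[str]:
        return iter(self._sizes)

    def __len__(self) -> int:
        return len(self._sizes)

    def __eq__(self, other) -> bool:
        return isinstance(other, ChromSizes) and self._sizes == other._sizes

    def items(self):
        return self._sizes.items()

    @property
    def names(self) -> list[str]:
        return list(self._sizes)

    @property
    def total_length(self) -> int:
        return sum(self._sizes.values())

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, length in self._sizes.items():
                fh.write(f"{name}\t{length}\n")

    def __repr__(self) -> str:
        return f"ChromSizes({len(self)} chromosomes, {self.total_length} bp)"


def read_chrom_sizes(path: str | Path) -> ChromSizes:
    """Read a two-column ``name<TAB>length`` chromosome sizes file.

    An empty file yields an empty (but valid) :class:`ChromSizes`; downstream
    operations that need a non-empty genome reject it themselves.
    """
    items: list[tuple[str, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            name, length_s = fields
            try:
                length = int(length_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric length {length_s!r}") from None
            if length <= 0:
                raise FormatError(f"{path}:{lineno}: non-positive length {length}")
            items.append((name, length))
    return ChromSizes(items)


@dataclass(frozen=True)
class Interval:
    """Half-open genomic interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass
class Gene:
    """A gene with its body span, strand, and the union of its isoform exons.

    ``exons`` are sorted, non-overlapping and contained in the body.  The TSS
    is ``body.start`` on the + strand and ``body.end - 1`` on the - strand.
    ``cds_start``/``cds_end`` (half-open, optional) let UTR classes be split
    off the exonic bases; without a CDS all exonic bases are class ``exon``.
    """

    id: str
    body: Interval
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self):
        if self.body.strand not in ("+", "-"):
            raise AnnotationError(f"gene {self.id}: strand must be + or -")
        self.exons = sorted((int(s), int(e)) for s, e in self.exons)
        prev_end = self.body.start
        for s, e in self.exons:
            if s < prev_end:
                raise AnnotationError(f"gene {self.id}: exons overlap or precede the gene body")
            if e > self.body.end or s >= e:
                raise AnnotationError(f"gene {self.id}: exon [{s},{e}) outside gene body")
            prev_end = e

    @property
    def chrom(self) -> str:
        return self.body.chrom

    @property
    def strand(self) -> str:
        return self.body.strand

    @property
    def tss(self) -> int:
        return self.body.start if self.strand == "+" else self.body.end - 1

    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons."""
        return [
            (e0[1], e1[0])
            for e0, e1 in zip(self.exons, self.exons[1:])
            if e1[0] > e0[1]
        ]


@dataclass
class GenomeAnnotation:
    """A collection of genes over a fixed chromosome set."""

    genes: list[Gene]
    chrom_sizes: ChromSizes

    def __post_init__(self):
        for g in self.genes:
            if g.chrom not in self.chrom_sizes:
                raise AnnotationError(f"gene {g.id}: unknown chromosome {g.chrom!r}")
            if g.body.end > self.chrom_sizes[g.chrom]:
                raise AnnotationError(
                    f"gene {g.id}: extends past end of {g.chrom} ({self.chrom_sizes[g.chrom]} bp)"
                )

    def __len__(self) -> int:
        return len(self.genes)

    def gene_ids(self) -> list[str]:
        return [g.id for g in self.genes]

    def to_gtf(self, path: str | Path, source: str = "peakscape") -> None:
        """Write the annotation as GTF (1-based closed coordinates)."""
        with open(path, "w") as fh:
            for g in self.genes:
                attrs = f'gene_id "{g.id}";'
                fh.write(
                    f"{g.chrom}\t{source}\tgene\t{g.body.start + 1}\t{g.body.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )
                for s, e in g.exons:
                    fh.write(f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n")
                if g.cds_start is not None and g.cds_end is not None:
                    for s, e in g.exons:
                        cs, ce = max(s, g.cds_start), min(e, g.cds_end)
                        if cs < ce:
                            fh.write(f"{g.chrom}\t{source}\tCDS\t{cs + 1}\t{ce}\t.\t{g.strand}\t.\t{attrs}\n")


_GTF_GENE_ID = re.compile(r'gene_id\s+"([^"]+)"')


def read_annotation(path: str | Path, chrom_sizes: ChromSizes, dialect: str = "gtf") -> GenomeAnnotation:
    """Read a gene annotation in GTF or refFlat dialect.

    Exons of all transcripts of a gene are unioned (merged where overlapping):
    the analyses operate at gene level.  GTF coordinates (1-based closed) are
    converted to internal 0-based half-open on read.
    """
    if dialect == "gtf":
        return _read_gtf(path, chrom_sizes)
    if dialect == "refflat":
        return _read_refflat(path, chrom_sizes)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def _merge_intervals(ivs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(ivs):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _read_gtf(path: str | Path, chrom_sizes: ChromSizes) -> GenomeAnnotation:
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            if not raw.strip() or raw.startswith("#"):
                continue
            fields = raw.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns, got {len(fields)}")
            chrom, _, feature, start_s, end_s, _, strand, _, attrs = fields[:9]
            if feature not in ("gene", "transcript", "exon", "CDS"):
                continue
            m = _GTF_GENE_ID.search(attrs)
            if not m:
                raise FormatError(f"{path}:{lineno}: missing gene_id attribute")
            gene_id = m.group(1)
            try:
                start, end = int(start_s) - 1, int(end_s)  # 1-based closed -> 0-based half-open
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric coordinates") from None
            if gene_id not in genes:
                genes[gene_id] = {"chrom": chrom, "strand": strand, "body": None,
                                  "exons": [], "cds": []}
                order.append(gene_id)
            rec = genes[gene_id]
            if feature == "gene":
                rec["body"] = (start, end)
            elif feature == "exon":
                rec["exons"].append((start, end))
            elif feature == "CDS":
                rec["cds"].append((start, end))
    out: list[Gene] = []
    for gene_id in order:
        rec = genes[gene_id]
        if rec["chrom"] not in chrom_sizes:
            raise AnnotationError(f"gene {gene_id}: unknown chromosome {rec['chrom']!r}")
        exons = _merge_intervals(rec["exons"])
        if rec["body"] is not None:
            bstart, bend = rec["body"]
        elif exons:
            bstart, bend = exons[0][0], exons[-1][1]
        else:
            raise AnnotationError(f"gene {gene_id}: no gene or exon records")
        cds_start = min(s for s, _ in rec["cds"]) if rec["cds"] else None
        cds_end = max(e for _, e in rec["cds"]) if rec["cds"] else None
        out.append(Gene(
            id=gene_id,
            body=Interval(rec["chrom"], bstart, bend, rec["strand"]),
            exons=exons or [(bstart, bend)],
            cds_start=cds_start,
            cds_end=cds_end,
        ))
    return GenomeAnnotation(out, chrom_sizes)


def _read_refflat(path: str | Path, chrom_sizes: ChromSizes) -> GenomeAnnotation:
    # refFlat: geneName name chrom strand txStart txEnd cdsStart cdsEnd
    #          exonCount exonStarts exonEnds  (0-based half-open)
    by_gene: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            if not raw.strip() or raw.startswith("#"):
                continue
            f = raw.rstrip("\n").split("\t")
            if len(f) < 11:
                raise FormatError(f"{path}:{lineno}: expected 11 refFlat columns, got {len(f)}")
            gene_id, _, chrom, strand, tx_s, tx_e, cds_s, cds_e, n_ex, ex_s, ex_e = f[:11]
            try:
                tx_start, tx_end = int(tx_s), int(tx_e)
                cds_start, cds_end = int(cds_s), int(cds_e)
                starts = [int(x) for x in ex_s.rstrip(",").split(",")]
                ends = [int(x) for x in ex_e.rstrip(",").split(",")]
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-numeric coordinates") from None
            if len(starts) != len(ends) or len(starts) != int(n_ex):
                raise FormatError(f"{path}:{lineno}: exon count mismatch")
            if gene_id not in by_gene:
                by_gene[gene_id] = {"chrom": chrom, "strand": strand,
                                    "body": [tx_start, tx_end], "exons": [], "cds": []}
                order.append(gene_id)
            rec = by_gene[gene_id]
            rec["body"][0] = min(rec["body"][0], tx_start)
            rec["body"][1] = max(rec["body"][1], tx_end)
            rec["exons"].extend(zip(starts, ends))
            if cds_start < cds_end:
                rec["cds"].append((cds_start, cds_end))
    out: list[Gene] = []
    for gene_id in order:
        rec = by_gene[gene_id]
        if rec["chrom"] not in chrom_sizes:
            raise AnnotationError(f"gene {gene_id}: unknown chromosome {rec['chrom']!r}")
        out.append(Gene(
            id=gene_id,
            body=Interval(rec["chrom"], rec["body"][0], rec["body"][1], rec["strand"]),
            exons=_merge_intervals(rec["exons"]),
            cds_start=min(s for s, _ in rec["cds"]) if rec["cds"] else None,
            cds_end=max(e for _, e in rec["cds"]) if rec["cds"] else None,
        ))
    return GenomeAnnotation(out, chrom_sizes)


def promoter_interval(gene: Gene, window_bp: int, chrom_sizes: ChromSizes) -> Interval | None:
    """The window immediately upstream of the TSS, strand-aware and clipped.

    Returns ``None`` when the TSS sits at the chromosome edge and the window
    is empty after clipping.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be positive")
    length = chrom_sizes[gene.chrom]
    if gene.strand == "+":
        start, end = max(0, gene.tss - window_bp), gene.tss
    else:
        start, end = gene.body.end, min(length, gene.body.end + window_bp)
    if start >= end:
        return None
    return Interval(gene.chrom, start, end, gene.strand)


class FeatureMap:
    """Disjoint partition of the genome into the six feature classes.

    Stored per chromosome as segment breakpoints plus a class code per
    segment, so class lookup for an array of positions is a single
    ``searchsorted``.  The union of all classes covers every base exactly
    once; ``class_lengths`` therefore sums to the genome length.
    """

    def __init__(self, chrom_sizes: ChromSizes,
                 segments: Mapping[str, tuple[np.ndarray, np.ndarray]],
                 promoter_window: int):
        self.chrom_sizes = chrom_sizes
        self._segments = dict(segments)  # chrom -> (breaks starting at 0, codes)
        self.promoter_window = promoter_window

    @property
    def classes(self) -> tuple[str, ...]:
        return FEATURE_CLASSES

    def class_at(self, chrom: str, positions) -> np.ndarray:
        """Class code for each 0-based position on ``chrom`` (vectorized)."""
        positions = np.asarray(positions, dtype=np.int64)
        length = self.chrom_sizes[chrom]
        if positions.size and (positions.min() < 0 or positions.max() >= length):
            raise ValueError(f"position outside chromosome {chrom} [0, {length})")
        breaks, codes = self._segments[chrom]
        idx = np.searchsorted(breaks, positions, side="right") - 1
        return codes[idx]

    def class_name_at(self, chrom: str, position: int) -> str:
        return FEATURE_CLASSES[int(self.class_at(chrom, [position])[0])]

    def class_lengths(self) -> dict[str, int]:
        out = dict.fromkeys(FEATURE_CLASSES, 0)
        for chrom, (breaks, codes) in self._segments.items():
            length = self.chrom_sizes[chrom]
            ends = np.append(breaks[1:], length)
            seg_len = ends - breaks
            for code, name in enumerate(FEATURE_CLASSES):
                out[name] += int(seg_len[codes == code].sum())
        return out

    def class_fractions(self) -> dict[str, float]:
        total = self.chrom_sizes.total_length
        return {k: v / total for k, v in self.class_lengths().items()}

    def intervals(self, class_name: str) -> list[Interval]:
        code = CLASS_CODE[class_name]
        out = []
        for chrom in self.chrom_sizes:
            breaks, codes = self._segments[chrom]
            ends = np.append(breaks[1:], self.chrom_sizes[chrom])
            for s, e, c in zip(breaks, ends, codes):
                if c == code:
                    out.append(Interval(chrom, int(s), int(e)))
        return out

    def to_bed(self, path: str | Path) -> None:
        """Export the partition as BED4 (name column = feature class)."""
        with open(path, "w") as fh:
            for chrom in self.chrom_sizes:
                breaks, codes = self._segments[chrom]
                ends = np.append(breaks[1:], self.chrom_sizes[chrom])
                for s, e, c in zip(breaks, ends, codes):
                    fh.write(f"{chrom}\t{s}\t{e}\t{FEATURE_CLASSES[c]}\n")

    @classmethod
    def from_bed(cls, path: str | Path, chrom_sizes: ChromSizes,
                 promoter_window: int = 5000) -> "FeatureMap":
        per_chrom: dict[str, list[tuple[int, int, int]]] = {c: [] for c in chrom_sizes}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                if not raw.strip():
                    continue
                f = raw.rstrip("\n").split("\t")
                if len(f) < 4 or f[3] not in CLASS_CODE:
                    raise FormatError(f"{path}:{lineno}: expected BED4 with a feature-class name")
                chrom, start, end = f[0], int(f[1]), int(f[2])
                if chrom not in per_chrom:
                    raise FormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                per_chrom[chrom].append((start, end, CLASS_CODE[f[3]]))
        segments = {}
        for chrom, rows in per_chrom.items():
            rows.sort()
            pos = 0
            breaks, codes = [], []
            for s, e, c in rows:
                if s != pos:
                    raise FormatError(f"feature map BED does not tile {chrom} (gap or overlap at {s})")
                breaks.append(s)
                codes.append(c)
                pos = e
            if pos != chrom_sizes[chrom]:
                raise FormatError(f"feature map BED does not cover {chrom} to its end")
            segments[chrom] = (np.array(breaks, dtype=np.int64), np.array(codes, dtype=np.uint8))
        return cls(chrom_sizes, segments, promoter_window)


def _gene_exon_paint(gene: Gene) -> list[tuple[int, int, int]]:
    """Exonic bases split into exon/utr5/utr3 paint jobs for one gene."""
    jobs: list[tuple[int, int, int]] = []
    cs, ce = gene.cds_start, gene.cds_end
    has_cds = cs is not None and ce is not None and cs < ce
    for s, e in gene.exons:
        if not has_cds:
            jobs.append((s, e, CLASS_CODE["exon"]))
            continue
        left_code = CLASS_CODE["utr5"] if gene.strand == "+" else CLASS_CODE["utr3"]
        right_code = CLASS_CODE["utr3"] if gene.strand == "+" else CLASS_CODE["utr5"]
        if s < cs:
            jobs.append((s, min(e, cs), left_code))
        mid_s, mid_e = max(s, cs), min(e, ce)
        if mid_s < mid_e:
            jobs.append((mid_s, mid_e, CLASS_CODE["exon"]))
        if e > ce:
            jobs.append((max(s, ce), e, right_code))
    return jobs


def build_feature_map(annotation: GenomeAnnotation, promoter_window: int = 5000) -> FeatureMap:
    """Build the disjoint feature partition with precedence
    exon > utr5 > utr3 > intron > promoter > intergenic.

    Implemented by painting a per-base label array in ascending precedence so
    later paints win, then run-length encoding into breakpoints.  Intended for
    desk-scale genomes (tens of Mb); memory is one byte per base.
    """
    if len(annotation.chrom_sizes) == 0:
        raise AnnotationError("empty genome: no chromosomes")
    chrom_sizes = annotation.chrom_sizes
    arrays = {c: np.zeros(chrom_sizes[c], dtype=np.uint8) for c in chrom_sizes}

    # paint in ascending precedence: promoter, intron, utr3, utr5, exon
    jobs_by_code: dict[int, list[tuple[str, int, int]]] = {c: [] for c in range(1, 6)}
    for g in annotation.genes:
        prom = promoter_interval(g, promoter_window, chrom_sizes)
        if prom is not None:
            jobs_by_code[CLASS_CODE["promoter"]].append((g.chrom, prom.start, prom.end))
        for s, e in g.introns():
            jobs_by_code[CLASS_CODE["intron"]].append((g.chrom, s, e))
        for s, e, code in _gene_exon_paint(g):
            jobs_by_code[code].append((g.chrom, s, e))
    for code in sorted(jobs_by_code):
        for chrom, s, e in jobs_by_code[code]:
            arrays[chrom][s:e] = code

    segments = {}
    for chrom, arr in arrays.items():
        change = np.flatnonzero(np.diff(arr)) + 1
        breaks = np.concatenate(([0], change)).astype(np.int64)
        codes = arr[breaks].astype(np.uint8)
        segments[chrom] = (breaks, codes)
    return FeatureMap(chrom_sizes, segments, promoter_window)
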