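# Methods

This note records the models, conventions and design choices behind
peakscape, in the spirit of a statistical package's methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Coordinates and the feature-class partition

All internal coordinates are 0-based, half-open `[start, end)`. GTF input
(1-based, closed) is converted on read; refFlat and BED are native. A single
convention avoids off-by-one drift between readers.

The genome is partitioned so that **every base belongs to exactly one** of
six classes: promoter, 5'UTR, exon, 3'UTR, intron, intergenic. Overlaps are
resolved by fixed precedence

    exon (CDS) > utr5 > utr3 > intron > promoter > intergenic

so gene-body bases are never counted as promoter, matching the treatment of
gene-body and promoter association as distinct categories. The promoter is
the strand-aware window `promoter_window` bases (default 5000) immediately
upstream of the TSS, clipped to the chromosome; the promoter of one gene may
be overridden by the body of another, deterministically. Whether a genuine
annotation pipeline should exclude other genes' bodies from promoter windows
is a judgment call; the precedence above is our documented choice and the
partition invariant (class lengths sum exactly to genome length) is enforced
by tests against an independent per-base brute-force classifier.

Genes are gene-level unions of their isoforms' exons (merged where
overlapping); introns are the gaps between consecutive merged exons. Without
an annotated CDS a gene contributes no UTR bases — its exonic bases are all
class `exon`.

The partition is stored per chromosome as breakpoint + class-code arrays, so
classifying a vector of positions is one `searchsorted`. Construction paints
a one-byte-per-base label array; this targets desk-scale genomes (tens of
Mb), not full mammalian assemblies.

## Peaks, anchors and gene association

Peaks come from MACS 1.4 tables (1-based starts converted; the seventh
column is −10·log10 p, so p = 10^(−x/10); the summit column is read as an
offset from the peak start) or from BED3+. Peak-level significance filtering
is a strict inequality (`p < max_p`), giving nested sets for the mild (0.01)
and stringent (0.001) thresholds.

A peak's **anchor** — the single base used for feature classification — is
its summit when present, else its midpoint. Fractional base-resolution
assignment was rejected for determinism and speed; the summit is the peak
caller's best position estimate.

Gene association uses any-overlap (≥ 1 bp) with the gene body, and
any-overlap with the promoter window, the standard reading of "peak within
the gene body"; full containment would silently drop boundary-straddling
peaks. A `mode="containment"` flag exposes the stricter rule. Peaks on
chromosomes absent from the annotation are retained but contribute no
associations (logged warning), tolerating scaffold mismatches.

## Permutation enrichment

The null re-places each peak uniformly at random on its own chromosome,
preserving peak length and per-chromosome counts; shuffled peaks may overlap
each other. This is the simplest exchangeable null consistent with a
length-preserving permutation test; GC- or mappability-matched nulls are out
of scope. Empirical p-values carry the +1 correction,

    p_enrich = (1 + #{permuted fraction ≥ observed}) / (n_perm + 1),

so the smallest attainable p is 1/(n_perm+1); the default n_perm = 10,000
resolves the 10⁻⁴ significance tier. p_deplete uses ≤; at ties both sides
count the tie, so p_enrich + p_deplete ≥ 1. The per-class enrichment score
is `log2((obs+ε)/(exp+ε))` with ε = 1/(2·n_peaks): the axis quantity of a
typical per-class "enrichment score" bar plot is not standardised anywhere,
so the log-ratio with a half-count pseudo-fraction is our documented choice —
zero when observed equals expected, finite for empty classes. Summary tables
star classes at p < 0.005 (*) and p < 0.0001 (****).

Because the permuted class fractions live on a grid of 1/n_peaks, ties make
the permutation p conservative (its exact size at α = 0.05 is below 0.05).
The calibration tests compute that exact size in closed form — under the
uniform null, observed and permuted anchor-class counts are iid binomial —
and verify both the size and the simulated rejection rate against it.

## Bin co-occurrence

Bins are anchored at coordinate 0 of each chromosome; the final bin may be
truncated but is kept, so bin lengths always sum to the genome length. A bin
is occupied by a peak set when ≥ 1 peak overlaps it by ≥ 1 base (presence,
not midpoint). The test conditions on the margins: with N bins, K occupied
by A, n occupied by B and k jointly occupied, p = P(X ≥ k) for
X ~ Hypergeometric(N, K, n), evaluated through scipy's log-space survival
function (stable to N ~ 10⁶ and p far below 10⁻³⁰⁰). Bonferroni correction
multiplies by the number of partner sets tested in one run, supplied
explicitly.

The default universe N is **all** genome bins; `restrict_universe=True`
limits it to bins occupied by at least one of the two sets. All-bins is the
conservative default; which universe an analysis should use depends on
whether unoccupiable bins (unmappable, unassayed) are plausible and is left
to the caller.

The per-class hypergeometric variant labels each bin by the feature class of
its midpoint base and tests whether peak-bearing bins over-represent a
class. At the default 3000 bp bin width this is far less sensitive than the
permutation test for classes much smaller than a bin (e.g. exons), because a
bin's midpoint label usually is not the class of the peak inside it; both
tests are provided and neither is privileged.

## Metagene profiles

Coverage is piecewise-constant per chromosome (bedGraph in; gaps are zero;
overlapping input intervals are rejected). TSS profiles average the window
`[TSS − flank, TSS + flank)` (minus-strand windows use the exact coordinate
mirror `[TSS − flank + 1, TSS + flank + 1)` and are reversed, which makes the
strand-mirror invariance exact). Length-scaled profiles cut each feature
into n_bins near-equal slices 5'→3'. Defaults: flank 5000 bp with 100 bins
(TSS); 50 bins with a 2·n_bins minimum feature length (scaled features).

Every per-feature vector is normalized by the **genome-wide mean coverage**,
not the per-feature mean, and features are averaged unweighted. Global
normalization preserves depletion — a promoter-depleted signal stays below 1
in the average — where per-feature normalization would erase it. Profiles of
a track and any scalar multiple of it are identical.

Profiles accept either read coverage or, through
`CoverageTrack.from_peaks`, a 0/1 peak-density track, since aggregate
binding plots are produced both ways in practice; both inputs are supported
and give the same invariances.

## Differential expression

The caller implements a microarray-style scheme for duplicate designs:

1. **Floor** (before any ratio): a gene is testable only if its signal is
   strictly above the background floor (default 45) in at least one compared
   sample. Floor-first ordering also disposes of 0/0 ratios.
2. **Pairwise consistency**: all replicate×replicate ratios b/a (2×2 = 4 for
   duplicates) must agree in direction; "up" requires every ratio > 1. A
   mean-vs-mean mode is available (`comparison="mean"`), but unanimous
   pairwise direction is the default because it is the most literal reading
   of selecting genes "either upregulated or downregulated in pairwise
   comparisons", and it is what makes the caller conservative at duplicate
   level: an unchanged gene passes only when both replicates of one group
   fall on the same side of both replicates of the other.
3. **Tiers**: the summary fold — geometric mean of the ratios, or of their
   reciprocals for "down" (symmetric under group swap) — is compared to the
   ordered tiers (1.5, 2.5). Tier sets are nested by construction. The 1.5x
   and 2.5x thresholds are treated as the operative rules; no parametric
   p-value model is reconstructed behind them.

A ratio with zero denominator and positive numerator is +∞; a gene whose
ratios include ∞ consistently gets an infinite summary fold (passes every
tier).

Fold-change concordance between two panels (e.g. array vs qRT-PCR) is the
squared Pearson correlation — equivalently the r² of the least-squares
trendline — computed on log2 fold changes by default (`log2_scale=False`
for the raw scale, since the scale used by spreadsheet trendlines varies).
Bound-gene × DE-gene overlap reuses the hypergeometric primitive; the
default universe is the genes present in both the annotation and the
expression matrix (the measurable universe).

## Synthetic data

Each generator is a pure function of (spec, seed) using one
`numpy.random.default_rng` stream; outputs are byte-identical across calls
and round-trip through the package's readers. A `TruthRecord` (JSON)
carries the planted parameters so every expected statistic is computable
without re-reading generator internals.

* **Genome**: 10 chromosomes × 100 kb, 100 non-overlapping genes (rejection
  sampling with bounded retries), geometric exon counts (mean 4, min 1),
  log-normal exon (~200 bp) and intron (~800 bp) lengths, random strands,
  80% of genes with a CDS so UTR classes are populated. The scale keeps
  whole-suite runs in seconds while giving every class a workable base
  fraction.
* **Peaks**: anchors drawn per class with probability ∝ propensity × class
  base fraction, then uniform within the class; log-normal lengths (~300
  bp); MACS-style −10·log10 p scores drawn in [30, 100] so significance
  filtering is exercised. Equal propensities reproduce the genomic base
  composition exactly.
* **Co-occurring peaks**: each bin occupied by the base set spawns a partner
  peak with probability `p_given`, every other bin with `p_background`;
  partner peaks are placed entirely inside their bin.
* **Expression**: duplicate design; log-normal baselines (floored at 60 so
  expressed genes clear the detection floor), a separate ~20% floor-region
  cohort with signals in [5, 40], planted folds (default 2.0, half up, half
  down) applied to group B, multiplicative log-normal noise with CV 0.10.

What the generators deliberately do **not** emulate: read-level sampling
noise, GC/mappability bias, probe effects, correlated replicates, or
overlapping genes. Passing tests therefore demonstrate that the statistics
recover what was planted under clean, independent noise — not that they are
robust to every artifact of real ChIP-Seq or microarray data.

## Problem sizes and numerical choices

The test and acceptance runs use the 1 Mb toy genome with 200–500 peaks,
2000 permutations, 200 null seeds and 50 recovery seeds, and 1000-gene
expression matrices over 50 seeds — sizes chosen so the full suite completes
in well under a minute while leaving the binomial error of every rate
estimate far smaller than the margins being tested.

Degenerate inputs are rejected loudly rather than coerced: empty genomes,
bins over empty chromosome sets, zero genome-wide coverage, peaks longer
than their chromosome, fold-change vectors with zero variance, and
occupancy-vector length mismatches all raise. Permutation seeds are
mandatory in the pipeline configuration; every pipeline run writes a
manifest with input checksums and the resolved configuration.

## Known limitations

* The per-base painting construction of the partition bounds practical
  genome size (roughly one byte per base of RAM).
* The permutation null preserves length and chromosome but not inter-peak
  spacing or chromatin context.
* The DE caller is designed for the duplicate setting; with many replicates,
  unanimous pairwise direction becomes increasingly strict and a
  moderated-variance method would be preferable.
* Bonferroni across partners is the only multiplicity correction offered.
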