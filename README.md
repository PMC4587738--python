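# peakscape

Downstream analyses for ChIP-Seq peak sets on annotated genomes, built around
the questions a chromatin-protein binding study asks once peaks are called:

* **Where does the protein bind?** Classify peaks into promoter / 5'UTR /
  exon / 3'UTR / intron / intergenic and test per-class enrichment or
  depletion with a length-preserving permutation null, plus a
  bin-based hypergeometric variant.
* **How does binding look on the average gene?** Metagene coverage profiles
  around the TSS and within length-scaled introns and exons.
* **Does binding co-occur with another mark?** Tile the genome with
  non-intersecting bins (3000 bp by default), score bin co-occupancy of two
  peak sets with an upper-tail hypergeometric test, Bonferroni-corrected
  across a panel of partners.
* **Which genes are bound, and are they misregulated?** Peak-to-gene
  association (gene body overlap, or the 5 kb window upstream of the TSS),
  a replicate-consistent fold-change differential-expression caller for
  duplicate designs (detection floor 45; 1.5x and 2.5x tiers), and the
  hypergeometric overlap between bound-gene and DE-gene sets.

A seeded synthetic-data module generates toy genomes, peak sets with
controlled feature-class propensities and co-occupancy, coverage tracks and
duplicate expression matrices with planted truth, so every stage is testable
without downloading any external data.

## The statistics in brief

**Permutation enrichment.** Each peak contributes one anchor base (summit if
present, midpoint otherwise) classified against a disjoint partition of the
genome. The null re-places every peak uniformly at random on its own
chromosome, preserving its length. For each class with observed fraction
*obs* and permuted fractions *f₁…f_B*:

    p_enrich = (1 + #{f_b ≥ obs}) / (B + 1)
    score    = log2((obs + ε) / (exp + ε)),  exp = mean f_b,  ε = 1/(2·n_peaks)

**Bin co-occurrence.** With *N* genome bins, *K* occupied by set A, *n* by
set B and *k* jointly occupied, the p-value is the upper tail
P(X ≥ k), X ~ Hypergeometric(N, K, n), multiplied by the number of partner
sets tested (Bonferroni).

**Differential expression.** A gene is testable if any compared signal
exceeds the floor (> 45). All replicate-by-replicate ratios b/a must agree
in direction; the summary fold is the geometric mean of the ratios (or their
reciprocals for "down") and is compared to the ordered tiers 1.5 and 2.5.

## Worked example

```python
import peakscape as pk

# a 10 x 100 kb toy genome with 100 genes, and peaks with a 4x exon preference
sizes, ann, _ = pk.simulate_genome(pk.GenomeSpec(), seed=11)
fm = pk.build_feature_map(ann, promoter_window=5000)
spec = pk.PeakSpec(n_peaks=500)
spec.propensities["exon"] = 4.0
peaks, _ = pk.simulate_peaks(ann, spec, seed=12, feature_map=fm)

res = pk.PeakFeatureEnrichment(peaks, fm).fit(n_permutations=10_000, seed=13)
print(res.summary())
```

```
Feature-class enrichment  (500 peaks, 10000 permutations, seed=13)
score = log2((obs+eps)/(exp+eps)), eps=0.001
            observed  expected   score  p_enrich  p_deplete   sig
intergenic     0.268    0.3142 -0.2289    0.9915     0.0124
promoter       0.226    0.2971 -0.3933         1  9.999e-05  ****
intron           0.2    0.2951 -0.5589         1  9.999e-05  ****
utr3           0.004  0.004797 -0.2134    0.6908     0.5643
utr5               0  0.004952  -2.573         1    0.08399
exon           0.302   0.08375   1.838 9.999e-05          1  ****
```

The planted exon preference is recovered: 30.2% of peaks anchor in exons
against an expected 8.4% under the permutation null (log2 score 1.8,
p = 1/(B+1), the smallest attainable value), while promoters and introns are
significantly depleted. The same objects feed the other analyses:

```python
de = pk.call_de(pk.simulate_expression(pk.ExpressionSpec(), seed=14)[0], "WT", "KO")
print(de.summary())
```

```
Differential expression: KO vs WT (2000 genes, floor>45, pairwise comparisons)
  fold >= 1.5: 100 genes (50 up, 50 down)
  fold >= 2.5: 3 genes (2 up, 1 down)
  exclusions: inconsistent=998, below_threshold=513, floor=389
```

All 100 planted 2-fold changes are recovered at the 1.5x tier with the
correct directions; replicate-direction consistency excludes almost every
unchanged gene.

A command-line interface mirrors the library
(`peakscape annotate|associate|enrich|metagene|cooccur|de-call|overlap|simulate|run`),
and `peakscape run --config run.yaml` executes the whole pipeline with a
reproducible manifest.

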