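# Methods

## The detection model

`isotrend` compares an isoform's pseudobulk CPM profile across selected cell
types against two references: the parent gene (the sum of the gene's isoform
CPM, which by linearity of CPM equals the CPM of summed gene counts) and the
gene's major isoform.  Pseudobulk is the sum of raw counts over each cell
type's cells, scaled to 1e6 per type.  Summing before normalising — rather
than averaging per-cell CPM — makes the profile insensitive to per-cell depth
variation and preserves the row-sum invariant that the tests assert.

Candidates must (a) be detected (count > 0) in at least `min_pct` of the
cells of **at least one** selected cell type, and (b) contribute strictly
more than `gene_fraction_min` (default 0.10) of the gene's raw counts pooled
over all selected cells.  The any-type reading of `min_pct` mirrors the
marker-detection convention the workflow builds on; computing the gene
fraction over pooled cells (not per type) keeps it a single per-isoform
quantity.  An optional one-vs-rest Wilcoxon rank-sum marker prefilter
(two-sided, on per-cell log-normalised expression with scale factor 1e4;
|avg log2 fold change| > 1 with pseudocount 1e-9, raw p < 0.05, Bonferroni
available but off) restricts candidates to cell-type markers.

The **major isoform** is the gene's isoform with the highest CPM summed over
the selected cell types, assigned once globally (not per comparison pair);
ties break to the lexicographically smallest identifier so runs are
deterministic.

### Multi-cell-type statistic (n ≥ 3)

For isoform vector *x* and reference vector *y* over the *n* selected cell
types, divergence is one minus the explanatory power of a single-predictor
linear regression:

    R2_adj = 1 − (1 − r²)(n − 1)/(n − k − 1),  k = 1,

with *r* the Pearson correlation (clamped to [−1, 1] against floating-point
drift; defined as 0 when either vector has no variance, which sends R2_adj to
its k = 1 floor — a flat reference explains nothing).  An isoform is a
multi-DEI when R2_adj < 0.2 **and** its isoform-to-gene CPM ratio spans a
range ≥ 0.05 across the types.  The ratio is always taken against the gene —
also for major-isoform comparisons — because the ratio is only meaningful
relative to total gene expression.  Note the statistic is sign-blind: a
perfectly anti-correlated isoform has R2_adj = 1 and is *not* called; such
results carry a `negative_r` flag instead of being silently reinterpreted.
Requests with n < 3 raise and point the caller to pair mode (the residual
degrees of freedom n − 2 would vanish).

### Two-cell-type statistic (n = 2)

With two points the Pearson correlation degenerates to the trend sign
(±1, undefined when either vector is constant between the two types).  The
sign is multiplied by the cosine similarity of the two CPM vectors; the
product is near +1 only when the isoform tracks its reference.  Selection is
sign-branched: positive products below 0.9, negative products above −1.
Because cosine is non-negative for CPM vectors and a product of −1 would
require the contradictory pair (r = −1, cos θ = 1), the negative branch as
literally defined admits every achievable negative product; the bound is
kept configurable and the consequences are discussed under *Benchmark
design* below.  A product of exactly 0 (maximal directional divergence, e.g.
expression confined to opposite cell types) falls in the positive branch and
is selected; an undefined sign contributes a product of 0.  Selected
candidates are pair-DEIs when the isoform-to-gene ratio changes by at least
0.05 between the two types (the threshold mirrors the multi-mode ratio-range
default).  Both-zero vector pairs are flagged degenerate and excluded.

Comparisons against the major isoform are suppressed for genes whose major
isoform is itself selected (by the same product rule) against the gene on
that pair, since its divergence would otherwise be attributed to the wrong
reference.  A candidate that *is* the major isoform is compared against the
gene only.

### Modes are independent

Multi-DEI and pair-DEI calling are independent analyses over different
cell-type selections; neither is a prerequisite of the other.  Candidates
are evaluated against gene and major isoform separately and the result
tables keep both references.

## Benchmark simulator

The generator plants known differential isoforms and regenerates the
factorial benchmark: 1000 genes × 3 isoforms, exactly one differential
isoform per gene, two conditions × two replicates, bulk depths 0.5M/1M/2M
reads (12 bulk samples) and 300/500/1000 cells at each depth (36 single-cell
datasets, one per condition; `simulate_paired_single_cell` merges the two
matching condition datasets into the analysis-ready two-group matrix).

* **Gene abundances** are log-normal (meanlog 4, sdlog 0.5), shared across
  conditions, so the differential signal is purely in isoform usage.  Only
  the sdlog matters for relative abundances; 0.5 gives moderate heterogeneity
  (~4-fold spread over the central 95% of genes).  At the benchmark scale —
  1M reads over 1000 genes and 500 cells per group, i.e. 2 reads per cell per
  gene on average — a wider spread (sdlog 1) would push the minor isoforms of
  the lower half of genes below the detection-rate floor of the candidate
  filters, leaving a benchmark that measures the abundance lottery rather
  than the statistics.
* **Isoform usage** within a gene is (0.65, 0.30, 0.05), dominant to minor.
  Effect tiers cycle over genes round-robin: *mild/moderate/strong* shift the
  minor isoform's usage up by 0.15/0.30/0.45 in condition 2 (a ≥4-fold usage
  change — the pair product rule is blind to changes below ~2.9-fold — while
  keeping the pooled gene fraction of the planted isoform above the 10%
  candidate filter), with siblings renormalised proportionally; *reversed*
  is a dominance reversal from base usage (0.50, 0.45, 0.05): the designated
  dominant isoform collapses to minor-level usage so the gene's major isoform
  differs between conditions.  An exact dominant↔minor swap is deliberately
  avoided: it would make the swap partner change by the same factor as the
  planted isoform, so any correct detector would flag both while the ground
  truth lists one differential isoform per gene — the benchmark would cap
  precision at 0.8 by construction.
* **Bulk counts** are Poisson around depth × abundance × usage: a count-level
  stand-in for read-level simulation and re-quantification, which the
  detector never sees beyond counts.  Replicates share expectations and
  differ only in noise.
* **Single-cell counts** per cell are negative binomial with mean
  (depth / cells) × relative abundance and dispersion 0.3
  (variance μ + 0.3 μ²), then zeroed with probability
  1/(1 + exp(shape·(ln μ − midpoint))) — logistic in log mean, following the
  Splatter/scDesign2 principle that technical loss falls with expression.
  Defaults shape 1, midpoint ln 0.02: dropout is concentrated in weakly
  expressed molecules (50% at μ = 0.02, ~9% at μ = 0.2).  At 2 reads per
  cell per gene, a midpoint near typical isoform means would remove most of
  the planted signal before any statistic sees it.
* **Seeding**: one master seed; every dataset draws from a substream keyed by
  its (condition, replicate, depth, cell-count) indices, so each dataset is
  independently reproducible and the paired matrix is exactly the
  column-concatenation of its two condition datasets.

### What the benchmark does and does not show

The simulator emulates count-level sparsity, overdispersion and
expression-dependent dropout, with planted usage shifts of controlled size.
It does **not** emulate read-level artefacts (mapping or isoform-assignment
errors, UMI collisions), correlated cell states within a type, batch
effects, or genes whose abundance itself differs between cell types.
Passing benchmarks therefore show the statistics and filters behave as
designed under the stated noise model — not that real long-read data meet
those assumptions.

The benchmark analysis uses `min_pct = 0.1` (the recommended sparse-data
setting; at 2 reads per cell per gene the 0.25 default filters isoforms the
statistics could otherwise detect) and scores the full workflow including
the marker prefilter.  The prefilter matters for planted-truth scoring:
usage is zero-sum, so the siblings of a shifted isoform change their gene
ratio by the complementary amount, and the literal negative branch of the
pair rule admits them whenever noise flips the trend sign of the near-flat
gene vector.  The marker step excludes those compensatory changes (fold
change ≤ ~1.9×) while keeping planted isoforms (≥ 4×); without it,
measured precision drops from ~0.95 to ~0.57 at unchanged recall.  This is
a property of scoring against a one-differential-per-gene truth, not of the
statistics: the sibling calls are real usage changes, just not the planted
ones.

## Empirical FDR

Detections on the true labels give N_detected(t); each of `n_perm` uniform
label permutations (group sizes preserved by construction) is re-analysed
end to end and its detections counted as false positives; FDR(t) is the mean
false-positive count over permutations divided by N_detected(t), reported
capped at 1 with the raw ratio retained, and flagged (0) where nothing is
detected on the true labels.  One permutation set is shared across the
threshold grid: the detection statistics do not depend on the threshold, so
each labelling is scored once and thresholded cheaply, which also removes
across-threshold permutation noise.  The grid scans the pair product
threshold in pair mode and the adjusted-R² threshold in multi mode.  The
marker prefilter is off by default here and, when enabled, is re-run on
every permuted labelling so the permuted analyses remain exchangeable with
the true one.

## Numerical choices and degenerate inputs

* Pearson r clamped to [−1, 1]; cosine computed on pre-normalised vectors
  (robust to extreme magnitudes) and clamped likewise.
* Zero-variance vectors: r := 0 in multi mode; undefined sign flag in pair
  mode.  Zero gene CPM gives ratio 0.  Cell types with zero total counts
  keep an all-zero CPM row and are flagged.
* Major-isoform ties and the all-zero-gene fallback resolve
  lexicographically and are flagged.
* Unannotated cells and unmapped isoforms are dropped with a logged warning;
  conflicting annotations or transcript-to-gene conflicts are errors.
* Result tables are sorted by (isoform, reference, comparison) so reruns are
  byte-identical.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_pct` | 0.25 (0.1 for sparse data) | detection-rate floor, any one type |
| `gene_fraction_min` | 0.10 (strict >) | isoform's share of gene counts |
| `adj_r2_threshold` | 0.2 | multi-mode divergence cutoff |
| `ratio_range_threshold` | 0.05 | multi-mode minimum ratio spread |
| `product_pos_threshold` | 0.9 | pair-mode positive product cutoff |
| `product_neg_threshold` | −1 | pair-mode negative bound (vacuous by default) |
| `ratio_diff_threshold` | 0.05 | pair-mode minimum ratio change |
| `nb_dispersion` | 0.3 | single-cell overdispersion |
| `dropout_midpoint`, `dropout_shape` | ln 0.02, 1 | logistic dropout in log mean |
| `abundance_meanlog`, `abundance_sdlog` | 4, 0.5 | log-normal gene abundances |

## Known limitations

* The pair statistic cannot see usage changes below ~2.9-fold (positive
  branch) and its negative branch is sign-noise-sensitive for near-flat
  references; the marker prefilter is the practical guard.
* The multi statistic is blind to anti-correlated divergence (flagged, not
  called).
* The empirical FDR reuses permutations across thresholds; estimates at
  different thresholds are therefore correlated.
* The simulator's effect tiers, usage patterns, dispersion and dropout
  parameters are package choices (the benchmark's original read-level
  generation pipeline is out of scope); they are all exposed on
  `SimulationDesign`.
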