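# isotrend

Differential isoform trend analysis for long-read single-cell RNA-seq.

Long reads quantify full-length transcripts, so a single-cell experiment
yields an isoform-level count matrix rather than only gene-level counts.
`isotrend` finds **differentially expressed isoforms (DEIs)**: isoforms whose
expression profile across cell types diverges from that of their parent gene
or from the gene's **major isoform** (its most highly expressed transcript).
Such isoforms mark cell-type-specific splicing regulation that gene-level
analysis cannot see.

## Method

All statistics operate on per-cell-type pseudobulk CPM profiles: raw counts
are summed over each cell type's cells and scaled to counts-per-million, so a
gene's CPM is exactly the sum of its isoforms' CPM.  Candidate isoforms must
be detected in at least a fraction `min.pct` of cells of some selected cell
type (default 0.25; 0.1 recommended for sparse data) and contribute more than
10% of their gene's expression.

**Across n ≥ 3 cell types** the divergence of isoform vector *x* from
reference vector *y* (gene or major isoform) is measured by the adjusted
coefficient of determination of a one-predictor linear regression,

    R²_adj = 1 − (1 − r²) (n − 1) / (n − k − 1),   k = 1,

with *r* the Pearson correlation of *x* and *y*.  Isoforms with
R²_adj < 0.2 whose isoform-to-gene CPM ratio spans a range ≥ 0.05 across
cell types are **multi-DEIs**.

**Between exactly 2 cell types** the Pearson correlation degenerates to the
trend sign (±1), so it is multiplied by the cosine similarity of the two CPM
vectors,

    score = sign(Δx · Δy) × (x·y) / (‖x‖‖y‖).

A score near +1 means the isoform tracks its reference; isoforms with a
positive score < 0.9 or any negative score, whose isoform-to-gene ratio
changes by ≥ 0.05 between the two types, are **pair-DEIs**.  Comparisons
against the major isoform are suppressed when the major isoform itself
diverges from the gene on that pair.

The package also ships a count-level benchmark simulator (log-normal gene
abundances, planted isoform-usage shifts, Poisson bulk counts,
negative-binomial single-cell counts with expression-dependent dropout) and
an empirical FDR estimator that permutes cell-type labels and reports
mean false positives over permutations divided by detections on the true
labels.

## Worked example

```python
from isotrend import (
    SimulationDesign, simulate_paired_single_cell, benchmark_dataset,
    DeiConfig, adjusted_r_squared, trend_similarity,
)

# two-cell-type divergence of an isoform from its gene
ts = trend_similarity([120.0, 480.0], [1000.0, 1020.0])
print(f"pearson={ts.pearson:+.0f}  cosine={ts.cosine:.3f}  product={ts.product:+.3f}")

# multi-cell-type divergence
adj = adjusted_r_squared([120.0, 480.0, 260.0, 90.0],
                         [1000.0, 1020.0, 990.0, 1010.0])
print(f"adjusted R^2 = {adj:.3f}")

# benchmark: 1M reads, 500 cells per condition, planted truth
design = SimulationDesign(seed=7)
counts, ann, gmap, truth = simulate_paired_single_cell(
    design, depth=1_000_000.0, cell_count=500)
m = benchmark_dataset(counts, ann, gmap, truth, DeiConfig(min_pct=0.1), mode="pair")
print(f"precision={m.precision:.3f}  recall={m.recall:.3f}  F1={m.f1:.3f}")
```

prints

```
pearson=+1  cosine=0.863  product=+0.863
adjusted R^2 = -0.186
precision=0.947  recall=0.991  F1=0.969
```

The first isoform quadruples between the two cell types while its gene stays
flat: the trends agree in sign (+1) but the vectors point in clearly
different directions (cosine 0.863), giving a product below the 0.9 cutoff —
a pair-DEI candidate.  The four-cell-type example shows an isoform whose
profile the flat gene explains essentially not at all (R²_adj ≈ −0.19 < 0.2).
The benchmark line runs the full workflow (marker prefilter, candidate
filters, pair calling against the gene) on a simulated dataset with 1000
planted differential isoforms and scores the calls against that truth.

## Command line

```bash
isotrend simulate --mode sc --seed 7 --out sim/           # benchmark datasets
isotrend detect --counts counts.csv --annotation ann.tsv \
    --gene-map genes.gtf --mode pair --pair alpha beta \
    --out results/                                        # DEI tables
isotrend fdr --counts counts.csv --annotation ann.tsv \
    --gene-map genes.gtf --grid 0.5:0.95:0.05 --n-perm 100 \
    --seed 7 --out fdr.tsv                                # permutation FDR
isotrend benchmark --seed 7                               # planted-truth scores
isotrend viz --counts counts.csv --annotation ann.tsv \
    --gene-map genes.gtf --isoform G1.T2 --out viz/       # plot tables
```

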