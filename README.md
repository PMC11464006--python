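# atacdeconv

Cell-type deconvolution of **bulk ATAC-seq** with an explicit
**uncharacterized** (e.g. malignant) fraction, plus the upstream pipeline
that builds cell-type-specific **marker peaks** and **reference
chromatin-accessibility profiles** from sorted-cell samples.

## Who this is for

Tumor and immunology groups profiling chromatin accessibility in bulk —
PBMCs or solid-tumor biopsies — who want per-sample estimates of the immune,
stromal and vascular composition *and* of the cell mass their reference does
not cover (chiefly cancer cells), without single-cell data.

## The model

A bulk sample's TPM-like accessibility over marker peaks, `b`, is modelled as
a non-negative mixture of reference cell-type profiles `R` (peaks × cell
types, per-type median accessibility):

```
minimize  Σ_j w_j (b_j − Σ_i R_ji p_i)²
subject to  p_i ≥ 0,  Σ_i p_i ≤ 1
```

solved exactly as a convex quadratic program (NNLS plus an active-set solve
when the sum constraint binds). The feature weights `w_j = 1 / (v̄_j + ε)`
down-weight peaks with large cross-sample variability, where `v̄_j` is the
mean interquartile range of peak `j` across reference cell types. Because
marker peaks are selected to be closed in cell types outside the reference
(and in other human tissues), the deficit

```
p_u = 1 − Σ_i p_i
```

estimates the uncharacterized fraction. Per-cell signal factors are fixed at
1 for ATAC (DNA-level signal), so no mRNA-style rescaling applies.

Upstream, marker peaks come from pairwise moderated-t differential
accessibility (TMM-normalized log-CPM, empirical-Bayes variance shrinkage,
BH adjustment) between every pair of sorted cell types *and* external tissue
groups: a marker must show log2FC > 0.2 favoring its type in every contrast,
rank in the top 200 by its worst adjusted p-value, recur in ≥ 3 of 10
leave-one-fold-out repetitions, avoid universally accessible chromatin
modules, and (optionally, for tumor work) co-vary with its peers in bulk
tumor samples.

## Worked example

```python
import atacdeconv as ad

config = ad.SimulationConfig(seed=7)
truth = ad.simulate_reference_truth(config)
profile = ad.truth_reference_profile(truth)

bulk, true_fractions = ad.simulate_bulk(truth, n_samples=5, seed=8)
result = ad.deconvolve(bulk, profile)
print(result.fractions.round(3))
metrics = ad.metrics_table(result.fractions, true_fractions)
print(metrics.round(4))
```

prints (abridged)

```
        celltype_1  celltype_2  ...  celltype_5  uncharacterized
bulk_1       0.088       0.207  ...       0.108            0.089
bulk_2       0.107       0.387  ...       0.194            0.275
...
                 pearson_r    rmse   n
celltype_1          0.9974  0.0132   5
...
uncharacterized     0.9562  0.0286   5
pooled              0.9943  0.0146  30
```

Each row of `result.fractions` is a bulk sample on the simplex: estimated
fractions of the five reference cell types plus the uncharacterized
remainder. The metrics table compares the estimates against the generator's
true mixing proportions — here Pearson r ≈ 0.99 and RMSE ≈ 0.015 pooled over
all (sample, cell type) pairs under negative-binomial counting noise.

The same workflow is available from the shell:

```
atacdeconv simulate --out-prefix demo --n-bulk 20 --seed 7
atacdeconv deconvolve demo.bulk.tsv demo.profile.tsv.gz --out fractions.tsv
atacdeconv evaluate fractions.tsv demo.truth.tsv --out metrics.tsv
```

plus `atacdeconv consensus` (reproducible peak sets from per-sample BED
calls) and `atacdeconv markers` (marker discovery + profile building from a
sorted-cell count matrix).

## Documentation

`docs/methods.md` describes the model, the selection pipeline, what the
synthetic-data generator does and does not emulate, the numerical choices,
and known limitations.
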