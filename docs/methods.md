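# Methods

## The mixture model

Bulk chromatin accessibility is treated as a linear mixture of cell-type
reference profiles. For each sample, fragment counts are matched onto the
reference peak set (nearest overlapping peak, ≥ 1 bp; counts of several bulk
peaks hitting one reference peak are summed), transformed to a TPM-like scale
(counts divided by peak length, rescaled so each sample sums to 10⁶), and
restricted to the union of marker peaks. The fractions `p` solve

    min_p Σ_j w_j (b_j − Σ_i R_ji p_i)²   s.t.   p ≥ 0, Σ p ≤ 1,

with `R` the per-type median TPM-like accessibility of the sorted reference
samples and `w_j = 1/(v̄_j + ε)`, `v̄_j` the mean across cell types of the
per-type interquartile range at peak `j`, `ε = 10⁻² ×` median positive `v̄`
(1 if all `v̄` are zero). The variability-inverse form is our concrete
instantiation of "weights reflecting feature variability"; it is isolated
behind `FeatureWeights` so alternatives can be swapped without touching the
solver. The uncharacterized fraction is the clamped deficit
`p_u = max(0, 1 − Σ p)`. This identifies the unreferenced cell mass exactly
when marker peaks are closed in uncharacterized cells — the assumption the
marker pipeline is designed to enforce. Per-cell signal factors are fixed at
1 (ATAC measures DNA-level signal), making the final renormalization the
identity.

Key modelling assumptions: accessibility mixes linearly in cell-fraction
space after TPM-like normalization; reference medians are representative of
the cell types in new samples; samples are fitted independently.

## Solving the constrained fit

The problem is a convex QP. We first solve the non-negative least-squares
relaxation (Lawson–Hanson NNLS on the weighted design); if its solution
already satisfies Σp ≤ 1 it is the global constrained optimum. Otherwise the
sum constraint is active and an active-set method solves the
equality-constrained problem: repeatedly solve the KKT system on the free
variables, move the most negative variable to the bound, and free the bound
variable with the most negative multiplier until the KKT conditions hold
(tolerances 10⁻¹² on primal feasibility, 10⁻¹⁰ on multipliers; iteration cap
200). The solver is deterministic. A rank-deficient reference matrix is
handled with a ridge of 10⁻¹⁰ × trace and flagged non-unique in the output.

## Consensus peaks

Per-sample peak calls are merged by iterative overlap collapse: repeatedly
keep the highest-scoring remaining peak and discard everything overlapping it
by ≥ 1 bp (score ties broken by coordinate), so output peaks are always
members of the input, never merged intervals. Study-level peaks must be
re-detected in at least ⌈n/2⌉ of a study's n samples (both, when n = 2);
"detected" means ≥ 1 bp overlap with any original call — the same overlap
unit as the collapse itself. Cell-type peaks must appear in every study of
origin; the global set is one more collapse of the pooled cell-type sets
with chromosome Y removed. The ceiling reading of "at least half" is the
stricter consistent choice for odd n. Sample quality filtering (e.g. by TSS
score) is a manifest-level metadata filter, not recomputed here.

## Differential accessibility and marker selection

The statistical engine is TMM normalization (trim fractions 0.3 on M and
0.05 on A, precision weights from the binomial variance approximation,
factors rescaled to geometric mean 1, reference sample chosen by the
upper-quartile rule), log-CPM with a prior count of 0.5, per-contrast
two-group linear fits, and empirical-Bayes variance moderation: the prior
(d₀, s₀²) is estimated by matching the mean and variance of log s² to their
digamma/trigamma expressions under the scaled-F model, inverting the
trigamma equation by Newton iteration; non-positive excess dispersion yields
d₀ = ∞. The moderated t uses d + d₀ degrees of freedom (normal tail at
d₀ = ∞); p-values are BH-adjusted within each contrast. Peaks with zero
residual variance are excluded from the moment fit but still moderated.
Per-observation mean–variance precision weights (the voom trend) are
deliberately omitted: marker selection consumes only the log2 fold change
and the adjusted p-value, which the moderated-t core provides at a fraction
of the complexity; borderline markers could differ from a weights-bearing
fit.

A marker candidate of cell type c must show log2FC > 0.2 favoring c in
*every* contrast involving c — other reference types and external tissue
groups alike ("recurrently differentially accessible"; a config switch
relaxes this to "any contrast"). Candidates are ranked by their maximum
adjusted p across those contrasts (ties: larger minimum log2FC, then peak
id) and truncated to 200. The sample collection is split into ten folds
stratified by cell type; each repetition analyses the complement of one fold
(the fold-as-analysis-set reading is not viable at reference-collection
sizes where a single fold cannot populate every group), and markers must
recur in at least three repetitions.

Two filters follow. The module filter removes markers overlapping
universally accessible chromatin modules, or tissue-class modules not
exempted for the marker's cell type (immune types keep immune modules,
endothelial keep endothelial, fibroblasts keep stromal). The correlation
filter computes, per cell type, the pairwise Pearson correlations of its
markers across bulk tumor samples, sets the cutoff at the 90th percentile of
the upper-triangle values (linear interpolation), and runs the standard
pairwise scan: pairs above the cutoff are visited in column-major order and
the member with the larger mean absolute correlation is flagged, skipping
pairs with an already-flagged member (ties flag the lower index). In the
default `keep_correlated` mode the *flagged* markers are retained — in tumor
bulk, genuine cell-type markers co-vary through the mixing proportions, so
the most inter-correlated subset is the trustworthy one; `drop_correlated`
exposes the conventional redundancy-pruning reading. If no pair exceeds the
cutoff, the set passes through unchanged with a warning rather than being
emptied. Note the percentile-based cutoff retains by construction only the
top-correlated subset (roughly 60 % of a uniformly co-varying set), so this
stage trades recall for specificity; it is intended for tumor applications
where non-co-varying markers are suspect.

## Interval machinery

Coordinates are 0-based half-open everywhere, with `chr:start-end`
identifiers in the same convention; chromosome names match by exact string
equality. Nearest-peak distance is the edge gap (0 for overlapping regions;
abutting half-open regions also measure 0 despite zero overlap), ties to the
leftmost target. Liftover implements single-best-chain semantics: a region
maps iff its start and end−1 fall inside the same aligned block of the
highest-scoring overlapping chain, so lifted regions always preserve length;
reverse-strand targets are flipped against the chromosome size and
re-normalized. Regions spanning block gaps or lacking a chain are dropped
with a reason rather than partially mapped — a conservative contract,
narrower than UCSC liftOver's split/partial mappings.

## Synthetic data

The generator emulates a sorted-cell reference collection and bulk mixtures
with known composition. Each reference cell type receives 100 disjoint
marker peaks (high accessibility in-type, near-closed elsewhere); 1000
background peaks share one log-normal accessibility profile across all cell
types and tissues (ubiquitous chromatin); 50 decoy peaks are open everywhere
(the universal-module role). The uncharacterized component has background
accessibility but is exactly closed at every marker — the idealization under
which the deficit identifies its fraction; a `leaky_markers` option breaks
it for robustness studies. A screening panel of 10 external tissue groups
(4 samples each) joins the differential analysis the way diverse-organ
samples do in practice; each tissue group constitutes its own study batch.
Counts are gamma-Poisson (negative binomial) with a single dispersion
φ = 0.2 around mean = profile × study batch multiplier × depth/10⁶, with
log-normal batch multipliers (σ = 0.2) drawn per study and 50-peak block,
and depth 10⁶ per sample. Default study design: 5 cell types × 3 studies ×
4 samples. Bulk mixtures draw cell-type proportions from Dirichlet(α = 1),
scaled by one minus an uncharacterized fraction drawn uniformly from
[0, 0.6]. All peaks share one length (500 bp), so the TPM-like transform is
exact on the generator's profile scale. Every generator is deterministic
under its seed.

The tissue-panel size and its one-batch-per-tissue structure were fixed once
so that the generator honors its planted-truth contract — the selection
pipeline recovers planted markers with per-type precision and recall ≥ 0.9
at default settings; with a panel this size, background peaks whose in-type
counts drift high by chance are screened out by the many independent
contrasts they must each survive. What passing tests on these data do *not*
show: robustness to cell types missing from the reference but present in
bulk beyond the idealized uncharacterized profile, to markers with residual
accessibility in uncharacterized cells, to fragment-level artefacts (Tn5
bias, duplicates, GC), or to single-cell sparsity. Real reference
collections are also far larger and noisier in structure than this
generator's clean block-batch model.

## Numerical choices

- Quantiles (median, IQR, correlation-cutoff percentile): linear
  interpolation between order statistics (NumPy default, R type 7) — stated
  because the IQR feeds the fit weights.
- TMM trims (0.3, 0.05), weighted trimmed mean, geometric-mean-1 rescaling:
  the canonical published constants; samples sharing no positive peak with
  the reference are an error.
- Bulk normalization order: match → sum → TPM-like on reference peak lengths
  (default); a `normalize="full"` switch normalizes the complete bulk matrix
  first instead.
- Degenerate guards: all-zero bulk samples are an error naming the sample; a
  fit summing to zero reports fully uncharacterized; fewer than 10 matched
  marker peaks is fatal, and losing over half a cell type's markers in
  matching warns.
- Score/rank ties everywhere break by coordinate or identifier, making every
  pipeline stage deterministic under fixed seeds.

## Known limitations

Confidence intervals on fractions are not provided; samples are fitted
independently with no information sharing; closely related cell types with
overlapping marker programs (e.g. CD4/CD8 subsets) remain intrinsically hard
and are only partly represented by the generator's idealized marker
structure; the uncharacterized estimate absorbs any non-malignant cell type
absent from the reference, not just cancer cells; liftover is intentionally
stricter than UCSC liftOver and drops split or partially mapped peaks.
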