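# Methods

## Problem and model

Sequencing-based spatial transcriptomics measures, at each capture spot, the
summed expression of an unknown mixture of cells. Given an annotated
scRNA-seq reference for the same tissue type, the package estimates the
cell-type composition of every spot. Its central modeling idea is that cell
types are not uniformly distributed across a tissue: spots belonging to the
same spatial domain (a region coherent in expression and histology) share a
common *set* of cell types, while the *proportions* of those types vary spot
to spot. The pipeline therefore has three stages.

**1. Spatial domains.** Domain detection proper is treated as an upstream
step: the package ingests a `spot_id,domain` CSV (e.g. exported by a
graph-convolutional domain detector). A fallback clusterer is provided so
the tool runs standalone: spot totals are scaled to a common library size,
log1p-transformed, reduced to the top 50 principal components; z-scaled
spatial coordinates (and mean spot RGB, if present) are appended with
weight 1; k-means with user-chosen D and a fixed seed clusters the joint
features, followed by one round of majority smoothing over each spot's 6
nearest spatial neighbors (ties keep the spot's own label). This is a
deliberately simple stand-in, not a reimplementation of GCN-based
detection; D must be supplied by the user.

**2. Cell-type selection per domain.** For each spot with expression
`y ∈ R^M` over the M feature genes and signature matrix `X ∈ R^{M×K}`, the
Lasso objective

    Σ_i (y_i − Σ_j β_j x_ij)²  +  λ Σ_j |β_j|

is minimized without intercept (scikit-learn coordinate descent; the
printed penalty maps to sklearn's `alpha = λ / 2M`). λ is chosen by 10-fold
cross-validation over genes-as-observations on a 50-point log grid from
λ_max (the smallest penalty that zeroes every coefficient, `2·max|Xᵀy|`)
down to λ_max·1e-4. The default selection rule is the **one-standard-error
rule** — the largest (sparsest) λ whose mean CV error is within one SE of
the minimum — which is the convention used when extracting coefficients
after cross-validated Lasso fits in glmnet; `lasso_lambda_rule="min"`
selects the error-minimizing λ instead. The 1-SE default matters: at the
error-minimizing λ, truly-absent cell types retain tiny nonzero
coefficients (≈1e-4 on the benchmark) that the scale-free adaptive
threshold below would sporadically call present.

The spot × type coefficient matrix (negative values clipped to 0, spots
ordered domain-major then by row/column so windows stay within domains) is
binarized by **adaptive thresholding**: each entry is compared to the local
moving mean computed by FFT convolution with a uniform odd window under
symmetric (reflect) padding; an entry becomes 1 only if it strictly exceeds
its filtered value. A numeric guard of 1e-10·(1+|filtered|) absorbs FFT
roundoff so exact ties (e.g. a constant matrix) binarize to all zeros. The
default window is **15×1** (15 spots, 1 cell-type column): filtering each
type against its own spatial neighborhood keeps selection invariant to the
order of cell-type columns, which a multi-column window cannot be (a minor
type seated next to a dominant column would be judged against the
dominant's local mean). Window and the aggregation threshold are config
knobs. A type enters the domain set S_d when at least τ = 0.25 of the
domain's spots call it; an empty S_d falls back to the type with the
largest mean coefficient in the domain.

**3. Proportion estimation.** Per spot, with X restricted to the columns
in S_d, proportions solve

    argmin_p  Σ_i | y_i − Σ_{j∈S} p_j x_ij |   s.t.  p_j ≥ 0,  Σ_{j∈S} p_j = 1.

The absolute loss is used because it is far less sensitive to outlying
genes than the quadratic loss (verified by the outlier-corruption test,
where the L1 fit beats a simplex-constrained least-squares baseline). The
production solver is the exact LP reformulation — split residuals
r⁺, r⁻ ≥ 0 with `Xp + r⁺ − r⁻ = y`, minimize Σ(r⁺+r⁻) — solved by HiGHS,
which certifies global optimality of this convex problem. An
augmented-Lagrangian backend (`method="auglag"`) is kept as an alternative
matching the classical constrained-optimization treatment: it smooths |r|
as √(r²+δ²) with δ continuation 1e-3→1e-9, carries the simplex equality in
the augmented Lagrangian, and handles p ≥ 0 by L-BFGS-B bounds. The two
backends agree to ≈1e-9 in objective on random instances; tests compare
objectives (not p) when X is column-degenerate, since LAD optima need not
be unique. Types outside S_d are exactly zero in the output; each row sums
to 1 within 1e-6.

## Reference construction

Cells of unwanted annotations and genes with zero total count are removed;
each cell is scaled by its library size (columns sum to 1; zero-total cells
dropped). Differential expression per cell type is one-vs-rest by default
(`pairwise=True` keeps a gene significant against any single other type):
two-sided Wilcoxon rank-sum per gene (exact null when the pooled sample is
≤12 with no ties, else normal approximation with tie and continuity
correction), Benjamini–Hochberg adjustment within each cell type, and
thresholds adjusted p ≤ 0.05, natural-log fold change ≥ 0.25 with
pseudo-value 1e-9. Feature genes are those shared with the spatial data,
user-supplied markers, or DEGs — then intersected with the spatial genes so
the fits are well-posed. The signature value x_ij is the mean scaled
expression of gene i over cells of type j, pooling cells across samples by
default (`per_sample_mean=True` averages within-sample means). Per-gene
cross-sample variance is reported in the run log as a reference-quality
diagnostic but does not weight the fits, whose objectives are unweighted as
written above. Types with fewer than 3 cells are excluded from DEG testing
with a warning.

## Normalization

Under the default `normalization_mode="sum1"`, each spot's feature-gene
vector and each signature column are scaled to unit sum before both the
selection and deconvolution fits. Unit-sum columns make the simplex
constraint exactly representable — a convex combination of unit-sum columns
can reproduce a unit-sum mixture with zero residual — so noise-free
mixtures are recovered exactly and coefficients live on the proportion
scale. `"none"` fits raw values. Estimated proportions are mRNA-fraction
proportions; they coincide with cell-count fractions only insofar as the
cell types have similar total mRNA content (true by construction in the toy
generator; only approximately true in real tissue).

## Synthetic data

The generator mirrors a standard pseudo-spot construction: per spot, draw
ground-truth proportions from a domain-specific Dirichlet (zero
concentration = absent type; the draw is renormalized to guard float
rounding), allocate `cells_per_spot` cells to types by largest-remainder
rounding (allocations always sum exactly; ties to the lower index), sample
cells with replacement, and sum their raw counts. Recorded truth is the
Dirichlet draw, not the rounded allocation. Optional noise multiplies every
count by an independent lognormal(0, σ) factor and rounds to the nearest
integer; preset levels σ ∈ {0, 0.2, 0.5, 1.0}. The noise mechanism is the
package's own choice of a simple heavy-tailed multiplicative model.

The bundled toy reference is synthetic: K cell types, 30 Poisson marker
genes per type (rate 8 inside / 0.2 outside), 40 housekeeping genes
(rate 2), 50 cells per type split over 2 samples, equal expected library
size per type. Defaults that define the standard benchmark: 20×20 grid
(400 spots), 3 banded domains, 6 types, Dirichlet concentration 5 for the
domain's dominant type and 1 for its two cyclic minors (absent types 0),
50 cells per spot. The noise sweep uses a 14×14 grid with 3 replicate
seeds per σ — a size chosen to keep the whole sweep to a couple of minutes
on one CPU. What passing these benchmarks does *not* show: robustness to
overdispersion, dropout, platform effects, mismatched references, rare
cell types, or imperfect domain labels — the toy generator has none of
these features, and real-data behavior is out of the test surface.

## Numerical choices and edge cases

- Lasso coefficients with |β| < 1e-10 are snapped to exactly 0; a single
  grid value skips CV (λ=0 reduces to ordinary least squares).
- Sparsity along the λ path is typically, but not universally, monotone:
  for correlated designs a coefficient can re-enter as λ decreases. The
  acceptance script reports the measured monotone fraction.
- LP tolerance 1e-8; simplex-sum check 1e-6; an all-zero spot yields the
  uniform vector over S_d with a warning.
- Threshold windows larger than the matrix are clamped (with a warning) to
  the nearest odd size that fits; even windows are rejected.
- All randomness (CV folds, k-means init, simulation) flows from the
  single integer seed in `PipelineConfig`; repeated runs are
  bitwise-identical.
- Pixel x/y coordinate files map x→col, y→row; gene matching between
  spatial and reference is case-sensitive exact intersection.

## Known limitations

- Domain quality bounds selection quality; the fallback clusterer is not a
  substitute for a dedicated spatial-domain method and requires D.
- Rare types within a domain (low Dirichlet mass) can fall below the τ
  aggregation threshold and be dropped from S_d, biasing their proportions
  to zero — the familiar rare-cell-type underestimation of reference-based
  deconvolution.
- A single scRNA-seq reference is assumed; no batch integration across
  references, no ambient-RNA or doublet handling, no uncertainty
  quantification on the proportions.
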