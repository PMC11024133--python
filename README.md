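# spade-deconv

Domain-aware cell-type deconvolution for sequencing-based spatial
transcriptomics.

Each capture spot in a Visium-style experiment measures the pooled
expression of several cells. Given an annotated scRNA-seq reference,
this package estimates the cell-type proportions at every spot, exploiting
the fact that tissue is organized into spatial domains: spots in the same
domain share a common set of cell types, while proportions vary spot to
spot. It is intended for computational biologists analyzing spatial
transcriptomics with a matched single-cell reference.

## Method

Three stages, run per dataset:

1. **Spatial domains** — ingested from a `spot_id,domain` CSV (e.g. the
   export of a dedicated domain-detection tool), or produced by a bundled
   fallback clusterer (expression PCA + spatially weighted k-means with
   neighbor smoothing).
2. **Cell-type selection per domain** — for each spot, an L1-penalized
   regression of its expression `y` on the signature matrix `X` built from
   the reference,

   `min_β Σᵢ (yᵢ − Σⱼ βⱼ xᵢⱼ)² + λ Σⱼ |βⱼ|`,

   with λ chosen by 10-fold cross-validation (one-standard-error rule).
   A cell type whose coefficient shrinks to zero is absent at that spot.
   The spot × type coefficient matrix is binarized by adaptive
   thresholding (each entry against its FFT-computed local moving mean)
   and the calls are aggregated into a cell-type set S_d per domain.
3. **Proportion estimation** — per spot, simplex-constrained least
   absolute deviations restricted to the domain's types:

   `min_p Σᵢ |yᵢ − Σ_{j∈S} pⱼ xᵢⱼ|  s.t.  pⱼ ≥ 0, Σ_{j∈S} pⱼ = 1`,

   solved exactly as a linear program (HiGHS); the L1 loss is robust to
   outlying genes.

The signature `x_ij` is the mean library-size-scaled expression of gene i
in reference cells of type j, over feature genes that are shared with the
spatial data, user-listed markers, or rank-sum/BH differentially expressed
genes. See `docs/methods.md` for assumptions, parameters and limitations.

## Worked example

Everything runs offline: the `simulate` module generates pseudo-spatial
data with known ground truth from a bundled toy reference.

```python
import spade

sc, spatial, truth = spade.standard_benchmark(
    seed=1, grid=(10, 10), n_domains=2, n_types=4, cells_per_spot=30
)
P, log = spade.run_pipeline(
    spatial, sc, domains=truth.domain_layout,
    config=spade.PipelineConfig(rng_seed=1, cv_folds=5),
)
mad, rmse, r = spade.compute_mad_rmse_r(P.P, truth.true_P)
print("domain sets:", log["domain_sets"])
print(f"mAD={mad:.4f}  RMSE={rmse:.4f}  R={r:.4f}")
```

prints

```
domain sets: {'0': ['T0', 'T1', 'T2'], '1': ['T0', 'T2', 'T3']}
mAD=0.0069  RMSE=0.0097  R=0.9995
```

The selected sets match the generating composition (each domain was
simulated with one dominant and two minor types), and the estimated
proportions deviate from the Dirichlet ground truth by under 1% on
average with correlation 0.9995. A single spot reads e.g. estimated
`T0=0.794, T1=0.100, T2=0.106` against truth `T0=0.806, T1=0.081,
T2=0.112`.

The same workflow from the shell:

```
spade simulate --out sim --seed 5 --grid-rows 10 --grid-cols 10 \
    --n-domains 2 --n-types 4 --cells-per-spot 30
spade run --spatial sim/spatial --coords sim/spatial/coords.csv \
    --sc sim/sc_counts.csv --sc-meta sim/sc_meta.csv \
    --domains sim/domains.csv --out out --seed 5
spade evaluate --estimated out/proportions.csv --truth sim/truth.csv \
    --out report.json
```

`spade reference`, `spade select` and `spade deconvolve` expose the
individual stages; real data enters as a 10x-style MTX triplet (or dense
CSV) plus coordinate and cell-metadata CSVs.

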