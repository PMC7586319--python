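# salsa

Parametric matrix focusing, gene stratification, and latent clustering for
ultra-sparse single-cell RNA-seq count matrices.

Droplet scRNA-seq experiments yield gene × barcode matrices of deduplicated
UMI tallies in which well over 90% of fields are empty and most data-positive
fields hold a single count. `salsa` is built for exactly this regime. Instead
of zero-imputing the matrix, it keeps only the data-positive triplet stack
and asks two questions:

1. **Which part of the matrix is informative?** Total UMI coverages per gene
   (and per barcode) are modeled as a two-component extreme-value mixture — a
   Weibull "common" component `P_C` for the low-coverage bulk plus a Fréchet
   "dominant" component `P_D` for the heavy upper tail — fit by quantile
   regression of log coverage. Repeating the fit while raising a minimum
   coverage admission cutoff (the *parametric sweep*) produces solver
   "spikes" where the cutoff crosses a regime boundary; the spike-flanked
   stable window yields the boundaries between *rare / facultative /
   constitutive* genes and *ambient / singlet / multiplet* barcodes. Analysis
   then *focuses* on the facultative-gene × singlet block.
2. **Which facultative genes are reliable markers?** Expression is normalized
   to UMIs-per-thousand (UPT) per cell, scored by a GLM linear predictor
   `B(θ)` (log-link, anchored at each gene's pseudo-bulk reference mean),
   embedded by a sparsity-preserving truncated SVD (Lanczos
   bidiagonalization), and clustered with Ward's method. Genes are then
   sifted through a nested ladder of reliability filters —

   `facultative ⊇ SG ⊇ LSTNR ⊇ DEG ⊇ DEGREE ⊇ Profiler`

   — built on a double-weighted ANOVA of Log₂FC across cell majors
   (coverage-resolution weights × within-cluster representation rates) with
   Benjamini–Hochberg adjustment, and benchmarked against an SNR = 1 unit:
   the half-width of the 95%/95% tolerance interval of weighed-expression
   residuals around cluster means. The surviving *Profiler* genes are a
   minimal biomarker panel that drives the final cell clustering.

Multi-replicate designs are integrated by running the sweep per specimen and
intersecting facultative calls within experimental rounds (*batch-consistent*
genes), keeping genes consistent in at least 3 of 4 rounds by default.

The package is organized as scikit-learn-style estimators
(`MatrixFocuser`, `ExpressionScorer`, `LatentWardClusterer`,
`GeneStratifier`) with plain functions underneath, plus a `salsa` CLI
(`simulate`, `profile`, `focus`, `score`, `cluster`, `stratify`,
`integrate`, `report`, `run`).

## Worked example

```python
from salsa import (SimulationConfig, simulate_stack, sparsity_profile, MatrixFocuser,
                   ExpressionScorer, LatentWardClusterer, GeneStratifier, truth_metrics)

stack, truth = simulate_stack(SimulationConfig(seed=0))
rep = sparsity_profile(stack)
print(f"stack: {stack.n_genes} genes x {stack.n_barcodes} barcodes, "
      f"occupancy {rep.occupancy:.1%}, 1-valued fields {rep.value_composition[1]:.1%}")

cells = MatrixFocuser(axis="barcode", seed=0, max_grid_points=60, n_starts=3).fit_transform(stack)
gene_focus = MatrixFocuser(axis="gene", seed=0, max_grid_points=60, n_starts=3).fit(cells)
focused = gene_focus.transform(cells)
part = gene_focus.partition_
print(f"gene regimes: {len(part.low_set)} rare / {len(part.mid_set)} facultative "
      f"/ {len(part.high_set)} constitutive; facultative coverage "
      f"[{part.lower_bound}, {part.upper_bound}] total UMIs")

scores = ExpressionScorer().fit_transform(focused, full_stack=cells)
clusters = LatentWardClusterer(k=5, seed=0).fit(scores)
majors = {c: int(l) for c, l in enumerate(clusters.labels_)}
orig = {b: i for i, b in enumerate(stack.barcode_ids)}
labels = {orig[focused.barcode_ids[c]]: l for c, l in majors.items()}
print(f"cell-type ARI vs planted truth: "
      f"{truth_metrics({'cell_labels': labels}, truth)['ari']:.3f}")

ladder = GeneStratifier().fit(scores, majors)
counts = ladder.strata_.counts
print(f"ladder: SNR unit = {ladder.benchmark_.ti_halfwidth:.3f} (weighed Log2FC); "
      f"{sum(v for k, v in counts.items() if k != 'facultative_only')} significant, "
      f"{counts['Profiler']} Profilers")
```

prints (exact numbers for this seed):

```
stack: 3050 genes x 1320 barcodes, occupancy 7.3%, 1-valued fields 67.4%
gene regimes: 2383 rare / 617 facultative / 50 constitutive; facultative coverage [109, 3884] total UMIs
cell-type ARI vs planted truth: 0.923
ladder: SNR unit = 0.654 (weighed Log2FC); 103 significant, 99 Profilers
```

The synthetic stack plants 5 cell types with 20 signature genes each; the
partition recovers the planted facultative band, clustering on `B(θ)` scores
recovers the planted types (adjusted Rand index 0.92), and 99 of the 103
significant genes survive to the Profiler stratum — almost exactly the 100
planted signatures.

The same pipeline runs from the shell:

```bash
salsa run --seed 7 --out runs/demo          # simulate -> focus -> ... -> report
salsa profile --matrix data/pbmc3k --out out/   # sparsity accounting for a 10X matrix
salsa focus --matrix data/pbmc3k --axis gene --out out/
```

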