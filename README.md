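# ltedyn

Time-course analysis of gene-expression dynamics during the development
of endocrine resistance in breast cancer, built around the long-term
estrogen-deprived (LTED) MCF7 cell model.

Estrogen-receptor-positive breast cancers treated by estrogen
deprivation frequently acquire resistance over weeks to months.
Profiling cells across that transition (e.g. an 8-point series at days
0, 3, 15, 30, 90, 120, 150, 180) yields one noisy trajectory per gene,
and the analysis questions are: which genes change *dynamically* over
the course, which temporal patterns do they share, which cell model
best mirrors patient tumors, and which genes sit at the hubs of the
candidate interaction network.  `ltedyn` implements that pipeline as a
tested, reusable Python library with a synthetic-data generator so
every stage can be validated against planted ground truth.

## The method

Each gene's centered trajectory is modeled as a smooth function of time
observed under iid Gaussian noise:

    Y_g(t_k) − μ_g = X_g(t_k) + ε_g(t_k),   ε ~ N(0, σ²)

1. **Smoothing** — X_g is estimated by a natural cubic smoothing spline
   with knots at the observed (uneven) time points, minimizing
   `Σ_k (y_k − x(t_k))² + λ ∫ x″(t)² dt`.  The single λ shared by all
   genes minimizes generalized cross-validation,
   `GCV(λ) = K·RSS/(K − tr S_λ)²`, averaged over the 200 genes with the
   largest interquartile range.
2. **Dynamic response genes (DRGs)** — each smoothed trajectory is
   tested against H₀: X_g(t) = 0 with
   `F = [(RSS₀−RSS)/df₁] / [RSS/df₂]`, df₁ = tr S_λ − 1,
   df₂ = K − tr S_λ; genes with Benjamini–Hochberg q < 0.05 are DRGs,
   and the top genes by F (up to 3000) go forward.
3. **Gene response modules (GRMs)** — selected trajectories are grouped
   by iterative hierarchical clustering (IHC): average-linkage
   initialization on d = 1 − ρ_Spearman cut at 1 − τ (τ = 0.7), then
   alternating center-merge and gene-reassignment rounds until the
   partition stabilizes.  Modules come out at many scales, from
   dominating clusters down to singletons.
4. **Summaries and downstream ranking** — per-module mean trends with
   bootstrap bands; similarity ranking of candidate cell models by
   Euclidean distance between log-fold-change profiles; Venn
   decomposition of the DRG set against external differential-expression
   sets; candidate ranking by interaction-network degree.

## Worked example

```python
import ltedyn as ld

matrix, truth = ld.generate_timecourse(
    n_null=30,
    module_sizes={"A1": 80, "A2": 60, "A3": 40, "A4": 20},
    amplitude=2.0, sigma=0.4, seed=7,
)
centered = ld.center_trajectories(matrix)
lam = ld.select_lambda(centered)
fit = ld.smooth_trajectories(centered, lam)
table = ld.f_test(fit, alpha=0.05)
print(f"lambda (GCV): {lam:.1f}   effective df: {fit.smoother_trace:.2f}")
print(f"DRGs at FDR 0.05: {int(table.is_drg.sum())} of {matrix.n_rows}")
top = ld.select_top_drgs(table, k=int(table.is_drg.sum()))
modules = ld.ihc_cluster(fit.subset(top), tau=0.7)
print(f"modules: {modules.n_modules}, sizes {modules.sizes}")
print(f"top-4 share: {ld.module_share(modules, 4):.3f}")
trend = ld.msm_trend(modules, 1, B=1000, seed=0)
print("module 1 mean trend:", [float(round(x, 2)) for x in trend.mean_trend])
```

prints

```
lambda (GCV): 1048.1   effective df: 5.44
DRGs at FDR 0.05: 156 of 230
modules: 4, sizes [70, 53, 20, 13]
top-4 share: 1.000
module 1 mean trend: [-0.57, -0.75, -1.41, -1.92, -0.09, 1.18, 1.8, 1.77]
```

230 simulated genes (200 dynamic in four planted temporal archetypes,
30 flat) are smoothed at the GCV-chosen λ; 156 clear the FDR threshold,
and clustering them recovers exactly four modules whose sizes track the
planted 80/60/40/20 design.  Module 1's mean trend shows the
down-to-day-30, sharply-up-to-day-150 pattern of its archetype.

The same stages are exposed on the command line:

```
ltedyn simulate --n-null 1000 --module-sizes A1:400,A2:300 --out data/
ltedyn run --config config.yaml --out results/
ltedyn smooth|drg|cluster|summarize|similarity|overlap|rank ...
```

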