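# Methods

## Model and assumptions

The pipeline treats a gene's time-course as noisy observations of a
smooth function.  For gene *g* observed at times t₁ < … < t_K,

    Y_g(t_k) − μ_g = X_g(t_k) + ε_g(t_k),    ε_g(t_k) ~ N(0, σ²) iid,

where μ_g is the gene's mean over the course.  The working assumptions
are: (i) only a minority-to-moderate fraction of genes respond to the
stimulus, the rest being flat; (ii) noise is homoscedastic across time
points and genes after log2 transformation; (iii) responses are smooth
on the scale of the sampling grid.  When several samples share a
nominal time point (replicate series), they are averaged per time
point before centering; a single series per gene (the primary use
case) is fully supported.

## Trajectory smoothing

X_g is estimated by the natural cubic smoothing spline with knots at
all observed time points, the minimizer of
`Σ (y_k − x(t_k))² + λ ∫ x″(t)² dt`.  At the knots the fit is linear in
the data, `x̂ = S_λ y` with `S_λ = (I + λK)⁻¹`, where `K = DᵀW⁻¹D` is
the Reinsch/Green–Silverman roughness matrix built from the knot
spacings.  The hat matrix is formed explicitly (K = 8, so dense algebra
is trivial), which makes the smoother's effective degrees of freedom
`tr S_λ` exact — the downstream F-test depends on it.  The
implementation is cross-checked in the test suite against two
independent routes: a dense construction of the natural-spline basis
with an exactly integrated curvature penalty, and
`scipy.interpolate.make_smoothing_spline`, which uses the same penalty
convention.

The time axis is raw days (uneven spacing respected), not ranks.  One λ
is shared by all genes; it minimizes the arithmetic mean of per-gene
`GCV(λ) = K·RSS(λ)/(K − tr S_λ)²` over the 200 genes with the largest
interquartile range of centered values.  The default search grid is 50
log-spaced points in [10⁻⁴, 10⁴]; with time in days on this 180-day
course, the grid spans fits from near-interpolation (tr S ≈ 8) to
near-linear (tr S ≈ 2.1), which is the meaningful range.  Candidates
that exhaust the residual degrees of freedom are skipped; ties resolve
to the smaller λ.

## Dynamic response gene test

Each gene is tested against H₀: X_g(t) = 0 by

    F_g = [(RSS₀ − RSS)/df₁] / [RSS/df₂],
    df₁ = tr S_λ − 1,   df₂ = K − tr S_λ,

with RSS₀ = ‖centered y‖² (the residual of the null fit) and p-values
from the F distribution with non-integer degrees of freedom.  The −1 in
df₁ is deliberate: the spline smoother reproduces constant functions
exactly, but centering has already removed the constant direction, so
the data live in a (K−1)-dimensional space and using tr S as the signal
df would overcount by one, making the test conservative.  With the
correction, simulated null data at the GCV-selected λ give a raw
p < 0.05 rate of ≈ 0.049 (checked in the test suite at n = 2000).
Degenerate all-zero trajectories are assigned F = 0, p = 1; a negative
numerator (impossible for a shrinking smoother, guarded anyway) clamps
to zero.  Multiplicity is handled by Benjamini–Hochberg; genes with
q < α (default 0.05) are DRGs, and the top k of them by F (default
k = 3000, truncated with a warning if fewer are significant) proceed to
clustering.  Ranking ties keep input order.

### A practical limit worth knowing

With a single shared λ and only K = 8 points, the F statistic
*saturates* as signal amplitude grows: the smoother's lack-of-fit to a
fixed curve scales with amplitude² and sits in the denominator, so
F → [sᵀ(2S−S²)s·df₂]/[sᵀ(I−S)²s·df₁], a constant of the shape and λ.
Per-gene p-values therefore have an effective floor (≈10⁻³ at typical
GCV-selected λ).  Two consequences, both visible in the tests: ranking
by F still orders dynamic genes ahead of flat ones at any amplitude,
but BH-FDR detection only fires when a substantial fraction of genes is
dynamic (the regime of the motivating study, where roughly a quarter of
probes were dynamic).  On sparse synthetic data (10% planted), FDR
calls can be zero even for strong signals while top-k recovery works;
the acceptance script reports both regimes.

## Iterative hierarchical clustering (IHC)

Selected DRG trajectories — the smoothed fitted values, not raw data —
are partitioned with a Spearman correlation threshold τ (default 0.7):

1. **Initialize**: average-linkage agglomeration on d = 1 − ρ_S, cut at
   height 1 − τ.
2. **Merge**: while any two cluster centers (pointwise mean member
   trajectories) have ρ_S ≥ τ, merge the best-correlated pair and
   recompute its center.
3. **Reassign**: move every gene to the center it correlates with most;
   genes whose best correlation falls below τ become singletons.
4. Repeat 2–3 until the partition repeats or `max_iter` (default 100)
   is reached.  A hash of every partition seen guarantees that cycles
   terminate.

Spearman correlation uses average ranks for ties; constant
trajectories (zero rank variance) get correlation 0 against everything,
with a warning.  Singleton modules are retained.  Labels are assigned
1..M by non-increasing size, ties broken by the smallest first-member
input index, so module membership is order-invariant for generic data
and label assignment follows a documented tie rule.  The
reassign-after-merge order within each round is one of two defensible
orderings; it is fixed, documented here, and localized in
`ihc_cluster` should the alternative be wanted.

## Module summaries

A module's mean trend is the pointwise arithmetic mean of member
trajectories.  The "multiple-sampling" band is implemented as a
nonparametric bootstrap over module members: B resamples (default
1000) with replacement, a mean trajectory per resample, and pointwise
percentile bands at the requested coverage (default 0.95).  Resampling
genes — rather than time points or subjects — is an explicit
interpretation; with one series per gene there is no subject axis to
resample, and time points are the quantity of interest.  Bands are
seed-deterministic.

## Cell-model similarity

Each candidate dataset is reduced to a per-gene log2 fold change
(difference of group means for the synthetic path; externally computed
LFC tables can be read directly).  Profiles are restricted to the
intersection of their gene universes (dropped genes are counted and
logged), compared by Euclidean distance, and agglomerated by complete
linkage — the defaults of the common heatmap tooling; correlation
distance (1 − Pearson) is available as an option.  The report names
the non-reference profile nearest the reference and includes the full
distance matrix and a Newick rendering of the tree.

## Set overlaps and candidate ranking

Venn decomposition of two or three uppercased gene-symbol sets is
exact enumeration; the directional patient-DE lists are merged
(up ∪ down) before intersection by default, with direction-aware
intersection available.  Candidate genes are ranked by their number of
neighbors in a user-supplied interaction network (degree over the full
network, not the candidate-induced subgraph); ties are alphabetical,
candidates absent from the network get degree 0 with a warning, and an
optional per-module view applies the top-n cutoff within each module.
The networks themselves are inputs (edge-list TSV exports from whatever
tool produced them); no network inference is performed.

## Synthetic data

The generator emulates the statistical structure the analysis assumes:

- the 8-point day grid 0/3/15/30/90/120/150/180 (so tests exercise
  uneven spacing) — configurable;
- per-gene baselines N(8, 1) on the log2 scale, irrelevant after
  centering but realistic for microarray intensities;
- iid N(0, σ²) noise;
- planted dynamic genes following four archetype curves, built as
  monotone piecewise-cubic interpolants through control points at days
  0/30/150/180 and normalized to zero mean and unit peak amplitude on
  the grid: A1 (down to day 30, sharply up to 150), A2 (its mirror),
  A3 (late transient peak), A4 (early drop, partial recovery).  A1/A2
  are perfectly anti-correlated by construction; all other pairs have
  |ρ_S| < 0.6, so the four shapes are distinguishable at τ = 0.7.

Two-group data with planted ±LFC genes and gene sets with exactly
prescribed Venn-region cardinalities round out the fixtures.  All
generators are bit-reproducible given a seed.

What the generator does *not* emulate: probe-level artifacts
(cross-hybridization, batch effects, saturation), count-based RNA-seq
noise, gene-gene correlation among null genes, and heteroscedasticity.
Passing tests therefore demonstrate correctness of the algorithms under
the model's own assumptions, not robustness to real-array pathologies.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale versions of the study design:
2,000 null genes for calibration, 1,000 genes (10% planted) for
ranking power, and 1,030 genes in four modules of 400/300/200/100 plus
30 noise genes for clustering recovery — the module-recovery runs
finish in seconds and the whole suite in well under a minute.
Tolerances: smoother-oracle agreement at 10⁻⁸; centering residual means
below 10⁻¹²; clustering recovery asserted at adjusted Rand index
≥ 0.95 for the four dominant modules.  Expression tables are written at
17 significant digits and parsed with round-trip float precision, so
write→read is exact.

## Known limitations

- One shared λ means genes whose smoothness differs wildly from the
  top-IQR subset are over- or under-smoothed; per-gene λ is out of
  scope by design.
- The F-saturation effect above limits absolute (FDR-based) detection
  in sparse-signal regimes at K = 8.
- IHC is a heuristic without an objective function; the documented
  tie rules make it reproducible, not optimal.
- The bootstrap band treats member trajectories as exchangeable, which
  module construction (genes selected for mutual correlation) slightly
  violates; bands are descriptive, not inferential.
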