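# Methods

## Model and assumptions

The package predicts donor chronological age from single-cell RNA-seq by
(1) collapsing each donor's cells of one type into per-gene summary
statistics, (2) expanding those statistics into polynomial features, and
(3) fitting a penalized linear regression.

The featurization assumes that age-relevant genes follow smooth expression
trajectories representable by first- and second-degree polynomials of age —
monotone drift as well as rise-then-fall participation — and that cell-to-cell
expression variability itself increases with age. Both assumptions enter only
through the *feature set*: donor-level mean u_i, sample variance v_i, and
their element-wise squares, 4n columns for n genes, in the fixed order
(means, variances, squared means, squared variances; genes in dataset order)
so fits and attributions are bit-for-bit reproducible. Third-degree features
are deliberately absent (no observed benefit, and they invite overfitting at
cohort sizes of tens of donors).

Statistical conventions:

- Variance uses the unbiased (n − 1) denominator; donors need at least
  `min_cells` cells of the type (default 10, minimum 2) or they are dropped
  from both training and scoring, with the drop reported.
- Normalization is the standard recipe: counts per cell scaled to a size
  factor of 10 000, then log1p with the natural logarithm.
- The elastic-net objective is 1/(2n)‖Xw − y‖² + αρ‖w‖₁ + α(1 − ρ)/2‖w‖₂²
  with an unpenalized intercept. Feature columns are standardized by training
  mean/SD before penalized fitting and the coefficients mapped back;
  without this the squared-mean columns would dominate shrinkage purely
  through their scale. Constant columns pass through with unit scale.

## Tunable parameters

| parameter | default | units / range | why |
|---|---|---|---|
| `size_factor` | 10 000 | counts per cell | standard single-cell normalization target |
| `min_cells` | 10 | cells | variance estimates below ~10 cells are too noisy to be features |
| `alpha_grid` | {0.001 … 100} | penalty strength | spans under- to over-regularized on standardized features |
| `rho_interval` | [0.1, 1.0] | L1 fraction | keeps at least a small ridge component available |
| `budget` | 30 | evaluations | sequential-search budget |
| `cv_folds` | 5 | folds | inner-CV granularity at 10–40 donors |
| `pca k` | 10 (per type), 20 (meta) | components | dimensionality reduction for large panels / concatenated designs |
| `n_runs` | 5 | repeats | run-to-run spread from tuning randomness |

## Hyperparameter search

The tuner is a seeded sequential optimizer: the first half of the budget
samples (α, ρ) uniformly from the grid/interval, the second half samples
around the incumbent best (neighbouring grid point for α, a local Gaussian
perturbation for ρ). It satisfies the contract that the returned
configuration minimizes the recorded trace; exact-duplicate configurations
consume budget without being re-scored. Candidate fits use a looser solver
tolerance (1e−3, 1000 iterations) than final fits — configuration comparison
does not need solver accuracy — and identical fold assignments across
candidates, so the comparison is paired.

Two tuning objectives exist because the protocol is genuinely ambiguous:

- `"cv"` (default): inner k-fold CV MSE on the training donors. Leak-free;
  used for all predictive evaluation (LOO, cross-dataset).
- `"train"`: MSE on the entire training set, i.e. tuning on the training data
  itself. This favours the weakest effective penalty and hence dense models.
  The importance pipeline uses it, for a statistical reason: empirical
  permutation p-values are only calibrated (uniform under the null) when the
  score statistic is continuous. Under CV tuning a null cohort correctly
  collapses to the empty model, pinning every unselected gene's aggregated
  attribution at exactly 0 and its p-value at exactly 1 — valid but
  maximally conservative, and useless for ranking-based enrichment. With the
  dense protocol the gene score is continuous and the null p-value
  distribution passes a KS uniformity check.

## Solver

`fit_elastic_net` dispatches by regime: α = 0 is solved by least squares
(minimum-norm on rank-deficient designs), ρ = 0 by the closed-form ridge
normal equations (exact), and the general case by coordinate descent
(scikit-learn's `ElasticNet`, which minimizes the identical objective) at
tolerance 1e−6, 10 000 iterations. Non-convergence is recorded in the model's
convergence record, never raised. A KKT checker reports the maximum
stationarity violation in the standardized coordinates; the test suite holds
lasso solutions to 1e−6 and ridge solutions to 1e−6 relative error against an
independently coded closed form.

## Evaluation protocols

Leave-one-out rebuilds everything per fold: the held-out donor is excluded
from feature aggregation, from any PCA fit (held-out cells are projected with
training loadings), and from hyperparameter tuning, which is re-run in every
fold. Gene-space donor statistics involve only that donor's own cells, so
they are computed once and subset per fold — numerically identical to
recomputation. Cross-dataset evaluation first restricts every cohort to the
shared gene panel (training-cohort order), asserts donor-disjointness of the
partitions, fits one model per run on the pooled training donors, and scores
R² over all test donors. Repeated runs differ only through tuning randomness;
per-run and per-fold seeds derive deterministically from a master seed.

Method comparison uses a two-sided Mann–Whitney U test on per-cell-type mean
R² samples (top-10 selection helper included). Summary tables sort by mean R²
and flag non-positive means, mirroring the barless-row presentation
convention.

## Interpretation

Attributions use the exact closed form for linear models under feature
independence — w_j (x_j − E_ref[x_j]) with the training donors as the default
reference — rather than a sampling approximation: the fitted model is linear
in its features, so the closed form is exact, deterministic and satisfies
local accuracy to machine precision. A gene's score sums the mean absolute
attribution of its four columns; a per-kind breakdown supports first- versus
second-order comparisons. PC-space models aggregate to components and are
flagged non-gene; the `.rnk` exporter refuses them. Permutation p-values
shuffle donor ages, keep the feature matrix intact, re-run tune/fit/attribute
/aggregate per permutation, and use the add-one estimator
p = (1 + #{null ≥ observed}) / (n_perm + 1), which cannot return 0.

## Synthetic cohorts

The generator draws donor ages uniformly on [20, 80] years and, per cell and
gene, Gaussian log-scale expression with mean b0 + b1·a + b2·a² and SD
c0 + c1·a; non-signal genes have age-constant mean (uniform in [1, 3]) and SD
0.5. A per-donor, per-gene Gaussian random effect (SD 0.05) adds
between-donor variability beyond the age trend. Values are clipped at zero to
respect the non-negativity of log-normalized expression; signal-gene
baselines sit several SD above zero so clipping is negligible (in the
variance-only scenario the baseline is 5.0 precisely so that truncation
cannot leak an age trend into the means). A negative-binomial counts mode
(gamma–Poisson with dispersion 5, optional zero-inflation dropout) exercises
the normalization path.

Preset scenarios fix the study conditions: `strong_mean` (40 donors, 50
genes, 5 linear signal genes with slopes ±0.015–0.025 per year, 200 cells per
donor), `quadratic` (rise-then-fall trends peaking inside the age range),
`variance_only` (flat means, SD slope 0.012/yr), `null` (no signal), and
`small_smoker_like` (12 donors with smoker/non-smoker labels). What these
cohorts do *not* emulate: library-size gradients, batch effects, doublets,
realistic dropout structure, or correlated gene programs — so passing tests
demonstrate correctness of the statistical machinery under the model's own
assumptions, not performance on real tissue atlases.

## Numerical and degenerate-input choices

- PCA uses full SVD with a deterministic sign convention (largest-magnitude
  loading positive); k above the numerical rank raises.
- Zero-variance feature columns standardize with unit scale.
- Constant donor ages, empty gene intersections, zero-total-count cells,
  donors referenced but unannotated, and double normalization all raise with
  the offending identifiers named; dropped donors are reported, never silent.
- R² requires non-constant truth and at least two donors; it is computed
  about the mean of the true ages and may be negative.
- Ties in gene ranking break by column order, making ranks a deterministic
  permutation.

## Problem sizes

The test suite and the acceptance script run the full pipeline at the preset
scenario size (40 donors × 50 genes × 200 cells/donor) with 2–3 repeated
evaluation runs per scenario and 200 permutations for the null calibration;
repeat counts only sharpen the SD estimate, not the mean. Unit tests use
smaller cohorts (6–16 donors) where the property under test does not depend
on cohort size.

## Known limitations

- The sequential tuner is a light SMBO (random exploration plus local
  refinement), not a full tree-structured Parzen estimator; with a budget of
  30 over a 6-point grid × one interval this is empirically indistinguishable
  from exhaustive search.
- Gene identifiers match as case-sensitive symbols; no alias resolution.
- Aggregated-attribution importance is one of several defensible
  aggregations; coefficient-based ranking is available as an alternative
  column but not the default.
- Cross-dataset evaluation assumes cohorts are already on comparable
  normalization scales; no batch integration is performed.
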