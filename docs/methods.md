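# Methods

## The model

`tissueclock` predicts a donor's chronological age from bulk gene
expression. For a tissue with M samples and N preselected genes, it fits
the penalized linear regression

    w_hat = argmin_w  sum_i (Age_i - w0 - sum_j x_ij w_j)^2
                      + lambda * ( alpha * sum_j |w_j|
                                 + (1 - alpha)/2 * sum_j w_j^2 )

where `x_ij` is the log2-transformed expression of gene j in sample i,
`alpha` in [0, 1] mixes the lasso (alpha = 1) and ridge (alpha = 0)
penalties, `lambda > 0` sets their strength, and the intercept `w0` is
never penalized. Prediction for a new sample y is the plain linear
evaluation `Age = w0 + sum_j y_j w_j`. The elastic net suits expression
data because co-expressed genes enter or leave the model together while
the fit stays sparse relative to the transcriptome.

Note the residual term is an **unscaled** sum of squares. Many solvers
(including scikit-learn's) divide it by 2M; our `lambda` is defined on the
unscaled objective — the scale on which a grid of 2^-10 ... 2^10 is
meaningful — and the adapter in `model.fit_elastic_net` converts
(`lambda_sklearn = lambda / (2M)` for `ElasticNet`, `lambda / 2` for
`Ridge`). The mapping is verified in the test suite against closed-form
ridge and normal-equation OLS solutions on small instances (agreement
around 1e-9, far inside the 1e-4 test tolerance).

## Pipeline

1. **Quantile normalization** of each tissue's raw genes x samples
   matrix: every column is mapped onto the vector of row means of the
   column-sorted matrix. Tied values within a column receive the mean of
   the reference values at their tied ranks — the standard convention,
   which makes the operation idempotent and permutation-equivariant on
   tie-free data. With ties, column sums are still equalized but the
   per-column multiset can deviate at tie groups; the tests distinguish
   the two regimes. Normalization is per-tissue by default (each modelled
   matrix on its own samples) and is computed on the full matrix before
   any cross-validation split, mirroring the usual
   preprocessing-then-modelling order; the mild information sharing this
   implies is a property of that order and is deliberately not "fixed".
2. **log2 transform** with pseudocount 1.0 (default). RPKM-scale inputs
   contain zeros, so a pseudocount is required; 1.0 keeps zero expression
   at 0 on the log scale.
3. **Gene preselection**: genes are ranked by the Pearson correlation of
   log2 expression with donor age and the top N are kept. Ranking is by
   |r| (so genes falling with age compete equally; the reference model
   contains coefficients of both signs), with `key="signed"` available.
   Zero-variance genes have undefined correlation and are excluded, with
   their count reported. Ties in |r| break lexicographically by gene id
   so rankings are platform-independent.
4. **Model selection**: (N, alpha, lambda) are tuned by k-fold CV
   (k = 10) repeated `repeats` times (reference: 100), each repeat
   re-randomizing the fold split; validation RMSE and PCC are averaged
   over all repeats x folds and the cell with the lowest mean RMSE wins.
   Crucially the gene ranking is recomputed inside every fold from the
   k-1 training folds only — feature selection never sees validation
   samples. The winning cell is refit on all samples (fold-free ranking)
   to produce the exported model.
5. **Two-tissue combination**: donors present in both tissues (>= 70
   required by default) form the rows; each tissue contributes its
   top-N_A / top-N_B genes as tissue-tagged features, ranked on the
   shared donors only (the donors that actually enter the model;
   `rank_on_shared=False` restores full-cohort ranking). The unit of CV
   splitting is the donor, so a donor never appears in train and
   validation through different tissues.

## Default grids

- N: 50, 100, 200, 400, 600, 800, 1600, 3200, 6400
- alpha: 0 to 1 in steps of 0.01
- lambda: 2^-10 to 2^10 in powers of two

The full joint lattice is ~19k cells x (repeats x k) fits. `grid_search`
therefore defaults in the CLI to a two-stage search — coarse alpha
{0, 0.25, 0.5, 0.75, 1} with full N and lambda, then alpha refined at
step 0.01 within +/-0.12 of the best coarse value — with the joint
lattice (`strategy="joint"`) as the reference behavior. Ties in mean
RMSE go to the smallest N, then the largest lambda, then the largest
alpha: the sparsest, most regularized candidate.

## Numerical choices

- Solver: scikit-learn coordinate descent (`ElasticNet`) with the
  penalty adapter above; pure ridge (alpha = 0) is solved exactly by
  Cholesky (`Ridge`). Default stopping rule is the solver's duality-gap
  tolerance 1e-4 with at most 10,000 sweeps; non-convergence warns, never
  errors. Tests that compare against closed-form optima tighten `tol`
  locally.
- Features are standardized to training mean 0 / variance 1 before the
  penalized fit and coefficients are back-transformed, so exported models
  are plain linear equations on the log2 scale. Constant features get
  coefficient 0.
- Fold assignment: a seeded permutation split into k nearly equal folds
  (sizes differ by at most 1). Repeat r uses seed `base_seed + r`; every
  stochastic step derives from one user-supplied master seed, and CV
  datasets canonicalize row order (sorted unit ids) so results are
  invariant to input sample order.
- Degenerate cases: correlation of a constant vector is flagged NaN, not
  forced to 0; folds whose validation PCC is undefined are dropped from
  the PCC average only.

## The synthetic cohort generator

Real GTEx expression with exact donor ages is access-controlled, so
every pipeline property is exercised on synthetic cohorts with known
ground truth. For gene g, donor s, tissue t:

    log2 x_gst = mu_g + delta_gt + beta_gt * a_st + eps,
    eps ~ N(0, noise_sd^2)

with `mu_g ~ N(5, 2)` log2 baseline, `delta_gt ~ N(0, 0.5)` tissue
offsets, and `a_st` the standardized *transcriptomic age*: chronological
age (integer years, uniform on 20-70) plus an independent per-donor,
per-tissue deviation `N(0, tissue_age_noise_sd^2)`, centered and scaled
by the age range's midpoint and half-width. Raw matrices are
2^(log2 value), flowing through the same preprocessing as real data.
Causal genes — a shared block plus optional tissue-specific blocks —
have slopes `beta ~ N(0, effect_size_sd^2)` (optionally floored away
from zero via `effect_size_floor` for power-controlled tests); all other
slopes are 0. Sex is generated (male:female 1.7, the GTEx-like ratio)
but unused by the model, existing to exercise cohort summaries.

The transcriptomic-age deviation (default 3 years) models heterogeneous
aging across tissues. It makes the simulation honest in two ways: it is
the irreducible error floor of any single-tissue predictor, and because
it is independent across tissues while the age signal is shared,
combining two tissues can average part of it away — the mechanism behind
the multi-tissue improvement the pipeline is designed to measure. A
second tissue carrying no age signal, by contrast, only contributes
noise features and degrades the combined model; both directions are
asserted over seeded replicates.

Reference condition (the generator defaults): 300 donors, two tissues
each including donors with probability 0.8, 2,000 genes, 50 shared
causal genes, effect sd 2 (log2 units per standardized age), residual
noise sd 0.5, transcriptomic-age deviation sd 3 years.

What the generator does **not** emulate: read-count sampling noise,
batch and technical artifacts, non-linear age trajectories (a quadratic
stress term can be injected via custom configs downstream, but is off by
default), correlated co-expression modules, and non-uniform age
distributions. Passing tests therefore certify the pipeline's
statistical machinery — leakage-free selection, correct solver scaling,
the direction of multi-tissue effects — not performance on real tissue.

## Problem sizes in the test suite

The long-running properties use deliberately reduced problem sizes, as
fixed study conditions of this package:

- leakage check: 150 samples x 2,000 genes, permuted ages, 20 repeats,
  grid N {50, 200} x alpha {0, 1} x lambda {0.25, 4}; every cell must
  score >= 0.7 x sd(age);
- recovery check: the reference cohort (above), 10 repeats, grid
  N {50, 100, 200} x alpha {0, 0.5, 1} x lambda {0.5, 4}; best cell RMSE
  <= 4.5 years and >= 15 of the top-20 |coefficient| genes truly causal;
- pairing direction: 10 seeded replicates of 150-donor, 1,000-gene
  cohorts, ridge-only grids (N {50, 100} single; budgets (25, 25) /
  (50, 50) paired; lambda {0.5, 4}), 5 repeats; paired wins >= 8/10 with
  shared signal and loses >= 7/10 against a pure-noise partner.

## Known limitations

- Feature selection by marginal correlation ignores conditionally
  age-informative genes whose marginal correlation is near zero.
- Quantile normalization before splitting, and hyperparameters selected
  on validation RMSE without an outer test set, both bias the reported
  validation RMSE slightly downward; an optional held-out split exists
  but is not the default reporting surface.
- Only pairs of tissues are combined; the block design generalizes to
  k tissues but shared-donor counts shrink quickly with k.
- Exact-age sample tables are required; age-bracket encodings (e.g.
  "60-69") are not supported.
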