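# Methods

## Model

For one gene, the expression of cell *s* from cell type *c* in individual
*i* is modelled as

    y_ics = beta_c + alpha_i + Gamma_ic + eps_ics

with fixed cell-type means `beta_c`, a shared individual effect
`alpha_i ~ N(0, sigma_alpha^2)`, a cell type-specific individual effect
`Gamma_i. ~ N(0, V)` (V a C x C covariance across cell types), and cell-level
residual noise with variance `sigma_ic^2`.  Averaging cells gives the two
pseudobulk summaries the package fits:

* **CTP** (cell type-specific pseudobulk): `y_ic = mean_s y_ics`, with
  measurement-noise variance `nu_ic = sigma_ic^2 / n_ic`.  Per-individual
  covariance block: `sigma_alpha^2 * J_C + V + diag(nu_i.)`.
* **OP** (overall pseudobulk): `y_i = mean over all cells`, variance
  `sigma_alpha^2 + P_i' V P_i + nu_i` with cell-type proportions
  `P_ic = n_ic / n_i` and `nu_i = sum_c (n_ic / n_i^2) sigma_ic^2`.

`sigma_ic^2` is estimated by the within-pair sample variance, which is
unbiased without Gaussian assumptions; the Gaussianity of the *averaged*
noise rests on the central limit theorem, which is why pairs with few cells
are excluded (default: pairs with more than 10 cells kept, individuals with
at least 100 cells; both configurable).

Nested covariance structures: **Hom** (V = 0), **IID** (V = v I), **Free**
(V diagonal), **Full** (V any symmetric matrix).  In the Full model a
constant can be passed between `sigma_alpha^2` and `V + c J` without
changing the likelihood, so `sigma_alpha^2` is pinned to 0 there.  Negative
variance components are allowed during fitting to avoid boundary bias; a
parameter vector is rejected only when the total implied covariance of some
observation stops being positive definite (minimum eigenvalue 1e-10).

## Fitting

* **ML / REML**: BFGS on the variance parameters with an analytic score.
  The fixed effects are profiled out (ML) or residualized (REML); because
  the GLS beta minimizes the weighted residual sum of squares, its
  dependence on the variance parameters drops out of the gradient (envelope
  theorem).  The restricted likelihood includes the `+ 1/2 log|X'X|`
  normalizer, making it invariant to full-rank reparameterizations of the
  fixed-effect design.  Likelihood evaluation exploits block-diagonality
  across individuals (cost O(N C^3)); a blocked extra random effect (e.g.
  experimental batch) is handled by a rank-B Woodbury update of the
  block-diagonal factorization, and both paths are tested against a dense
  multivariate-normal oracle.  Gradient tolerance 1e-6, at most 500
  iterations.  A stalled line search is retried up to twice from the stall
  point (resetting the Hessian approximation); a failed initial attempt
  triggers up to 10 random restarts with each variance component drawn from
  |N(0, s^2/2)| on the scale of the residual sample variance.  Optional
  Nelder-Mead refinement is off by default.  A fit that never reaches a
  small gradient is returned flagged `converged=False`, never silently.
* **HE** (Haseman-Elston, method of moments): closed form.  The OLS
  residual second-moment matrix, divided by the residual degrees of freedom
  (N - 1 - K per cell type; this correction keeps the moments unbiased at
  small N) and with the known noise `diag(mean nu)` subtracted, is
  projected onto the covariance basis of the chosen structure.  For OP, the
  squared residuals (scaled by N/(N-p)) are regressed on [1, P_ic^2, ...].

Parameter counts: Hom C+1, IID C+2, Free 2C+1, Full C + C(C+1)/2.

## Tests

* **LRT** Free vs Hom: `2 * (ll_free - ll_hom)` against chi-square with C
  degrees of freedom (one added variance per cell type).  A plain
  chi-square is used rather than a boundary chi-bar-square mixture; since
  negative components are allowed the boundary is soft, but the reference
  distribution can be mildly mis-calibrated in small samples.
* **Wald F-test** of `diag(V) = 0`: quadratic form divided by C against
  `F(C, N - R)`, `R = 2C + 1`.  The precision comes either from the
  observed information (central finite differences of the analytic-free
  objective) or from the delete-one-individual jackknife covariance
  `((N-1)/N) * sum_i (theta_(-i) - theta_bar)(theta_(-i) - theta_bar)'`.
  By default the covariance sub-block of `diag(V)` is inverted; selecting
  the sub-block of the full-parameter precision instead is available behind
  `use_full_precision`.  Leave-one-out refits warm-start at the full-sample
  optimum.
* **Mean differentiation**: F-test of `beta_c = beta_c'` via C-1
  successive-difference contrasts of the GLS beta with jackknife precision,
  df (C-1, N-R); any full-rank contrast yields the same statistic.  HE
  pipelines use OLS coefficients (the HE moment covariance can be
  singular).
* **Bonferroni** across genes at `alpha / n_tests`.

Finite-sample behavior: under the Hom truth the jackknife standard errors
track the empirical sampling SD of the `V_cc` estimates closely, but the
F-calibrated quadratic form is slightly anticonservative around N = 100
because variance estimates are non-Gaussian there.  This mirrors the
method's known residual inflation at modest cohort sizes and is why
results near the significance boundary at N ~ 100 deserve caution.

## Synthetic-data generator

`simulate_ctp` / `simulate_op` draw directly from the pseudobulk model.
Baseline conditions (used throughout the test suite and the acceptance
script): C = 4 equal-proportion cell types, `beta = 0`,
`sigma_alpha^2 = 0.1`, Free-model `V = diag(0.1, 0.1, 0.1, 0.1)`, true
`nu_ic ~ Uniform(0.05, 0.15)`, N in {20, 50, 100, 300, 1000}, 1000
replicates per cell.  OP mode draws per-individual proportions from a
Dirichlet around the target proportions with concentration 10; real
cohorts show substantial proportion variability, and with near-constant
proportions only the *sum* of the cell type-specific variances is
identified in OP, which makes small-N OP Free fits genuinely ill-posed
(they are reported as non-converged).

Noise in the reported `nu` is injected as `nu' = nu (1 + s x)` with
`x ~ Beta(2, b)` and an independent fair-coin sign per entry
(`E[x] = 2/(2+b)`; b = 10 corresponds to the coefficient of variation
~0.2 seen in real data, b = 3 to ~0.45).  What the generator does *not*
emulate: count-level sampling, non-Gaussian cell-level distributions,
mean-variance coupling, cell-type misassignment, or covariate/batch
structure unless configured — so passing tests demonstrate correctness of
the estimators and tests under the model's own assumptions, not robustness
to every artifact of real scRNA-seq data.

A note on the nu-noise experiment: mis-specified per-entry noise biases the
REML `V_cc` estimates upward by an amount proportional to `E[x^2]`, while
the sampling SD of `V_cc` scales like `nu * sqrt(2/N)`.  The bias-to-SE
ratio therefore grows with sqrt(N) and is invariant to the overall variance
scale.  Consequently the likelihood-ratio test degrades quickly with noise;
the jackknife Wald test degrades far more slowly (its standard errors track
the true sampling spread) but is not immune at strong noise; and HE is
essentially unaffected because its moment equations are linear in `nu`
(mean-zero noise cancels in expectation).

## Imputation

Structured missingness (whole individual x cell-type pairs) is completed
by (a) an iterative soft-thresholded SVD (softImpute-style), per gene or on
the N x (C*G) transcriptome-wide stack — the stack borrows strength across
genes sharing individual-level structure and is the recommended default;
or (b) an EM-fitted C-variate Gaussian with conditional-mean fill.  The
soft threshold is chosen by 5-fold entry-held-out cross-validation over a
small grid scaled to the top singular value (the grid excludes zero: an
unshrunk full-rank reconstruction is the identity on refilled entries, so
`lam = 0` without a rank cap falls back to a hard rank cap of
min(N, C) - 1).  Observed entries are never altered.  Imputation operates
on the standardized scale; `nu` is imputed on its raw scale.  Negative
imputed `nu` values are repaired by clamping to 0 (OP) or by substituting
the per-gene, per-cell-type maximum observed raw `nu` (CTP), which
down-weights the repaired entries in the likelihood.  Copy-mask
benchmarking copies one individual's real missing cell-type set onto
another until ~10% of pairs are hidden, then scores median correlation and
MSE over (default) 10 replicates with seeds `base + replicate`.

## Variance decomposition

For a converged Free fit on standardized data, the total variance is split
into: sample variance of the fitted covariate predictor, the batch
variance, `sigma_alpha^2`, the proportion-weighted cell type-specific
component `sum_c w_c V_cc` with `w_c` the mean proportion of cell type c,
and the mean `nu`; the pieces are normalized to sum to one.  This is a
standard ANOVA-style decomposition chosen here as the design was open.
Transcriptome summaries report both mean and median across genes.  Full-
model correlations `V_cc' / sqrt(V_cc V_c'c')` exclude genes with any
negative fitted diagonal (flagged, not dropped silently).

## Problem sizes

The test suite and acceptance script run the full 1000-replicate
experiments for the headline rates (N = 1000 calibration, N = 50 and 20
power) and smaller replicate counts (40-300) for secondary checks such as
jackknife calibration, noise robustness, and estimator recovery; those
sizes keep every Monte-Carlo band used in an assertion wide enough for the
replicate count actually run.

## Known limitations

* Discrete, pre-assigned cell types; no continuous/pseudo-time states.
* Gaussian pseudobulk likelihood; low-count genes with few cells per pair
  violate the CLT premise and are excluded rather than modelled.
* The Full model needs hundreds of individuals for stable per-gene
  estimates.
* The variance Wald test retains slight anticonservatism at N ~ 100.
* HE with CTP degrades when a cell type's proportion is very small; OP
  Free fits are weakly identified when proportions barely vary.
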