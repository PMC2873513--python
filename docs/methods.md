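# Methods note

This note records the statistical model implemented by `lcsem`, the
assumptions behind it, the conventions the package commits to where more than
one reasonable choice exists, and the numerical decisions in the estimator and
the synthetic-data generator.

## 1. Model

### 1.1 Variables

Analyses are run separately by sex on 11 within-sex mean-centered variables:
four baseline adiposity indicators (percent body fat `pbf0` and the logarithms
of BMI, skinfold thickness and waist circumference), the four corresponding
changes over follow-up (differences of logs for the logged indicators), and
three observed covariates: baseline age `age0`, baseline cognitive restraint
score `crs0`, and the change in restraint `d_crs`. Indicator variables other
than percent body fat are log-transformed because their raw distributions are
right-skewed; working with differences of logs makes an indicator's change
interpretable as a relative (ratio) change.

### 1.2 Measurement model

Two latent variables carry the substance: baseline adiposity `A0` and
adiposity change `A1`. Each of the four indicators loads on `A0` at baseline
and its change loads on `A1`, with the loading λ_j **constrained equal**
across baseline and change — the indicator is assumed to measure the same
construct on the same scale at both waves, so that `A1` genuinely is the
change in `A0`. The percent-body-fat loading is fixed at 1 to give both
latents the metric of percent body fat. Measurement residuals are mutually
uncorrelated by default; a builder switch (`free_residual_cov=True`) frees the
four baseline↔change residual covariances for sensitivity analysis.

### 1.3 Structural model

The structural graph is recursive (a DAG) on
{`age0`, `crs0`, `A0`, `d_crs`, `A1`}:

- `A0` regressed on `age0` and `crs0`;
- `d_crs` regressed on `A0`, `age0` and `crs0`;
- `A1` regressed on `A0`, `age0`, `crs0` and `d_crs`;
- a free covariance between the exogenous `age0` and `crs0`.

This yields 26 free parameters (3 loadings, 8 measurement residual variances,
9 regression coefficients, 3 structural residual variances, 2 exogenous
variances, 1 exogenous covariance) against 66 observed moments: 40 degrees of
freedom. Two reduced builders are provided: a single-wave measurement model
(one latent, 4 indicators, df = 2) and a latent-change measurement model
without covariates (two latents linked by an `A1`-on-`A0` regression, equal
loadings, 14 free parameters, df = 22). The baseline→change link in the
latent-change model is a directed regression rather than a covariance, so its
coefficient reads as the dependence of adiposity change on initial level.

### 1.4 Assumptions

- Multivariate normality of the observed variables (normal-theory ML; the
  pipeline reports Lilliefors-corrected Kolmogorov–Smirnov statistics per
  variable as a diagnostic, not a gate).
- Linear relations among latents and observables; no latent interactions.
- Equal loadings across waves (tested implicitly through overall model fit).
- Independent subjects; listwise deletion of incomplete records.
- Covariance-structure analysis only: means are removed by centering and carry
  no model content.

## 2. Estimation

The engine uses the RAM parameterization: all variables (observed and latent)
enter a directed-coefficient matrix `A` and a residual-covariance matrix `S₀`;
the implied covariance is `Σ_all = (I−A)⁻¹ S₀ (I−A)⁻ᵀ`, filtered to the
observed block. Equality constraints are expressed by giving several matrix
cells the same free-parameter label.

- **Discrepancy.** `F_ML = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p`, minimized by BFGS
  with an **analytic gradient** (matrix calculus on the RAM structure), which
  makes a 26-parameter fit run in ~0.04 s.
- **Variance parameters** are optimized on the log scale, guaranteeing
  positivity without box constraints; standard errors are mapped back to the
  natural scale by the delta method.
- **Restarts.** Up to 5 jittered restarts (multiplicative jitter 0.25, seeded)
  around moment-based starting values; convergence requires gradient
  max-norm ≤ 1e−6 within 500 iterations. Non-convergence raises a
  `RuntimeWarning` and is flagged on the fit object, never silently ignored.
- **Inference.** `χ² = (N−1)·F_ML`; the parameter covariance is
  `(2/(N−1))·H⁻¹` with `H` the finite-difference Hessian of the analytic
  gradient. Identification is checked on the **correlation-form Hessian**
  `D^(−1/2) H D^(−1/2)` (D = diag H), declaring singularity when its smallest
  eigenvalue is ≤ 1e−8; this makes the check invariant to the ~8 orders of
  magnitude of curvature spanned by loadings versus log-variances. A failure
  raises `IdentificationError` naming the parameters in the null space.
- **Fit indices.** RMSEA = √(max(χ²−df,0)/(df·(n−1))) with its confidence
  interval obtained by inverting the noncentral-χ² CDF in the noncentrality
  parameter (Brent root-finding); a degenerate lower bound of 0 is rendered
  "`.`". NFI = (χ²_b − χ²_m)/χ²_b against the independence baseline, whose χ²
  has the closed form (N−1)(ln|diag S| − ln|S|).

## 3. Effect decomposition

Effects of `crs0` on `A1` are products of coefficients along directed paths.
The structural graph contains **four** simple paths from `crs0` to `A1`:
direct; via `d_crs`; via `A0`; and the compound `crs0 → A0 → d_crs → A1`.
The decomposition convention used in the original analysis of these data sums
only the direct effect and the two single-mediator indirects; the compound
path, though present in the graph, was not enumerated there. The package keeps
both books:

- `direct`, `indirects` (single-mediator), `partial` = direct + via-`d_crs`,
  `total` = direct + single-mediator indirects (the reporting convention);
- `extra_paths` (the compound path) and `total_all_paths`, which equals the
  `(A1, crs0)` entry of the reduced form `(I−A)⁻¹` exactly and is the
  mathematically complete total effect.

The two totals differ by the compound-path product, typically an order of
magnitude below the single-mediator terms. Bootstrap inference resamples
subjects with replacement within sex (default B = 1000, minimum 100), refits
the full model per replicate, and reports both normal-approximation and
percentile intervals; failed replicates are counted, with a warning above 5%
and an error above 50%. A Lilliefors normality check of the replicate
distributions indicates when the percentile interval should be preferred.

## 4. Synthetic-data generator

The generator's defaults are the study conditions: per-sex sample sizes
(201 male, 256 female), observed means and SDs, loadings, and structural
coefficients are taken directly from the published tables and used as
generating truth. Quantities the tables do not print are **derived**, not
tuned, and each derivation is recorded in `GeneratorParams.derivation`:

- Baseline measurement-residual variances from published squared standardized
  loadings R²_j: `var(ε_j0) = (1 − R²_j)·var(x_j0)`, with the variance of a
  logged indicator obtained by lognormal moment matching,
  `varlog = ln(1 + (sd/mean)²)`.
- Latent residual variances solved sequentially so that `var(A0) = R²_pbf ·
  var(pbf0)`, `sd(d_crs) = 12`, and `sd(A1) = 2.0` — scales consistent with
  the published change-score dispersions.
- Change-indicator residual variances from the published standardized change
  loadings `s_j`: `var(ε_j1) = λ_j²·var(A1)·(1/s_j² − 1)`.
- The exogenous `age0`–`crs0` correlation has no published value and defaults
  to 0 (configurable through `default_params(..., age_crs_corr=...)`).

Raw-scale records are produced by un-centering: anchor means are chosen by
lognormal moment matching (`μ = ln(m) − v/2`) so that the **raw** means of the
exponentiated indicators match the published table means. Out-of-range values
(e.g. negative percent body fat under extreme parameterizations) are counted
and flagged but never truncated, preserving the exact generative distribution.

Scope and limitations: the generator produces exactly multivariate-normal
centered data, so it cannot exercise robustness to skewness, floor effects, or
missingness mechanisms; it matches first and second moments of the published
cohort but not higher moments; and the three derived scale choices above
(`sd(A1) = 2.0`, `sd(d_crs) = 12`, zero age–restraint correlation) are
plausible study-consistent settings, not published facts.

## 5. Verification problem sizes

The test suite validates the estimator against independent oracles
(closed-form just-identified factor solutions, reduced-form matrix totals,
closed-form baseline χ²), checks SE calibration by Monte Carlo (500 replicates
at n = 2000, empirical SD vs mean reported SE within 15%), runs
parameter-recovery studies (200 replicates × n = 2000 per sex: per-parameter
bias below 0.002 for loadings and 0.02 for structural coefficients, 95% CI
coverage within [0.90, 0.99]), and compares bootstrap to asymptotic standard
errors (within 25% at n = 2000, B = 300). Recovery criteria are stated as
bias (mean estimate minus truth) rather than per-replicate absolute error,
since the latter is bounded below by sampling noise that no correct estimator
can remove.
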