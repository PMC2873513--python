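# lcsem — latent-change structural equation models for adiposity and dietary restraint

`lcsem` is a small, self-contained toolkit for fitting **latent-variable
structural equation models of longitudinal change**, built around one concrete
scientific question: does cognitive restraint of eating (measured by a
restraint score, CRS) drive subsequent change in adiposity, or does adiposity
drive subsequent change in restraint?

Because no single anthropometric measurement captures adiposity without error,
the package treats adiposity as a **latent variable** measured by four
indicators — percent body fat, log BMI, log skinfold thickness and log waist
circumference — and models *change* in adiposity over a follow-up period as a
second latent variable sharing the same measurement structure. Restraint and
its change are treated as observed. All models are fitted separately by sex to
sex-specific covariance matrices by normal-theory maximum likelihood.

## The model

Observed analysis variables (per subject, within-sex mean-centered):

| variable | meaning |
|---|---|
| `pbf0`, `log_bmi0`, `log_skinfold0`, `log_waist0` | baseline adiposity indicators |
| `d_pbf`, `d_log_bmi`, `d_log_skinfold`, `d_log_waist` | changes in the indicators |
| `age0`, `crs0`, `d_crs` | baseline age, baseline restraint score, change in restraint |

Measurement model (loadings λ constrained equal for baseline and change,
percent-body-fat loading fixed at 1 to scale the latents `A0` = baseline
adiposity, `A1` = adiposity change):

```
x_j0   = λ_j · A0 + ε_j0
d_x_j  = λ_j · A1 + ε_j1            j ∈ {pbf, log_bmi, log_skinfold, log_waist}
```

Structural model (all five structural variables, recursive):

```
A0    = γ_A0,age · age0 + γ_A0,crs · crs0 + ζ0
d_crs = β · A0 + γ · age0 + γ' · crs0 + ζd
A1    = β' · A0 + γ'' · age0 + γ''' · crs0 + β'' · d_crs + ζ1
```

with a free `age0 ↔ crs0` covariance. The full longitudinal model has 26 free
parameters and 40 degrees of freedom on the 11×11 observed covariance matrix.

Effects of `crs0` on `A1` are decomposed by product-of-coefficients along the
directed paths of the structural graph: a direct effect, an indirect effect
mediated by restraint change (`via_d_crs`), an indirect effect mediated by
baseline adiposity (`via_A0`), and the longer compound path
(`via_A0_d_crs`). Two totals are reported: `total` (direct plus the two
single-mediator indirects — the decomposition convention used in the original
analysis) and `total_all_paths` (the exact reduced-form entry of `(I − A)⁻¹`,
which additionally includes the compound path). See `docs/methods.md`.

## Worked example

Simulate a male cohort at the study conditions (n = 201, published means,
loadings and structural coefficients as generating truth), fit the full
longitudinal model, and decompose the effect of baseline restraint on
adiposity change:

```python
from lcsem import (default_params, simulate, derive_analysis_dataset,
                   sample_covariance, fit_ml, fit_report, decompose)
from lcsem.models import longitudinal_structural_spec

params = default_params("male")
cohort = simulate(params, seed=7, n=201)
ds = derive_analysis_dataset(cohort, "male")
cov = sample_covariance(ds)
spec = longitudinal_structural_spec()
fit = fit_ml(spec, cov)

print(fit_report(fit, cov).render())
for row in decompose(fit, spec, "crs0", "A1").as_rows():
    print(row)
```

Output:

```
chi2(40) = 37.54, p = 0.582
RMSEA 0.00 [. ; 0.05]
NFI 0.966
{'effect': 'direct', 'estimate': 0.02803330924642428}
{'effect': 'via_A0', 'estimate': -0.002157951850314327}
{'effect': 'via_d_crs', 'estimate': -0.003326802822387765}
{'effect': 'partial', 'estimate': 0.024706506424036514}
{'effect': 'total', 'estimate': 0.022548554573722186}
```

Selected structural coefficients from the same fit:

```
  beta_dcrs_A0  +0.599  (SE 0.144)
 gamma_A1_crs0  +0.028  (SE 0.009)
  beta_A1_dcrs  +0.009  (SE 0.013)
```

The same analysis is available from the command line:

```bash
lcsem simulate --sex male --seed 7 --n 201 --out cohort.csv
lcsem fit --input cohort.csv --sex male --model longitudinal
lcsem effects --input cohort.csv --sex male --bootstrap-b 1000 --seed 1
lcsem report --input cohort.csv --sex male --seed 1 --out report/
lcsem recovery --sex female --n 2000 --replicates 200 --seed 0
```

## Package layout

| module | contents |
|---|---|
| `lcsem.data` | record loading, listwise deletion, log-change derivation, within-sex centering, covariance and normality summaries |
| `lcsem.engine` | RAM-parameterized ML SEM engine: analytic-gradient BFGS, Hessian-based standard errors, identification diagnostics, standardization |
| `lcsem.models` | the three model builders (`single_wave`, `latent_change`, `longitudinal`) with equality constraints |
| `lcsem.fit_indices` | χ², RMSEA with noncentral-χ² confidence interval, NFI, baseline model |
| `lcsem.effects` | path enumeration, product-of-coefficients decomposition, subject-level bootstrap |
| `lcsem.simulate` | synthetic cohort generator at the study conditions; parameter-recovery studies |
| `lcsem.pipeline` / `lcsem.cli` | full per-sex analysis pipeline, JSON/text reports, `lcsem` command line |
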