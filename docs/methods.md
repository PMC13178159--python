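# Methods

## Model and estimand

The package targets the standard harmonized multi-cohort linear model

    Y = β₀ + β₁X₁ + … + β_mX_m + γ₁C₁ + … + γ_kC_k + ε,

where `X₁` is the exposure of interest (RBC DHA, % of total fatty acids in
the motivating application), `X₂…X_m` are covariates, `C₁…C_k` are cohort
membership indicators (fixed cohort effects) and `Y` is a quantitative
outcome — here the Trail Making Test part B minus part A time in minutes,
a measure of executive dysfunction. Effect modification by a binary
stratum variable `G` (APOE-ε4 carriership) is expressed by adding `G` and
the product `G·X₁`; the interaction is tested by the nested-model ANOVA
F-test, and stratified fits repeat the covariate-adjusted model within
each stratum.

Everything is computed from pre-computed summary statistics (PCSS): per
cohort×stratum cell, the variable means, the sample covariance matrix and
the sample size. Because OLS is a function of first and second sample
moments only, the summary route is *algebraically identical* to row-level
least squares — the package's defining property, asserted at 1e-8 relative
tolerance over randomized configurations in the test suite (observed
discrepancies are ~1e-11, i.e. accumulated floating-point error only).

## Pooling algebra and its assumptions

Pooled covariances come from the between/within decomposition
SSTO = SSG + SSE described in the README; pooled covariance uses divisor
`N − 1`. The implementation stores *sample* covariances (divisor `n − 1`)
together with `n`, so cross-product sums `(n−1)·cov` are always
recoverable; any consistent divisor convention yields the same OLS
results, and the file format pins the convention (`cov_divisor: "n-1"`)
to prevent silent mixing.

Synthesized columns exploit that cohort indicators and the stratum
indicator are constant within a cell: each cell is augmented with
constant columns (and, for products `G·X`, with `g·X` as an exact linear
map of the cell's variables) and then pooled. This reproduces, exactly,
the moments of explicit row-level 0/1 and product columns; the
closed-form identities (indicator mean `nⱼ/N`, variance `Npⱼ(1−pⱼ)/(N−1)`,
indicator–variable covariance `nⱼ(x̄ⱼ−x̿)/(N−1)`, indicator cross-covariance
`−Npⱼp_k/(N−1)`) are verified against concatenation oracles in the tests.

Assumptions: complete cases within each cell (PCSS are taken as computed
on the analysis sample); identical variable lists across cells; cells
with fewer than 2 rows are rejected ("insufficient cell size") because a
sample covariance is undefined there — mean-only cells are deliberately
unsupported. A cohort may be absent from a stratum; it then contributes
only to the stratum it has. Cells with `n ≥ 2` always enter pooled fits,
including cells too small to support their own cohort-specific model.

## Fitting and inference choices

* Slopes solve `S_xx b = s_xy` via a Cholesky factorization of the
  predictor covariance block (no explicit inversion); the inverse needed
  for standard errors reuses the factorization.
* Singularity is declared when the predictor *correlation* block's
  condition number exceeds 1e10; the error names the column with the
  largest loading on the smallest eigenvector. Zero-variance predictors
  are rejected by name.
* `n > p + 1` is enforced; per-cohort fit requests that fail the guard
  return an "Insufficient Sample Size (n = …)" marker instead of numbers,
  mirroring how multi-cohort tables report such cells.
* Inference uses the t distribution with `N − p − 1` degrees of freedom
  for pooled OLS (CIs, p-values) and normal (z) inference for the IVW
  meta-analysis — the conventional pairing.
* When an intercept and a complete indicator family are both present,
  the lexicographically first indicator is dropped as the reference
  level (deterministic and order-independent); `reference_drop`
  overrides.
* Nested F-tests clamp numerators in `[−1e-12, 0)` to zero (floating
  cancellation) and refuse genuinely negative improvements.
* Categorical covariates are expected pre-encoded as indicator columns
  by the PCSS producer; the model layer has no factor-coding language.
* Predictions are point predictions `ŷ` at supplied covariate vectors;
  no prediction intervals.

## Synthetic emulation: what it does and does not show

`GeneratorConfig` defaults encode the published study conditions: cohort
sizes (1201, 778, 135, 44), APOE-ε4 carrier prevalences (0.276, 0.262,
0.215, 0.136) and per-cohort DHA means/SDs (4.8/1.4, 4.4/1.3, 5.2/1.4,
5.1/1.0 % of total FA). The outcome difference is generated linearly:
DHA main effect `b_dha = −0.06` and carrier-specific addition
`b_int = −0.07` min per 1% DHA, so the published stratified associations
(−0.06 non-carriers, −0.13 carriers) are the *generating truth* — the
published fitted values themselves derive from access-restricted data and
are not reproduction targets.

Where the study conditions do not pin a value, the generator makes one
documented choice: covariates age ~ truncated normal(58.9, 5.5) on
[50, 70] with effect +0.02 min/yr, female sex ~ Bernoulli(0.543) with
−0.05 min, BMI ~ normal(28.6, 5.7) with +0.01 min per kg/m² (calibrated
to the pooled descriptive column; small, plausible nuisance effects);
residual noise SD 0.75 min and cohort intercept shifts (0, −0.2, +0.4, 0)
around a base intercept of −0.16, chosen so pooled outcome mean and SD
land near the published 0.8 (0.8) min. Part A time is lognormal with
median 0.5 min and is raised where needed to keep both raw times
positive; only the B − A difference enters any model, so this is a
presentation choice.

Not emulated: familial correlation, longitudinal structure, the
measurement-window filter, race/ethnicity, education and medication
covariates (available via `covariate_spec` but not defaulted). Passing
tests therefore certify the *algebra and calibration of the method*, not
any substantive claim about the real cohorts.

Monte-Carlo studies redraw a replicate when a generated design contains
a cell with fewer than 2 rows (at the reduced type-I sizes with the
smallest cohort at n=40 and prevalence 0.136 this affects ~2% of draws);
i.e. results are conditional on design feasibility, as any stratified
analysis is.

## Problem sizes in the validation studies

Equivalence: 200 random configurations (1–6 cohorts of 30–2000 rows,
1–10 predictors, optional stratification). Type-I error: 2000 null
replicates at cohort sizes 300/200/60/40. Coverage/bias and power: 500
replicates each at the default cohort sizes. These sizes give binomial
Monte-Carlo SEs of ~0.5% (type-I) and ~1% (coverage/power), adequate for
the asserted bands; all studies together run in about a minute on one
CPU. Fixed seeds are used throughout (hypothesis tests derandomized);
`scripts/acceptance.py` derives all streams from its `--seed`.

## Known limitations

* Quantitative outcomes and OLS only; no logistic/nonlinear models, no
  weighted or robust/clustered errors, no random cohort effects.
* Exact interaction designs require per-stratum PCSS; approximating
  product moments when stratified summaries are unavailable is out of
  scope.
* Meta-analysis is fixed-effects IVW only (no heterogeneity statistics),
  serving as the comparison baseline, and drops cohorts that cannot fit
  the model — an asymmetry the power study quantifies rather than hides.
* PCSS carry no missing-data information; harmonization and complete-case
  filtering must happen before summarization.
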