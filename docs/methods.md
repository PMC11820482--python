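# Methods

This note records the model, the defaults, the numerical choices and the
limits of what the package's tests demonstrate.

## Water-balance model

Daily water balance is accounted in mL/day as intake minus loss.

Intake has three components:

* **Foods** — Σ over items of (recoded frequency, times/day) × (serving
  size, g) × (water fraction), with 1 g water ≡ 1 mL. The shipped
  composition table is a twenty-item fixture with water fractions typical of
  standard nutrient-composition databases and household servings; real
  studies should supply their instrument's item list and composition data
  through `ScoringConfig`.
* **Beverages** — the same construction over the five instrument categories
  (juices/soft drinks, coffee/milk, milkshake/granita, tea, alcohol) with
  per-category serving volumes and water fractions. Plain drinking water is
  never included here.
* **Drinking water** — reported directly in mL/day.

Loss has three components: urinary and fecal loss from 5-point frequency
scales via lookup tables, and sweat as a resting component (10-point scale →
mL/day) plus an exercise component, Σ over IPAQ activity classes of
(weekly hours / 7) × class base rate (mL/h) × a 10-point sweat-scale
multiplier. Respiratory loss and metabolic water are taken as cancelling and
are omitted from both sides.

The frequency recode (0, 0.066, 0.214, 0.643, 1, 2.5 times/day) is the
instrument's published mapping and is reproduced bit-exactly by the default
`FrequencyRecode`. The value 1 for "3–4 times per day" breaks the midpoint
pattern of the neighbouring categories but is the published constant and is
used as-is.

### Default mapping tables

The instrument's sources do not print the mL values behind the excretion and
sweating scales, so the defaults are neutral grids over published
healthy-adult ranges, and everything is overridable in `ScoringConfig`:

| table | default | rationale |
|---|---|---|
| urine (1–5) | 800 → 2000 mL/day, linear | healthy-adult daily urinary water span |
| feces (1–5) | 50, 100, 150, 250, 400 mL/day | published fecal water for healthy adults |
| resting sweat (1–10) | 300 → 1000 mL/day, linear | insensible-to-noticeable sweating span |
| exercise base rates | vigorous 1000, moderate 600, walking 300 mL/h | typical sweating rates by intensity |
| sweat multipliers (1–10) | 0.2 → 2.0, linear | scales the base rate by reported sweating |
| beverage servings | 330/150/250/250/330 mL; fractions 0.90/0.95/0.80/0.99/0.92 | household servings, composition-table fractions |

BMI is weight/height² (kg/m²) with WHO classes (<18.5, [18.5, 25),
[25, 30), ≥30); beverage variety counts categories with recoded frequency
strictly > 0 and is dichotomised at >3 types (the cohort-median cut-off);
IPAQ MET·min/week uses the standard short-form weights 8.0/4.0/3.3.

### Numerical choices

Every mL/day component is snapped to a dyadic grid of 2⁻³⁰ mL (≈10⁻⁹,
far below questionnaire resolution). All components are then exact binary
floats with fewer than 53 significant bits, so the accounting identity
`balance + loss_total − intake_total == 0` holds *exactly* in floating
point — a deliberate choice so conservation can be asserted without
tolerance. Missing food/beverage frequencies contribute zero intake (and
are distinguishable from zero only in the validation log); a missing
drinking-water amount, excretion scale or sweat scale propagates to a
missing balance. Imputation is the analysis module's job, never the
scorer's.

## Statistical pipeline

* **Test selection.** Gender comparisons use chi-square for categorical
  variables (continuity-corrected only for 2×2 tables), Student's t when
  both groups pass Shapiro–Wilk at α = 0.05, otherwise the Wilcoxon
  rank-sum with normal approximation and tie correction. All tests are
  two-sided at 0.05; no multiplicity adjustment is applied, matching the
  analysis this pipeline reproduces.
* **Univariate screen.** One OLS per predictor (a multi-level factor enters
  as one model with dummy terms). Reference levels: female; profession
  "other"; limited (≤3) beverage variety; "no" for yes/no items. Likert
  items enter as continuous 1–5 scores.
* **MAR screen.** Each incomplete variable's missingness indicator is
  regressed (ridge-stabilised IRLS logistic, ridge 10⁻⁶–10⁻⁴) on the fully
  observed covariates; separated or non-converged effects are reported as
  non-estimable rather than raised. A "systematic pattern" flag is set when
  any covariate is significant at 5%.
* **Chained-equation imputation.** Continuous variables: Bayesian linear
  regression draws (σ² from the scaled inverse-χ² posterior, coefficients
  from N(β̂, σ²(XᵀX)⁻¹), then predictive noise). Binary variables: logistic
  fit with an approximate-normal coefficient draw, then a Bernoulli draw.
  Defaults m = 20 chains, 10 cycles, seed 20220512; chains are seeded by
  spawning a `SeedSequence`, so results are reproducible and chains are
  independent. The imputation model always conditions on the outcome and
  all modelling covariates (congenial with the analysis models). The
  imputer is hand-rolled rather than delegated because the recovery
  Monte Carlo needs per-chain seed control and mixed
  linear/logistic conditionals behind one small API.
* **Models 1–3.** Model 1 pools OLS on the full 20-term DAG set over the m
  completions by Rubin's rules (between-imputation variance with the
  standard degrees-of-freedom formula, capped at the complete-data residual
  df; with identical completions it reduces exactly to the single fit).
  Backward AIC elimination runs on the *first* completed dataset —
  deterministic and simple where no standard exists for selection under
  imputation — with AIC = n·log(RSS/n) + 2p and factors dropped as whole
  groups; Model 2 pools the selected terms over all completions. Model 3
  refits the Model 2 terms with pooled p < 0.05 (a factor survives if any
  level does). Nesting terms₃ ⊆ terms₂ ⊆ terms₁ holds by construction.
  Pooled adjusted R² and RMSE (√(RSS/n)) are means across completions.
* **Power.** `required_sample_size` returns the smallest n whose
  noncentral-F power (λ = f²·n, F(k, n−k−1)) reaches the target. For
  f² = 0.15, 80% power, α = 0.05 and 5 predictors this gives n = 92; a
  smaller figure sometimes quoted for this configuration is not reproducible
  from the standard omnibus-test calculation, and the standard formula is
  what ships.

## Synthetic cohorts

The generator emulates a Greek working-population cohort: gender split
98/110, the printed residence/family/profession and Likert distributions,
container-use prevalences (bottle at work 0.553, bottle during day 0.848,
glass during day 0.693), work hours ~ N(38.87, 10), education ~ N(16, 3)
truncated to [6, 25]. Distributions the emulated tables do not report
(age, anthropometry by gender, drinking-without-thirst and for-pleasure
prevalences, food/beverage category probabilities, excretion and sweating
scales, IPAQ) are fixed once at values a nutrition researcher would call
realistic for working adults; beverage-category probabilities were chosen so
the implied broad-variety share (~0.66) and per-category median recoded
frequencies match the emulated cohort's, which makes mean beverage water
run somewhat above its printed median — variety calibration was given
priority because variety is a model covariate.

The planted model defaults to the reduced multivariable model the package
reproduces: education −21.88, work hours +30.17, glass use +423.13, bottle
use +873.50, water for pleasure +478.63 mL/day, intercept −3052.46, noise
SD 1377.49 (the reduced model's RMSE). The latent balance is drawn on that
scale and the drinking-water field — the only continuous free intake
input — is back-solved, keeping every ordinal marginal intact. When the
back-solve would need negative drinking water, the loss-side answers
(excretion scales, IPAQ) are redrawn with the latent target held fixed (up
to 30 rounds), and any residual cases get a deterministic loss augmentation
(maximal scales, then exactly enough extra walking time). Because the
latent balance itself is never altered, planted coefficients remain exactly
recoverable — feasibility handling biases only the loss-side marginals,
which are not model covariates. With the default spec roughly 15–20% of
respondents need at least one redraw and ~1–2% the deterministic fallback.

Missingness injection supports MCAR and MAR; MAR deletes with logistic
probability in designated fully observed covariates (default: age and
gender at 10%), with the intercept calibrated by root-finding so the
realised expected rate equals the nominal rate. A truth mask retains
deleted values, so observed cells plus mask reconstruct the cohort exactly.

### What passing tests do and do not show

The recovery Monte Carlo (500 cohorts of n = 208, full pipeline) shows the
estimator chain is unbiased for effects planted *under the generator's
assumptions*: linear effects, Gaussian noise, MAR missingness congenial
with the imputation model, and marginals as configured. It says nothing
about misreporting, seasonal variation, non-linear dose–response,
informative (MNAR) missingness, or the sampling biases of a convenience
cohort — none of which the generator emulates. Cohort descriptive values
from the emulated study are *not* reproduction targets: its raw data are
available only on request, and some printed percentages are internally
inconsistent, so descriptives are covered by marginal-structure checks
only.

The reported recovery estimand is the pooled coefficient of the
planted-term specification refit on every replicate. The data-driven
AIC/significance selection path runs in the same Monte Carlo and is
summarised as per-term selection frequencies; averaging a term's estimate
only over replicates where selection retained it would measure
winner's-curse conditioning (selection keeps a term exactly when its
estimate is large relative to its SE, inflating the conditional mean by an
amount comparable to one standard error for moderately powered terms)
rather than estimation bias, so it is deliberately not the reported
recovery quantity.

### Problem sizes

Defaults were chosen to keep the full suite comfortably interactive:
recovery uses 500 replicates of n = 208 with m = 20 and 10 MICE cycles
(the Monte-Carlo SE of a mean coefficient is then ~1.5 mL/day for
education and ~13 mL/day for bottle use); conservation and
marginal-matching checks use 10⁴-respondent cohorts; the type-I-error
calibration uses 1000 null replicates at n = 50.

## Known limitations

* The excretion/sweat mL tables are package defaults, not instrument
  constants; absolute balance levels shift under other defensible tables
  (the planted-effect recovery does not, since effects ride on top).
* Backward AIC on the first completion ignores between-imputation
  selection uncertainty; stability across completions is not assessed.
* The logistic imputation draw uses the asymptotic normal posterior, which
  can be poor for rare categories at small n.
* `ipaq_walking_min` can be non-integral for loss-augmented synthetic
  respondents; real questionnaire exports would carry integers.
* The Wilcoxon and chi-square choices follow common defaults
  (tie-corrected normal approximation; Yates correction only at 2×2); exact
  small-sample tests are not implemented.
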