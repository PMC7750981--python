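# Methods

## The estimation problem

The pipeline estimates the causal effect of a continuous exposure
(motivating case: BMI) on continuous and binary outcomes (deprivation
index, income, cohabitation, ...) when the observational association is
contaminated by confounding and reverse causation. Genetic variants
associated with the exposure serve as instrumental variables: alleles are
randomized at conception, so a weighted allele score is (under the IV
assumptions) independent of the confounders that distort the
observational regression.

Every analysis operates on an SD-scale exposure and (for continuous
outcomes) an SD-scale outcome produced by rank-based inverse-normal
transformation, so effects are "SD of outcome per SD of exposure" and are
converted back to natural units by multiplying by the raw variable's SD.

## The synthetic data-generating process

The generator exists so each estimator can be validated by parameter
recovery; its defaults encode the cohort structure the estimators assume.

* **Variant panel.** `n_variants` (default 73) independent biallelic
  variants, frequencies uniform on (0.05, 0.95), in Hardy–Weinberg
  proportions. Positive per-allele weights are drawn half-normal and
  rescaled analytically so the HWE score variance Σ 2pᵢ(1−pᵢ)βᵢ² equals
  `target_r2` (default 0.017, i.e. the score explains 1.7% of a
  unit-variance exposure — a realistic polygenic-score strength for an
  anthropometric trait panel of this size).
* **Exposure.** Latent SD scale: x = (score − E[score]) + a·U + ε, with
  U ~ N(0,1) a single individual-level confounder, a =
  `confounder_effect_on_exposure` (default 0.3) and var(ε) chosen so
  var(x) = 1 analytically. Reported in natural units as mean 27.4,
  SD 4.8 (BMI-like).
* **Outcomes.** A linear predictor f(x) + b·U (+ family terms, below)
  drives both a continuous outcome (plus N(0,1) noise; natural units
  mean −1.48, SD 2.99, deprivation-index-like) and a binary outcome
  through a logit link with intercept `binary_baseline_logodds`
  (default 1.0 ⇒ ≈73% prevalence). Causal shapes: `linear` (slope·x),
  `quadratic` (a·(x−c)², the U-shape), `piecewise` (hinge), each
  optionally with separate male/female parameters. The default
  confounder effects (0.3, 0.3) inflate a true slope of 0.1 to a naive
  slope of ≈ 0.19 — a visible observational-vs-MR discordance.
* **Sibships.** Two parents per family drawn in HWE; each sibling
  receives one allele per variant from each parent independently
  (sib–sib score correlation 0.5 under random mating). Assortative
  mating couples the two parental scores by a Gaussian-copula rank
  coupling at correlation ρ; a dynastic effect adds δ × the standardized
  mid-parental score to every offspring outcome. Both violate the IV
  independence assumption in population samples but are family-constant,
  so within-family centring removes them. `confounder_family_share`
  splits the confounder into family-shared and individual parts
  (default 0: purely individual) for testing the non-genetic sibling
  design against shared-environment confounding.

What the generator does **not** emulate: linkage disequilibrium,
population stratification, genotyping error, X-chromosome dosages,
selection/collider bias, age structure in the effects, real covariate–
outcome associations (age, sex, centre and PCs are inert noise columns by
default). Passing recovery tests therefore demonstrates the estimators'
correctness under the stated model, not robustness to those further
features of real cohort data.

## Estimators and numerical choices

* **2SLS (continuous outcomes).** Point estimate
  (X̂ᵀX̂)⁻¹X̂ᵀy with X̂ the projection of [exposure | covariates] onto
  [score | covariates]; the variance uses residuals y − Xβ̂ computed
  with the *observed* exposure (not the fitted values) — the correct
  2SLS variance — sandwiched as HC1 by default, or clustered. Estimates
  are invariant to linear rescaling of the instrument, so weighted and
  rescaled scores give identical results (asserted in tests).
* **2SPS (binary outcomes).** Logistic regression of the outcome on the
  first-stage fitted exposure plus covariates, sandwich (HC1 or
  cluster) SEs, exactly the plug-in two-stage form; log-OR per SD
  exposure. A control-function variant is deliberately not offered.
* **First stage** is fit on the same covariate set as the second stage.
  A partial F below 10 raises a warning, never an error — weak
  instruments are reported, not censored.
* **Confidence intervals** are Wald with 1.96; p-values two-sided
  normal. Records enforce se > 0 and p ∈ (0, 1].
* **Sex differences**: z = (β_m − β_f)/√(SE_m² + SE_f²), valid only for
  two estimates on the same scale (enforced).
* **Two-sample estimators.** IVW: zero-intercept WLS, weights 1/se_gy²,
  fixed-effect SE (multiplicative random-effects inflation behind a
  flag). MR-Egger: free-intercept WLS, multiplicative random-effects
  scale max(1, √(RSS_w/(m−2))) on both SEs. Weighted median:
  inverse-delta-variance weighted median of Wald ratios, SE from a
  seeded 1000-draw parametric bootstrap. Summary statistics are
  harmonized so every variant-exposure effect is non-negative; variants
  with beta_gx = 0 are dropped from ratio-based estimators with a
  warning. In-sample extraction residualizes exposure, outcome and
  dosages on the covariates once and computes all per-variant slopes in
  one vectorized pass; the sample-overlap caveat of in-sample summary
  statistics is acknowledged, not corrected.
* **Non-linear MR.** Stratification is on residuals of exposure on
  score + covariates ("IV-free" exposure) — the residual-based design,
  not the later doubly-ranked one. Equal-count strata are cut on a
  stable sort, so ties break by input order and counts differ by at
  most 1. LACE_k divides the stratum-specific score→outcome coefficient
  by the *full-sample* first-stage coefficient (homogeneous-instrument
  assumption); its delta-method SE propagates the estimated
  denominator. With k = 1 the estimator reduces exactly (to 1e-8) to
  linear 2SLS. The piecewise curve integrates LACE slopes across
  stratum widths on the analysis-exposure scale, anchored to 0 at the
  reference knot (default: lowest); stratum boundaries are additionally
  labelled with observed natural-unit exposure quantiles. The
  "quadratic" non-linearity p is the zero-slope test of an
  inverse-variance-weighted meta-regression of LACE on mean stratum
  exposure (a trend-test reading; implemented and labelled as such);
  Cochran's Q tests LACE heterogeneity against χ²(K−1).
* **Within-sibling models.** The between-family component enters as the
  family-mean covariate rather than per-family fixed effects —
  identical within coefficients for balanced sibships at a fraction of
  the cost; on two-sib families the MR point estimate equals the
  sib-pair difference estimator to 1e-8 (asserted). SEs are
  cluster-robust by family. Covariates (age, sex) enter uncentred:
  they vary within family and are not the confounders being purged.
  Sex-stratified sibling analyses restrict membership to one sex
  *before* applying the ≥2-sibs filter.

## Tunable parameters that matter

| parameter | default | units / meaning |
|---|---|---|
| `target_r2` | 0.017 | fraction of exposure variance explained by the score |
| `confounder_effect_on_exposure/outcome` | 0.3 / 0.3 | SD units per SD of U |
| `dynastic_effect` | 0 | outcome SD per SD of mid-parental score |
| `assortative_mating_corr` | 0 | correlation of parental scores, [0, 1) |
| `confounder_family_share` | 0 | family-shared fraction of confounder variance |
| `causal_shape` / `causal_params` | linear, slope 0.1 | see above; per-sex dicts allowed |
| `binary_baseline_logodds` | 1.0 | logit intercept of the binary outcome |
| non-linear `k` | 10 | strata (deciles chosen a priori) |
| weak-instrument floor | F = 10 | warning threshold, never fatal |

## Validation design and problem sizes

Recovery suites run at sizes chosen to make the targeted property
decisively measurable while keeping the default test run fast: 2SLS
recovery and coverage over 200 replicates of n = 50 000; Egger-intercept
recovery over 500 replicates of 73-variant summary sets; U-shape sign
recovery over 200 replicates of n = 20 000 (quadratic coefficient 0.15);
non-linearity-test calibration over 1000 replicates of n = 5000 (decile
strata of 500 — the smallest size at which stratum fits are routinely
stable); within-sibling recovery over 200 replicates of 10 000 two-sib
families with dynastic effect 0.1 and assortative-mating correlation
0.4; sex-difference calibration over 2000 replicates. The acceptance
script uses the same scenarios at somewhat smaller replicate counts and
reports means, rates and coverages as computed.

## Known limitations

* Ordinal outcomes, multivariable MR, MR-PRESSO/mode-based estimators,
  Steiger filtering and parental-genotype imputation are out of scope.
* MR-Egger is estimated on observed variant-exposure effects; with
  weights near the noise floor it would inherit regression-dilution
  bias (the simulated panels keep effects at genome-wide-significant
  magnitude, as a selected panel's are).
* The bootstrap SE of the weighted median treats summary statistics as
  independent normals; in-sample summary statistics mildly violate
  this.
* p-values are reported unadjusted for multiple testing throughout.
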