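# mrsuite

A tested, reusable implementation of a one-sample Mendelian-randomization
(MR) analysis pipeline for estimating causal effects of a continuous
exposure (the motivating case: body mass index) on social and
socio-economic outcomes, together with the sensitivity analyses such a
study requires and a synthetic cohort generator with known causal ground
truth so that every estimator can be validated by parameter recovery.

It is written for epidemiologists and biostatisticians who want the whole
chain — genetic risk score construction, phenotype transformation, IV
estimation, pleiotropy diagnostics, non-linearity assessment and
family-based designs — as composable library functions plus a thin CLI,
rather than as a one-off analysis script.

## What it implements

**Genetic risk score (GRS).** For variants i = 1..n with per-allele
weights β_i and effect-allele dosages SNP_i ∈ [0, 2]:

    weighted score = β₁·SNP₁ + β₂·SNP₂ + ⋯ + βₙ·SNPₙ
    rescaled score = weighted score × n / Σᵢ βᵢ        (allele-count scale)

with allele alignment (dosage flipping for swapped effect/other alleles,
rejection of strand-ambiguous A/T and C/G mismatches), pleiotropic-variant
exclusion by id, and first-stage strength reporting (incremental R², partial F).

**Phenotype transformation.** Rank-based inverse-normal transform
Φ⁻¹((r − 3/8)/(n + ¼)) (Blom offset, average ranks for ties), and
conversion of SD-scale effects back to natural units by multiplying by
the raw variable's SD — e.g. 0.05 SD × 2.99 deprivation-index units/SD
= 0.150 units.

**One-sample MR.** Two-stage least squares for continuous outcomes with
the correct 2SLS variance (residuals from the *observed* exposure,
HC1-robust); the two-stage plug-in ("2SPS") logistic estimator for binary
outcomes with sandwich SEs; sex-difference testing via
z = (β_m − β_f)/√(SE_m² + SE_f²); subgroup orchestration (sex, age bands,
arbitrary filters).

**Two-sample sensitivity estimators** on per-variant summary statistics:
inverse-variance weighted (IVW), MR-Egger with its directional-pleiotropy
intercept test, and the weighted median, plus in-sample summary-statistic
extraction and a generative model for validating them.

**Non-linear MR.** Stratification on the IV-free exposure (residuals of
exposure on the score), localized average causal effects (LACE) per
decile with delta-method SEs, a continuous piecewise-linear
exposure–outcome curve, and two non-linearity tests (meta-regression
trend "quadratic" p and Cochran's Q).

**Within-sibling analyses.** Family centring of the exposure
(non-genetic) or the GRS (MR) with the family mean as covariate and
cluster-robust SEs — robust to dynastic effects and assortative mating,
the family-level violations of the IV independence assumption.

**Synthetic cohorts.** Independent biallelic variants in Hardy–Weinberg
proportions whose weighted score explains a configurable fraction
(default 1.7%) of exposure variance; individual- or family-level
confounding; sibships by Mendelian transmission from simulated parents;
dynastic effects (mid-parental score → offspring outcome) and assortative
mating (rank-coupled parental scores); linear, U-shaped and sex-specific
causal shapes; logit-linked binary outcomes. Same config + seed ⇒
bit-identical tables.

## Worked example

```python
import mrsuite as M

cfg = M.SimConfig(n_individuals=20_000, seed=42)   # true causal effect 0.1 SD/SD
weights = M.simulate_variant_panel(cfg)
genotypes, cohort = M.simulate_unrelated(cfg, weights)

plan = M.AnalysisPlan(methods=["observational", "tsls"])
results, manifest, records = M.run_plan(plan, cohort, genotypes, weights)
print(M.report_natural_units(results, records))
```

which prints (whole-sample rows):

```
    outcome             method subgroup    beta     se      p     n  beta_natural
    cohabit      observational      all  0.1910 0.0161 0.0000 20000           NaN
    cohabit two_stage_logistic      all -0.0344 0.1228 0.7793 20000           NaN
deprivation      observational      all  0.1851 0.0069 0.0000 20000        0.5905
deprivation               tsls      all  0.2471 0.0543 0.0000 20000        0.7880
```

Reading it: the generator's true causal effect is 0.1 SD of outcome per
SD of exposure, and its confounder inflates the naive observational
slope to ≈ 0.19 — which is exactly what the `observational` row shows.
The `tsls` row is the MR estimate: 0.247 ± 0.054, within two SEs of the
truth, because the genetic score is unconfounded. For the binary outcome
the true log-OR is 0 by default and the 2SPS estimate is null (p = 0.78)
even though the confounded logistic regression (0.19, p ≈ 10⁻³²) is not.
`beta_natural` converts SD effects to the outcome's natural units via
its sample SD (3.19 here). On this cohort the score explains 1.66% of
exposure variance (first-stage F ≈ 339).

The same analyses are available from a shell:

```sh
mrsuite simulate --out-dir sim --seed 42
mrsuite grs --weights sim/weights.tsv --dosages sim/genotypes.tsv --out scores.csv
mrsuite mr   --cohort sim/cohort.csv --scores scores.csv \
             --outcomes deprivation:linear,cohabit:logistic \
             --transform deprivation --by sex --out results.csv
mrsuite nlmr --cohort sim/cohort.csv --scores scores.csv \
             --outcomes deprivation:linear --k 10 --out-dir nlmr
```

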