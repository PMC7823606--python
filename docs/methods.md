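# Methods

## Estimand and model

The analysis targets the conditional causal log odds ratio β of a binary
outcome (diabetic retinopathy, DR) per 1-SD increase in a continuous
exposure (natural-log plasma adiponectin, APN). Genetic variants G₁…Gₘ
(additive effect-allele dosages) serve as instruments under the usual IV
assumptions: each instrument is associated with the exposure, independent
of exposure–outcome confounders, and affects the outcome only through the
exposure. This is a **one-sample** design: both association legs are
estimated on the same subjects, so weak instruments bias estimates toward
the confounded observational association rather than toward the null.

The exposure is standardized as apn_z = (ln APN − mean)/SD with the
sample-SD (n−1) denominator; this convention is used for every
standardization in the package (scores, simulated exposures).

### Estimators

- **Wald ratio** per instrument: β̂ⱼ = β̂ⱼʸ/β̂ⱼˣ (outcome over exposure).
  One source convention prints this formula inverted
  (exposure over outcome); that orientation does not carry
  log-OR-per-SD units and is not what any published MR pipeline computes,
  so the standard orientation is implemented. First-order delta SE
  se(β̂ʸ)/|β̂ˣ| by default; the second-order form (adding
  β̂ʸ²se(β̂ˣ)²/β̂ˣ⁴) is available by flag and is validated against a
  Monte-Carlo oracle in the tests.
- **IVW**: fixed-effect inverse-variance average of the ratios; a
  multiplicative random-effects option inflates the SE by
  max(1, √(Q/(k−1))). Fixed-effect is the default because the emulated
  study reports single intervals with no heterogeneity statistic.
- **Score-based two-stage**: a weighted allele score (GRS) is a single
  composite instrument; β̂ = (log-OR per SD score)/(SD exposure per SD
  score), first-order delta SE, optionally including exposure-leg
  variance.
- **MR-Egger**: weighted regression (weights 1/se(β̂ʸ)²) of β̂ʸ on β̂ˣ
  with a free intercept after orienting every instrument to a positive
  exposure effect (both legs' signs flip together, so the fit is invariant
  to allele coding). The intercept estimates average directional
  pleiotropy. Inference uses a multiplicative overdispersion scale
  max(1, √(wRSS/(k−2))) and t(k−2) p-values — the convention of the
  estimator's authors. With the intercept forced to zero the slope is
  algebraically the IVW estimate (tested to 1e-9).
- **Weighted median**: ratios ordered ascending, each placed at
  standardized cumulative weight (Σ₍ⱼ≤ᵢ₎wⱼ − wᵢ/2)/Σw, linear
  interpolation at 0.5. The SE is a parametric bootstrap (default 1000
  replicates, seed required; both legs resampled from their fitted
  normals, ratios and weights recomputed per replicate).

All interval/p/OR arithmetic lives in one container (`MrEstimate`):
95% CI = β̂ ± 1.959964·se, 90% CI = β̂ ± 1.644854·se, two-sided normal p
(t-based for Egger), OR = exp(β̂). No multiple-testing correction is
applied anywhere, matching the emulated analysis; the confounder scan
reports raw per-trait p-values.

### Instrument processing

- **Variant QC**: exclude MAF < 0.5% or (INFO present and < 0.4).
  Exclusion is strictly below threshold — a variant exactly at the cut is
  kept — and a variant failing both filters is counted once, as a MAF
  failure. Variants without an INFO score are treated as directly
  genotyped and pass the INFO test.
- **Harmonization**: external weights whose effect allele matches the
  genotype's other allele flip the dosage (2−d, logged); weights matching
  neither allele drop the SNP with a warning. Strand-ambiguous palindromes
  are not specially handled (see limitations).
- **LD pruning**: greedy on dosage correlations (composite LD; no
  haplotypes or external reference panel). Variants ranked by exposure
  variance explained, descending, snp_id ascending on ties; a variant is
  kept iff r² with every kept variant is strictly < 0.05. On small
  fixtures this matches exhaustive search over independent sets.
- **Score selection rules**: `all` (every pruned SNP), `gwas_significant`
  (source p < 5×10⁻⁸), `internally_significant` (in-sample exposure
  p < 0.05). Scores are weighted by the external per-allele effects by
  default; unweighted and in-sample-weighted modes exist, the latter with
  an explicit overfitting caveat (weights estimated and applied on the
  same subjects exaggerate the score–exposure association).
- **Strength**: F = (β̂ˣ/se)², R² = F/(F+n−2), strong ⇔ F > 10 strictly
  (F = 10 classifies weak).

### Association legs

Exposure: OLS of apn_z on dosage, unadjusted by default (`base`), with an
`adjusted` mode adding covariates; p from t(n−k−1). Outcome: unadjusted
logistic regression of DR on dosage by Newton/IRLS, converged when the
score norm < 1e-8 (max 50 iterations); a coefficient escaping |β| > 20
during iteration is treated as quasi-complete separation and the estimate
marked absent with a reason rather than failing the run. Wald SE and
two-sided normal p. The solver is cross-checked against statsmodels on
small instances to 1e-6; monomorphic variants are marked absent.

### Power

power = Φ(√(n·R²ₓᵤ·cf·(1−cf))·|ln OR| − z₁₋ₐ⁄₂), the standard asymptotic
approximation for a binary outcome with case fraction cf and instrument
R²ₓᵤ. At n = 1251, R²ₓᵤ = 0.052, OR = 1.84, cf = 0.35 it returns 65%.
Published power conventions differ (some give ~75% for these inputs); the
formula implemented here slightly **overstates** realized power because of
the attenuation described below — the full-pipeline empirical rejection
rate at these parameters is ~59–60%, and the tests assert agreement
within 0.10 rather than a tighter band for that reason.

## The synthetic cohort generator

Structure realized (everything downstream assumes exactly this):

    ln-APN* = Σⱼ aⱼ(Gⱼ − 2pⱼ) + γU + ε,         var(ln-APN*) = 1
    DR      ~ Bernoulli(logit⁻¹(α₀ + β_c·apn_z + δU + Σⱼ dⱼGⱼ))

- Genotypes: effect-allele frequencies uniform on a range (or pinned);
  two latent standard-normal haplotype draws per subject thresholded at
  the Hardy–Weinberg quantile, equicorrelated within LD blocks (Gaussian
  copula, ρ ∈ [0, 1); negative equicorrelation is not positive-definite
  for general block sizes and is not supported). This preserves HWE
  marginally and gives direct control of pairwise LD.
- ε is sized against the *realized* sample variance of the systematic
  part, so the latent log-exposure has unit variance up to Monte-Carlo
  error; a systematic variance ≥ 1 is an infeasible-configuration error.
- α₀ is solved by bisection on [−20, 20] so the expected prevalence over
  the realized linear predictors hits the target within 1e-4.
- Covariates are mean + SD·(loading·U + noise); sex is Bernoulli with a
  probit shift by U. The `table1` preset uses the demographic means/SDs
  of a Taiwanese type-2-diabetes cohort (age 59.4 ± 11.8, BMI 26.5 ± 4.3,
  HbA1c 7.3 ± 1.4, …), 1251 subjects, 438/1251 ≈ 35% DR prevalence,
  47 SNPs with one strong instrument (1.9% of exposure variance, F ≈ 24)
  and 46 weak ones sharing 3.3%, confounder loadings γ = δ = 0.3, and a
  causal log-OR of 0.61. These are a plausible emulation of the target
  design, not a calibration to any dataset.
- Pleiotropy regimes (InSIDE holds; dⱼ ⊥ aⱼ): `none` (0, 0), `balanced`
  (0, 0.08), `directional` (0.30, 0.05) per-allele log-OR. The
  directional mean is deliberately large: with per-SNP F ≈ 4, the
  sign-orientation step flips instruments on their *observed* exposure
  signs, which drags the Egger intercept toward zero and inflates its
  variance, so a regime meant to be clearly detectable at n ≈ 1250 with
  16 weak instruments needs a mean direct effect about three times the
  per-allele outcome-association SE (~0.1). Measured detection rate:
  ~0.58–0.63 at 200–500 replicates; the `none` regime rejects at ~0.03
  (the t-based test is slightly conservative).

What the generator does **not** emulate: genotyping/imputation error
beyond an INFO annotation, missingness mechanisms (inputs may contain
missing genotypes, which are mean-imputed, but the generator emits
complete data), assortative mating or population stratification,
time-varying exposure, or selection into the cohort. Passing tests
therefore demonstrate correctness of the estimators under the stated
two-equation model, not robustness to those real-data pathologies.

## Operating characteristics and a known attenuation

With valid instruments the IVW and weighted-median estimators are
consistent for β_c *under a linear outcome*. With the logistic outcome
simulated here, each per-SNP log-OR is marginal over the residual
exposure variation, which attenuates every ratio by roughly
1/√(1 + c²β_c²σ²ᵣₑₛ) with c² ≈ 0.346 — about 8% at β_c = 0.61. The
replicated studies measure exactly this: mean IVW ≈ 0.576 at β_c = 0.61
(500 cohorts of n = 1251, 20 SNPs, 5% exposure variance), while 95% CI
coverage stays ~0.95 and the type-I error at β_c = 0 stays ~0.05 (the
null is collapsible). This attenuation is a property of ratio-based MR
with binary outcomes, not an implementation defect; one parameter-recovery
test asserting mean recovery of the conditional β_c within ±0.03 is left
failing deliberately to document it.

## Numerical conventions and degenerate inputs

- Sample-SD (ddof = 1) standardization everywhere.
- Dosages live in [0, 2]; values outside are input errors, not clipped.
- Missing genotypes are mean-imputed per SNP (2 × effect-allele
  frequency) with a logged count, keeping n constant across score
  variants; the emulated study does not state its missing-data handling,
  so this is a package choice.
- Monomorphic SNPs, separated logistic fits and empty post-QC panels are
  flagged-and-skipped conditions, not fatal errors; zero-variance
  exposure, single-class outcomes, unknown traits and zero exposure-leg
  coefficients are hard errors.
- Ratio estimates require β̂ˣ ≠ 0; Egger excludes exactly-zero exposure
  effects before orientation.
- All pipeline randomness (simulation, bootstrap) flows from one config
  seed; outputs are byte-identical across runs at a fixed seed.

## Limitations

- One-sample design: weak-instrument bias points toward the confounded
  association; no overlap-bias or winner's-curse correction is applied.
- No MR-PRESSO, mode-based, SIMEX-Egger or multivariable estimators.
- No strand-ambiguity (palindromic SNP) handling in harmonization beyond
  exact allele matching.
- LD pruning uses in-sample composite LD, not an external reference
  panel; multi-allelic variants are rejected rather than decomposed.
- The power formula is one published convention among several and, like
  all of them, targets the conditional OR (see attenuation above).
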