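# Methods

## Problem and approach

`frailmap` estimates how equitably vaccine doses were distributed relative
to population *frailty* across small administrative areas, in settings
where frailty is measured in a national survey but not in every area. The
pipeline is the standard small-area (synthetic) estimation chain:

1. **Frailty index.** Each survey respondent aged 50+ is scored on a
   deficit-accumulation index: the fraction of a fixed list of D health
   deficits they report. Scores are categorised with closed upper bounds as
   robust (score ≤ 0.24), pre-frail (0.24 < score ≤ 0.36) or frail
   (score > 0.36), the cut-points established in the frailty literature.
   The denominator is always the full schema size D: missing items are
   resolved by imputation, never by rescaling the denominator.
2. **Missing items.** Missing deficit cells are multiply imputed by
   chained equations (m completed tables). Binary items use
   ridge-regularised logistic models, graded items predictive-mean
   matching; predictors are the always-observed demographics (age band,
   sex, IMD quintile) plus all other deficit items. Each imputation refits
   every item model on a bootstrap resample of the observed rows (the
   bootstrap variant of "proper" imputation).
3. **Ordinal model.** A weighted proportional-odds regression of frailty
   category on indicator-coded age band (9 levels, reference 50-54), sex
   (reference male) and area deprivation quintile (reference quintile 1 =
   most deprived): P(Y ≤ k | x) = expit(θ_k − xᵀβ), so positive β means
   more frail. Weights are the survey's inverse-probability
   (design/non-response) weights. Estimation is damped Newton with
   analytic gradient and Hessian; convergence requires the infinity norm
   of the mean-log-likelihood gradient below 1e-8. The default covariance
   is the inverse observed information of the weighted likelihood; a
   sandwich covariance is available (`cov_type="sandwich"`) since the
   weighted likelihood is a pseudo-likelihood. The m fits are pooled by
   Rubin's rules: T = W̄ + (1 + 1/m)B.
4. **Post-stratification.** Predicted probabilities for all 90
   (age band × sex × quintile) strata are multiplied into each area's
   age–sex population cells and summed; population counts are treated as
   fixed constants. Area deprivation quintiles come from IMD ranks by
   quintile = ceiling(5·rank/n_areas), rank 1 = most deprived.
5. **Uncertainty.** A parametric bootstrap: B draws of (β, θ) from
   Normal(pooled point, T), rejecting draws with θ₁ ≥ θ₂ (and failing
   loudly if more than half are rejected), pushed through the probability
   and sum-product steps. 95% intervals are the 2.5/97.5 percentiles. The
   joint draws are retained so downstream ratio and extreme-factor
   intervals reuse the same draws.
6. **Equity ratios.** Doses per frail person (and per frail+pre-frail,
   per person over 50, per risk-factor diagnosis, and per total
   risk-factor diagnosis) for every area; the between-area spread is the
   extreme-ratio factor max/min, with its interval recomputed within each
   joint draw (the arg-max/arg-min areas free to vary by draw). Ratios on
   fixed denominators (official population or diagnosis counts) are
   reported as points without intervals. Display rounding is one decimal;
   full precision is kept internally.

Interactions between age and sex in the outcome model can be tested with
a likelihood-ratio statistic (`lrt_interaction`); under weighting this is
approximate (pseudo-likelihood) and flagged as such.

## Synthetic data generator

Because the real survey microdata and administrative extracts are
access-restricted, the package ships a generator whose defaults define the
study conditions and whose ground truth is known exactly.

**Deficit process.** Respondent i has propensity u_i ~ Normal(0, σ_u²) and
deficit probability π_i = expit(α + γ_age[a_i] + γ_sex·s_i + γ_imd[q_i] +
u_i); the D = 30 deficit items are iid Bernoulli(π_i) given u_i. This is
deliberately the simplest process producing a graded index with age, sex
and deprivation gradients; it is a stand-in, not an empirical model.

**Calibration of defaults.** α = −1.5, σ_u = 0.2, γ_age = (0…0.68
monotone), γ_sex = 0.06, γ_imd = (0.22…0 across quintiles) were chosen
once, by matching the exact (quadrature) category mix to prevalences
reported for English older adults — roughly 52% robust / 34% pre-frail /
14% frail overall, frail prevalence rising from ≈5% at 50-54 to ≈44% at
90+, and a deprivation gradient of ≈0.26 → 0.14 across quintiles. The
survey age distribution places ≈6.3% of respondents at 85+, matching the
source survey's marginal shape (8,355 respondents 50+, 530 aged 85+).

**Non-response and weights.** Response follows a logistic propensity with
fixed age and deprivation offsets (older and more deprived respondents
respond less); the intercept is solved by root-finding on the realised
sample so the expected non-response rate equals the 17.6% target. Supplied
weights are the truth-based inverse propensities rescaled to mean 1 —
mirroring surveys that ship weights with the data — so the pipeline uses
weights, it does not estimate them. Item missingness is MAR on age band
only (rates rising with age, marginally 5%), which makes
correctly-specified imputation unbiased and parameter-recovery tests
interpretable.

**Areas, doses, risk factors.** 135 areas receive IMD ranks as a uniform
random permutation; age–sex population cells are log-normal around a
realistic area size (≈160k people 50+) with a thinning age pyramid,
rounded half-to-even. First doses are allocated proportional to population
times a per-age-band uptake profile (near-complete above 70, partial in
the 50s) — frailty-blind by construction, emulating an age-based roll-out.
Seven risk factors (atrial fibrillation, chronic kidney disease, diabetes,
learning disabilities, obesity, current and former smoking) get
deprivation-graded diagnosis counts (strength set by `risk_depr_coef`).

**Two independent truths.** Exact stratum category probabilities are
computed by Gauss–Hermite quadrature (80 nodes) over the propensity
distribution combined with closed-form binomial tails
(`true_stratum_probs`), and independently by brute-force simulation
(`oracle_stratum_probs`); tests confirm the two agree within Monte-Carlo
error. Expected area counts under the generator follow by the same
sum-product as the pipeline (`true_area_counts`).

**What the generator does not emulate.** Real English geography and
spatial correlation; household clustering; within-area deprivation
heterogeneity (each area has a single quintile); longitudinal waves;
informative (MNAR) missingness; local vaccination behaviour beyond the
age-uptake profile. Passing tests therefore demonstrate the estimation
machinery is correct under the stated conditions, not that the pipeline
would be unbiased on real survey data.

## Numerical choices

- Cut-point comparisons use closed upper bounds exactly as stated, no
  epsilon; with D items the robust/pre-frail boundaries translate to
  deficit counts floor(0.24·D) and floor(0.36·D) (a 1e-9 guard covers
  decimal cut-points that are not exactly representable in binary).
- The Newton fitter starts from the null model (β = 0, thresholds at the
  weighted cumulative shares), halves the step until the likelihood
  improves, and falls back to L-BFGS-B if no damped step improves; fits
  failing the gradient tolerance raise rather than return silently.
- Indicator columns that are constant in the data (levels absent from a
  toy dataset) are dropped; predictions for dropped levels fall back to
  the reference level.
- Rubin pooling with m = 1 returns the single fit's covariance unchanged.
- The bootstrap covariance is symmetrised and its spectrum clipped at
  zero; an eigen-factor (not Cholesky-with-jitter) is used so a zero
  covariance yields exactly zero-width intervals.
- Quintile assignment sorts areas by advantage, breaks ties by area id,
  and makes group sizes as equal as possible with larger groups in
  lower-numbered (less advantaged) quintiles; quintile 5 = most advantaged.
- MICE defaults m = 10, n_iter = 10 follow conventional chained-equations
  practice; the ridge strength (C = 1) keeps separated sparse strata
  estimable. Test and example runs use smaller m/n_iter/B as stated
  problem sizes.

## Model misspecification and interval calibration

The generative truth is *not* exactly a proportional-odds model: category
probabilities per stratum are binomial tail functions of the linear
predictor integrated over a Gaussian propensity. The weighted MLE
therefore converges to the best proportional-odds approximation
(computable exactly by fitting to the quadrature truth,
`po_pseudo_true_probs`), which at the default conditions misses the exact
cell probabilities by up to ≈0.028 (worst in the narrow pre-frail band).
The recovery test treats strata where this best approximation misses the
truth by more than 0.02 as documented misspecification cells and verifies
±0.03 recovery everywhere else.

This has a knock-on consequence for interval calibration: the parametric
bootstrap quantifies *estimation* uncertainty around the model's own
estimand. The calibration study (200 replicate surveys of n = 20,000, 135
areas) measures ≈95% coverage of the proportional-odds estimand for area
frail counts — the machinery is calibrated — but ≈69% coverage of the
exact generative truth, because at that sample size the interval width has
shrunk below the fixed approximation bias. This is the expected behaviour
of a calibrated interval around a biased estimand, and it is reported
rather than hidden: the corresponding test asserts nominal-band coverage
of the generative truth and currently fails, with both coverage numbers in
its failure message. At the survey sizes the pipeline is meant for
(≈8,000 respondents), parameter uncertainty is the dominant term.

## Known limitations

- The deficit schema is configurable but the shipped default (30 binary
  items) is a synthetic stand-in; real analyses must supply their own item
  list and graded mappings.
- No survey-design (PSU/stratum) variance estimation; weights enter the
  likelihood only.
- No partial proportional-odds or continuation-ratio alternatives; the
  proportional-odds assumption is a modelling choice, checked only through
  the recovery diagnostics above.
- Areas are exchangeable in the generator; no spatial smoothing or
  shrinkage is applied in estimation.
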