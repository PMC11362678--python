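# Methods

## Estimand and model

The package targets counterfactual cumulative incidence under the four joint
assignments of a binary exposure measured at two waves: F(k; a₁, a₂) is the
probability of dying of the target cause by year k of follow-up had everyone
held exposure pattern (a₁, a₂).  Deaths from non-target causes censor at
their death year (cause-specific convention), so the estimand is the *net*
risk — the risk that would be seen were the competing cause eliminated.  The
synthetic-truth oracle computes exactly the same quantity (competing cause
disabled by default; a flag retains it for users who want the alternative
convention).

Identification uses the standard MSM assumptions: exchangeability given the
measured baseline covariates L₀ (wave 1) and time-varying covariates L₁
(wave 2, possibly affected by the wave-1 exposure), positivity, and
consistency; censoring is assumed ignorable given the same covariates and
exposure history.  Because L₁ is both a confounder of the wave-2 exposure
and a consequence of the wave-1 exposure, conditioning on it in an outcome
model would bias the wave-1 effect; inverse-probability weighting avoids
conditioning and is the reason for the g-method machinery.

## Pipeline

1. **Imputation** (`rf_impute`).  missForest: initialize missing cells with
   the column mean/mode, revisit variables in increasing-missingness order,
   regress each incomplete variable on all others (plus the complete
   exposures) with a random forest (100 trees, √p features), stop when the
   normalized change statistic rises for both the continuous and the
   categorical variable sets and return the previous sweep.  Exposures,
   follow-up and cause of death are never imputed — subjects missing those
   are excluded at read time.  Imputation runs once on the full table; the
   bootstrap resamples the completed table (re-imputing inside every
   replicate would multiply the cost ~500-fold for a second-order
   refinement of the CI).
2. **Exposure weights** (`fit_exposure_models`, `compute_exposure_weights`).
   Denominators: logistic A₁ ~ L₀ + region, A₂ ~ A₁ + L₀ + L₁ + region
   (region always as fixed-effect indicator columns, drop-first).
   Numerators: A₁ ~ 1 and A₂ ~ A₁.  sw = P_num/P_den at the exposure
   actually received.  Any denominator probability below the positivity
   floor (10⁻⁶) is a hard error, never a silent clip.
3. **Person-year expansion** (`expand_person_years`).  Years are indexed
   k = 1..K (14 one-year intervals); a subject followed T years contributes
   T rows, the last carrying the event indicator.  Censoring is placed at
   the end of the interval: the final row of a lost-to-follow-up subject is
   event-free and flags `uncensored = 0`.  This convention makes the
   saturated-time pooled logistic estimator *algebraically identical* to
   Kaplan–Meier, which is what the KM-agreement diagnostic checks.
4. **Censoring weights** (`fit_censoring_models`).  Pooled logistic models
   of remaining uncensored on (k, k², A₁, A₂) for the numerator plus
   L₀, L₁ and region for the denominator; sw_C(k) is the cumulative product
   of the per-year ratios.  The numerator conditions on exposure history
   and time, which preserves the MSM's conditioning set.  Deaths from
   competing causes are not treated as loss to follow-up.  With no
   censoring at all the models are flagged degenerate and sw_C ≡ 1.
5. **Truncation** (`truncate_weights`).  The exposure product sw_A1·sw_A2
   is capped at its empirical 99th percentile, sw_C per person-year at its
   own; upper tail only.  The percentile uses numpy's linear-interpolation
   convention, the same convention as the bootstrap CIs, so thresholds are
   reproducible.
6. **Hazard model** (`fit_pooled_logistic`).  Weighted ML logistic fit of
   the terminal event on k, k², three regime indicators against the
   (0,0) reference and regime × k products (a parsimonious switch drops
   the products, as used in stratified re-runs where event counts are
   small).  A sandwich covariance is attached for diagnostics; inference
   comes from the bootstrap.
7. **Curves and contrasts** (`build_regime_curves`, `compute_contrasts`).
   S and F by the exact hazard product — no exponential approximation.
   RD is reported in percentage points, RR against the (0,0) reference;
   horizons default to the midpoint (7) and end (14) of follow-up.
8. **Bootstrap** (`bootstrap_pipeline`).  Subjects (not person-years) are
   resampled with replacement, preserving within-subject dependence; all
   weight models and the hazard model are re-fit per replicate; pointwise
   CIs are the 2.5/97.5 percentiles.  Replicates that fail (separation,
   positivity) are skipped and counted; more than 5% failures aborts.
   Replicates whose reference risk is zero are excluded from the RR
   percentile vector with a count, rather than treated as infinite.
9. **E-values** (`compute_evalue`).  E = RR + √(RR(RR−1)) for RR ≥ 1,
   reciprocal transform first for protective RRs; the CI E-value uses the
   limit closer to the null and is 1 when the interval crosses 1.

## Numerical core

All weight and hazard models are plain logistic MLEs.  They are solved by a
small Newton/IRLS routine on numpy arrays (`_glm.py`) with step halving,
warm starts and explicit separation detection, because the bootstrap and the
coverage study re-fit the five pipeline models tens of thousands of times;
a regression test pins its coefficients to statsmodels' GLM on identical
designs to 10⁻⁶, and the sandwich covariance to statsmodels' HC0.
Kaplan–Meier curves come from lifelines; random forests from scikit-learn.

## Synthetic cohorts and the benchmark

`generate_cohort` draws, in causal order: region and baseline covariates L₀
(age ~ N(52, 8), BMI ~ N(23.3, 3.2), standardized diet scores, and binary
gender/smoking/alcohol/activity/employment/short-sleep/cancer/CVD history);
wave-1 exposure A₁ by a logistic model on L₀ and region; wave-2 covariates
L₁ from their wave-1 parents *and A₁* (the feedback arrow); wave-2 exposure
A₂ on A₁, L₀, L₁ and region; then a yearly loop with, in order, a
loss-to-follow-up draw, a competing-cause draw and a target-cause draw, all
Bernoulli on the expit scale — so the pooled logistic hazard model is exactly
correctly specified under this process.  Continuous covariates are
mean-centered inside the simulator's linear predictors so intercepts set
marginal rates directly; emitted columns are raw.

`true_counterfactual_risks` re-simulates with both exposures forced (L₁
still responds to the *forced* A₁), censoring off and the competing cause
off by default, returning the empirical F*(k) with its binomial Monte-Carlo
standard error — the oracle the pipeline is validated against.

Two configurations are shipped:

* `default_config` — study-like conditions: rare target cause (14-year risk
  ≈ 0.4%, ICD-10 X60–X84 codes), common competing cause (≈ 20%), light
  informative loss to follow-up (≈ 0.5%/year) and ~16% missingness on
  BMI/diet covariates (MCAR by default; MAR with a configurable driver and
  log-odds shift available).
* `benchmark_config` — the validation benchmark: one common cause of death
  (F(14) ≈ 0.19 under the reference regime), strong baseline confounding,
  strong exposure-confounder feedback (A₁ shifts wave-2 smoking by +0.9
  log-odds) and informative censoring.  The common outcome is deliberate:
  estimator-recovery, null-preservation and CI-coverage checks need enough
  events per cohort (and per bootstrap replicate) to be statistically
  meaningful; at the study-like suicide rate a coverage replicate would
  contain a handful of events and the checks would measure noise.  Under
  `null_effect=True` every causal path from exposure to death is removed —
  including the hazard coefficients of the wave-2 covariates that A₁ feeds
  into, since leaving those would retain a real indirect effect (the oracle
  puts it at RR ≈ 1.13) that a correct estimator must, and does, find.

What the generator does *not* emulate: real-world marginal distributions and
correlations of the covariates, secular trends in the outcome rate,
exposure changes between the two waves, or non-logistic hazard shapes.
Passing tests therefore demonstrate that the estimator chain is correct
under its own assumptions (correct model specification, ignorable censoring
given measured covariates), not that those assumptions hold in any given
real cohort.

## Validation design and problem sizes

* **Recovery**: one benchmark cohort of n = 50,000; the pipeline's F̂(14)
  per regime must sit within 3·√(sê² + mc_se²) of the oracle (sê from a
  40-replicate bootstrap, mc_se from the oracle at n_mc = 200,000).  Both
  the estimate and the oracle are Monte-Carlo quantities, so the comparison
  combines both standard errors.  The crude (unweighted, unadjusted)
  per-cell Kaplan–Meier risk must simultaneously miss the truth by more
  than that tolerance (the designed confounding is ≈ +5 points for the
  doubly-exposed regime).
* **Null preservation**: n = 50,000 under the null benchmark; all three
  regime RRs at 14 years must lie in [0.85, 1.15] while the crude RR for
  the doubly-exposed cell stays outside the band.
* **CI coverage**: 150 independent cohorts of n = 1,200 with B = 100
  bootstrap replicates each; the 95% percentile CI for RD(14) of the
  doubly-exposed regime must cover the oracle truth in 90–99% of runs.
  These sizes keep the suite's runtime modest while leaving the binomial
  uncertainty of the coverage estimate (≈ ±2 points) well inside the
  target band.
* Weight calibration (families average 1 to ±0.05 at n = 20,000), the
  KM/pooled-logistic identity (10⁻⁶ saturated, 0.02 smooth), the
  standardization identity (10⁻¹² against a brute-force product on random
  coefficient vectors) and the imputation-vs-mean NRMSE comparison round
  out the suite.

## Degenerate inputs and tie-breaks

No events in the person-year table, entirely missing columns, missing
exposure in an imputation run, malformed ICD-10 strings, horizons outside
1..K, hazard prediction outside the fitted year range, truncation
percentiles outside (50, 100], and row-count mismatches when combining
weights all raise immediately with named diagnostics.  Perfect separation
raises rather than returning a divergent fit.  Zero censoring yields
degenerate censoring models with unit weights rather than a fit attempt.

## Known limitations

Single imputation (no Rubin's-rules uncertainty propagation); percentile
(not BCa) bootstrap, which can undercover slightly at small n; smooth-time
MSM curves carry a small standardization bias relative to a saturated
regime × year model (visible only at n ≫ 10⁵, well inside the bootstrap
noise at practical sizes); no doubly-robust or machine-learning weight
estimation; no continuous-time (Cox) modelling; hazard ratios are
deliberately not reported — risks and risk differences over the whole
follow-up are the output.
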