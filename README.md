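# msmcurves

Causal survival analysis of a **two-wave time-varying binary exposure** on
discrete-time mortality, by inverse-probability-weighted pooled logistic
regression — the marginal structural model (MSM) workflow used in
epidemiology when a time-varying exposure (here: living alone, asked at two
survey waves five years apart) shares feedback with time-varying confounders,
so that ordinary covariate adjustment is biased and g-methods are required.

The package is for epidemiologists and biostatisticians who want the whole
workflow as tested, reusable code: stabilized inverse-probability weights for
exposure and censoring, the weighted pooled logistic discrete-time hazard
model, counterfactual cumulative-incidence curves under the four joint
exposure regimes, risk differences/ratios with percentile-bootstrap CIs,
E-value sensitivity analysis, random-forest (missForest) imputation of
missing covariates, and a synthetic-cohort generator with a
counterfactual-truth oracle for validating the whole chain.

## The model

Follow-up is divided into years k = 1..K (K = 14).  For exposure regime
(a₁, a₂) ∈ {0,1}² the discrete-time hazard is modelled as

    h(k; a₁, a₂) = expit(β₀ + β₁k + β₂k² + θ₀₁ r₀₁ + θ₁₀ r₁₀ + θ₁₁ r₁₁ + γ·(regime × k))

where r's are regime indicators against the doubly-unexposed reference.  The
model is fit by weighted maximum likelihood on the person-year expansion,
with per-person-year weights

    w(k) = trunc₉₉[sw_A1 · sw_A2] · trunc₉₉[sw_C(k)]

built from stabilized inverse-probability-of-exposure weights (wave 1: a
logistic model of A₁ on baseline covariates and region; wave 2: A₂ on A₁,
baseline and time-varying covariates and region, each stabilized by an
exposure-history-only numerator) and cumulative stabilized censoring weights
sw_C(k) = Π_{j≤k} P_num(uncensored)/P_den(uncensored), each truncated at its
99th percentile.  Counterfactual cumulative incidence is the exact product

    F(k; a₁, a₂) = 1 − Π_{j≤k} (1 − h(j; a₁, a₂)),

contrasted as RD and RR against the "with someone at both waves" reference at
the follow-up midpoint and end, with pointwise percentile bootstrap CIs from
subject-level resampling (weights re-estimated per replicate).  E-values
report the minimum confounder strength (RR scale) able to explain the
association away: E = RR + √(RR(RR−1)).

## Worked example

```python
import msmcurves as m

cohort = m.generate_cohort(m.benchmark_config(10_000, seed=42))
res = m.MSMPooledLogistic.from_dataframe(cohort, target_cause="all_cause").fit()
res.bootstrap(B=200, seed=42)
print(res.contrasts(horizons=(7, 14)).round(3))
print(res.evalues(horizon=14).round(2))
```

prints

```
     regime  horizon     rd  rd_ci_lower  rd_ci_upper    rr  rr_ci_lower  rr_ci_upper
 with-alone        7  4.017        1.838        6.288 1.442        1.197        1.712
 alone-with        7  3.448        0.909        5.898 1.380        1.097        1.658
alone-alone        7 16.147       14.203       18.366 2.778        2.533        3.032
 with-alone       14  7.693        4.656       10.527 1.419        1.253        1.579
 alone-with       14  8.622        4.578       11.585 1.469        1.245        1.656
alone-alone       14 25.399       22.803       28.265 2.383        2.188        2.565

     regime  horizon   rr  evalue_point  evalue_ci
 with-alone       14 1.42          2.19       1.82
 alone-with       14 1.47          2.30       1.80
alone-alone       14 2.38          4.20       3.80
```

`rd` is the risk difference at the horizon in percentage points against the
"with–with" reference; `rr` the corresponding risk ratio; the CI columns are
2.5th/97.5th percentiles over 200 bootstrap replicates.  Subjects who lived
alone at both waves have a 25.4-point higher 14-year risk (RR 2.38) in this
benchmark scenario, and an unmeasured confounder would need RR ≈ 4.2 with
both exposure and outcome to explain that away.  `res.summary()` adds the
hazard coefficients and the weight diagnostics (each untruncated stabilized
weight family should average ≈ 1, which the example does:
mean(sw_A1) = 0.999, mean(sw_A2) = 1.000, mean(sw_C) = 0.999).

A command line covers the same pipeline end to end:

```bash
msmcurves simulate --n 20000 --seed 1 --out cohort.csv
msmcurves impute cohort.csv imputed.csv
msmcurves run --config analysis.yaml --input imputed.csv
msmcurves evalue 4.00 1.83 7.41
```

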