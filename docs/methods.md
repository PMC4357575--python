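# Methods

This note records the statistical model implemented by `frailtycompare`,
the default parameters and the reasoning behind them, what the synthetic
cohort generator does and does not emulate, and the numerical conventions
that affect results.

## 1. Instruments

### Frailty index (FI)

The FI is the proportion of accumulated deficits over a fixed 34-item
panel: 6 symptoms/signs, 15 comorbidities, 12 activities of daily living
(ADL), 1 healthcare-utilisation item. Each item response is coded into
[0, 1]; binary items map no/yes → 0/1, three-level items → 0/0.5/1, and
five-level frequency items → 0/0.25/0.5/0.75/1. FI = Σ coded values / 34.
The denominator is always 34 — the package refuses vectors of any other
length rather than renormalising, because a variable denominator changes
the estimand. The shipped codebook (`data/codebook.yaml`) is a structural
stand-in with the standard domain split; users supply their own item
wording via `load_codebook`.

### Phenotypic frailty (PF)

A questionnaire adaptation of the physical-frailty phenotype for cohorts
without performance measures. Components:

* **slowness & weakness**: mean of the 10 SF-36 physical-functioning items,
  each 0 ("limited a lot") / 50 ("limited a little") / 100 ("not limited");
* **endurance & exhaustion**: mean of the 4 SF-36 vitality items on
  0/25/50/75/100; positively worded items ("full of life", "energy") are
  reverse-coded; "some of the time" takes the midpoint 50, interpolating
  between the printed 25 and 75 anchors;
* **physical activity**: days in the past 30 with a ≥ 20-minute walk;
* **weight loss**: lost ≥ 10 lb in the past year (binary).

Scoring: lowest quartile of slowness & weakness = 2 points (the phenotype's
slowness and weakness criteria are collapsed into one scale, so it carries
double weight); lowest quartile of exhaustion and of activity, and reported
weight loss, 1 point each. Quartile cuts are the empirical 25th percentiles
(NumPy default linear interpolation, R type 7) and the boundary is
inclusive (≤ cut scores), so ties at the cut are treated consistently.
Total 0 → robust, 1–2 → pre-frail, 3–5 → frail. A component is the mean of
answered items when at least half are answered, otherwise missing and
deferred to the missing-data policy.

## 2. Common-footing strategies

1. **Per-one-fifth increments.** The FI increment is (max − min)/5 of the
   observed FI; it is rounded to 2 dp for reporting and the strategy-1
   cutpoints are successive multiples of the rounded value, so the printed
   cutpoints are exact multiples. Bins are right-closed, (c_{k−1}, c_k],
   with level 0 reserved for FI exactly 0 (no deficits) and level 5 open
   above c₄. Both instruments then have six ordered levels.
2. **Density-overlap trichotomisation.** Gaussian KDEs (Silverman
   bandwidth, 512-point grid on [0, 1]) of the FI within each PF category;
   the cutpoint between adjacent categories is the density crossing, found
   by linear interpolation of sign changes and restricted to the interval
   between the two group means (the crossing nearest the midpoint of the
   means wins when several exist). If no crossing exists in that interval,
   the midpoint of the group means is used with a warning. Each group needs
   ≥ 10 members. FI groups are left-closed: robust < cut1 ≤ pre-frail
   < cut2 ≤ frail.
3. **Predicted-probability grouping.** A multivariable logistic model of
   falls in follow-up year 3 on the FI (adjusted for age, smoking, drinking,
   BMI, education, baseline falls) yields in-sample predicted probabilities,
   cut at 0.27 and 0.50 (low < 0.27 ≤ medium < 0.50 ≤ high). The defaults
   follow published annual fall-risk anchors: ~27% of older adults fall in a
   year, and the risk reaches ~50% after a prior fall or gait/balance
   abnormality.

## 3. Outcome models

* **Falls (year 3 of follow-up)** and **death**: maximum-likelihood
  logistic regression (statsmodels, tolerance 1e-8). Adjustment sets —
  age only, or multivariable: age, smoking, drinking, BMI, education, plus
  baseline falls for the falls outcome.
* **Fractures**: Cox proportional hazards on time to first incident
  fracture (lifelines, Efron tie handling), 3-year administrative
  censoring, death treated as censoring. The multivariable set swaps
  baseline falls for prior fracture and family history of fracture.
* Effects are reported per increment: exp(β·Δ) with Wald CI
  exp((β ± 1.96·SE)·Δ), Δ = 1 PF point or one (rounded) FI increment for
  strategy 1, and indicator contrasts against the first (reference) group
  for strategies 2–3.
* Non-convergence or separation raises an error suggesting a ridge fallback
  rather than returning silently unstable estimates.
* Proportional hazards are checked with the Grambsch–Therneau score test on
  Schoenfeld residuals using the rank-of-event-time transform:
  with per-event residual matrix S (d × p), centred time ranks g,
  u = gᵀS and V the parameter covariance, χ²_j = d·(Vu)_j² / (V_jj·Σg²)
  per covariate and χ²_global = d·uᵀVu / Σg². This matches
  `lifelines.statistics.proportional_hazard_test(..., time_transform="rank")`
  to machine precision (the test suite pins this).

## 4. Discrimination, calibration, agreement (from scratch)

These statistics are the comparison primitive, so they are implemented
independently; scikit-learn/lifelines/scipy serve only as test oracles.

* **AUC**: Mann–Whitney rank statistic, ties counted ½. Variance by
  DeLong's structural components: placement values V10 (per case) and V01
  (per control), var = S10/m + S01/n with sample variances (ddof 1).
* **Paired DeLong test**: both predictors share the same labels; the
  covariance of the two AUCs comes from the paired placement values and
  the contrast z = (AUC_a − AUC_b)/√(var_a + var_b − 2cov). A non-positive
  variance of the difference (identical predictors) reports z = 0, p = 1.
* **Harrell's c**: pairs are usable when the earlier time is an event, or
  the times tie with exactly one event (the censored subject is known to
  outlive the case). Concordant if the higher risk score has the shorter
  event time; score ties count ½. Equals the AUC when censoring is absent.
* **c-index contrast**: paired bootstrap over participants (default 1000
  resamples, seeded); the observed difference is referred to the bootstrap
  SE with a normal reference; percentile CIs accompany each c-index.
  All-censored resamples are skipped.
* **Hosmer–Lemeshow**: groups from quantiles of predicted probability
  (default 10), statistic Σ(O − E)²/(E(1 − E/n_g)), df = groups − 2.
  Degenerate groups (zero binomial variance) merge into their neighbour
  with a warning.
* **Spearman**: Pearson correlation of mid-ranks (standard tie
  correction), CI via Fisher transform with SE 1/√(n − 3), p from the
  t-distribution with n − 2 df.

## 5. Cohort schema and missing data

Cohorts are CSV tables validated against a YAML column manifest (ids,
ranges, level sets, fracture time/event cross-checks). Missing cells are
empty strings. The missing-data policy fills covariates and instrument
items before scoring: variables missing in < 10% of rows take the
within-group median (numeric) or mode (categorical); at ≥ 10% each missing
cell takes a single seeded draw from the variable's observed within-group
empirical distribution. This is a deliberately simple stand-in for full
multiple imputation — adequate because no downstream inference pools
across imputations — and every filled cell is logged. Outcomes are never
imputed; rows with missing outcomes are excluded from the relevant model.

## 6. Synthetic cohort generator

The generator emulates a cohort of community-dwelling women aged ≥ 55
recruited in two age strata (one third 55–64, mean 60, SD 2.8; two thirds
≥ 65, mean 73.8, SD 6.6; truncated normals). A single latent frailty trait
Z = 0.55·(age − 70)/10 + N(0, 1) drives everything:

* **items**: each deficit/instrument item is an ordered-probit-style draw —
  latent = loading·Z + N(0, 1) cut at fixed thresholds. Domain loadings
  (symptoms 0.70, comorbidities 0.50, ADL 0.75, hospitalisation 0.80,
  SF-36 0.62, vitality 0.56, walking 0.56) and the per-item thresholds were
  calibrated once so the default cohort reproduces the target FI
  distribution (mean ≈ 0.24, SD ≈ 0.13), a ~44/31/24 robust/pre-frail/frail
  split and PF–FI Spearman agreement ≈ 0.5–0.65 across strategies; they are
  frozen defaults, not fitted per run.
* **outcomes** are drawn from the *realised* FI — not from Z — so the
  downstream outcome models are correctly specified and parameter recovery
  is well posed. Falls and death are logistic in FI/0.144 (true OR 1.4 and
  1.8 per 0.144 of FI) plus small covariate effects; fracture times are
  exponential given covariates (true HR 1.25 per 0.144 of FI), which makes
  proportional hazards hold exactly, censored at min(3 years, death time).
  Intercepts are calibrated by bisection so expected marginal rates hit
  0.32 / 0.064 / 0.027.
* one `numpy.random.default_rng(seed)` supplies all randomness, so cohorts
  are bitwise reproducible; `generate` returns the table plus a
  `TruthRecord` (latent traits, per-subject event probabilities,
  calibrated intercepts, full config).

**What it does not emulate**: item-level wording of any real instrument;
informative missingness (the `make_missing` helper masks completely at
random); competing-risks structure beyond censoring fractures at death;
multimorbidity correlation beyond the single factor; secular or seasonal
effects; recruitment by site. The single-factor design implies
exchangeable residual correlation among items, which is simpler than real
deficit co-occurrence; it was chosen as the simplest mechanism producing
the target marginal structure and inter-instrument agreement with a small,
auditable parameter set.

## 7. Numerical choices

* Quartiles and the strategy-2 KDE grid use fixed conventions (type-7
  percentiles; 512 grid points on [0, 1]) so results are reproducible
  across platforms.
* Strategy-1 boundaries are right-closed; strategy-2/3 boundaries are
  left-closed; the PF quartile boundary is inclusive. Each convention is
  asserted by boundary tests.
* Logistic fits use tolerance 1e-8, max 200 iterations; convergence
  warnings are escalated to errors.
* Cox fits use Efron's tie correction; AIC for Cox models is the partial
  AIC, 2k − 2·log PL.
* Bootstrap contrasts default to 1000 resamples — enough for a stable SE
  of a c-index difference at cohort sizes in the thousands; reduce
  `RunConfig.n_boot` for quick exploration.
* Default problem sizes (n = 4000 cohort) run the full pipeline in ~10 s
  on one CPU.

## 8. Limitations

* The shipped codebook and schema are structural stand-ins; scientific use
  requires mapping a real instrument's items and wording onto them.
* The missing-data policy is single imputation; standard errors downstream
  do not reflect imputation uncertainty.
* Strategy 3 uses in-sample predicted probabilities, as in the original
  design; its discrimination statistics are therefore optimistic relative
  to out-of-sample assignment.
* The Hosmer–Lemeshow statistic's chi-square reference with df = g − 2 is
  an approximation whose adequacy the acceptance suite checks empirically
  under a correctly specified generator.
* Small cohorts or rare outcomes (e.g. death in a young subgroup) can make
  the dummy-coded group models inestimable; the package fails loudly with
  a ridge suggestion rather than reporting unstable estimates.
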