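# Methods

This note documents the statistical models, the synthetic-data design, the
numerical choices, and the known limitations of `natri`.

## 1. Usual-intake amount model

### Model

Person-day sodium totals `T_ij > 0` (mg) are modeled on the Box–Cox scale:

    z_ij = g(T_ij; λ) = (T_ij^λ − 1)/λ   (log T for λ = 0)
    z_ij = x_ij'β + u_i + ε_ij,   u_i ~ N(0, σ_b²),  ε_ij ~ N(0, σ_w²)

A one-part (amount-only) model is appropriate because sodium is consumed at
some level on essentially every day; there is no consumption-probability
part. Fixed effects use **cell-mean coding** of the full
age group × gender × ethnicity interaction (up to 30 cells, including the
"Other" ethnicity, which is fitted but not reported), plus a weekend
indicator and a day-2/telephone indicator. Cell means rather than additive
age + gender effects were chosen because the reporting domains are the
cells themselves and an additive model would leak interaction bias into
subgroup estimates. With two recall days per person the day-2 indicator is
confounded with interview mode by design, exactly as in the survey the
generator emulates; the coefficient captures their joint effect.

### Estimation

All estimation is survey-weighted with weights normalized to mean 1
(a *pseudo-likelihood* / estimating-equation weighting). Consequently every
estimate is invariant to rescaling all weights, and duplicating each person
while halving weights changes nothing.

* **λ** is profiled over the grid {0, 0.05, …, 1.0}. For each candidate the
  model is fit by WLS and the weighted residuals are scored by a
  Jarque–Bera-style distance from normality, `skew² + (kurtosis − 3)²/4`;
  the smallest score wins (ties break toward smaller λ). A coarse grid is
  deliberately reproducible; the recovery tests show ±0.05–0.10 resolution
  in practice, comfortably within the ±0.15 band the tests assert.
* **β** by weighted least squares at the selected λ. Covariate columns with
  zero variance (e.g. a fixture with no weekend recalls) are dropped.
* **σ_w²** by weighted method-of-moments from within-person residual
  differences: `σ̂_w² = ½ · Σ w_i (r_i1 − r_i2)² / Σ w_i` over persons with
  two days. At least two such persons are required (identifiability error
  otherwise).
* **σ_b²** from the weighted second moment of person-mean residuals minus
  the within-person contribution, clipped at 0.

### Prediction

A person's usual intake is

    U_i = E[ g⁻¹(x_ref,i'β + u + ε; λ) ]

with the expectation over *both* the day noise `ε ~ N(0, σ_w²)` and the
person effect's full conditional distribution given the person's observed
days, `u | data ~ N(κ_i r̄_i, κ_i σ_w²/n_i)` with
`κ_i = σ_b²/(σ_b² + σ_w²/n_i)`. Integrating over the conditional rather
than plugging in the point shrinkage estimate matters: the plug-in version
underestimates subgroup means by a factor `exp((κ−1)σ_b²/2)` (about −1.5%
at the default variance components), whereas the conditional integral is
exactly unbiased in the lognormal case (`κσ_b² + κσ_w²/n = σ_b²`).

Reference covariates `x_ref`: the person's own demographic cell, weekend at
its population frequency (default 3/7, configurable), and the
day-2/telephone indicator balanced at 1/2 — a "balanced" prediction in the
NCI sense. The expectation is evaluated by Gauss–Hermite quadrature with 41
nodes by default (convergence from 9 to 41 nodes changes results by less
than 1e-4 relative; at λ = 0 the quadrature agrees with the lognormal
closed form to better than 1e-6). For λ > 0 the back-transform argument is
clipped at the transform's lower bound (`max(λz + 1, 0)^{1/λ}`), the
standard truncation.

### Subgroup summaries and thresholds

Point estimates are weighted means of per-person usual intakes per
age × gender × ethnicity domain ("Other" ethnicity excluded from reports).
`prop_below_1500` / `prop_below_2300` are computed from the *model-implied*
usual-intake distribution: for each cell the person-effect value at which
usual intake crosses the threshold is found by root-finding (Brent), and
the normal CDF gives the probability; empirical counterparts (share of
per-person point estimates below the threshold) are reported alongside.
The nesting `prop_below_1500 ≤ prop_below_2300` holds by monotonicity of
the back-transform.

### Variance estimation

SEs come from a stratified PSU bootstrap (Rao–Wu rescaling: draw
`n_h − 1` PSUs with replacement per stratum, multiply weights by
`n_h/(n_h − 1) ×` draw count), re-running the whole chain — WLS, variance
components, quadrature, domain means — per replicate. Default 200
replicates, seeded. λ is held at its point estimate inside replicates:
re-profiling on a coarse grid adds discretization jumps to the replicate
distribution without adding information. Domains represented in fewer than
two PSUs get `se = NaN` with the point estimate retained. The recovery
suite checks the bootstrap SE against the across-replicate empirical SD of
independently generated cohorts (factor-1.5 agreement).

Descriptive weighted means use Taylor linearization instead: stratum/PSU
aggregation of influence terms `w_i(y_i − μ̂)/ΣW`, with the
`n_h/(n_h − 1)` finite-sample factor. Lonely-PSU strata either raise an
error naming the stratum or are collapsed into the adjacent stratum
(configurable).

## 2. Density metrics and trends

Sodium density is computed per person from 2-day means: mean daily sodium
divided by mean daily kcal (mg/kcal) and by mean daily grams of food
(mg/g). Persons with zero kcal/gram totals are excluded with a flag.

Cross-cycle trends are person-level survey-weighted linear regressions of
each metric on the cycle index (0, 1, 2, …; five cycles in the standard
layout), pooling cycles with per-cycle weights divided by the number of
cycles, the standard practice for combined survey cycles. The slope's
variance is design-based: the WLS influence functions are aggregated to
PSU totals with out-of-domain scores set to zero (naive row subsetting
would create spurious single-PSU strata), and the Wald p-value uses a t
reference with (PSUs − strata) degrees of freedom. Significance is flagged
at α = 0.01. An alternative cycle-level granularity (OLS on the five
weighted cycle means) is available; person-level is the default. A null
simulation suite confirms the 0.01-level flag fires at about its nominal
rate (≤ 3% allowing Monte-Carlo slack).

## 3. Food-group sources

Group contributions are ratios of survey-weighted sodium totals on the
observed recall days — no usual-intake modeling per group — because source
attribution describes consumed foods, not long-run averages. Percentages
sum to 100 per domain and are invariant to weight rescaling and to
permuting food codes within a group. Unmapped codes either raise (strict)
or pool into an "unmapped" bucket (lenient).

## 4. Reformulation scenario engine

A scenario is `(r_food, reduction_scaling, penetration)` with all factors
in [0, 1]. In **expected-value** mode (default) each targeted record's
sodium is multiplied by `1 − r·scaling·penetration`; record-level
reductions are therefore exactly linear in each factor and conserve the
person-day total. Penetration-as-multiplier is the parsimonious reading of
"reduction factor × market-penetration factor"; the **stochastic** mode —
each targeted food code independently adopts the reformulation with
probability = penetration — is provided for sensitivity and converges to
the expected-value totals in mean (the 1% agreement check requires enough
targeted foods for draw noise to average out; with a handful of foods the
Monte-Carlo floor at 500 draws is ~3%).

`run_scenario` re-fits the usual-intake model on the modified recalls with
identical settings; λ is profiled once on the baseline arm and shared with
the counterfactual arm (configurable), so the two arms differ only in the
data, not in the transform. Per-person reduction is
`usual_before − usual_after`; percent reduction divides by the person's own
baseline and is then averaged over the domain ("average of reductions in
individuals"); the ratio-of-means variant is reported alongside. Per-group
breakdowns run single-group sub-scenarios; both the share-of-total-
reduction and a within-group percent (reduction over the person's
observed group sodium share times baseline usual intake) are emitted,
because the within-group denominator is not uniquely defined by the
published table layouts. Full re-estimation per arm was chosen over
scaling usual intake by the observed-day reduction share; on noise-free
lognormal fixtures the two coincide exactly, which the closed-form tests
exploit (targeted foods carrying 28% of sodium at a 25% cut give exactly
7.000% per-person reduction).

Bootstrap SEs for scenario reports share one set of replicate weights
across both arms, so arm-to-arm sampling noise cancels within a replicate.

## 5. Synthetic cohort generator

The generator emits NHANES-shaped demographics (stratified two-PSU design,
lognormal weights with configurable CV), exactly two recall days per person
(day 1 in person, day 2 telephone), and a ground-truth table.

* **Intake process**: `log T_ij = μ(cell) + cycle shift + u_i + β_wk·W_ij +
  β_seq·S_ij + ε_ij` — i.e. the generator's truth is the λ = 0 case of the
  estimation model, which is what makes closed-form recovery tests
  possible. Defaults: σ_b = 0.25, σ_w = 0.35 (between-person spread smaller
  than day-to-day spread, as observed for sodium), β_wk = 0.05,
  β_seq = −0.05 (slightly lower reported intake on the telephone day).
* **Cell means**: calibrated from a mg table (adults 19–50 by ethnicity
  near 3550–3900 mg/day; males ×1.18, females ×0.84; children and older
  adults ×0.82–0.84) so that White > Black ≈ Hispanic orderings and
  age/gender patterns of US surveillance are planted and recoverable.
  The log-scale location subtracts `(σ_b² + σ_w²)/2` and the
  weekend/sequence factors so the configured mg value *is* the expected
  day total.
* **True usual intake** is the exact long-run mean over the day-covariate
  distribution: `exp(μ + u + σ_w²/2) · E[e^{β_wk W}] · E[e^{β_seq S}]`
  with W ~ Bernoulli(p_weekend) and S ~ Bernoulli(1/2).
* **Food partition**: each day total is split across the 9 FNDDS groups by
  a Dirichlet draw centered on the composition vector (concentration 60 by
  default; `None` gives exact proportional shares for deterministic
  fixtures), then uniformly-Dirichlet across each group's food codes.
  Default composition puts 40% in Grain Products and 27% in Meat, Poultry,
  Fish & Mixtures (jointly two-thirds of sodium; top four groups 86%),
  mirroring the source-attribution pattern of US surveys. Grams and kcal
  are emitted from per-person lognormal ratio jitters around 0.64 g/mg and
  0.60 kcal/mg, so baseline densities sit near 1.56 mg/g and 1.68 mg/kcal;
  per-cycle mg/g targets override the gram ratio to plant density trends.
* **Filters have work to do**: a small rate of under-2 children and
  pregnant/lactating women is planted.

What the generator does **not** emulate: multi-stage probability sampling
with oversampling and nonresponse adjustment (weights are iid lognormal),
FNDDS recipe disaggregation, day-of-week structure beyond an independent
weekend Bernoulli (the survey's actual weekend definition is a knob,
default p = 3/7), correlated energy–sodium behavior beyond a shared ratio,
and real food-level sodium heterogeneity. Passing recovery tests therefore
demonstrate correctness of the estimation machinery under the stated model,
not agreement with real US population values, which require the real
survey microdata.

## 6. Problem sizes and defaults

Recovery suites use cohorts of n = 2000 persons (20 replicates), trend
fixtures n = 500 per cycle over 5 cycles, null-trend calibration 500
simulations at n = 150 per cycle, and 100-replicate bootstraps where speed
matters; these sizes give Monte-Carlo noise well inside the asserted
tolerances while keeping the full suite fast. Reported defaults elsewhere:
200 bootstrap replicates, 41 quadrature nodes, α = 0.01, thresholds
1500/2300 mg/day.

## 7. Known limitations

* The λ grid is coarse (0.05); sub-grid precision is not attempted.
* Variance components are method-of-moments, not REML; for two days per
  person they are nearly equivalent and far cheaper inside bootstraps.
* The bootstrap treats strata as fixed and PSUs as with-replacement draws;
  finite-population corrections are not applied.
* `prop_below` assumes the fitted normal person-effect distribution;
  heavy-tailed person effects would distort tail proportions.
* Scenario re-estimation assumes no behavioral compensation (no taste
  adaptation, no discretionary-salt offset) and leaves grams/kcal
  unchanged, so density metrics mechanically fall under reformulation.
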