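# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the limits of what the test suite demonstrates.

## Setting and estimands

Two routes to a cancer diagnosis are compared: emergency presentation (EP)
and GP/two-week-wait referral (GP/TWW), pooled over non-urgent and urgent
referrals.  For each of four tumour sites (colorectal, breast, prostate,
lung) the quantities of interest are, per patient rerouted from EP to
GP/TWW:

* the cumulative difference in hospital costs from diagnosis to a horizon
  of 60 months (36 for lung), decomposed into an **intensity** channel
  (different cost per unit of alive time) and a **survival** channel
  (different amount of alive time);
* the difference in pre-diagnosis costs over months −12..−1;
* the survival-probability difference at the horizon and the restricted
  years of life saved;
* the diagnostic cost of negative referrals needed per extra converted
  diagnosis; and
* aggregate annual impacts when every commissioning group (CCG) is brought
  to the EP share of the best-performing 20%.

All costs are GBP at 2010 prices with no discounting.  Cancer stage is
deliberately *not* adjusted for: the stage distribution is part of what
distinguishes the routes, so controlling for it would absorb the effect of
interest.  Adjustment covariates are age, sex, income deprivation, region,
eleven Charlson comorbidity flags, co-diagnosis count, and surgery within
12 months.

## The three-part censored-cost estimator

Estimating cumulative costs is complicated by right censoring (staggered
entry against a fixed administrative cutoff) and by the U-shaped cost
trajectory — spikes at diagnosis and in the final months of life — which
makes naive per-month averaging over a shrinking risk set badly biased.

Follow-up is split into intervals *j* (default: monthly for the first 12
months, quarterly thereafter).  In each interval, among patients at risk at
the interval's start and not censored before its end (decedents within the
interval are retained):

1. a **probit hazard model**: death within *j* on covariates + route
   (logit available by option);
2. a **decedent cost model**: interval cost among those dying in *j*;
3. a **survivor cost model**: interval cost among those surviving *j*.

Cost models are hurdle models: `P(cost > 0 | x)` (probit) times a gamma GLM
with log link on the positive costs — the standard specification for
zero-heavy, right-skewed monthly hospital costs.  Expected cumulative cost
to month *m* with the route forced to a value is

    mu(m; x) = sum_{j: end(j) <= m} S_{j-1}(x) [h_j(x) muD_j(x) + (1-h_j(x)) muS_j(x)],

with survival weights `S_{j-1}(x) = prod_{k<j} (1 - h_k(x))`, averaged over
the pooled (both-route) estimation sample (recycled predictions).  The key
identifying assumption is random censoring conditional on covariates.

**Decomposition.**  With EP as baseline, the total effect is
`Delta(m) = mu_GPTWW(m) - mu_EP(m)`.  The intensity effect substitutes
GP/TWW cost components into EP survival components:
`I(m) = mu~(m) - mu_EP(m)` where `mu~` uses EP's `h, S` and GP/TWW's
`muD, muS`.  The survival effect is defined residually as `Delta - I`, so
additivity holds to machine precision by construction.  The decomposition
is path-dependent (intensity-first, EP baseline); this matches the
convention of treating EP as the status quo.  Note that the *split* is
identified only through the interval structure: cost models know a
patient's proximity to death only through the decedent/survivor dichotomy,
so the two channels are estimated more coarsely than their sum, which is
what the recovery tests bind tightly.

**Pre-diagnosis contrast.**  A single hurdle GLM on cumulative cost over
months −12..−1 with recycled predictions; no survival machinery is needed
because everyone is alive before diagnosis.

**Uncertainty.**  Percentile bootstrap over patients (2.5/97.5 bands),
seed-deterministic; degenerate resamples (a lost route arm, or an interval
with nobody at risk) are redrawn and counted.

## Survival model

A Weibull accelerated failure time model,
`S(t|x) = exp(-(t/lambda(x))^rho)`, `log lambda(x) = beta'x`, fitted by
maximum likelihood with right censoring (lifelines).  The route
coefficient is the log time-ratio GP/TWW vs EP.  Survival probabilities
and restricted mean survival are population averages with the route forced.
RMST uses the closed form
`(lambda/rho) Gamma(1/rho) P(1/rho, (tau/lambda)^rho)` with adaptive
quadrature as an independent numerical cross-check (the two agree to
1e-8 across the tested shape/scale/truncation grid).  Years of life saved
is the RMST difference at the site horizon divided by 12 — the published
"years of life saved up to 5 years" figure is treated as this
restricted-mean construct, the natural truncation-consistent estimand.

## Referral economics and policy arithmetic

Non-conversion cost per converted case: `a = c_test (1 - r) / r`.
Published conversion rates are 3-decimal roundings; the ledger accepts
unrounded rates and by default back-solves `r = c_test / (a + c_test)`
from the published non-conversion cost, which reproduces the published
chain exactly (e.g. 0.0435 rather than 0.043 for colorectal).  Ledger
identities (`total = a + b + c + d`, ratios over survival gain and YLS)
are kept exact internally; rounding to the pound (half away from zero)
happens only at reporting.  Zero denominators flag the ratio undefined
rather than infinite.

Policy benchmark: CCGs sorted by EP share ascending; the unweighted mean
of the lowest `floor(0.2 N)` is the benchmark (a diagnoses-weighted
variant was considered and rejected as the default because the benchmark
describes attainable practice, not patient volume).  Rerouted counts are
`sum_g max(0, share_g - benchmark) * volume_g`, rounded once at the end.
Both total referrals (`rerouted / r`) and non-conversions (referrals minus
conversions) are reported, labelled explicitly.  The scale-up covers one
year of rerouting with no dynamic feedback on conversion rates.

## Synthetic cohorts

The registry/hospital linkage behind the original analysis is not
deposited, so `reroutecost.simulate` generates cohorts with the structure
the estimators assume:

* **Confounded route assignment** — logistic in standardised age,
  deprivation and Charlson count, so EP patients are older, more deprived
  and more comorbid.
* **Route-dependent Weibull AFT survival** — `log T` linear in
  standardised covariates plus `log(aft_route_factor)` for GP/TWW, Gumbel
  error scaled by 1/shape.
* **Independent administrative censoring** — uniform staggered entry
  against a fixed cutoff, independent of the survival error given
  covariates.
* **U-shaped monthly costs** — gamma draws (shape 0.8) with a 0.35
  probability of a zero-cost month; unconditional mean = baseline +
  diagnosis spike (months 0–2) + terminal spike (three months before the
  *latent* death time, anchored to death even when censoring truncates
  observation), all multiplied by `route_intensity_ratio` for EP;
  route-specific pre-diagnosis means.

Configured means are unconditional, so the Monte-Carlo oracle
(`true_effects`) can evaluate expected cumulative costs in closed form
given simulated death times, using common random numbers across the two
route arms — a null configuration yields exactly zero effects, and the
oracle decomposition is additive by construction.

Per-site presets ship as JSON.  Weibull scales are set from the
closed-form inversion of registry 12-month survival by route (e.g.
colorectal EP 0.497 / GP-TWW 0.787); shapes are 0.8–1.1 by site.  Cost
parameters were calibrated once against the oracle so each preset shows
the documented dynamic — early intensity-driven savings progressively
offset by survival costs, with the prostate-like preset remaining net
cost saving at its horizon — and then frozen.  The generator does *not*
emulate tumour stage, CCG geography at patient level, hospital cost
heterogeneity, or the registry's Charlson coding mix (preset targets are
survival ranks, not the published comorbidity index means).  Passing
recovery tests therefore demonstrate internal consistency of the
estimators under the assumed data-generating structure, not agreement
with the original registry estimates, which require the confidential
linkage.

## Numerical choices

* Saturated part-model designs (at most as many distinct covariate rows as
  parameters — e.g. intercept-only or intercept + route) are fitted in
  closed form as group means/proportions.  This makes the estimator exact
  on uncensored data with saturated parts (it collapses to the per-route
  empirical mean cumulative cost) and keeps bootstrap loops fast.
* Gamma GLMs use IRLS (maxiter 2000) with an L-BFGS fallback; positive-part
  fits with fewer than three observations per parameter fall back to group
  means.  Intervals with fewer than 5 decedents have their decedent cost
  model pooled with the next interval's; intervals with no decedents get
  hazard ≡ 0; intervals where everyone at risk dies get a zero survivor
  model (its weight `1 - h` is ≈ 0).
* Month convention: month 0 contains the diagnosis; bins are half-open;
  the month containing death or censoring is included in the cost history;
  missing months for alive patients are zero-cost months, since hospital
  data record activity, not inactivity.
* CSV round-trips preserve integers exactly and reals to 12 significant
  digits; every pipeline output carries a SHA-256 hash of the run
  configuration and reruns are byte-identical.

## Problem sizes

Parameter-recovery checks use cohorts of 10,000 patients with ~25–30%
administrative censoring against a 200,000-draw Monte-Carlo oracle;
distributional sanity checks use 20,000; bootstrap behaviour is
demonstrated on 300–1,600-patient cohorts with 40–60 replicates; the
published-table arithmetic is exact and runs in milliseconds.  At these
sizes the total-effect estimate lands within ±8% of the oracle across
seeds, against the 10% acceptance band.

## Known limitations

* Hospital inpatient/outpatient costs only; primary and social care are
  out of scope, as are lead-time and overdiagnosis corrections.
* The survival/intensity *split* (unlike the total) inherits the interval
  coarseness described above and is reported with that caveat.
* The three-part estimator assumes random censoring given covariates;
  informative censoring is not handled.
* Published-table verification reproduces the arithmetic chain of the
  per-patient and policy tables; the published abstract quotes a slightly
  different (mutually inconsistent) set of totals, and this package
  follows the tables.
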