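# Methods

## Model structure

A deterministic cohort (Markov) model with states PFS, PD and death tracks
the fraction of patients in each state per 28-day cycle — the treatment cycle
length — for 10 years (`floor(10 × 365.25 / 28) = 130` cycles). Everyone
starts in PFS; death is absorbing. Occupancy propagates as
`occ(t) = occ(t-1) · M(t)` with per-cycle matrices

| from \ to | PFS | PD | death |
|---|---|---|---|
| PFS | 1 − p_prog(t) − p_bg | p_prog(t) | p_bg |
| PD | 0 | 1 − p_os(t) | p_os(t) |
| death | 0 | 0 | 1 |

where the total PFS exit probability is the discrete hazard of the fitted PFS
curve, `1 − S_pfs(t)/S_pfs(t−1)`; background mortality `p_bg` claims its
share first and the remainder `p_prog` flows to PD (clamped at zero, with a
warning, should background mortality ever exceed the total exit). PD→death is
the discrete hazard of the fitted OS curve **at model time** `t`: the model
does not track time since progression (no tunnel states), so modelled overall
survival is an upper envelope of the fitted OS curve that tightens as PFS
shortens. The property suite checks this approximation directly, and both
arms reach ≥ 95% absorption by cycle 130 under the default inputs.

State membership is credited per cycle as the average of start- and
end-of-cycle occupancy (trapezoidal half-cycle correction), which makes total
credited person-time a trapezoid-rule estimate of restricted mean survival.
One-off terminal-care costs attach to incident deaths (a transition, not
membership) and are therefore not half-cycle corrected.

## Background mortality convention

The 2021 all-cause mortality of the Chinese general population, 7.18‰, is
applied **directly as the per-cycle PFS→death probability**
(`background_mode: per_cycle`), the literal reading of the published model
description this package re-implements; it is also the convention under which
the package reproduces the published per-arm QALY totals. The properly
compounded alternative, `1 − (1 − 0.00718)^(28/365.25) ≈ 5.52e−4` per cycle,
is implemented behind `background_mode: annual_compound` and covered by
tests; switching to it lengthens modelled survival by about 0.2 QALYs in the
intervention arm and 0.1 in the reference arm.

## Survival extrapolation

Six families are supported, all parameterised with a rate-like scale λ > 0
(and shape γ > 0) so that S(0) = 1, S is non-increasing, and S → 0:

| family | S(t) |
|---|---|
| Weibull | exp(−λ t^γ) |
| exponential | exp(−λ t) |
| log-normal | 1 − Φ((ln t + ln λ)/γ) |
| log-logistic | 1/(1 + (λt)^γ) |
| Gompertz | exp(−(λ/γ)(e^{γt} − 1)) |
| generalized gamma (Stacy) | Q(a, (λt)^γ) |

The Gompertz shape is restricted to γ > 0 (γ ≤ 0 gives an improper
distribution); the generalized gamma's extra shape a = 1 recovers a Weibull
with rate λ^γ. Maximum likelihood under right censoring
(`Σ_events log f + Σ_censored log S`) runs L-BFGS-B on log-parameters from
fixed starting values (λ₀ = crude event rate, γ₀ = a₀ = 1), so fits are
deterministic given the data. Model selection minimises AIC, breaking ties by
BIC, then parameter count, then family name. Whether the original analysis
fitted reconstructed individual data or least squares on digitised curve
coordinates is not recorded; this package fits censored pseudo-IPD, and the
synthetic-data generator exists precisely so that stage can be validated
(parameter recovery within 10% at n = 2000; family recovery in ≥ 80% of
replicates).

The default Weibull inputs put the palbociclib-arm median PFS at
(ln 2/λ)^{1/γ} ≈ 11.93 cycles ≈ 11.0 months, consistent with the ~11.2-month
trial median — the check that fixes the cycle (not month) time axis of the
published parameters.

## Costs and QALYs

All costs are USD (the RMB exchange rate 7.116 is carried as metadata only).
Accrual conventions are explicit, configurable policy, because published
descriptions of this model class rarely pin them down:

* **Drugs and administration — PFS only** (treat to progression).
  Palbociclib $640.39 is read as one 28-day cycle of therapy (one 21-capsule
  125 mg course); a per-capsule reading would put the intervention arm's drug
  cost several-fold above any published total for this comparison.
  Fulvestrant costs 2 × $287.90 per 500 mg administration, twice in cycle 1
  (loading, days 1 and 15) and once per cycle thereafter.
* **Follow-up ($166/cycle) — all alive states**: disease monitoring continues
  after progression.
* **Supportive care ($807/cycle) — PFS only**: modelled as supportive
  co-medication alongside active therapy. This is the convention under which
  the reference-arm total matches the published value; accruing it to all
  alive states roughly doubles the placebo-arm total.
* **Adverse events — incidence-weighted cost per treated (PFS) cycle**
  (default). The grade ≥ 3 incidence × unit-cost dot product is
  $425.27/cycle for the palbociclib arm and $19.73 for placebo. A one-off
  at-entry variant (`ae_mode: entry_once`) is implemented and tested; under
  it AE costs are immaterial to the ICER (< $500 total), which is
  incompatible with neutropenia cost being reported among the main ICER
  drivers of this comparison — the recurring reading is therefore the
  default.
* **Terminal care ($1,893)** — once per incident death, discounted at the
  cycle of death.

QALYs: `Σ_t df(t) (u_PFS · PFS_t + u_PD · PD_t) × 28/365.25`, with
`df(t) = (1 + r_c)^{-t}` and the per-cycle rate compounded from the 5% annual
rate, `r_c = 1.05^{28/365.25} − 1 ≈ 0.00375`.

## Sensitivity analysis

**One-way DSA** re-runs the whole two-arm pipeline at each parameter's
published lower/upper bound (all 23 parameters, including the discount rate
at 0–8%), holding everything else at base; parameters are ranked by ICER
range width (ties lexicographic). A bound that makes the model invalid is
recorded as a failed bound, not an exception.

**PSA** draws all parameters jointly and independently: Gamma for costs,
Beta for utilities and incidences, Normal for the discount rate, each
moment-matched to mean = base and sd = (upper − lower)/3.92 (bounds read as a
95% interval — the parameterisation is isolated in one function for easy
substitution). Survival parameters are held fixed: no uncertainty is
published for them, which will understate the spread of the incremental
cloud relative to analyses that resampled the curves. Joint draws violating
support or ordering constraints (u_PD ≥ u_PFS, ~3–5% of draws; negative
discount rates, <1%) are redrawn and counted. With the survival curves fixed
the cohort traces never change, so each draw only re-prices a fixed trace —
1000 draws take ~2 s. The CEAC reports, per WTP on a $0–120,000 grid
($500 steps), the fraction of draws with positive net monetary benefit
ΔE·WTP − ΔC.

## What the synthetic data does and does not show

`simulate_ipd` inverts S in closed form per family, with uniform or
administrative censoring (default: administrative at 79.6 cycles ≈ the
trial-like 73.3-month follow-up). It validates the fitting/selection
machinery against known truth. It does not emulate real KM artefacts —
step-function digitisation error, number-at-risk granularity, informative
censoring, covariate mix — so passing recovery tests says the estimator is
correct, not that digitised published curves would yield these exact
parameters.

## Numerical and degenerate-input choices

* Transition probabilities are clipped to [0, 1]; survival ratios guard
  against underflow (S < 1e−320 floors the log).
* All-censored samples raise a non-identifiability error; optimiser failure
  raises rather than returning defaults.
* Zero-width parameter bounds give a point mass in PSA and zero tornado
  width.
* ICER is undefined (flagged) at ΔE = 0; sign-discordant quadrants are
  flagged as dominance rather than reported as a ratio.
* All randomness flows from explicit integer seeds (`numpy` Generator); PSA
  output is bit-reproducible given a seed.

## Known limitations

* PD→death uses the OS hazard at model time, not time since progression;
  modelled OS therefore slightly exceeds the fitted OS curve in the
  intervention arm (final absorption 96.6% vs 99.3% in the placebo arm).
* The base-case incremental QALY (0.56) sits below the published 0.65 for
  this comparison; the per-arm totals and the ICER agree within 10%. The gap
  traces to the background-mortality convention interacting with the longer
  intervention-arm PFS.
* Costs are not CPI-adjusted and no price-scenario logic (insurance
  negotiation, patient-assistance pricing) is built in; both are expressible
  as config overrides.
* No EVPI/EVPPI, no correlated PSA, no microsimulation or tunnel states.
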