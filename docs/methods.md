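# Methods

## Model structure and assumptions

`ssbsim` is a deterministic expected-value cohort model, not an individual
microsimulation: the population is partitioned into cells (sex ×
single-year age 35–94 × diabetes yes/no × CVD state ∈ {none, CHD, stroke,
CHD+stroke}) and each annual cycle moves expected fractions of each cell
along cause-specific transitions. Determinism makes replay-oracle
equivalence exact and keeps a 10-year national run under a millisecond,
which in turn makes 1,000-draw uncertainty analysis cheap.

Key structural assumptions:

- **Risk functions.** Annual hazards for incident diabetes, incident CHD,
  incident stroke and non-CVD death (in the CVD-free population) are
  logistic in age, sex, SBP, BMI, HDL, LDL, smoking prevalence and
  diabetes status, with covariates centred at (age 60, SBP 120, BMI 25,
  HDL 50, LDL 120) so intercepts are interpretable log-odds of reference
  annual risks. The logistic form and the shipped coefficient values are
  this package's own synthetic choices: they have epidemiologically
  correct signs and produce nationally plausible event counts, but they
  are not estimates from any cohort. Users with real Framingham-style
  coefficients supply them through the bundle config.
- **Competing risks.** Cause-specific hazards are converted to annual
  probabilities by hazard allocation,
  p_c = (1 − exp(−Σh)) · h_c / Σh. This is order-invariant, sums to the
  correct all-cause probability, and never produces negative cell counts.
- **Disease states are absorbing attributes.** No diabetes remission; CVD
  states persist; the CHD+stroke state prevents double-counting people
  who have both. Diabetes incidence is modelled only in the CVD-free
  population (the incident-diabetes risk function is defined there);
  diabetic CVD patients still carry their diabetes into the cost
  accounting and excess-mortality terms.
- **Post-CVD dynamics.** Occupants of CVD states face a flat CHD-death
  hazard (CHD-containing states, default 0.05/y), a flat stroke-death
  hazard (stroke-containing states, default 0.025/y), an elevated non-CVD
  death hazard (1.5× the risk-function value), subsequent first events of
  the other disease via the incident risk functions, and acute case
  fatality of incident events (12% CHD, 18% stroke). Myocardial
  infarctions are reported as a configurable share (default 0.30) of
  incident CHD plus a recurrent-MI rate (default 0.015/y) among
  CHD-state occupants; both are presentation parameters, not transitions.
  These defaults were chosen once so that a full-scale synthetic run
  produces 10-year national totals at a realistic scale (≈3.2M CHD
  events, ≈1.2M CVD deaths, ≈6.1M all-cause deaths among 46.8M adults).
- **Demography.** Stratum risk-factor means are constant within age
  decile and over calendar time ("current obesity rates"); each year a
  fixed-size cohort of 35-year-olds enters with the baseline age-35
  composition and the 35–44 stratum means. Cells aging past 94 leave the
  model. The accounting identity
  N_next = N_prev − deaths − aged_out + entrants holds exactly each cycle.

## Calibration

Three multipliers scale (i) the incident-CHD hazard, (ii) the
incident-stroke hazard, and (iii) all CHD-death parameters (acute case
fatality and the post-CVD CHD-death hazard). Iterative proportional
fitting — multiply each by target/simulated after a one-year reference
run — converges in a handful of iterations because reference-year counts
are nearly linear in the multipliers; the loop stops when all three
quantities are within the configured relative tolerance (default 1%).
Note the couplings: CHD deaths scale with the CHD-events multiplier too
(fatal events), so the death multiplier absorbs the residual.

## Exposure chain

For a scenario (reduction r, compensation c) and stratum baseline intake
S servings/day:

| quantity | formula | units |
|---|---|---|
| Δservings | r·S | servings/day |
| net Δkcal | Δservings · 150 · (1−c) | kcal/day |
| Δweight | net Δkcal · 365 / 3500 · 0.45359237 | kg |
| ΔBMI | Δweight / height² | kg/m² |
| ΔSBP | Δservings · (0.78♂/0.61♀) + ΔBMI · (1.43♂/1.24♀) | mm Hg |
| diabetes multiplier | 1.19^(−Δservings) | — |

Design choices where the evidence base is silent:

- **Weight dynamics.** The steady-state weight change is applied in full
  from year 1 and held for the horizon — the simplest reading of a
  sustained consumption change. A linear phase-in over n years is
  available (`EffectParameters.weight_phase_in_years`); with it, the
  diabetes multiplier is raised to the phase-in fraction so the chain
  stays consistent.
- **Dose–response.** The per-serving diabetes RR is extended to
  non-integer doses as a power law (log-linear), the standard reading of
  a "per additional serving" relative risk. It stacks multiplicatively on
  the BMI-mediated effect, which flows through the BMI term of the risk
  function.
- **SBP effect scope.** Applied to the stratum-mean SBP of all adults
  (not only untreated hypertensives).
- **Mean heights** (1.64 m men, 1.53 m women) are plausible placeholders
  used to convert weight to BMI change; they are config inputs, not
  survey estimates.

Percent-change and rounding (events to the nearest 100, percents to one
decimal) are applied only in presentation tables; every internal quantity
carries full precision.

## Cost accounting

Unit costs are institution expenditure ÷ service count per service type
(generalist visit, specialist visit, hospital day); per-patient annual
cost per age decile is the institution-weighted sum of services ×
unit costs; pesos convert at 7.67 per international dollar and inflate by
3.57% to the reporting year. Costs attach to *prevalent* diabetes
person-years counted at cycle start (no half-cycle correction), and
savings are base-minus-scenario totals. No discounting by default (a
`discount_rate` argument exists, default 0). CVD and kidney-disease
costs, indirect costs and tax revenue are out of scope.

## Uncertainty analysis

Each varied parameter is drawn as mean + z·SD with
SD = (upper95 − lower95)/3.919928, z ~ N(0,1); ratio parameters are drawn
on the log scale centred at ln(mean). The women's per-serving SBP effect
may legitimately draw negative (its CI crosses zero). Draws are
deterministic in (seed, iteration), base and scenario runs within an
iteration share one draw (paired differences), and 95% uncertainty
intervals are the 2.5th/97.5th percentiles of the stored differences —
percentile intervals, not normal approximations, matching how stored
Monte Carlo outcomes are usually summarised. Failed iterations are
excluded with a warning above 1%. The default varied set is the three
published exposure effect sizes plus six synthetic risk-function
coefficients at ±30%; the list is fully config-driven.

## Synthetic data: what it does and does not emulate

The generator reproduces the *structure* of the real inputs: zero-inflated
right-skewed daily SSB volumes (two-part lognormal with stratum means
matching the published national survey summary, mean > median everywhere,
declining with age, higher in men), survey weights as population/sample
per stratum, age-rising diabetes/CVD prevalence and risk-factor means,
and institution-level cost tables whose per-patient costs rise with age
(≈$760–$2,000/year) and whose implied national diabetes expenditure sits
at the right order (~$11–12B/year).

It does **not** emulate: multi-stage cluster sampling (weights are
self-weighting within stratum), secular trends in risk factors or
demography, real Framingham coefficients, institution-specific case
fatality, or within-stratum risk-factor variance (interventions act on
means, so only the survey generator would use it). Passing tests
therefore demonstrate the correctness of the *machinery* — conservation,
competing risks, calibration, the exposure arithmetic, paired uncertainty
— on realistic-scale inputs, not the accuracy of any national projection.

## Numerical choices and degenerate inputs

- Hazard → probability conversion uses `expm1` for small-hazard accuracy;
  zero total hazard yields zero probabilities.
- Covariates are clamped (SBP ≥ 60, BMI ≥ 12) with a warning if an
  intervention would push a stratum mean below plausibility.
- Acute case fatality × calibration multiplier is capped at 1.
- Calibration raises with diagnostics after 100 iterations or if any
  target's simulated count is zero.
- Zero population cells propagate exact zeros end to end.
- Negative cell counts are impossible by construction; the engine asserts
  this and clips float noise at −10⁻⁶.

## Problem sizes used in the shipped tests

Tests run the same engine at 1/1000 population scale (all rates,
prevalences and calibration targets scale together, so every property is
scale-free); oracle-equivalence tests use 4-cell toys over 5 years where
a pure-Python per-cell replay is exact; the PSA reproducibility test uses
the full 1,000 iterations. The acceptance script runs the full 46.8M
population with 1,000 PSA draws.

## Known limitations

Single-year ages with decile-constant risk-factor means create small
discontinuities at decile boundaries; entering cohorts inherit baseline
composition rather than projected trends; stroke deaths are not a
calibration target (only CHD events, stroke events, CHD deaths); and the
under-35 population, renal-disease events, revascularization counts and
heterogeneous price elasticity are out of scope.
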