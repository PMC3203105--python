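# Methods

## Model structure

The model is a proportional multi-state life table: a cohort life table
coupled to nine parallel disease sub-models whose prevalence and mortality
deltas feed back into total mortality and average disability. Two
populations are simulated — a reference population under current morbidity
and mortality, and an intervention population identical except that a share
of its obese members receives a one-year drug course. The populations are
split into sex × 5-year cohorts (band midpoints 22, 27, …, 97 in the 2003
start year) and followed in annual cycles until everyone has died or
reached age 100; person-years use a half-cycle correction and the table is
closed at 100 (no person-years beyond it).

### Exposure

Baseline BMI in each sex/age stratum is normal. Treatment shifts the
recruited fraction (42% = 83.5% GP contact × 50% willingness) of the
BMI ≥ 30 mass down by the current mean weight loss divided by height
squared (fixed heights 1.78 m men / 1.64 m women). The weight trajectory
builds linearly to the 12-month loss (4.45 kg sibutramine, 2.89 kg
orlistat) during the intervention year and is then regained at 0.385
kg/month, floored at the permanent fraction (0 in the base case); each
annual cycle uses the trajectory value at its midpoint as the
representative exposure, so the intervention year contributes half the
12-month loss. An alternative regain preset of 0.0309 kg/month and a
linear-over-3-years mode are available as named scenarios.

### Risk

Relative risks per BMI unit are log-linear and compound multiplicatively;
they are 1 below age 35 for every disease (the printed all-age entries for
endometrial cancer, kidney cancer and osteoarthritis are overridden by this
convention, which is what makes the 20–29 age group gain exactly nothing).
The PIF is computed from expectations of `r^X` over the exposure densities.
Because baseline and counterfactual are normal / shifted-obese-normal
mixtures, the expectations have closed forms via the lognormal-mean
identity; the cohort engine uses these, while an adaptive-quadrature route
over a BMI window (default [10, 60], widened to mean ± 9 SD when the
stratum SD makes the default tails non-negligible) exists for arbitrary
densities and is cross-asserted against the closed forms and a 10⁶-sample
Monte Carlo estimate in the test suite. PIFs are independent of the
reference BMI (it cancels in the ratio), and no floor is applied to RRs
below the reference.

### Disease models

Each disease is a three-state (well, diseased, dead-from-disease) model in
annual cycles with all flows evaluated at the start-of-cycle state:
`S' = S − S·i + C·ρ`, `C' = C + S·i − C·ρ − C·φ`, disease deaths `C·φ`.
S and C are proportions of the living cohort; disease deaths leave through
the life table's total-mortality channel (all-cause mortality already
includes them), so the sub-model conserves `S + C` rather than shrinking
its own denominator — removing the deaths twice would double-count and
shifts the constant-rate fixed point away from the classic steady state
`i/(i+ρ+φ)`. Remission is 0 for all nine diseases; cancers are handled
through incident-case costing rather than remission. Baseline prevalence at
cohort start is derived with the model itself under a steady-state
(trend-free) assumption by running the youngest cohort forward from age 20.
Prevalence among the obese, where needed, is derived the same way after
scaling incidence by the obese/population mean-RR ratio computed from the
truncated-at-30, renormalised BMI distribution.

### Life table linkage and DALYs

Intervention total mortality is reference mortality minus the summed
disease-mortality deltas (clamped at 0, with clamp events logged);
intervention disability is the baseline YLD rate minus the summed
prevalence deltas weighted by disability weights (clamped to [0, 1]) — the
additive-delta formulation reproduces the null case exactly. DALYs averted
are the cohort-size-weighted, discounted (3%/year, referenced to the
intervention year; cycle 0 undiscounted) difference in
disability-adjusted person-years. Health gains are also expressed as a
fraction of the theoretical-minimum scenario in which the whole population
has BMI N(21, 1) for the rest of their lifetime.

### Costs (2003 AUD)

Intervention costs accrue in the intervention year: drug price ($1,467
sibutramine / $1,486 orlistat per full year) scaled by an attrition-based
exposure factor, 10 minutes of GP time at $109.36/h for the initial
prescription, and 1.3 / 1.6 follow-up visits at the $30.20 consultation
rate. Two attrition conventions coexist deliberately: the *year-equivalent
of drug use* metric (0.64 / 0.75) counts early dropouts as zero use, while
the *drug cost* rule charges them one month of medication; completers and
late (month-6) dropouts contribute a full year and half a year under both.
Patient time ($17.44/h covering visit, 30 min waiting and 30 min travel)
and travel ($7.45/trip) are added in the wider perspectives. Cost offsets
credit averted incident cases (cancers) or averted prevalent case-years
(other diseases) at the age/sex costs of the packaged schedule; unrelated
health-care costs in added years of life are charged per added person-year
and reported as a separate perspective, both ways.

### Uncertainty and sensitivity

Monte Carlo uncertainty (2000 iterations) draws the 12-month weight change
and the regain rate from normals truncated at zero, ln RR per schedule
entry from normals with SEs back-calculated from the printed 95% CIs, and
the GP/travel minutes from triangular distributions; drug prices are fixed
(centrally administered). The regain SD for the 0.385 kg/month preset keeps
the relative uncertainty of the 0.0309 (SD 0.0084) estimate. Draws are held
common across arms within an iteration; since the reference arm contains no
uncertain parameter it is simulated once and cached. The ICER point
estimate is the ratio of means; its interval comes from percentiles of the
per-iteration ratios, and the probability of cost-effectiveness is the
share of iterations under A$50,000/DALY. The univariate grid covers halved
regain, linear 3-year regain, 23% permanent loss, a 0.017-per-BMI-unit-year
utility weight added to the effect measure, no discounting, a disease-free
baseline, and age-decade subgroups (which restrict benefits, costs and
starters to those cohorts).

## Synthetic world

The generator emulates the shape, not the identity, of the national inputs:

* **Mortality** — Gompertz `a·e^{b·age}` at band midpoints (male a = 3.2e-5,
  b = 0.090; female a = 1.6e-5, b = 0.095), giving ~0.003 at age 50 and
  ~0.04 at 80 for men. Exact (no jitter) so monotonicity holds by
  construction.
* **Cohort sizes** — a 2003-like adult pyramid, ~0.7 million per young band
  declining to thousands at 95–99 (≈13.9 million adults), with 2% lognormal
  jitter.
* **Disease rates** — log-linear in age from disease-specific onsets, e.g.
  diabetes incidence 6/1000 at age 50 growing 5%/year, stroke case fatality
  8%/year-prevalent; female-only cancers have zero male incidence;
  3% lognormal jitter on incidence.
* **BMI** — per-sex SDs of 4 (men) and 5 (women) with means fitted exactly
  so P(BMI ≥ 30) hits the 21% / 23% targets (≈26.8 / 26.3); no age gradient
  or secular trend by default (a per-year mean-drift hook exists in the
  config).
* **Baseline disability** — YLD rate 0.04 + 0.0025·(age−20), capped at 0.35.

What the synthetic world does **not** emulate: real age gradients in
adiposity, cohort trends in obesity or mortality, comorbidity clustering,
risk-dependent case fatality, or the actual Australian rate levels. Tests
passing on this world therefore establish the correctness and the
qualitative behaviour of the machinery (directions, orders of magnitude,
invariances), not quantitative agreement with any national estimate; on the
default world the headline ICERs come out at roughly A$60,000–150,000 per
DALY with ~0.07–0.15% of the total BMI burden averted, the same qualitative
conclusion (not cost-effective, negligible burden impact) as the real-data
analyses of this intervention class.

## Numerical choices

* Annual discrete-time difference equations throughout (the model has
  one-year cycles); flows within a cycle are evaluated simultaneously at
  the start-of-cycle state.
* Quadrature: `scipy.integrate.quad` with kink/mode anchor points;
  unnormalised densities (mass off by > 1e-4) are rejected, residual tail
  mass is renormalised away.
* Mortality clamps at 0 and disability clamps to [0, 1] are logged through
  the `pmslt` logger.
* Reported ratios are rounded to two significant figures; a non-positive
  health gain yields the `inf` ("dominated") sentinel rather than a
  negative ICER.
* Determinism: every stochastic element (world jitter, Monte Carlo draws)
  flows from an explicit `numpy` Generator seed; identical seeds are
  bit-reproducible.

## Problem sizes

The default test and reproduction runs use the full 16-cohort × 2-sex world
with all 81 single-year ages, 2000-iteration Monte Carlo analyses for the
headline results, smaller (30–60 iteration) runs for determinism and
coverage properties, and 10⁶ samples for the Monte Carlo PIF cross-check.

## Known limitations

* Starters are all recruited obese adults; no explicit exclusion of
  prevalent cases at recruitment (the disease-free-at-baseline scenario
  probes the starting-prevalence assumption instead).
* The disease models do not condition incident risk on medical history, and
  comorbid disability combines additively.
* BMI normality is an artifact choice; the treated-segment shift is a
  translation, ignoring heterogeneity in response.
* Side-effects, productivity effects and secular obesity trends are out of
  scope.
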