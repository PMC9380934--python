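# Methods

## Model structure

The analysis is a deterministic cohort model: it tracks the *mean* IQ and
adaptive-behaviour (VABS) score of a single starting cohort (age 36
months, IQ 59.43, VABS 63.19, ADOS severity 6.98), not individuals.
Cycles are monthly; the childhood horizon is 186 cycles (age 3 → 18.5).
Three phases partition the horizon: pre-school (months 0–17), primary
school (18–101) and secondary school (102–185).

Scores evolve in closed form. Under TAU each score declines linearly
(−0.28 IQ, −0.45 VABS points per year). The intervention arm adds a
piecewise-linear effect: 0 at month 0, the one-year estimate at month 12,
the two-year estimate at month 24; afterwards the effect is either held
constant (optimistic durability) or decays linearly to zero at month 84
(pessimistic), the longest follow-up in the underlying evidence. The
within-year linear ramp is a modelling choice — only the one- and two-year
effects are evidenced — consistent with the model's "mean change per
month" formulation.

All flows (utility, every cost category) are accrued per cycle with a
half-cycle correction: the flow for cycle *t* is evaluated from the
midpoint state (the average of the month-*t* and month-*t*+1 states) and
discounted at month *t* + ½. Discounting at 3.5% per annum supports two
modes: `monthly` (continuous power form, (1+r)^(−t/12)) and `annual`
(stepped once per completed model year). Survival weights every flow;
with the default mortality inputs childhood survival exceeds 99%, so
mortality is immaterial before the lifetime scenario.

## Outcome equations

**School placement.** An ordered logit per phase:
P(setting ≤ k) = expit(cut_k − β_vabs·VABS − β_iq·IQ), with settings
ordered mainstream < mainstream-with-support < special. This orientation
(score coefficients negative, cuts as printed) makes higher-functioning
cohorts more likely to attend mainstream school and gives plausible
baseline mixes; the opposite orientation degenerates to ~100% special
placement for any input. Placement is evaluated once at each phase entry
(months 18 and 102) and frozen for the phase; a
`reevaluate_placement_monthly` switch re-evaluates it every cycle from the
drifting scores (default off — phase-entry determination is the described
behaviour).

**Utility.** u = −0.2438 + 0.0119·age + 0.0003·age² − 0.0063·ADOS +
0.0304·ln IQ + 0.0103·VABS (age in years). IQ and ADOS enter at their
baseline values by default — the source algorithm used *baseline*
cognitive ability and symptom severity as predictors — while VABS and age
are time-varying; `utility_model.time_varying_iq` lets the IQ term track
the cohort mean instead (one of the calibration variants below). A
`cap_at_one` flag truncates predictions at full health. It is **off by
default**: the point prediction never exceeds ~0.81 so the cap cannot
affect deterministic results, but in the probabilistic analysis the
coefficients are drawn independently (no covariance is published) and
roughly a third of draws push utilities past 1 at older ages; capping
censors exactly those draws and asymmetrically suppresses the incremental
QALY, whereas the published probabilistic results track the linear
prediction with no sign of censoring.

**Costs** (GBP, 2016/17 prices; no inflation machinery). Intervention:
£36,682.78/yr for the 24-month treatment period. TAU provision:
£8,634.33/yr over a configurable window (`tau_cost_window_months`; the
source description does not pin it down — a calibration variant).
Schooling: mix-weighted unit costs £4,417.70 / £8,689.78 / £15,702.78 per
year, zero pre-school. Social/medical: max(0, 1900.09 − 8.78·VABS −
7.81·IQ) per year, both arms, whole horizon — an extrapolation of an
adolescent-sample regression down to age 3, inherited from the original
analysis. Perspectives: `nhs_social` = intervention + social/medical;
`public_sector` adds schooling.

## Calibration of under-determined conventions

Three implementation details of the original spreadsheet cannot be
recovered from its description: the TAU cost window (12 or 24 months),
discount stepping (monthly or annual) and the utility IQ term (frozen or
time-varying). `aba_cea.calibration` enumerates the 2×2×2 grid, recomputes
the full deterministic analysis under each combination
(`aba-cea variants`), and scores each against externally supplied
reference results by mean absolute relative error. The selected
convention — 24-month TAU window, annual-step discounting, frozen IQ —
reproduces the reference incremental QALYs and most ICERs within a few
percent. The packaged defaults keep the neutral conventions (24-month
window, monthly discounting, frozen IQ); selection happens in the
acceptance script and tests, never silently.

Two quantities resist reproduction under every variant, and are reported
as computed rather than adjusted:

- the absolute TAU QALY total: the printed utility coefficients give a
  baseline utility of 0.526 *rising* with age, which bounds discounted
  childhood QALYs below by ≈ 6.3, yet the reference table prints 4.37.
  Incremental QALYs and ICERs are unaffected — they depend only on the
  VABS/IQ gradients of utility, not its level;
- the public-sector pessimistic ICER (≈ +15%): the reference tables imply
  a schooling-cost offset under pessimistic durability about twice what
  the model structure permits, since the treatment effect has fully washed
  out before secondary placement is determined.

## Mortality

Annual death probabilities qx convert to monthly hazards −ln(1−qx)/12; a
relative risk for autistic people multiplies on the hazard scale (the
published point estimate is not reprinted in the source analysis, so the
default RR = 2.56 is a clearly-labelled placeholder — immaterial in
childhood, visible in the lifetime scenario). Mortality is identical in
both arms. The default life table is synthetic Gompertz–Makeham,
qx = 2×10⁻⁴ + 2.5×10⁻⁵·e^{0.10·age}, chosen so childhood cumulative
mortality stays below 0.5% while old-age rates ramp realistically; a real
table can be supplied as CSV (`age,qx`).

## Lifetime (adult) scenario

VABS at age 18.5 maps to five ordered independence levels through a
cumulative logit fitted by maximum likelihood (statsmodels; an L2-penalised
fallback handles separation) to simulated individual records. The
generator draws a level by prevalence and a VABS score around that level's
mean (common SD, truncated to the 20–140 instrument range). The per-level
means (95/80/68/55/42, SD 8) and prevalences are **synthetic defaults**,
calibrated only to the ordering reported in adult-outcome cohort studies;
the true summary lives in a technical report outside this package and can
be injected through the config, as can externally estimated coefficients.

Each level carries an annual care-cost bundle assembled from published
unit costs (residential £115,553, high-intensity sheltered £99,336, … own
home £0); the bundle composition is config-driven with a synthetic default
that enforces cost monotonicity with dependence. The mix is frozen through
adulthood (no transitions), adult utility freezes the age term at 18 and
applies an additive per-decade decrement schedule (zeros by default — a
slot for published ageing decrements), and all adult flows are discounted
from model start to a maximum age of 80. Because the pessimistic effect
has fully decayed by 18.5, both arms enter adulthood identical and the
lifetime ICER collapses to the childhood one; under optimistic durability
the adult care savings dominate.

## Sensitivity analysis

One-way: each uncertain parameter moves to its published range limits
(or mean ± 1.96·SE where the printed range is unusable) with all else at
means; rows are ranked by ICER range. A one-way excursion that breaks
model structure (a cut-point crossing its neighbour) is recorded as
undefined rather than extrapolated.

Probabilistic: 10,000 iterations, independent draws — normal for effects
and regression coefficients, gamma by method of moments (shape = (m/se)²,
scale = se²/m) for costs, moment-matched beta for proportions, truncated
normal on the printed bounds for continuous "beta-like" entries.
Structurally invalid draws (cohort IQ ≤ 0, or unordered education cuts,
~10% of draws given the secondary-model SEs) are redrawn with a counter
and a hard limit. Summaries use the ICER of mean incrementals, not the
mean of per-iteration ICERs. The CEAC uses the net-monetary-benefit rule
(λ·ΔQALY − Δcost > 0) by default; a literal-ICER rule is available since
the source description is ambiguous between the two.

## Problem sizes and determinism

Deterministic runs evaluate 186-month arrays and complete in milliseconds;
the full variant grid takes ~2 s and a 10,000-iteration PSA ~5 s on one
CPU, so the default test suite and the acceptance script each finish in
well under a minute. All stochastic components (PSA, synthetic data,
fixtures) are pure functions of their seed; identical seeds give
bit-identical outputs.

## Limitations

- The synthetic adult-phase inputs (level means, prevalences, bundles)
  and the mortality relative risk are placeholders for values held in an
  external technical report; lifetime-scenario magnitudes are therefore
  only qualitatively meaningful (ordering, dominance), not point-accurate.
- Regression coefficient blocks are sampled without covariance, inflating
  PSA spread relative to a joint draw from the estimated models.
- Several printed input ranges are internally inconsistent (misaligned
  bound columns); the affected bounds are omitted and replaced by
  ±1.96·SE ranges, which changes one-way sensitivity ranges for those
  entries.
- The cohort-mean design cannot represent heterogeneity: placement,
  costs and utilities respond to the mean scores, not their distribution.
- Passing tests show the pipeline reproduces the published *computational*
  results from the published inputs; they say nothing about the clinical
  effectiveness evidence those inputs rest on.
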