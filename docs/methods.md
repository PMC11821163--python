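# Methods

## Model structure

`ricesim` implements a deterministic (macro-) Markov cohort model. The unit
of simulation is a stratum: one sex × 10-year age band cell of the closed
cohort of Japanese adults aged 40–79 in 2019. Each stratum's population is
split at cycle 0 between *no T2D* and *T2D* by prevalence and then updated
through annual cycles by a 3×3 transition matrix; *death* is absorbing and
remission (T2D → no T2D) is structurally zero. Rates are held at their 2019
age-band values for all 10 cycles: members of the "60–69" stratum keep
60–69 rates even as they age into their 70s. That is the closed-cohort
reading of the design; an open-cohort or band-migration model would need
time-varying rates and is out of scope.

Incident T2D in a cycle is counted from start-of-cycle no-T2D occupancy
times that cycle's incidence probability, so cases are registered before
same-cycle mortality. Occupancy is conserved to floating point at every
cycle (checked to 1e-6 persons in tests).

## Transition probabilities

Epidemiological inputs are rates (events per person-year); the engine
converts them with `p = 1 − exp(−r·Δt)` (Δt = 1 year), which is exact under
a constant within-cycle hazard and keeps probabilities in [0, 1) for any
input. The T2D mortality hazard ratio multiplies the all-cause rate *before*
conversion — hazard ratios act on hazards, and applying them on the
probability scale could exceed 1. No-T2D mortality uses the all-cause rate
unadjusted, accepting a slight double-count of diabetic deaths in that
state's background mortality; the alternative (subtracting T2D-attributable
deaths) would require cause-deleted life-table inputs the model does not
have. If a row's off-diagonal probabilities ever summed past 1 (unreachable
with plausible inputs), they are renormalized proportionally and a warning
names the stratum and cycle.

## Dose–response and scenarios

The protective association is RR = 0.84 (95% CI 0.79–0.91) per 50 g/day of
white rice replaced by brown rice (dry-grain equivalent). Intermediate doses
use a log-linear model, `RR(d) = exp(ln(0.84)·d/50)`: this is how
substitution RRs from prospective-cohort meta-analyses are conventionally
rescaled, it makes doses compose multiplicatively, and it cannot produce a
negative risk at high doses. The 50 g unit is configurable
(`EffectParams.substitution_unit_g`).

Scenarios replace a fraction (30%, 80%) of each stratum's mean white-rice
intake. The default trajectory ramps the attained brown-rice intake linearly
from the 1 g/day baseline floor at cycle 1 to the full target at cycle 10;
an `immediate` ramp applies the full dose from cycle 1 and brackets the
"effects start at once" reading. Both are exposed and recorded in run
metadata. The base case holds intake at the baseline floor, giving a
substituted dose of exactly 0 g and bit-for-bit identity with any scenario
whose fraction is 0.

## Costs

National annual T2D healthcare expenditure per stratum is assigned to the
T2D state as a per-occupant rate: expenditure divided by the modeled
baseline prevalent count (prevalence × population). A cohort trace needs a
per-person-year rate, and this choice reproduces the aggregate exactly when
multiplied back. Costs accrue against half-cycle-corrected T2D person-time
(trapezoid rule, the mean of start- and end-of-cycle occupancy — the
variant of half-cycle correction implemented here), are discounted at
2%/year and converted at JPY 109.01/USD. Discounting uses an end-of-cycle
convention — cycle c is discounted c periods — switchable to midpoint
(c − ½); the convention is logged in run metadata. Savings of a scenario are
base-case cost minus scenario cost, per stratum and overall; with RR = 1
they are exactly zero.

## Sensitivity analysis

The one-way deterministic analysis reruns the whole pipeline (base case and
scenario) twice per parameter: discount rate at 0% and 4%, the substitution
RR at its CI bounds, and white-rice intake, T2D incidence and T2D prevalence
with *all strata moved simultaneously* to their respective CI bounds
(stratum-by-stratum perturbation would produce 8× the rows without changing
the ranking logic). Prevalence perturbation changes the initial state split
and the per-case cost denominator — its only two roles in the model.
Results are sorted by descending span of the savings outcome, the order a
tornado diagram uses; sex-level rows rerun the same analysis with the
outcome restricted to one sex's strata.

## Synthetic calibration

The original stratum-level inputs (burden-of-disease rates, survey intake,
expenditure accounts) are not redistributable, so the `japan_like` generator
emulates their structure: 2019 census stratum populations verbatim;
incidence, prevalence and mortality midpoints with the right age and sex
gradients (mortality rising steeply with age, male above female); white-rice
intake of 150–220 g/day dry equivalent; HR for all-cause mortality with T2D
of 1.7 (1.5–1.9); per-case annual costs rising with age at the scale implied
by the published expenditure projections. Seeded lognormal noise
(σ = 5% by default) makes every draw distinct but reproducible; every draw
passes full schema validation. The incidence midpoints were calibrated once
so the base-case 10-year cumulative T2D incidence lands in 3–9% per stratum
— an order-of-magnitude envelope around the published 2.8–8.8%, not a fit.
Confidence-interval half-widths are ±20% (incidence), ±10% (prevalence) and
±7% (intake), the scales typical of burden-of-disease uncertainty intervals
and national dietary-survey precision respectively.

What the generator does **not** emulate: individual-level intake
distributions (the model is population-mean throughout), correlation between
rates across strata, secular trends, or the survey's dietary-record
processing (food-code classification, cooked-to-dry weight conversion).
Passing tests on synthetic data therefore demonstrate the *mechanics* —
conservation, dominance, discounting, tornado ordering — not the real-world
magnitudes of any particular input source.

## Known limitations

- **Scenario effect sizes.** Applying RR 0.84 per 50 g/day to realistic
  dry-equivalent intakes makes the 30%-replacement scenario avert ~9% of
  base-case cases on the synthetic calibration, several times the published
  1.3%. Back-calculation shows the published averted fractions correspond to
  a mean effective dose of only a few grams/day, which no combination of the
  documented intake levels and replacement fractions can produce; the
  attained-intake schedule behind the published figures is in an appendix
  that is not available. The packaged reference tables carry the published
  stratum-level values, and the aggregation layer reproduces the published
  cohort summaries from them exactly; the simulation pipeline reports its
  own, internally consistent, magnitudes.
- T2D complications, productivity losses, long-term care and QALYs are
  outside the model's health-sector cost perspective.
- The cohort is closed: no entry at age 40, no migration, no population
  aging into or out of the 40–79 range.
- The two averted-death cohort totals in the reference tables disagree by
  ±1 with their own sex-subtotal sums (printed rounding); the fixture
  manifest lists every such discordance and aggregation tests use the
  sex-subtotal rows.

## Numerical conventions

Problem sizes are small throughout (8 strata × 10 cycles), so everything is
exact double arithmetic; the engine agrees with an independent scalar
reference to better than 1e-9 relative on 100 random parameter sets.
Percentages are computed from unrounded counts and rounded to one decimal
only at format time; cohort totals are sums of unrounded stratum values.
Ties in the tornado ordering (exactly equal spans) keep plan order, and a
degenerate low = high = point plan entry reproduces the base run bit-for-bit.
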