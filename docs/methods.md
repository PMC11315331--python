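# Methods

## Model overview

`psorcea` implements a cost-utility model of sequential biologic therapy for
moderate-to-severe plaque psoriasis in adults starting at age 40, compared
with conventional systemic therapy (standard of care, SoC: methotrexate or
ciclosporin plus topicals), from a societal perspective over a lifetime
horizon.  Three sequences of an IL-17 inhibitor, a second IL-17 inhibitor
(one of two alternatives, split 50:50) and an IL-23 inhibitor rescue
(guselkumab) are evaluated against pure SoC.

The structure is a hybrid: a **decision tree** resolves per-line treatment
response (response assessed after a 6-month induction period per line;
failures switch to the next line, and patients exhausting all three lines
fall back to SoC), feeding a **Markov cohort model** for the long-term
course.  Responders enter drug-specific maintenance, from which they can

* drop out (annual, drug-specific probability) to SoC,
* stop as planned after `stop_years` (default 3) of continuous maintenance,
  entering a topical-only off-treatment state,
* die.

Off-treatment patients relapse at a drug-specific annual rate; relapsers are
retreated with their last biologic and, per the model assumption, continue
it for life (no further planned stop, no drop-out from retreatment).  The
SoC state is absorbing except for death.

Mortality is identical in every alive state — biologics are assumed not to
prolong life — and equals the age-specific annual death probability times a
psoriasis relative risk, capped at 1, converted to a per-cycle probability.
Because mortality is the only exit to death and is state-independent,
total life-years are identical across all four strategies by construction;
the test suite asserts this to 1e-9.

## Cycle grid and accrual conventions

* **Cycle length** is 14 days, i.e. 26 cycles per 364-day model year.  This
  is the least common grid for the q2w/q4w/q8w dosing intervals and makes
  the 6-month response assessment an exact 13 cycles.  The cycle length is
  configurable; a 7-day grid is used in tests to show annualised drug cost
  is stable under grid refinement.
* **Accrual** uses end-of-cycle (post-transition) occupancy: a member of the
  cohort earns the cycle's costs, utility and life-time only if they
  complete the cycle.  Under a constant per-cycle death probability q this
  yields the geometric life expectancy (1−q)/q cycles in the long-horizon
  limit, which the tests verify to 0.1%.  The complementary convention
  (start-of-cycle credit) would instead yield 1/q.  A `half_cycle_correction`
  flag averages start- and end-of-cycle occupancy; it is off by default
  because 14-day cycles make the correction negligible.
* **Discounting** is annual at 3% for both costs and QALYs, with year 0 at
  par: the factor for cycle t is (1+r)^(−⌊t/26⌋).
* **Horizon**: age 100 (1,560 cycles from age 40).

## The three-year stop clock

The planned treatment stop is ambiguous between "three years on the current
biologic" and "the end of model year 3".  The cost-utility analysis uses the
per-biologic reading (`stop_clock="per_line"`): each drug's clock starts at
its own maintenance entry.  The budget-impact model uses the model-start
reading (`stop_clock="model_start"`), under which every biologic stops at
the end of model year 3 — this is the reading its year-4/5 relapse
assumption requires.  Both are available as a configuration switch.

## Adverse events

Adverse events are expected-count streams, not health states:

* **serious infection** — a one-time probability applied to the fraction
  starting each biologic line, at that line's first cycle;
* **malignancy** — an annual probability (converted per cycle) applied to
  biologic maintenance and retreatment occupancy once at least one year has
  elapsed since the line's start;
* **cirrhosis** — an annual probability applied to the methotrexate fraction
  of the SoC state.

Infection and malignancy carry one-time QALY decrements (`du_infection`,
`du_malignancy`) and per-event management costs.  **Cirrhosis is costed but
carries no QALY decrement**: the scenario analyses that vary the
MTX:ciclosporin mix are defined as cost-only variations (their QALY columns
are identical to base case), which is only possible if the mix does not
enter the QALY calculation.  The `du_cirrhosis` field remains in the data
model and is validated, but the engine does not apply it.

## Utilities

Baseline (uncontrolled-disease) utility applies during induction and in the
SoC state; responders accrue the utility of the active response definition
(PASI 75 by default; PASI 90/100 in scenarios 2–3) during maintenance,
off-treatment (response assumed retained until relapse) and retreatment.
No separate induction utility trajectory is modelled.  Retreatment after
relapse is assumed effective from the next cycle.

`SoCProfile.response_prob_soc` is carried and varied in sensitivity analyses
as a model input but the engine does not branch on it: the SoC arm is a
single absorbing health state.

## Costing

* Drug cost per dose is `ceil(dose_mg / mg_per_unit) × price_per_unit` — no
  vial sharing.  Induction schedules are the label regimens; maintenance
  doses run every `maintenance_interval_weeks` starting one interval after
  the last induction dose (so secukinumab's q4w maintenance resumes at week
  8 after the weeks-0–4 loading; guselkumab doses at weeks 0, 8, 16, …).
  Retreatment uses the steady-state mean maintenance cost per cycle.
* One-time screening (11 tests) is charged at each biologic line start and
  not re-charged at retreatment.
* Biologic monitoring: bi-yearly CBC/AST/ALT plus a yearly IGRA, spread
  uniformly over the year's cycles.  SoC monitoring: CBC/AST/ALT/BUN/Cr at a
  configurable 3–6-month frequency (default quarterly — midpoint of the
  stated range), quarterly lipid profile, and quarterly uric acid and
  magnesium for the ciclosporin fraction.
* SoC drug cost blends MTX 25 mg/week (tablet or injection price) and
  ciclosporin 5 mg/kg/day at 60 kg by the mix fraction (default 85:15).
* Visits (with a direct-medical and a non-medical food/transport component)
  and topical treatment accrue in every alive state, including off-treatment.
* All monetary values are 2021 THB; a CPI factor inflates raw-year inputs at
  load; USD conversion uses 0.0313 $/THB.  Indirect costs are out of scope.

## Decision analysis

* **ICERs** are computed from unrounded totals; report tables round to
  integer THB/USD and 3-decimal QALYs.  Rounding sensitivity matters: at
  frontier QALY differences of ~0.16, a 0.001 rounding step moves the
  Sequence2-vs-Sequence1 frontier ICER by roughly 45,000 THB/QALY, so
  frontier ratios recomputed from rounded published totals can differ from
  published ratios by several percent.  No exact match is asserted on such
  ratios; the worked-example tests target the incremental cost/QALY columns,
  which are exact differences.
* **Fully incremental analysis** sorts by ascending cost (ties: higher QALY
  first), flags strict dominance, then iteratively removes
  extended-dominated strategies (ICER vs the previous frontier point larger
  than the next frontier ICER).  Frontier ICERs are strictly increasing by
  construction.
* **One-way DSA** uses 95% CI bounds when supplied, otherwise ±20% of the
  base value, with probabilities and utilities clamped to [0,1]; tornado
  entries are sorted by descending ICER span.
* **PSA** draws every parameter with a `DistributionSpec` jointly per
  iteration: beta for probabilities/utilities, gamma for costs, log-normal
  for relative risks, fitted by method of moments around the base value with
  SE defaulting to 20% of the mean (these families are the standard choices
  for the respective parameter types).  Draws are shared across strategies
  within an iteration and fully reproducible from the seed.  ICER credible
  intervals exclude iterations with zero QALY difference (counted and
  reported).
* **CEAC** uses net-monetary-benefit maximisation across all four strategies
  simultaneously at each willingness-to-pay on a grid from 0 to 1.6 million
  THB/QALY in 20,000-THB steps; ties split equally.
* **Scenarios**: (1) alternative utility source (supplied as an
  `alt_utilities` block in the config — the mapping that produces those
  alternative values is out of scope), (2–3) response definition PASI 90/100,
  (4–7) MTX:ciclosporin mix 80:20, 70:30, 100:0, 0:100, (8) MTX injection
  prices.

## Budget impact

A dynamic cohort: the year-1 stock is prevalent patients on systemic
therapy; later years decay by an annual death rate and add incident
systemically-treated patients.  A 5% uptake fraction of the stock receives
the sequence.  Per-patient annual cost streams come from the cohort engine
run under the model-start stop clock with every drug's relapse probability
set to the 91% year-4/5 retreatment rate; hence with a zero relapse rate the
biologic spend in years 4–5 is exactly zero, and the budget impact is linear
in the uptake rate and in drug prices.  Streams are undiscounted and exclude
the non-medical cost category (payer perspective).  New starters after year
1 accrue half a year of sequence cost and half of SoC cost in their first
calendar year (`incident_half_year`, switchable).  BIA population mortality
is applied to patient counts, separately from the engine's within-cohort
mortality; this mild double-counting is a standard BIA simplification.

## Synthetic inputs

The study's numeric input tables (response rates, utilities, unit costs,
life table, budget-impact population) are supplementary material not
distributed here, so the generator produces internally consistent synthetic
sets with the same statistical structure: response probabilities ordered
PASI 75 ≥ 90 ≥ 100 with PASI-75 means in 0.60–0.90; annual drop-out
0.05–0.25 and relapse 0.30–0.95; ordered utilities (baseline 0.55–0.72,
responder gains 0.08–0.23); biologic unit prices (10k–40k THB) 1–3 orders of
magnitude above SoC per-mg prices, so biologic cost dominates; a
Gompertz-like monotone life table for ages 40–100; plausible lab, visit and
adverse-event costs.  Dosing schedules are the real label regimens, not
synthetic.  Generation is bit-reproducible from a seed and always passes
validation (property-tested over 100 seeds).

Because the synthetic values are not the study's values, passing tests
establish the *structural* correctness of the pipeline (engine equals
exhaustive path enumeration, conservation, equal life-years, discounting
identities, dominance logic, scenario structure, budget-impact linearity)
and the worked-example arithmetic on the published totals — not the study's
absolute cost/QALY levels.  The published totals themselves are available as
`table1_fixture()` (provenance `"paper:Table1"`) for exercising the decision
analysis.

## Numerical notes and problem sizes

* Engine verification compares the matrix-propagation engine against an
  independently coded exhaustive path-enumeration oracle on 100 randomized
  instances of up to 12 annual cycles, at 1e-12.
* Occupancy conservation is checked at 1e-9 per cycle row.
* The default test and acceptance runs use 1,000 and 500 PSA iterations
  respectively on the full 1,560-cycle horizon; the study-scale 10,000
  iterations run in a few minutes via `psorcea run-psa --n 10000`.
* Degenerate inputs: zero-width dose windows yield zero doses; zero
  QALY differences yield undefined (not infinite) ICERs; cost ties in the
  frontier sort are broken by higher QALY.

## Known limitations

* Cohort fractions only — no microsimulation, no patient-level memory beyond
  the state structure (e.g. a patient who drops out and later relapses is
  not tracked distinctly from the SoC pool).
* Malignancy risk is applied only while on biologic; whether it persists
  after stopping is not modelled.
* Relapsed-and-retreated patients cannot relapse again (they are assumed to
  continue treatment for life).
* No treatment effect on mortality; no dose escalation or wastage beyond
  whole-unit dispensing; no indirect costs.
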