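# Methods

## Scope and unit of analysis

The package models *reimbursement potential*: how activity documented in a
CoCM care-management registry maps onto CoCM and General BHI billing codes
under 2024 Medicare rules, and what revenue per hour of care-manager effort
that implies. It deliberately excludes the cost side (wages, fringe,
overhead), payer adjudication, claims-file generation, and commercial-payer
schedules.

The unit of analysis is the patient **calendar month** — the service and
time requirements of the codes are stated per calendar month, so rolling
30-day windows are not used. Only documented activity is analysed; no
missing-activity imputation is performed. The intervention window is six
calendar months from each patient's randomization date, half-open
(`randomization ≤ date < randomization + 6 months`, day-anchored); a
fixed-day window (`window_days`, e.g. 183) is available as a config option
because the day-level convention is not standardized. Entries inside a
calendar month but past the window boundary are truncated at the date, not
the month. Months with no registry entries are never emitted.

## Registry model and aggregation

Registry entries carry a patient, clinic, date, activity type (initial
care-manager encounter, follow-up encounter, contact attempt, consultant
consultation), minutes, and — on care-manager encounters — the fraction of
MBC items answered. Contact attempts have no recorded duration; each is
assumed to take 5 minutes (10 in the pessimistic sensitivity variant), a
parameter of every scenario. MBC counts as complete at ≥ 50 % of items
answered; a precomputed 0/1 completeness column works unchanged through the
same threshold. Verbal consent to CoCM is modelled as always satisfied
(obtained during initial engagement for every patient), so there is no
consent gate. Minute conservation is an invariant: the sum over emitted
patient-months equals the sum over in-window imputed entries.

## Service requirements

CoCM codes require, per month: a care-manager encounter, a consultant
(BHC) consultation, complete MBC, and a registry entry (implied by the
month existing — a month only exists because entries do). The code-specific
extras (treatment plan, care coordination, relapse prevention) are
operationalized onto the same three flags, so the binding triple is
{CM encounter, BHC consult, MBC}. General BHI codes drop the consultation
requirement; continuity of care is assumed met because every patient has an
assigned care manager. Every month therefore falls in exactly one class:
CoCM-eligible, BHI-only-eligible (missing only the consultation), or
service-ineligible for any code.

**Engagement** is the first month meeting the full CoCM triple. Months
strictly before it are pre-engagement; their *unbillable* minutes are
tallied separately (a pre-engagement month can still bill a BHI code — only
its unbilled time counts in the pre-engagement tally).

## Billing engine

Non-FQHC timed-range codes follow the CPT half-plus-one rule
(minimum = ⌊max/2⌋ + 1): 99492 36–70, 99493 31–60, 99494 16–30 (≤ 2/month),
G2214 16–30. 99484, G0511 are set-amount 20-minute codes; G0512 is a
set-amount code whose qualifying minimum (and credited amount) is 70 minutes
for the patient's first G0512 billing and 60 after.

Precedence when CoCM services are met (non-FQHC): bill the base code
(99492 until it has been billed once, then 99493), filling it to its
maximum before add-ons; each residual ≥ 16 minutes takes a 99494 (max two);
any remainder is over-maximum. Below the base minimum, G2214 is attempted
first (it is the CoCM-specific code and all CoCM services are present),
falling back to 99484 only when G2214 is excluded by the scenario and the
month has ≥ 20 minutes. The 31–35-minute initial-month gap bills G2214 at
30 with the excess over-maximum. An initial month billed through
G2214/99484 does **not** start the follow-up sequence: 99492 is attempted
again the next month (deferral), and 99493 is never billed before the
patient's 99492.

FQHC months attempt G0512 (if CoCM services met and the qualifying minimum
reached, crediting exactly 70/60 with the excess over-maximum), then G0511
(crediting exactly 20); under 20 minutes is under-minimum. The 70-minute
first-month threshold attaches to the first *G0512 billing*, not to the
first engaged month. Because the printed G0511-style totals are exact
multiples of 20, set-amount crediting is the default; an
`actual_minutes` G0512 crediting variant (credit all minutes once the
minimum is met) sits behind `fqhc_credit_mode` since the rule text does not
uniquely determine the behavior.

Unbillable reasons are assessed in a fixed order: missing services first,
then scenario availability, then time thresholds. Consequently, when the
only code(s) that could have billed a month are excluded by the restrictive
scenario, the entire month is categorized `CODE_UNAVAILABLE_RESTRICTIVE`
rather than split with an over-maximum component. Contact-attempt minutes
in qualifying months count toward billable time like any other documented
minutes. Minute conservation (billable + unbillable = total) holds per
month and in aggregate.

The engine is verified against an independent brute-force reference that
enumerates all feasible code multisets under the time/frequency constraints
(sequential fill, base before add-on) and selects by maximal billable
minutes with precedence tie-breaks, across ≥ 10,000 randomized months.

## Pricing and metrics

Fee schedules map code → per-instance payment; rates are stored as integer
cents and pricing is cent-exact. The 2024 Medicare non-facility schedule is
built in (`medicare_2024`); `medicaid_min`/`medicaid_max` are named
placeholders that require user-supplied rate files, because state Medicaid
schedules are policy inputs, not package constants. Revenue per hour
divides total revenue by **all** documented minutes in scope / 60 — the
denominator is the care manager's full documented effort, not just billable
time (a billable-hours variant is available but non-default). Display
rounding is half-up: dollars to cents, percentages to integers, ratios to
one decimal; exact values are retained on the report objects. Revenue
scales linearly in the fee schedule, and percent-billable is invariant to
it.

## Scenarios and sensitivity analyses

The expansive scenario assumes every code is billable; the restrictive
scenario drops 99484 and G2214 for non-FQHCs (the FQHC G-codes are kept in
both, since neither appears billable without the other). The scenario grid
{expansive, restrictive} × {combined, non-FQHC, FQHC} re-summarizes a
single pipeline run per scenario, so combined totals equal the sum of
setting totals by construction.

Three sensitivity analyses: (1) alternative fee schedules (config inputs);
(2) 10-minute contact attempts — total minutes rise, revenue per hour
weakly falls because the denominator grows at least as fast as any billable
gain; (3) an *unbilled fraction* f of billable months assumed never billed.
The unbilled fraction has two modes, since how unbilled months would be
selected is genuinely open: `deterministic_scaling` (default) multiplies
every month's revenue by 1 − f, leaving minute tallies unchanged and
scaling revenue per hour by exactly 1 − f; `random_month_drop` zeroes a
seeded uniformly-random subset of billable months of expected proportion f,
moving their billable minutes to a `NOT_BILLED` bucket so minute
conservation still holds. The two agree in expectation. The fraction is
applied after pricing within each scenario. Deterministically scaled
revenue is carried as exact fractional cents (no per-month re-rounding), so
the 1 − f identity is exact.

## Synthetic registry generator

The generator's defaults describe a 381-patient caseload over six months,
calibrated once to the trial-scale reference structure:

* **Engagement delay** per patient (number of outreach-only months before
  the first full-service month) is categorical over 0…6 with default pmf
  {0: .35, 1: .25, 2: .12, 3: .05, 4: .03, 5: .02, never: .18}; the
  never-engaged mass matches the share of patients without an initial
  encounter at trial scale, and the delay profile puts pre-engagement
  minutes near one-seventh of all minutes.
* **Counts** per engaged month are Poisson (follow-ups 1.25, contact
  attempts 1.4, consultations 1.0; pre-engagement months draw attempts only,
  at rate 3.5) — totals only are known at trial scale, so the simplest
  count model is used.
* **Durations** are normal (initial 33 ± 17, follow-up 24 ± 14,
  consultation 7 ± 5 minutes), truncated at 0.5 and rounded, so recorded
  minutes are ≥ 1; the distribution family is a modelling choice since only
  means/SDs are known. Contact attempts carry no duration in raw output.
* The first engaged month structurally contains the patient's single
  initial encounter with complete MBC and at least one consultation, placed
  at the start of the month — engagement is thereby realized downstream in
  that month, so a zero-delay cohort has zero pre-engagement minutes.
  MBC completeness on follow-ups is Bernoulli (default 0.85); the joint
  distribution of consultation presence with encounter intensity is assumed
  independent, which real caseloads need not satisfy.

`estimate_generator_params` recovers duration models by truncated-normal
maximum likelihood (lower bound 0.5, matching the sampler) and Poisson rates
from engaged relative months (the consultation rate excludes each patient's
first engaged month, where one consultation is structural). At 2,000
patients recovery is within 5 % relative error.

`fixture_trial_scale` post-processes a generated registry so each activity
type hits its reference entry count and minute total exactly
(314 / 1,925 / 4,747 / 1,582 entries; 10,216 / 45,839 / 23,735 / 11,206
minutes; 90,996 total with 5-minute attempts): surplus initial encounters
are demoted to follow-up type (each engaging patient keeps a first-month
encounter), trimming prefers months holding ≥ 2 entries of the type, and
minutes are rescaled by largest remainder with a 1-minute floor.

**What passing tests do and do not show.** The generator reproduces the
marginal structure the billing rules consume — monthly service-presence
patterns, duration scale, engagement delays — not clinical realism:
no seasonality, no within-patient duration correlation, no dependence
between consultation cadence and encounter intensity, and clinic effects
only through the FQHC flag. Aggregate outcomes on synthetic cohorts
(percent billable, per-hour revenue) land near the reference figures but
are not estimates of any real caseload; the exact-arithmetic checks use the
forced trial-scale fixture, and the engine's correctness rests on the
brute-force oracle and invariant suites rather than on synthetic realism.

## Numerical choices and edge cases

* Currency: integer cents for pricing; floats only after deliberate exact
  scaling. Rounding half-up at display time only.
* Zero-minute months (possible with zero-minute entries) classify as
  under-minimum with an empty reason map (no zero-valued buckets).
* Degenerate inputs fail loudly: schema errors name the missing column; row
  errors carry 1-based row numbers; entries dated before randomization are
  rejected rather than dropped; aggregation refuses unimputed contact
  attempts; incomplete fee schedules list the missing codes.
* Problem sizes: the oracle-equivalence suite runs 10,000 randomized
  months; monotonicity suites use 200-patient cohorts; parameter recovery
  uses 2,000 patients; the random-drop convergence check averages 200
  seeds. These sizes give comfortable statistical margins for every
  assertion while keeping the default suite fast.

## Known limitations

Documented-activity analysis only (undocumented work is invisible);
calendar-month billing ignores payer-specific rolling-window variants; the
restrictive scenario is a single preset rather than payer-specific
profiles; FQHC G0512 crediting is not uniquely determined by public rule
text (both readings are implemented); no modifier codes, place-of-service
logic, or 2025 FQHC rule changes.
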