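# cocm-billing

Billing eligibility and reimbursement-potential modelling for Collaborative
Care Model (CoCM) care-management registries.

## The problem

CoCM is a team-based model of integrated behavioral health care in primary
care: a care manager coordinates each patient's care with a psychiatric
(behavioral health) consultant and the primary care team, tracks progress in
a patient registry, and administers measurement-based care (MBC). Since 2017
CMS reimburses CoCM through dedicated billing codes — but the codes carry
strict monthly service and time requirements, and much of the work a care
manager actually documents (outreach to not-yet-engaged patients, months
without a consultant note, time beyond the monthly caps) is not billable.
This package lets health-services researchers and clinic analysts quantify
that gap: given a registry of documented activity, how many minutes could be
billed, through which codes, at what revenue per hour of care-manager
effort, and why is the rest unbillable?

## The model

The unit of analysis is the **patient calendar month** inside a six-month
intervention window starting at randomization (or enrollment). For each
month the pipeline:

1. **Aggregates** registry entries (initial/follow-up care-manager
   encounters, contact attempts at an assumed 5 minutes each, consultant
   consultations) into total minutes and service-presence flags.
2. **Evaluates service requirements.** CoCM codes require all of
   {care-manager encounter, behavioral-health-consultant consultation,
   complete MBC (≥ 50 % of items answered)}; General BHI codes require only
   {care-manager encounter, MBC}.
3. **Assigns codes** by deterministic precedence. Non-FQHC CoCM codes are
   timed-range codes under the CPT *half-plus-one* rule (billable from
   ⌊max/2⌋+1 minutes): 99492 (initial, 36–70 min), 99493 (follow-up, 31–60),
   99494 (add-on, 16–30, up to twice monthly), with G2214 (16–30) when the
   base minimum is unmet and 99484 (set 20 min) for BHI-only months. FQHCs
   bill set-amount G-codes: G0512 (70 min qualifying minimum the first time,
   60 after) and G0511 (20 min). An initial month too short for 99492 bills
   the fallback and the initial code is deferred to the next month.
   Unbilled minutes are categorized: missing services, under minimum, over
   maximum, or code-unavailable under a *restrictive* payer scenario that
   drops 99484 and G2214.
4. **Prices** line items against a fee schedule (2024 Medicare non-facility
   rates built in) and reports revenue per hour as total revenue divided by
   **all** documented hours, billable or not.

A seeded synthetic registry generator reproduces the statistical structure
this analysis consumes (engagement delays, Poisson activity counts,
truncated-normal durations), including a trial-scale fixture whose per-type
entry counts and minute totals are forced exactly (90,996 minutes overall).

## Worked example

`examples/02_billing_walkthrough.py` pushes one patient's months
(20, 50, 140 minutes, all services met) through the engine:

```
month 1:  20 min -> G2214@20min                              revenue $57.25  unbillable {}
month 2:  50 min -> 99492@50min                              revenue $153.12  unbillable {}
month 3: 140 min -> 99493@60min, 99494@30min, 99494@30min    revenue $258.31  unbillable {'OVER_MAXIMUM': 20}
```

Month 1 is under the 36-minute 99492 minimum, so the CoCM management code
bills it and the initial code is deferred; month 2 bills the deferred
99492; month 3 fills 99493 to its 60-minute cap plus two add-ons, leaving
20 minutes over-maximum. `examples/03_scenario_grid.py` runs the full grid
on the trial-scale fixture:

```
scenario/scope                minutes billable%   $/hour
expansive/combined              90996       55%    94.73
expansive/non_fqhc              45935       67%   105.27
expansive/fqhc                  45061       43%    83.98
restrictive/combined            90996       49%    85.78
restrictive/non_fqhc            45935       55%    87.55
restrictive/fqhc                45061       43%    83.98
```

Roughly half of documented care-manager time is billable even under ideal
(expansive) conditions; the restrictive scenario lowers non-FQHC revenue,
while FQHC results are identical in both scenarios because both FQHC
G-codes are billable in either. The other examples cover simulation,
the ineligibility taxonomy, and the sensitivity analyses.

There is also a thin CLI:

```bash
cocm-billing simulate --n-patients 381 --seed 0 --out-dir sim/
cocm-billing run --registry sim/registry.csv --patients sim/patients.csv --out-dir out/
cocm-billing grid --registry sim/registry.csv --patients sim/patients.csv --out-dir grid/
```

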