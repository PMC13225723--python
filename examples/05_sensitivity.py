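"""The three sensitivity analyses around the expansive baseline.

(1) alternative fee schedules (shown here with a uniformly halved schedule,
since state Medicaid rates are user-supplied inputs); (2) assuming each
contact attempt took 10 minutes instead of 5; (3) assuming 40% of billable
months are never actually billed.
"""

from cocm_billing import (
    MEDICARE_2024,
    apply_unbilled_fraction,
    expansive_scenario,
    fixture_trial_scale,
    run_scenario,
    summarize,
)

entries, patients = fixture_trial_scale(seed=0)
baseline = run_scenario(entries, patients, expansive_scenario())
print(f"baseline:            ${baseline.report.display_revenue_per_hour:.2f}/hour")

half_rates = MEDICARE_2024.scaled(0.5, name="half_medicare")
halved = run_scenario(entries, patients, expansive_scenario(fee_schedule=half_rates))
print(f"half-rate schedule:  ${halved.report.display_revenue_per_hour:.2f}/hour")

ten = run_scenario(entries, patients, expansive_scenario(contact_attempt_minutes=10))
print(f"10-min attempts:     ${ten.report.display_revenue_per_hour:.2f}/hour")

scaled = summarize(apply_unbilled_fraction(baseline.decisions, 0.4))
print(f"40% months unbilled: ${scaled.display_revenue_per_hour:.2f}/hour")
# Halving rates exactly halves the per-hour figure; 10-minute attempts grow
# the denominator (all documented time) faster than any billable gain; the
# 40% unbilled assumption scales revenue per hour by exactly 0.6.
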