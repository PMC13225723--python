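"""Why minutes go unbilled: the ineligibility taxonomy.

Splits unbillable minutes into missing-service months (with the subset of
missing requirements), under-minimum and over-maximum time, and — in the
restrictive scenario — months billable only through excluded codes. Also
reports pre-engagement minutes: documented time before the first month in
which all three CoCM service requirements were met.
"""

from cocm_billing import expansive_scenario, fixture_trial_scale, run_scenario

entries, patients = fixture_trial_scale(seed=0)
result = run_scenario(entries, patients, expansive_scenario())
b = result.breakdown

print(f"total minutes: {b.total_minutes}, unbillable: {b.unbillable_minutes}")
for reason, minutes in sorted(b.minutes_by_reason.items(), key=lambda kv: -kv[1]):
    print(f"  {reason.value:<28} {minutes:>6} min")
print("missing-service months by gap subset (all minutes of those months):")
for gap, minutes in sorted(b.service_gap_minutes.items(), key=lambda kv: -kv[1]):
    label = "+".join(sorted(c.value for c in gap))
    print(f"  missing {label:<28} {minutes:>6} min")
if b.over_under_ratio is not None:
    print(f"over/under time-ineligible ratio: {b.over_under_ratio:.1f}")
print(
    f"pre-engagement unbillable: {b.pre_engagement_unbillable_minutes} min "
    f"({b.pre_engagement_share_of_unbillable:.0f}% of unbillable, "
    f"{b.pre_engagement_share_of_total:.0f}% of all minutes)"
)
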