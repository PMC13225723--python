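"""Run the expansive/restrictive scenario grid on the trial-scale registry.

The trial-scale fixture forces per-activity-type entry counts and minute
totals to a fixed reference (90,996 minutes overall), then the grid reports
percent billable and reimbursement per hour for each payer scenario and
practice setting.
"""

from cocm_billing import fixture_trial_scale, run_grid

entries, patients = fixture_trial_scale(seed=0)
reports = run_grid(entries, patients)

print(f"{'scenario/scope':<28} {'minutes':>8} {'billable%':>9} {'$/hour':>8}")
for (scenario, scope), r in reports.items():
    print(
        f"{scenario + '/' + scope:<28} {r.total_minutes:>8} "
        f"{r.display_percent_billable:>8}% {r.display_revenue_per_hour:>8.2f}"
    )
# Restrictive never beats expansive (it drops 99484 and G2214 for
# non-FQHCs); the FQHC rows are identical across scenarios because both
# FQHC G-codes are billable in either.
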