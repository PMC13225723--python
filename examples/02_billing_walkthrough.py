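"""Walk one patient's months through the billing rules engine.

Shows the initial-code deferral: a first qualified month that is too short
for the initial CoCM code (99492 needs 36-70 minutes) bills the CoCM
management code G2214 instead, and 99492 is attempted again the next month.
"""

import datetime as dt

from cocm_billing import (
    MEDICARE_2024,
    evaluate_services,
    expansive_scenario,
    price_decisions,
    process_patient,
)
from cocm_billing.registry import ActivityType, PatientMonth


def month(total, index):
    return PatientMonth(
        patient_id="P1",
        year_month=dt.date(2022, 2 + index, 1),
        total_minutes=total,
        minutes_by_type={ActivityType.FOLLOWUP_CM_ENCOUNTER: total},
        has_cm_encounter=True,
        has_bhc_consult=True,
        has_mbc=True,
        month_index=index,
    )


profiles = [evaluate_services(month(t, i + 1)) for i, t in enumerate([20, 50, 140])]
decisions = price_decisions(
    process_patient(profiles, expansive_scenario(), is_fqhc=False), MEDICARE_2024
)

for d in decisions:
    codes = ", ".join(f"{i.code}@{i.credited_minutes}min" for i in d.line_items) or "(none)"
    reasons = {r.value: m for r, m in d.unbillable_by_reason.items()}
    print(
        f"month {d.month_index}: {d.total_minutes:>3} min -> {codes:<40}"
        f" revenue ${d.revenue_cents / 100:.2f}  unbillable {reasons}"
    )
# Month 1 (20 min) is under the 99492 minimum: G2214 bills it and the
# initial code is deferred. Month 3 (140 min) fills 99493 to its 60-minute
# maximum plus two 99494 add-ons; the remaining 20 minutes are over-maximum.
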