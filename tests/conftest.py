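import datetime as dt

import pytest

from cocm_billing.registry import (
    ActivityType,
    PatientMonth,
    PatientRecord,
    RegistryEntry,
)


@pytest.fixture
def patient():
    return PatientRecord("P1", "C1", dt.date(2022, 3, 10), is_fqhc=False)


@pytest.fixture
def fqhc_patient():
    return PatientRecord("P2", "C2", dt.date(2022, 3, 10), is_fqhc=True)


def make_month(
    total=40,
    has_cm=True,
    has_bhc=True,
    has_mbc=True,
    patient_id="P1",
    year_month=dt.date(2022, 3, 1),
    month_index=1,
):
    """A patient-month with the given service flags; minutes lumped by type."""
    by_type = {}
    if total > 0:
        if has_cm:
            by_type[ActivityType.FOLLOWUP_CM_ENCOUNTER] = total
        else:
            by_type[ActivityType.CONTACT_ATTEMPT] = total
    return PatientMonth(
        patient_id=patient_id,
        year_month=year_month,
        total_minutes=total,
        minutes_by_type=by_type,
        has_cm_encounter=has_cm,
        has_bhc_consult=has_bhc,
        has_mbc=has_mbc,
        month_index=month_index,
    )


@pytest.fixture
def small_registry(patient):
    """One patient, two calendar months: outreach only, then full services."""
    d = patient.randomization_date
    entries = [
        RegistryEntry("P1", "C1", d, ActivityType.CONTACT_ATTEMPT),
        RegistryEntry("P1", "C1", d + dt.timedelta(days=3), ActivityType.CONTACT_ATTEMPT),
        RegistryEntry(
            "P1", "C1", dt.date(2022, 4, 2), ActivityType.INITIAL_CM_ENCOUNTER,
            minutes=33, mbc_fraction_answered=0.8,
        ),
        RegistryEntry("P1", "C1", dt.date(2022, 4, 5), ActivityType.BHC_CONSULTATION, minutes=7),
    ]
    return entries, [patient]
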