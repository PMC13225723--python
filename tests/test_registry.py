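import datetime as dt

import pytest
from hypothesis import given, settings, strategies as st

from cocm_billing.errors import ConfigError, RegistryValidationError, SchemaError
from cocm_billing.registry import (
    ActivityType,
    PatientRecord,
    RegistryEntry,
    add_months,
    aggregate_months,
    impute_contact_minutes,
    load_patients,
    load_registry,
    month_index,
)

REG_HEADER = "patient_id,clinic_id,date,activity_type,minutes,mbc_fraction_answered\n"


def write_csv(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadRegistry:
    def test_one_row_per_activity_type_parses(self, tmp_path):
        p = write_csv(
            tmp_path,
            "r.csv",
            REG_HEADER
            + "P1,C1,2022-03-10,INITIAL_CM_ENCOUNTER,33,0.8\n"
            + "P1,C1,2022-03-15,FOLLOWUP_CM_ENCOUNTER,24,0.6\n"
            + "P1,C1,2022-03-16,CONTACT_ATTEMPT,,\n"
            + "P1,C1,2022-03-20,BHC_CONSULTATION,7,\n",
        )
        result = load_registry(p)
        assert [e.activity_type for e in result.entries] == list(ActivityType)
        assert result.entries[0].minutes == 33
        assert result.entries[0].mbc_fraction_answered == 0.8
        assert result.entries[0].date == dt.date(2022, 3, 10)

    def test_contact_attempt_minutes_absent_is_accepted(self, tmp_path):
        # the registry does not allow time entry for contact attempts
        p = write_csv(tmp_path, "r.csv", REG_HEADER + "P1,C1,2022-03-16,CONTACT_ATTEMPT,,\n")
        (entry,) = load_registry(p).entries
        assert entry.minutes is None

    @pytest.mark.parametrize(
        "row, fragment",
        [
            ("P1,C1,2022-03-10,INITIAL_CM_ENCOUNTER,-5,", "negative"),
            ("P1,C1,2022-03-10,INITIAL_CM_ENCOUNTER,,", "missing minutes"),
            ("P1,C1,not-a-date,BHC_CONSULTATION,7,", "date"),
            ("P1,C1,2022-03-10,TELEPATHY,5,", "activity_type"),
            ("P1,C1,2022-03-10,BHC_CONSULTATION,7,0.5", "care-manager encounter"),
            ("P1,C1,2022-03-10,INITIAL_CM_ENCOUNTER,30,1.7", "[0, 1]"),
        ],
    )
    def test_bad_rows_rejected_with_diagnostics(self, tmp_path, row, fragment):
        p = write_csv(tmp_path, "r.csv", REG_HEADER + row + "\n")
        with pytest.raises(RegistryValidationError) as err:
            load_registry(p)
        assert fragment in str(err.value)
        assert err.value.issues[0].row == 1

    def test_missing_column_names_the_column(self, tmp_path):
        p = write_csv(tmp_path, "r.csv", "patient_id,clinic_id,date,minutes\nP1,C1,2022-01-01,5\n")
        with pytest.raises(SchemaError, match="activity_type"):
            load_registry(p)

    def test_column_mapping(self, tmp_path):
        p = write_csv(
            tmp_path,
            "r.csv",
            "pid,clinic,when,what,mins,mbc\nP1,C1,2022-03-10,BHC_CONSULTATION,7,\n",
        )
        result = load_registry(
            p,
            column_map={
                "patient_id": "pid", "clinic_id": "clinic", "date": "when",
                "activity_type": "what", "minutes": "mins", "mbc_fraction_answered": "mbc",
            },
        )
        assert result.entries[0].patient_id == "P1"

    def test_load_patients(self, tmp_path):
        p = write_csv(
            tmp_path,
            "p.csv",
            "patient_id,clinic_id,randomization_date,is_fqhc\nP1,C1,2022-03-10,1\nP2,C2,2022-04-01,0\n",
        )
        pats = load_patients(p).entries
        assert pats[0].is_fqhc and not pats[1].is_fqhc


class TestImputeContactMinutes:
    def test_attempts_get_fixed_minutes_others_unchanged(self):
        entries = [
            RegistryEntry("P1", "C1", dt.date(2022, 1, 1), ActivityType.CONTACT_ATTEMPT),
            RegistryEntry("P1", "C1", dt.date(2022, 1, 2), ActivityType.CONTACT_ATTEMPT),
            RegistryEntry("P1", "C1", dt.date(2022, 1, 3), ActivityType.CONTACT_ATTEMPT),
            RegistryEntry("P1", "C1", dt.date(2022, 1, 4), ActivityType.BHC_CONSULTATION, minutes=7),
        ]
        out = impute_contact_minutes(entries, 5)
        attempt_total = sum(e.minutes for e in out if e.activity_type is ActivityType.CONTACT_ATTEMPT)
        assert attempt_total == 15
        assert out[3].minutes == 7

    @pytest.mark.parametrize("n,per,total", [(4747, 5, 23735), (4747, 10, 47470)])
    def test_trial_scale_attempt_totals(self, n, per, total):
        entries = [
            RegistryEntry("P1", "C1", dt.date(2022, 1, 1), ActivityType.CONTACT_ATTEMPT)
        ] * n
        out = impute_contact_minutes(entries, per)
        assert sum(e.minutes for e in out) == total

    def test_nonpositive_minutes_is_config_error(self):
        with pytest.raises(ConfigError):
            impute_contact_minutes([], 0)

    @given(k=st.integers(min_value=1, max_value=30), n=st.integers(min_value=0, max_value=50))
    @settings(max_examples=30, deadline=None)
    def test_rescaling_is_linear_in_per_attempt_minutes(self, k, n):
        entries = [
            RegistryEntry("P1", "C1", dt.date(2022, 1, 1), ActivityType.CONTACT_ATTEMPT)
        ] * n + [RegistryEntry("P1", "C1", dt.date(2022, 1, 2), ActivityType.BHC_CONSULTATION, minutes=9)]
        base = impute_contact_minutes(entries, 5)
        scaled = impute_contact_minutes(entries, k)

        def attempt_total(es):
            return sum(e.minutes for e in es if e.activity_type is ActivityType.CONTACT_ATTEMPT)

        assert attempt_total(scaled) * 5 == attempt_total(base) * k
        assert scaled[-1].minutes == base[-1].minutes == 9


class TestAggregateMonths:
    def test_direct_aggregation_with_all_services(self, patient):
        d = patient.randomization_date
        entries = [
            RegistryEntry("P1", "C1", d, ActivityType.INITIAL_CM_ENCOUNTER, 33, 0.8),
            RegistryEntry("P1", "C1", d + dt.timedelta(days=2), ActivityType.BHC_CONSULTATION, 7),
        ]
        (m,) = aggregate_months(entries, [patient])
        assert m.total_minutes == 40
        assert m.has_cm_encounter and m.has_bhc_consult and m.has_mbc
        assert m.month_index == 1

    def test_entries_past_window_are_truncated(self, patient):
        late = add_months(patient.randomization_date, 7)
        entries = [RegistryEntry("P1", "C1", late, ActivityType.BHC_CONSULTATION, 7)]
        assert aggregate_months(entries, [patient]) == []

    def test_window_is_half_open_at_six_months(self, patient):
        edge = add_months(patient.randomization_date, 6)
        inside = edge - dt.timedelta(days=1)
        entries = [
            RegistryEntry("P1", "C1", edge, ActivityType.BHC_CONSULTATION, 7),
            RegistryEntry("P1", "C1", inside, ActivityType.BHC_CONSULTATION, 9),
        ]
        months = aggregate_months(entries, [patient])
        assert sum(m.total_minutes for m in months) == 9

    def test_incomplete_mbc_does_not_count(self, patient):
        d = patient.randomization_date
        entries = [RegistryEntry("P1", "C1", d, ActivityType.FOLLOWUP_CM_ENCOUNTER, 24, 0.4)]
        (m,) = aggregate_months(entries, [patient])
        assert m.has_cm_encounter and not m.has_mbc

    def test_entry_before_randomization_rejected(self, patient):
        early = patient.randomization_date - dt.timedelta(days=1)
        entries = [RegistryEntry("P1", "C1", early, ActivityType.CONTACT_ATTEMPT, 5)]
        with pytest.raises(RegistryValidationError, match="before randomization"):
            aggregate_months(entries, [patient])

    def test_unimputed_contact_attempt_rejected(self, patient):
        entries = [
            RegistryEntry("P1", "C1", patient.randomization_date, ActivityType.CONTACT_ATTEMPT)
        ]
        with pytest.raises(RegistryValidationError, match="impute"):
            aggregate_months(entries, [patient])

    @given(
        data=st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=200),  # day offset within window
                st.sampled_from(list(ActivityType)),
                st.integers(min_value=0, max_value=120),
            ),
            max_size=40,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_minute_conservation(self, data):
        """Sum over patient-months equals sum over in-window imputed entries."""
        rand = dt.date(2022, 3, 10)
        patient = PatientRecord("P1", "C1", rand, False)
        end = add_months(rand, 6)
        entries = [
            RegistryEntry(
                "P1", "C1", rand + dt.timedelta(days=off), t,
                minutes=None if t is ActivityType.CONTACT_ATTEMPT else m,
            )
            for off, t, m in data
        ]
        imputed = impute_contact_minutes(entries, 5)
        months = aggregate_months(imputed, [patient])
        expected = sum(e.minutes for e in imputed if e.date < end)
        assert sum(m.total_minutes for m in months) == expected
        for m in months:
            assert m.total_minutes == sum(m.minutes_by_type.values())


def test_month_index_starts_at_randomization_month():
    rand = dt.date(2022, 3, 10)
    assert month_index(rand, dt.date(2022, 3, 31)) == 1
    assert month_index(rand, dt.date(2022, 9, 1)) == 7
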