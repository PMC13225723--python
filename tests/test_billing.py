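import datetime as dt

import pytest
from hypothesis import given, settings, strategies as st

from cocm_billing.billing import (
    MonthBillingState,
    Reason,
    assign_codes,
    half_plus_one_minimum,
    process_patient,
)
from cocm_billing.eligibility import evaluate_services
from cocm_billing.errors import ConfigError
from cocm_billing.scenarios import expansive_scenario, restrictive_scenario
from conftest import make_month


def decide(total, has_cm=True, has_bhc=True, has_mbc=True, is_fqhc=False,
           initial_billed=False, scenario=None):
    scenario = scenario or expansive_scenario()
    month = make_month(total=total, has_cm=has_cm, has_bhc=has_bhc, has_mbc=has_mbc)
    profile = evaluate_services(month)
    state = MonthBillingState(initial_billed=initial_billed)
    return assign_codes(month, profile, state, scenario, is_fqhc)


def items_of(decision):
    return [(i.code, i.credited_minutes) for i in decision.line_items]


def reasons_of(decision):
    return {r.value: m for r, m in decision.unbillable_by_reason.items()}


class TestHalfPlusOne:
    @pytest.mark.parametrize("maximum, minimum", [(70, 36), (60, 31), (30, 16)])
    def test_published_ranges(self, maximum, minimum):
        assert half_plus_one_minimum(maximum) == minimum

    def test_nonpositive_is_config_error(self):
        with pytest.raises(ConfigError):
            half_plus_one_minimum(0)


class TestAssignCodesNonFqhc:
    def test_initial_month_in_range(self):
        d, _ = decide(50)
        assert items_of(d) == [("99492", 50)]
        assert d.billable_minutes == 50 and not d.unbillable_by_reason

    def test_follow_up_with_two_addons_and_overflow(self):
        d, _ = decide(140, initial_billed=True)
        assert items_of(d) == [("99493", 60), ("99494", 30), ("99494", 30)]
        assert reasons_of(d) == {"OVER_MAXIMUM": 20}

    def test_restrictive_follow_up_under_base_minimum_is_unavailable(self):
        d, _ = decide(25, initial_billed=True, scenario=restrictive_scenario())
        assert items_of(d) == []
        assert reasons_of(d) == {"CODE_UNAVAILABLE_RESTRICTIVE": 25}

    def test_initial_gap_bills_management_code_with_excess(self):
        # 31-35 minutes: under the 99492 minimum but over the G2214 maximum
        d, _ = decide(33)
        assert items_of(d) == [("G2214", 30)]
        assert reasons_of(d) == {"OVER_MAXIMUM": 3}

    def test_below_all_minimums_is_under_minimum(self):
        d, _ = decide(10)
        assert items_of(d) == []
        assert reasons_of(d) == {"UNDER_MINIMUM": 10}

    def test_bhi_only_month_bills_general_bhi(self):
        d, _ = decide(45, has_bhc=False)
        assert items_of(d) == [("99484", 20)]
        assert reasons_of(d) == {"OVER_MAXIMUM": 25}

    def test_bhi_only_restrictive_is_fully_unavailable(self):
        d, _ = decide(45, has_bhc=False, scenario=restrictive_scenario())
        assert reasons_of(d) == {"CODE_UNAVAILABLE_RESTRICTIVE": 45}

    def test_attempts_only_is_missing_services(self):
        d, _ = decide(15, has_cm=False, has_bhc=False, has_mbc=False)
        assert reasons_of(d) == {"MISSING_SERVICES": 15}
        assert d.service_gap and len(d.service_gap) == 3

    def test_billing_initial_code_flips_state(self):
        _, state = decide(50)
        assert state.initial_billed
        _, state = decide(25)  # G2214 does not start the follow-up sequence
        assert not state.initial_billed


class TestAssignCodesFqhc:
    def test_first_qualified_month_credits_set_amount(self):
        d, state = decide(80, is_fqhc=True)
        assert items_of(d) == [("G0512", 70)]
        assert reasons_of(d) == {"OVER_MAXIMUM": 10}
        assert state.initial_billed

    def test_subsequent_month_uses_sixty_minute_minimum(self):
        d, _ = decide(65, is_fqhc=True, initial_billed=True)
        assert items_of(d) == [("G0512", 60)]
        assert reasons_of(d) == {"OVER_MAXIMUM": 5}

    def test_under_g0512_minimum_falls_back_to_g0511(self):
        d, _ = decide(45, is_fqhc=True)
        assert items_of(d) == [("G0511", 20)]
        assert reasons_of(d) == {"OVER_MAXIMUM": 25}

    def test_under_twenty_minutes_unbillable(self):
        d, _ = decide(10, is_fqhc=True)
        assert reasons_of(d) == {"UNDER_MINIMUM": 10}

    def test_restrictive_identical_for_fqhc(self):
        for total in (10, 45, 80):
            exp, _ = decide(total, is_fqhc=True)
            res, _ = decide(total, is_fqhc=True, scenario=restrictive_scenario())
            assert items_of(exp) == items_of(res)
            assert reasons_of(exp) == reasons_of(res)

    def test_actual_minutes_credit_mode(self):
        scenario = expansive_scenario(fqhc_credit_mode="actual_minutes")
        d, _ = decide(80, is_fqhc=True, scenario=scenario)
        assert items_of(d) == [("G0512", 80)]
        assert not d.unbillable_by_reason

    def test_setting_mismatch_is_config_error(self):
        with pytest.raises(ConfigError):
            decide(50, is_fqhc=True, scenario=expansive_scenario(setting="non_fqhc"))


class TestProcessPatient:
    def profiles(self, totals, **flags):
        months = [
            make_month(total=t, year_month=dt.date(2022, 3 + i, 1), month_index=i + 1, **flags)
            for i, t in enumerate(totals)
        ]
        return [evaluate_services(m) for m in months]

    def test_initial_code_deferred_after_short_first_month(self):
        d1, d2 = process_patient(self.profiles([20, 50]), expansive_scenario(), False)
        assert items_of(d1) == [("G2214", 20)]
        assert items_of(d2) == [("99492", 50)]

    def test_canonical_initial_then_follow_up(self):
        d1, d2 = process_patient(self.profiles([50, 40]), expansive_scenario(), False)
        assert items_of(d1) == [("99492", 50)]
        assert items_of(d2) == [("99493", 40)]

    def test_fqhc_seventy_minimum_attaches_to_first_g0512(self):
        d1, d2 = process_patient(self.profiles([40, 75]), expansive_scenario(), True)
        assert items_of(d1) == [("G0511", 20)] and reasons_of(d1) == {"OVER_MAXIMUM": 20}
        assert items_of(d2) == [("G0512", 70)] and reasons_of(d2) == {"OVER_MAXIMUM": 5}

    def test_pre_engagement_flagging(self):
        months = [
            make_month(total=15, has_cm=False, has_bhc=False, has_mbc=False,
                       year_month=dt.date(2022, 3, 1), month_index=1),
            make_month(total=50, year_month=dt.date(2022, 4, 1), month_index=2),
        ]
        d1, d2 = process_patient([evaluate_services(m) for m in months],
                                 expansive_scenario(), False)
        assert d1.pre_engagement and not d2.pre_engagement

    def test_unsorted_months_rejected(self):
        profiles = self.profiles([50, 40])[::-1]
        with pytest.raises(ValueError, match="sorted"):
            process_patient(profiles, expansive_scenario(), False)


@given(
    total=st.integers(min_value=0, max_value=250),
    cm=st.booleans(), bhc=st.booleans(), mbc=st.booleans(),
    fqhc=st.booleans(), initial=st.booleans(), restrictive=st.booleans(),
)
@settings(max_examples=300, deadline=None)
def test_minute_conservation_and_credit_ranges(total, cm, bhc, mbc, fqhc, initial, restrictive):
    """Billable + unbillable minutes always partition the month's total, and
    every credited instance respects its code's printed time model."""
    mbc = mbc and cm
    scenario = restrictive_scenario() if restrictive else expansive_scenario()
    d, _ = decide(total, has_cm=cm, has_bhc=bhc, has_mbc=mbc, is_fqhc=fqhc,
                  initial_billed=initial, scenario=scenario)
    assert d.billable_minutes + d.unbillable_minutes == total
    ranges = {"99492": (36, 70), "99493": (31, 60), "99494": (16, 30), "G2214": (16, 30)}
    for item in d.line_items:
        if item.code in ranges:
            lo, hi = ranges[item.code]
            assert lo <= item.credited_minutes <= hi
        elif item.code in ("99484", "G0511"):
            assert item.credited_minutes == 20
        elif item.code == "G0512":
            assert item.credited_minutes in (60, 70)
    # restrictive never bills the excluded codes
    if restrictive:
        assert all(i.code not in ("99484", "G2214") for i in d.line_items)
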