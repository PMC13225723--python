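"""The CoCM/BHI billing rules engine.

Assigns billing codes to patient-months under 2024 Medicare rules:

* non-FQHC CoCM codes (99492 initial, 99493 follow-up, 99494 add-on) are
  timed-range codes under the CPT "half-plus-one" convention — billable once
  service time reaches one minute over half the monthly maximum;
* G2214 (CoCM management) covers 16-30 minutes when the base CoCM code's
  minimum is not reached; 99484 is the non-FQHC General BHI code (a set
  20-minute amount);
* FQHCs bill set-amount G-codes instead: G0512 (psychiatric CoCM; qualifying
  minimum 70 minutes the first time it is billed for a patient, 60 after)
  and G0511 (General BHI, 20 minutes).

Precedence per month: if the CoCM service triple is met, the base CoCM code
is attempted first, then add-ons (non-FQHC, up to two 99494 per month), then
the management/General-BHI fallbacks; if only the General BHI services are
met, only the BHI code is attempted. Minutes that no code can absorb are
categorized as over-maximum, under-minimum, missing-services, or
unavailable-in-scenario. An initial month too short for 99492 bills the
fallback and the initial CoCM code is attempted again the following month.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Sequence

from .eligibility import ServiceProfile, build_engagement_timeline
from .errors import ConfigError
from .registry import PatientMonth

__all__ = [
    "Reason",
    "CodeDef",
    "CODES",
    "NON_FQHC_CODES",
    "FQHC_CODES",
    "EXPANSIVE_AVAILABILITY",
    "RESTRICTIVE_AVAILABILITY",
    "LineItem",
    "MonthBillingState",
    "BillingDecision",
    "half_plus_one_minimum",
    "assign_codes",
    "process_patient",
]


class Reason(str, Enum):
    """Why documented minutes could not be billed."""

    MISSING_SERVICES = "MISSING_SERVICES"
    UNDER_MINIMUM = "UNDER_MINIMUM"
    OVER_MAXIMUM = "OVER_MAXIMUM"
    CODE_UNAVAILABLE_RESTRICTIVE = "CODE_UNAVAILABLE_RESTRICTIVE"
    NOT_BILLED = "NOT_BILLED"  # sensitivity: eligible month assumed not billed


def half_plus_one_minimum(max_minutes: int) -> int:
    """CPT half-plus-one rule: minimum billable time for a timed-range code.

    A range code becomes billable at 50% of its maximum plus one minute
    (e.g. a 70-minute maximum yields a 36-minute minimum).
    """
    if max_minutes < 1:
        raise ConfigError(f"max_minutes must be >= 1, got {max_minutes}")
    return max_minutes // 2 + 1


@dataclass(frozen=True)
class CodeDef:
    """Static definition of one billing code's time model and limits."""

    code: str
    setting: str  # "non_fqhc" | "fqhc"
    kind: str  # "range" | "set"
    max_minutes: int  # range max, or set amount
    min_minutes: int  # range min (half-plus-one), or qualifying minimum
    monthly_frequency_limit: int
    role: str


CODES: dict[str, CodeDef] = {
    "99492": CodeDef("99492", "non_fqhc", "range", 70, half_plus_one_minimum(70), 1, "COCM_BASE_INITIAL"),
    "99493": CodeDef("99493", "non_fqhc", "range", 60, half_plus_one_minimum(60), 1, "COCM_BASE_FOLLOWUP"),
    "99494": CodeDef("99494", "non_fqhc", "range", 30, half_plus_one_minimum(30), 2, "COCM_ADDON"),
    "G2214": CodeDef("G2214", "non_fqhc", "range", 30, half_plus_one_minimum(30), 1, "COCM_MANAGEMENT"),
    "99484": CodeDef("99484", "non_fqhc", "set", 20, 20, 1, "GENERAL_BHI"),
    "G0511": CodeDef("G0511", "fqhc", "set", 20, 20, 1, "GENERAL_BHI"),
    # G0512's set amount is 70 for the patient's first G0512 month, 60 after;
    # resolved at assignment time from the billing state.
    "G0512": CodeDef("G0512", "fqhc", "set", 70, 70, 1, "COCM_FQHC"),
}

NON_FQHC_CODES = frozenset(c for c, d in CODES.items() if d.setting == "non_fqhc")
FQHC_CODES = frozenset(c for c, d in CODES.items() if d.setting == "fqhc")

#: All codes billable (the expansive payer scenario).
EXPANSIVE_AVAILABILITY: dict[str, bool] = {c: True for c in CODES}
#: Only the commonly-reimbursed codes; 99484 and G2214 are excluded for
#: non-FQHCs, the FQHC G-codes are always available.
RESTRICTIVE_AVAILABILITY: dict[str, bool] = {
    **{c: True for c in CODES},
    "99484": False,
    "G2214": False,
}


@dataclass(frozen=True)
class LineItem:
    """One billed instance of a code with the minutes credited to it."""

    code: str
    credited_minutes: int


@dataclass(frozen=True)
class MonthBillingState:
    """Cross-month billing memory for one patient.

    ``initial_billed`` becomes true once the initial CoCM code has been
    billed — 99492 for non-FQHC patients, the first G0512 for FQHC patients —
    and stays true (it selects 99493 vs 99492 and the 60- vs 70-minute G0512
    qualifying minimum).
    """

    initial_billed: bool = False


@dataclass(frozen=True)
class BillingDecision:
    """Outcome of billing one patient-month.

    Minutes are conserved: ``billable_minutes`` plus the sum over
    ``unbillable_by_reason`` equals ``total_minutes``. ``revenue_cents`` is
    set by pricing (float to allow exact fractional scaling in sensitivity
    analyses; pricing itself is integer cents).
    """

    patient_id: str
    year_month: dt.date
    month_index: int
    is_fqhc: bool
    total_minutes: int
    line_items: tuple[LineItem, ...]
    billable_minutes: int
    unbillable_by_reason: Mapping[Reason, int]
    pre_engagement: bool = False
    service_gap: frozenset | None = None  # missing CoCM components, if any
    revenue_cents: float | None = None

    @property
    def unbillable_minutes(self) -> int:
        return sum(self.unbillable_by_reason.values())


def _decision(month, is_fqhc, items, reasons, gap) -> BillingDecision:
    billable = sum(i.credited_minutes for i in items)
    reasons = {r: m for r, m in reasons.items() if m > 0}
    assert billable + sum(reasons.values()) == month.total_minutes
    return BillingDecision(
        patient_id=month.patient_id,
        year_month=month.year_month,
        month_index=month.month_index,
        is_fqhc=is_fqhc,
        total_minutes=month.total_minutes,
        line_items=tuple(items),
        billable_minutes=billable,
        unbillable_by_reason=reasons,
        service_gap=gap,
    )


def assign_codes(
    month: PatientMonth,
    profile: ServiceProfile,
    state: MonthBillingState,
    scenario: "ScenarioConfig",
    is_fqhc: bool,
) -> tuple[BillingDecision, MonthBillingState]:
    """Bill one patient-month; returns the decision and the updated state.

    Reasons are assessed in order: service requirements first, then scenario
    code availability, then time thresholds. When the only code(s) that could
    have billed the month are excluded by the scenario, the whole month is
    categorized CODE_UNAVAILABLE_RESTRICTIVE.
    """
    if scenario.setting == "fqhc" and not is_fqhc:
        raise ConfigError("non-FQHC patient-month under an FQHC-only scenario")
    if scenario.setting == "non_fqhc" and is_fqhc:
        raise ConfigError("FQHC patient-month under a non-FQHC-only scenario")

    avail = scenario.code_availability
    total = month.total_minutes
    gap = None if profile.cocm_services_met else profile.missing_components

    if not profile.bhi_services_met and not profile.cocm_services_met:
        return (
            _decision(month, is_fqhc, [], {Reason.MISSING_SERVICES: total}, gap),
            state,
        )

    if is_fqhc:
        return _assign_fqhc(month, profile, state, scenario, gap)
    return _assign_non_fqhc(month, profile, state, scenario, gap)


def _assign_non_fqhc(month, profile, state, scenario, gap):
    avail = scenario.code_availability
    total = month.total_minutes
    is_fqhc = False

    if profile.cocm_services_met:
        base = CODES["99493"] if state.initial_billed else CODES["99492"]
        if total >= base.min_minutes:
            items = [LineItem(base.code, min(total, base.max_minutes))]
            residual = total - items[0].credited_minutes
            addon = CODES["99494"]
            n_addons = 0
            while (
                residual >= addon.min_minutes
                and n_addons < addon.monthly_frequency_limit
                and avail.get("99494", False)
            ):
                credit = min(residual, addon.max_minutes)
                items.append(LineItem("99494", credit))
                residual -= credit
                n_addons += 1
            decision = _decision(
                month, is_fqhc, items, {Reason.OVER_MAXIMUM: residual}, gap
            )
            new_state = state if state.initial_billed else replace(state, initial_billed=True)
            return decision, (new_state if base.code == "99492" else state)

        # below the base minimum: G2214 first, then the General BHI code
        g2214 = CODES["G2214"]
        if total >= g2214.min_minutes:
            if avail.get("G2214", False):
                credit = min(total, g2214.max_minutes)
                return (
                    _decision(
                        month,
                        is_fqhc,
                        [LineItem("G2214", credit)],
                        {Reason.OVER_MAXIMUM: total - credit},
                        gap,
                    ),
                    state,
                )
            if avail.get("99484", False) and total >= CODES["99484"].min_minutes:
                return (
                    _decision(
                        month,
                        is_fqhc,
                        [LineItem("99484", CODES["99484"].max_minutes)],
                        {Reason.OVER_MAXIMUM: total - CODES["99484"].max_minutes},
                        gap,
                    ),
                    state,
                )
            # some excluded code could have billed this month
            return (
                _decision(
                    month, is_fqhc, [], {Reason.CODE_UNAVAILABLE_RESTRICTIVE: total}, gap
                ),
                state,
            )
        # below 16 minutes nothing qualifies (99484 needs 20)
        return (
            _decision(month, is_fqhc, [], {Reason.UNDER_MINIMUM: total}, gap),
            state,
        )

    # General BHI services only
    bhi = CODES["99484"]
    if total < bhi.min_minutes:
        return (
            _decision(month, is_fqhc, [], {Reason.UNDER_MINIMUM: total}, gap),
            state,
        )
    if avail.get("99484", False):
        return (
            _decision(
                month,
                is_fqhc,
                [LineItem("99484", bhi.max_minutes)],
                {Reason.OVER_MAXIMUM: total - bhi.max_minutes},
                gap,
            ),
            state,
        )
    return (
        _decision(month, is_fqhc, [], {Reason.CODE_UNAVAILABLE_RESTRICTIVE: total}, gap),
        state,
    )


def _assign_fqhc(month, profile, state, scenario, gap):
    avail = scenario.code_availability
    total = month.total_minutes
    is_fqhc = True
    g0511 = CODES["G0511"]

    qualifying = 60 if state.initial_billed else 70
    would_g0512 = profile.cocm_services_met and total >= qualifying
    would_g0511 = total >= g0511.min_minutes

    if would_g0512 and avail.get("G0512", False):
        if scenario.fqhc_credit_mode == "actual_minutes":
            credit = total
        else:
            credit = qualifying
        return (
            _decision(
                month,
                is_fqhc,
                [LineItem("G0512", credit)],
                {Reason.OVER_MAXIMUM: total - credit},
                gap,
            ),
            replace(state, initial_billed=True),
        )
    if would_g0511 and avail.get("G0511", False):
        return (
            _decision(
                month,
                is_fqhc,
                [LineItem("G0511", g0511.max_minutes)],
                {Reason.OVER_MAXIMUM: total - g0511.max_minutes},
                gap,
            ),
            state,
        )
    if would_g0512 or would_g0511:
        return (
            _decision(month, is_fqhc, [], {Reason.CODE_UNAVAILABLE_RESTRICTIVE: total}, gap),
            state,
        )
    return (
        _decision(month, is_fqhc, [], {Reason.UNDER_MINIMUM: total}, gap),
        state,
    )


def process_patient(
    profiles: Sequence[ServiceProfile],
    scenario: "ScenarioConfig",
    is_fqhc: bool,
) -> list[BillingDecision]:
    """Bill all of one patient's months in chronological order.

    Threads the billing state across months (initial-code deferral: a month
    too short for the initial CoCM code bills the fallback, and the initial
    code is attempted again in later months) and flags pre-engagement months
    from the patient's engagement timeline.
    """
    if not profiles:
        return []
    months = [p.month.year_month for p in profiles]
    if months != sorted(months) or len(set(months)) != len(months):
        raise ValueError("profiles must be sorted ascending with distinct months")

    timeline = build_engagement_timeline(profiles)
    state = MonthBillingState()
    decisions = []
    for p in profiles:
        decision, state = assign_codes(p.month, p, state, scenario, is_fqhc)
        if p.month.year_month in timeline.pre_engagement_months:
            decision = replace(decision, pre_engagement=True)
        decisions.append(decision)
    return decisions
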