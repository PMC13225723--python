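"""Pricing and summary metrics for billing decisions.

Revenue is computed at cent precision against a fee schedule (2024 Medicare
non-facility rates ship as the named default ``medicare_2024``). The headline
surfaces are: total documented minutes/hours, billable minutes and percent,
total revenue, and revenue per hour of care management — where the per-hour
denominator is ALL documented minutes in scope (billable and unbillable),
since the care manager is paid for all of them.

Display conventions: dollars rounded half-up to cents, percentages to the
nearest integer, ratios to one decimal. Exact values are retained alongside.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .billing import BillingDecision, CODES, Reason
from .errors import PricingError

__all__ = [
    "FeeSchedule",
    "MEDICARE_2024",
    "SummaryReport",
    "IneligibilityBreakdown",
    "price_decisions",
    "summarize",
    "breakdown_ineligible",
    "round_half_up",
    "revenue_per_hour",
    "percent_billable",
    "over_under_ratio",
    "report_to_dict",
    "report_rows",
]


def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention used for printed figures)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class FeeSchedule:
    """Per-instance reimbursement rates, stored as integer cents."""

    name: str
    rates_cents: Mapping[str, int]

    def __post_init__(self):
        for code, cents in self.rates_cents.items():
            if cents < 0:
                raise PricingError(f"negative rate for {code}")

    @classmethod
    def from_dollars(cls, name: str, rates: Mapping[str, float]) -> "FeeSchedule":
        return cls(
            name=name,
            rates_cents={
                code: int(round_half_up(dollars * 100))
                for code, dollars in rates.items()
            },
        )

    def rate_cents(self, code: str) -> int:
        try:
            return self.rates_cents[code]
        except KeyError:
            raise PricingError(f"fee schedule {self.name!r} has no rate for code {code}")

    def scaled(self, factor: float, name: str | None = None) -> "FeeSchedule":
        return FeeSchedule(
            name=name or f"{self.name}_x{factor}",
            rates_cents={c: int(round_half_up(r * factor)) for c, r in self.rates_cents.items()},
        )


#: 2024 Medicare non-facility payment amounts per billing instance.
MEDICARE_2024 = FeeSchedule.from_dollars(
    "medicare_2024",
    {
        "99484": 54.92,
        "99492": 153.12,
        "99493": 139.81,
        "99494": 59.25,
        "G2214": 57.25,
        "G0511": 83.88,
        "G0512": 146.57,
    },
)


def price_decisions(
    decisions: Iterable[BillingDecision], schedule: FeeSchedule
) -> list[BillingDecision]:
    """Attach per-month revenue (cents) to each decision.

    Month revenue is the sum of the schedule rate over billed instances.
    Raises :class:`PricingError` naming the code if a billed code lacks a rate.
    """
    priced = []
    for d in decisions:
        revenue = sum(schedule.rate_cents(item.code) for item in d.line_items)
        priced.append(dataclasses.replace(d, revenue_cents=float(revenue)))
    return priced


# ---------------------------------------------------------------------------
# pure metric helpers (shared by reports and identity checks)


def revenue_per_hour(revenue_cents: float, total_minutes: float) -> float:
    """Revenue in dollars per hour of documented care-manager time (exact)."""
    if total_minutes == 0:
        return 0.0
    return (revenue_cents / 100.0) / (total_minutes / 60.0)


def percent_billable(billable_minutes: float, total_minutes: float) -> float:
    """Percent of documented minutes that could be billed (exact, 0-100)."""
    if total_minutes == 0:
        return 0.0
    return 100.0 * billable_minutes / total_minutes


def over_under_ratio(over_max_minutes: float, under_min_minutes: float) -> float | None:
    """Minutes over code maximums per minute under minimums.

    Absent (None) when either side is zero — the ratio is then undefined or
    uninformative.
    """
    if under_min_minutes == 0 or over_max_minutes == 0:
        return None
    return over_max_minutes / under_min_minutes


# ---------------------------------------------------------------------------
# summary report


@dataclass(frozen=True)
class SummaryReport:
    """Aggregate reimbursement summary for one scope and scenario.

    Exact values throughout; ``display_*`` properties apply the printed
    rounding conventions.
    """

    scope: str  # "combined" | "non_fqhc" | "fqhc"
    scenario_name: str
    total_minutes: int
    billable_minutes: int
    total_revenue_cents: float
    minutes_by_code: Mapping[str, int]
    instances_by_code: Mapping[str, int]
    unbillable_by_reason: Mapping[Reason, int]
    pre_engagement_unbillable_minutes: int
    n_patient_months: int
    is_empty: bool = False

    @property
    def total_hours(self) -> float:
        return self.total_minutes / 60.0

    @property
    def percent_billable(self) -> float:
        return percent_billable(self.billable_minutes, self.total_minutes)

    @property
    def revenue_per_hour(self) -> float:
        return revenue_per_hour(self.total_revenue_cents, self.total_minutes)

    @property
    def total_revenue_dollars(self) -> float:
        return self.total_revenue_cents / 100.0

    @property
    def display_percent_billable(self) -> int:
        return int(round_half_up(self.percent_billable))

    @property
    def display_revenue_per_hour(self) -> float:
        return round_half_up(self.revenue_per_hour, 2)

    @property
    def display_total_revenue(self) -> float:
        return round_half_up(self.total_revenue_dollars, 2)


def summarize(
    decisions: Sequence[BillingDecision],
    scope: str = "combined",
    scenario_name: str = "",
) -> SummaryReport:
    """Aggregate priced decisions into a summary for the requested scope.

    ``scope`` filters to FQHC or non-FQHC patient-months ("combined" keeps
    all). An empty scope yields a zero report flagged ``is_empty``.
    """
    if scope == "combined":
        selected = list(decisions)
    elif scope == "fqhc":
        selected = [d for d in decisions if d.is_fqhc]
    elif scope == "non_fqhc":
        selected = [d for d in decisions if not d.is_fqhc]
    else:
        raise ValueError(f"unknown scope {scope!r}")

    minutes_by_code: dict[str, int] = {}
    instances_by_code: dict[str, int] = {}
    unbillable: dict[Reason, int] = {}
    total = billable = pre = months = 0
    revenue = 0.0
    for d in selected:
        months += 1
        total += d.total_minutes
        billable += d.billable_minutes
        revenue += d.revenue_cents or 0.0
        for item in d.line_items:
            minutes_by_code[item.code] = minutes_by_code.get(item.code, 0) + item.credited_minutes
            instances_by_code[item.code] = instances_by_code.get(item.code, 0) + 1
        for r, m in d.unbillable_by_reason.items():
            unbillable[r] = unbillable.get(r, 0) + m
        if d.pre_engagement:
            pre += d.unbillable_minutes

    return SummaryReport(
        scope=scope,
        scenario_name=scenario_name,
        total_minutes=total,
        billable_minutes=billable,
        total_revenue_cents=revenue,
        minutes_by_code=minutes_by_code,
        instances_by_code=instances_by_code,
        unbillable_by_reason=unbillable,
        pre_engagement_unbillable_minutes=pre,
        n_patient_months=months,
        is_empty=not selected,
    )


# ---------------------------------------------------------------------------
# ineligibility taxonomy


@dataclass(frozen=True)
class IneligibilityBreakdown:
    """Why minutes could not be billed, with service-gap detail.

    ``service_gap_minutes`` tallies ALL minutes of CoCM-ineligible months by
    the subset of missing services (a month missing only the BHC consultation
    appears here even though it may bill a General BHI code).
    """

    total_minutes: int
    unbillable_minutes: int
    minutes_by_reason: Mapping[Reason, int]
    service_gap_minutes: Mapping[frozenset, int]
    over_under_ratio: float | None
    pre_engagement_unbillable_minutes: int

    @property
    def pre_engagement_share_of_unbillable(self) -> float:
        if self.unbillable_minutes == 0:
            return 0.0
        return 100.0 * self.pre_engagement_unbillable_minutes / self.unbillable_minutes

    @property
    def pre_engagement_share_of_total(self) -> float:
        if self.total_minutes == 0:
            return 0.0
        return 100.0 * self.pre_engagement_unbillable_minutes / self.total_minutes

    @property
    def service_ineligible_share_of_total(self) -> float:
        """Share of all minutes ineligible for any code (missing BHI services)."""
        if self.total_minutes == 0:
            return 0.0
        return 100.0 * self.minutes_by_reason.get(Reason.MISSING_SERVICES, 0) / self.total_minutes


def breakdown_ineligible(decisions: Sequence[BillingDecision]) -> IneligibilityBreakdown:
    """Tally unbillable minutes by reason and missing-service subset."""
    by_reason: dict[Reason, int] = {}
    gap_minutes: dict[frozenset, int] = {}
    total = unbillable = pre = 0
    for d in decisions:
        total += d.total_minutes
        unbillable += d.unbillable_minutes
        for r, m in d.unbillable_by_reason.items():
            by_reason[r] = by_reason.get(r, 0) + m
        if d.service_gap:
            gap_minutes[d.service_gap] = gap_minutes.get(d.service_gap, 0) + d.total_minutes
        if d.pre_engagement:
            pre += d.unbillable_minutes
    return IneligibilityBreakdown(
        total_minutes=total,
        unbillable_minutes=unbillable,
        minutes_by_reason=by_reason,
        service_gap_minutes=gap_minutes,
        over_under_ratio=over_under_ratio(
            by_reason.get(Reason.OVER_MAXIMUM, 0), by_reason.get(Reason.UNDER_MINIMUM, 0)
        ),
        pre_engagement_unbillable_minutes=pre,
    )


# ---------------------------------------------------------------------------
# rendering


def report_to_dict(report: SummaryReport) -> dict:
    """JSON-ready rendition of a summary report."""
    return {
        "scope": report.scope,
        "scenario": report.scenario_name,
        "n_patient_months": report.n_patient_months,
        "total_minutes": report.total_minutes,
        "total_hours": round_half_up(report.total_hours, 2),
        "billable_minutes": report.billable_minutes,
        "percent_billable": report.display_percent_billable,
        "percent_billable_exact": report.percent_billable,
        "total_revenue": report.display_total_revenue,
        "revenue_per_hour": report.display_revenue_per_hour,
        "minutes_by_code": dict(sorted(report.minutes_by_code.items())),
        "instances_by_code": dict(sorted(report.instances_by_code.items())),
        "unbillable_by_reason": {
            r.value: m for r, m in sorted(report.unbillable_by_reason.items(), key=lambda kv: kv[0].value)
        },
        "pre_engagement_unbillable_minutes": report.pre_engagement_unbillable_minutes,
        "is_empty": report.is_empty,
    }


def report_rows(report: SummaryReport) -> list[tuple[str, object]]:
    """Stable (label, value) rows mirroring the headline summary layout."""
    return [
        ("scenario", report.scenario_name),
        ("scope", report.scope),
        ("total_minutes", report.total_minutes),
        ("total_hours", round_half_up(report.total_hours, 2)),
        ("minutes_eligible_to_bill", report.billable_minutes),
        ("percent_eligible_to_bill", report.display_percent_billable),
        ("potential_reimbursement", f"{report.display_total_revenue:.2f}"),
        ("reimbursement_per_hour", f"{report.display_revenue_per_hour:.2f}"),
    ]


def reports_to_frame(reports: Iterable[SummaryReport]) -> pd.DataFrame:
    """Wide table with one column per report (for CSV export)."""
    data = {}
    for r in reports:
        rows = report_rows(r)
        data[f"{r.scenario_name}/{r.scope}"] = {k: v for k, v in rows[2:]}
    return pd.DataFrame(data)
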