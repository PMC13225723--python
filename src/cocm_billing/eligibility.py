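"""Service-requirement evaluation for CoCM and General BHI billing.

A patient-month is eligible for the psychiatric collaborative care codes
only when all three service components are documented that month: a
care-manager encounter, a behavioral-health-consultant (BHC) caseload
consultation, and complete measurement-based care (MBC). The General BHI
codes drop the BHC-consultation requirement (continuity of care with an
assigned care manager is assumed met for every patient).

"Engagement" is defined as the first calendar month in which all three CoCM
service requirements are met; months strictly before it are pre-engagement,
and their unbillable minutes are tallied separately downstream.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import pandas as pd

from .registry import PatientMonth

__all__ = [
    "ServiceComponent",
    "ServiceProfile",
    "EngagementTimeline",
    "evaluate_services",
    "build_engagement_timeline",
    "classify_service_gap",
    "eligibility_table",
]


class ServiceComponent(str, Enum):
    CM_ENCOUNTER = "CM_ENCOUNTER"
    BHC_CONSULT = "BHC_CONSULT"
    MBC = "MBC"


@dataclass(frozen=True)
class ServiceProfile:
    """Which service requirements a patient-month satisfies."""

    month: PatientMonth
    cocm_services_met: bool
    bhi_services_met: bool
    missing_components: frozenset[ServiceComponent]


@dataclass(frozen=True)
class EngagementTimeline:
    """Per-patient engagement: first fully-qualified month and what precedes it."""

    patient_id: str
    first_engaged_month: dt.date | None
    pre_engagement_months: frozenset[dt.date]


def evaluate_services(month: PatientMonth) -> ServiceProfile:
    """Evaluate a patient-month against CoCM and General BHI requirements.

    CoCM requires all of {CM encounter, BHC consultation, MBC} (plus a
    registry entry, implied by the month existing); General BHI requires
    {CM encounter, MBC} only.
    """
    missing = set()
    if not month.has_cm_encounter:
        missing.add(ServiceComponent.CM_ENCOUNTER)
    if not month.has_bhc_consult:
        missing.add(ServiceComponent.BHC_CONSULT)
    if not month.has_mbc:
        missing.add(ServiceComponent.MBC)
    missing_f = frozenset(missing)
    return ServiceProfile(
        month=month,
        cocm_services_met=not missing_f,
        bhi_services_met=not (
            missing_f & {ServiceComponent.CM_ENCOUNTER, ServiceComponent.MBC}
        ),
        missing_components=missing_f,
    )


def build_engagement_timeline(profiles: Sequence[ServiceProfile]) -> EngagementTimeline:
    """Locate the first month meeting all CoCM service requirements.

    ``profiles`` must belong to a single patient with distinct months. Months
    are sorted internally. A month can be billable to General BHI and still
    be pre-engagement: pre-engagement status depends only on the CoCM triple.
    """
    if not profiles:
        raise ValueError("build_engagement_timeline requires at least one profile")
    pids = {p.month.patient_id for p in profiles}
    if len(pids) != 1:
        raise ValueError(f"profiles span multiple patients: {sorted(pids)}")
    months = [p.month.year_month for p in profiles]
    if len(set(months)) != len(months):
        raise ValueError("duplicate months in profiles")

    ordered = sorted(profiles, key=lambda p: p.month.year_month)
    first = next(
        (p.month.year_month for p in ordered if p.cocm_services_met), None
    )
    if first is None:
        pre = frozenset(months)
    else:
        pre = frozenset(m for m in months if m < first)
    return EngagementTimeline(
        patient_id=pids.pop(), first_engaged_month=first, pre_engagement_months=pre
    )


def classify_service_gap(profile: ServiceProfile) -> frozenset[ServiceComponent]:
    """The nonempty set of missing CoCM services for an ineligible month.

    Because MBC can only happen during a CM encounter, subsets with MBC
    present but CM missing never occur.
    """
    if profile.cocm_services_met:
        raise ValueError("classify_service_gap called on a CoCM-eligible month")
    return profile.missing_components


def eligibility_table(
    profiles: Iterable[ServiceProfile],
    timelines: dict[str, EngagementTimeline] | None = None,
) -> pd.DataFrame:
    """Per-month eligibility table for CSV export/audit."""
    rows = []
    for p in profiles:
        m = p.month
        pre = False
        if timelines is not None and m.patient_id in timelines:
            pre = m.year_month in timelines[m.patient_id].pre_engagement_months
        rows.append(
            {
                "patient_id": m.patient_id,
                "month": m.year_month.strftime("%Y-%m"),
                "cocm_met": int(p.cocm_services_met),
                "bhi_met": int(p.bhi_services_met),
                "gap": "+".join(sorted(c.value for c in p.missing_components)),
                "pre_engagement": int(pre),
            }
        )
    return pd.DataFrame(rows)
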