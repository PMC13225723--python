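"""Scenario configuration, the end-to-end pipeline, and sensitivity analyses.

A scenario bundles everything that varies between analyses: the practice
setting (FQHC / non-FQHC / both), which codes the payer reimburses
(expansive vs restrictive presets), the fee schedule, the assumed duration
of undocumented contact attempts (5 minutes; 10 in the pessimistic variant),
and an optional "unbilled fraction" modelling practices that fail to bill a
share of their billable months.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .billing import (
    CODES,
    EXPANSIVE_AVAILABILITY,
    RESTRICTIVE_AVAILABILITY,
    BillingDecision,
    Reason,
    process_patient,
)
from .eligibility import ServiceProfile, evaluate_services
from .errors import ConfigError, PricingError
from .metrics import (
    MEDICARE_2024,
    FeeSchedule,
    IneligibilityBreakdown,
    SummaryReport,
    breakdown_ineligible,
    price_decisions,
    summarize,
)
from .registry import (
    PatientMonth,
    PatientRecord,
    RegistryEntry,
    aggregate_months,
    impute_contact_minutes,
)

__all__ = [
    "ScenarioConfig",
    "ScenarioResult",
    "expansive_scenario",
    "restrictive_scenario",
    "run_scenario",
    "run_grid",
    "apply_unbilled_fraction",
    "load_fee_schedule_variant",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """All knobs of one analysis scenario."""

    name: str = "expansive"
    setting: str = "both"  # "fqhc" | "non_fqhc" | "both"
    code_availability: Mapping[str, bool] = field(
        default_factory=lambda: dict(EXPANSIVE_AVAILABILITY)
    )
    fee_schedule: FeeSchedule = MEDICARE_2024
    contact_attempt_minutes: int = 5
    unbilled_fraction: float = 0.0
    unbilled_mode: str = "deterministic_scaling"  # or "random_month_drop"
    rng_seed: int | None = None
    window_months: int = 6
    window_days: int | None = None
    mbc_complete_threshold: float = 0.5
    fqhc_credit_mode: str = "set_amount"  # or "actual_minutes"

    def __post_init__(self):
        unknown = set(self.code_availability) - set(CODES)
        if unknown:
            raise ConfigError(f"unknown billing code(s) in availability map: {sorted(unknown)}")
        if self.setting not in {"fqhc", "non_fqhc", "both"}:
            raise ConfigError(f"unknown setting {self.setting!r}")
        if not 0.0 <= self.unbilled_fraction < 1.0:
            raise ConfigError("unbilled_fraction must be in [0, 1)")
        if self.unbilled_mode not in {"deterministic_scaling", "random_month_drop"}:
            raise ConfigError(f"unknown unbilled_mode {self.unbilled_mode!r}")
        if self.fqhc_credit_mode not in {"set_amount", "actual_minutes"}:
            raise ConfigError(f"unknown fqhc_credit_mode {self.fqhc_credit_mode!r}")
        if (
            self.unbilled_mode == "random_month_drop"
            and self.unbilled_fraction > 0
            and self.rng_seed is None
        ):
            raise ConfigError("random_month_drop requires rng_seed")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["fee_schedule"] = {
            "name": self.fee_schedule.name,
            "rates_cents": dict(self.fee_schedule.rates_cents),
        }
        return d


def expansive_scenario(**overrides) -> ScenarioConfig:
    """All codes assumed billable."""
    overrides.setdefault("name", "expansive")
    overrides.setdefault("code_availability", dict(EXPANSIVE_AVAILABILITY))
    return ScenarioConfig(**overrides)


def restrictive_scenario(**overrides) -> ScenarioConfig:
    """Only the commonly-reimbursed codes (99484 and G2214 excluded)."""
    overrides.setdefault("name", "restrictive")
    overrides.setdefault("code_availability", dict(RESTRICTIVE_AVAILABILITY))
    return ScenarioConfig(**overrides)


@dataclass
class ScenarioResult:
    """Everything one scenario run produces."""

    config: ScenarioConfig
    report: SummaryReport
    breakdown: IneligibilityBreakdown
    decisions: list[BillingDecision]
    months: list[PatientMonth]
    profiles: list[ServiceProfile]

    def report_for(self, scope: str) -> SummaryReport:
        return summarize(self.decisions, scope=scope, scenario_name=self.config.name)


def run_scenario(
    entries: Sequence[RegistryEntry],
    patients: Sequence[PatientRecord],
    config: ScenarioConfig,
) -> ScenarioResult:
    """Run the full pipeline under one scenario configuration.

    Steps: filter patients to the scenario's setting, impute contact-attempt
    minutes, aggregate to patient-months, evaluate service requirements, bill
    each patient's months in order, price against the fee schedule, apply the
    unbilled-fraction adjustment, and summarize. Deterministic given the
    config (and its seed, in random-drop mode).
    """
    if config.setting == "fqhc":
        patients = [p for p in patients if p.is_fqhc]
    elif config.setting == "non_fqhc":
        patients = [p for p in patients if not p.is_fqhc]
    pids = {p.patient_id for p in patients}
    entries = [e for e in entries if e.patient_id in pids]

    imputed = impute_contact_minutes(entries, config.contact_attempt_minutes)
    months = aggregate_months(
        imputed,
        patients,
        window_months=config.window_months,
        mbc_complete_threshold=config.mbc_complete_threshold,
        window_days=config.window_days,
    )
    profiles = [evaluate_services(m) for m in months]

    fqhc_by_pid = {p.patient_id: p.is_fqhc for p in patients}
    by_patient: dict[str, list[ServiceProfile]] = {}
    for prof in profiles:
        by_patient.setdefault(prof.month.patient_id, []).append(prof)

    decisions: list[BillingDecision] = []
    for pid in sorted(by_patient):
        patient_profiles = sorted(by_patient[pid], key=lambda p: p.month.year_month)
        decisions.extend(process_patient(patient_profiles, config, fqhc_by_pid[pid]))

    decisions = price_decisions(decisions, config.fee_schedule)
    if config.unbilled_fraction > 0:
        decisions = apply_unbilled_fraction(
            decisions, config.unbilled_fraction, config.unbilled_mode, config.rng_seed
        )

    report = summarize(decisions, scope="combined", scenario_name=config.name)
    return ScenarioResult(
        config=config,
        report=report,
        breakdown=breakdown_ineligible(decisions),
        decisions=decisions,
        months=months,
        profiles=profiles,
    )


def run_grid(
    entries: Sequence[RegistryEntry],
    patients: Sequence[PatientRecord],
    fee_schedule: FeeSchedule = MEDICARE_2024,
    **config_overrides,
) -> dict[tuple[str, str], SummaryReport]:
    """The full scenario grid: {expansive, restrictive} x {combined, non-FQHC, FQHC}.

    Returns six reports keyed by (scenario, scope); each scenario's pipeline
    runs once and is re-summarized per scope, so combined totals equal the
    sum of the setting-specific totals by construction.
    """
    reports: dict[tuple[str, str], SummaryReport] = {}
    for factory in (expansive_scenario, restrictive_scenario):
        config = factory(fee_schedule=fee_schedule, **config_overrides)
        result = run_scenario(entries, patients, config)
        for scope in ("combined", "non_fqhc", "fqhc"):
            reports[(config.name, scope)] = result.report_for(scope)
    return reports


def apply_unbilled_fraction(
    decisions: Sequence[BillingDecision],
    fraction: float,
    mode: str = "deterministic_scaling",
    seed: int | None = None,
) -> list[BillingDecision]:
    """Model a share of billable months not actually being billed.

    ``deterministic_scaling`` multiplies every month's revenue by
    ``1 - fraction`` (minute tallies unchanged); ``random_month_drop`` zeroes
    the revenue and billable-minute credit of a uniformly random subset of
    billable months of expected proportion ``fraction`` (the dropped months'
    billable minutes move to the NOT_BILLED reason so minutes stay conserved).
    """
    if not 0.0 <= fraction < 1.0:
        raise ConfigError("fraction must be in [0, 1)")
    if fraction == 0.0:
        return list(decisions)
    if mode == "deterministic_scaling":
        return [
            replace(d, revenue_cents=(d.revenue_cents or 0.0) * (1.0 - fraction))
            for d in decisions
        ]
    if mode != "random_month_drop":
        raise ConfigError(f"unknown unbilled mode {mode!r}")
    if seed is None:
        raise ConfigError("random_month_drop requires a seed")
    rng = np.random.default_rng(seed)
    out = []
    for d in decisions:
        if d.billable_minutes > 0 and rng.random() < fraction:
            reasons = dict(d.unbillable_by_reason)
            reasons[Reason.NOT_BILLED] = reasons.get(Reason.NOT_BILLED, 0) + d.billable_minutes
            out.append(
                replace(
                    d,
                    line_items=(),
                    billable_minutes=0,
                    unbillable_by_reason=reasons,
                    revenue_cents=0.0,
                )
            )
        else:
            out.append(d)
    return out


def load_fee_schedule_variant(name_or_path: str | Path) -> FeeSchedule:
    """Resolve a fee schedule by name or from a YAML/JSON file.

    ``medicare_2024`` is built in. ``medicaid_min`` / ``medicaid_max`` are
    named placeholders for the lowest/highest state Medicaid schedules: their
    rates are not distributed with the package and must be supplied as a
    file. A file must provide a rate (dollars) for every known code.
    """
    name = str(name_or_path)
    if name == "medicare_2024":
        return MEDICARE_2024
    if name in {"medicaid_min", "medicaid_max"}:
        raise PricingError(
            f"fee schedule {name!r} requires user-supplied rates; "
            "provide a YAML/JSON file with a 'rates' mapping for codes "
            + ", ".join(sorted(CODES))
        )
    path = Path(name_or_path)
    if not path.exists():
        raise PricingError(f"unknown fee schedule {name!r} (not a built-in name or file)")
    text = path.read_text(encoding="utf-8")
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict) or "rates" not in data:
        raise PricingError(f"fee schedule file {path} must contain a 'rates' mapping")
    rates = data["rates"]
    missing = sorted(set(CODES) - set(rates))
    if missing:
        raise PricingError(f"fee schedule file {path} missing rates for: {missing}")
    return FeeSchedule.from_dollars(data.get("name", path.stem), rates)
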