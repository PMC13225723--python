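"""Seeded synthetic care-management registries.

The generator emulates the statistical structure the billing analysis
consumes: per-patient engagement timelines over a six-month window (some
patients take months to engage, some never do), per-activity-type entry
counts (Poisson per engaged month) and durations (truncated normal, rounded
to whole minutes), contact attempts with no recorded duration, and MBC
completeness per care-manager encounter.

Engagement here is structural: a patient's first engaged month contains the
single initial care-manager encounter (with complete MBC) and at least one
BHC consultation, placed at the start of the month, so a patient with zero
engagement delay has no pre-engagement minutes downstream. Pre-engagement
months contain only contact attempts. Never-engaged patients emit only
contact attempts for the whole window.

``fixture_trial_scale`` post-hoc forces per-type entry counts and minute
totals to a fixed trial-scale reference (314 / 1,925 / 4,747 / 1,582 entries;
10,216 / 45,839 / 23,735 / 11,206 minutes; 90,996 minutes grand total with
5-minute contact attempts) for exact-arithmetic checks.
"""

from __future__ import annotations

import calendar
import dataclasses
import datetime as dt
import math
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ConfigError
from .registry import (
    ActivityType,
    CM_ENCOUNTER_TYPES,
    PatientRecord,
    RegistryEntry,
    add_months,
    month_index,
)

__all__ = [
    "GeneratorParams",
    "TRIAL_SCALE_TARGETS",
    "generate",
    "fixture_trial_scale",
    "estimate_generator_params",
    "write_registry",
]

#: Trial-scale per-type targets: (entry count, total minutes). Contact-attempt
#: minutes are whatever the per-attempt assumption implies (4,747 x 5 = 23,735).
TRIAL_SCALE_TARGETS: dict[ActivityType, tuple[int, int]] = {
    ActivityType.INITIAL_CM_ENCOUNTER: (314, 10216),
    ActivityType.FOLLOWUP_CM_ENCOUNTER: (1925, 45839),
    ActivityType.CONTACT_ATTEMPT: (4747, 23735),
    ActivityType.BHC_CONSULTATION: (1582, 11206),
}


def _default_delay_pmf() -> dict[int, float]:
    # delay = number of pre-engagement months; delay == months means the
    # patient never engages within the window (attempts only).
    return {0: 0.35, 1: 0.25, 2: 0.12, 3: 0.05, 4: 0.03, 5: 0.02, 6: 0.18}


def _default_rates() -> dict[str, float]:
    return {"followup": 1.25, "contact_attempt": 1.4, "bhc": 1.0}


def _default_durations() -> dict[str, tuple[float, float]]:
    return {"initial": (33.0, 17.0), "followup": (24.0, 14.0), "bhc": (7.0, 5.0)}


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the synthetic registry generator.

    ``monthly_rates`` are expected counts per engaged month;
    ``pre_engagement_attempt_rate`` governs contact attempts in months before
    engagement (outreach is heavier there). ``duration_models`` are
    (mean, SD) minutes per entry; sampling is normal truncated at 0.5 and
    rounded, so recorded durations are always >= 1 minute.
    """

    n_patients: int = 381
    fqhc_share: float = 0.5
    months: int = 6
    engagement_delay_pmf: Mapping[int, float] = field(default_factory=_default_delay_pmf)
    monthly_rates: Mapping[str, float] = field(default_factory=_default_rates)
    pre_engagement_attempt_rate: float = 3.5
    duration_models: Mapping[str, tuple[float, float]] = field(default_factory=_default_durations)
    mbc_completion_probability: float = 0.85
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ConfigError("n_patients must be positive")
        if not 0.0 <= self.fqhc_share <= 1.0:
            raise ConfigError("fqhc_share must be in [0, 1]")
        if self.months < 1:
            raise ConfigError("months must be positive")
        total = sum(self.engagement_delay_pmf.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigError(f"engagement_delay_pmf must sum to 1, got {total}")
        if any(d < 0 or d > self.months for d in self.engagement_delay_pmf):
            raise ConfigError("engagement delays must lie in 0..months")
        if any(r < 0 for r in self.monthly_rates.values()) or self.pre_engagement_attempt_rate < 0:
            raise ConfigError("rates must be nonnegative")
        if not 0.0 <= self.mbc_completion_probability <= 1.0:
            raise ConfigError("mbc_completion_probability must be in [0, 1]")
        for name, (mu, sd) in self.duration_models.items():
            if sd <= 0 or mu <= 0:
                raise ConfigError(f"duration model {name!r} needs positive mean and SD")


_DURATION_TRUNC = 0.5  # continuous truncation point; rounding then gives >= 1


def _sample_durations(rng: np.random.Generator, mu: float, sd: float, n: int) -> np.ndarray:
    if n == 0:
        return np.zeros(0, dtype=int)
    a = (_DURATION_TRUNC - mu) / sd
    x = stats.truncnorm.rvs(a, np.inf, loc=mu, scale=sd, size=n, random_state=rng)
    return np.floor(x + 0.5).astype(int)


def _mbc_fraction(rng: np.random.Generator, complete_p: float) -> float:
    # complete responses answer at least half the items
    if rng.random() < complete_p:
        return round(float(rng.uniform(0.5, 1.0)), 3)
    return round(float(rng.uniform(0.0, 0.5)), 3)


def _date_in_relative_month(
    rng: np.random.Generator, randomization: dt.date, k: int, at_start: bool = False
) -> dt.date:
    """A date inside the patient's k-th relative month (1-based).

    ``at_start`` keeps the date in the same calendar month as the relative
    month's first day (used for the engagement-defining entries).
    """
    start = add_months(randomization, k - 1)
    end = add_months(randomization, k)
    span = (end - start).days
    if at_start:
        room = calendar.monthrange(start.year, start.month)[1] - start.day
        offset = int(rng.integers(0, min(3, room) + 1))
    else:
        offset = int(rng.integers(0, span))
    return start + dt.timedelta(days=offset)


def generate(params: GeneratorParams) -> tuple[list[RegistryEntry], list[PatientRecord]]:
    """Generate a registry and patient table; reproducible given the seed."""
    rng = np.random.default_rng(params.rng_seed)
    delays = sorted(params.engagement_delay_pmf)
    delay_p = np.array([params.engagement_delay_pmf[d] for d in delays], dtype=float)
    delay_p = delay_p / delay_p.sum()

    rate_f = params.monthly_rates.get("followup", 0.0)
    rate_a = params.monthly_rates.get("contact_attempt", 0.0)
    rate_b = params.monthly_rates.get("bhc", 0.0)
    dur = params.duration_models

    base = dt.date(2021, 1, 4)
    horizon_days = (dt.date(2023, 6, 30) - base).days

    patients: list[PatientRecord] = []
    entries: list[RegistryEntry] = []
    width = len(str(params.n_patients))
    for i in range(params.n_patients):
        pid = f"P{i + 1:0{width}d}"
        is_fqhc = bool(rng.random() < params.fqhc_share)
        clinic = f"C{'F' if is_fqhc else 'N'}{int(rng.integers(1, 8)):02d}"
        rand_date = base + dt.timedelta(days=int(rng.integers(0, horizon_days + 1)))
        patients.append(PatientRecord(pid, clinic, rand_date, is_fqhc))

        delay = int(rng.choice(delays, p=delay_p))
        for k in range(1, params.months + 1):
            if k <= delay:  # pre-engagement: outreach only
                n_att = int(rng.poisson(params.pre_engagement_attempt_rate))
                for _ in range(n_att):
                    entries.append(
                        RegistryEntry(
                            pid, clinic, _date_in_relative_month(rng, rand_date, k),
                            ActivityType.CONTACT_ATTEMPT,
                        )
                    )
                continue

            first_engaged = k == delay + 1
            if first_engaged:
                mu, sd = dur["initial"]
                entries.append(
                    RegistryEntry(
                        pid, clinic,
                        _date_in_relative_month(rng, rand_date, k, at_start=True),
                        ActivityType.INITIAL_CM_ENCOUNTER,
                        minutes=int(_sample_durations(rng, mu, sd, 1)[0]),
                        mbc_fraction_answered=round(float(rng.uniform(0.5, 1.0)), 3),
                    )
                )
            n_follow = int(rng.poisson(rate_f))
            mu, sd = dur["followup"]
            for m in _sample_durations(rng, mu, sd, n_follow):
                entries.append(
                    RegistryEntry(
                        pid, clinic, _date_in_relative_month(rng, rand_date, k),
                        ActivityType.FOLLOWUP_CM_ENCOUNTER,
                        minutes=int(m),
                        mbc_fraction_answered=_mbc_fraction(rng, params.mbc_completion_probability),
                    )
                )
            n_bhc = int(rng.poisson(rate_b))
            if first_engaged:
                n_bhc = max(1, n_bhc)
            mu, sd = dur["bhc"]
            for j, m in enumerate(_sample_durations(rng, mu, sd, n_bhc)):
                entries.append(
                    RegistryEntry(
                        pid, clinic,
                        _date_in_relative_month(
                            rng, rand_date, k, at_start=first_engaged and j == 0
                        ),
                        ActivityType.BHC_CONSULTATION,
                        minutes=int(m),
                    )
                )
            n_att = int(rng.poisson(rate_a))
            for _ in range(n_att):
                entries.append(
                    RegistryEntry(
                        pid, clinic, _date_in_relative_month(rng, rand_date, k),
                        ActivityType.CONTACT_ATTEMPT,
                    )
                )

    entries.sort(key=lambda e: (e.patient_id, e.date, e.activity_type.value))
    return entries, patients


# ---------------------------------------------------------------------------
# trial-scale fixture


def _force_count(
    items: list[RegistryEntry], target: int, rng: np.random.Generator,
    protect_last_of_month: bool = False,
) -> list[RegistryEntry]:
    """Trim or duplicate entries so their count equals ``target``.

    When trimming with ``protect_last_of_month``, entries that are the last
    of their type in their (patient, calendar month) are removed only if
    unavoidable, preserving month-level service structure where possible.
    """
    n = len(items)
    if n == target:
        return list(items)
    if n < target:
        extra_idx = rng.choice(n, size=target - n, replace=True)
        return list(items) + [items[int(i)] for i in extra_idx]

    order = rng.permutation(n)
    to_remove: set[int] = set()
    surplus = n - target
    if protect_last_of_month:
        counts: dict[tuple[str, int, int], int] = defaultdict(int)
        for e in items:
            counts[(e.patient_id, e.date.year, e.date.month)] += 1
        for idx in order:
            if surplus == 0:
                break
            e = items[int(idx)]
            key = (e.patient_id, e.date.year, e.date.month)
            if counts[key] >= 2:
                counts[key] -= 1
                to_remove.add(int(idx))
                surplus -= 1
    for idx in order:
        if surplus == 0:
            break
        if int(idx) not in to_remove:
            to_remove.add(int(idx))
            surplus -= 1
    return [e for i, e in enumerate(items) if i not in to_remove]


def _force_minutes(
    items: list[RegistryEntry], target_total: int, rng: np.random.Generator
) -> list[RegistryEntry]:
    """Rescale entry durations so they sum exactly to ``target_total`` (each >= 1)."""
    if not items:
        return items
    if target_total < len(items):
        raise ConfigError("target total below one minute per entry")
    current = np.array([e.minutes for e in items], dtype=float)
    scaled = current * (target_total / current.sum())
    floors = np.maximum(1, np.floor(scaled)).astype(int)
    deficit = target_total - int(floors.sum())
    if deficit > 0:  # hand out the remainder to largest fractional parts
        frac = scaled - np.floor(scaled)
        for idx in np.argsort(-frac, kind="stable")[:deficit]:
            floors[idx] += 1
    elif deficit < 0:  # max(1,...) overshoot: take back from the largest
        for idx in np.argsort(-floors, kind="stable")[: -deficit]:
            floors[idx] -= 1
    assert int(floors.sum()) == target_total and floors.min() >= 1
    return [dataclasses.replace(e, minutes=int(m)) for e, m in zip(items, floors)]


def fixture_trial_scale(seed: int = 0) -> tuple[list[RegistryEntry], list[PatientRecord]]:
    """A 381-patient registry with per-type counts and minutes forced exactly.

    Generates an over-provisioned registry, then post-hoc forces each
    activity type to its trial-scale entry count and minute total
    (:data:`TRIAL_SCALE_TARGETS`). Surplus initial encounters are demoted to
    follow-up type so every engaging patient keeps a care-manager encounter
    in their first engaged month. With the default 5-minute contact-attempt
    assumption the grand total is 90,996 minutes.
    """
    params = GeneratorParams(
        n_patients=381,
        engagement_delay_pmf={0: 0.40, 1: 0.27, 2: 0.13, 3: 0.06, 4: 0.03, 5: 0.01, 6: 0.10},
        monthly_rates={"followup": 1.45, "contact_attempt": 1.65, "bhc": 1.25},
        pre_engagement_attempt_rate=4.4,
        rng_seed=seed,
    )
    entries, patients = generate(params)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2024]))

    by_type: dict[ActivityType, list[RegistryEntry]] = {t: [] for t in ActivityType}
    for e in entries:
        by_type[e.activity_type].append(e)

    # initial encounters: demote surplus to follow-up (never delete, so each
    # engaging patient keeps a CM encounter in the first engaged month)
    initials = by_type[ActivityType.INITIAL_CM_ENCOUNTER]
    n_init_target = TRIAL_SCALE_TARGETS[ActivityType.INITIAL_CM_ENCOUNTER][0]
    if len(initials) >= n_init_target:
        order = rng.permutation(len(initials))
        keep = set(order[:n_init_target].tolist())
        kept, demoted = [], []
        for i, e in enumerate(initials):
            (kept if i in keep else demoted).append(e)
        by_type[ActivityType.INITIAL_CM_ENCOUNTER] = kept
        by_type[ActivityType.FOLLOWUP_CM_ENCOUNTER].extend(
            dataclasses.replace(e, activity_type=ActivityType.FOLLOWUP_CM_ENCOUNTER)
            for e in demoted
        )
    else:  # unlikely at these rates: promote follow-ups
        deficit = n_init_target - len(initials)
        follows = by_type[ActivityType.FOLLOWUP_CM_ENCOUNTER]
        idx = set(rng.choice(len(follows), size=deficit, replace=False).tolist())
        by_type[ActivityType.INITIAL_CM_ENCOUNTER].extend(
            dataclasses.replace(follows[i], activity_type=ActivityType.INITIAL_CM_ENCOUNTER)
            for i in idx
        )
        by_type[ActivityType.FOLLOWUP_CM_ENCOUNTER] = [
            e for i, e in enumerate(follows) if i not in idx
        ]

    forced: list[RegistryEntry] = []
    for t in ActivityType:
        count_target, minute_target = TRIAL_SCALE_TARGETS[t]
        items = _force_count(
            by_type[t], count_target, rng,
            protect_last_of_month=t is not ActivityType.CONTACT_ATTEMPT,
        )
        if t is not ActivityType.CONTACT_ATTEMPT:
            items = _force_minutes(items, minute_target, rng)
        forced.extend(items)

    forced.sort(key=lambda e: (e.patient_id, e.date, e.activity_type.value))
    return forced, patients


# ---------------------------------------------------------------------------
# parameter recovery


def _truncnorm_mle(values: np.ndarray) -> tuple[float, float]:
    """MLE of (mean, SD) for a normal truncated below at 0.5.

    Recorded minutes are rounded; treating them as continuous adds negligible
    bias at the SDs used here.
    """
    x = np.asarray(values, dtype=float)

    def nll(theta):
        mu, log_sd = theta
        sd = math.exp(log_sd)
        z = (x - mu) / sd
        log_tail = stats.norm.logsf((_DURATION_TRUNC - mu) / sd)
        return float(len(x) * (math.log(sd) + log_tail) + 0.5 * np.sum(z * z))

    res = optimize.minimize(
        nll,
        x0=np.array([x.mean(), math.log(max(x.std(), 0.5))]),
        method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
    )
    return float(res.x[0]), float(math.exp(res.x[1]))


def _relative_month(randomization: dt.date, date: dt.date) -> int:
    """The 1-based month of the patient's timeline containing ``date``.

    Relative months are anchored at the randomization date (month k spans
    ``[randomization + (k-1) months, randomization + k months)``), matching
    the generator's engagement bookkeeping rather than calendar months.
    """
    k = month_index(randomization, date)
    if date < add_months(randomization, k - 1):
        return k - 1
    return k


def estimate_generator_params(
    entries: Sequence[RegistryEntry], patients: Sequence[PatientRecord]
) -> dict:
    """Recover duration models and monthly rates from a generated registry.

    Engagement delay per patient is read off the relative month of the
    initial encounter. Follow-up and contact-attempt rates are estimated over
    engaged relative months; the BHC rate excludes each patient's first
    engaged month (where one consultation is structural, not Poisson).
    """
    rand_by_pid = {p.patient_id: p.randomization_date for p in patients}
    months_window = 6

    initial_month: dict[str, int] = {}
    for e in entries:
        if e.activity_type is ActivityType.INITIAL_CM_ENCOUNTER:
            k = _relative_month(rand_by_pid[e.patient_id], e.date)
            initial_month[e.patient_id] = min(k, initial_month.get(e.patient_id, k))

    engaged_months = sum(months_window - (k - 1) for k in initial_month.values())
    engaged_after_first = sum(months_window - k for k in initial_month.values())

    counts = {"followup": 0, "attempt_engaged": 0, "bhc_after_first": 0}
    durations: dict[str, list[int]] = {"initial": [], "followup": [], "bhc": []}
    for e in entries:
        k = _relative_month(rand_by_pid[e.patient_id], e.date)
        first = initial_month.get(e.patient_id)
        if e.activity_type is ActivityType.INITIAL_CM_ENCOUNTER:
            durations["initial"].append(int(e.minutes))
        elif e.activity_type is ActivityType.FOLLOWUP_CM_ENCOUNTER:
            durations["followup"].append(int(e.minutes))
            if first is not None and k >= first:
                counts["followup"] += 1
        elif e.activity_type is ActivityType.BHC_CONSULTATION:
            durations["bhc"].append(int(e.minutes))
            if first is not None and k > first:
                counts["bhc_after_first"] += 1
        else:
            if first is not None and k >= first:
                counts["attempt_engaged"] += 1

    duration_models = {
        name: _truncnorm_mle(np.array(vals)) for name, vals in durations.items() if vals
    }
    monthly_rates = {
        "followup": counts["followup"] / engaged_months if engaged_months else float("nan"),
        "contact_attempt": counts["attempt_engaged"] / engaged_months if engaged_months else float("nan"),
        "bhc": counts["bhc_after_first"] / engaged_after_first if engaged_after_first else float("nan"),
    }
    return {"duration_models": duration_models, "monthly_rates": monthly_rates}


# ---------------------------------------------------------------------------
# output


def write_registry(
    entries: Sequence[RegistryEntry],
    patients: Sequence[PatientRecord],
    out_dir: str | Path,
) -> tuple[Path, Path]:
    """Write registry and patient CSVs in the loader's input format."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reg_path = out / "registry.csv"
    pat_path = out / "patients.csv"
    pd.DataFrame(
        [
            {
                "patient_id": e.patient_id,
                "clinic_id": e.clinic_id,
                "date": e.date.isoformat(),
                "activity_type": e.activity_type.value,
                "minutes": "" if e.minutes is None else e.minutes,
                "mbc_fraction_answered": (
                    "" if e.mbc_fraction_answered is None else e.mbc_fraction_answered
                ),
            }
            for e in entries
        ]
    ).to_csv(reg_path, index=False)
    pd.DataFrame(
        [
            {
                "patient_id": p.patient_id,
                "clinic_id": p.clinic_id,
                "randomization_date": p.randomization_date.isoformat(),
                "is_fqhc": int(p.is_fqhc),
            }
            for p in patients
        ]
    ).to_csv(pat_path, index=False)
    return reg_path, pat_path
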