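"""Care-management registry data model, I/O and patient-month aggregation.

The registry is the care manager's activity log: one row per documented
activity (initial or follow-up care-manager encounter, contact attempt, or
consultation with the behavioral health consultant), with a duration in
minutes and — on care-manager encounters — the completeness of any
measurement-based-care (MBC) instruments administered.

The billing unit downstream is the patient calendar month. This module
aggregates raw entries into :class:`PatientMonth` records restricted to the
intervention window (by default six calendar months from each patient's
randomization date, half-open).
"""

from __future__ import annotations

import calendar
import csv
import dataclasses
import datetime as dt
from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigError, RegistryValidationError, RowIssue, SchemaError

__all__ = [
    "ActivityType",
    "CM_ENCOUNTER_TYPES",
    "RegistryEntry",
    "PatientRecord",
    "PatientMonth",
    "LoadResult",
    "load_registry",
    "load_patients",
    "impute_contact_minutes",
    "aggregate_months",
    "write_patient_months",
    "add_months",
    "month_of",
    "month_index",
]


class ActivityType(str, Enum):
    """The four documented activity types in the registry."""

    INITIAL_CM_ENCOUNTER = "INITIAL_CM_ENCOUNTER"
    FOLLOWUP_CM_ENCOUNTER = "FOLLOWUP_CM_ENCOUNTER"
    CONTACT_ATTEMPT = "CONTACT_ATTEMPT"
    BHC_CONSULTATION = "BHC_CONSULTATION"


#: Activity types that count as a care-manager encounter with the patient.
CM_ENCOUNTER_TYPES = frozenset(
    {ActivityType.INITIAL_CM_ENCOUNTER, ActivityType.FOLLOWUP_CM_ENCOUNTER}
)


@dataclass(frozen=True)
class RegistryEntry:
    """One documented care-manager/BHC activity.

    ``minutes`` may be absent only on contact attempts (the registry does not
    allow time entry for them); :func:`impute_contact_minutes` fills them in.
    ``mbc_fraction_answered`` is the fraction of MBC items answered and is
    only meaningful on care-manager encounters (MBC happens during them).
    A precomputed completeness boolean can be supplied as 0.0/1.0.
    """

    patient_id: str
    clinic_id: str
    date: dt.date
    activity_type: ActivityType
    minutes: int | None = None
    mbc_fraction_answered: float | None = None


@dataclass(frozen=True)
class PatientRecord:
    """One patient randomized to collaborative care."""

    patient_id: str
    clinic_id: str
    randomization_date: dt.date
    is_fqhc: bool


@dataclass(frozen=True)
class PatientMonth:
    """Calendar-month aggregate of one patient's documented activity.

    ``year_month`` is the first day of the calendar month. ``month_index`` is
    the ordinal of the calendar month in the patient's timeline (1 = month of
    randomization). A month object exists only if at least one in-window
    entry fell in it, so ``has_registry_entry`` is always true.
    """

    patient_id: str
    year_month: dt.date
    total_minutes: int
    minutes_by_type: Mapping[ActivityType, int]
    has_cm_encounter: bool
    has_bhc_consult: bool
    has_mbc: bool
    month_index: int
    has_registry_entry: bool = True


# ---------------------------------------------------------------------------
# calendar helpers


def add_months(d: dt.date, n: int) -> dt.date:
    """Shift a date by ``n`` calendar months, clamping the day of month."""
    y, m = divmod(d.month - 1 + n, 12)
    year, month = d.year + y, m + 1
    day = min(d.day, calendar.monthrange(year, month)[1])
    return dt.date(year, month, day)


def month_of(d: dt.date) -> dt.date:
    """First day of ``d``'s calendar month."""
    return d.replace(day=1)


def month_index(randomization_date: dt.date, d: dt.date) -> int:
    """Ordinal of ``d``'s calendar month, 1 = month of randomization."""
    return (d.year - randomization_date.year) * 12 + (d.month - randomization_date.month) + 1


# ---------------------------------------------------------------------------
# loading

DEFAULT_REGISTRY_COLUMNS: dict[str, str] = {
    "patient_id": "patient_id",
    "clinic_id": "clinic_id",
    "date": "date",
    "activity_type": "activity_type",
    "minutes": "minutes",
    "mbc_fraction_answered": "mbc_fraction_answered",
}

DEFAULT_PATIENT_COLUMNS: dict[str, str] = {
    "patient_id": "patient_id",
    "clinic_id": "clinic_id",
    "randomization_date": "randomization_date",
    "is_fqhc": "is_fqhc",
}


@dataclass
class LoadResult:
    """Parsed rows plus row-level diagnostics for the rejected ones."""

    entries: list = field(default_factory=list)
    issues: list[RowIssue] = field(default_factory=list)


def _open_rows(path: str | Path, columns: Mapping[str, str], required: Sequence[str]):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for logical in required:
            if columns[logical] not in header:
                raise SchemaError(
                    f"missing required column {columns[logical]!r} in {path}"
                )
        yield from enumerate(reader, start=1)


def _parse_date(value: str) -> dt.date:
    return dt.date.fromisoformat(value.strip())


def load_registry(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    strict: bool = True,
) -> LoadResult:
    """Read registry entries from a UTF-8 CSV with ISO-8601 dates.

    ``column_map`` maps the logical field names to the file's column names.
    Rows that fail validation are reported as :class:`RowIssue`; with
    ``strict=True`` (default) any issue raises :class:`RegistryValidationError`.
    """
    cols = dict(DEFAULT_REGISTRY_COLUMNS)
    if column_map:
        cols.update(column_map)
    required = ["patient_id", "clinic_id", "date", "activity_type", "minutes"]
    result = LoadResult()
    for rownum, row in _open_rows(path, cols, required):
        try:
            result.entries.append(_parse_registry_row(row, cols))
        except ValueError as exc:
            result.issues.append(RowIssue(rownum, str(exc)))
    if strict and result.issues:
        raise RegistryValidationError(result.issues)
    return result


def _parse_registry_row(row: Mapping[str, str], cols: Mapping[str, str]) -> RegistryEntry:
    raw_type = (row[cols["activity_type"]] or "").strip()
    try:
        activity = ActivityType(raw_type)
    except ValueError:
        raise ValueError(f"unknown activity_type {raw_type!r}")

    try:
        date = _parse_date(row[cols["date"]])
    except (ValueError, AttributeError):
        raise ValueError(f"unparseable date {row[cols['date']]!r}")

    raw_minutes = (row.get(cols["minutes"]) or "").strip()
    minutes: int | None
    if raw_minutes == "":
        if activity is not ActivityType.CONTACT_ATTEMPT:
            raise ValueError(f"missing minutes on {activity.value} row")
        minutes = None
    else:
        try:
            minutes = int(raw_minutes)
        except ValueError:
            raise ValueError(f"unparseable minutes {raw_minutes!r}")
        if minutes < 0:
            raise ValueError(f"negative minutes {minutes}")

    mbc_col = cols.get("mbc_fraction_answered")
    raw_mbc = (row.get(mbc_col) or "").strip() if mbc_col else ""
    mbc: float | None = None
    if raw_mbc != "":
        if activity not in CM_ENCOUNTER_TYPES:
            raise ValueError(
                "mbc_fraction_answered only allowed on care-manager encounter rows"
            )
        try:
            mbc = float(raw_mbc)
        except ValueError:
            raise ValueError(f"unparseable mbc_fraction_answered {raw_mbc!r}")
        if not 0.0 <= mbc <= 1.0:
            raise ValueError(f"mbc_fraction_answered {mbc} outside [0, 1]")

    return RegistryEntry(
        patient_id=str(row[cols["patient_id"]]).strip(),
        clinic_id=str(row[cols["clinic_id"]]).strip(),
        date=date,
        activity_type=activity,
        minutes=minutes,
        mbc_fraction_answered=mbc,
    )


_TRUTHY = {"1", "true", "t", "yes", "y"}
_FALSY = {"0", "false", "f", "no", "n"}


def load_patients(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    strict: bool = True,
) -> LoadResult:
    """Read the patient table (randomization date, clinic, FQHC flag)."""
    cols = dict(DEFAULT_PATIENT_COLUMNS)
    if column_map:
        cols.update(column_map)
    required = ["patient_id", "clinic_id", "randomization_date", "is_fqhc"]
    result = LoadResult()
    for rownum, row in _open_rows(path, cols, required):
        try:
            try:
                rdate = _parse_date(row[cols["randomization_date"]])
            except (ValueError, AttributeError):
                raise ValueError(
                    f"unparseable randomization_date {row[cols['randomization_date']]!r}"
                )
            raw_fqhc = (row[cols["is_fqhc"]] or "").strip().lower()
            if raw_fqhc in _TRUTHY:
                fqhc = True
            elif raw_fqhc in _FALSY:
                fqhc = False
            else:
                raise ValueError(f"unparseable is_fqhc {raw_fqhc!r}")
            result.entries.append(
                PatientRecord(
                    patient_id=str(row[cols["patient_id"]]).strip(),
                    clinic_id=str(row[cols["clinic_id"]]).strip(),
                    randomization_date=rdate,
                    is_fqhc=fqhc,
                )
            )
        except ValueError as exc:
            result.issues.append(RowIssue(rownum, str(exc)))
    if strict and result.issues:
        raise RegistryValidationError(result.issues)
    return result


# ---------------------------------------------------------------------------
# transformation


def impute_contact_minutes(
    entries: Iterable[RegistryEntry], per_attempt_minutes: int = 5
) -> list[RegistryEntry]:
    """Assign a fixed duration to every contact attempt.

    The registry does not record time for contact attempts; per care-manager
    input each is assumed to take five minutes (ten in the pessimistic
    sensitivity variant). All other entries are returned unchanged.
    """
    if per_attempt_minutes <= 0:
        raise ConfigError(
            f"per_attempt_minutes must be positive, got {per_attempt_minutes}"
        )
    out = []
    for e in entries:
        if e.activity_type is ActivityType.CONTACT_ATTEMPT:
            out.append(dataclasses.replace(e, minutes=per_attempt_minutes))
        else:
            out.append(e)
    return out


def aggregate_months(
    entries: Iterable[RegistryEntry],
    patients: Iterable[PatientRecord],
    window_months: int = 6,
    mbc_complete_threshold: float = 0.5,
    window_days: int | None = None,
) -> list[PatientMonth]:
    """Aggregate entries into patient calendar months inside the window.

    Only entries with ``randomization_date <= date < end`` contribute, where
    ``end`` is ``window_months`` calendar months after randomization (or
    ``randomization_date + window_days`` when ``window_days`` is given).
    Entries past the window are silently truncated; entries *before*
    randomization are rejected with row-level diagnostics. MBC counts as
    present in a month when some care-manager encounter that month has
    ``mbc_fraction_answered >= mbc_complete_threshold``.

    Months with no entries are never emitted.
    """
    by_patient = {p.patient_id: p for p in patients}
    issues: list[RowIssue] = []
    buckets: dict[tuple[str, dt.date], list[RegistryEntry]] = defaultdict(list)

    for i, e in enumerate(entries, start=1):
        patient = by_patient.get(e.patient_id)
        if patient is None:
            issues.append(RowIssue(i, f"unknown patient_id {e.patient_id!r}"))
            continue
        if e.date < patient.randomization_date:
            issues.append(
                RowIssue(
                    i,
                    f"entry dated {e.date} before randomization "
                    f"{patient.randomization_date} for patient {e.patient_id}",
                )
            )
            continue
        if window_days is not None:
            end = patient.randomization_date + dt.timedelta(days=window_days)
        else:
            end = add_months(patient.randomization_date, window_months)
        if e.date >= end:
            continue  # past the intervention window
        if e.minutes is None:
            issues.append(
                RowIssue(
                    i,
                    "contact attempt with absent minutes; call "
                    "impute_contact_minutes before aggregation",
                )
            )
            continue
        buckets[(e.patient_id, month_of(e.date))].append(e)

    if issues:
        raise RegistryValidationError(issues)

    months: list[PatientMonth] = []
    for (pid, ym), es in sorted(buckets.items()):
        minutes_by_type: dict[ActivityType, int] = defaultdict(int)
        has_mbc = False
        for e in es:
            minutes_by_type[e.activity_type] += int(e.minutes)  # type: ignore[arg-type]
            if (
                e.activity_type in CM_ENCOUNTER_TYPES
                and e.mbc_fraction_answered is not None
                and e.mbc_fraction_answered >= mbc_complete_threshold
            ):
                has_mbc = True
        has_cm = any(t in minutes_by_type for t in CM_ENCOUNTER_TYPES)
        months.append(
            PatientMonth(
                patient_id=pid,
                year_month=ym,
                total_minutes=sum(minutes_by_type.values()),
                minutes_by_type=dict(minutes_by_type),
                has_cm_encounter=has_cm,
                has_bhc_consult=ActivityType.BHC_CONSULTATION in minutes_by_type,
                has_mbc=has_mbc,
                month_index=month_index(by_patient[pid].randomization_date, ym),
            )
        )
    return months


def write_patient_months(months: Sequence[PatientMonth], path: str | Path) -> None:
    """Write the normalized patient-month table as CSV for audit."""
    rows = []
    for m in months:
        row = {
            "patient_id": m.patient_id,
            "year_month": m.year_month.strftime("%Y-%m"),
            "month_index": m.month_index,
            "total_minutes": m.total_minutes,
            "has_cm_encounter": int(m.has_cm_encounter),
            "has_bhc_consult": int(m.has_bhc_consult),
            "has_mbc": int(m.has_mbc),
        }
        for t in ActivityType:
            row[f"minutes_{t.value.lower()}"] = m.minutes_by_type.get(t, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
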