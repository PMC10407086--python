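"""Visit-log data model, delimited-text I/O and exclusion filters.

One :class:`VisitRecord` describes a single ED visit: who arrived, where and
when, when a physician first saw them, when they left, basic demographics,
triage acuity on the RETTS scale (1 = highest urgency, optional 5th lowest
category), a chief-complaint code and — when the patient died within the
registry's follow-up — the calendar date of death.

Cleaning removes, in fixed precedence order, (a) duplicate rows, (b) visits
with implausibly long stays (> 72 h) and (c) rows whose death date precedes
the arrival date.  "Duplicate" is defined as an identical
``(patient_id, ed_id, arrival_ts)`` triple — the only key in a generic log
that cannot represent two distinct real visits; the first row in file order
is kept.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from datetime import date, datetime, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ConfigurationError
from .timeutil import (
    format_date,
    format_ts,
    parse_date,
    parse_ts,
)

__all__ = [
    "VisitRecord",
    "CleanReport",
    "RowDiagnostic",
    "read_visit_log",
    "write_visit_log",
    "clean_visits",
    "visits_to_frame",
    "frame_to_visits",
    "load_dialect",
]

#: Canonical column order for delimited visit logs.
COLUMNS = (
    "visit_id",
    "patient_id",
    "ed_id",
    "arrival_ts",
    "physician_ts",
    "departure_ts",
    "age_years",
    "sex",
    "ambulance",
    "admitted",
    "acuity",
    "complaint",
    "death_date",
)

_MAX_LOS = timedelta(hours=72)

_TRUE = {"true", "1", "yes", "y", "t"}
_FALSE = {"false", "0", "no", "n", "f"}


@dataclass(frozen=True)
class VisitRecord:
    """A single validated ED visit at minute/date resolution."""

    visit_id: str
    patient_id: str
    ed_id: str
    arrival_ts: datetime
    physician_ts: datetime | None
    departure_ts: datetime
    age_years: int
    sex: str  # "female" | "male"
    ambulance: bool
    admitted: bool
    acuity: int  # RETTS 1-5, 1 = highest urgency
    complaint: str
    death_date: date | None

    def invariant_violations(self) -> list[str]:
        """Return human-readable descriptions of violated invariants."""
        problems: list[str] = []
        if not self.arrival_ts < self.departure_ts:
            problems.append("arrival_ts must precede departure_ts")
        if self.physician_ts is not None and not (
            self.arrival_ts <= self.physician_ts <= self.departure_ts
        ):
            problems.append("physician_ts must lie within [arrival_ts, departure_ts]")
        if self.age_years < 0:
            problems.append("age_years must be non-negative")
        if self.sex not in ("female", "male"):
            problems.append("sex must be 'female' or 'male'")
        if self.acuity not in (1, 2, 3, 4, 5):
            problems.append("acuity must be an integer in 1..5")
        return problems

    @property
    def los_hours(self) -> float:
        return (self.departure_ts - self.arrival_ts).total_seconds() / 3600.0


@dataclass(frozen=True)
class CleanReport:
    """Tally of rows removed by :func:`clean_visits`, one reason per row."""

    n_input: int
    n_duplicates: int
    n_long_los: int
    n_bad_mortality: int
    n_retained: int

    def as_dict(self) -> dict[str, int]:
        return {
            "n_input": self.n_input,
            "n_duplicates": self.n_duplicates,
            "n_long_los": self.n_long_los,
            "n_bad_mortality": self.n_bad_mortality,
            "n_retained": self.n_retained,
        }


@dataclass(frozen=True)
class RowDiagnostic:
    """A row-indexed validation problem found while reading a log."""

    row: int  # 1-based data-row index (header excluded)
    message: str


def load_dialect(source: str | Path | Mapping[str, str] | None) -> dict[str, str]:
    """Load a column-name dialect: external column name -> canonical name.

    Accepts a mapping, a path to a JSON file, or ``None`` (identity).
    """
    if source is None:
        return {}
    if isinstance(source, Mapping):
        return dict(source)
    with open(source, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError("dialect file must contain a JSON object")
    return {str(k): str(v) for k, v in data.items()}


def _parse_bool(text: str, field: str) -> bool:
    low = text.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ValueError(f"{field}: cannot parse boolean from {text!r}")


def _parse_row(row: Mapping[str, str]) -> VisitRecord:
    physician_raw = (row["physician_ts"] or "").strip()
    death_raw = (row["death_date"] or "").strip()
    return VisitRecord(
        visit_id=row["visit_id"].strip(),
        patient_id=row["patient_id"].strip(),
        ed_id=row["ed_id"].strip(),
        arrival_ts=parse_ts(row["arrival_ts"].strip()),
        physician_ts=parse_ts(physician_raw) if physician_raw else None,
        departure_ts=parse_ts(row["departure_ts"].strip()),
        age_years=int(row["age_years"].strip()),
        sex=row["sex"].strip().lower(),
        ambulance=_parse_bool(row["ambulance"], "ambulance"),
        admitted=_parse_bool(row["admitted"], "admitted"),
        acuity=int(row["acuity"].strip()),
        complaint=row["complaint"].strip(),
        death_date=parse_date(death_raw) if death_raw else None,
    )


def read_visit_log(
    path: str | Path,
    dialect: str | Path | Mapping[str, str] | None = None,
    delimiter: str = ",",
) -> tuple[list[VisitRecord], list[RowDiagnostic]]:
    """Read a delimited visit log.

    Returns ``(records, diagnostics)``: one record per parseable row, and one
    row-indexed diagnostic per rejected row.  Rejections are collected, never
    silently dropped.  A required column that cannot be resolved through the
    dialect raises :class:`ConfigurationError`.
    """
    mapping = load_dialect(dialect)
    records: list[VisitRecord] = []
    diagnostics: list[RowDiagnostic] = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise ConfigurationError(f"{path}: empty file, header row required")
        canonical = [mapping.get(name, name) for name in reader.fieldnames]
        missing = [c for c in COLUMNS if c not in canonical]
        if missing:
            raise ConfigurationError(
                f"{path}: required columns not resolvable: {', '.join(missing)}"
            )
        rename = dict(zip(reader.fieldnames, canonical))
        for i, raw in enumerate(reader, start=1):
            row = {rename[k]: (v if v is not None else "") for k, v in raw.items() if k in rename}
            try:
                rec = _parse_row(row)
            except (ValueError, KeyError) as exc:
                diagnostics.append(RowDiagnostic(row=i, message=str(exc)))
                continue
            problems = rec.invariant_violations()
            if problems:
                diagnostics.append(RowDiagnostic(row=i, message="; ".join(problems)))
            else:
                records.append(rec)
    return records, diagnostics


def write_visit_log(
    records: Iterable[VisitRecord], path: str | Path, delimiter: str = ","
) -> None:
    """Write records as delimited text (absent values as empty fields)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.visit_id,
                    r.patient_id,
                    r.ed_id,
                    format_ts(r.arrival_ts),
                    format_ts(r.physician_ts) if r.physician_ts is not None else "",
                    format_ts(r.departure_ts),
                    r.age_years,
                    r.sex,
                    "true" if r.ambulance else "false",
                    "true" if r.admitted else "false",
                    r.acuity,
                    r.complaint,
                    format_date(r.death_date) if r.death_date is not None else "",
                ]
            )


def clean_visits(
    records: Sequence[VisitRecord],
) -> tuple[list[VisitRecord], CleanReport]:
    """Apply the exclusion filters and tally removals.

    Precedence per record is fixed — duplicate, then LOS > 72 h (strict), then
    death date strictly before the arrival date — so each removed record is
    counted under exactly one reason and the report is deterministic.
    The operation is idempotent.
    """
    retained: list[VisitRecord] = []
    n_dup = n_los = n_mort = 0
    seen: set[tuple[str, str, datetime]] = set()
    for rec in records:
        key = (rec.patient_id, rec.ed_id, rec.arrival_ts)
        if key in seen:
            n_dup += 1
            continue
        seen.add(key)
        if rec.departure_ts - rec.arrival_ts > _MAX_LOS:
            n_los += 1
            continue
        if rec.death_date is not None and rec.death_date < rec.arrival_ts.date():
            n_mort += 1
            continue
        retained.append(rec)
    report = CleanReport(
        n_input=len(records),
        n_duplicates=n_dup,
        n_long_los=n_los,
        n_bad_mortality=n_mort,
        n_retained=len(retained),
    )
    return retained, report


# ---------------------------------------------------------------------------
# pandas interop — the vectorized metric/survival code works on DataFrames

def visits_to_frame(records: Sequence[VisitRecord]) -> pd.DataFrame:
    """Convert records to the canonical DataFrame layout (datetime64 columns,
    ``NaT`` for absent physician contact / death)."""
    return pd.DataFrame(
        {
            "visit_id": [r.visit_id for r in records],
            "patient_id": [r.patient_id for r in records],
            "ed_id": [r.ed_id for r in records],
            "arrival_ts": pd.to_datetime([r.arrival_ts for r in records]),
            "physician_ts": pd.to_datetime([r.physician_ts for r in records]),
            "departure_ts": pd.to_datetime([r.departure_ts for r in records]),
            "age_years": [r.age_years for r in records],
            "sex": [r.sex for r in records],
            "ambulance": [r.ambulance for r in records],
            "admitted": [r.admitted for r in records],
            "acuity": [r.acuity for r in records],
            "complaint": [r.complaint for r in records],
            "death_date": pd.to_datetime(
                [r.death_date for r in records]
            ),
        }
    )


def frame_to_visits(frame: pd.DataFrame) -> list[VisitRecord]:
    out: list[VisitRecord] = []
    for row in frame.itertuples(index=False):
        out.append(
            VisitRecord(
                visit_id=str(row.visit_id),
                patient_id=str(row.patient_id),
                ed_id=str(row.ed_id),
                arrival_ts=row.arrival_ts.to_pydatetime(),
                physician_ts=None
                if pd.isna(row.physician_ts)
                else row.physician_ts.to_pydatetime(),
                departure_ts=row.departure_ts.to_pydatetime(),
                age_years=int(row.age_years),
                sex=str(row.sex),
                ambulance=bool(row.ambulance),
                admitted=bool(row.admitted),
                acuity=int(row.acuity),
                complaint=str(row.complaint),
                death_date=None
                if pd.isna(row.death_date)
                else row.death_date.date(),
            )
        )
    return out
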