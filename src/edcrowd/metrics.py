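"""Per-ED, per-clock-hour crowding measurements.

Implements the workload-based mSEAL score (modified Skåne Emergency
Department Assessment of Patient Load) and the occupancy rate.

For the hourly window ``[H-1h, H)``:

* **census** — number of distinct patients present at any moment of the
  window (arrival inclusive, departure exclusive);
* **Patient Hours** — sum of time in hours that those patients spent in the
  ED during the window, divided by the census; a dimensionless fraction in
  ``(0, 1]``, absent when the census is zero;
* **Time to Physician** — mean realized registration-to-first-physician
  wait, in hours, over patients whose waiting interval overlaps the window;
  absent when nobody was waiting;
* **mSEAL** = ``1.485 + 9.715 * PatientHours + 0.177 * TimeToPhysician``,
  clamped into [1, 6] by default (the clamp can be bypassed for
  diagnostics); absent whenever either input is absent;
* **occupancy rate** — patients present at the instant ``H`` divided by the
  number of treatment beds.

All intervals are half-open, so a patient departing exactly at *t* is not
present at *t*, and no patient is double-counted at window boundaries.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError
from .timeutil import format_ts, hours_between, is_on_hour, parse_ts
from .visitlog import VisitRecord, visits_to_frame

__all__ = [
    "Window",
    "HourlyMetrics",
    "MSEAL_INTERCEPT",
    "MSEAL_PATIENT_HOURS_COEF",
    "MSEAL_TTP_COEF",
    "present_interval",
    "census_during",
    "patient_hours",
    "time_to_physician",
    "mseal_score",
    "occupancy_at",
    "hourly_metrics",
    "write_metrics",
    "read_metrics",
]

MSEAL_INTERCEPT = 1.485
MSEAL_PATIENT_HOURS_COEF = 9.715
MSEAL_TTP_COEF = 0.177
MSEAL_MIN = 1.0
MSEAL_MAX = 6.0

METRIC_COLUMNS = (
    "ed_id",
    "hour_start",
    "census",
    "patient_hours",
    "time_to_physician",
    "mseal",
    "occupancy_rate",
    "beds",
)


@dataclass(frozen=True)
class Window:
    """Half-open time window ``[start, end)``."""

    start: datetime
    end: datetime

    def __post_init__(self):
        if not self.start < self.end:
            raise DomainError("window start must precede end")

    @property
    def length_hours(self) -> float:
        return hours_between(self.start, self.end)


@dataclass(frozen=True)
class HourlyMetrics:
    """Crowding measurements for one ED and one clock hour.

    ``census``/``patient_hours``/``time_to_physician``/``mseal`` describe the
    preceding one-hour window ``[hour_start - 1h, hour_start)``;
    ``occupancy_rate`` is instantaneous at ``hour_start``.  Absent values are
    ``None``.
    """

    ed_id: str
    hour_start: datetime
    census: int
    patient_hours: float | None
    time_to_physician: float | None
    mseal: float | None
    occupancy_rate: float
    beds: int


def present_interval(visit: VisitRecord, window: Window) -> float:
    """Length in hours of ``[arrival, departure) ∩ [start, end)``."""
    lo = max(visit.arrival_ts, window.start)
    hi = min(visit.departure_ts, window.end)
    if hi <= lo:
        return 0.0
    return hours_between(lo, hi)


def census_during(
    visits: Iterable[VisitRecord], ed: str, window: Window
) -> int:
    """Number of distinct visits at *ed* present at any moment of *window*."""
    return sum(
        1
        for v in visits
        if v.ed_id == ed and present_interval(v, window) > 0.0
    )


def patient_hours(
    visits: Sequence[VisitRecord], ed: str, window: Window
) -> float | None:
    """Patient Hours for the window, or ``None`` when the census is zero."""
    overlaps = [
        present_interval(v, window)
        for v in visits
        if v.ed_id == ed
    ]
    overlaps = [o for o in overlaps if o > 0.0]
    if not overlaps:
        return None
    return sum(overlaps) / len(overlaps)


def time_to_physician(
    visits: Sequence[VisitRecord],
    ed: str,
    window: Window,
    elapsed: bool = False,
) -> float | None:
    """Mean wait in hours among patients waiting during the window.

    A visit qualifies when its waiting interval ``[arrival, physician)``
    overlaps the window with positive length (patients never seen by a
    physician are excluded).  By default the realized full wait is averaged;
    with ``elapsed=True`` the wait-so-far censored at the window end is used
    instead.
    """
    waits: list[float] = []
    for v in visits:
        if v.ed_id != ed or v.physician_ts is None:
            continue
        lo = max(v.arrival_ts, window.start)
        hi = min(v.physician_ts, window.end)
        if hi <= lo:
            continue
        if elapsed:
            waits.append(hours_between(v.arrival_ts, min(v.physician_ts, window.end)))
        else:
            waits.append(hours_between(v.arrival_ts, v.physician_ts))
    if not waits:
        return None
    return sum(waits) / len(waits)


def mseal_score(ph: float, ttp: float, clamp: bool = True) -> float:
    """mSEAL workload score from Patient Hours and Time to Physician.

    The linear form can exceed 6 even though the score is described as
    ranging from 1 (no crowding) to 6 (extreme crowding); by default the
    result is truncated into [1, 6].
    """
    if ph < 0 or ttp < 0:
        raise DomainError("patient hours and time to physician must be >= 0")
    score = MSEAL_INTERCEPT + MSEAL_PATIENT_HOURS_COEF * ph + MSEAL_TTP_COEF * ttp
    if clamp:
        score = min(max(score, MSEAL_MIN), MSEAL_MAX)
    return score


def occupancy_at(
    visits: Iterable[VisitRecord], ed: str, t: datetime, beds: int
) -> float:
    """Patients present at instant *t* divided by treatment beds."""
    if beds <= 0:
        raise ConfigurationError("beds must be > 0")
    present = sum(
        1
        for v in visits
        if v.ed_id == ed and v.arrival_ts <= t < v.departure_ts
    )
    return present / beds


# ---------------------------------------------------------------------------
# Vectorized hourly series


def _explode_hour_overlaps(
    start_h: np.ndarray, end_h: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Explode half-open intervals (in fractional hours relative to an
    origin) over the integer-hour windows they touch.

    Returns ``(visit_index, window_start, overlap_hours)`` with every overlap
    strictly positive.  Window ``s`` covers ``[s, s+1)``.
    """
    if len(start_h) == 0:
        empty = np.array([], dtype=np.int64)
        return empty, empty, np.array([], dtype=float)
    s0 = np.floor(start_h).astype(np.int64)
    s1 = np.ceil(end_h).astype(np.int64) - 1  # inclusive last touched window
    counts = s1 - s0 + 1
    vi = np.repeat(np.arange(len(start_h)), counts)
    # per-visit running offsets 0..counts-1
    offs = np.arange(counts.sum()) - np.repeat(
        np.concatenate(([0], np.cumsum(counts)[:-1])), counts
    )
    win = np.repeat(s0, counts) + offs
    ov = np.minimum(end_h[vi], win + 1.0) - np.maximum(start_h[vi], win)
    keep = ov > 0.0
    return vi[keep], win[keep], ov[keep]


def hourly_metrics(
    visits: Sequence[VisitRecord] | pd.DataFrame,
    ed_config: Mapping[str, int],
    period: Window,
    clamp: bool = True,
    elapsed_wait: bool = False,
) -> pd.DataFrame:
    """Compute the full hourly metric series for every configured ED.

    For every ED in *ed_config* and every clock hour ``H`` in ``[period.start,
    period.end)``, window statistics are computed on ``[H-1h, H)`` and the
    occupancy rate at the instant ``H``.  Visits outside the period still
    contribute to windows they overlap.  mSEAL is absent for hours where
    Patient Hours or Time to Physician is absent.

    Returns a DataFrame with columns :data:`METRIC_COLUMNS`, sorted by
    ``(ed_id, hour_start)``.
    """
    if not (is_on_hour(period.start) and is_on_hour(period.end)):
        raise ConfigurationError("period boundaries must lie on the hour")
    frame = visits if isinstance(visits, pd.DataFrame) else visits_to_frame(visits)
    if len(frame):
        unknown = set(frame["ed_id"].unique()) - set(ed_config)
        if unknown:
            raise ConfigurationError(
                f"EDs present in visits but not configured: {sorted(unknown)}"
            )
    for ed, beds in ed_config.items():
        if beds <= 0:
            raise ConfigurationError(f"beds must be > 0 for ED {ed!r}")

    n_hours = int(round(period.length_hours))
    origin = period.start
    pieces: list[pd.DataFrame] = []
    for ed in sorted(ed_config):
        beds = int(ed_config[ed])
        sub = frame[frame["ed_id"] == ed] if len(frame) else frame
        census = np.zeros(n_hours, dtype=np.int64)
        ph_sum = np.zeros(n_hours, dtype=float)
        ttp_sum = np.zeros(n_hours, dtype=float)
        ttp_n = np.zeros(n_hours, dtype=np.int64)
        occ = np.zeros(n_hours, dtype=np.int64)
        if len(sub):
            a = (sub["arrival_ts"] - origin).dt.total_seconds().to_numpy() / 3600.0
            d = (sub["departure_ts"] - origin).dt.total_seconds().to_numpy() / 3600.0
            # presence over windows: window s = [s, s+1) maps to row H = s+1
            vi, win, ov = _explode_hour_overlaps(a, d)
            row = win + 1  # hour row index of window [H-1, H)
            ok = (row >= 0) & (row < n_hours)
            census += np.bincount(row[ok], minlength=n_hours)
            ph_sum += np.bincount(row[ok], weights=ov[ok], minlength=n_hours)
            # waiting intervals
            seen = sub["physician_ts"].notna().to_numpy()
            if seen.any():
                aw = a[seen]
                pw = (
                    (sub.loc[seen, "physician_ts"] - origin)
                    .dt.total_seconds()
                    .to_numpy()
                    / 3600.0
                )
                pos = pw > aw
                aw, pw = aw[pos], pw[pos]
                if len(aw):
                    wi, wwin, _ = _explode_hour_overlaps(aw, pw)
                    wrow = wwin + 1
                    wok = (wrow >= 0) & (wrow < n_hours)
                    if elapsed_wait:
                        # wait-so-far censored at window end (window end = wwin+1)
                        wait_vals = np.minimum(pw[wi], wwin + 1.0) - aw[wi]
                    else:
                        wait_vals = (pw - aw)[wi]
                    ttp_sum += np.bincount(
                        wrow[wok], weights=wait_vals[wok], minlength=n_hours
                    )
                    ttp_n += np.bincount(wrow[wok], minlength=n_hours)
            # instantaneous occupancy at hours 0..n_hours-1
            a_sorted = np.sort(a)
            d_sorted = np.sort(d)
            hours = np.arange(n_hours, dtype=float)
            occ = np.searchsorted(a_sorted, hours, side="right") - np.searchsorted(
                d_sorted, hours, side="right"
            )

        ph = np.where(census > 0, ph_sum / np.maximum(census, 1), np.nan)
        ttp = np.where(ttp_n > 0, ttp_sum / np.maximum(ttp_n, 1), np.nan)
        mseal = MSEAL_INTERCEPT + MSEAL_PATIENT_HOURS_COEF * ph + MSEAL_TTP_COEF * ttp
        if clamp:
            mseal = np.clip(mseal, MSEAL_MIN, MSEAL_MAX)
        pieces.append(
            pd.DataFrame(
                {
                    "ed_id": ed,
                    "hour_start": pd.date_range(
                        origin, periods=n_hours, freq="h"
                    ),
                    "census": census,
                    "patient_hours": ph,
                    "time_to_physician": ttp,
                    "mseal": mseal,
                    "occupancy_rate": occ / beds,
                    "beds": beds,
                }
            )
        )
    if not pieces:
        return pd.DataFrame(columns=list(METRIC_COLUMNS))
    return pd.concat(pieces, ignore_index=True)


def metrics_to_records(frame: pd.DataFrame) -> list[HourlyMetrics]:
    """Row-wise view of a metric series as :class:`HourlyMetrics` objects."""
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            HourlyMetrics(
                ed_id=str(row.ed_id),
                hour_start=row.hour_start.to_pydatetime(),
                census=int(row.census),
                patient_hours=None if math.isnan(row.patient_hours) else float(row.patient_hours),
                time_to_physician=None
                if math.isnan(row.time_to_physician)
                else float(row.time_to_physician),
                mseal=None if math.isnan(row.mseal) else float(row.mseal),
                occupancy_rate=float(row.occupancy_rate),
                beds=int(row.beds),
            )
        )
    return out


def write_metrics(frame: pd.DataFrame, path: str | Path, delimiter: str = ",") -> None:
    """Write a metric series as delimited text; absent values as empty fields."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(METRIC_COLUMNS)
        for row in frame.itertuples(index=False):
            writer.writerow(
                [
                    row.ed_id,
                    format_ts(row.hour_start.to_pydatetime()),
                    int(row.census),
                    "" if math.isnan(row.patient_hours) else repr(float(row.patient_hours)),
                    ""
                    if math.isnan(row.time_to_physician)
                    else repr(float(row.time_to_physician)),
                    "" if math.isnan(row.mseal) else repr(float(row.mseal)),
                    repr(float(row.occupancy_rate)),
                    int(row.beds),
                ]
            )


def read_metrics(path: str | Path, delimiter: str = ",") -> pd.DataFrame:
    rows = []
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        for raw in reader:
            rows.append(
                {
                    "ed_id": raw["ed_id"],
                    "hour_start": parse_ts(raw["hour_start"]),
                    "census": int(raw["census"]),
                    "patient_hours": float(raw["patient_hours"]) if raw["patient_hours"] else np.nan,
                    "time_to_physician": float(raw["time_to_physician"])
                    if raw["time_to_physician"]
                    else np.nan,
                    "mseal": float(raw["mseal"]) if raw["mseal"] else np.nan,
                    "occupancy_rate": float(raw["occupancy_rate"]),
                    "beds": int(raw["beds"]),
                }
            )
    frame = pd.DataFrame(rows, columns=list(METRIC_COLUMNS))
    frame["hour_start"] = pd.to_datetime(frame["hour_start"])
    return frame
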