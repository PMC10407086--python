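"""Stratified percentile exposure categories and left truncation.

Crowding exposure for a visit is the value of a crowding metric (mSEAL or
occupancy rate) at the visit's arrival hour, categorized against the
empirical 85th/90th/95th percentiles of that metric computed separately for
every (ED, hour-of-day) stratum.  Stratification absorbs baseline
differences between sites and intra-day variation, so the categories are
comparable across EDs.  Bins are lower-inclusive: a value exactly equal to a
cutpoint goes to the higher-crowding bin.  Hours where the metric could not
be computed yield the MISSING category, which is excluded from regression
models downstream.

Left truncation removes, per patient, every visit arriving within the
follow-up horizon of an already-retained visit of the same patient, so that
repeated visits shortly before death cannot enter the analysis twice.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError
from .timeutil import floor_hour
from .visitlog import VisitRecord, visits_to_frame

__all__ = [
    "ExposureCategory",
    "ExposureThresholds",
    "compute_thresholds",
    "assign_exposure",
    "assign_exposure_frame",
    "left_truncate",
    "METRIC_COLUMN",
]

#: metric name -> column of the hourly metric series holding its values
METRIC_COLUMN = {"mseal": "mseal", "occupancy": "occupancy_rate"}

#: Strata narrower than this get an instability warning when thresholds
#: are computed (empirical 95th percentiles on <20 points are noisy).
MIN_STRATUM_N = 20


class ExposureCategory(str, Enum):
    """Quantile bin of a visit's arrival-hour crowding value."""

    REF_LT85 = "REF_LT85"  # < 85th percentile (reference)
    Q85_90 = "Q85_90"  # [85th, 90th)
    Q90_95 = "Q90_95"  # [90th, 95th)
    GT95 = "GT95"  # >= 95th percentile
    MISSING = "MISSING"  # metric not computable for the arrival hour

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Canonical display order of the categories.
CATEGORY_ORDER = (
    ExposureCategory.REF_LT85,
    ExposureCategory.Q85_90,
    ExposureCategory.Q90_95,
    ExposureCategory.GT95,
    ExposureCategory.MISSING,
)


@dataclass
class ExposureThresholds:
    """Per-(ED, hour-of-day) 85/90/95th percentile cutpoints for one metric."""

    metric: str
    cutpoints: dict[tuple[str, int], tuple[float, float, float]] = field(
        default_factory=dict
    )

    def lookup(self, ed_id: str, hour_of_day: int) -> tuple[float, float, float]:
        try:
            return self.cutpoints[(ed_id, hour_of_day)]
        except KeyError:
            raise ConfigurationError(
                f"no thresholds for stratum (ed={ed_id!r}, hour={hour_of_day})"
            ) from None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"ed_id": ed, "hour": hod, "q85": q85, "q90": q90, "q95": q95}
            for (ed, hod), (q85, q90, q95) in sorted(self.cutpoints.items())
        ]
        return pd.DataFrame(rows, columns=["ed_id", "hour", "q85", "q90", "q95"])

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "metric": self.metric,
            "strata": [
                {"ed": ed, "hour": hod, "q85": q85, "q90": q90, "q95": q95}
                for (ed, hod), (q85, q90, q95) in sorted(self.cutpoints.items())
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ExposureThresholds":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text(encoding="utf-8")
        data = json.loads(text)
        cuts = {
            (s["ed"], int(s["hour"])): (s["q85"], s["q90"], s["q95"])
            for s in data["strata"]
        }
        return cls(metric=data["metric"], cutpoints=cuts)


def compute_thresholds(series: pd.DataFrame, metric: str) -> ExposureThresholds:
    """Empirical 85/90/95th percentile cutpoints per (ED, hour-of-day).

    Quantiles use linear interpolation between order statistics.  Absent
    metric values do not contribute; strata with no observed values get no
    cutpoints.  Strata with fewer than ``MIN_STRATUM_N`` values trigger an
    instability warning.
    """
    if metric not in METRIC_COLUMN:
        raise ConfigurationError(f"unknown metric {metric!r}")
    col = METRIC_COLUMN[metric]
    thresholds = ExposureThresholds(metric=metric)
    if not len(series):
        return thresholds
    work = series[["ed_id", "hour_start", col]].copy()
    work["hour"] = pd.DatetimeIndex(work["hour_start"]).hour
    for (ed, hod), grp in work.groupby(["ed_id", "hour"], sort=True):
        values = grp[col].dropna().to_numpy(dtype=float)
        if len(values) == 0:
            continue
        if len(values) < MIN_STRATUM_N:
            warnings.warn(
                f"stratum (ed={ed!r}, hour={hod}) has only {len(values)} "
                "values; percentile cutpoints may be unstable",
                stacklevel=2,
            )
        q85, q90, q95 = np.quantile(values, [0.85, 0.90, 0.95], method="linear")
        thresholds.cutpoints[(str(ed), int(hod))] = (float(q85), float(q90), float(q95))
    return thresholds


def categorize(value: float, cuts: tuple[float, float, float]) -> ExposureCategory:
    """Bin a metric value against (q85, q90, q95); lower-inclusive bins."""
    q85, q90, q95 = cuts
    if value >= q95:
        return ExposureCategory.GT95
    if value >= q90:
        return ExposureCategory.Q90_95
    if value >= q85:
        return ExposureCategory.Q85_90
    return ExposureCategory.REF_LT85


def assign_exposure(
    visit: VisitRecord,
    series: pd.DataFrame,
    thresholds: ExposureThresholds,
) -> ExposureCategory:
    """Exposure category for one visit.

    The visit's arrival hour ``H`` (arrival floored to the hour) indexes the
    metric row whose window is the most recent completed hour ``[H-1h, H)``.
    An absent metric value yields MISSING; otherwise the value is binned
    against the visit's (ED, hour-of-day) cutpoints.
    """
    col = METRIC_COLUMN[thresholds.metric]
    hour = floor_hour(visit.arrival_ts)
    match = series[
        (series["ed_id"] == visit.ed_id) & (series["hour_start"] == hour)
    ]
    if not len(match):
        raise ConfigurationError(
            f"metric series has no row for (ed={visit.ed_id!r}, hour={hour})"
        )
    value = float(match.iloc[0][col]) if not pd.isna(match.iloc[0][col]) else None
    if value is None:
        return ExposureCategory.MISSING
    return categorize(value, thresholds.lookup(visit.ed_id, hour.hour))


def assign_exposure_frame(
    visits: Sequence[VisitRecord] | pd.DataFrame,
    series: pd.DataFrame,
    thresholds: ExposureThresholds,
) -> pd.Series:
    """Vectorized :func:`assign_exposure` for a whole log.

    Returns a Series of category strings aligned with the input order.
    """
    frame = visits if isinstance(visits, pd.DataFrame) else visits_to_frame(visits)
    if not len(frame):
        return pd.Series([], dtype=object)
    col = METRIC_COLUMN[thresholds.metric]
    hours = frame["arrival_ts"].dt.floor("h")
    lookup = frame[["ed_id"]].copy()
    lookup["hour_start"] = hours
    merged = lookup.merge(
        series[["ed_id", "hour_start", col]],
        on=["ed_id", "hour_start"],
        how="left",
        validate="many_to_one",
        indicator=True,
    )
    if (merged["_merge"] == "left_only").any():
        bad = merged.loc[merged["_merge"] == "left_only", ["ed_id", "hour_start"]].iloc[0]
        raise ConfigurationError(
            f"metric series has no row for (ed={bad['ed_id']!r}, hour={bad['hour_start']})"
        )
    values = merged[col].to_numpy(dtype=float)
    hod = pd.DatetimeIndex(merged["hour_start"]).hour.to_numpy()
    eds = merged["ed_id"].to_numpy()

    cuts = thresholds.to_frame()
    cut_map = cuts.set_index(["ed_id", "hour"]) if len(cuts) else None
    out = np.empty(len(frame), dtype=object)
    observed = ~np.isnan(values)
    out[~observed] = ExposureCategory.MISSING.value
    if observed.any():
        if cut_map is None:
            raise ConfigurationError("thresholds are empty but observed values exist")
        keys = pd.MultiIndex.from_arrays([eds[observed], hod[observed]])
        try:
            sel = cut_map.loc[keys]
        except KeyError as exc:
            raise ConfigurationError(f"uncovered stratum: {exc}") from None
        q85 = sel["q85"].to_numpy()
        q90 = sel["q90"].to_numpy()
        q95 = sel["q95"].to_numpy()
        v = values[observed]
        cat = np.full(v.shape, ExposureCategory.REF_LT85.value, dtype=object)
        cat[v >= q85] = ExposureCategory.Q85_90.value
        cat[v >= q90] = ExposureCategory.Q90_95.value
        cat[v >= q95] = ExposureCategory.GT95.value
        out[observed] = cat
    return pd.Series(out, index=frame.index, name="exposure")


def left_truncate(
    visits: Sequence[VisitRecord], horizon_days: int
) -> list[VisitRecord]:
    """Keep, per patient, only visits separated from the last retained visit
    of the same patient by more than *horizon_days*.

    Scanning each patient's visits in arrival order, a visit is retained iff
    no retained visit of that patient arrived within the preceding
    *horizon_days*.  Visits of different patients never interact.  The
    operation is idempotent and preserves the original relative order.
    """
    if horizon_days <= 0:
        raise DomainError("horizon_days must be > 0")
    horizon = pd.Timedelta(days=horizon_days)
    order: dict[str, list[tuple]] = {}
    for idx, v in enumerate(visits):
        order.setdefault(v.patient_id, []).append((v.arrival_ts, idx))
    keep: set[int] = set()
    for _patient, items in order.items():
        items.sort()
        last_kept = None
        for ts, idx in items:
            if last_kept is None or (ts - last_kept) > horizon:
                keep.add(idx)
                last_kept = ts
    return [v for i, v in enumerate(visits) if i in keep]
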