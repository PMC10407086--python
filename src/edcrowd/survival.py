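"""Covariate encoding, unadjusted mortality tables and Cox models.

Outcomes are all-cause death within 1, 7 or 30 days of ED arrival.  Death
dates carry calendar-day resolution, so a death counts toward a horizon when
``death_date - arrival_date`` is strictly less than the horizon in days, and
the event time is that whole-day difference plus 0.5 days — the half-day
offset avoids zero-length survival times while keeping every event time
inside the horizon.  Censoring time is the horizon itself.

Adjustment covariates follow the study encoding: age bands 0-18 / 19-39 /
40-59 / 60-79 / 80+, sex, arrival by ambulance, hospital admission, RETTS
acuity with the optional 5th category merged into 4 and then inverted
(``acuity_inv = 5 - acuity``, so 1 is the lowest acuity), and chief
complaint collapsed to the ten codes with the highest absolute 30-day death
counts plus OTHER.  The proportional-hazards fit uses Efron tie handling
(day-resolution data are heavily tied) and 95% Wald intervals on the
hazard-ratio scale; the numeric engine is lifelines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError, EstimationError
from .exposure import CATEGORY_ORDER, ExposureCategory
from .visitlog import VisitRecord, visits_to_frame

__all__ = [
    "AnalysisRow",
    "CoxResult",
    "OTHER_COMPLAINT",
    "AGE_BANDS",
    "top_complaints",
    "encode_covariates",
    "build_analysis_frame",
    "mortality_table",
    "mortality_percent",
    "fit_cox",
    "repeat_visit_summary",
]

OTHER_COMPLAINT = "OTHER"

AGE_BANDS = ("0-18", "19-39", "40-59", "60-79", "80+")
_AGE_EDGES = (-1, 18, 39, 59, 79, np.inf)  # right-inclusive edges for pd.cut

#: Reference levels for the regression design matrix.
REFERENCE_LEVELS = {
    "exposure": ExposureCategory.REF_LT85.value,
    "age_band": AGE_BANDS[0],
    "sex": "female",
    "acuity_inv": 1,
    "complaint_cat": OTHER_COMPLAINT,
}


@dataclass(frozen=True)
class AnalysisRow:
    """One encoded visit ready for survival modelling."""

    time: float  # days, in (0, horizon]
    event: bool
    exposure: str  # ExposureCategory value
    age_band: str
    sex: str
    ambulance: bool
    admitted: bool
    acuity_inv: int  # 1..4, 1 = lowest acuity
    complaint_cat: str


@dataclass(frozen=True)
class CoxResult:
    """Adjusted proportional-hazards estimates for one follow-up horizon."""

    horizon_days: int
    hazard_ratios: dict[str, tuple[float, float, float]]  # level -> (HR, lo, hi)
    coefficients: dict[str, float]
    n_rows: int
    n_events: int

    def as_dict(self) -> dict:
        return {
            "horizon_days": self.horizon_days,
            "hazard_ratios": {
                k: {"hr": v[0], "ci_low": v[1], "ci_high": v[2]}
                for k, v in self.hazard_ratios.items()
            },
            "coefficients": dict(self.coefficients),
            "n_rows": self.n_rows,
            "n_events": self.n_events,
        }


def _death_days(visit: VisitRecord) -> int | None:
    """Whole days from arrival date to death date, or None."""
    if visit.death_date is None:
        return None
    return (visit.death_date - visit.arrival_ts.date()).days


def died_within(visit: VisitRecord, horizon_days: int) -> bool:
    """Death strictly within *horizon_days* of the arrival date."""
    d = _death_days(visit)
    return d is not None and 0 <= d < horizon_days


def top_complaints(
    visits: Sequence[VisitRecord], k: int = 10
) -> dict[str, str]:
    """Map complaint codes to analysis categories.

    Codes are ranked by their absolute count of deaths within 30 days of
    arrival (count, not rate); the top *k* map to themselves and the rest to
    ``OTHER``.  Ties at rank *k* are broken by lexicographic code order.
    """
    deaths: dict[str, int] = {}
    codes: set[str] = set()
    for v in visits:
        codes.add(v.complaint)
        if died_within(v, 30):
            deaths[v.complaint] = deaths.get(v.complaint, 0) + 1
    ranked = sorted(codes, key=lambda c: (-deaths.get(c, 0), c))
    top = set(ranked[:k])
    return {c: (c if c in top else OTHER_COMPLAINT) for c in sorted(codes)}


def age_band(age_years: int) -> str:
    """Study age band; age 80 falls in the oldest band."""
    if age_years < 0:
        raise DomainError("age must be non-negative")
    for label, hi in zip(AGE_BANDS, _AGE_EDGES[1:]):
        if age_years <= hi:
            return label
    raise AssertionError("unreachable")


def encode_covariates(
    visit: VisitRecord,
    complaint_map: Mapping[str, str],
    horizon_days: int,
    exposure: ExposureCategory | str,
) -> AnalysisRow:
    """Encode one visit (with its already-assigned exposure) for modelling."""
    if visit.age_years < 0:
        raise DomainError("age must be non-negative")
    if visit.acuity not in (1, 2, 3, 4, 5):
        raise DomainError("acuity must be in 1..5")
    acuity = min(visit.acuity, 4)  # optional 5th category merged into 4
    d = _death_days(visit)
    event = d is not None and 0 <= d < horizon_days
    time = (d + 0.5) if event else float(horizon_days)
    return AnalysisRow(
        time=time,
        event=event,
        exposure=str(getattr(exposure, "value", exposure)),
        age_band=age_band(visit.age_years),
        sex=visit.sex,
        ambulance=visit.ambulance,
        admitted=visit.admitted,
        acuity_inv=5 - acuity,
        complaint_cat=complaint_map.get(visit.complaint, OTHER_COMPLAINT),
    )


def build_analysis_frame(
    visits: Sequence[VisitRecord] | pd.DataFrame,
    exposures: Sequence[str] | pd.Series,
    complaint_map: Mapping[str, str],
    horizon_days: int,
) -> pd.DataFrame:
    """Vectorized covariate encoding for a whole log.

    Equivalent to :func:`encode_covariates` row by row; returns a DataFrame
    with one column per :class:`AnalysisRow` field.
    """
    frame = visits if isinstance(visits, pd.DataFrame) else visits_to_frame(visits)
    exp = pd.Series(list(exposures), index=frame.index, dtype=object).map(
        lambda e: str(getattr(e, "value", e))
    )
    death_days = (
        frame["death_date"] - frame["arrival_ts"].dt.normalize()
    ).dt.days
    event = death_days.notna() & (death_days >= 0) & (death_days < horizon_days)
    time = np.where(event, death_days + 0.5, float(horizon_days))
    bands = pd.cut(
        frame["age_years"], bins=_AGE_EDGES, labels=AGE_BANDS, right=True
    ).astype(str)
    acuity_inv = 5 - frame["acuity"].clip(upper=4)
    return pd.DataFrame(
        {
            "time": time,
            "event": event.to_numpy(),
            "exposure": exp.to_numpy(),
            "age_band": bands.to_numpy(),
            "sex": frame["sex"].to_numpy(),
            "ambulance": frame["ambulance"].to_numpy(),
            "admitted": frame["admitted"].to_numpy(),
            "acuity_inv": acuity_inv.to_numpy(),
            "complaint_cat": frame["complaint"]
            .map(lambda c: complaint_map.get(c, OTHER_COMPLAINT))
            .to_numpy(),
        }
    )


def mortality_percent(deaths: int, n: int) -> float:
    """Unadjusted mortality percentage, rounded to 2 decimals."""
    if n <= 0:
        raise DomainError("group size must be positive")
    if deaths < 0 or deaths > n:
        raise DomainError("deaths must lie in [0, n]")
    return round(100.0 * deaths / n, 2)


def mortality_table(
    visits: Sequence[VisitRecord],
    exposures: Sequence[str | ExposureCategory],
    horizons: Sequence[int] = (1, 7, 30),
) -> pd.DataFrame:
    """Unadjusted outcome characteristics per exposure category.

    One row per category (in canonical order) with group size, death counts
    and percentages at each horizon, and LOS mean/SD/median/IQR in hours.
    Empty categories yield absent (NaN) entries.  LOS SD uses the sample
    estimator (ddof=1), reported as 0 for singleton groups.
    """
    if len(visits) != len(exposures):
        raise ConfigurationError("visits and exposures must align")
    cats = [str(getattr(e, "value", e)) for e in exposures]
    rows = []
    for cat in (c.value for c in CATEGORY_ORDER):
        members = [v for v, c in zip(visits, cats) if c == cat]
        row: dict = {"exposure": cat, "n": len(members)}
        if members:
            for h in horizons:
                deaths = sum(died_within(v, h) for v in members)
                row[f"deaths_{h}d"] = deaths
                row[f"pct_{h}d"] = mortality_percent(deaths, len(members))
            los = np.array([v.los_hours for v in members], dtype=float)
            row["los_mean_h"] = float(np.mean(los))
            row["los_sd_h"] = float(np.std(los, ddof=1)) if len(los) > 1 else 0.0
            q1, med, q3 = np.percentile(los, [25, 50, 75])
            row["los_median_h"] = float(med)
            row["los_iqr_low_h"] = float(q1)
            row["los_iqr_high_h"] = float(q3)
        else:
            for h in horizons:
                row[f"deaths_{h}d"] = np.nan
                row[f"pct_{h}d"] = np.nan
            for key in (
                "los_mean_h",
                "los_sd_h",
                "los_median_h",
                "los_iqr_low_h",
                "los_iqr_high_h",
            ):
                row[key] = np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("exposure")


_EXPOSURE_DUMMY_ORDER = (
    ExposureCategory.Q85_90.value,
    ExposureCategory.Q90_95.value,
    ExposureCategory.GT95.value,
)


def _design_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Dummy-encode the analysis frame with fixed reference levels.

    One indicator per non-reference level actually present; boolean
    covariates as 0/1; constant columns dropped (a Cox model has no
    intercept, so constants are unidentifiable).
    """
    X = pd.DataFrame(index=df.index)
    for level in _EXPOSURE_DUMMY_ORDER:
        if (df["exposure"] == level).any():
            X[f"exposure[{level}]"] = (df["exposure"] == level).astype(float)
    for band in AGE_BANDS[1:]:
        if (df["age_band"] == band).any():
            X[f"age_band[{band}]"] = (df["age_band"] == band).astype(float)
    X["sex[male]"] = (df["sex"] == "male").astype(float)
    X["ambulance"] = df["ambulance"].astype(float)
    X["admitted"] = df["admitted"].astype(float)
    for level in (2, 3, 4):
        if (df["acuity_inv"] == level).any():
            X[f"acuity_inv[{level}]"] = (df["acuity_inv"] == level).astype(float)
    ref_complaint = REFERENCE_LEVELS["complaint_cat"]
    levels = sorted(set(df["complaint_cat"]) - {ref_complaint})
    if ref_complaint not in set(df["complaint_cat"]) and levels:
        # reference absent: drop the first level instead to keep the
        # design identifiable
        levels = levels[1:]
    for level in levels:
        X[f"complaint[{level}]"] = (df["complaint_cat"] == level).astype(float)
    keep = [c for c in X.columns if X[c].nunique() > 1]
    return X[keep]


def fit_cox(
    rows: pd.DataFrame | Sequence[AnalysisRow],
    horizon_days: int,
) -> CoxResult:
    """Adjusted Cox proportional-hazards fit for one horizon.

    MISSING-exposure rows are excluded.  Partial likelihood is maximized
    with Efron tie handling; 95% Wald confidence intervals are reported on
    the hazard-ratio scale.  Raises :class:`EstimationError` when there are
    no events, no identifiable contrast, or the optimizer fails.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    df = (
        rows.copy()
        if isinstance(rows, pd.DataFrame)
        else pd.DataFrame([r.__dict__ for r in rows])
    )
    df = df[df["exposure"] != ExposureCategory.MISSING.value]
    if not len(df):
        raise EstimationError("no usable rows (all MISSING exposure or empty)")
    n_events = int(df["event"].sum())
    if n_events == 0:
        raise EstimationError("no events within the horizon")
    X = _design_matrix(df)
    if X.shape[1] == 0:
        raise EstimationError(
            "degenerate design: all rows share one covariate pattern, "
            "no exposure contrast to estimate"
        )
    data = X.copy()
    data["time"] = df["time"].astype(float).to_numpy()
    data["event"] = df["event"].astype(bool).to_numpy()
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise EstimationError(f"Cox fit did not converge: {exc}") from exc
    summary = cph.summary
    hrs: dict[str, tuple[float, float, float]] = {}
    for level in _EXPOSURE_DUMMY_ORDER:
        name = f"exposure[{level}]"
        if name in summary.index:
            row = summary.loc[name]
            hrs[level] = (
                float(row["exp(coef)"]),
                float(row["exp(coef) lower 95%"]),
                float(row["exp(coef) upper 95%"]),
            )
    coefs = {str(i): float(c) for i, c in cph.params_.items()}
    return CoxResult(
        horizon_days=horizon_days,
        hazard_ratios=hrs,
        coefficients=coefs,
        n_rows=int(len(df)),
        n_events=n_events,
    )


def repeat_visit_summary(
    visits: Sequence[VisitRecord], horizon_days: int
) -> tuple[float, float]:
    """Percent of patients with more than one visit inside the horizon,
    split by whether the patient died within the horizon of any visit.

    Returns ``(percent among dying, percent among surviving)``.
    """
    by_patient: dict[str, list[VisitRecord]] = {}
    for v in visits:
        by_patient.setdefault(v.patient_id, []).append(v)
    horizon = pd.Timedelta(days=horizon_days)
    dying_multi = dying_total = surv_multi = surv_total = 0
    for items in by_patient.values():
        items.sort(key=lambda v: v.arrival_ts)
        died = any(died_within(v, horizon_days) for v in items)
        multi = any(
            (items[j].arrival_ts - items[i].arrival_ts) <= horizon
            for i in range(len(items))
            for j in range(i + 1, len(items))
        )
        if died:
            dying_total += 1
            dying_multi += multi
        else:
            surv_total += 1
            surv_multi += multi
    pct_dying = 100.0 * dying_multi / dying_total if dying_total else 0.0
    pct_surv = 100.0 * surv_multi / surv_total if surv_total else 0.0
    return pct_dying, pct_surv
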