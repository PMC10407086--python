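"""Descriptive reports: per-ED characteristics, outcome tables by exposure
category, and mean metric score by ED and crowding group.

Durations are printed as zero-padded ``HH:MM``; report objects are pandas
DataFrames with plain-text and JSON renderings for files.
"""

from __future__ import annotations

import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exposure import CATEGORY_ORDER, ExposureThresholds, METRIC_COLUMN, categorize
from .survival import CoxResult, died_within
from .timeutil import format_hhmm
from .visitlog import VisitRecord

__all__ = [
    "ed_summary",
    "score_by_group",
    "render_ed_summary",
    "render_mortality_table",
    "render_cox_results",
    "df_to_json",
]


def ed_summary(
    visits: Sequence[VisitRecord], horizons: Sequence[int] = (1, 7, 30)
) -> pd.DataFrame:
    """Per-ED visit volume, admission fraction, mortality and LOS summary.

    One row per ED: visit count, admission percentage, mortality percentage
    at each horizon, and LOS mean/SD/median/IQR in hours.
    """
    by_ed: dict[str, list[VisitRecord]] = {}
    for v in visits:
        by_ed.setdefault(v.ed_id, []).append(v)
    rows = []
    for ed in sorted(by_ed):
        members = by_ed[ed]
        n = len(members)
        los = np.array([v.los_hours for v in members])
        q1, med, q3 = np.percentile(los, [25, 50, 75])
        row = {
            "ed_id": ed,
            "n_visits": n,
            "pct_admitted": round(100.0 * sum(v.admitted for v in members) / n, 2),
        }
        for h in horizons:
            deaths = sum(died_within(v, h) for v in members)
            row[f"pct_mortality_{h}d"] = round(100.0 * deaths / n, 2)
        row.update(
            {
                "los_mean_h": float(np.mean(los)),
                "los_sd_h": float(np.std(los, ddof=1)) if n > 1 else 0.0,
                "los_median_h": float(med),
                "los_iqr_low_h": float(q1),
                "los_iqr_high_h": float(q3),
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def score_by_group(
    metrics: pd.DataFrame, thresholds: ExposureThresholds
) -> pd.DataFrame:
    """Mean (SD) of the metric per ED and exposure bin over hourly values.

    Bins every non-absent hourly value of the thresholds' metric by its own
    (ED, hour-of-day) cutpoints and aggregates per ED x bin.  SD is the
    sample estimator, 0 for singleton cells.
    """
    col = METRIC_COLUMN[thresholds.metric]
    work = metrics[["ed_id", "hour_start", col]].dropna(subset=[col]).copy()
    work["hour"] = pd.DatetimeIndex(work["hour_start"]).hour
    records = []
    bins = [c.value for c in CATEGORY_ORDER[:4]]
    for ed, grp in work.groupby("ed_id", sort=True):
        values: dict[str, list[float]] = {b: [] for b in bins}
        for hod, sub in grp.groupby("hour"):
            cuts = thresholds.lookup(str(ed), int(hod))
            for v in sub[col]:
                values[categorize(float(v), cuts).value].append(float(v))
        for b in bins:
            vals = np.array(values[b])
            records.append(
                {
                    "ed_id": ed,
                    "bin": b,
                    "n_hours": len(vals),
                    "mean": float(np.mean(vals)) if len(vals) else np.nan,
                    "sd": (float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0)
                    if len(vals)
                    else np.nan,
                }
            )
    return pd.DataFrame(records, columns=["ed_id", "bin", "n_hours", "mean", "sd"])


# ---------------------------------------------------------------------------
# text / JSON renderings


def _fmt_hhmm_cols(df: pd.DataFrame) -> pd.DataFrame:
    """Replace *_h duration columns by HH:MM composite display columns."""
    out = df.copy()
    if "los_mean_h" in out.columns:
        out["los_mean_sd"] = [
            f"{format_hhmm(m)} ({format_hhmm(s)})" if not np.isnan(m) else ""
            for m, s in zip(df["los_mean_h"], df["los_sd_h"])
        ]
        out["los_median_iqr"] = [
            f"{format_hhmm(m)} ({format_hhmm(a)}-{format_hhmm(b)})"
            if not np.isnan(m)
            else ""
            for m, a, b in zip(
                df["los_median_h"], df["los_iqr_low_h"], df["los_iqr_high_h"]
            )
        ]
        out = out.drop(
            columns=[
                "los_mean_h",
                "los_sd_h",
                "los_median_h",
                "los_iqr_low_h",
                "los_iqr_high_h",
            ]
        )
    return out


def render_ed_summary(df: pd.DataFrame) -> str:
    return _fmt_hhmm_cols(df).to_string(index=False)


def render_mortality_table(df: pd.DataFrame) -> str:
    return _fmt_hhmm_cols(df.reset_index()).to_string(index=False)


def render_cox_results(results: Mapping[int, CoxResult], metric: str) -> str:
    """Aligned text of hazard ratios (95% CI) per exposure level x horizon."""
    horizons = sorted(results)
    lines = [f"Cox proportional hazard ratios - exposure: {metric}"]
    header = f"{'level':<10}" + "".join(f"{f'{h}-day':>22}" for h in horizons)
    lines.append(header)
    levels = ["Q85_90", "Q90_95", "GT95"]
    for level in levels:
        cells = []
        for h in horizons:
            hr = results[h].hazard_ratios.get(level)
            cells.append(
                f"{hr[0]:.2f} ({hr[1]:.2f}-{hr[2]:.2f})" if hr else "-"
            )
        lines.append(f"{level:<10}" + "".join(f"{c:>22}" for c in cells))
    lines.append(
        "n/events: "
        + ", ".join(
            f"{h}d={results[h].n_rows}/{results[h].n_events}" for h in horizons
        )
    )
    return "\n".join(lines)


def df_to_json(df: pd.DataFrame) -> str:
    """Deterministic JSON rendering of a report DataFrame."""

    def _clean(v):
        if isinstance(v, (np.integer,)):
            return int(v)
        if isinstance(v, (np.floating, float)):
            return None if np.isnan(v) else float(v)
        if isinstance(v, (np.bool_,)):
            return bool(v)
        return v

    flat = df.reset_index(drop=df.index.name is None)
    records = [
        {k: _clean(v) for k, v in row.items()}
        for row in flat.to_dict(orient="records")
    ]
    return json.dumps(records, indent=2)
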