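"""End-to-end pipeline: read -> clean -> hourly metrics -> thresholds ->
exposure -> (optional left truncation) -> encoding -> tables + Cox models.

Outputs are written as delimited-text / JSON twins and are byte-identical
across re-runs with the same inputs and configuration; timing information
goes to the log stream only, never into output files.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .errors import EdCrowdError, PipelineError
from .exposure import (
    assign_exposure_frame,
    compute_thresholds,
    left_truncate,
)
from .metrics import Window, hourly_metrics, write_metrics
from .reporting import (
    df_to_json,
    ed_summary,
    render_cox_results,
    render_ed_summary,
    render_mortality_table,
    score_by_group,
)
from .survival import (
    build_analysis_frame,
    fit_cox,
    mortality_table,
    repeat_visit_summary,
    top_complaints,
)
from .timeutil import floor_hour, HOUR
from .visitlog import (
    VisitRecord,
    clean_visits,
    read_visit_log,
    visits_to_frame,
)

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("edcrowd.pipeline")


@dataclass
class PipelineConfig:
    """Everything one analysis run needs."""

    input_path: str | Path
    beds: Mapping[str, int]
    out_dir: str | Path
    dialect: str | Path | Mapping[str, str] | None = None
    metric: str = "mseal"  # "mseal" | "occupancy"
    horizons: tuple[int, ...] = (1, 7, 30)
    apply_left_truncation: bool = False
    #: percentile exposure uses the unclamped linear mSEAL score; clamping
    #: at the score ceiling would tie the upper strata cutpoints together
    clamp_mseal: bool = False
    delimiter: str = ","
    seed: int = 0  # echoed into the run log for provenance
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.metric not in ("mseal", "occupancy"):
            raise EdCrowdError(f"unknown metric {self.metric!r}")
        if not set(self.horizons) <= {1, 7, 30}:
            raise EdCrowdError("horizons must be a subset of {1, 7, 30}")


def _stage(name: str):
    """Decorator-free stage context: logs timing, rewraps errors."""

    class _Ctx:
        def __enter__(self):
            self.t0 = time.perf_counter()
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is None:
                log.info("stage %s: done in %.2fs", name, dt)
                return False
            if isinstance(exc, PipelineError):
                return False
            raise PipelineError(name, str(exc)) from exc

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the full analysis and write the report set.

    Returns a mapping of logical output names to written paths.  Any stage
    failure is re-raised as :class:`PipelineError` carrying the stage name.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    counts: dict[str, int] = {}

    with _stage("read"):
        visits, diagnostics = read_visit_log(
            config.input_path, config.dialect, config.delimiter
        )
        counts["rows_read"] = len(visits)
        counts["rows_rejected"] = len(diagnostics)
        if diagnostics:
            log.warning("%d rows rejected during read", len(diagnostics))

    with _stage("clean"):
        visits, report = clean_visits(visits)
        counts.update(report.as_dict())
        paths["clean_report"] = out / "clean_report.json"
        paths["clean_report"].write_text(
            json.dumps(report.as_dict(), indent=2) + "\n", encoding="utf-8"
        )

    with _stage("metrics"):
        if not visits:
            raise EdCrowdError("no visits retained after cleaning")
        start = floor_hour(min(v.arrival_ts for v in visits))
        end_raw = max(v.departure_ts for v in visits)
        end = floor_hour(end_raw) + (0 if end_raw == floor_hour(end_raw) else 1) * HOUR
        period = Window(start, end + HOUR)
        frame = visits_to_frame(visits)
        series = hourly_metrics(
            frame, dict(config.beds), period, clamp=config.clamp_mseal
        )
        paths["metrics"] = out / "hourly_metrics.csv"
        write_metrics(series, paths["metrics"])

    with _stage("thresholds"):
        thresholds = compute_thresholds(series, config.metric)
        paths["thresholds"] = out / "thresholds.json"
        thresholds.to_json(paths["thresholds"])

    with _stage("exposure"):
        exposure = assign_exposure_frame(frame, series, thresholds)
        exposed = frame.copy()
        exposed["exposure"] = exposure.to_numpy()
        paths["visits_exposed"] = out / "visits_exposed.csv"
        _write_exposed(visits, exposure, paths["visits_exposed"], config.delimiter)

    with _stage("descriptives"):
        summary = ed_summary(visits)
        paths["ed_summary_csv"] = out / "ed_summary.csv"
        summary.to_csv(paths["ed_summary_csv"], index=False)
        paths["ed_summary_txt"] = out / "ed_summary.txt"
        paths["ed_summary_txt"].write_text(
            render_ed_summary(summary) + "\n", encoding="utf-8"
        )
        mort = mortality_table(visits, list(exposure), horizons=config.horizons)
        paths["mortality_table_json"] = out / "mortality_by_exposure.json"
        paths["mortality_table_json"].write_text(
            df_to_json(mort) + "\n", encoding="utf-8"
        )
        paths["mortality_table_txt"] = out / "mortality_by_exposure.txt"
        paths["mortality_table_txt"].write_text(
            render_mortality_table(mort) + "\n", encoding="utf-8"
        )
        scores = score_by_group(series, thresholds)
        paths["score_by_group"] = out / "score_by_group.csv"
        scores.to_csv(paths["score_by_group"], index=False)

    with _stage("survival"):
        complaint_map = top_complaints(visits)
        results = {}
        repeat = {}
        for horizon in config.horizons:
            use_visits = visits
            use_exposure = exposure
            if config.apply_left_truncation:
                use_visits = left_truncate(visits, horizon)
                kept_ids = {v.visit_id for v in use_visits}
                mask = [v.visit_id in kept_ids for v in visits]
                use_exposure = exposure[pd.Series(mask, index=exposure.index)]
            rows = build_analysis_frame(
                visits_to_frame(use_visits),
                use_exposure.to_numpy(),
                complaint_map,
                horizon,
            )
            results[horizon] = fit_cox(rows, horizon)
            repeat[horizon] = repeat_visit_summary(visits, horizon)
        paths["cox_results_json"] = out / "cox_results.json"
        paths["cox_results_json"].write_text(
            json.dumps(
                {str(h): r.as_dict() for h, r in sorted(results.items())}, indent=2
            )
            + "\n",
            encoding="utf-8",
        )
        paths["cox_results_txt"] = out / "cox_results.txt"
        paths["cox_results_txt"].write_text(
            render_cox_results(results, config.metric) + "\n", encoding="utf-8"
        )
        paths["repeat_visits"] = out / "repeat_visits.json"
        paths["repeat_visits"].write_text(
            json.dumps(
                {
                    str(h): {"pct_dying_multi": a, "pct_surviving_multi": b}
                    for h, (a, b) in sorted(repeat.items())
                },
                indent=2,
            )
            + "\n",
            encoding="utf-8",
        )

    with _stage("runlog"):
        import lifelines
        import numpy
        import scipy

        paths["run_log"] = out / "run_log.json"
        paths["run_log"].write_text(
            json.dumps(
                {
                    "edcrowd": __version__,
                    "numpy": numpy.__version__,
                    "pandas": pd.__version__,
                    "scipy": scipy.__version__,
                    "lifelines": lifelines.__version__,
                    "seed": config.seed,
                    "metric": config.metric,
                    "horizons": list(config.horizons),
                    "left_truncation": config.apply_left_truncation,
                    "counts": counts,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n",
            encoding="utf-8",
        )
    return paths


def _write_exposed(
    visits: Sequence[VisitRecord],
    exposure: pd.Series,
    path: Path,
    delimiter: str,
) -> None:
    """Visit log with the exposure category as an added final column."""
    import csv
    from .visitlog import COLUMNS
    from .timeutil import format_date, format_ts

    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(list(COLUMNS) + ["exposure"])
        for r, e in zip(visits, exposure):
            writer.writerow(
                [
                    r.visit_id,
                    r.patient_id,
                    r.ed_id,
                    format_ts(r.arrival_ts),
                    format_ts(r.physician_ts) if r.physician_ts else "",
                    format_ts(r.departure_ts),
                    r.age_years,
                    r.sex,
                    "true" if r.ambulance else "false",
                    "true" if r.admitted else "false",
                    r.acuity,
                    r.complaint,
                    format_date(r.death_date) if r.death_date else "",
                    str(e),
                ]
            )
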