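"""Shared test utilities: visit factories, minute-grid brute-force oracles
and the end-to-end simulate-and-fit loop."""

from __future__ import annotations

import warnings
from datetime import datetime, timedelta

from edcrowd.exposure import assign_exposure_frame, compute_thresholds
from edcrowd.metrics import Window, hourly_metrics
from edcrowd.simulate import scenario_like_paper, simulate_ed
from edcrowd.survival import build_analysis_frame, fit_cox, top_complaints
from edcrowd.visitlog import VisitRecord, visits_to_frame

T0 = datetime(2017, 1, 1, 0, 0)


def ts(hours: float = 0.0, days: float = 0.0) -> datetime:
    return T0 + timedelta(days=days, hours=hours)


def make_visit(
    visit_id="V1",
    patient_id="P1",
    ed_id="ED1",
    arrival=None,
    physician=None,
    departure=None,
    age=40,
    sex="female",
    ambulance=False,
    admitted=False,
    acuity=3,
    complaint="MINOR_OTHER",
    death=None,
) -> VisitRecord:
    arrival = arrival if arrival is not None else ts(0)
    departure = departure if departure is not None else arrival + timedelta(hours=3)
    return VisitRecord(
        visit_id=visit_id,
        patient_id=patient_id,
        ed_id=ed_id,
        arrival_ts=arrival,
        physician_ts=physician,
        departure_ts=departure,
        age_years=age,
        sex=sex,
        ambulance=ambulance,
        admitted=admitted,
        acuity=acuity,
        complaint=complaint,
        death_date=death,
    )


# ---------------------------------------------------------------------------
# minute-grid brute-force oracles (independent of the interval arithmetic)


def grid_census(visits, ed, window: Window) -> int:
    count = 0
    for v in visits:
        if v.ed_id != ed:
            continue
        if _grid_minutes(v.arrival_ts, v.departure_ts, window) > 0:
            count += 1
    return count


def grid_patient_hours(visits, ed, window: Window):
    minutes = []
    for v in visits:
        if v.ed_id != ed:
            continue
        m = _grid_minutes(v.arrival_ts, v.departure_ts, window)
        if m > 0:
            minutes.append(m)
    if not minutes:
        return None
    return sum(minutes) / 60.0 / len(minutes)


def grid_occupancy(visits, ed, t: datetime, beds: int) -> float:
    present = sum(
        1 for v in visits if v.ed_id == ed and v.arrival_ts <= t < v.departure_ts
    )
    return present / beds


def _grid_minutes(start: datetime, end: datetime, window: Window) -> int:
    """Count whole minutes m in the window with start <= m < end."""
    n = 0
    t = window.start
    while t < window.end:
        if start <= t < end:
            n += 1
        t += timedelta(minutes=1)
    return n


# ---------------------------------------------------------------------------
# end-to-end loop: simulate -> metrics -> thresholds -> exposure -> Cox


def simulate_and_fit(scale, days, seed, crowding_log_hr, horizon=7):
    """Run the full pipeline in memory and return (n_visits, CoxResult)."""
    cfg = scenario_like_paper(
        scale, period_days=days, seed=seed, crowding_log_hr=crowding_log_hr
    )
    visits = simulate_ed(cfg)
    frame = visits_to_frame(visits)
    series = hourly_metrics(
        frame, cfg.beds_map, Window(cfg.period_start, cfg.period_end), clamp=False
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        thresholds = compute_thresholds(series, "mseal")
    exposure = assign_exposure_frame(frame, series, thresholds)
    complaint_map = top_complaints(visits)
    rows = build_analysis_frame(frame, exposure.to_numpy(), complaint_map, horizon)
    return len(visits), fit_cox(rows, horizon)
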