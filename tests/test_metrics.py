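"""Interval arithmetic, hourly crowding metrics and the mSEAL score."""

from __future__ import annotations

import math
from datetime import timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from edcrowd.errors import ConfigurationError, DomainError
from edcrowd.metrics import (
    Window,
    census_during,
    hourly_metrics,
    mseal_score,
    occupancy_at,
    patient_hours,
    present_interval,
    read_metrics,
    time_to_physician,
    write_metrics,
)
from tests.helpers import (
    grid_census,
    grid_occupancy,
    grid_patient_hours,
    make_visit,
    ts,
)

W = Window(ts(1), ts(2))  # [01:00, 02:00)


class TestPresentInterval:
    @pytest.mark.parametrize(
        "arrival,departure,expected",
        [
            (ts(3), ts(4), 0.0),  # disjoint
            (ts(0), ts(5), 1.0),  # spans the window
            (ts(1.5), ts(5), 0.5),  # enters mid-window
            (ts(0), ts(1), 0.0),  # departs exactly at window start
            (ts(2), ts(3), 0.0),  # arrives exactly at window end
        ],
    )
    def test_overlap_hours(self, arrival, departure, expected):
        v = make_visit(arrival=arrival, departure=departure)
        assert present_interval(v, W) == pytest.approx(expected)


class TestCensusAndPatientHours:
    def test_empty(self):
        assert census_during([], "ED1", W) == 0
        assert patient_hours([], "ED1", W) is None

    def test_overlapping_and_disjoint_visits(self):
        visits = [
            make_visit(visit_id="A", arrival=ts(0.5), departure=ts(1.5)),
            make_visit(visit_id="B", arrival=ts(1), departure=ts(2)),
            make_visit(visit_id="C", arrival=ts(1.9), departure=ts(3)),
            make_visit(visit_id="D", arrival=ts(4), departure=ts(5)),
            make_visit(visit_id="E", ed_id="ED9", arrival=ts(1), departure=ts(2)),
        ]
        assert census_during(visits, "ED1", W) == 3

    def test_departing_at_window_start_not_counted(self):
        visits = [make_visit(arrival=ts(0), departure=ts(1))]
        assert census_during(visits, "ED1", W) == 0

    def test_patient_hours_mean_presence_fraction(self):
        visits = [
            make_visit(visit_id="A", arrival=ts(0), departure=ts(3)),  # full hour
            make_visit(visit_id="B", arrival=ts(1.5), departure=ts(3)),  # half hour
        ]
        assert patient_hours(visits, "ED1", W) == pytest.approx(0.75)

    def test_single_full_hour_patient_gives_one(self):
        visits = [make_visit(arrival=ts(0), departure=ts(3))]
        assert patient_hours(visits, "ED1", W) == pytest.approx(1.0)


class TestTimeToPhysician:
    def test_nobody_waiting_is_absent(self):
        visits = [make_visit(arrival=ts(0), physician=ts(0.5), departure=ts(3))]
        assert time_to_physician(visits, "ED1", W) is None

    def test_full_realized_wait_counted(self):
        # arrival 00:30, physician 02:00 -> 1.5 h, waiting during [01:00, 02:00)
        visits = [make_visit(arrival=ts(0.5), physician=ts(2), departure=ts(4))]
        assert time_to_physician(visits, "ED1", W) == pytest.approx(1.5)

    def test_mean_of_qualifying_waits(self):
        visits = [
            make_visit(visit_id="A", arrival=ts(0.5), physician=ts(1.5), departure=ts(4)),
            make_visit(visit_id="B", arrival=ts(1), physician=ts(3), departure=ts(4)),
        ]
        assert time_to_physician(visits, "ED1", W) == pytest.approx(1.5)

    def test_never_seen_patients_excluded(self):
        visits = [make_visit(arrival=ts(0.5), physician=None, departure=ts(4))]
        assert time_to_physician(visits, "ED1", W) is None

    def test_elapsed_variant_censors_at_window_end(self):
        visits = [make_visit(arrival=ts(0.5), physician=ts(3), departure=ts(4))]
        assert time_to_physician(visits, "ED1", W, elapsed=True) == pytest.approx(1.5)


class TestMseal:
    def test_intercept_exact(self):
        assert mseal_score(0.0, 0.0, clamp=False) == 1.485

    def test_linear_form(self):
        assert mseal_score(0.3, 1.0, clamp=False) == pytest.approx(4.5765)

    def test_clamp_ceiling(self):
        assert mseal_score(1.0, 10.0, clamp=True) == 6.0

    def test_clamp_floor(self):
        assert mseal_score(0.0, 0.0, clamp=True) == 1.485  # already above 1

    def test_negative_input_rejected(self):
        with pytest.raises(DomainError):
            mseal_score(-0.1, 0.0)

    @given(
        st.floats(0, 1),
        st.floats(0, 1),
        st.floats(0, 5),
        st.floats(0, 5),
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_both_arguments(self, ph1, dph, ttp1, dttp):
        low = mseal_score(ph1, ttp1, clamp=False)
        high = mseal_score(ph1 + dph, ttp1 + dttp, clamp=False)
        assert high >= low - 1e-12


class TestOccupancy:
    def test_nobody_present(self):
        assert occupancy_at([], "ED1", ts(1), beds=16) == 0.0

    def test_ratio(self):
        visits = [
            make_visit(visit_id=f"V{i}", arrival=ts(0), departure=ts(2))
            for i in range(24)
        ]
        assert occupancy_at(visits, "ED1", ts(1), beds=16) == pytest.approx(1.5)

    def test_departure_exactly_at_instant_excluded(self):
        visits = [make_visit(arrival=ts(0), departure=ts(1))]
        assert occupancy_at(visits, "ED1", ts(1), beds=4) == 0.0

    def test_nonpositive_beds_rejected(self):
        with pytest.raises(ConfigurationError):
            occupancy_at([], "ED1", ts(1), beds=0)


def _random_visits(rng, n, ed="ED1", span_h=48):
    visits = []
    for i in range(n):
        a = int(rng.integers(0, span_h * 60))
        los = int(rng.integers(1, 12 * 60))
        seen = rng.uniform() < 0.9
        wait = int(rng.integers(0, min(los, 180) + 1)) if seen else None
        visits.append(
            make_visit(
                visit_id=f"V{i}",
                patient_id=f"P{i}",
                ed_id=ed,
                arrival=ts(0) + timedelta(minutes=a),
                physician=(ts(0) + timedelta(minutes=a + wait)) if wait is not None else None,
                departure=ts(0) + timedelta(minutes=a + los),
            )
        )
    return visits


class TestHourlySeries:
    def test_empty_log_gives_zero_census_absent_mseal(self):
        series = hourly_metrics([], {"ED1": 10}, Window(ts(0), ts(6)))
        assert len(series) == 6
        assert (series["census"] == 0).all()
        assert series["mseal"].isna().all()
        assert (series["occupancy_rate"] == 0).all()

    def test_rows_match_direct_per_window_recomputation(self):
        rng = np.random.default_rng(5)
        visits = _random_visits(rng, 120, span_h=48)
        series = hourly_metrics(visits, {"ED1": 10}, Window(ts(0), ts(48)))
        for row in series.sample(n=12, random_state=3).itertuples():
            h = row.hour_start.to_pydatetime()
            window = Window(h - timedelta(hours=1), h)
            assert row.census == census_during(visits, "ED1", window)
            ph = patient_hours(visits, "ED1", window)
            tt = time_to_physician(visits, "ED1", window)
            if ph is None:
                assert math.isnan(row.patient_hours)
            else:
                assert row.patient_hours == pytest.approx(ph)
            if tt is None:
                assert math.isnan(row.time_to_physician)
            else:
                assert row.time_to_physician == pytest.approx(tt)
            if ph is None or tt is None:
                assert math.isnan(row.mseal)
            else:
                assert row.mseal == pytest.approx(mseal_score(ph, tt))
            assert row.occupancy_rate == pytest.approx(
                occupancy_at(visits, "ED1", h, 10)
            )

    def test_hour_with_patients_but_none_waiting_has_absent_mseal(self):
        visits = [make_visit(arrival=ts(0), physician=ts(0.25), departure=ts(5))]
        series = hourly_metrics(visits, {"ED1": 10}, Window(ts(0), ts(4)))
        row = series[series["hour_start"] == ts(3)].iloc[0]
        assert row["census"] == 1
        assert math.isnan(row["time_to_physician"])
        assert math.isnan(row["mseal"])
        assert not math.isnan(row["patient_hours"])

    def test_unknown_ed_rejected(self):
        visits = [make_visit(ed_id="EDX")]
        with pytest.raises(ConfigurationError, match="EDX"):
            hourly_metrics(visits, {"ED1": 10}, Window(ts(0), ts(6)))

    def test_period_must_be_on_the_hour(self):
        with pytest.raises(ConfigurationError):
            hourly_metrics([], {"ED1": 10}, Window(ts(0.5), ts(6)))

    def test_patient_hours_in_unit_interval_when_defined(self):
        rng = np.random.default_rng(11)
        visits = _random_visits(rng, 200, span_h=24)
        series = hourly_metrics(visits, {"ED1": 10}, Window(ts(0), ts(30)))
        defined = series["patient_hours"].dropna()
        assert len(defined) > 0
        assert ((defined > 0) & (defined <= 1.0)).all()
        # absent exactly when census is zero
        assert (series["patient_hours"].isna() == (series["census"] == 0)).all()

    def test_matches_minute_grid_oracle(self):
        rng = np.random.default_rng(23)
        visits = _random_visits(rng, 60, span_h=12)
        series = hourly_metrics(visits, {"ED1": 7}, Window(ts(0), ts(14)))
        for row in series.iloc[2:8].itertuples():
            h = row.hour_start.to_pydatetime()
            window = Window(h - timedelta(hours=1), h)
            assert row.census == grid_census(visits, "ED1", window)
            gph = grid_patient_hours(visits, "ED1", window)
            if gph is None:
                assert math.isnan(row.patient_hours)
            else:
                assert row.patient_hours == pytest.approx(gph, abs=1 / 60)
            assert row.occupancy_rate == pytest.approx(
                grid_occupancy(visits, "ED1", h, 7)
            )

    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(2)
        visits = _random_visits(rng, 40, span_h=12)
        series = hourly_metrics(visits, {"ED1": 7}, Window(ts(0), ts(14)))
        path = tmp_path / "metrics.csv"
        write_metrics(series, path)
        back = read_metrics(path)
        pd.testing.assert_frame_equal(series, back, check_dtype=False)
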