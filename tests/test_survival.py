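"""Covariate encoding, outcome tables and Cox model behaviour."""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from edcrowd.errors import DomainError, EstimationError
from edcrowd.exposure import ExposureCategory
from edcrowd.survival import (
    OTHER_COMPLAINT,
    age_band,
    build_analysis_frame,
    encode_covariates,
    fit_cox,
    mortality_percent,
    mortality_table,
    repeat_visit_summary,
    top_complaints,
)
from edcrowd.visitlog import visits_to_frame
from tests.helpers import make_visit, ts


class TestTopComplaints:
    def _cohort(self, death_counts: dict[str, int], extra_codes=()):
        visits = []
        i = 0
        for code, deaths in death_counts.items():
            for j in range(deaths):
                visits.append(
                    make_visit(
                        visit_id=f"V{i}", patient_id=f"P{i}",
                        arrival=ts(0), complaint=code, death=date(2017, 1, 5),
                    )
                )
                i += 1
            visits.append(  # one survivor per code so the code exists
                make_visit(visit_id=f"V{i}", patient_id=f"P{i}", complaint=code)
            )
            i += 1
        for code in extra_codes:
            visits.append(
                make_visit(visit_id=f"V{i}", patient_id=f"P{i}", complaint=code)
            )
            i += 1
        return visits

    def test_top_k_self_mapped_rest_other(self):
        counts = {f"C{i:02d}": 20 - i for i in range(12)}  # C00..C11, distinct
        cmap = top_complaints(self._cohort(counts), k=10)
        self_mapped = {c for c, v in cmap.items() if v == c}
        assert self_mapped == {f"C{i:02d}" for i in range(10)}
        assert cmap["C10"] == OTHER_COMPLAINT and cmap["C11"] == OTHER_COMPLAINT

    def test_fewer_codes_than_k_all_self_mapped(self):
        cmap = top_complaints(self._cohort({"A": 2, "B": 1}), k=10)
        assert cmap == {"A": "A", "B": "B"}

    def test_tie_at_rank_k_broken_lexicographically(self):
        counts = {f"C{i}": 10 - i for i in range(2)}  # C0:10, C1:9
        counts.update({"ZZ": 5, "AA": 5})  # tied at rank 3
        cmap = top_complaints(self._cohort(counts), k=3)
        assert cmap["AA"] == "AA"
        assert cmap["ZZ"] == OTHER_COMPLAINT

    def test_deaths_beyond_30_days_do_not_count(self):
        visits = [
            make_visit(visit_id="V1", complaint="LATE", death=date(2017, 2, 15)),
            make_visit(visit_id="V2", patient_id="P2", complaint="EARLY",
                       death=date(2017, 1, 3)),
            make_visit(visit_id="V3", patient_id="P3", complaint="LATE"),
        ]
        cmap = top_complaints(visits, k=1)
        assert cmap["EARLY"] == "EARLY"
        assert cmap["LATE"] == OTHER_COMPLAINT


class TestEncode:
    CMAP = {"X": "X"}

    def test_acuity_5_merged_then_inverted_to_1(self):
        row = encode_covariates(
            make_visit(acuity=5), self.CMAP, 7, ExposureCategory.REF_LT85
        )
        assert row.acuity_inv == 1

    def test_acuity_1_inverts_to_4(self):
        row = encode_covariates(
            make_visit(acuity=1), self.CMAP, 7, ExposureCategory.REF_LT85
        )
        assert row.acuity_inv == 4

    def test_age_80_death_day_2_horizon_7(self):
        visit = make_visit(age=80, arrival=ts(10), death=date(2017, 1, 3))
        row = encode_covariates(visit, self.CMAP, 7, ExposureCategory.GT95)
        assert row.age_band == "80+"
        assert row.event is True
        assert row.time == pytest.approx(2.5)

    def test_death_at_horizon_is_censored(self):
        visit = make_visit(arrival=ts(10), death=date(2017, 1, 8))  # day 7
        row = encode_covariates(visit, self.CMAP, 7, ExposureCategory.REF_LT85)
        assert row.event is False
        assert row.time == 7.0

    def test_unknown_complaint_maps_to_other(self):
        row = encode_covariates(
            make_visit(complaint="RARE"), self.CMAP, 7, ExposureCategory.REF_LT85
        )
        assert row.complaint_cat == OTHER_COMPLAINT

    @pytest.mark.parametrize(
        "age,band",
        [(0, "0-18"), (18, "0-18"), (19, "19-39"), (59, "40-59"), (79, "60-79"), (80, "80+"), (101, "80+")],
    )
    def test_age_bands(self, age, band):
        assert age_band(age) == band

    def test_negative_age_rejected(self):
        with pytest.raises(DomainError):
            age_band(-1)

    def test_vectorized_encoding_matches_scalar(self):
        rng = np.random.default_rng(3)
        visits = []
        for i in range(60):
            death = (
                date(2017, 1, 1) + timedelta(days=int(rng.integers(0, 40)))
                if rng.uniform() < 0.3
                else None
            )
            visits.append(
                make_visit(
                    visit_id=f"V{i}",
                    patient_id=f"P{i}",
                    arrival=ts(float(rng.integers(0, 72))),
                    age=int(rng.integers(0, 100)),
                    sex=["female", "male"][rng.integers(2)],
                    acuity=int(rng.integers(1, 6)),
                    complaint=["X", "Y", "Z"][rng.integers(3)],
                    death=death,
                )
            )
        # keep only death >= arrival date (as after cleaning)
        visits = [
            v for v in visits
            if v.death_date is None or v.death_date >= v.arrival_ts.date()
        ]
        cmap = {"X": "X", "Y": "Y", "Z": OTHER_COMPLAINT}
        exposures = [
            [c.value for c in ExposureCategory][i % 5] for i in range(len(visits))
        ]
        frame = build_analysis_frame(visits_to_frame(visits), exposures, cmap, 7)
        for i, v in enumerate(visits):
            row = encode_covariates(v, cmap, 7, exposures[i])
            got = frame.iloc[i]
            assert got["time"] == pytest.approx(row.time)
            assert bool(got["event"]) == row.event
            assert got["age_band"] == row.age_band
            assert got["acuity_inv"] == row.acuity_inv
            assert got["complaint_cat"] == row.complaint_cat


class TestMortalityTable:
    def test_percent_is_rounded_ratio(self):
        assert mortality_percent(1277, 143_041) == 0.89
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(1, 10_000))
            d = int(rng.integers(0, n + 1))
            assert mortality_percent(d, n) == round(100 * d / n, 2)

    def test_counts_and_percentages_per_category(self):
        visits, exposures = [], []
        for i in range(10):
            died = i < 3
            visits.append(
                make_visit(
                    visit_id=f"V{i}", patient_id=f"P{i}", arrival=ts(0),
                    departure=ts(4), death=date(2017, 1, 2) if died else None,
                )
            )
            exposures.append("GT95")
        table = mortality_table(visits, exposures)
        row = table.loc["GT95"]
        assert row["n"] == 10
        assert row["deaths_7d"] == 3
        assert row["pct_7d"] == 30.0
        assert row["los_mean_h"] == pytest.approx(4.0)

    def test_empty_category_reports_absent(self):
        visits = [make_visit()]
        table = mortality_table(visits, ["REF_LT85"])
        assert np.isnan(table.loc["GT95", "pct_7d"])
        assert table.loc["GT95", "n"] == 0


def _synthetic_rows(rng, n_per_group, hr, rate_ref=0.01, horizon=30.0):
    """Two-group exponential survival rows: REF vs GT95 with a true HR."""
    rows = []
    for group, rate in (("REF_LT85", rate_ref), ("GT95", rate_ref * hr)):
        t = rng.exponential(1.0 / rate, size=n_per_group)
        for x in t:
            event = x < horizon
            rows.append(
                {
                    "time": min(x, horizon),
                    "event": event,
                    "exposure": group,
                    "age_band": "19-39",
                    "sex": "female",
                    "ambulance": False,
                    "admitted": False,
                    "acuity_inv": 1,
                    "complaint_cat": OTHER_COMPLAINT,
                }
            )
    return pd.DataFrame(rows)


class TestCox:
    def test_two_group_exponential_recovers_hr_2(self):
        rng = np.random.default_rng(42)
        df = _synthetic_rows(rng, 5000, hr=2.0)
        res = fit_cox(df, 30)
        hr, lo, hi = res.hazard_ratios["GT95"]
        assert 1.8 <= hr <= 2.2
        assert lo <= hr <= hi

    def test_estimate_consistency_improves_with_n(self):
        errs = []
        for n in (500, 5000):
            log_errs = []
            for seed in range(4):
                rng = np.random.default_rng(100 + seed)
                df = _synthetic_rows(rng, n, hr=2.0)
                hr = fit_cox(df, 30).hazard_ratios["GT95"][0]
                log_errs.append(abs(np.log(hr) - np.log(2.0)))
            errs.append(np.mean(log_errs))
        assert errs[1] < errs[0]

    def test_no_contrast_is_estimation_error(self):
        rng = np.random.default_rng(0)
        df = _synthetic_rows(rng, 50, hr=1.0)
        df["exposure"] = "REF_LT85"  # no exposure contrast, all else constant
        with pytest.raises(EstimationError, match="degenerate|contrast"):
            fit_cox(df, 30)

    def test_no_events_is_estimation_error(self):
        rng = np.random.default_rng(0)
        df = _synthetic_rows(rng, 50, hr=1.0)
        df["event"] = False
        with pytest.raises(EstimationError, match="events"):
            fit_cox(df, 30)

    def test_missing_exposure_rows_excluded(self):
        rng = np.random.default_rng(1)
        df = _synthetic_rows(rng, 400, hr=2.0)
        n_before = len(df)
        extra = df.iloc[:100].copy()
        extra["exposure"] = ExposureCategory.MISSING.value
        res = fit_cox(pd.concat([df, extra], ignore_index=True), 30)
        assert res.n_rows == n_before

    def test_row_order_invariance(self):
        rng = np.random.default_rng(9)
        df = _synthetic_rows(rng, 800, hr=1.5)
        res1 = fit_cox(df, 30)
        res2 = fit_cox(df.sample(frac=1.0, random_state=7).reset_index(drop=True), 30)
        assert res1.hazard_ratios["GT95"][0] == pytest.approx(
            res2.hazard_ratios["GT95"][0], rel=1e-8
        )

    def test_independent_covariate_barely_moves_exposure_hr(self):
        rng = np.random.default_rng(21)
        df = _synthetic_rows(rng, 10_000, hr=1.5)
        with_noise = df.copy()
        with_noise["sex"] = np.where(rng.uniform(size=len(df)) < 0.5, "male", "female")
        hr_with = fit_cox(with_noise, 30).hazard_ratios["GT95"][0]
        hr_without = fit_cox(df, 30).hazard_ratios["GT95"][0]
        assert abs(hr_with - hr_without) / hr_without < 0.02


class TestRepeatVisits:
    def test_all_single_visits_gives_zero_both(self):
        visits = [
            make_visit(visit_id=f"V{i}", patient_id=f"P{i}") for i in range(5)
        ]
        assert repeat_visit_summary(visits, 7) == (0.0, 0.0)

    def test_hand_counted_toy_cohort(self):
        visits = [
            # P1 dies within 7 days and revisits on day 2 -> dying, multi
            make_visit(visit_id="A1", patient_id="P1", arrival=ts(0),
                       death=date(2017, 1, 4)),
            make_visit(visit_id="A2", patient_id="P1", arrival=ts(0, days=2),
                       death=date(2017, 1, 4)),
            # P2 survives, revisits within 7 days -> surviving, multi
            make_visit(visit_id="B1", patient_id="P2", arrival=ts(0)),
            make_visit(visit_id="B2", patient_id="P2", arrival=ts(0, days=5)),
            # P3 survives, revisit far apart -> surviving, not multi
            make_visit(visit_id="C1", patient_id="P3", arrival=ts(0)),
            make_visit(visit_id="C2", patient_id="P3", arrival=ts(0, days=20)),
            # P4 dies, single visit -> dying, not multi
            make_visit(visit_id="D1", patient_id="P4", arrival=ts(0),
                       death=date(2017, 1, 2)),
        ]
        pct_dying, pct_surv = repeat_visit_summary(visits, 7)
        assert pct_dying == pytest.approx(50.0)  # 1 of 2 dying patients
        assert pct_surv == pytest.approx(50.0)  # 1 of 2 surviving patients

    def test_invariant_to_patient_relabeling(self):
        visits = [
            make_visit(visit_id="A1", patient_id="P1", arrival=ts(0)),
            make_visit(visit_id="A2", patient_id="P1", arrival=ts(0, days=3)),
            make_visit(visit_id="B1", patient_id="P2", arrival=ts(5)),
        ]
        relabeled = [
            make_visit(visit_id=v.visit_id, patient_id="Q" + v.patient_id,
                       arrival=v.arrival_ts)
            for v in visits
        ]
        assert repeat_visit_summary(visits, 7) == repeat_visit_summary(relabeled, 7)
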