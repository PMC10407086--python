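# edcrowd

Emergency-department (ED) crowding is associated with worse care, and a
recurring epidemiological question is whether arriving at a *crowded hour*
raises a patient's short-term risk of death. `edcrowd` is a Python package
for answering that question from routine timestamped ED visit logs. It
computes two crowding metrics per ED and clock hour, converts them into
stratified percentile exposure categories per visit, and estimates adjusted
1-/7-/30-day all-cause mortality hazard ratios with Cox
proportional-hazards models. A built-in discrete-event visit-log simulator
with a configurable crowding effect on the death hazard makes the entire
pipeline testable — including full parameter recovery — without any
patient data.

It is intended for emergency-medicine researchers and biostatisticians
working with registry-style visit logs (one row per visit: arrival, first
physician contact, departure, demographics, triage acuity, chief complaint,
admission, date of death if any).

## The metrics and the model

For every ED and hourly window `[H-1h, H)`:

- **Patient Hours (PH)** — total time patients spent in the ED during the
  window, divided by the window census (patients present at any moment);
  a fraction in (0, 1].
- **Time to Physician (TTP)** — mean realized registration-to-physician
  wait in hours among patients waiting during the window.
- **mSEAL** (modified Skåne Emergency Department Assessment of Patient
  Load), a staff-workload crowding score:

  ```
  mSEAL = 1.485 + 9.715 · PH + 0.177 · TTP
  ```

  described as ranging from 1 (no crowding) to 6 (extreme crowding); the
  linear form can exceed 6 and the clamp is optional.
- **Occupancy rate** — patients present at instant `H` divided by
  treatment beds.

Each visit's exposure is its arrival-hour metric value categorized against
the empirical 85th/90th/95th percentiles of its own (ED, hour-of-day)
stratum: `<85%` (reference), `85–90%`, `90–95%`, `>95%`, or `missing` when
the score was not computable for that hour. Stratification absorbs
between-site and intra-day baseline differences. Mortality is modelled as

```
h(t | x) = h0(t) · exp(β_exposure + β_age + β_sex + β_ambulance + β_admission + β_acuity + β_complaint)
```

with Efron tie handling (death dates are day-resolution) and 95% Wald
intervals on the hazard-ratio scale. Repeat visits can optionally be
left-truncated: per patient, any visit within the follow-up horizon of an
already retained visit is dropped.

## Worked example

Simulate a six-ED cohort (bed counts 16–72, ~24% admissions, ~2% 30-day
mortality, diurnal arrivals, load-dependent physician waits) and run the
full analysis:

```python
from edcrowd import (PipelineConfig, run_pipeline, scenario_like_paper,
                     simulate_ed, write_visit_log)

cfg = scenario_like_paper(0.25, period_days=90, seed=11)
visits = simulate_ed(cfg)                      # 20,931 synthetic visits
write_visit_log(visits, "visits.csv")
paths = run_pipeline(PipelineConfig(
    input_path="visits.csv", beds=cfg.beds_map, out_dir="out",
    metric="mseal", horizons=(7, 30), seed=11))
```

`out/clean_report.json` tallies the exclusion filters (duplicates, stays
over 72 h, death dates before arrival):

```json
{"n_input": 20931, "n_duplicates": 0, "n_long_los": 2,
 "n_bad_mortality": 0, "n_retained": 20929}
```

`out/cox_results.txt` holds the adjusted hazard ratios per exposure bin
(reference `<85%`):

```
Cox proportional hazard ratios - exposure: mseal
level                      7-day                30-day
Q85_90          1.58 (0.89-2.80)      1.18 (0.79-1.77)
Q90_95          0.86 (0.38-1.95)      0.71 (0.41-1.23)
GT95            1.34 (0.74-2.43)      1.00 (0.65-1.52)
n/events: 7d=18441/162, 30d=18441/402
```

This cohort was generated with **no** crowding effect
(`crowding_log_hr = 0`), and indeed every confidence interval covers 1.0:
arriving above the 95th percentile shows no significant mortality signal.
Rows with `missing` exposure (here 20,929 − 18,441) are excluded from the
regression. `out/ed_summary.txt` gives per-ED volume, admission and
mortality percentages, and length-of-stay summaries printed `HH:MM`:

```
ed_id  n_visits  pct_admitted  pct_mortality_7d  pct_mortality_30d   los_mean_sd      los_median_iqr
  ED1      5469         24.19              0.79               2.10 04:07 (03:40) 03:02 (01:48-05:07)
  ED2      2521         25.98              0.60               2.26 04:09 (04:03) 02:57 (01:45-05:08)
```

Setting `crowding_log_hr = ln 1.5` in the generator injects a hazard ratio
of 1.5 for top-bin arrivals through the same exposure definition the
pipeline estimates; fitting large simulated cohorts recovers it (see
`tests/test_acceptance.py`).

The same stages are available as a CLI:

```
edcrowd simulate --scenario-scale 0.25 --period-days 90 --seed 11 --out visits.csv
edcrowd report --input visits.csv --beds beds.json --metric mseal --out out/
edcrowd power 0.005 0.009          # exact Fisher-test sample size
```

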