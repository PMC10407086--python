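# Methods

This note documents the models, conventions and numerical choices in
`edcrowd`, and what the synthetic-data generator does and does not emulate.

## Visit model and cleaning

A visit is a half-open stay `[arrival, departure)` at one ED with optional
first-physician-contact time, demographics, RETTS triage acuity (1 =
highest urgency; an optional 5th, lowest category exists at some sites), a
chief-complaint code, admission flag and an optional calendar date of
death. Timestamps are naive local wall-clock times at minute resolution;
sub-minute times are floored, and daylight-saving duplicated hours are
taken at face value because source systems log wall-clock time.

Cleaning removes rows in a fixed precedence so the removal tallies are
deterministic: (a) duplicates — identical `(patient, ED, arrival)`
triples, keeping the first in file order; (b) stays longer than 72 h
(strict; exactly 72 h is kept); (c) death dates strictly before the
arrival date. Duplicate detection by field equality rather than visit
identifiers is an assumption: a generic log carries no reliable visit key,
and two true visits cannot share that triple. The operation is idempotent
and the tallies partition the input.

## Crowding metrics

All presence logic is half-open (`arrival` inclusive, `departure`
exclusive), so a patient departing exactly at *t* is not present at *t*
and nothing is double-counted at window boundaries. For the hourly window
`[H-1h, H)`:

- census = distinct patients present at any moment of the window;
- Patient Hours = summed within-window presence divided by the census —
  equivalently the mean presence fraction, in (0, 1], absent when the
  census is 0;
- Time to Physician = mean *realized* wait among patients whose waiting
  interval `[arrival, physician)` overlaps the window; patients never seen
  are excluded. Retrospective data make the full wait known at analysis
  time; an alternative elapsed-wait-so-far reading (censored at the window
  end) is available behind a switch, off by default;
- mSEAL = 1.485 + 9.715·PH + 0.177·TTP, absent when either input is
  absent; occupancy = presence at the instant `H` over treatment beds.

"Census during the hour" is read as any-moment presence; counting at a
fixed instant is an alternative reading that the occupancy rate already
embodies.

**The clamp and the saturation problem.** The score is described as
ranging 1–6, and `mseal_score` (and the hourly series by default) truncate
into that range. However, under the presence-fraction definition of
Patient Hours, any ED with mean stays of 3–5 h operates at PH ≈ L/(L+1) ≈
0.75–0.95 almost every busy hour (L = mean length of stay in hours), which
puts the linear score above 6 nearly always. Clamping then ties the values
at the ceiling and collapses the stratified 85/90/95th percentile
cutpoints into one another (measured on simulated data: ~93% of visits in
the top bin, a reference bin of ~0.4%). The percentile *rank* of the
score, not its absolute value, is the analysis quantity — so the pipeline
and the simulator compute the exposure series from the **unclamped**
linear score (`clamp=False`), restoring well-defined 85/5/5/5 strata. The
clamped score remains the default of the scalar scoring function and is
available everywhere for display.

## Exposure

Per metric, per (ED, hour-of-day) stratum, cutpoints are the empirical
0.85/0.90/0.95 quantiles with linear interpolation between order
statistics (the mainstream default; bin proportions, not cutpoint values,
drive the analysis). Cutpoints are computed on the full study period,
matching a retrospective design. Strata with fewer than 20 observed values
trigger an instability warning. Bins are lower-inclusive — a value equal
to a cutpoint goes to the higher-crowding bin — a deterministic
tie-break that is conservative toward exposure. A visit arriving in
`[H, H+1h)` is scored with the series row at `H`, i.e. the most recent
completed hour known at arrival. Hours without a computable score yield
the `MISSING` category; such visits are excluded from regression models.
Occupancy is never missing (an empty department is occupancy 0).

Left truncation retains, per patient scanning in arrival order, only
visits separated from the last retained visit by more than the follow-up
horizon of the model being fitted (1, 7 or 30 days — horizon-specific,
matching "until censoring"); it is idempotent.

## Survival model

Death dates have day resolution. A death counts toward horizon *h* when
`death_date − arrival_date < h` days, and its event time is that whole-day
difference plus 0.5 days — the offset avoids zero-length survival times
while keeping every event time within the horizon; censoring time is *h*.
Covariates: age bands 0–18 / 19–39 / 40–59 / 60–79 / 80+ (age 80 in the
oldest band, a documented choice for the boundary), sex, ambulance
arrival, hospital admission, acuity with category 5 merged into 4 and then
inverted (`acuity_inv = 5 − acuity`, 1 = lowest) entered categorically,
and chief complaint collapsed to the ten codes with the highest absolute
30-day death count (ties at rank ten broken lexicographically) plus
`OTHER`. Reference levels: `<85%` exposure, youngest age band, female, no
ambulance, not admitted, `acuity_inv` 1, `OTHER` complaint.

The partial likelihood is maximized by lifelines with Efron tie handling
(appropriate under heavy day-resolution ties); Wald 95% intervals are
reported on the hazard-ratio scale. The design matrix is dummy-encoded in
this package with the fixed reference levels above so results are
engine-independent; constant columns are dropped (a Cox model has no
intercept), and if `OTHER` is absent the first complaint level becomes the
reference to keep the design identifiable. Degenerate inputs raise
explicit estimation errors: no events, or no remaining contrast after
dropping constants.

## Synthetic-data generator

The generator emulates the structure the analysis assumes:

- **Arrivals**: nonhomogeneous Poisson by thinning, rate = per-ED base
  rate × a shared 24-value diurnal profile (night trough ~0.3× mean,
  afternoon plateau ~1.5×; normalized to mean 1 so the base rate is the
  true average). The ready-made six-ED scenario uses bed counts
  52/48/35/72/16/29 and annual volumes 88,486/40,502/67,458/79,412/
  21,194/40,748 (rate = scale × annual/8760), giving ~167k visits at full
  scale over 181 days.
- **Stays**: lognormal, median 3.0 h, σ = 0.8 → mean ≈ 4.1 h, inside the
  3.2–5.0 h range the scenario targets. Stays are global, not per-ED.
- **Waits**: exponential with mean 0.35 h + 0.04 h × (number of patients
  concurrently waiting at arrival), computed by a chronological sweep.
  This couples the two mSEAL inputs the way real workload does. 4% of
  visits have no physician contact, which (with empty hours) produces the
  missing-score hours the pipeline must handle.
- **Patients**: each visit spawns a future return visit with probability
  0.08 after an exponential delay (mean 4 days); the returning patient
  keeps age and sex. This yields ~6% of surviving patients with a repeat
  visit within 7 days, near the ~7.5% reported in comparable Swedish
  registry data, and gives left truncation something to do.
- **Mortality**: per-visit death times are Weibull with shape 0.556 and a
  per-complaint scale calibrated so the 30-day death probability equals
  that complaint's configured baseline (12 complaint codes, mixture
  average ≈ 1.9%). The decreasing hazard reproduces the front-loaded
  ~0.3% / 0.9% / 2% gradient of 1-/7-/30-day ED mortality; shape 1 would
  recover a constant hazard, which cannot produce that gradient. The
  optional crowding effect multiplies the hazard by `exp(crowding_log_hr)`
  for visits whose arrival-hour mSEAL reaches their stratum's 95th
  percentile — injected through the very exposure definition the pipeline
  estimates, so recovery exercises the whole chain, not just the fitter.
  A patient dies at most once (earliest candidate across their visits);
  return visits scheduled after death are removed (~0.1% of visits, a
  documented approximation since the generator's internal exposure pass
  precedes the removal).
- **Determinism**: one integer seed; per-ED substreams are keyed by a
  stable hash of the ED id so adding an ED leaves the others' draws
  untouched; the patient and death passes use their own substreams. Same
  seed ⇒ byte-identical logs.

What it does **not** emulate: bed-blocking/boarding queue dynamics, staff
rosters, seasonal or epidemic waves, per-ED case-mix differences,
comorbidity structure, or informative missingness. Passing recovery tests
therefore show that the pipeline estimates what the generator injects
under proportional hazards and correct exposure alignment — not that
real-world confounding (e.g. sicker patients arriving at busier hours) is
handled; the model adjusts only for the measured covariates.

## Power calculation

Exact power of the two-sided Fisher test for two equal groups is computed
by enumerating both binomial margins, truncated where the tail mass drops
below 1e-12; the two-sided p-value sums tables no more probable than the
observed one. Because exact-test power is saw-toothed in *n*, the search
(normal-approximation pilot, geometric bracketing, bisection, then a local
scan) stops at the smallest *n* meeting the target at both *n* and
*n* + 1. Both the per-group and total sizes are reported, since a "visits
needed" statement can refer to either convention.

## Problem sizes and numerical checks

The test suite validates interval arithmetic against an independent
1-minute-grid brute force (exact at minute resolution), bin occupancies at
5,000 values per stratum (±1.5 percentage points), null CI coverage over
100 seeded 20,000-visit replicates (≥93/100 covering 1.0), and recovery of
a generated hazard ratio of 1.5 from a ~220,000-visit cohort within
[1.3, 1.7] — a size chosen so the estimator's sampling spread (~0.12 on
the log scale at ~1,000 events) sits well inside the recovery band.
Reports are byte-reproducible: wall-clock timings go to the log stream,
never into output files.

## Known limitations

- The Patient-Hours reading saturates the absolute mSEAL score on
  long-stay EDs (see above); absolute scores are therefore not comparable
  to staff-calibrated 1–6 values, while percentile categories remain
  meaningful.
- Cox standard errors ignore within-patient correlation from repeat
  visits; left truncation is the provided mitigation.
- No comorbidity adjustment (no such covariate exists in a generic log),
  no competing risks, no time-varying covariates, and no
  proportional-hazards diagnostics beyond convergence checks.
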