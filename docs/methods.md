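# Methods

`actiscan` implements a timing-of-physical-activity analysis for wrist-worn
actigraphy cohorts: minute-level MIMS (monitor-independent movement summary)
records are reduced to 24 hourly activity exposures per participant — anchored
either to the clock or to the individual's average sleep midpoint — and each
hourly exposure is tested for association with prevalent diabetes and with
continuous glycaemic markers using survey-weighted quintile regressions.
This note describes the procedure, its assumptions, and the design choices
made where the design was genuinely open.

## Data model and validity rules

Input is one row per participant-minute: timestamp (local clock, minute
resolution, no DST adjustment), a non-negative MIMS value, an upstream wear
classification (wake wear / sleep wear / non-wear), and an upstream quality
flag for signal unlikely to be human movement. The package does not compute
MIMS from raw accelerations and does not re-implement the wake/sleep/non-wear
classifier; both are consumed as inputs.

A **valid minute** is labelled wake or sleep wear; quality-flagged and
unknown-code minutes are treated as invalid (conservative — the upstream flag
semantics do not license using their MIMS values). A **valid day** is a
midnight-to-midnight calendar day with >= 1200 valid minutes (20 h).
Participants need >= 4 valid days to enter any analysis.

The exclusion cascade runs in a fixed order — age <= 20 years, pregnancy,
< 4 valid days, any missing hourly activity window, unknown diabetes status,
then (biomarker analyses only) missing outcome and current diabetes
medication — and a participant meeting several criteria is audited once,
under the first reason. The order matters only for audit bookkeeping, not
for the final cohort.

## Sleep timing

Sleep is searched between 20:00 and 10:00 the next morning (the "night
axis", 840 minutes). Restricting to this window deliberately discards
severely misaligned schedules (e.g. night-shift sleep); such nights simply
fail detection. **Onset** is the first sleep-wear minute inside the first
forward-rolling 30-minute window containing >= 15 sleep-wear minutes;
**offset** applies the mirrored rule rolling backward from 10:00 (last
sleep-wear minute inside the latest qualifying window). The backward rule is
implemented literally as the mirror image of the forward rule, and both are
verified against a brute-force enumeration of every 30-minute window.

Nights where either detector fails, or where offset precedes onset,
contribute nothing. Per-participant **mean onset** and **mean offset** are
arithmetic means on the 20:00-anchored axis — the search window precludes
midnight wrap-around, so no circular statistics are needed — and the
**overall sleep midpoint** is the midpoint of those two means (midpoint of
averages, not average of nightly midpoints). The **weekend midpoint**
(chronotype proxy) repeats the computation over Friday- and Saturday-anchored
nights and is missing when the recording covers neither. Midpoints are
carried at second resolution; nothing is rounded before window construction.

## Hourly exposures

Hourly windows are half-open and labelled by their ending hour. Clock window
1 is (00:00, 01:00]; midpoint-relative window k is
(midpoint + (k-1) h, midpoint + k h], with the 24-window frame anchored at
the participant's single overall midpoint replicated on every calendar day
(not per-night midpoints). Window means pool valid minutes across valid days
(minute-weighted); with complete data this coincides with averaging per-day
window means. A window is missing iff zero valid minutes fall in it across
the recording, which feeds the missing-hourly-window exclusion upstream.

Total activity is the mean over valid days of the within-day MIMS sum
(MIMS/day); sleep duration is the mean daily sleep-wear time in hours, banded
<7 / 7–9 / >9 h with the middle band closed on both ends.

Per window, exposures are quintiles cut at the unweighted 20/40/60/80th
percentiles of the analysis sample (survey-weighted quantiles were considered
and rejected: the cut-points define the exposure, not a population estimate).
Ties share the quintile of their common value; quintile 1 (least active) is
the reference.

## Outcomes and covariates

Diabetes is HbA1c >= 48 mmol/mol (6.5%) or self-reported diagnosis; it is
false only when both criteria are known negative, unknown otherwise.
Fasting insulin measured under the 2013–2014 laboratory protocol is mapped
to the 2011–2012 scale by the published calibration
10^(1.024·log10(x) − 0.0802) before anything else uses it; cycle tags
prevent double application. **HOMA-IR** uses the standard HOMA1-IR form,
glucose[mmol/l] × insulin[µU/ml] / 22.5 — the source analysis cites but does
not print its formula, so the standard one is adopted and stated prominently.
All four continuous markers are modelled on the natural-log scale. OGTT
protocol eligibility (fasting time, completed solution, phlebotomy consent,
…) arrives as a boolean flag and is applied as an exclusion for the OGTT
analysis only.

The adjustment set is: age (years, continuous), gender, race/ethnicity,
education (4 levels), household income (4 bands), marital status, smoking
(3 levels), alcohol (3 levels), BMI band (<18.5 / 18.5–<25 / 25–<30 / >=30),
total energy intake (kJ, continuous), sleep-duration band, sleep midpoint
(continuous, minutes on the 20:00-anchored axis) and total activity
(MIMS/day). BMI is included by default with a switch to drop it (the
narrower covariate list without BMI is a documented alternative). Missing
covariates are handled complete-case within each analysis; no imputation.

## Association models

For each of the 24 windows of a framing, the quintile factor enters a
weighted logistic (diabetes) or linear (log marker) regression with the
covariates above; weights are probability (survey) weights, so point
estimates are the weighted-MLE solution. The trend p value refits the model
with the quintile index 1–5 as one continuous regressor and reports its Wald
p value (invariant to affine recoding of the index). Subgroup analyses use
only this continuous-index trend per window (the power-preserving choice);
the chronotype split uses the in-sample median weekend midpoint, never a
hard-coded time. The sensitivity analysis repeats the main scan excluding
sleep durations <= 4 or >= 10 h.

Variance: design-based Taylor linearisation when stratum/PSU identifiers are
supplied (score totals per PSU, centred within stratum, with the
n_h/(n_h − 1) correction), otherwise a per-observation weight-robust
sandwich. With the Taylor variance, confidence intervals and Wald p values
use Student-t quantiles with design df = (#PSUs − #strata), the convention of
the established survey packages; with a realistically small number of PSUs,
normal quantiles measurably undercover. The sandwich path keeps normal
quantiles. Multiple-testing correction is not applied to the per-window
trend p values (each window is reported as its own comparison); downstream
consumers can apply Benjamini–Hochberg to the long-format output if wanted.

Numerical details: design-matrix columns are rescaled to unit
root-mean-square inside the fitter (continuous covariates live on scales of
1e4, which otherwise makes the sandwich numerically indefinite) and results
are mapped back exactly. Windows with a single quintile level are skipped
with a warning; complete separation or non-convergence yields an explicit
`non_estimable` flag in the output grid, never a silent gap. Fits require
>= 50 complete cases and both outcome levels.

## Synthetic cohort generator

The generator is first-class, tested code and defines the study conditions
for every simulation result in the package.

Per participant: a habitual sleep midpoint ~ N(03:00, 40 min) and habitual
duration ~ N(7.5, 1.0) h (both truncated to plausible ranges); nightly bouts
centred on the midpoint with N(0, 0.3 h) night-to-night duration wobble, for
the n_days − 1 nights fully contained in the midnight-to-midnight recording;
i.i.d. per-minute wake intrusions during sleep (fragmentation, default 0.05)
and non-wear minutes outside sleep (default 0.02). Minute MIMS are lognormal
(shape 0.5) around a diurnal wake profile: base 6.4 MIMS, a plateau of 12.0
between 7 and 17 h after the sleep midpoint with 2-h linear ramps, and 1.5
during sleep. Mean-one lognormal person (sd 0.2) and person-by-window
(sd 0.35) multipliers add realistic between-person and window-specific
variation. These values calibrate the cohort median total activity to about
11 thousand MIMS/day. Survey design is a two-stratum unequal-probability
sample (35% oversampled stratum, weights ~ inverse sampling rate with 10%
lognormal jitter) with 12 PSUs per stratum, so the design-based variance
path is genuinely exercised.

Diabetes is drawn from a logistic model whose intercept is solved (Brent's
method on the mean probability) to hit the target prevalence (default 18.7%)
given an age gradient and, optionally, a log-OR per quintile step of the
*true* hourly mean at one chosen midpoint-relative window. Continuous
markers take an analogous additive effect on the log scale. HbA1c and
self-report are emitted consistently with the drawn status; 2013–2014-cycle
insulin is emitted on that cycle's laboratory scale (the inverse of the
published calibration), so the pipeline must re-apply the harmonisation to
recover the generating values.

Two entry points share this diurnal model. `simulate_cohort` writes minute
records and is used wherever the detectors and feature extraction are under
test. `simulate_feature_cohort` draws the per-participant hourly means
directly — true means times mean-one lognormal observation noise (sd 0.03,
matching the sampling error of a window mean pooled over ~400 minutes) — and
is used for Monte-Carlo studies (type-I error, recovery, coverage), where
regenerating tens of millions of minutes per replicate would dominate the
runtime without exercising anything new. The recovery harness therefore runs
the pipeline from the features stage downward (per-window quintiles →
weighted scan → trend test), which is the machinery those studies are about.

What the generator does **not** emulate: joint covariate distributions of
any real survey (covariates are drawn independently), shift-worker or
free-running sleep schedules, day-of-week activity structure, device
non-wear patterns that correlate with behaviour, and cluster-level outcome
correlation (PSU labels are pure design labels). Passing simulation tests
therefore demonstrates correctness of the machinery under a faithful but
idealised data-generating process, not agreement with any real cohort.

## Monte-Carlo problem sizes

Type-I error: 500 null cohorts of n = 1000, trend test at one fixed window,
nominal 5% level. Recovery: 50 cohorts of n = 4000 with −0.2 log-OR per
quintile step injected at relative window 13; recorded are the mean trend
estimate, 95% CI coverage of the injected value, and the localization rate
(the window with the minimum Q5-vs-Q1 estimate equals the injected window).
CI-calibration check: 200 cohorts of n = 2000. Detector verification: 1000
random nights against brute-force enumeration; midpoint identifiability: 500
participants with clean bouts (no fragmentation/non-wear), where the
detected overall midpoint must sit within 0.5 min of truth for everyone
(the half-minute bound is the exact discretisation limit of minute-resolution
bouts).

## Known limitations

* Cluster-robust CIs with few PSUs remain slightly anti-conservative even
  with design-df t quantiles; the per-observation sandwich is better
  calibrated when no true cluster structure exists.
* Quintile cut-points are treated as fixed once estimated; their sampling
  noise adds a small attenuation (about 3% of the injected effect at the
  default noise levels) that the model-based CIs do not account for.
* Arithmetic (non-circular) sleep averaging is only valid because detection
  is confined to 20:00–10:00; widening that window would require circular
  statistics and a different treatment of shift workers.
* The SAS-transport reader is an optional adapter over `pandas.read_sas`;
  the CSV dialect is canonical and is what the tests exercise.
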