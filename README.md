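# actiscan

**Does it matter *when* you move?** `actiscan` is an analysis pipeline for
studying the timing of 24-hour physical activity in relation to diabetes and
glycaemic markers, built for epidemiologists working with minute-level
wrist-actigraphy data (MIMS units with upstream wake/sleep/non-wear labels,
as distributed by large health surveys).

The pipeline:

1. **Ingest & QC** — normalise minute records, apply validity rules (valid
   minute = wake or sleep wear; valid day >= 20 h of valid data) and an
   audited exclusion cascade (age, pregnancy, < 4 valid days, missing hourly
   windows, unknown diabetes; plus outcome/medication exclusions for the
   biomarker subsamples).
2. **Sleep timing** — detect nightly sleep onset and offset with a rolling
   30-minute window rule (first/last sleep-labelled minute inside the first
   window holding >= 15 sleep minutes, searched between 20:00 and 10:00),
   then average to an overall sleep midpoint and a weekend midpoint
   (chronotype proxy).
3. **Hourly exposures** — 24 hourly mean-MIMS values per participant in two
   framings: clock time, and hours elapsed since the individual's sleep
   midpoint (the primary framing, which aligns people by circadian phase
   rather than by the wall clock); plus total activity and sleep duration.
4. **Association scan** — per window, cut the exposure into quintiles
   (Q1 = least active = reference) and fit a survey-weighted logistic
   (prevalent diabetes) or linear (log glycaemic marker) regression adjusted
   for demographics, lifestyle, BMI, energy intake, sleep duration, sleep
   midpoint and total activity. Report OR/β with 95% CI per quintile and a
   Wald p-trend from the continuous quintile index (1–5):

   logit P(diabetes) = α + Σₖ βₖ·1[Q=k] + γ'·covariates,  k = 2…5

   with design-based (Taylor-linearised) variances when stratum/PSU
   identifiers exist, and subgroup/sensitivity re-runs.
5. **Synthetic cohorts** — a generator with known sleep timing, a diurnal
   MIMS profile (plateau 7–17 h after the sleep midpoint), survey design and
   outcomes with an injectable window-specific timing effect, used as the
   test bed for everything above.

## Worked example

The numbered scripts under `analysis/` form the full study on a synthetic
cohort with a known timing effect (−0.2 log-OR per quintile step injected at
midpoint-relative window 13, i.e. the hour ending 13 h after the sleep
midpoint — early afternoon for a 03:00 midpoint):

```bash
python analysis/01_simulate_cohort.py      # 600 participants, minute-level
python analysis/02_scan_diabetes.py        # main 24-window scan, both framings
python analysis/03_scan_glycaemic_markers.py
python analysis/04_subgroups_sensitivity.py
python analysis/05_calibration_simulations.py
```

Step 02 prints, for this cohort:

```
cascade: 600 -> 568 included; exclusions {'none': 568, 'age_le_20': 23, 'unknown_diabetes': 8, 'pregnant': 1}
relative: lowest Q5-vs-Q1 OR 0.23 at window 13
clock: lowest Q5-vs-Q1 OR 0.31 at window 10
```

Reading this: after the exclusion cascade, 568 of 600 participants enter the
diabetes analysis. Scanning all 24 midpoint-relative windows, the strongest
inverse association between activity and diabetes odds (highest vs lowest
activity quintile) lands exactly on window 13, where the effect was
injected. In the clock-time framing the same signal surfaces as low ORs at
the windows ending 15:00–16:00 (0.55 and 0.42 in `curve_clock.tsv` — where
relative window 13 falls for a typical 03:00 midpoint), but because
participants differ in sleep timing the effect is diluted, and at this
sample size the pointwise minimum lands on a noisy morning window instead.
That contrast is exactly why the midpoint-relative framing is the primary
one. Full grids (`scan_*.tsv`), report-style tables (`table_*.tsv`), curve
data and figures land under `results/`.

The same machinery runs on real data: point `actiscan scan` (or
`actiscan.pipeline.run`) at a minute-level CSV
(`participant_id,timestamp,mims,wear_class,quality_flag`; SAS-transport also
accepted) and a participant table documented in the module docstrings.

```bash
actiscan scan --input minutes.csv --participants participants.csv \
    --analysis diabetes --framing both --out results/mystudy --seed 0
```

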