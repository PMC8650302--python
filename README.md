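# mbooi

Urodynamic obstruction indices and prediction of TURP surgical efficacy for
LUTS/BPH cohorts.

Men with benign prostatic hyperplasia (BPH) are often treated with
transurethral resection of the prostate (TURP), but a quarter of patients do
not benefit. Pressure-flow studies quantify the bladder outlet obstruction
(BOO) driving symptoms, classically through the obstruction index

```
BOOI  = PdetQmax − 2·Qmax          (detrusor pressure only)
```

Many obstructed patients strain abdominally to void, which the detrusor-only
index ignores. The *modified* index keeps the abdominal component:

```
MBOOI = Pves − 2·Qmax,      with   Pves = PdetQmax + Pabd
```

so that `MBOOI − BOOI = Pabd` identically. This package implements, for
clinical researchers working with pressure-flow cohorts:

- **indices** — PdetQmax, BOOI, MBOOI, BOO grade (unobstructed ≤ 20 <
  equivocal ≤ 40 < obstructed), prostate ellipsoid volumes and the
  transitional-zone index TZI = TZV/TPV;
- **grading** — four-level efficacy grades (poor/fair/good/excellent) on
  three axes (post/pre IPSS-t ratio, QoL score drop, Qmax gain), combined by
  the median into an overall grade; grades 3–4 count as *effective*;
- **cohort_stats** — Kolmogorov–Smirnov-screened t / Mann–Whitney group
  comparisons, a simple-linear-regression predictor screen, forward stepwise
  binary logistic regression (likelihood-ratio entry, Wald odds-ratio CIs),
  and ROC/AUC predictor comparison with DeLong confidence intervals;
- **simulate** — a calibrated synthetic cohort generator reproducing the
  published baseline moments and an MBOOI-driven outcome mechanism, used to
  exercise and validate the whole pipeline end to end (the study's
  patient-level data were never deposited).

## Worked example

```bash
mbooi simulate --n 403 --seed 7 --out cohort.csv
mbooi analyze --input cohort.csv --out report --seed 7
```

prints `overall effective rate: 72.70%` and writes a report bundle;
`report/efficacy_summary.txt` begins

```
symptom  (effective rate 76.92%)
  excellent    147  (36.48%)
  good         163  (40.45%)
  ...
overall  (effective rate 72.70%)
```

meaning 76.9% of the simulated patients improved their IPSS total by more
than 50%, and 72.7% reached an overall (median) grade of good or excellent.
The statistics stage screens baseline variables, fits the stepwise logistic
model and compares predictors by ROC; for this cohort it selects MBOOI as
the only predictor (odds ratio 1.051 per cmH2O, 95% CI 1.040–1.063,
p = 5×10⁻¹⁹) and ranks the predictors for overall efficacy as

```
predictor   auc  ci_low  ci_high
    mbooi 0.845   0.805    0.885
     booi 0.815   0.771    0.859
      tzi 0.530   0.466    0.593
      tzv 0.498   0.432    0.564
```

— the generator's outcome mechanism is driven by baseline MBOOI, and the
pipeline recovers exactly that: MBOOI beats the detrusor-only BOOI, while
the anatomical measures carry almost no signal. `mbooi recover --seed 11`
repeats this generate→grade→analyse loop over many replicates and reports
how often MBOOI is selected first and out-ranks BOOI.

Library use mirrors the CLI: `simulate.generate_cohort`,
`indices.add_indices`, `grading.grade_cohort`, and the functions in
`cohort_stats` all operate on pandas DataFrames with the documented cohort
schema (`mbooi.io`).

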