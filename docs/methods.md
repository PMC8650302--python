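# Methods

## Indices

A pressure-flow study measures, at the instant of maximum urinary flow
`Qmax` (mL/s), the intravesical pressure `Pves` and the abdominal pressure
`Pabd` (both cmH2O, rectal catheter reference). Detrusor pressure is
`PdetQmax = Pves − Pabd`. The obstruction indices are linear:
`BOOI = PdetQmax − 2·Qmax` and `MBOOI = Pves − 2·Qmax`, hence
`MBOOI − BOOI = Pabd` per patient and — by linearity — for cohort means.
BOO grade bands close on the upper edge: unobstructed (BOOI ≤ 20),
equivocal (20 < BOOI ≤ 40), obstructed (BOOI > 40).

Negative `PdetQmax` (transducer drift, straining artefact) is retained with
a quality flag; analyses exclude flagged records only when
`exclude_negative_pdet` is set. Units are fixed (cmH2O, mL/s, mL); there is
no conversion layer.

Prostate volumes use the TRUS ellipsoid formula `h·w·l·π/6`; the
transitional-zone index TZI = TZV/TPV is computed per patient and then
averaged — cohort TZI is never the ratio of mean volumes, which differs
whenever TZI and TPV covary (the published cohort mean TZI, 0.43, is
visibly not 24.90/52.84 ≈ 0.47).

## Efficacy grading

Improvement is graded 1–4 per axis:

| axis | statistic | 4 excellent | 3 good | 2 fair | 1 poor |
|---|---|---|---|---|---|
| symptom | r = IPSS-t post/pre | r ≤ 0.25 | ≤ 0.50 | ≤ 0.75 | > 0.75 |
| QoL | d = pre − post | d ≥ 4 | d = 3 | d ∈ {1,2} | d ≤ 0 |
| function | g = Qmax post − pre | g ≥ 10 | [5, 10) | [2.5, 5) | < 2.5 |

IPSS-ratio bands close on the right, Qmax bands on the left, exactly as the
cutoffs are worded ("improvement ≥ 10.0 mL/s", "≤ 25 %"). Worsening (r > 1
or d < 0 or g < 0) falls in the poor band — extending the lowest band
downward is the only monotone completion of the published cutoffs. A
baseline IPSS-t of 0 leaves the ratio undefined; such records are excluded
with a reason code rather than imputed (surgical candidates realistically
score ≥ 8). The overall grade is the median of the three axis grades
(always an attained level for three values); grades 3–4 define *effective*.
Table percentages are rounded half-up to 2 decimals.

## Statistical pipeline

1. **Normality screen**: one-sample Kolmogorov–Smirnov against a normal law
   with sample-estimated mean/SD, α = 0.05. Estimating parameters from the
   same sample makes the plain KS anti-conservative toward normality; a
   Lilliefors-corrected variant is available (`lilliefors=True`) but the
   plain screen is the default because it is what standard clinical
   software reports. Constant samples are non-normal with a degenerate flag.
2. **Group comparison**: Student's t (equal variances) when the screen
   accepts normality, else Mann–Whitney U — exact enumeration for small
   tie-free samples, tie-corrected normal approximation otherwise (SciPy's
   `method="auto"` policy). Two-sided throughout.
3. **Univariate screen**: each candidate regressed alone against the
   ordinal overall grade (1–4 treated as numeric); candidates kept at
   p < 0.05. Zero-variance predictors are excluded with a reason.
4. **Forward stepwise logistic regression** on the binary
   effective/ineffective outcome: at each step the remaining candidate with
   the smallest likelihood-ratio p enters if p < 0.05; refit by Newton MLE
   to convergence after every entry. Pure forward by default; `p_remove`
   (e.g. 0.10) enables a removal step for parity with SPSS's "forward
   conditional". Odds ratios are `exp(coef)` with Wald 95 % intervals
   `exp(coef ± 1.96·SE)` and Wald p-values (the CI flavour is a choice;
   profile-likelihood intervals are not provided). Because the cohort
   schema contains exact identities (MBOOI = Pves − 2·Qmax,
   BOOI = MBOOI − Pabd), a candidate whose entry would make the design
   matrix rank-deficient is skipped at that step and reported. Perfect or
   quasi-separation (non-convergence or |coef| > 30) aborts with a
   diagnostic rather than reporting meaningless intervals.
5. **ROC analysis**: AUC via the Mann–Whitney identity (ties half credit),
   equal to the trapezoidal area under the empirical curve; 95 % CI by
   DeLong's method in the midrank formulation (verified to 7 digits against
   R `pROC::ci.auc(method="delong")`), clipped to [0, 1]; a seeded
   percentile bootstrap is available. Predictors are compared per outcome
   axis (grade ≥ 3 on symptom/QoL/function/overall) and ranked by AUC.

Missing data are handled complete-case per analysis, with exclusion counts
logged. All group tests need n ≥ 2 per group; the pipeline refuses the
statistics stage below 20 records, with a logged diagnostic, while still
writing the grading outputs.

## Synthetic cohort generator

The study's patient-level data were never deposited, so validation runs on
synthetic cohorts built from the published summary moments:

- Continuous baselines are truncated normals. The parent location is
  re-solved (Brent) so the **post-truncation** mean hits the published
  target — naive truncation at 0 would inflate Pabd's mean by ≈ 4 cmH2O.
  Targets (mean ± SD, truncation): PdetQmax 84.92 ± 35.23 (≥ 5 cmH2O),
  Pabd 17.79 ± 16.40 (≥ 0), Qmax 8.10 ± 3.37 (≥ 1 mL/s), TPV 52.84 ± 27.63
  (≥ 15 mL), TZI 0.43 ± 0.14 (0.05–0.95), age 70.94 ± 7.50 (53–90),
  questionnaire scores at their published moments within legal ranges,
  rounded to integers.
- `Pves = PdetQmax + Pabd` and `TZV = TZI·TPV` hold by construction, so the
  index identity and `0 < TZV ≤ TPV` are exact. TZV's marginal mean emerges
  as ≈ 22.7 mL versus the published 24.90; the gap is the unpublished
  TPV–TZI correlation, which is deliberately not modelled.
- PSA (4.86 ± 4.98) and PVR (74.36 ± 78.10) are heavy-right-skewed and drawn
  from moment-matched log-normals.
- Beyond the structural identities, variables are independent: the true
  inter-variable correlations are unpublished, and inventing a copula would
  assert structure the summary tables do not support.

**Outcome mechanism.** Each patient gets a latent improvement propensity
`η = β·(MBOOI − 86.52)/40.59 + ε`, ε ~ N(0,1) — more obstructed bladders
(higher MBOOI) benefit more from resection. Each axis adds its own noise
`τ·ε_axis` before mapping to an observable: the IPSS post/pre ratio is a
logistic function of the axis latent, the QoL drop a rounded affine map,
and the Qmax gain an affine map floored at zero.

**Calibration (done once, frozen).** Per-axis intercepts and slopes are
solved (closed-form Gaussian band matching plus an empirical polish at
n = 200 000) so the per-axis grade distributions match the published bands
(effective rates 76.2/65.5/71.5 %); the axis noise τ = 1.889 pins the
overall effective rate at ≈ 73.7 %; β = 2.5. β is deliberately *larger*
than the value that would reproduce the study's observed AUC of 0.744
(that would be β ≈ 0.8): under the published SDs, Pves and MBOOI correlate
at ≈ 0.986, so at the study's effect size forward selection cannot reliably
distinguish the true driver from its near-duplicate at n = 403. The
generator's job is to make the mechanism *identifiable* so that recovery
failures indicate pipeline defects, not sampling noise; with β = 2.5 the
stepwise model selects MBOOI first and ROC ranks MBOOI above BOOI in ≈ 92 %
of replicates (the attainable maximum is ≈ 93 %: the published per-axis
versus overall effective rates bound the inter-axis correlation and hence
MBOOI's achievable signal share). Consequently the synthetic AUC (≈ 0.90)
intentionally exceeds the study's 0.744, and passing recovery tests show
the pipeline recovers a strong MBOOI mechanism — they do not show that
real data carry one that strong.

**What passing tests do not show.** The generator reproduces marginal
moments, structural identities and an outcome mechanism, not the joint
distribution of real urodynamic data: no TZV–MBOOI or age–pressure
correlations, no measurement error in the pressure traces, no dropout, a
single follow-up time. Group-difference *directions* (effective group
higher Pves/Pabd/BOOI, lower Qmax) emerge from the mechanism and match the
published table; magnitudes need not.

**Null configuration** (`beta_mbooi = 0`) switches the mechanism off:
MBOOI's AUC is ≈ 0.5 and the 0.05-level univariate screen selects it at its
nominal ≈ 5 % false-positive rate. The downstream stepwise stage selects it
less often (≈ 1–2 %): entry requires a second 0.05-level test, and chance
associations are split among the collinear Pves/BOOI/MBOOI cluster, so the
two-stage pipeline is conservative, never anticonservative.

## Numerical choices

- Truncated-normal location solving: Brent on the analytic truncated mean,
  xtol 1e-10.
- Logistic fits: statsmodels Newton, tol 1e-10, max 100 iterations;
  non-convergence is treated as (quasi-)separation.
- DeLong variance via midranks, O(n log n); z = 1.96 for 95 % intervals.
- Replicate seeds are spawned from a master seed via `SeedSequence` and
  reduced mod 2³¹; identical (config, seed) gives bit-identical cohorts and
  byte-identical `results.json` (sorted keys, no timestamps in
  machine-readable output).
- Simulation sizes in the test suite (50 recovery replicates at n = 403,
  200 null replicates, moment checks at n = 10⁵) were chosen as the
  smallest designs whose binomial/standard errors are well inside the
  asserted tolerances.

## Known limitations

- The efficacy grading needs exactly one follow-up; multiple visits or
  time-to-event outcomes are out of scope.
- The stepwise procedure inherits the usual caveats of stepwise selection
  (post-selection inference is not adjusted); it is implemented because it
  is the analysis this pipeline mirrors, not as a recommendation.
- Wald intervals can misbehave near separation; the fit aborts rather than
  reporting them in that regime.
- The follow-up interval is metadata, not modelled; the grading applies to
  whatever single reassessment the cohort file carries.
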