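# Methods

## Study design emulated

The pipeline reproduces a matched-cohort interrupted time series (ITS)
design: subjects first exposed (index event) inside a configurable calendar
window, each exactly matched 1:1 with a never-exposed control on age at
index (completed years), sex, race and ethnicity. The matched control
inherits its case's index month, so both members of a pair contribute the
same calendar months to the ±72-month analysis window. Diagnosis
trajectories are cumulative ("percent ever diagnosed"), with a fixed
closed-cohort denominator: eligibility guarantees every retained subject is
observable across the whole window, so no censoring is modeled.

## Segmented regression

Each condition × group prevalence series is fit by OLS to
`Y = b0 + b1·T + b2·D + b3·P + ε` with `T` centered at the index month,
`D = 1[T ≥ 0]`, `P = D·T`. Conventions and caveats:

- **Index month placement.** Offset 0 carries `D = 1, P = 0`: the level
  jump `b2` is located in the month of the index event, consistent with the
  index-month incidence rate being measured there. A config flag
  (`include_index_month=False`) drops offset 0 from the fit instead.
- **Errors.** Classical (homoskedastic, independent) standard errors.
  Cumulative prevalence is serially correlated by construction, so these
  SEs understate uncertainty; no Newey–West or ARIMA correction is applied,
  keeping the model the plain linear approximation whose coefficients map
  directly onto the reported metrics. Inference on the simulated cohorts in
  the tests therefore uses a delta-method Monte-Carlo SE built from the
  (approximately independent) monthly increments, not the OLS SEs.
- **Degeneracy.** Fewer than five points, fewer than two points on either
  side of the index, an all-zero series, a rank-deficient design, or no
  residual degrees of freedom set `status = "fit_error"` rather than
  raising; reports print `*` for such cells. Undefined incidence-rate
  ratios (control IR = 0) also print `*` but carry a distinct status in the
  machine-readable output.
- **Units.** Time is months inside the model; all annual quantities are 12×
  the monthly slopes. Everything is on the percent (0–100) scale.

IR and IRR are computed from the raw month-0 prevalence increment, not from
`b2`; IRD comes from the fitted `b3`. Both alternatives (fitted `b2`, a
model-free mean-increment IRD) are cross-exported in `metrics.csv` for
comparison.

## Ascertainment

A subject is diagnosed with a condition only when two codes for it are at
least 30 days apart (threshold inclusive; dates are exact days, so the rule
is exercised with real day arithmetic rather than month bins). Since a
qualifying pair exists iff the earliest and latest codes span the
threshold, the decision is order- and duplicate-insensitive. Onset is dated
at the earliest code of a qualifying pair by default; dating it at the
confirming code is available (`onset_rule="second"`) because either reading
is defensible. Conditions with no pre-index onset in either group are
excluded from fitting, since a pre-period with no events cannot anchor a
pre-index trend.

## Synthetic cohort generator

The simulator emulates exactly the structure the analysis assumes:

- **Onset process.** Per condition, a monthly Bernoulli onset hazard,
  absorbing per subject. Baseline hazard is shared by both groups; exposed
  subjects additionally receive an extra onset probability in the index
  month (`index_spike`) and a step increase in hazard for months after the
  index (`post_slope_delta`). A mild secular trend (default 1 %/yr,
  relative, anchored at the calendar-window start) multiplies the baseline
  in both groups. Subjects are simulated over a single calendar grid
  spanning six years beyond the index-year range on both sides, so controls
  need no index date of their own until matching assigns one.
- **Codes.** After onset the subject emits the onset code, a guaranteed
  confirmation code 30–44 days later (so ascertainment sensitivity is 1 by
  default, and can be degraded deliberately), and Poisson extra codes for
  12 months.
- **Demographics.** Age ~ round(Normal(30.1, 9.0)) clipped to [18, 70];
  sex 92.7/7.3, race 77.3/14.1/8.6, ethnicity 85.1/14.9, severity mix
  67.5/14.0/2.6/15.9 (mild / moderate-severe / penetrating / unclassified) —
  the demographic mix of the veteran cohort this design targets. The first
  `n_exposed` members of the control pool are exact demographic twins of
  the cases, guaranteeing that 1:1 exact matching can saturate; the rest of
  the pool is iid from the same marginals.
- **Randomness.** One seed, split per subject × condition through
  `SeedSequence` spawn keys: adding a condition or extending the pool never
  perturbs existing event streams, and a fixed seed reproduces every output
  byte-identically.
- **Ground truth.** `truth.json` records, per condition, the exact expected
  prevalence curves from the deterministic at-risk recursion
  `S(m) = S(m−1)(1 − p(m))`, the expected index-month increment, the
  implied IRR, and the *estimand* of the annual IRD — the `12·b3` obtained
  by fitting the segmented model to the noiseless expected curve. The
  estimand is the right recovery target because a step in the conditional
  hazard does not translate one-for-one into a prevalence slope change:
  at-risk depletion makes the cumulative curve slightly concave, so e.g. a
  0.001/month hazard step over a +72-month window yields an IRD estimand of
  ≈1.10 %/yr against the naive 1.2 %/yr. Tests compare estimates to the
  estimand within delta-method Monte-Carlo error.

What the simulator does **not** emulate: realistic ICD code vocabularies,
care-utilization intensity (surveillance bias after the index event),
mortality or censoring, correlated comorbidity onsets, or
exposure-dependent demographics. Passing recovery tests therefore shows the
estimator chain is correct under the design's own assumptions, not that
those assumptions hold in real health records.

## Matching and strata

Greedy first-available matching over a seed-shuffled pool, deterministic
given seed and input order; unmatched cases are dropped with a logged
warning rather than failing the run. Analysis strata: `control`,
`all_tbi` (every matched case), `mild`, and `moderate_or_above`
(moderate/severe ∪ penetrating); unclassified severity contributes to
`all_tbi` only.

## Numerical and formatting choices

- Prevalence matrices round-trip as wide CSV or XLSX; the reader tolerates
  shuffled columns and offset headers written as integers, "month −12" or
  "year −1" (years × 12). Monotonicity violations beyond a 0.05-percentage-
  point rounding tolerance warn rather than fail, since deposited summary
  tables are rounded.
- Ranked summary tables print one decimal at magnitude ≥ 1 and two below;
  IRRs print as integers at ≥ 10 and one decimal below. Top-k rankings
  break ties by condition label, exclude undefined IRRs, and the reported
  condition set is the union of the four top-k lists.
- Problem sizes in the test suite: engine checks run on 1 000 random series
  (length ≤ 145); recovery and null checks simulate 20 000 matched pairs
  with one condition each, enough that binomial error on a 5 %/month spike
  is ±0.4 percentage points at 99% confidence; the end-to-end pipeline
  example uses 2 000 pairs and four conditions.

## Known limitations

- OLS p-values on cumulative series are anti-conservative (see above); they
  are reported, never used as gates, and no multiple-testing correction is
  applied.
- The IRR is a ratio of single-month binomial increments; at small group
  sizes the control increment is frequently zero and the ratio undefined —
  by design this surfaces as `*` rather than a capped value.
- Greedy matching does not maximize the number of matched pairs in
  pathological pool configurations; with twin-guaranteed pools it is
  exhaustive.
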