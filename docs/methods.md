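# Methods

## Scope and assumptions

The package models night-time sleep inferred from two sources that must
agree: a diary window saying the athlete was in bed attempting sleep, and
wrist activity counts low enough to indicate immobility. Everything
outside a diary window is wake by definition, so daytime naps do not
exist in this model, and wake after sleep onset (WASO) appears only
through total sleep time and efficiency — never in the regularity state
vector.

Timestamps are naive local clock time on a contiguous 1-minute grid;
epochs are half-open `[t, t+60 s)` intervals. Inputs spanning a
daylight-saving transition are out of scope (timezone-aware timestamps
are rejected outright). All clock summaries live on a noon-referenced
axis (minutes since the preceding 12:00), the standard convention that
keeps a whole night inside one "day" so medians and MADs of bedtimes
never straddle midnight.

## Sleep/wake scoring

Each epoch's activity score is the five-epoch weighted sum
`0.04, 0.2, 1.0, 0.2, 0.04` over counts `c[i-2..i+2]`, with out-of-range
neighbours treated as zero; an epoch inside the diary window is scored
sleep when the score is **at or below** the threshold (ties sleep). The
threshold presets are low/medium/high = 80/40/20 counts; medium (40) is
the default. A configuration switch (`weighted=False`) reduces the rule
to a plain per-epoch threshold, which exists mainly so tests can compare
against a naive reimplementation.

Sleep onset is the start of the first run of `onset_consecutive_epochs`
sleep-scored epochs after bedtime; offset is, symmetrically, the end of
the last such run before get-up. The default run length is 1 — onset is
simply the first epoch scored asleep — because the per-night variable is
defined as the moment the athlete first fell asleep; a stricter
consecutive-minutes criterion is exposed but not default.

Off-wrist time is represented by a per-epoch validity mask. Masked epochs
inside a window are scored wake, and a night with more than
`max_invalid_fraction` (default 10%) invalid window epochs is dropped
from all aggregates, with a log entry. This masking policy is this
package's choice; there is no canonical rule.

Derived variables per night: bedtime, onset, offset, midpoint
(= onset + period/2) in noon-referenced minutes; sleep period
(offset − onset) and TST (sleep-scored minutes within the period) in
hours; efficiency = 100·TST/period; onset latency = onset − bedtime in
minutes. Invariants enforced by construction and verified on randomised
nights: bedtime ≤ onset ≤ midpoint ≤ offset, TST ≤ period,
0 < efficiency ≤ 100, latency ≥ 0.

## Sleep Regularity Index

The SRI is `-100 + 200 f`, where `f` is the fraction of epoch pairs 24 h
apart in the same binary state. The printed double-sum form runs the day
index to `N` with an undefined `s_{N+1,j}`; it is implemented over
`i = 1..N-1`, consistent with the `M(N-1)` normaliser. Three conventions,
each configurable or documented because no canonical choice exists:

* **Whole weeks.** The index is computed over the longest whole number of
  weeks; the *first* `7⌊days/7⌋` days are kept (deterministic, no
  look-ahead). At least 7 days are required.
* **Missing epochs.** Pairs with a missing member are dropped from
  numerator and denominator alike (`missing_epoch_policy='mask'` marks
  days without a valid night missing; the default `'wake'` codes them
  wake).
* **State content.** Sleep epochs are exactly the minutes in
  `[onset, offset)` of valid nights; interior wake is not reintroduced.

Note that the index is not an overlap fraction: fully anti-phased
half-day sleep scores −100, and two disjoint 8-h sleep periods score
−33.3, not 0. The formula is authoritative over intuition here.

Per-athlete variability is summarised two ways: the MAD (median absolute
deviation from the athlete's own median) of onset, offset, bedtime,
midpoint (clock minutes), TST (minutes) and efficiency (%); and the
absolute night-to-night variation — |difference to the previous night|
over consecutive night pairs — aggregated per athlete as the **median**
of pair values (the mean is available via `aggregate='mean'`; which one
the convention intends is genuinely open, and the median matches the
median/IQR reporting style used everywhere else).

Regular/irregular classification takes the empirical 20th/80th SRI
percentiles (linear interpolation): regular means SRI ≥ the 80th,
irregular ≤ the 20th, boundary ties joining the extreme group — which is
how group sizes can differ. A degenerate cohort (an athlete tied into
both boundaries) raises and demands an explicit
`quintile_tie_policy='exclusive'` override.

## Group statistics

Medians and IQRs use type-7 (linear-interpolation) percentiles. The
two-sided Wilcoxon rank-sum test uses the tie- and continuity-corrected
normal approximation; when both groups have ≤ 8 observations and no ties
the p value comes from exact enumeration instead (the z statistic is
always the corrected normal one, since it also feeds the effect size).
Two identical samples return p = 1, z = 0 rather than an error.

Effect size: `r = z/√(n_a+n_b)`, positive when the first group tends to
be larger. The 95% CI is a seeded percentile bootstrap (default 1000
resamples of athletes within group), widened if necessary to bracket the
point estimate — relevant only for saturated effects, where resampling
introduces ties that perturb the tie-corrected z. Magnitude labels on
|r|: trivial ≤ 0.10 < small ≤ 0.3 < medium ≤ 0.5 < large. No
multiple-testing correction is applied.

## Importance models

For each outcome (median TST in hours, or median efficiency in %), the
predictors are the athlete's SRI, onset/offset/midpoint/bedtime medians,
onset/offset MADs, absolute onset/offset variation, and the
complementary outcome. The pipeline is: seeded unstratified 80/20
shuffle split; iterative VIF filtering on the training design (drop the
highest VIF while any ≥ 10, `VIF_k = 1/(1−R²_k)` from auxiliary
regressions with intercept; perfect collinearity reported as infinite;
ties at the maximum drop the alphabetically first name, which makes the
result independent of column order); tenfold cross-validation with 5
repeats of an OLS fit; a final OLS fit on the full training set; held-out
R² and NRMSE on the test set; and importance as the |t| statistic of each
coefficient min-max scaled to [0, 100].

NRMSE is normalised by the observed **range** of the outcome on the test
set (mean-normalisation via `nrmse_norm='mean'`); range is the most
common reading where only "normalised RMSE (%)" is specified. The sleep
midpoint is exactly (onset+offset)/2 and is reliably removed by the VIF
filter on realistic data; nothing hard-codes its removal. On the
synthetic cohorts the filter typically also removes the onset median
(nearly collinear with bedtime, since latency is short) — synthetic
profiles are more collinear than real cohorts because every variable
derives from the same few latent parameters.

## Synthetic cohort generator

The generator emulates a team-sport cohort at the scale the analysis was
designed for: ~200 athletes, 7–43 nights each (7 + Poisson(2.7) ≈ 9.7 on
average), bedtimes near 23:00 (minute 660), a nightly sleep need of
8.3 h, onset latency ~ Exponential(5 min), WASO at 9.4 wake-minutes per
sleep hour (so efficiency centres on 60/(60+9.4) ≈ 86.5%), a 30-min
Friday/Saturday delay, and 30-min night-to-night jitter SDs on bedtime
and sleep duration. `mean_sleep_need` is the target **TST**; WASO is
added on top, so the sleep period is TST + WASO and recovered median TST
tracks the configured need.

Between-athlete heterogeneity is what gives cohort-level spread and makes
quintile classification meaningful: athletes differ in habitual bedtime
(SD 55 min), sleep need (SD 35 min), jitter magnitude (log-normal
multiplier, geometric SD 1.6), latency scale (geometric SD 1.8) and WASO
propensity (gamma, SD 4), with WASO weakly coupled (square-root) to the
jitter multiplier so that irregular sleepers also have somewhat lower
efficiency. With the defaults this lands cohort medians near SRI 87,
bedtime 23:05, TST 8:17, efficiency 87% with IQRs of realistic width.

The count model is deliberately *deterministic in its classification*:
wake minutes draw 205 + Gamma(3, 65) capped at 900 counts, WASO minutes
draw uniform 45–150, sleep minutes are 0 apart from occasional bursts
(p = 0.05, Poisson(8) capped at 25) kept 5 min from interval ends and
2 min from WASO. Under the weighted rule at threshold 40 these bounds
guarantee that every wake/WASO minute scores wake, every interior sleep
minute scores sleep, and exactly the first and last minute of each sleep
interval are eroded by neighbour contamination. Consequences: a
zero-noise configuration recovers SRI = 100 and efficiency = 100%
*exactly*; in general onset is recovered 1 min late, offset 1 min early,
TST 2 min short, and per-night recovery RMSE equals |bias|. This is a
validation-oriented choice — real accelerometry is noisy at the
boundaries, and a model with stochastic boundary misclassification would
show the same structure with noise on top.

What the generator does **not** emulate: physiologically realistic
accelerometer waveforms, circadian dynamics (two-process regulation,
sleep pressure), naps, off-wrist gaps, or device artefacts. Passing
tests therefore demonstrate that the pipeline recovers what this model
encodes — schedules, durations, regularity structure — not that the
scoring algorithm would agree with polysomnography on real recordings.

All randomness flows from one master seed through per-athlete
substreams (`numpy` `SeedSequence.spawn`), so cohorts are bit-reproducible
and regenerating a subset of athletes reproduces identical data.

## Numerical choices and degenerate inputs

* Ties at the scoring threshold are sleep; epochs are half-open.
* Sampling tails are clipped to plausible ranges (bedtime 20:00–06:00,
  nightly TST 4–14 h, latency ≤ 120 min), and diary windows are kept
  under 18 h by trimming WASO, then TST; configurations whose *expected*
  window reaches 18 h are rejected at construction.
* Quantiles/IQRs: type-7 everywhere (numpy default).
* A night with no sleep-scored epoch is invalid — excluded from
  aggregates and logged; a window not fully covered by the timeline
  raises.
* Athletes spanning fewer than 7 days are excluded from profiles (the
  SRI is undefined for them), also logged.

## Problem sizes in the test suite

The heavier checks run at the scale the analysis targets: 200-athlete,
14-night cohorts for the jitter sweep (SDs 0/30/60/120 min), ten seeded
200-athlete cohorts for the importance-ranking check, a 200-athlete mixed
low/high-jitter cohort for classification, 10,000 randomised nights for
the per-night invariants, and 1,000 random schedules for the SRI oracle
equivalence. The full suite completes in well under a minute on one core
apart from the cohort-level recovery test, which dominates at roughly
half a minute.

## Known limitations

* Naps and WASO are absent from the state vector by design; regularity
  of nappers is overstated.
* The MAD and night-to-night variation operate on the noon-referenced
  axis linearly; sleep episodes centred near noon would wrap. Night-time
  sleep never approaches this.
* The Wilcoxon exact branch requires both groups ≤ 8 and no ties; with
  ties, small-sample p values rely on the corrected normal approximation.
* The importance score (scaled |t|) inherits OLS assumptions; it is a
  ranking device, not an inferential quantity.
* Synthetic profiles are more collinear than real cohorts (see above),
  so VIF removal sets on synthetic data are larger than one should
  expect on real data.
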