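# Methods

This note documents the statistical machinery, the generative model behind
the synthetic streams, the numerical conventions, and the design choices
that were genuinely open.

## Problem setting

A clinical risk model scores inpatients continuously, but ground-truth
outcomes (did the patient receive the consult? deteriorate?) are not fed
back. Monitoring is therefore *label-free*: the observable quantities are
the input feature distributions, their missingness, the predicted
probability distribution, and the daily call volume. Performance loss can
only be inferred — a shift in the score distribution is its earliest proxy,
and feature drift is its differential diagnosis.

All comparisons are made against a frozen **training reference**. The unit
of analysis is the calendar day; intra-day batches are pooled per day. Date
gaps are never imputed: an absent day is itself a signal (outage), and the
volume monitor reports it.

## Window statistics

The trailing window (default 14 days — long enough to reveal gradual
movement, short enough to audit in minutes) is pooled across days and
compared to the reference:

* **Standardized difference** `d = (m1 - m2) / sqrt((s1² + s2²)/2)` with
  sample variances for continuous features and Bernoulli variances
  `p(1-p)` for binary ones. Signed; 0 when both variances vanish with equal
  means; ±∞ when means differ with no variance (a degenerate case that is
  reported, not raised).
* **Kolmogorov–Smirnov** for continuous features. The p-value is exact for
  small samples and asymptotic (effective n = n₁n₂/(n₁+n₂)) at production
  window sizes, where the two regimes agree to the third decimal. Pooled
  per-call scores are serially dependent in real deployments (the same
  patient is scored repeatedly); the test is computed per call regardless,
  and its p-values should be read as descriptive ranking devices, not
  literal error rates — this is a known caveat of the design.
* **Pearson chi-square** (2×2 presence table, no continuity correction,
  df = 1) for binary features. A zero margin yields (0, 1) with a
  degenerate flag.

No multiple-testing correction is applied across the feature table: the
table is an investigation surface, ranked by model importance (gradient-
boosting relative influence) and effect size. Under control, about
`alpha × n_features` rows are significant by chance; the escalation policy
(below) accounts for this.

## Phase-I rank control charts

Each feature's full post-deployment history is charted retrospectively
against the baseline, in the distribution-free Phase-I tradition: many
clinical labs are highly skewed and heavily tied, so normal-theory charts
are unusable. Construction, per feature:

1. Pool the reference sample with all daily groups (days with < 2 usable
   values are dropped) and assign midranks.
2. **Level score** = the midrank itself; **scale score** = the Mood
   dispersion score `(R_i - (N+1)/2)²`. Both are functions of ranks alone,
   so the level chart is invariant under any strictly increasing transform
   and the scale chart under location shifts — bit-identical at a fixed
   seed, not merely approximately.
3. Per-day statistic: the day's mean score, centered at the pooled mean and
   studentized by the day's *within-group* score variance, shrunk toward
   the pooled variance with 5 pseudo-observations and finite-population
   corrected. Studentizing by the within-group variance (rather than the
   pooled variance) keeps the level chart quiet when only a day's
   dispersion changes; the shrinkage keeps the statistic finite for
   zero-variance days (e.g. a day whose values are all missing → all-equal
   indicators), which are exactly the days that must flag hard.
4. Chart statistic = max over days of |statistic|. Its p-value comes from
   `n_permutations` (default 2000) random permutations of the pooled scores
   across the reference block and the day groups, with the add-one
   estimator `(b+1)/(B+1)`. Because the permutation distribution is that of
   the exact same statistic, the p-value is finite-sample valid under
   exchangeability for *any* choice of statistic — the studentization
   affects power and robustness, never validity. The chart is red when
   p < alpha; the displayed control limit is the (1 − FAP) permutation
   quantile of the null maximum. With alpha = FAP = 0.05 the two coincide.
5. The reference block participates in pooling and permutation but is never
   a flaggable group: the baseline is the yardstick, not a suspect.

Missingness is charted with identical machinery on per-call 0/1 indicators.
Degenerate cases are explicit, never silent: too little data yields an
`insufficient_data` result (p = NaN, green), zero variation (e.g. a feature
never missing anywhere) yields `no_variation` (p = 1, green).

Measured operating characteristics (reproduced by the test suite and
`scripts/acceptance.py`): null red-flag rates within [0.03, 0.07] at
FAP 0.05 on skewed data; an SD×3 dispersion burst is caught by the scale
chart essentially always while the level chart stays green; a +2 SD day is
caught by the level chart essentially always. On heavily tied 0/1 data the
permutation p-values are conservative (discreteness), which errs in the
safe direction for missingness charts.

## Volume, trend, and label-gated performance

* **Volume**: a day is anomalous when its count is 0, when the date is
  absent entirely, or when the count leaves the median ± 5·MAD band of the
  window's counts. The MAD band is robust to bursty census streams; 5 MADs
  ≈ 3.4 SD for Poisson-like counts, so in-control fortnights are quiet.
* **Trend**: OLS of daily mean predicted probability on integer days since
  deployment (mean by default; median available), two-sided slope test and
  95% CI, requiring ≥ 30 days. This catches slow score inflation that the
  14-day window is blind to.
* **Outcome metrics** (only when an outcome feed exists): AUROC (rank
  formula, ties at half credit), AUPRC (step integration), logistic
  recalibration of logit(p) (intercept 0 / slope 1 = calibrated), and
  outcome prevalence as the prior-probability-shift tracker. Absent labels,
  prior-probability shift is only indirectly visible through the score
  distribution.

## Triage and retraining policy

Findings are classified into four categories: *technical infrastructure*
(pipeline errors, volume anomalies, stale scores, interface changes),
*performance loss* (probability-distribution shift — the label-free proxy),
and *explained* vs *unexplained shift* (covariate/missingness shift with or
without an identified root cause). The protocol stage is the maximum over
per-finding stages — monotone by construction, so new evidence can never
lower the alert level:

| stage | color  | trigger                                            | action              |
|-------|--------|----------------------------------------------------|---------------------|
| 1     | blue   | nothing actionable                                 | none                |
| 2     | green  | interface/layout change                            | notify              |
| 3     | yellow | stale scores; escalating performance loss or unexplained shift | use with discretion |
| 4     | red    | unusable output: wholly-absent covariate, pipeline failure | suspend use |

**Escalation vs flagging.** Per-feature flags are deliberately uncorrected
(alpha per table row, FAP per chart), so an in-control dashboard shows a
few reds by chance. A finding moves the protocol stage only if it is
*escalating*: Bonferroni-significant within its tab (p < alpha/n for the
feature table, p < alpha/(2·n_features) for a chart grid). The probability
monitor is a single designed test and escalates at alpha. How much drift
warrants action is ultimately a team judgment; every threshold here
(alpha, FAP, staleness ≥ 1 day, sustained days, importance cutoff) is a
config field so that judgment is declarative. Stage-banner wording is this
package's own (plain-text templates with named placeholders).

Retraining advice follows three rules in order: never retrain while open
infrastructure findings exist (fix upstream first — a pipeline fix usually
dissolves the apparent shift); retrain when performance loss persists for
≥ `sustained_days` (default 14); treat shifts confined to features ranked
below the importance cutoff as nuisance drift.

## Synthetic streams

The generator is the package's study population — a ~400× scale-down of a
large deployment (126 features, ~80k calls/day) to desk size:

* defaults: 12 continuous + 8 binary features, 1000 training records,
  Poisson(200) calls/day, 60 days;
* continuous features alternate log-normal and gamma families with a skew
  profile cycling from mild to heavy (σ = 0.3…1.3 / shape 8…1) — clinical
  labs are right-skewed, and the rank charts are tested on exactly that;
* binary prevalences spread over [0.05, 0.5]; base missingness 5% per
  feature;
* scores come from a toy logistic model on the first 3 continuous + 2
  binary features (standardized, missing → 0, i.e. mean imputation), with
  intercept −3.5 so the mean predicted probability stays below 0.1 —
  probabilities cluster near zero, as they do when most patients are not
  high-risk. The log-scale display therefore floors probabilities at 1e−4.

Seed discipline: every (day, feature) pair draws from its own
counter-derived substream of the master seed. Injections therefore have
*exact* locality — a feature not targeted by any injection draws values
bit-identical to the null stream — which turns the locality invariant into
an equality test rather than a statistical one.

Injectable failure modes: `mean_shift` (SD units, optional linear ramp),
`scale_shift` (SD multiplier), `missingness_ramp` (base → target
proportion), `code_change` (feature fully missing — the unmapped-lab-code
incident), `prevalence_shift`, `outage` (zero-call days), score
`mean_shift` on the probabilities (linear ramp = score inflation with a
configurable slope), and `concept_shift` (coefficient perturbation: every
marginal stays put while the score distribution moves — the defining
signature of a changed input–outcome relationship). A scenario library
packages these as named (config, injections) pairs, and a YAML incident log
maps dated real-world failure modes onto expected categories and stages for
integration tests.

What the generator does **not** model: repeat-patient serial correlation
(calls are i.i.d. within and across days), realistic per-analyte lab
distributions, within-day batching, and correlated multi-feature failures.
Passing tests therefore demonstrate correctness of the statistics and the
policy engine under the stated generative law, not performance on any real
EHR stream; in particular, real pooled-window p-values will be
anti-conservative under serial dependence (see the KS caveat above).

## Numerical conventions and problem sizes

* Missing = empty CSV field = NaN internally; never a sentinel value.
* CSV I/O uses `float_precision="round_trip"` parsing so save/load is
  bit-exact, which the determinism guarantees depend on.
* Ties get midranks throughout. Permutation p-values use (b+1)/(B+1) with a
  1e-12 comparison tolerance on the observed maximum.
* All randomness flows from explicit integer seeds; chart seeds are derived
  from the config seed and the feature name via CRC-32 + SeedSequence, kept
  below 2³¹. Identical inputs + seed ⇒ byte-identical CSV/JSON artifacts
  (the run manifest's wall-clock timestamp is the single volatile field).
* Calibration and power checks in the test suite run at reference n = 1000,
  30 daily groups of n = 100, 1000 permutations, and 200–500 replicates;
  trend-recovery simulations use a trimmed 6-feature, 50-calls/day
  configuration over 365 days — sizes chosen so the whole suite runs on one
  CPU in minutes while keeping Monte-Carlo error well inside the asserted
  bands.

## Known limitations

* Phase-I only: the charts judge a completed history; no CUSUM/EWMA-style
  sequential (Phase-II) monitoring, and no changepoint localization beyond
  the per-day statistics.
* Univariate per feature: correlated multi-feature drift is seen only
  feature by feature.
* The concept-shift injection is detectable label-free only through the
  score distribution; true concept drift detection requires outcomes, which
  the label-gated metrics cover when present.
* The chi-square presence test treats binary features only; multi-level
  categorical features must be catalogued as sets of indicators.
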