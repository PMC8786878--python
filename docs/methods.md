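# Methods

This note documents the models and procedures implemented in `riskaudit`,
the parameters that matter, what the synthetic cohorts do and do not
emulate, and the numerical choices made where the design was open.

## 1. The audit

The package audits a binary in-hospital-mortality (IHM) risk model in
three stages — internal validation on the development cohort, external
validation of the same fitted model on an independent cohort, and internal
validation after retraining on the external cohort. By default stages 2
and 3 score the *same* held-out partition of the external cohort (seeded
80/20 split) so their numbers are directly comparable; with
`external_full_test=True` stage 2 scores the entire external cohort
instead, the natural protocol when the external dataset arrives without a
designated split. Stage 1 uses a seeded 85/15 split of the development
cohort. Each stage runs cohort profiling, performance evaluation and
fairness evaluation, and assembles everything into one JSON-serializable
report. Every stochastic block consumes a child seed derived by hashing
the master seed with the stage and block names, so disabling one block
never changes the numbers of another, and identical configurations are
byte-identical (timestamps aside).

## 2. Eligibility screening

A stay is eligible when: age ≥ 18 years; its hospital admission contains
no other ICU stay (transfer/readmission ambiguity); length of stay
*strictly* greater than 48 h ("more than 48 hours" is read as a strict
inequality, so a 48.0-h stay is excluded); and at least one physiological
observation falls inside the 48-h analysis window. Exclusion predicates
are evaluated on the input cohort, and each excluded stay is counted under
the first rule it violates in the fixed order age → multi-stay → LOS →
observations, making the per-rule counts unambiguous. The stays schema
carries an explicit `admission_id` because the multi-stay rule is keyed on
admissions, not patients: a patient may legitimately contribute several
stays through separate admissions.

## 3. Performance metrics

* **AUROC** — Mann–Whitney form: the probability that a uniformly random
  decedent outranks a uniformly random survivor, cross-label score ties
  counted ½.
* **AUPRC** — step-wise average precision (no trapezoidal interpolation):
  the mean over decedents, ranked by descending score, of the precision at
  each decedent's rank. Tied scores form one rank block and every decedent
  in the block is credited the block-level precision (cumulative TP over
  cumulative count at the block end); this makes the statistic invariant
  to the arbitrary ordering of equal scores. Its chance level is the
  event rate, which is why it is reported alongside AUROC under class
  imbalance.
* **Threshold metrics** — accuracy and per-class precision/recall with
  `score ≥ threshold` predicting the event (default threshold 0.5).
  Empty-denominator ratios (e.g. event precision when nothing is predicted
  positive) are returned as flagged-undefined, never as 0 — silently
  zeroing them is exactly how imbalance artifacts hide.

**Bootstrap.** Confidence intervals are empirical percentile intervals
(α = 0.05) over K = 10,000 joint n-out-of-n resamples of (score, label)
pairs; the resampling unit is the ICU stay. Internally a resample is
represented by its multinomial count vector over the score-sorted sample,
which reduces every metric — including the two ranking metrics with their
tie blocks — to cumulative sums and dot products, so no per-resample
sorting is needed; this representation is distributionally identical to
index resampling. Resamples on which a requested metric is undefined
(single-class draws) are redrawn and the redraw count is recorded on the
estimate. When several metrics are requested together they are evaluated
on shared resamples, so all intervals describe one resample population.
An exhaustive mode enumerates all n^n ordered resamples for n ≤ 8, used
to verify the percentile machinery against full enumeration.

## 4. Calibration

**Exponential-quantile risk groups.** Equal-count deciles waste nine of
ten bins on the low-risk bulk of a skewed score distribution. The bin
edges are therefore placed at the empirical quantiles (linear
interpolation between order statistics, the common "type 7" rule) of the
transformed levels f(i/10) = (i/10)^e with exponent e = 1/5 by default;
with uniform scores the first interior edge already sits at the 63rd
percentile, so most bins resolve the high-risk tail. The exponent should
be adapted to the skew of the data at hand; e = 1 recovers plain deciles.
Bins are half-open [lo, hi) with the last bin closed. Duplicate edges
from heavily tied scores and empty bins are merged leftward (the first bin
merges rightward if empty), with every merge logged; merging preserves the
partition of the sample.

**Wilson intervals.** Each bin's observed event proportion carries the
closed-form Wilson score interval, exact 0/1 at the k = 0 / k = n
boundaries. Within-bin score heterogeneity makes the binomial variance an
upper bound, so bin coverage is, if anything, slightly conservative.

**LOWESS.** The grouping-free overlay is locally weighted linear
regression with the tricube kernel over the k = ⌈span·n⌉ nearest
neighbours (span 0.5 by default) and zero robustness iterations —
calibration residuals are Bernoulli, not outlier-contaminated, so the
robust reweighting passes would only cost time. It is fitted to the raw
(score, outcome) pairs, not to bin summaries, and evaluated on an
equally spaced 100-point grid across the observed score range (sorted
unique x when called directly). Degenerate windows (no x spread) fall
back to the weighted mean. The implementation is in-package because the
contract above is pinned precisely; the statsmodels implementation serves
as an independent cross-check in the test suite.

## 5. Fairness

**Classification parity.** Per level of gender, ethnicity and insurance:
bootstrap AUROC/AUPRC (resampling within the level, level-specific child
seeds). Because both metrics are functions of the group event rate, a
performance gap between two levels is attributed to unfair predictions
only in two scenarios where imbalance cannot be the explanation:

1. the levels' event rates differ by at most 1 percentage point
   (configurable tolerance), or
2. the rate ordering is the *converse* of the performance ordering — the
   group whose higher event rate should disadvantage it nevertheless
   scores higher.

In either scenario, disjoint 95% intervals yield `parity_violation`
(interval disjointness operationalizes "distinctively worse" without
inventing a formal two-sample test the audit design never specified).
Disjoint intervals outside both scenarios are `imbalance_confounded`;
overlapping intervals are `no_material_difference`. Levels with fewer
than two stays or one outcome class are reported not-assessable. Note
that scenario 2 deliberately encodes higher-event-rate-should-hurt for
both metrics; for AUPRC the baseline argument could be made in the other
direction, but a single consistent rule keeps verdicts interpretable and
anti-symmetric in the pair.

**Calibration-in-the-large.** Per level: the relative difference
(mean predicted − observed rate)/observed rate, negative when the model
underestimates the group's risk, with the percentile interval of the
per-resample relative differences. Levels with zero observed events are
flagged, never divided. The n-weighted recombination of per-level means
reproduces the whole-cohort relative difference exactly (tested to 1e-9).

**Charlson comorbidity index.** An integer burden score: the weighted sum
over *distinct* comorbidity factors present within a 730-day lookback
before admission; multiple codes mapping to one factor count once, and
unmapped codes are counted but ignored. The bundled code table is
synthetic — 12 factors with weights (1,1,1,1,1,1,2,2,2,3,6,6) and
placeholder codes — because classic Charlson formulations enumerate 17–19
conditions and no canonical 12-factor ICD mapping exists; real audits
supply their own mapping.

**Comorbidity–risk curves.** Score percentiles are ranked on the pooled
test cohort (not within group) so all groups share one x-axis; each
level's curve is the mean Charlson score of its stays within ±5
percentile points of each grid point 1..100, with windows under 10 stays
flagged sparse. The block is produced only for cohorts carrying diagnosis
data (ICU-only databases cannot support lookback comorbidity scoring).

## 6. The synthetic cohorts

The generator emulates the statistical skeleton the audit assumes, with
two bundled presets: a development-style cohort (pooled IHM 13.23%,
mostly White, Medicare-heavy, 15% of patients contributing two stays) and
an external-style cohort (pooled IHM 10.18%, more diverse, 5% multi-stay,
with diagnosis codes). Components:

* **Demographics** sampled independently per *patient* from the published
  patient-share marginals of the two cohorts (gender, five ethnicity
  levels, four insurance levels, five adult age bands); multi-stay
  patients share their demographics across stays, each stay being its own
  admission. Independence is a deliberate simplification — only marginals
  are published — and a joint probability table can be supplied to
  override it.
* **Outcome**: label ~ Bernoulli(invlogit(intercept + Σ offsets)), with
  per-level offsets set to the log-odds difference between the level's
  published mortality rate and the pooled rate, and the intercept solved
  by root-finding over the exact cell enumeration so the implied pooled
  rate equals the published pooled rate (a plain logit(rate) intercept is
  off by a Jensen gap under additive offsets). The per-stay latent "true
  risk" is this probability; cohorts are calibrated by construction. The
  latent risk lives only on the in-memory object and is excluded from all
  file schemas.
* **Scores**: `emit_predictions` returns
  invlogit(logit(true risk) + shift(group) + N(0, sd(group))) — the
  identity when all shifts and noise are zero — so known miscalibration
  and discrimination degradation can be injected per demographic level
  and recovered downstream.
* **Observations**: per variable, a stay is entirely missing the variable
  with probability `p_none`; otherwise each of the 48 hour buckets holds
  an observation independently with probability `p_hour`, with one
  observation forced into a uniformly random hour if every draw lands
  empty (a stay that measures a variable at all has at least one value).
  `p_none` is the published per-variable "no data" share and `p_hour`
  solves 48q + (1−q)^48 = published mean covered hours / (1−p_none), so
  both statistics are matched in expectation. Values are Gaussian with
  fixed plausible means/SDs and feed no audit statistic.
* **Diagnoses**: each of the 12 synthetic Charlson factors is present with
  probability invlogit(logit(prevalence) + association·(η − intercept)),
  η the stay's outcome log-odds, so comorbidity burden rises with risk;
  present factors emit one of two codes dated uniformly within 730 days,
  plus a 3% rate of unmapped codes to exercise the unmapped counter.

**What is not emulated** — and hence what passing tests do not show about
real data: correlations between demographic attributes; within-patient
outcome correlation; serial correlation of observation hours (the
published "full coverage" share is therefore *not* reproduced — hourly
coverage is i.i.d. given presence); physiological signal in the
observation values (the bundled predictor's discrimination, AUROC ≈ 0.63
at development scale, comes from demographics alone and is deliberately
below what a sequence model achieves on real data); and real ICD coding
practice.

**Determinism.** One master seed; every component (demographics, labels,
lengths of stay, observations, diagnoses, scores) draws from its own
child generator with a fixed spawn key, and level/factor iteration orders
are canonicalized, so identical (config, seed) pairs are byte-identical
on disk — including after a YAML round-trip of the configuration.

## 7. The baseline predictor

A binomial GLM (IRLS, statsmodels) on dummy-coded demographics and age
band plus, per catalog variable, an indicator of being observed at all in
the window, plus the pooled fraction of variable-hours covered. Indicator
coding, rather than raw per-variable coverage fractions, keeps the design
well-conditioned: a variable nearly unmeasured in the development cohort
but routinely measured externally would otherwise carry a noise-fitted
coefficient that explodes the external linear predictor. The model is a
deterministic stand-in for whatever model is under audit — anything with
`fit`/`score` plugs in via the `Predictor` protocol.

## 8. Validation studies and problem sizes

The test suite validates the statistics against independent oracles
(pair-count AUROC, rank-enumeration AUPRC, exhaustive bootstrap
enumeration at n = 3, hand-solved weighted least squares for LOWESS,
scikit-learn and statsmodels cross-checks) and runs two replicate
operating-characteristic studies: a −0.5 log-odds score shift on one
gender recovered by calibration-in-the-large (100 replicates, 20,000
stays per group, K = 1,000), and equal-rate score-noise injection
(SD 2.0) flagged by the parity verdicts (100 replicates, 10,000 stays per
group, K = 200) with the false-flag rate measured across all pairwise
findings on untouched attributes. Injection studies put all outcome
heterogeneity on age — independent of the audited attributes — so any
systematic group difference is attributable to the injection alone, and
they skip observation generation, which no fairness statistic reads.

Two multiplicity conventions are fixed in the calibrated-cohort audit
test: of the ten simultaneous 95% Wilson bin intervals, at least eight
must cover; of the eleven simultaneous 95% group CITL intervals, at most
one may exclude zero. Both allowances are the binomial 95%-coverage
arithmetic — demanding all intervals cover simultaneously would fail a
perfectly calibrated model roughly half the time.

The acceptance script runs the full three-stage audit at 12,000 + 6,000
stays with K = 2,000 — sizes chosen so the smallest demographic level in
a stage-2/3 test partition still holds on the order of a hundred stays
while the whole script stays desk-scale.

## 9. Known limitations

* Parity verdicts at small per-level sample sizes are noisy: percentile
  intervals of AUPRC in levels with a handful of events can be
  erratically narrow, occasionally producing spurious disjointness.
* The percentile bootstrap has no second-order correction; for extreme
  event rates a BCa interval would be preferable.
* The generator's independence assumptions (section 6) mean cross-
  attribute confounding — a central difficulty in real fairness audits —
  is absent unless a joint table is supplied.
* The Charlson table is synthetic; results involving comorbidity are
  structural demonstrations, not clinically interpretable burdens.
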