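# riskaudit

Fairness and generalizability auditing for binary clinical risk-prediction
models, with a synthetic ICU cohort generator so the whole pipeline runs
without access to restricted EHR data.

## The problem

Risk models for in-hospital mortality (IHM) in the ICU are usually trained
and reported on a single dataset, with performance summarized by accuracy
or AUROC alone. Under the heavy class imbalance typical of mortality
prediction (event rates of 10–13%), those summaries hide two failure modes
that matter clinically:

* **class-imbalance artifacts** — a model that never predicts the minority
  class can still post ~0.9 accuracy (the accuracy paradox), and AUROC/AUPRC
  comparisons between demographic groups are confounded by their differing
  event rates;
* **masked unfairness** — a model can be well calibrated and discriminative
  overall while systematically under-serving specific ethnic or
  socioeconomic groups.

`riskaudit` implements a three-stage audit: **(1)** internal validation on
the development cohort, **(2)** external validation of the same fitted
model on an independent cohort, and **(3)** internal validation after
retraining on the external cohort. Each stage runs three tasks:
cohort profiling (demographics/outcome table, per-variable missingness),
performance evaluation, and fairness evaluation, all assembled into a
machine-readable report.

## The statistics at the core

* **Discrimination with bootstrap intervals.** AUROC as the Mann–Whitney
  statistic (ties ½), AUPRC as step-wise average precision with tie-block
  handling, accuracy and per-class precision/recall at a risk threshold
  (default 0.5, with empty-denominator ratios *flagged*, never reported as
  zero). Confidence intervals are percentile intervals over K = 10,000
  joint (score, label) resamples.
* **Calibration with exponential-quantile risk groups.** Validation-plot
  bins are cut at the empirical quantiles of levels f(q) = q^(1/5)
  (exponent configurable), concentrating resolution in the sparse
  high-risk tail; each bin carries a Wilson score interval for its
  observed event proportion, with a LOWESS smooth (tricube kernel, span
  0.5) of outcome on score as a grouping-free overlay.
* **Classification parity with imbalance-aware verdicts.** Per-group
  AUROC/AUPRC gaps are attributed to unfair predictions only when event
  rates are materially similar (within 1 percentage point) or when the
  rate ordering is the converse of the performance ordering — otherwise a
  disjoint-interval gap is labelled `imbalance_confounded`.
* **Calibration-in-the-large per group**: the relative difference
  (mean predicted − observed)/observed with a bootstrap interval;
  intervals covering zero are consistent with calibration.
* **Comorbidity–risk curves**: mean Charlson comorbidity score (12
  weighted factors, two-year lookback) per demographic group within a
  ±5-point sliding window of pooled risk-score percentiles.

The synthetic generator emulates the published structure of two real ICU
cohorts — demographic marginals, group-specific mortality rates under an
additive logistic model, per-variable 48-hour observation missingness, and
outcome-correlated comorbidity codes — and can *inject* known biases
(group-specific score shifts and noise) that the fairness statistics must
recover. See `docs/methods.md` for the model and its limits.

## Worked example

```bash
riskaudit generate --preset starr-like --n-stays 1200 --seed 5 \
    --output-dir cohort --emit-scores
riskaudit evaluate --cohort-dir cohort --predictions cohort/predictions.csv \
    --bootstrap-k 2000 --seed 5 --output-dir eval-out
```

prints (scores here come from the generator's own score model, which equals
the latent risk, so the model is calibrated by construction):

```
precision_event: undefined at threshold 0.5 (flagged, not reported)
auroc: 0.611 (0.554, 0.668)
auprc: 0.153 (0.116, 0.211)
accuracy: 0.905 (0.889, 0.922)
precision_nonevent: 0.905 (0.889, 0.922)
recall_event: 0.000 (0.000, 0.000)
recall_nonevent: 1.000 (1.000, 1.000)
```

Read: the model ranks decedents above survivors about 61% of the time;
AUPRC (0.15) should be judged against its chance level, the ~10% event
rate, not against 1; accuracy 0.905 is *entirely* the majority class — at
the 0.5 threshold the model identifies no deaths at all (event recall 0),
so event precision is undefined and comes back flagged rather than as a
silent zero. This is the accuracy paradox the audit is designed to
surface.

The numbered scripts under `analysis/` run the full study: simulate both
cohorts, profile them, run the three-stage audit, and measure the fairness
statistics' operating characteristics under injected bias. Tables land in
`results/`, large cohort files in `scratch/`.

```bash
python analysis/01_simulate_cohorts.py --seed 7
python analysis/02_profile_cohorts.py
python analysis/03_run_audit.py --seed 7
python analysis/04_bias_recovery.py --seed 7
```

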