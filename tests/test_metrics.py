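"""Discrimination metrics and the bootstrap against independent oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from riskaudit import (
    BootstrapConfig,
    MetricConfig,
    UndefinedMetricError,
    auprc,
    auroc,
    bootstrap_ci,
    bootstrap_cis,
    threshold_metrics,
)

# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def pair_count_auroc(scores, labels):
    """Enumerate every positive-negative pair; ties count one half."""
    s = np.asarray(scores, dtype=float)
    l = np.asarray(labels)
    pos = s[l == 1]
    neg = s[l == 0]
    total = 0.0
    for p in pos:
        total += (p > neg).sum() + 0.5 * (p == neg).sum()
    return total / (len(pos) * len(neg))


def rank_enum_auprc(scores, labels):
    """Walk distinct score values in descending order accumulating
    block-level precision for each positive."""
    s = np.asarray(scores, dtype=float)
    l = np.asarray(labels, dtype=float)
    total, cumtp, cumn = 0.0, 0.0, 0.0
    for v in np.unique(s)[::-1]:
        m = s == v
        cumtp += l[m].sum()
        cumn += m.sum()
        total += l[m].sum() * (cumtp / cumn)
    return total / l.sum()


# ---------------------------------------------------------------------------
# point metrics
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "scores, labels, expected",
    [
        ([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 1.0),  # perfect separation
        ([0.9, 0.8, 0.7, 0.3], [1, 0, 1, 0], 0.75),  # 3 of 4 pairs ordered
        ([0.5, 0.5, 0.5, 0.5], [1, 0, 1, 0], 0.5),  # all ties -> chance
    ],
)
def test_auroc_examples(scores, labels, expected):
    assert auroc(scores, labels) == pytest.approx(expected)


@pytest.mark.parametrize(
    "scores, labels, expected",
    [
        ([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0], 1.0),
        ([0.9, 0.8, 0.7, 0.3], [1, 0, 1, 0], (1.0 + 2.0 / 3.0) / 2.0),
    ],
)
def test_auprc_examples(scores, labels, expected):
    assert auprc(scores, labels) == pytest.approx(expected)


def test_single_class_labels_are_rejected():
    with pytest.raises(UndefinedMetricError):
        auroc([0.1, 0.2], [1, 1])
    with pytest.raises(UndefinedMetricError):
        auprc([0.1, 0.2], [0, 0])
    with pytest.raises(UndefinedMetricError):
        threshold_metrics([0.1, 0.2], [0, 0])


@settings(max_examples=120, derandomize=True, deadline=None)
@given(
    n=st.integers(2, 50),
    seed=st.integers(0, 10_000),
    tie_scale=st.sampled_from([None, 4, 10]),
)
def test_ranking_metrics_match_bruteforce_oracles(n, seed, tie_scale):
    """AUROC equals the pair-count oracle and AUPRC the rank-enumeration
    oracle on arbitrary small inputs, including heavily tied scores."""
    rng = np.random.default_rng(seed)
    scores = rng.random(n)
    if tie_scale is not None:
        scores = np.round(scores * tie_scale) / tie_scale
    labels = rng.integers(0, 2, n)
    if labels.min() == labels.max():
        labels[0] = 1 - labels[0]
    assert auroc(scores, labels) == pytest.approx(pair_count_auroc(scores, labels), abs=1e-12)
    assert auprc(scores, labels) == pytest.approx(rank_enum_auprc(scores, labels), abs=1e-12)


def test_auroc_complement_identity_for_tie_free_scores(rng):
    scores = rng.random(500)
    labels = rng.integers(0, 2, 500)
    labels[:2] = [0, 1]
    assert auroc(scores, labels) + auroc(scores, 1 - labels) == pytest.approx(1.0)


def test_ranking_metrics_invariant_under_monotone_transform(rng):
    scores = rng.random(300)
    labels = rng.integers(0, 2, 300)
    labels[:2] = [0, 1]
    warped = 1.0 / (1.0 + np.exp(-(5.0 * scores - 2.0)))  # strictly increasing
    assert auroc(scores, labels) == pytest.approx(auroc(warped, labels), abs=1e-12)
    assert auprc(scores, labels) == pytest.approx(auprc(warped, labels), abs=1e-12)


def test_score_equal_to_label_gives_perfect_auprc():
    labels = np.array([0, 1, 0, 1, 1, 0])
    assert auprc(labels.astype(float), labels) == pytest.approx(1.0)


def test_agreement_with_sklearn_on_tie_free_inputs(rng):
    from sklearn.metrics import average_precision_score, roc_auc_score

    scores = rng.normal(size=800)
    labels = (rng.random(800) < 0.25).astype(int)
    labels[:2] = [0, 1]
    assert auroc(scores, labels) == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)
    assert auprc(scores, labels) == pytest.approx(
        average_precision_score(labels, scores), abs=1e-12
    )


# ---------------------------------------------------------------------------
# threshold metrics
# ---------------------------------------------------------------------------


def test_threshold_metrics_hand_confusion_matrix():
    # predictions (1,1,0,0) against labels (1,0,1,0): TP=FP=FN=TN=1
    tm = threshold_metrics([0.9, 0.6, 0.4, 0.2], [1, 0, 1, 0], MetricConfig(0.5))
    assert tm.accuracy == pytest.approx(0.5)
    assert tm.precision_event == pytest.approx(0.5)
    assert tm.recall_event == pytest.approx(0.5)
    assert tm.precision_nonevent == pytest.approx(0.5)
    assert tm.recall_nonevent == pytest.approx(0.5)
    assert not tm.undefined


def test_threshold_metrics_perfect_predictions():
    tm = threshold_metrics([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], MetricConfig(0.5))
    assert tm.accuracy == 1.0
    assert tm.precision_event == 1.0 and tm.recall_event == 1.0
    assert tm.precision_nonevent == 1.0 and tm.recall_nonevent == 1.0


def test_accuracy_paradox_flags_undefined_precision():
    """All scores below threshold: accuracy is 1-r yet the model finds no
    events — event precision must come back flagged, never silently 0."""
    labels = np.array([1, 0, 0, 0, 0, 0, 0, 0, 0, 0])
    tm = threshold_metrics(np.full(10, 0.2), labels, MetricConfig(0.5))
    assert tm.accuracy == pytest.approx(0.9)
    assert tm.recall_event == 0.0
    assert tm.precision_event is None
    assert "precision_event" in tm.undefined


def test_score_at_threshold_predicts_event():
    tm = threshold_metrics([0.5, 0.4], [1, 0], MetricConfig(0.5))
    assert tm.accuracy == 1.0


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------


def test_bootstrap_same_seed_same_interval(rng):
    scores = rng.random(300)
    labels = (rng.random(300) < 0.3).astype(int)
    labels[:2] = [0, 1]
    cfg = BootstrapConfig(n_resamples=400, seed=7)
    a = bootstrap_ci("auroc", scores, labels, cfg)
    b = bootstrap_ci("auroc", scores, labels, cfg)
    assert (a.ci_lo, a.ci_hi) == (b.ci_lo, b.ci_hi)
    c = bootstrap_ci("auroc", scores, labels, BootstrapConfig(n_resamples=400, seed=8))
    assert (a.ci_lo, a.ci_hi) != (c.ci_lo, c.ci_hi)


def test_constant_metric_gives_degenerate_interval():
    """Accuracy on perfectly separated data is 1 on every resample."""
    est = bootstrap_ci(
        "accuracy",
        [0.9, 0.8, 0.1, 0.2],
        [1, 1, 0, 0],
        BootstrapConfig(n_resamples=200, seed=0),
    )
    assert est.point == est.ci_lo == est.ci_hi == 1.0
    assert not est.degenerate


def test_exhaustive_bootstrap_matches_independent_enumeration():
    """At n=3 the percentile interval over all 27 ordered resamples must
    equal a from-scratch enumeration (undefined resamples dropped)."""
    scores = np.array([0.2, 0.6, 0.9])
    labels = np.array([0, 1, 1])
    cfg = BootstrapConfig(alpha=0.05, exhaustive=True)
    est = bootstrap_ci("auroc", scores, labels, cfg)

    vals = []
    for idx in itertools.product(range(3), repeat=3):
        l = labels[list(idx)]
        if l.min() == l.max():
            continue  # AUROC undefined on single-class draws
        vals.append(pair_count_auroc(scores[list(idx)], l))
    lo, hi = np.quantile(vals, [0.025, 0.975])
    assert est.k == len(vals)
    assert est.ci_lo == pytest.approx(lo, abs=1e-12)
    assert est.ci_hi == pytest.approx(hi, abs=1e-12)


def test_bootstrap_redraws_are_counted():
    """With a single positive among 6 points, many resamples miss the
    positive class; they must be redrawn and logged, not dropped."""
    scores = np.array([0.9, 0.1, 0.2, 0.3, 0.4, 0.5])
    labels = np.array([1, 0, 0, 0, 0, 0])
    est = bootstrap_ci("auroc", scores, labels, BootstrapConfig(n_resamples=300, seed=1))
    assert est.k == 300
    assert est.n_redraws > 0


def test_custom_callable_metric_agrees_with_named_kernel(rng):
    scores = rng.random(80)
    labels = (rng.random(80) < 0.4).astype(int)
    labels[:2] = [0, 1]
    cfg = BootstrapConfig(n_resamples=150, seed=3)
    named = bootstrap_ci("event_rate", scores, labels, cfg)
    custom = bootstrap_ci(lambda s, l: float(np.mean(l)), scores, labels, cfg)
    # different resampling representations, same estimand: points identical,
    # intervals statistically indistinguishable
    assert named.point == custom.point
    assert abs(named.ci_lo - custom.ci_lo) < 0.12
    assert abs(named.ci_hi - custom.ci_hi) < 0.12


def test_bootstrap_interval_covers_true_auroc():
    """Coverage simulation: percentile intervals at alpha=0.05 cover the
    population AUROC in at least 90% of replicates."""
    rng = np.random.default_rng(42)
    # population: score ~ U(0,1), P(event | s) = 0.6 s  (event rate 0.3)
    big_s = rng.random(400_000)
    big_l = (rng.random(400_000) < 0.6 * big_s).astype(int)
    true_auroc = auroc(big_s, big_l)

    n, covered, reps = 250, 0, 200
    for rep in range(reps):
        s = rng.random(n)
        l = (rng.random(n) < 0.6 * s).astype(int)
        if l.min() == l.max():
            covered += 1  # degenerate draw, not informative
            continue
        est = bootstrap_ci("auroc", s, l, BootstrapConfig(n_resamples=400, seed=rep))
        covered += int(est.ci_lo <= true_auroc <= est.ci_hi)
    assert covered / reps >= 0.90


def test_shared_resample_estimates_report_joint_redraws(rng):
    scores = rng.random(60)
    labels = (rng.random(60) < 0.1).astype(int)
    labels[0] = 1
    ests = bootstrap_cis(
        ["auroc", "auprc", "accuracy"], scores, labels, BootstrapConfig(300, seed=5)
    )
    redraws = {e.n_redraws for e in ests.values()}
    assert len(redraws) == 1  # same resample population for all metrics
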