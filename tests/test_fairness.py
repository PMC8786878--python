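"""Classification parity, calibration-in-the-large, Charlson scoring and
comorbidity-risk curves."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from riskaudit import (
    BootstrapConfig,
    CharlsonConfig,
    ConfigurationError,
    calibration_in_the_large,
    charlson_score,
    charlson_scores,
    classification_parity,
    comorbidity_risk_curve,
    emit_predictions,
    generate_cohort,
    synthetic_charlson_config,
)
from riskaudit.experiments import scenario_config

BCFG = BootstrapConfig(n_resamples=300, seed=7)


def _groups(levels, n_per):
    return pd.DataFrame({"site": np.repeat(levels, n_per)})


# ---------------------------------------------------------------------------
# classification parity
# ---------------------------------------------------------------------------


def test_identical_groups_show_no_material_difference(rng):
    s = rng.beta(1.5, 6, 8_000)
    l = (rng.random(8_000) < s).astype(int)
    groups = _groups(["A", "B"], 4_000)  # halves of one iid sample
    _, findings = classification_parity(s, l, groups, BCFG)
    assert findings
    assert all(f.verdict == "no_material_difference" for f in findings)


def test_similar_rates_with_degraded_scores_is_flagged(rng):
    """Scenario 1: equal event rates but one group's scores are noise;
    the performance gap cannot be an imbalance artifact."""
    n = 6_000
    risk = rng.beta(2, 10, 2 * n)
    l = (rng.random(2 * n) < risk).astype(int)
    s = risk.copy()
    s[n:] = rng.permutation(s[n:])  # destroy group B's score-label link
    panels, findings = classification_parity(s, l, _groups(["A", "B"], n), BCFG)
    f = [x for x in findings if x.metric == "auroc"][0]
    assert abs(f.event_rate_gap_pp) <= 1.0
    assert f.scenario == 1
    assert f.verdict == "parity_violation"


def test_converse_rate_ordering_is_flagged(rng):
    """Scenario 2: the group with the *higher* event rate also scores
    higher on both metrics — imbalance would predict the opposite."""
    n = 6_000
    risk_a = rng.beta(2, 10, n)  # rate ~17%
    s_a = np.clip(risk_a + 0.25 * (rng.random(n) < risk_a), 0, 1)  # sharp scores
    l_a = (rng.random(n) < risk_a).astype(int)
    risk_b = rng.beta(1, 10, n)  # rate ~9%
    s_b = rng.permutation(risk_b)  # uninformative scores
    l_b = (rng.random(n) < risk_b).astype(int)
    s = np.r_[s_a, s_b]
    l = np.r_[l_a, l_b]
    _, findings = classification_parity(s, l, _groups(["A", "B"], n), BCFG)
    f = [x for x in findings if x.metric == "auroc"][0]
    assert f.event_rate_gap_pp > 1.0
    assert f.scenario == 2
    assert f.verdict == "parity_violation"


def test_rate_explained_gap_is_confounded_not_violation(rng):
    """The group with the markedly higher event rate performs worse: the
    gap runs in the direction class imbalance explains, so disjoint
    intervals must not be read as bias."""
    n = 8_000
    risk_a = rng.beta(3, 7, n)  # rate ~30%
    s_a = rng.permutation(risk_a)  # uninformative scores for the high-rate group
    l_a = (rng.random(n) < risk_a).astype(int)
    risk_b = rng.beta(1, 19, n)  # rate ~5%, calibrated scores
    l_b = (rng.random(n) < risk_b).astype(int)
    s = np.r_[s_a, risk_b]
    l = np.r_[l_a, l_b]
    _, findings = classification_parity(s, l, _groups(["A", "B"], n), BCFG)
    f = [x for x in findings if x.metric == "auroc"][0]
    assert f.event_rate_gap_pp > 1.0
    assert f.ci_disjoint
    assert f.scenario is None
    assert f.verdict == "imbalance_confounded"


def test_parity_verdicts_invariant_under_level_relabeling(rng):
    n = 5_000
    risk = rng.beta(2, 10, 2 * n)
    l = (rng.random(2 * n) < risk).astype(int)
    s = risk.copy()
    s[n:] = rng.permutation(s[n:])
    g1 = _groups(["A", "B"], n)
    g2 = g1.replace({"A": "B", "B": "A"})
    _, f1 = classification_parity(s, l, g1, BCFG)
    _, f2 = classification_parity(s, l, g2, BCFG)
    v1 = {(f.metric, frozenset((f.level_a, f.level_b))): f.verdict for f in f1}
    v2 = {(f.metric, frozenset((f.level_a, f.level_b))): f.verdict for f in f2}
    assert v1 == v2


def test_tiny_or_single_class_levels_reported_not_assessable(rng):
    s = np.r_[rng.random(200), [0.5], rng.random(50)]
    l = np.r_[(rng.random(200) < 0.3).astype(int), [1], np.zeros(50, dtype=int)]
    groups = pd.DataFrame({"site": ["A"] * 200 + ["B"] + ["C"] * 50})
    panels, findings = classification_parity(s, l, groups, BCFG)
    by = {p.level: p for p in panels}
    assert by["A"].assessable
    assert not by["B"].assessable  # single stay
    assert not by["C"].assessable  # single class
    assert findings == []  # no assessable pair remains


# ---------------------------------------------------------------------------
# calibration-in-the-large
# ---------------------------------------------------------------------------


def test_calibrated_groups_are_consistent_with_zero(rng):
    cfg = scenario_config(30_000, seed=3)
    cohort = generate_cohort(cfg)
    s = emit_predictions(cohort, cfg).to_numpy()
    l = cohort.stays["label"].to_numpy(float)
    ests = calibration_in_the_large(s, l, cohort.stays[["gender"]], BCFG)
    for e in ests:
        assert e.assessable
        assert e.ci_lo <= 0.0 <= e.ci_hi


def test_halved_scores_give_minus_half_relative_difference(rng):
    risk = rng.beta(2, 8, 30_000)
    l = (rng.random(30_000) < risk).astype(int)
    groups = _groups(["A", "B"], 15_000)
    ests = calibration_in_the_large(risk / 2.0, l, groups, BCFG)
    for e in ests:
        assert e.rel_diff == pytest.approx(-0.5, abs=0.05)
        assert e.ci_hi < 0.0


def test_injected_shift_is_pinned_to_the_shifted_group():
    cfg = scenario_config(40_000, seed=4, shift_level=("gender", "Female", -0.5))
    cohort = generate_cohort(cfg)
    s = emit_predictions(cohort, cfg).to_numpy()
    l = cohort.stays["label"].to_numpy(float)
    ests = calibration_in_the_large(
        s, l, cohort.stays[["gender"]], BootstrapConfig(n_resamples=1000, seed=5)
    )
    by = {e.level: e for e in ests}
    assert by["Female"].ci_hi < 0.0
    assert by["Male"].ci_lo <= 0.0 <= by["Male"].ci_hi


def test_zero_event_level_is_flagged_not_divided(rng):
    s = rng.random(120)
    l = np.r_[np.zeros(60, dtype=int), (rng.random(60) < 0.5).astype(int)]
    l[60] = 1
    ests = calibration_in_the_large(s, l, _groups(["empty", "ok"], 60), BCFG)
    by = {e.level: e for e in ests}
    assert not by["empty"].assessable and by["empty"].rel_diff is None
    assert by["ok"].assessable


def test_group_estimates_pool_to_cohort_estimate(rng):
    """n-weighted recombination of the per-level means reproduces the
    whole-cohort relative difference exactly."""
    s = rng.beta(2, 8, 9_000)
    l = (rng.random(9_000) < 0.15).astype(int)
    l[0] = 1
    groups = pd.DataFrame({"site": rng.choice(["A", "B", "C"], 9_000)})
    ests = calibration_in_the_large(s, l, groups, BCFG)
    num = sum(e.n * (e.mean_predicted - e.observed_rate) for e in ests)
    den = sum(e.n * e.observed_rate for e in ests)
    whole = (s.mean() - l.mean()) / l.mean()
    assert num / den == pytest.approx(whole, abs=1e-9)


# ---------------------------------------------------------------------------
# Charlson comorbidity index
# ---------------------------------------------------------------------------

CHARLSON = synthetic_charlson_config()
CODE_OF = {f: f"SYN:{f}:1" for f, _ in CHARLSON.factor_weights.items()}


def test_charlson_empty_and_dedup():
    assert charlson_score([], CHARLSON) == 0
    code = CODE_OF["renal_disease"]  # weight 2
    alt = "SYN:renal_disease:2"
    assert charlson_score([(code, 700), (alt, 10)], CHARLSON) == 2


def test_charlson_lookback_window():
    picks = [
        ("myocardial_infarction", 1, 10),
        ("congestive_heart_failure", 1, 300),
        ("renal_disease", 2, 800),  # outside the 730-day window
        ("metastatic_solid_tumor", 6, 729),
    ]
    dx = [(CODE_OF[f], d) for f, _, d in picks]
    assert charlson_score(dx, CHARLSON) == 1 + 1 + 6


def test_charlson_unmapped_codes_counted_not_fatal():
    dx = [("ICD9:xxx", 5), (CODE_OF["diabetes"], 5)]
    assert charlson_score(dx, CHARLSON) == 1
    from riskaudit import Cohort
    from conftest import make_stay

    cohort = Cohort.from_records([make_stay("s1", diagnoses=tuple(dx))])
    scores, unmapped = charlson_scores(cohort, CHARLSON)
    assert scores.loc["s1"] == 1
    assert unmapped == 1


def test_charlson_monotone_under_added_factors():
    dx = []
    prev = 0
    for factor in CHARLSON.factor_weights:
        dx.append((CODE_OF[factor], 100))
        now = charlson_score(dx, CHARLSON)
        assert now >= prev
        prev = now
    assert prev == sum(CHARLSON.factor_weights.values())


def test_charlson_config_requires_12_factors():
    with pytest.raises(ConfigurationError):
        CharlsonConfig(mapping={"c1": ("f1", 1), "c2": ("f2", 2)})


def test_vectorized_charlson_matches_scalar():
    cfg = scenario_config(300, seed=8)
    from riskaudit.presets import _charlson_gen_model

    cfg.charlson_model = _charlson_gen_model()
    cohort = generate_cohort(cfg)
    series, _ = charlson_scores(cohort, CHARLSON)
    dx = cohort.diagnoses
    for sid in cohort.stays["stay_id"].sample(25, random_state=0):
        rows = dx[dx.stay_id == sid]
        expected = charlson_score(
            list(zip(rows.code, rows.days_before_admission)), CHARLSON
        )
        assert series.loc[sid] == expected


# ---------------------------------------------------------------------------
# comorbidity-risk curves
# ---------------------------------------------------------------------------


def test_constant_charlson_gives_flat_curves(rng):
    s = rng.random(3_000)
    groups = _groups(["A", "B"], 1_500)
    curves = comorbidity_risk_curve(s, np.full(3_000, 3.0), groups)
    for c in curves:
        assert np.allclose(c.mean_charlson[~np.isnan(c.mean_charlson)], 3.0)


def test_positive_dependence_yields_monotone_curve(rng):
    n = 50_000
    s = rng.random(n)
    charlson = rng.binomial(12, 0.1 + 0.6 * s)  # burden rises with risk
    curves = comorbidity_risk_curve(s, charlson, pd.DataFrame({"all": ["x"] * n}))
    curve = curves[0]
    rho, _ = spearmanr(curve.percentiles, curve.mean_charlson)
    assert rho > 0.9


def test_identical_groups_have_matching_curves(rng):
    n = 40_000
    s = rng.random(n)
    charlson = rng.poisson(2.0, n).astype(float)
    curves = comorbidity_risk_curve(s, charlson, _groups(["A", "B"], n // 2))
    a, b = curves[0].mean_charlson, curves[1].mean_charlson
    assert np.nanmax(np.abs(a - b)) < 0.2


def test_sparse_windows_are_flagged(rng):
    s = rng.random(60)
    curves = comorbidity_risk_curve(
        s, np.ones(60), pd.DataFrame({"g": ["A"] * 60}), min_window_n=10
    )
    c = curves[0]
    assert c.sparse.dtype == bool
    assert (c.window_n[c.sparse] < 10).all()
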