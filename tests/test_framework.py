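"""Baseline predictor, stage execution and the three-stage orchestration."""

from __future__ import annotations

import copy
import json

import numpy as np
import pytest
from scipy.special import logit

from riskaudit import (
    BaselinePredictor,
    BootstrapConfig,
    FitError,
    FrameworkConfig,
    generate_cohort,
    mimic_like_config,
    run_framework,
    run_stage,
    starr_like_config,
    synthetic_charlson_config,
    write_json,
    read_json,
)
from riskaudit.experiments import scenario_config
from riskaudit.framework import STAGE_METRICS, _split, cohort_digest

from conftest import light_obs, obs_free

FAST = FrameworkConfig(
    bootstrap=BootstrapConfig(n_resamples=200, seed=3),
    charlson=synthetic_charlson_config(),
    seed=3,
)


# ---------------------------------------------------------------------------
# baseline predictor
# ---------------------------------------------------------------------------


def test_refit_is_deterministic(dev_cohort):
    a = BaselinePredictor(seed=1).fit(dev_cohort)
    b = BaselinePredictor(seed=1).fit(dev_cohort)
    assert np.allclose(a.coef_.to_numpy(), b.coef_.to_numpy())


def test_single_class_training_raises(dev_cohort):
    broken = copy.deepcopy(dev_cohort)
    broken.stays["label"] = 0
    with pytest.raises(FitError):
        BaselinePredictor().fit(broken)


def test_null_demographic_effects_recovered_as_zero():
    """Age-only outcome model: fitted gender/ethnicity/insurance
    coefficients must be statistically indistinguishable from zero."""
    cfg = scenario_config(20_000, seed=21)
    model = BaselinePredictor().fit(generate_cohort(cfg))
    for name in model.coef_.index:
        if name.startswith(("gender[", "ethnicity[", "insurance[")):
            z = model.coef_[name] / model.bse_[name]
            assert abs(z) < 3.5, name


def test_known_offsets_recovered():
    cfg = obs_free(mimic_like_config(n_stays=40_000, seed=22))
    cfg.outcome_model = type(cfg.outcome_model)(
        intercept=float(logit(0.12)), offsets={"gender": {"Female": 0.0, "Male": 0.8}}
    )
    model = BaselinePredictor().fit(generate_cohort(cfg))
    est = model.coef_["gender[Male]"]
    se = model.bse_["gender[Male]"]
    assert est == pytest.approx(0.8, abs=3 * se)


def test_scores_lie_in_unit_interval(dev_cohort):
    model = BaselinePredictor().fit(dev_cohort)
    s = model.score(dev_cohort)
    assert s.index.tolist() == dev_cohort.stays["stay_id"].tolist()
    assert ((s >= 0) & (s <= 1)).all()


# ---------------------------------------------------------------------------
# run_stage
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def fitted_stage(dev_cohort):
    train, test = _split(dev_cohort, 0.7, seed=5)
    predictor = BaselinePredictor(seed=1)
    report = run_stage(train, test, predictor, FAST, stage_id="internal")
    return train, test, predictor, report


def test_stage_blocks_present(fitted_stage):
    _, test, _, report = fitted_stage
    assert report.n_test == len(test)
    assert set(STAGE_METRICS) <= set(report.metric_block)
    assert report.validation is not None
    assert report.group_panels and report.citl
    assert report.comorbidity is None  # development cohort has no diagnoses
    assert any("comorbidity" in note for note in report.notes)


def test_stage_determinism_excluding_timestamp(fitted_stage, dev_cohort):
    train, test, _, report = fitted_stage
    again = run_stage(train, test, BaselinePredictor(seed=1), FAST, stage_id="internal")
    d1, d2 = report.to_dict(), again.to_dict()
    for d in (d1, d2):
        d["metadata"].pop("created_at")
    assert json.dumps(d1, sort_keys=True) == json.dumps(d2, sort_keys=True)


def test_stage_with_diagnoses_includes_comorbidity_block():
    cohort = generate_cohort(starr_like_config(n_stays=2_500, seed=9))
    train, test = _split(cohort, 0.6, seed=1)
    report = run_stage(train, test, BaselinePredictor(), FAST, stage_id="internal")
    assert report.comorbidity is not None
    assert {c.attribute for c in report.comorbidity} == {"gender", "ethnicity", "insurance"}


def test_prefit_model_gives_identical_points_on_same_test_set(fitted_stage):
    """External scoring of an already-fitted model on the same test data
    reproduces the internal metric points exactly (stage degeneracy)."""
    _, test, predictor, report = fitted_stage
    external = run_stage(None, test, predictor, FAST, stage_id="external")
    for m in STAGE_METRICS:
        assert external.metric_block[m].point == report.metric_block[m].point
    assert external.test_digest == report.test_digest


def test_disabling_tasks_leaves_other_numbers_unchanged(fitted_stage, dev_cohort):
    train, test, _, full = fitted_stage
    slim_cfg = FrameworkConfig(
        bootstrap=FAST.bootstrap,
        charlson=FAST.charlson,
        seed=FAST.seed,
        tasks=("performance",),
    )
    slim = run_stage(train, test, BaselinePredictor(seed=1), slim_cfg, stage_id="internal")
    for m in STAGE_METRICS:
        assert slim.metric_block[m].to_dict() == full.metric_block[m].to_dict()
    assert slim.validation is None and slim.demographics is None


# ---------------------------------------------------------------------------
# run_framework
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def framework_report():
    a = generate_cohort(mimic_like_config(n_stays=5_000, seed=31))
    b = generate_cohort(starr_like_config(n_stays=2_500, seed=32))
    return run_framework(a, b, FAST)


def test_three_stages_in_order(framework_report):
    ids = [s["stage_id"] for s in framework_report["stages"]]
    assert ids == ["internal", "external", "retrained_internal"]


def test_stage2_and_stage3_share_test_set(framework_report):
    s2, s3 = framework_report["stages"][1], framework_report["stages"][2]
    assert s2["test_digest"] == s3["test_digest"]


def test_external_event_rate_matches_generating_config(framework_report):
    s2 = framework_report["stages"][1]
    total = [r for r in s2["demographics"] if r["attribute"] == "total"][0]
    n = s2["n_test"]
    se = 100 * np.sqrt(0.1018 * (1 - 0.1018) / n)
    assert total["ihm_rate_pct"] == pytest.approx(10.18, abs=3 * se)


def test_cross_stage_deltas_reported(framework_report):
    deltas = framework_report["deltas"]
    assert set(deltas) == {"external_minus_internal", "retrained_minus_external"}
    for block in deltas.values():
        assert set(block) == set(STAGE_METRICS)
        for d in block.values():
            if d.get("undefined"):
                continue  # e.g. no predicted events at the threshold
            assert isinstance(d["ci_overlap"], bool)
    # at least the ranking metrics are always defined
    assert deltas["external_minus_internal"]["auroc"]["delta"] is not None


def test_report_serialization_roundtrip(framework_report, tmp_path):
    p1 = write_json(framework_report, tmp_path / "r1.json")
    loaded = read_json(p1)
    p2 = write_json(loaded, tmp_path / "r2.json")
    assert p1.read_bytes() == p2.read_bytes()


def test_external_full_test_mode_scores_whole_cohort():
    a = generate_cohort(light_obs(mimic_like_config(n_stays=3_000, seed=41)))
    b = generate_cohort(light_obs(starr_like_config(n_stays=1_500, seed=42)))
    cfg = FrameworkConfig(
        bootstrap=BootstrapConfig(n_resamples=100, seed=1),
        external_full_test=True,
        tasks=("performance",),
        seed=1,
    )
    report = run_framework(a, b, cfg)
    from riskaudit import apply_exclusions

    eligible, _ = apply_exclusions(b)
    assert report["stages"][1]["n_test"] == len(eligible)


def test_retraining_repairs_injected_external_miscalibration():
    """External cohort generated with uniformly higher mortality than its
    scores imply for the development-trained model: stage 2 shows negative
    calibration-in-the-large (risk underestimated), retraining on the
    external data shrinks the deviation."""
    a = generate_cohort(light_obs(mimic_like_config(n_stays=8_000, seed=51)))
    b_cfg = light_obs(starr_like_config(n_stays=5_000, seed=52))
    om = b_cfg.outcome_model
    b_cfg.outcome_model = type(om)(intercept=om.intercept + 0.8, offsets=om.offsets)
    b = generate_cohort(b_cfg)
    cfg = FrameworkConfig(
        bootstrap=BootstrapConfig(n_resamples=300, seed=2),
        tasks=("performance", "fairness"),
        seed=2,
    )
    report = run_framework(a, b, cfg)
    citl1 = report["stages"][0]["citl_overall"]["rel_diff"]
    citl2 = report["stages"][1]["citl_overall"]["rel_diff"]
    citl3 = report["stages"][2]["citl_overall"]["rel_diff"]
    assert citl2["point"] < citl1["point"]  # external shift is negative
    assert citl2["ci_hi"] < 0.0  # and significant
    assert abs(citl3["point"]) < abs(citl2["point"])  # retraining helps
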