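"""Three-stage audit orchestration.

The audit runs the same assessment battery in three stages: (1) internal
validation on a train/test split of the development cohort, (2) external
validation of the stage-1 model on held-out data from an independent
cohort, and (3) internal validation after retraining on the external
cohort.  Each stage performs task A (cohort profiling: demographics and
missingness), task B (performance: discrimination with bootstrap intervals
and a calibration validation curve; fairness: classification parity,
calibration-in-the-large, and — when diagnosis data exist — comorbidity–
risk curves) and task C (report assembly).

By default stages 2 and 3 score the *same* held-out partition of the
external cohort so their numbers are directly comparable; setting
``external_full_test=True`` instead scores the entire external cohort at
stage 2 (the protocol used when an external dataset arrives without a
pre-existing split).

The bundled :class:`BaselinePredictor` is a logistic model on demographics
plus per-variable observation counts.  It is a deliberately simple,
deterministic stand-in for whatever risk model is under audit; any object
with ``fit(cohort)`` and ``score(cohort)`` can be plugged in instead.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
from dataclasses import dataclass, field, replace
from typing import Callable, Protocol, runtime_checkable

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._util import stable_seed
from .calibration import CalibrationConfig, ValidationCurve, validation_curve
from .cohorts import CohortConfig, apply_exclusions, demographics_table, missingness_profile
from .exceptions import FitError, UndefinedMetricError, UnsupportedInputError
from .fairness import (
    CharlsonConfig,
    calibration_in_the_large,
    charlson_scores,
    classification_parity,
    comorbidity_risk_curve,
)
from .metrics import BootstrapConfig, MetricConfig, bootstrap_cis, point_estimate
from .schema import (
    ADULT_AGE_BAND_LEVELS,
    ATTRIBUTE_LEVELS,
    DEMOGRAPHIC_ATTRIBUTES,
    VARIABLES,
    age_band,
)
from .synthetic import Cohort

__all__ = [
    "Predictor",
    "BaselinePredictor",
    "FrameworkConfig",
    "StageReport",
    "run_stage",
    "run_framework",
    "cohort_digest",
    "render_summary",
]

#: metrics reported in the per-stage performance block
STAGE_METRICS = (
    "auroc",
    "auprc",
    "accuracy",
    "precision_event",
    "precision_nonevent",
    "recall_event",
    "recall_nonevent",
)


@runtime_checkable
class Predictor(Protocol):
    """Contract for a pluggable risk model: scores must lie in [0, 1] and
    be deterministic given the predictor's internal seed."""

    identifier: str

    def fit(self, train: Cohort) -> "Predictor": ...

    def score(self, test: Cohort) -> pd.Series: ...


def cohort_digest(cohort: Cohort) -> str:
    """Stable digest of a cohort's stays table (report provenance)."""
    payload = cohort.stays.to_csv(index=False).encode("utf-8")
    return hashlib.sha256(payload).hexdigest()[:16]


# ---------------------------------------------------------------------------
# baseline predictor
# ---------------------------------------------------------------------------


@dataclass
class BaselinePredictor:
    """Logistic risk model on demographics and observation structure.

    Features: dummy-coded gender, ethnicity, insurance and age band (first
    level of each as reference); per catalog variable, an indicator that it
    was observed at all inside the window; and the pooled fraction of
    variable-hours covered.  Indicators rather than raw per-variable
    coverage fractions keep the design well-conditioned when a variable is
    nearly unmeasured in the training cohort but common in an external one.
    Fitting is a plain binomial GLM (IRLS), so refits on the same data are
    identical; the seed is recorded for report metadata only.
    """

    seed: int = 0
    window_hours: int = 48
    identifier: str = "baseline-logistic"
    coef_: pd.Series | None = None
    bse_: pd.Series | None = None

    def _design(self, cohort: Cohort) -> pd.DataFrame:
        stays = cohort.stays
        X = pd.DataFrame(index=stays.index)
        X["const"] = 1.0
        levels = dict(ATTRIBUTE_LEVELS, age_band=ADULT_AGE_BAND_LEVELS)
        work = stays.copy()
        work["age_band"] = age_band(work["age"]).to_numpy()
        for attr in (*DEMOGRAPHIC_ATTRIBUTES, "age_band"):
            cats = levels[attr]
            for lvl in cats[1:]:  # first level is the reference
                X[f"{attr}[{lvl}]"] = (work[attr] == lvl).astype(float)
        obs = cohort.observations
        obs = obs[(obs["hour"] >= 0) & (obs["hour"] < self.window_hours)]
        cover = (
            obs.drop_duplicates(["stay_id", "variable_id", "hour"])
            .groupby(["stay_id", "variable_id"])
            .size()
            .unstack(fill_value=0)
        )
        cover = cover.reindex(index=stays["stay_id"], columns=list(VARIABLES), fill_value=0)
        cover = cover.fillna(0).to_numpy(dtype=float) / self.window_hours
        for j, var in enumerate(VARIABLES):
            X[f"obs[{var}]"] = (cover[:, j] > 0).astype(float)
        X["obs_coverage_mean"] = cover.mean(axis=1)
        return X

    def fit(self, train: Cohort) -> "BaselinePredictor":
        y = train.stays["label"].to_numpy(dtype=float)
        if y.min() == y.max():
            raise FitError("baseline predictor requires both outcome classes in training data")
        X = self._design(train)
        model = sm.GLM(y, X.to_numpy(), family=sm.families.Binomial())
        res = model.fit(maxiter=200)
        self.coef_ = pd.Series(res.params, index=X.columns)
        self.bse_ = pd.Series(res.bse, index=X.columns)
        return self

    def score(self, test: Cohort) -> pd.Series:
        if self.coef_ is None:
            raise FitError("predictor is not fitted")
        X = self._design(test)
        eta = X.to_numpy() @ self.coef_.to_numpy()
        p = 1.0 / (1.0 + np.exp(-eta))
        p = np.clip(p, 1e-9, 1.0 - 1e-9)
        return pd.Series(p, index=test.stays["stay_id"].to_numpy(), name="score")


# ---------------------------------------------------------------------------
# configuration and report containers
# ---------------------------------------------------------------------------

ALL_TASKS = ("profile", "performance", "calibration", "fairness", "comorbidity")


@dataclass(frozen=True)
class FrameworkConfig:
    """One bundle for every tunable of the three-stage audit."""

    cohort: CohortConfig = CohortConfig()
    metric: MetricConfig = MetricConfig()
    bootstrap: BootstrapConfig = BootstrapConfig()
    calibration: CalibrationConfig = CalibrationConfig()
    charlson: CharlsonConfig | None = None
    parity_tolerance_pp: float = 1.0
    split_a_train: float = 0.85
    split_b_train: float = 0.80
    external_full_test: bool = False
    tasks: tuple = ALL_TASKS
    seed: int = 0

    def with_seed(self, seed: int) -> "FrameworkConfig":
        return replace(self, seed=int(seed))


@dataclass
class StageReport:
    """All blocks of one audit stage, JSON-serializable via ``to_dict``."""

    stage_id: str
    test_digest: str
    train_digest: str | None
    n_test: int
    n_train: int | None
    predictor_id: str
    demographics: pd.DataFrame | None = None
    missingness: pd.DataFrame | None = None
    metric_block: dict = field(default_factory=dict)
    validation: ValidationCurve | None = None
    group_panels: list = field(default_factory=list)
    parity_findings: list = field(default_factory=list)
    citl: list = field(default_factory=list)
    citl_overall: dict | None = None
    comorbidity: list | None = None
    notes: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "stage_id": self.stage_id,
            "test_digest": self.test_digest,
            "train_digest": self.train_digest,
            "n_test": self.n_test,
            "n_train": self.n_train,
            "predictor_id": self.predictor_id,
            "demographics": None
            if self.demographics is None
            else self.demographics.to_dict(orient="records"),
            "missingness": None
            if self.missingness is None
            else self.missingness.to_dict(orient="records"),
            "metric_block": {
                k: (v.to_dict() if hasattr(v, "to_dict") else v)
                for k, v in self.metric_block.items()
            },
            "validation": None if self.validation is None else self.validation.to_dict(),
            "group_panels": [p.to_dict() for p in self.group_panels],
            "parity_findings": [f.to_dict() for f in self.parity_findings],
            "citl": [c.to_dict() for c in self.citl],
            "citl_overall": self.citl_overall,
            "comorbidity": None
            if self.comorbidity is None
            else [c.to_dict() for c in self.comorbidity],
            "notes": list(self.notes),
            "metadata": dict(self.metadata),
        }


# ---------------------------------------------------------------------------
# stage execution
# ---------------------------------------------------------------------------


def _align_scores(scores: pd.Series, test: Cohort) -> np.ndarray:
    aligned = scores.reindex(test.stays["stay_id"].to_numpy())
    if aligned.isna().any():
        missing = test.stays["stay_id"][aligned.isna().to_numpy()].iloc[0]
        raise UnsupportedInputError(f"no prediction for stay {missing!r}")
    s = aligned.to_numpy(dtype=float)
    if (s < 0).any() or (s > 1).any():
        raise UnsupportedInputError("predictor emitted scores outside [0, 1]")
    return s


def run_stage(
    train: Cohort | None,
    test: Cohort,
    predictor: Predictor,
    config: FrameworkConfig = FrameworkConfig(),
    stage_id: str = "internal",
) -> StageReport:
    """Execute one audit stage on ``test``.

    Fits ``predictor`` on ``train`` when given (otherwise it must already
    be fitted), then runs the enabled tasks.  The comorbidity block is
    produced only when the test cohort carries diagnosis data *and* a
    Charlson mapping is configured; its absence is noted, not an error.
    Every stochastic block consumes its own child seed derived from
    ``config.seed``, so disabling one block never changes the numbers of
    another.
    """
    if train is not None:
        predictor.fit(train)
    scores = _align_scores(predictor.score(test), test)
    labels = test.stays["label"].to_numpy(dtype=float)
    groups = test.stays[list(DEMOGRAPHIC_ATTRIBUTES)]

    report = StageReport(
        stage_id=stage_id,
        test_digest=cohort_digest(test),
        train_digest=None if train is None else cohort_digest(train),
        n_test=len(test),
        n_train=None if train is None else len(train),
        predictor_id=getattr(predictor, "identifier", type(predictor).__name__),
        metadata={
            "seed": config.seed,
            "bootstrap_k": config.bootstrap.n_resamples,
            "alpha": config.bootstrap.alpha,
            "threshold": config.metric.threshold,
            "created_at": _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
        },
    )

    if "profile" in config.tasks:
        report.demographics = demographics_table(test)
        report.missingness = missingness_profile(test, config.cohort)

    if "performance" in config.tasks:
        bcfg = config.bootstrap.with_seed(
            stable_seed(config.seed, stage_id, "performance")
        )
        available, undefined = [], []
        for m in STAGE_METRICS:
            try:
                point_estimate(m, scores, labels, config.metric.threshold)
                available.append(m)
            except UndefinedMetricError:
                undefined.append(m)
        report.metric_block = bootstrap_cis(
            available, scores, labels, bcfg, threshold=config.metric.threshold
        )
        for m in undefined:
            # e.g. no predicted events at the threshold (accuracy paradox
            # territory): flagged, never silently zero
            report.metric_block[m] = {"name": m, "undefined": True}
            report.notes.append(
                f"metric {m} undefined on this test set at threshold "
                f"{config.metric.threshold}"
            )

    if "calibration" in config.tasks:
        report.validation = validation_curve(
            scores, labels, config.calibration, threshold=config.metric.threshold
        )

    if "fairness" in config.tasks:
        bcfg = config.bootstrap.with_seed(stable_seed(config.seed, stage_id, "parity"))
        report.group_panels, report.parity_findings = classification_parity(
            scores,
            labels,
            groups,
            bootstrap_config=bcfg,
            rate_tolerance_pp=config.parity_tolerance_pp,
        )
        ccfg = config.bootstrap.with_seed(stable_seed(config.seed, stage_id, "citl"))
        report.citl = calibration_in_the_large(scores, labels, groups, ccfg)
        overall = bootstrap_cis(
            ["citl_relative", "mean_score", "event_rate"], scores, labels, ccfg
        )
        report.citl_overall = {
            "rel_diff": overall["citl_relative"].to_dict(),
            "mean_predicted": overall["mean_score"].point,
            "observed_rate": overall["event_rate"].point,
        }

    if "comorbidity" in config.tasks:
        if len(test.diagnoses) and config.charlson is not None:
            cscores, unmapped = charlson_scores(test, config.charlson)
            report.comorbidity = comorbidity_risk_curve(scores, cscores.to_numpy(), groups)
            report.metadata["charlson_unmapped_codes"] = unmapped
        else:
            report.comorbidity = None
            report.notes.append(
                "comorbidity block skipped: no diagnosis data or no Charlson mapping"
            )

    return report


# ---------------------------------------------------------------------------
# full three-stage run
# ---------------------------------------------------------------------------


def _split(cohort: Cohort, train_fraction: float, seed: int):
    rng = np.random.default_rng(seed)
    ids = cohort.stays["stay_id"].to_numpy()
    perm = rng.permutation(len(ids))
    n_train = int(round(train_fraction * len(ids)))
    train_ids = ids[np.sort(perm[:n_train])]
    test_ids = ids[np.sort(perm[n_train:])]
    return cohort.subset(train_ids), cohort.subset(test_ids)


def _ci_overlap(a: dict, b: dict) -> bool:
    return not (a["ci_lo"] > b["ci_hi"] or b["ci_lo"] > a["ci_hi"])


def run_framework(
    cohort_a: Cohort,
    cohort_b: Cohort,
    config: FrameworkConfig = FrameworkConfig(),
    predictor_factory: Callable[[int], Predictor] | None = None,
) -> dict:
    """Full three-stage audit of a development cohort ``cohort_a`` and an
    external cohort ``cohort_b``.

    Both cohorts first pass the eligibility rules.  Stage 1 audits a seeded
    train/test split of A; stage 2 scores the stage-1 model on B's held-out
    partition (all of B with ``external_full_test=True``); stage 3 retrains
    on B's training partition and audits the same held-out partition.
    Returns a JSON-ready report dict with per-stage blocks, exclusion logs
    and cross-stage metric deltas.
    """
    if predictor_factory is None:
        predictor_factory = lambda seed: BaselinePredictor(seed=seed)

    ex_a, log_a = apply_exclusions(cohort_a, config.cohort)
    ex_b, log_b = apply_exclusions(cohort_b, config.cohort)

    a_train, a_test = _split(ex_a, config.split_a_train, stable_seed(config.seed, "split", "A"))
    b_train, b_test = _split(ex_b, config.split_b_train, stable_seed(config.seed, "split", "B"))

    model_a = predictor_factory(stable_seed(config.seed, "predictor", "A"))
    stage1 = run_stage(a_train, a_test, model_a, config, stage_id="internal")

    stage2_test = ex_b if config.external_full_test else b_test
    stage2 = run_stage(None, stage2_test, model_a, config, stage_id="external")

    model_b = predictor_factory(stable_seed(config.seed, "predictor", "B"))
    stage3 = run_stage(b_train, b_test, model_b, config, stage_id="retrained_internal")

    deltas = {}
    for pair_name, r_from, r_to in (
        ("external_minus_internal", stage1, stage2),
        ("retrained_minus_external", stage2, stage3),
    ):
        block = {}
        for m in STAGE_METRICS:
            ea = r_from.metric_block.get(m)
            eb = r_to.metric_block.get(m)
            if not (hasattr(ea, "to_dict") and hasattr(eb, "to_dict")):
                block[m] = {"delta": None, "ci_overlap": None, "undefined": True}
                continue
            a, b = ea.to_dict(), eb.to_dict()
            block[m] = {
                "delta": b["point"] - a["point"],
                "ci_overlap": _ci_overlap(a, b),
            }
        deltas[pair_name] = block

    return {
        "stages": [stage1.to_dict(), stage2.to_dict(), stage3.to_dict()],
        "deltas": deltas,
        "exclusions": {"cohort_a": log_a.to_dict(), "cohort_b": log_b.to_dict()},
        "metadata": {
            "seed": config.seed,
            "split_a_train": config.split_a_train,
            "split_b_train": config.split_b_train,
            "external_full_test": config.external_full_test,
            "cohort_a_provenance": cohort_a.provenance,
            "cohort_b_provenance": cohort_b.provenance,
        },
    }


# ---------------------------------------------------------------------------
# human-readable summary (MINIMAR-style headings)
# ---------------------------------------------------------------------------


def render_summary(report: dict) -> str:
    """Plain-text summary of a framework report with reporting-guideline
    headings (population, predictors, outcome, model, performance,
    fairness)."""
    lines = ["# Audit summary", ""]
    for stage in report["stages"]:
        lines.append(f"## Stage: {stage['stage_id']}")
        lines.append("### Population")
        lines.append(
            f"- test stays: {stage['n_test']}"
            + (f"; training stays: {stage['n_train']}" if stage["n_train"] else "")
        )
        if stage.get("demographics"):
            total = [r for r in stage["demographics"] if r["attribute"] == "total"][0]
            lines.append(f"- in-hospital mortality rate: {total['ihm_rate_pct']:.2f}%")
        lines.append("### Predictors / Outcome / Model")
        lines.append(
            "- hourly physiological observations (48 h window) and demographics; "
            "outcome: in-hospital mortality; model: " + stage["predictor_id"]
        )
        if stage.get("metric_block"):
            lines.append("### Performance")
            for name, est in stage["metric_block"].items():
                if est.get("undefined"):
                    lines.append(f"- {name}: undefined at this threshold")
                else:
                    lines.append(
                        f"- {name}: {est['point']:.3f} ({est['ci_lo']:.3f}, {est['ci_hi']:.3f})"
                    )
        if stage.get("parity_findings"):
            lines.append("### Fairness")
            n_viol = sum(
                1 for f in stage["parity_findings"] if f["verdict"] == "parity_violation"
            )
            lines.append(
                f"- classification parity: {n_viol} violation(s) across "
                f"{len(stage['parity_findings'])} pairwise checks"
            )
            if stage.get("citl_overall"):
                rd = stage["citl_overall"]["rel_diff"]
                lines.append(
                    f"- calibration-in-the-large: {rd['point']:+.3f} "
                    f"({rd['ci_lo']:+.3f}, {rd['ci_hi']:+.3f}) relative"
                )
        lines.append("")
    return "\n".join(lines)
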