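"""Group-stratified fairness assessments.

Three complementary views of model fairness for a binary risk model:

* **Classification parity** — per-group AUROC/AUPRC with bootstrap
  intervals.  Because both metrics are driven by the group event rate
  (class imbalance), a performance gap is attributed to unfair predictions
  only in two scenarios where imbalance cannot explain it: (1) the two
  groups have materially similar event rates, or (2) the event-rate
  ordering is the converse of the performance ordering (the group that the
  imbalance argument says should do worse actually does better).  In either
  scenario, disjoint confidence intervals yield a ``parity_violation``
  verdict.
* **Calibration-in-the-large** — per-group relative difference between the
  mean predicted and the observed event rate, with a percentile bootstrap
  interval of the per-resample relative differences.  An interval covering
  zero is consistent with calibration.
* **Comorbidity–risk curves** — mean Charlson comorbidity score per group
  within a sliding window of pooled risk-score percentiles: under
  calibration fairness, equal risk scores should carry comparable
  comorbidity burden across groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._util import as_float_array, as_label_array, stable_seed
from .exceptions import ConfigurationError, SchemaError
from .metrics import BootstrapConfig, MetricEstimate, bootstrap_cis
from .schema import ATTRIBUTE_LEVELS
from .synthetic import Cohort

__all__ = [
    "GroupPanel",
    "ParityFinding",
    "CITLEstimate",
    "CharlsonConfig",
    "ComorbidityCurve",
    "classification_parity",
    "calibration_in_the_large",
    "charlson_score",
    "charlson_scores",
    "comorbidity_risk_curve",
]

VERDICTS = ("parity_violation", "imbalance_confounded", "no_material_difference")


@dataclass
class GroupPanel:
    """Per-group sample size, event rate and metric estimates."""

    attribute: str
    level: str
    n: int
    event_rate_pct: float
    estimates: dict[str, MetricEstimate] = field(default_factory=dict)
    assessable: bool = True
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "attribute": self.attribute,
            "level": self.level,
            "n": self.n,
            "event_rate_pct": self.event_rate_pct,
            "estimates": {k: v.to_dict() for k, v in self.estimates.items()},
            "assessable": self.assessable,
            "note": self.note,
        }


@dataclass
class ParityFinding:
    """Pairwise classification-parity verdict for one metric."""

    attribute: str
    level_a: str
    level_b: str
    metric: str
    verdict: str
    event_rate_gap_pp: float  # rate(a) - rate(b), percentage points
    ci_disjoint: bool
    scenario: int | None  # 1 = similar rates, 2 = converse ordering, None
    rationale: str

    def to_dict(self) -> dict:
        return {
            "attribute": self.attribute,
            "level_a": self.level_a,
            "level_b": self.level_b,
            "metric": self.metric,
            "verdict": self.verdict,
            "event_rate_gap_pp": self.event_rate_gap_pp,
            "ci_disjoint": self.ci_disjoint,
            "scenario": self.scenario,
            "rationale": self.rationale,
        }


@dataclass
class CITLEstimate:
    """Calibration-in-the-large for one group.

    ``rel_diff = (mean predicted - observed rate) / observed rate``;
    negative values mean the model underestimates the group's risk.
    """

    attribute: str
    level: str
    n: int
    mean_predicted: float
    observed_rate: float
    rel_diff: float | None
    ci_lo: float | None
    ci_hi: float | None
    assessable: bool = True
    note: str = ""

    @property
    def consistent_with_calibration(self) -> bool | None:
        if not self.assessable:
            return None
        return self.ci_lo <= 0.0 <= self.ci_hi

    def to_dict(self) -> dict:
        return {
            "attribute": self.attribute,
            "level": self.level,
            "n": self.n,
            "mean_predicted": self.mean_predicted,
            "observed_rate": self.observed_rate,
            "rel_diff": self.rel_diff,
            "ci_lo": self.ci_lo,
            "ci_hi": self.ci_hi,
            "assessable": self.assessable,
            "consistent_with_calibration": self.consistent_with_calibration,
            "note": self.note,
        }


@dataclass(frozen=True)
class CharlsonConfig:
    """Charlson comorbidity mapping: diagnosis code -> (factor, weight),
    exactly 12 distinct factors, with a lookback window before admission."""

    mapping: Mapping[str, tuple[str, int]]
    lookback_days: int = 730

    def __post_init__(self) -> None:
        factors = {}
        for code, (factor, weight) in self.mapping.items():
            if int(weight) < 1:
                raise ConfigurationError(f"weight for code {code!r} must be >= 1")
            if factor in factors and factors[factor] != int(weight):
                raise ConfigurationError(f"factor {factor!r} mapped with conflicting weights")
            factors[factor] = int(weight)
        if len(factors) != 12:
            raise ConfigurationError(
                f"Charlson mapping must define exactly 12 factors, got {len(factors)}"
            )
        if self.lookback_days < 1:
            raise ConfigurationError("lookback_days must be >= 1")

    @property
    def factor_weights(self) -> dict[str, int]:
        return {factor: int(w) for _, (factor, w) in sorted(self.mapping.items())}


@dataclass
class ComorbidityCurve:
    """Mean Charlson score per pooled risk-percentile window for one group."""

    attribute: str
    level: str
    percentiles: np.ndarray  # grid 1..100
    mean_charlson: np.ndarray  # NaN where the window holds no stays
    window_n: np.ndarray
    sparse: np.ndarray  # True where window_n < min_window_n

    def to_dict(self) -> dict:
        return {
            "attribute": self.attribute,
            "level": self.level,
            "percentiles": self.percentiles.tolist(),
            "mean_charlson": [None if np.isnan(v) else float(v) for v in self.mean_charlson],
            "window_n": self.window_n.tolist(),
            "sparse": self.sparse.tolist(),
        }


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _group_frame(groups) -> pd.DataFrame:
    if isinstance(groups, pd.Series):
        groups = groups.to_frame()
    if not isinstance(groups, pd.DataFrame):
        raise SchemaError("groups must be a pandas Series or DataFrame of attribute columns")
    for attr in groups.columns:
        if attr in ATTRIBUTE_LEVELS:
            unknown = set(groups[attr].unique()) - set(ATTRIBUTE_LEVELS[attr])
            if unknown:
                raise SchemaError(f"unknown {attr} level(s): {sorted(unknown)!r}")
    return groups.reset_index(drop=True)


def _levels_in_order(col: pd.Series, attr: str) -> list[str]:
    if attr in ATTRIBUTE_LEVELS:
        return [lvl for lvl in ATTRIBUTE_LEVELS[attr] if lvl in set(col)]
    return sorted(set(col))


# ---------------------------------------------------------------------------
# classification parity
# ---------------------------------------------------------------------------


def classification_parity(
    scores,
    labels,
    groups,
    bootstrap_config: BootstrapConfig = BootstrapConfig(),
    metrics: Sequence[str] = ("auroc", "auprc"),
    rate_tolerance_pp: float = 1.0,
) -> tuple[list[GroupPanel], list[ParityFinding]]:
    """Classification-parity assessment across every attribute in ``groups``.

    Per level: bootstrap estimates of the requested ranking metrics
    (resampling within the level, with a level-specific child seed so the
    assessment is deterministic and order-independent).  Per level pair and
    metric: a verdict —

    * ``parity_violation`` when imbalance cannot explain the gap (event
      rates within ``rate_tolerance_pp`` percentage points, scenario 1, or
      converse rate/performance ordering, scenario 2) *and* the 95%
      intervals are disjoint;
    * ``imbalance_confounded`` when the intervals are disjoint but the rate
      gap runs in the direction that explains the performance gap;
    * ``no_material_difference`` when the intervals overlap.

    Levels with fewer than 2 stays or a single outcome class are reported
    as not assessable and excluded from pairing.
    """
    s = as_float_array(scores, "scores")
    l = as_label_array(labels)
    gf = _group_frame(groups)
    if len(gf) != s.size:
        raise SchemaError("groups must align with scores/labels")

    panels: list[GroupPanel] = []
    findings: list[ParityFinding] = []
    for attr in gf.columns:
        col = gf[attr]
        attr_panels = []
        for lvl in _levels_in_order(col, attr):
            mask = (col == lvl).to_numpy()
            n = int(mask.sum())
            rate = float(100.0 * l[mask].mean()) if n else float("nan")
            panel = GroupPanel(attribute=attr, level=str(lvl), n=n, event_rate_pct=rate)
            if n < 2 or l[mask].min() == l[mask].max():
                panel.assessable = False
                panel.note = "not assessable: fewer than 2 stays or single outcome class"
            else:
                cfg = bootstrap_config.with_seed(
                    stable_seed(bootstrap_config.seed, "parity", attr, str(lvl))
                )
                panel.estimates = bootstrap_cis(list(metrics), s[mask], l[mask], cfg)
            panels.append(panel)
            attr_panels.append(panel)

        assessable = [p for p in attr_panels if p.assessable]
        for i, pa in enumerate(assessable):
            for pb in assessable[i + 1 :]:
                gap = pa.event_rate_pct - pb.event_rate_pct
                for metric in metrics:
                    ea, eb = pa.estimates[metric], pb.estimates[metric]
                    disjoint = ea.ci_lo > eb.ci_hi or eb.ci_lo > ea.ci_hi
                    scenario: int | None = None
                    if abs(gap) <= rate_tolerance_pp:
                        scenario = 1
                    elif (gap > 0) == (ea.point > eb.point):
                        # the group with the higher event rate also performs
                        # better: converse of the imbalance argument
                        scenario = 2
                    if scenario is not None and disjoint:
                        verdict = "parity_violation"
                        worse = pa.level if ea.point < eb.point else pb.level
                        why = (
                            f"scenario {scenario}: class imbalance cannot explain the "
                            f"{metric} gap; {worse!r} receives distinctively worse predictions"
                        )
                    elif disjoint:
                        verdict = "imbalance_confounded"
                        why = (
                            f"{metric} intervals are disjoint but the event-rate gap "
                            f"({gap:+.2f} pp) runs in the direction that explains it"
                        )
                    else:
                        verdict = "no_material_difference"
                        why = f"{metric} intervals overlap"
                    findings.append(
                        ParityFinding(
                            attribute=attr,
                            level_a=pa.level,
                            level_b=pb.level,
                            metric=metric,
                            verdict=verdict,
                            event_rate_gap_pp=float(gap),
                            ci_disjoint=bool(disjoint),
                            scenario=scenario,
                            rationale=why,
                        )
                    )
    return panels, findings


# ---------------------------------------------------------------------------
# calibration-in-the-large
# ---------------------------------------------------------------------------


def calibration_in_the_large(
    scores,
    labels,
    groups,
    bootstrap_config: BootstrapConfig = BootstrapConfig(),
) -> list[CITLEstimate]:
    """Per-group relative difference between mean predicted and observed
    risk, with percentile-bootstrap intervals (resampling within level).

    Groups with zero observed events are flagged not assessable; no
    division is attempted for them.
    """
    s = as_float_array(scores, "scores")
    l = as_label_array(labels)
    gf = _group_frame(groups)
    if len(gf) != s.size:
        raise SchemaError("groups must align with scores/labels")

    out: list[CITLEstimate] = []
    for attr in gf.columns:
        col = gf[attr]
        for lvl in _levels_in_order(col, attr):
            mask = (col == lvl).to_numpy()
            n = int(mask.sum())
            mean_pred = float(s[mask].mean())
            obs_rate = float(l[mask].mean())
            if obs_rate == 0.0:
                out.append(
                    CITLEstimate(
                        attribute=attr,
                        level=str(lvl),
                        n=n,
                        mean_predicted=mean_pred,
                        observed_rate=obs_rate,
                        rel_diff=None,
                        ci_lo=None,
                        ci_hi=None,
                        assessable=False,
                        note="not assessable: zero observed events",
                    )
                )
                continue
            cfg = bootstrap_config.with_seed(
                stable_seed(bootstrap_config.seed, "citl", attr, str(lvl))
            )
            est = bootstrap_cis(["citl_relative"], s[mask], l[mask], cfg)["citl_relative"]
            out.append(
                CITLEstimate(
                    attribute=attr,
                    level=str(lvl),
                    n=n,
                    mean_predicted=mean_pred,
                    observed_rate=obs_rate,
                    rel_diff=est.point,
                    ci_lo=est.ci_lo,
                    ci_hi=est.ci_hi,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Charlson comorbidity index
# ---------------------------------------------------------------------------


def charlson_score(
    diagnoses: Iterable[tuple[str, int]],
    config: CharlsonConfig,
) -> int:
    """Weighted sum over the distinct comorbidity factors present within the
    lookback window.  Multiple codes mapping to one factor count once;
    unmapped codes are ignored."""
    score, _ = _charlson_one(diagnoses, config)
    return score


def _charlson_one(diagnoses, config) -> tuple[int, int]:
    seen: set[str] = set()
    unmapped = 0
    total = 0
    for code, days in diagnoses:
        if days < 0:
            raise ValueError("days_before_admission must be >= 0")
        if days > config.lookback_days:
            continue
        hit = config.mapping.get(code)
        if hit is None:
            unmapped += 1
            continue
        factor, weight = hit
        if factor not in seen:
            seen.add(factor)
            total += int(weight)
    return total, unmapped


def charlson_scores(cohort: Cohort, config: CharlsonConfig) -> tuple[pd.Series, int]:
    """Charlson score per stay of a cohort (0 where no diagnoses) and the
    total count of unmapped in-window diagnosis codes."""
    dx = cohort.diagnoses
    stay_ids = cohort.stays["stay_id"]
    if len(dx) == 0:
        return pd.Series(0, index=stay_ids.to_numpy(), name="charlson", dtype=int), 0
    in_window = dx[dx["days_before_admission"] <= config.lookback_days]
    mapped = in_window["code"].map(
        {c: f for c, (f, _) in config.mapping.items()}
    )
    unmapped = int(mapped.isna().sum())
    weights = {f: w for _, (f, w) in config.mapping.items()}
    hit = in_window.assign(factor=mapped).dropna(subset=["factor"])
    per_stay = (
        hit.drop_duplicates(["stay_id", "factor"])
        .assign(weight=lambda d: d["factor"].map(weights))
        .groupby("stay_id")["weight"]
        .sum()
    )
    out = per_stay.reindex(stay_ids.to_numpy(), fill_value=0).astype(int)
    out.name = "charlson"
    return out, unmapped


# ---------------------------------------------------------------------------
# comorbidity-risk curves
# ---------------------------------------------------------------------------


def comorbidity_risk_curve(
    scores,
    charlson,
    groups,
    window_pp: float = 5.0,
    min_window_n: int = 10,
) -> list[ComorbidityCurve]:
    """Mean Charlson score per group along pooled risk-score percentiles.

    Percentile ranks are computed on the pooled sample (so curves for
    different groups share an x-axis); at each grid point 1..100 the curve
    value is the mean Charlson score of the group's stays whose pooled
    percentile lies within ``window_pp`` points.  Windows holding fewer than
    ``min_window_n`` stays are flagged sparse.
    """
    s = as_float_array(scores, "scores")
    c = np.asarray(charlson, dtype=float).ravel()
    gf = _group_frame(groups)
    if not (len(gf) == s.size == c.size):
        raise SchemaError("scores, charlson and groups must align")

    pct = 100.0 * rankdata(s, method="average") / s.size
    grid = np.arange(1, 101, dtype=float)

    curves = []
    for attr in gf.columns:
        col = gf[attr]
        for lvl in _levels_in_order(col, attr):
            mask = (col == lvl).to_numpy()
            p = pct[mask]
            cc = c[mask]
            order = np.argsort(p)
            p_sorted = p[order]
            c_sorted = cc[order]
            csum = np.concatenate([[0.0], np.cumsum(c_sorted)])
            lo = np.searchsorted(p_sorted, grid - window_pp, side="left")
            hi = np.searchsorted(p_sorted, grid + window_pp, side="right")
            n_win = (hi - lo).astype(int)
            with np.errstate(invalid="ignore", divide="ignore"):
                means = np.where(n_win > 0, (csum[hi] - csum[lo]) / n_win, np.nan)
            curves.append(
                ComorbidityCurve(
                    attribute=attr,
                    level=str(lvl),
                    percentiles=grid,
                    mean_charlson=means,
                    window_n=n_win,
                    sparse=n_win < min_window_n,
                )
            )
    return curves
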