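"""Synthetic ICU cohort generator.

Real audits of in-hospital-mortality (IHM) models run on restricted EHR
extracts.  This module generates cohorts with the same statistical skeleton —
demographic marginals, group-specific event rates under an additive
logistic outcome model, per-variable observation missingness over a 48-hour
window, and comorbidity codes correlated with outcome — so that every stage
of the audit pipeline can be exercised, and so that known biases can be
*injected* into the emitted risk scores and recovered by the fairness
statistics downstream.

Design notes
------------
* Demographic attributes are sampled independently from their marginals (no
  copula); a joint probability table can be supplied via
  ``GeneratorConfig.joint_table`` to override this.
* The latent per-stay "true risk" is the inverse-logit of the outcome
  model's linear predictor.  The outcome label is Bernoulli in that risk,
  so generated cohorts are calibrated by construction.  The latent risk is
  carried on the in-memory :class:`Cohort` only and never written to disk.
* One master seed; each stochastic component draws from its own child
  generator derived with a fixed spawn key, so adding a component never
  perturbs the draws of another.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit

from .exceptions import ConfigurationError, UnsupportedInputError
from .schema import (
    ADULT_AGE_BAND_LEVELS,
    AGE_BANDS,
    ATTRIBUTE_LEVELS,
    DX_COLUMNS,
    OBS_COLUMNS,
    STAY_COLUMNS,
    VARIABLES,
)

__all__ = [
    "MissingnessSpec",
    "OutcomeModel",
    "CharlsonGenModel",
    "GeneratorConfig",
    "StayRecord",
    "Cohort",
    "generate_cohort",
    "emit_predictions",
    "expected_event_rate",
    "calibrate_intercept",
]

_SAMPLED_ATTRIBUTES = ("gender", "ethnicity", "insurance", "age_band")


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MissingnessSpec:
    """Missingness model for one physiological variable.

    ``p_none`` is the probability that a stay records *no* observation of the
    variable during the analysis window.  Otherwise each hour bucket contains
    an observation independently with probability ``p_hour``, with one
    observation placed in a uniformly random hour if every draw lands empty —
    a stay that measures a variable at all has at least one value, so the
    zero-observation fraction equals ``p_none`` exactly.  Values are drawn
    from a Gaussian and are carried for missingness accounting only — no
    audit statistic reads them.
    """

    p_none: float
    p_hour: float
    value_mean: float = 0.0
    value_sd: float = 1.0


@dataclass(frozen=True)
class OutcomeModel:
    """Additive log-odds outcome model.

    ``intercept`` plus one offset per demographic level and per age band;
    the per-stay event probability is the inverse logit of the sum.
    """

    intercept: float
    offsets: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def linear_predictor(self, stays: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(stays), self.intercept, dtype=float)
        for attr, levels in self.offsets.items():
            col = stays[attr].map(lambda lvl: levels.get(lvl, 0.0))
            eta += col.to_numpy(dtype=float)
        return eta


@dataclass(frozen=True)
class CharlsonGenModel:
    """Generator for comorbidity diagnosis codes correlated with outcome.

    Each factor is present with probability
    ``invlogit(logit(prevalence) + association * (eta - intercept))`` where
    ``eta`` is the stay's outcome linear predictor, so sicker stays carry
    more comorbidity.  A present factor emits one code drawn from its code
    list, dated uniformly within ``max_days_before`` days of admission.
    """

    prevalence: Mapping[str, float]
    association: Mapping[str, float]
    codes: Mapping[str, tuple[str, ...]]
    max_days_before: int = 730
    unmapped_rate: float = 0.03

    def factors(self) -> tuple[str, ...]:
        return tuple(sorted(self.prevalence))


@dataclass
class GeneratorConfig:
    """Full parameterization of a synthetic cohort.

    Attributes
    ----------
    n_stays:
        Number of ICU stays to generate.
    demographic_marginals:
        Probability vector per attribute (``gender``, ``ethnicity``,
        ``insurance``, ``age_band``); each must sum to one.
    outcome_model:
        Additive log-odds model for the in-hospital mortality label.
    miscalibration_shifts:
        Log-odds shift per demographic level applied to emitted risk scores
        (bias injection; zero by default).
    noise_degradation:
        Per-level standard deviation of Gaussian log-odds noise added to
        emitted scores (discrimination degradation; zero by default).
    missingness_profile:
        :class:`MissingnessSpec` per variable; must cover the 17-variable
        catalog exactly.
    charlson_model:
        Optional comorbidity code generator; ``None`` emits no diagnoses.
    multi_stay_fraction:
        Fraction of patients contributing two stays (separate hospital
        admissions, shared demographics).
    joint_table:
        Optional joint demographic distribution as a DataFrame with columns
        ``gender, ethnicity, insurance, age_band, prob``; overrides the
        independent marginals when given.
    """

    n_stays: int
    demographic_marginals: Mapping[str, Mapping[str, float]]
    outcome_model: OutcomeModel
    miscalibration_shifts: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    noise_degradation: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    missingness_profile: Mapping[str, MissingnessSpec] = field(default_factory=dict)
    charlson_model: CharlsonGenModel | None = None
    multi_stay_fraction: float = 0.15
    los_meanlog: float = math.log(120.0)
    los_sdlog: float = 0.6
    joint_table: pd.DataFrame | None = None
    seed: int = 0

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        if self.n_stays < 1:
            raise ConfigurationError("n_stays must be >= 1")
        expected_levels = dict(ATTRIBUTE_LEVELS, age_band=ADULT_AGE_BAND_LEVELS)
        for attr in _SAMPLED_ATTRIBUTES:
            if attr not in self.demographic_marginals:
                raise ConfigurationError(f"missing marginal for attribute {attr!r}")
            marg = self.demographic_marginals[attr]
            if set(marg) != set(expected_levels[attr]):
                raise ConfigurationError(
                    f"marginal for {attr!r} must cover levels {expected_levels[attr]}"
                )
            probs = np.array(list(marg.values()), dtype=float)
            if (probs < 0).any() or (probs > 1).any():
                raise ConfigurationError(f"marginal for {attr!r} has probability outside [0, 1]")
            if abs(probs.sum() - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"marginal for {attr!r} sums to {probs.sum():.12f}, expected 1"
                )
        if set(self.missingness_profile) != set(VARIABLES):
            raise ConfigurationError(
                "missingness_profile must cover the 17-variable catalog exactly"
            )
        for var, spec in self.missingness_profile.items():
            for name, p in (("p_none", spec.p_none), ("p_hour", spec.p_hour)):
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(f"{name} for {var!r} outside [0, 1]")
        if not 0.0 <= self.multi_stay_fraction < 1.0:
            raise ConfigurationError("multi_stay_fraction must be in [0, 1)")
        if self.charlson_model is not None:
            for f, p in self.charlson_model.prevalence.items():
                if not 0.0 < p < 1.0:
                    raise ConfigurationError(f"charlson prevalence for {f!r} outside (0, 1)")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d: dict = {
            "n_stays": int(self.n_stays),
            "demographic_marginals": {
                a: {k: float(v) for k, v in m.items()}
                for a, m in self.demographic_marginals.items()
            },
            "outcome_model": {
                "intercept": float(self.outcome_model.intercept),
                "offsets": {
                    a: {k: float(v) for k, v in m.items()}
                    for a, m in self.outcome_model.offsets.items()
                },
            },
            "miscalibration_shifts": {
                a: {k: float(v) for k, v in m.items()}
                for a, m in self.miscalibration_shifts.items()
            },
            "noise_degradation": {
                a: {k: float(v) for k, v in m.items()}
                for a, m in self.noise_degradation.items()
            },
            "missingness_profile": {
                v: {
                    "p_none": float(s.p_none),
                    "p_hour": float(s.p_hour),
                    "value_mean": float(s.value_mean),
                    "value_sd": float(s.value_sd),
                }
                for v, s in self.missingness_profile.items()
            },
            "multi_stay_fraction": float(self.multi_stay_fraction),
            "los_meanlog": float(self.los_meanlog),
            "los_sdlog": float(self.los_sdlog),
            "seed": int(self.seed),
        }
        if self.charlson_model is not None:
            cm = self.charlson_model
            d["charlson_model"] = {
                "prevalence": {k: float(v) for k, v in cm.prevalence.items()},
                "association": {k: float(v) for k, v in cm.association.items()},
                "codes": {k: list(v) for k, v in cm.codes.items()},
                "max_days_before": int(cm.max_days_before),
                "unmapped_rate": float(cm.unmapped_rate),
            }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        cm = None
        if d.get("charlson_model") is not None:
            c = d["charlson_model"]
            cm = CharlsonGenModel(
                prevalence=dict(c["prevalence"]),
                association=dict(c["association"]),
                codes={k: tuple(v) for k, v in c["codes"].items()},
                max_days_before=int(c.get("max_days_before", 730)),
                unmapped_rate=float(c.get("unmapped_rate", 0.03)),
            )
        return cls(
            n_stays=int(d["n_stays"]),
            demographic_marginals={a: dict(m) for a, m in d["demographic_marginals"].items()},
            outcome_model=OutcomeModel(
                intercept=float(d["outcome_model"]["intercept"]),
                offsets={a: dict(m) for a, m in d["outcome_model"].get("offsets", {}).items()},
            ),
            miscalibration_shifts={a: dict(m) for a, m in d.get("miscalibration_shifts", {}).items()},
            noise_degradation={a: dict(m) for a, m in d.get("noise_degradation", {}).items()},
            missingness_profile={
                v: MissingnessSpec(**s) for v, s in d["missingness_profile"].items()
            },
            charlson_model=cm,
            multi_stay_fraction=float(d.get("multi_stay_fraction", 0.15)),
            los_meanlog=float(d.get("los_meanlog", math.log(120.0))),
            los_sdlog=float(d.get("los_sdlog", 0.6)),
            seed=int(d.get("seed", 0)),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "GeneratorConfig":
        return cls.from_dict(yaml.safe_load(text))

    def digest(self) -> str:
        """Stable hash of the configuration (for report provenance)."""
        return hashlib.sha256(self.to_yaml().encode("utf-8")).hexdigest()[:16]

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=int(seed))


# ---------------------------------------------------------------------------
# cohort containers
# ---------------------------------------------------------------------------


@dataclass
class StayRecord:
    """One ICU stay; convenience type for hand-building toy cohorts."""

    stay_id: str
    patient_id: str
    age: int
    gender: str
    ethnicity: str
    insurance: str
    label: int
    los_hours: float
    admission_id: str | None = None
    observations: Sequence[tuple[str, int, float]] = ()
    diagnoses: Sequence[tuple[str, int]] = ()


@dataclass
class Cohort:
    """A cohort of ICU stays with hourly observations and dated diagnoses.

    ``true_risk`` holds the latent generating event probability per stay for
    synthetic cohorts; it is excluded from all file exports so round-trips
    through disk cannot leak it.
    """

    stays: pd.DataFrame
    observations: pd.DataFrame
    diagnoses: pd.DataFrame
    provenance: str = ""
    config_digest: str = ""
    true_risk: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.stays["stay_id"].duplicated().any():
            dup = self.stays.loc[self.stays["stay_id"].duplicated(), "stay_id"].iloc[0]
            raise ConfigurationError(f"duplicate stay_id {dup!r} in cohort")

    def __len__(self) -> int:
        return len(self.stays)

    @property
    def n_patients(self) -> int:
        return int(self.stays["patient_id"].nunique())

    @property
    def event_rate(self) -> float:
        return float(self.stays["label"].mean())

    def subset(self, stay_ids: Iterable[str], provenance: str | None = None) -> "Cohort":
        """Return the sub-cohort restricted to ``stay_ids`` (order preserved)."""
        keep = pd.Index(stay_ids)
        stays = self.stays[self.stays["stay_id"].isin(keep)].reset_index(drop=True)
        obs = self.observations[self.observations["stay_id"].isin(keep)].reset_index(drop=True)
        dx = self.diagnoses[self.diagnoses["stay_id"].isin(keep)].reset_index(drop=True)
        tr = None
        if self.true_risk is not None:
            tr = self.true_risk.loc[stays["stay_id"]]
        return Cohort(
            stays=stays,
            observations=obs,
            diagnoses=dx,
            provenance=provenance if provenance is not None else self.provenance,
            config_digest=self.config_digest,
            true_risk=tr,
        )

    @classmethod
    def from_records(cls, records: Sequence[StayRecord], provenance: str = "") -> "Cohort":
        stay_rows, obs_rows, dx_rows = [], [], []
        for r in records:
            stay_rows.append(
                {
                    "stay_id": r.stay_id,
                    "patient_id": r.patient_id,
                    "admission_id": r.admission_id or r.stay_id,
                    "age": int(r.age),
                    "gender": r.gender,
                    "ethnicity": r.ethnicity,
                    "insurance": r.insurance,
                    "label": int(r.label),
                    "los_hours": float(r.los_hours),
                }
            )
            for var, hour, value in r.observations:
                obs_rows.append(
                    {"stay_id": r.stay_id, "variable_id": var, "hour": int(hour), "value": value}
                )
            for code, days in r.diagnoses:
                dx_rows.append(
                    {"stay_id": r.stay_id, "code": code, "days_before_admission": int(days)}
                )
        stays = pd.DataFrame(stay_rows, columns=STAY_COLUMNS)
        obs = pd.DataFrame(obs_rows, columns=OBS_COLUMNS)
        dx = pd.DataFrame(dx_rows, columns=DX_COLUMNS)
        return cls(stays=stays, observations=obs, diagnoses=dx, provenance=provenance)


# ---------------------------------------------------------------------------
# outcome-model helpers
# ---------------------------------------------------------------------------


def _cell_iterator(marginals: Mapping[str, Mapping[str, float]]):
    """Yield (prob, {attr: level}) over the independent joint distribution."""
    import itertools

    attrs = list(_SAMPLED_ATTRIBUTES)
    level_lists = [list(marginals[a].items()) for a in attrs]
    for combo in itertools.product(*level_lists):
        p = 1.0
        cell = {}
        for a, (lvl, q) in zip(attrs, combo):
            p *= q
            cell[a] = lvl
        yield p, cell


def expected_event_rate(
    intercept: float,
    marginals: Mapping[str, Mapping[str, float]],
    offsets: Mapping[str, Mapping[str, float]],
) -> float:
    """Exact pooled event rate implied by an additive logistic outcome model
    under independent demographic marginals (enumeration over all cells)."""
    total = 0.0
    for p, cell in _cell_iterator(marginals):
        eta = intercept + sum(offsets.get(a, {}).get(lvl, 0.0) for a, lvl in cell.items())
        total += p * expit(eta)
    return float(total)


def calibrate_intercept(
    target_rate: float,
    marginals: Mapping[str, Mapping[str, float]],
    offsets: Mapping[str, Mapping[str, float]],
) -> float:
    """Solve for the intercept whose implied pooled event rate equals
    ``target_rate`` (averaging the inverse logit over demographic cells makes
    ``logit(target)`` alone slightly off; this removes that Jensen gap)."""
    if not 0.0 < target_rate < 1.0:
        raise ConfigurationError("target_rate must be in (0, 1)")
    f = lambda b: expected_event_rate(b, marginals, offsets) - target_rate
    return float(brentq(f, -20.0, 20.0, xtol=1e-12))


def expected_group_rate(
    config: GeneratorConfig, attribute: str, level: str
) -> float:
    """Event rate the outcome model implies for one demographic level."""
    num = 0.0
    den = 0.0
    om = config.outcome_model
    for p, cell in _cell_iterator(config.demographic_marginals):
        if cell[attribute] != level:
            continue
        eta = om.intercept + sum(
            om.offsets.get(a, {}).get(lvl, 0.0) for a, lvl in cell.items()
        )
        num += p * expit(eta)
        den += p
    return float(num / den)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

_AGE_RANGE = {label: (lo, min(hi, 99)) for label, lo, hi in AGE_BANDS}


def _child_rng(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(key,)))


def _sample_level(rng, attr: str, marg: Mapping[str, float], n: int) -> np.ndarray:
    # canonical level order so draws are independent of dict ordering
    order = dict(ATTRIBUTE_LEVELS, age_band=ADULT_AGE_BAND_LEVELS)[attr]
    levels = np.array(order, dtype=object)
    probs = np.array([marg[lvl] for lvl in order], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(levels, size=n, p=probs)


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate a synthetic cohort of ``config.n_stays`` ICU stays.

    Demographics are sampled per *patient* (multi-stay patients share them),
    the mortality label is Bernoulli in the inverse-logit of the outcome
    model, observations follow the per-variable missingness profile, and
    diagnoses follow the comorbidity model.  Fully reproducible from
    ``config.seed``.
    """
    config.validate()
    n_stays = config.n_stays

    # patients and their demographics
    f = config.multi_stay_fraction
    n_patients = max(1, int(round(n_stays / (1.0 + f))))
    n_multi = n_stays - n_patients
    if n_multi < 0:
        n_patients, n_multi = n_stays, 0
    n_multi = min(n_multi, n_patients)
    n_patients = n_stays - n_multi  # keep stay count exact

    rng_demo = _child_rng(config.seed, 0)
    if config.joint_table is not None:
        jt = config.joint_table
        probs = jt["prob"].to_numpy(dtype=float)
        idx = rng_demo.choice(len(jt), size=n_patients, p=probs / probs.sum())
        pat = jt.iloc[idx][list(_SAMPLED_ATTRIBUTES)].reset_index(drop=True)
    else:
        pat = pd.DataFrame(
            {
                a: _sample_level(rng_demo, a, config.demographic_marginals[a], n_patients)
                for a in _SAMPLED_ATTRIBUTES
            }
        )
    lo = np.array([_AGE_RANGE[b][0] for b in pat["age_band"]])
    hi = np.array([_AGE_RANGE[b][1] for b in pat["age_band"]])
    pat["age"] = rng_demo.integers(lo, hi + 1)

    # stay -> patient map: the first n_multi patients contribute two stays
    patient_of_stay = np.concatenate([np.arange(n_patients), np.arange(n_multi)])
    patient_of_stay.sort(kind="stable")

    stays = pat.iloc[patient_of_stay].reset_index(drop=True)
    width = max(6, len(str(n_stays)))
    stays.insert(0, "stay_id", [f"s{i:0{width}d}" for i in range(n_stays)])
    stays.insert(1, "patient_id", [f"p{i:0{width}d}" for i in patient_of_stay])
    stays.insert(2, "admission_id", [f"a{i:0{width}d}" for i in range(n_stays)])

    # outcome
    rng_label = _child_rng(config.seed, 1)
    eta = config.outcome_model.linear_predictor(stays)
    true_risk = expit(eta)
    stays["label"] = (rng_label.random(n_stays) < true_risk).astype(int)

    rng_los = _child_rng(config.seed, 2)
    stays["los_hours"] = np.round(
        rng_los.lognormal(config.los_meanlog, config.los_sdlog, n_stays), 1
    )

    stays = stays[STAY_COLUMNS]

    # observations
    rng_obs = _child_rng(config.seed, 3)
    obs_frames = []
    stay_ids = stays["stay_id"].to_numpy()
    for var in VARIABLES:
        spec = config.missingness_profile[var]
        if spec.p_none >= 1.0:
            continue
        present = rng_obs.random(n_stays) >= spec.p_none
        idx_present = np.nonzero(present)[0]
        if idx_present.size == 0:
            continue
        hour_mask = rng_obs.random((idx_present.size, 48)) < spec.p_hour
        # a stay that measures the variable at all has >= 1 observation
        empty = ~hour_mask.any(axis=1)
        if empty.any():
            forced = rng_obs.integers(0, 48, int(empty.sum()))
            hour_mask[np.nonzero(empty)[0], forced] = True
        rows, hours = np.nonzero(hour_mask)
        values = np.round(
            rng_obs.normal(spec.value_mean, spec.value_sd, rows.size), 3
        )
        obs_frames.append(
            pd.DataFrame(
                {
                    "stay_id": stay_ids[idx_present[rows]],
                    "variable_id": var,
                    "hour": hours.astype(int),
                    "value": values,
                }
            )
        )
    if obs_frames:
        observations = pd.concat(obs_frames, ignore_index=True)
        observations = observations.sort_values(
            ["stay_id", "variable_id", "hour"], kind="stable"
        ).reset_index(drop=True)
    else:
        observations = pd.DataFrame(columns=OBS_COLUMNS)

    # diagnoses
    rng_dx = _child_rng(config.seed, 4)
    dx_rows = []
    cm = config.charlson_model
    if cm is not None:
        eta_centered = eta - config.outcome_model.intercept
        for factor in cm.factors():
            prev = cm.prevalence[factor]
            assoc = cm.association.get(factor, 0.0)
            p = expit(logit(prev) + assoc * eta_centered)
            present = rng_dx.random(n_stays) < p
            idx = np.nonzero(present)[0]
            if idx.size == 0:
                continue
            codes = np.asarray(cm.codes[factor], dtype=object)
            code_pick = codes[rng_dx.integers(0, len(codes), idx.size)]
            days = rng_dx.integers(0, cm.max_days_before, idx.size)
            dx_rows.append(
                pd.DataFrame(
                    {
                        "stay_id": stay_ids[idx],
                        "code": code_pick,
                        "days_before_admission": days.astype(int),
                    }
                )
            )
        if cm.unmapped_rate > 0:
            present = rng_dx.random(n_stays) < cm.unmapped_rate
            idx = np.nonzero(present)[0]
            if idx.size:
                dx_rows.append(
                    pd.DataFrame(
                        {
                            "stay_id": stay_ids[idx],
                            "code": "UNMAPPED",
                            "days_before_admission": rng_dx.integers(
                                0, cm.max_days_before, idx.size
                            ).astype(int),
                        }
                    )
                )
    if dx_rows:
        diagnoses = pd.concat(dx_rows, ignore_index=True)
        diagnoses = diagnoses.sort_values(
            ["stay_id", "code", "days_before_admission"], kind="stable"
        ).reset_index(drop=True)
    else:
        diagnoses = pd.DataFrame(columns=DX_COLUMNS)

    return Cohort(
        stays=stays,
        observations=observations,
        diagnoses=diagnoses,
        provenance="synthetic",
        config_digest=config.digest(),
        true_risk=pd.Series(true_risk, index=stays["stay_id"], name="true_risk"),
    )


def emit_predictions(cohort: Cohort, config: GeneratorConfig) -> pd.Series:
    """Emit per-stay risk scores from the latent true risk, with optional
    group-specific bias.

    ``score = invlogit(logit(true_risk) + shift(group) + N(0, sd(group)))``

    With all shifts and noise at zero the score equals the true risk exactly.
    Raises :class:`UnsupportedInputError` on cohorts without latent risks
    (e.g. loaded from files).
    """
    if cohort.true_risk is None:
        raise UnsupportedInputError(
            "cohort carries no latent true risk; emit_predictions requires a "
            "generated cohort"
        )
    stays = cohort.stays
    eta = logit(np.clip(cohort.true_risk.to_numpy(dtype=float), 1e-12, 1 - 1e-12))

    shift = np.zeros(len(stays))
    for attr, levels in config.miscalibration_shifts.items():
        shift += stays[attr].map(lambda lvl: levels.get(lvl, 0.0)).to_numpy(dtype=float)

    var = np.zeros(len(stays))
    for attr, levels in config.noise_degradation.items():
        sd = stays[attr].map(lambda lvl: levels.get(lvl, 0.0)).to_numpy(dtype=float)
        var += sd**2
    sd_total = np.sqrt(var)

    rng = _child_rng(config.seed, 5)
    noise = rng.standard_normal(len(stays)) * sd_total
    scores = expit(eta + shift + noise)
    scores = np.clip(scores, 1e-9, 1.0 - 1e-9)
    return pd.Series(scores, index=stays["stay_id"].to_numpy(), name="score")
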