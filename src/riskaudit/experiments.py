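"""Bias-injection and parameter-recovery experiments.

These replicate studies quantify the operating characteristics of the
fairness statistics on synthetic cohorts where the ground truth is known:

* :func:`citl_shift_recovery` — inject a log-odds shift into one group's
  scores and count how often calibration-in-the-large pins it (shifted
  group's CI excludes zero on the correct side) without false-flagging the
  unshifted group.
* :func:`parity_operating_characteristics` — degrade one gender's scores
  with log-odds noise while all groups share one event rate (the
  similar-rates scenario), then measure the parity flag's sensitivity on
  the degraded attribute and its false-flag rate on untouched attributes.

The scenario cohorts put all outcome heterogeneity on age, which is
independent of gender, ethnicity and insurance: every audit attribute then
has identical expected event rates and score distributions across its
levels, so any systematic performance difference is attributable to the
injected bias alone.  Observations are not generated (they feed no fairness
statistic), which keeps replicate loops fast.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logit

from ._util import stable_seed
from .fairness import calibration_in_the_large, classification_parity
from .metrics import BootstrapConfig
from .schema import DEMOGRAPHIC_ATTRIBUTES, VARIABLES
from .synthetic import (
    GeneratorConfig,
    MissingnessSpec,
    OutcomeModel,
    calibrate_intercept,
    emit_predictions,
    generate_cohort,
)

__all__ = [
    "scenario_config",
    "citl_shift_recovery",
    "parity_operating_characteristics",
    "RecoveryResult",
]

# development-cohort age structure and per-band mortality gradient
_AGE_MARGINAL = {"18-29": 0.043, "30-49": 0.148, "50-69": 0.367, "70-89": 0.389, "90+": 0.053}
_AGE_RATES = {"18-29": 0.056, "30-49": 0.093, "50-69": 0.111, "70-89": 0.165, "90+": 0.218}
_POOLED_RATE = 0.13


def scenario_config(
    n_stays: int,
    seed: int,
    shift_level: tuple[str, str, float] | None = None,
    noise_level: tuple[str, str, float] | None = None,
) -> GeneratorConfig:
    """Cohort configuration for injection experiments.

    Equal gender split, development-cohort ethnicity/insurance marginals,
    age-only outcome offsets (pooled event rate 13%), no observations.
    ``shift_level``/``noise_level`` are ``(attribute, level, value)`` tuples
    injecting a score log-odds shift or score noise SD for one group.
    """
    marginals = {
        "gender": {"Female": 0.5, "Male": 0.5},
        "ethnicity": {"Asian": 0.024, "Black": 0.082, "Hispanic": 0.031,
                      "White": 0.710, "Other": 0.153},
        "insurance": {"Medicare": 0.571, "Medicaid": 0.082, "Private": 0.310,
                      "Other": 0.037},
        "age_band": dict(_AGE_MARGINAL),
    }
    offsets = {
        "age_band": {b: float(logit(r) - logit(_POOLED_RATE)) for b, r in _AGE_RATES.items()}
    }
    intercept = calibrate_intercept(_POOLED_RATE, marginals, offsets)
    shifts = {}
    if shift_level is not None:
        attr, lvl, val = shift_level
        shifts = {attr: {lvl: float(val)}}
    noise = {}
    if noise_level is not None:
        attr, lvl, val = noise_level
        noise = {attr: {lvl: float(val)}}
    return GeneratorConfig(
        n_stays=n_stays,
        demographic_marginals=marginals,
        outcome_model=OutcomeModel(intercept=intercept, offsets=offsets),
        miscalibration_shifts=shifts,
        noise_degradation=noise,
        missingness_profile={v: MissingnessSpec(p_none=1.0, p_hour=0.0) for v in VARIABLES},
        multi_stay_fraction=0.0,
        seed=seed,
    )


@dataclass
class RecoveryResult:
    """Outcome of a replicate study."""

    n_replicates: int
    n_success: int
    details: list = field(default_factory=list)

    @property
    def success_rate(self) -> float:
        return self.n_success / self.n_replicates


def citl_shift_recovery(
    n_per_group: int = 20_000,
    shift: float = -0.5,
    n_replicates: int = 100,
    bootstrap_k: int = 1_000,
    seed: int = 0,
    biased_level: str = "Female",
) -> RecoveryResult:
    """Replicate study of miscalibration detection by calibration-in-the-large.

    Each replicate generates a fresh two-group cohort (``n_per_group`` stays
    per gender), applies ``shift`` log-odds to the biased group's scores and
    runs the group-wise CITL assessment.  A replicate is a success when the
    biased group's interval lies entirely on the shift's side of zero while
    the unbiased group's interval covers zero.
    """
    side = np.sign(shift)
    successes = 0
    details = []
    for rep in range(n_replicates):
        cfg = scenario_config(
            2 * n_per_group,
            seed=stable_seed(seed, "citl-recovery", rep),
            shift_level=("gender", biased_level, shift),
        )
        cohort = generate_cohort(cfg)
        scores = emit_predictions(cohort, cfg).to_numpy()
        labels = cohort.stays["label"].to_numpy(dtype=float)
        bcfg = BootstrapConfig(
            n_resamples=bootstrap_k, seed=stable_seed(seed, "citl-boot", rep)
        )
        ests = calibration_in_the_large(scores, labels, cohort.stays[["gender"]], bcfg)
        by_level = {e.level: e for e in ests}
        biased = by_level[biased_level]
        others = [e for e in ests if e.level != biased_level]
        detected = biased.assessable and (
            (side < 0 and biased.ci_hi < 0.0) or (side > 0 and biased.ci_lo > 0.0)
        )
        clean = all(o.assessable and o.ci_lo <= 0.0 <= o.ci_hi for o in others)
        successes += int(detected and clean)
        details.append(
            {
                "replicate": rep,
                "detected": bool(detected),
                "clean": bool(clean),
                "biased_ci": (biased.ci_lo, biased.ci_hi),
            }
        )
    return RecoveryResult(n_replicates=n_replicates, n_success=successes, details=details)


def parity_operating_characteristics(
    n_per_group: int = 10_000,
    noise_sd: float = 2.0,
    n_replicates: int = 100,
    bootstrap_k: int = 200,
    seed: int = 0,
    biased_level: str = "Female",
) -> dict:
    """Replicate study of the parity flag under similar-rates bias injection.

    One gender's scores are degraded with log-odds noise; ethnicity and
    insurance are left untouched.  Returns sensitivity (fraction of
    replicates flagging the degraded attribute), the false-flag rate
    (fraction of pairwise findings on untouched attributes with a
    ``parity_violation`` verdict, pooled over replicates) and the per-
    replicate details.
    """
    hits = 0
    false_flags = 0
    clean_findings = 0
    details = []
    unbiased_attrs = tuple(a for a in DEMOGRAPHIC_ATTRIBUTES if a != "gender")
    for rep in range(n_replicates):
        cfg = scenario_config(
            2 * n_per_group,
            seed=stable_seed(seed, "parity-recovery", rep),
            noise_level=("gender", biased_level, noise_sd),
        )
        cohort = generate_cohort(cfg)
        scores = emit_predictions(cohort, cfg).to_numpy()
        labels = cohort.stays["label"].to_numpy(dtype=float)
        bcfg = BootstrapConfig(
            n_resamples=bootstrap_k, seed=stable_seed(seed, "parity-boot", rep)
        )
        _, findings = classification_parity(
            scores, labels, cohort.stays[list(DEMOGRAPHIC_ATTRIBUTES)], bcfg
        )
        flagged = any(
            f.attribute == "gender" and f.verdict == "parity_violation" for f in findings
        )
        others = [f for f in findings if f.attribute in unbiased_attrs]
        n_false = sum(1 for f in others if f.verdict == "parity_violation")
        hits += int(flagged)
        false_flags += n_false
        clean_findings += len(others)
        details.append({"replicate": rep, "flagged": bool(flagged), "n_false": n_false})
    return {
        "sensitivity": hits / n_replicates,
        "false_flag_rate": false_flags / max(clean_findings, 1),
        "n_replicates": n_replicates,
        "n_unbiased_findings": clean_findings,
        "details": details,
    }
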