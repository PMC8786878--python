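"""Bundled default generator configurations.

Two presets emulate the published characteristics of the two ICU cohorts the
audit framework was designed around:

* ``mimic_like`` — a large single-center development cohort (pooled IHM rate
  13.23%, mostly White, Medicare-heavy, older age distribution).
* ``starr_like`` — a smaller, more ethnically diverse external cohort
  (pooled IHM rate 10.18%) that also carries pre-admission diagnosis codes,
  so comorbidity analyses are only possible on this preset, mirroring the
  fact that ICU-only databases cannot support Charlson scoring.

Marginals are the exact patient-share proportions of the cohort tables;
per-level outcome offsets are the log-odds differences between each level's
published IHM rate and the pooled rate, with the intercept solved so the
model's implied pooled rate matches the published pooled rate exactly.
The per-variable missingness parameters are derived from the published
coverage table: ``p_none`` is the fraction of stays with no data at all and
``p_hour`` is chosen so the expected number of covered hours matches the
published per-stay average.  Hour-to-hour correlation is NOT modelled, so
the "full coverage" share of a preset cohort is below the published one
(see docs/methods.md).
"""

from __future__ import annotations

from scipy.special import logit

from .fairness import CharlsonConfig
from .synthetic import (
    CharlsonGenModel,
    GeneratorConfig,
    MissingnessSpec,
    OutcomeModel,
    calibrate_intercept,
)

__all__ = [
    "mimic_like_config",
    "starr_like_config",
    "synthetic_charlson_config",
    "SYNTHETIC_CHARLSON_FACTORS",
]

# patient counts per level, published cohort tables
_MIMIC_COUNTS = {
    "gender": {"Female": 8090, "Male": 10004},
    "age_band": {"18-29": 782, "30-49": 2680, "50-69": 6636, "70-89": 7043, "90+": 953},
    "ethnicity": {"Asian": 437, "Black": 1480, "Hispanic": 568, "White": 12851, "Other": 2758},
    "insurance": {"Medicare": 10337, "Medicaid": 1489, "Private": 5601, "Other": 667},
}
_MIMIC_RATES = {  # in-hospital mortality %, per level
    "gender": {"Female": 13.5, "Male": 13.0},
    "age_band": {"18-29": 5.6, "30-49": 9.3, "50-69": 11.1, "70-89": 16.5, "90+": 21.8},
    "ethnicity": {"Asian": 13.8, "Black": 9.2, "Hispanic": 8.1, "White": 12.9, "Other": 18.7},
    "insurance": {"Medicare": 15.3, "Medicaid": 10.3, "Private": 10.2, "Other": 11.6},
}
_MIMIC_TOTAL_RATE = 0.1323

_STARR_COUNTS = {
    "gender": {"Female": 2485, "Male": 3581},
    "age_band": {"18-29": 275, "30-49": 879, "50-69": 2660, "70-89": 2076, "90+": 176},
    "ethnicity": {"Asian": 837, "Black": 329, "Hispanic": 945, "White": 3199, "Other": 756},
    "insurance": {"Medicare": 3144, "Medicaid": 944, "Private": 1711, "Other": 267},
}
_STARR_RATES = {
    "gender": {"Female": 11.6, "Male": 9.2},
    "age_band": {"18-29": 7.2, "30-49": 8.8, "50-69": 9.1, "70-89": 11.7, "90+": 20.8},
    "ethnicity": {"Asian": 11.9, "Black": 9.3, "Hispanic": 11.4, "White": 8.7, "Other": 13.5},
    "insurance": {"Medicare": 10.5, "Medicaid": 10.3, "Private": 9.1, "Other": 12.1},
}
_STARR_TOTAL_RATE = 0.1018

# (pct_none, mean covered hours out of 48) per variable, published coverage table
_MIMIC_COVERAGE = {
    "capillary_refill_rate": (98.1, 0.2),
    "diastolic_blood_pressure": (1.2, 43.4),
    "fraction_inspired_oxygen": (70.5, 3.0),
    "gcs_eye_opening": (0.9, 14.8),
    "gcs_motor_response": (0.9, 14.8),
    "gcs_total": (41.8, 8.8),
    "gcs_verbal_response": (1.0, 14.8),
    "glucose": (0.1, 12.5),
    "heart_rate": (1.2, 44.4),
    "height": (81.0, 0.2),
    "mean_arterial_pressure": (1.2, 43.2),
    "oxygen_saturation": (0.7, 42.8),
    "respiratory_rate": (1.3, 43.7),
    "systolic_blood_pressure": (1.2, 43.4),
    "temperature": (2.0, 15.7),
    "weight": (27.0, 1.5),
    "ph": (17.3, 6.3),
}
_STARR_COVERAGE = {
    "capillary_refill_rate": (100.0, 0.0),
    "diastolic_blood_pressure": (11.0, 20.2),
    "fraction_inspired_oxygen": (43.5, 3.5),
    "gcs_eye_opening": (14.3, 6.7),
    "gcs_motor_response": (14.2, 7.2),
    "gcs_total": (14.0, 9.8),
    "gcs_verbal_response": (14.7, 5.6),
    "glucose": (9.8, 15.2),
    "heart_rate": (1.8, 45.8),
    "height": (9.7, 42.9),
    "mean_arterial_pressure": (11.0, 20.2),
    "oxygen_saturation": (1.7, 45.5),
    "respiratory_rate": (13.7, 38.1),
    "systolic_blood_pressure": (11.0, 20.2),
    "temperature": (3.8, 20.0),
    "weight": (4.8, 45.3),
    "ph": (22.2, 7.8),
}

# plausible marginal value distributions; carried for realism only
_VALUE_DIST = {
    "capillary_refill_rate": (0.2, 0.4),
    "diastolic_blood_pressure": (60.0, 12.0),
    "fraction_inspired_oxygen": (0.5, 0.2),
    "gcs_eye_opening": (3.5, 0.8),
    "gcs_motor_response": (5.5, 1.0),
    "gcs_total": (13.0, 3.0),
    "gcs_verbal_response": (4.0, 1.3),
    "glucose": (140.0, 45.0),
    "heart_rate": (85.0, 15.0),
    "height": (168.0, 10.0),
    "mean_arterial_pressure": (78.0, 14.0),
    "oxygen_saturation": (96.5, 2.5),
    "respiratory_rate": (19.0, 5.0),
    "systolic_blood_pressure": (120.0, 20.0),
    "temperature": (37.0, 0.7),
    "weight": (80.0, 20.0),
    "ph": (7.38, 0.07),
}


def _marginals(counts: dict) -> dict:
    return {
        attr: {lvl: c / sum(m.values()) for lvl, c in m.items()} for attr, m in counts.items()
    }


def _offsets(rates: dict, total_rate: float) -> dict:
    base = logit(total_rate)
    return {
        attr: {lvl: float(logit(r / 100.0) - base) for lvl, r in m.items()}
        for attr, m in rates.items()
    }


def _solve_p_hour(avg_present: float) -> float:
    """Per-hour probability whose expected covered hours per *present* stay,
    48q + (1-q)^48 (the trailing term is the guaranteed single observation
    when all hourly draws land empty), equals ``avg_present``."""
    from scipy.optimize import brentq

    if avg_present >= 48.0:
        return 1.0
    if avg_present <= 1.0:
        return 0.0
    f = lambda q: 48.0 * q + (1.0 - q) ** 48 - avg_present
    return float(brentq(f, 0.0, 1.0, xtol=1e-12))


def _missingness(coverage: dict) -> dict:
    profile = {}
    for var, (pct_none, avg_hours) in coverage.items():
        p_none = pct_none / 100.0
        p_hour = 0.0 if p_none >= 1.0 else _solve_p_hour(avg_hours / (1.0 - p_none))
        mean, sd = _VALUE_DIST[var]
        profile[var] = MissingnessSpec(p_none=p_none, p_hour=p_hour, value_mean=mean, value_sd=sd)
    return profile


# ---------------------------------------------------------------------------
# synthetic Charlson table: 12 factors, weights 1,1,1,1,1,1,2,2,2,3,6,6.
# Codes are synthetic placeholders; real ICD mappings are user-supplied.
# ---------------------------------------------------------------------------

SYNTHETIC_CHARLSON_FACTORS: dict[str, int] = {
    "myocardial_infarction": 1,
    "congestive_heart_failure": 1,
    "chronic_pulmonary_disease": 1,
    "diabetes": 1,
    "mild_liver_disease": 1,
    "dementia": 1,
    "renal_disease": 2,
    "malignancy": 2,
    "hemiplegia": 2,
    "severe_liver_disease": 3,
    "metastatic_solid_tumor": 6,
    "aids": 6,
}

_FACTOR_PREVALENCE = {
    "myocardial_infarction": 0.10,
    "congestive_heart_failure": 0.16,
    "chronic_pulmonary_disease": 0.18,
    "diabetes": 0.22,
    "mild_liver_disease": 0.05,
    "dementia": 0.07,
    "renal_disease": 0.13,
    "malignancy": 0.10,
    "hemiplegia": 0.03,
    "severe_liver_disease": 0.02,
    "metastatic_solid_tumor": 0.05,
    "aids": 0.01,
}
_FACTOR_ASSOCIATION = {  # slope on centred outcome log-odds
    "myocardial_infarction": 0.4,
    "congestive_heart_failure": 0.5,
    "chronic_pulmonary_disease": 0.3,
    "diabetes": 0.25,
    "mild_liver_disease": 0.3,
    "dementia": 0.35,
    "renal_disease": 0.5,
    "malignancy": 0.45,
    "hemiplegia": 0.4,
    "severe_liver_disease": 0.6,
    "metastatic_solid_tumor": 0.8,
    "aids": 0.5,
}


def _factor_codes() -> dict[str, tuple[str, ...]]:
    # two synthetic codes per factor so code-to-factor dedup is exercised
    return {f: (f"SYN:{f}:1", f"SYN:{f}:2") for f in SYNTHETIC_CHARLSON_FACTORS}


def synthetic_charlson_config(lookback_days: int = 730) -> CharlsonConfig:
    """The bundled 12-factor synthetic Charlson code table."""
    mapping = {}
    for factor, weight in SYNTHETIC_CHARLSON_FACTORS.items():
        for code in _factor_codes()[factor]:
            mapping[code] = (factor, weight)
    return CharlsonConfig(mapping=mapping, lookback_days=lookback_days)


def _charlson_gen_model() -> CharlsonGenModel:
    return CharlsonGenModel(
        prevalence=dict(_FACTOR_PREVALENCE),
        association=dict(_FACTOR_ASSOCIATION),
        codes=_factor_codes(),
    )


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------


def mimic_like_config(n_stays: int = 21339, seed: int = 0, **overrides) -> GeneratorConfig:
    """Development-cohort preset (no diagnosis data)."""
    marginals = _marginals(_MIMIC_COUNTS)
    offsets = _offsets(_MIMIC_RATES, _MIMIC_TOTAL_RATE)
    intercept = calibrate_intercept(_MIMIC_TOTAL_RATE, marginals, offsets)
    cfg = GeneratorConfig(
        n_stays=n_stays,
        demographic_marginals=marginals,
        outcome_model=OutcomeModel(intercept=intercept, offsets=offsets),
        missingness_profile=_missingness(_MIMIC_COVERAGE),
        charlson_model=None,
        multi_stay_fraction=0.15,
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    cfg.validate()
    return cfg


def starr_like_config(n_stays: int = 6407, seed: int = 0, **overrides) -> GeneratorConfig:
    """External-cohort preset (carries synthetic diagnosis codes)."""
    marginals = _marginals(_STARR_COUNTS)
    offsets = _offsets(_STARR_RATES, _STARR_TOTAL_RATE)
    intercept = calibrate_intercept(_STARR_TOTAL_RATE, marginals, offsets)
    cfg = GeneratorConfig(
        n_stays=n_stays,
        demographic_marginals=marginals,
        outcome_model=OutcomeModel(intercept=intercept, offsets=offsets),
        missingness_profile=_missingness(_STARR_COVERAGE),
        charlson_model=_charlson_gen_model(),
        multi_stay_fraction=0.05,
        seed=seed,
    )
    for k, v in overrides.items():
        setattr(cfg, k, v)
    cfg.validate()
    return cfg
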