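"""Shared fixtures: toy stay builders and reusable generated cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from riskaudit import Cohort, StayRecord, generate_cohort, mimic_like_config
from riskaudit.schema import VARIABLES
from riskaudit.synthetic import GeneratorConfig, MissingnessSpec


def make_stay(
    stay_id: str,
    *,
    patient_id: str | None = None,
    admission_id: str | None = None,
    age: int = 60,
    gender: str = "Female",
    ethnicity: str = "White",
    insurance: str = "Medicare",
    label: int = 0,
    los_hours: float = 72.0,
    observations=(("heart_rate", 0, 80.0),),
    diagnoses=(),
) -> StayRecord:
    """One ICU stay with sensible defaults; eligible unless overridden."""
    return StayRecord(
        stay_id=stay_id,
        patient_id=patient_id or f"pat-{stay_id}",
        admission_id=admission_id,
        age=age,
        gender=gender,
        ethnicity=ethnicity,
        insurance=insurance,
        label=label,
        los_hours=los_hours,
        observations=observations,
        diagnoses=diagnoses,
    )


def obs_free(config: GeneratorConfig) -> GeneratorConfig:
    """Disable observation generation (keeps the 17-variable catalog); used
    by tests whose statistics do not read observations."""
    config.missingness_profile = {
        v: MissingnessSpec(p_none=1.0, p_hour=0.0) for v in VARIABLES
    }
    return config


def light_obs(config: GeneratorConfig) -> GeneratorConfig:
    """Minimal observation structure (one guaranteed heart-rate point per
    stay) so cohorts survive the observation exclusion rule cheaply."""
    profile = {v: MissingnessSpec(p_none=1.0, p_hour=0.0) for v in VARIABLES}
    profile["heart_rate"] = MissingnessSpec(p_none=0.0, p_hour=0.0, value_mean=85, value_sd=15)
    config.missingness_profile = profile
    return config


@pytest.fixture(scope="session")
def dev_config():
    return mimic_like_config(n_stays=4000, seed=11)


@pytest.fixture(scope="session")
def dev_cohort(dev_config) -> Cohort:
    """A small development-style cohort with full observation structure."""
    return generate_cohort(dev_config)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
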