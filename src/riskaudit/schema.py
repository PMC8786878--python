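"""Column schemas, categorical levels and the physiological variable catalog.

The cohort container is a trio of plain tables (stays, hourly observations,
dated diagnoses).  Everything downstream keys on the column names and level
sets defined here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# -- file schemas -----------------------------------------------------------

STAY_COLUMNS = [
    "stay_id",
    "patient_id",
    "admission_id",
    "age",
    "gender",
    "ethnicity",
    "insurance",
    "label",
    "los_hours",
]
OBS_COLUMNS = ["stay_id", "variable_id", "hour", "value"]
DX_COLUMNS = ["stay_id", "code", "days_before_admission"]

# -- demographic attributes -------------------------------------------------

GENDER_LEVELS = ("Female", "Male")
ETHNICITY_LEVELS = ("Asian", "Black", "Hispanic", "White", "Other")
INSURANCE_LEVELS = ("Medicare", "Medicaid", "Private", "Other")

#: Attributes used for fairness stratification.
DEMOGRAPHIC_ATTRIBUTES = ("gender", "ethnicity", "insurance")

ATTRIBUTE_LEVELS: dict[str, tuple[str, ...]] = {
    "gender": GENDER_LEVELS,
    "ethnicity": ETHNICITY_LEVELS,
    "insurance": INSURANCE_LEVELS,
}

# -- age bands --------------------------------------------------------------

#: (label, low, high) inclusive age bands; the under-18 band exists only so
#: pre-exclusion cohorts can be tabulated, the audit cohorts are adults.
AGE_BANDS = (
    ("0-17", 0, 17),
    ("18-29", 18, 29),
    ("30-49", 30, 49),
    ("50-69", 50, 69),
    ("70-89", 70, 89),
    ("90+", 90, 200),
)
ADULT_AGE_BAND_LEVELS = tuple(label for label, lo, _ in AGE_BANDS if lo >= 18)

ATTRIBUTE_LEVELS_WITH_AGE = dict(ATTRIBUTE_LEVELS, age_band=ADULT_AGE_BAND_LEVELS)


def age_band(ages) -> pd.Series:
    """Map ages (years) to band labels.

    Parameters
    ----------
    ages : array-like of int
        Ages in whole years, non-negative.
    """
    ages = pd.Series(np.asarray(ages, dtype=float))
    edges = [lo for _, lo, _ in AGE_BANDS] + [np.inf]
    labels = [label for label, _, _ in AGE_BANDS]
    return pd.cut(ages, bins=edges, labels=labels, right=False).astype(str)


# -- physiological variable catalog (17 variables) --------------------------

VARIABLES = (
    "capillary_refill_rate",
    "diastolic_blood_pressure",
    "fraction_inspired_oxygen",
    "gcs_eye_opening",
    "gcs_motor_response",
    "gcs_total",
    "gcs_verbal_response",
    "glucose",
    "heart_rate",
    "height",
    "mean_arterial_pressure",
    "oxygen_saturation",
    "respiratory_rate",
    "systolic_blood_pressure",
    "temperature",
    "weight",
    "ph",
)
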