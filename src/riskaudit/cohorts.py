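"""Benchmark-cohort exclusion rules and descriptive screening statistics.

The screening task of the audit: apply the benchmark eligibility rules
(adults, single ICU stay per hospital admission, length of stay over the
analysis window, at least one observation inside it), then tabulate the
demographic/outcome distribution and the per-variable data missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import SchemaError
from .schema import (
    ATTRIBUTE_LEVELS,
    AGE_BANDS,
    DEMOGRAPHIC_ATTRIBUTES,
    VARIABLES,
    age_band,
)
from .synthetic import Cohort

__all__ = [
    "CohortConfig",
    "ExclusionLog",
    "apply_exclusions",
    "demographics_table",
    "missingness_profile",
]

#: fixed order in which exclusion rules claim a stay
EXCLUSION_RULES = ("age", "multi_stay", "los", "observations")


@dataclass(frozen=True)
class CohortConfig:
    """Eligibility parameters: analysis window, adult age cut-off and the
    minimum length of stay (strict inequality: a stay of exactly
    ``min_los_hours`` is excluded)."""

    window_hours: int = 48
    min_age: int = 18
    min_los_hours: float = 48.0

    def __post_init__(self) -> None:
        if self.window_hours <= 0 or self.min_age <= 0 or self.min_los_hours <= 0:
            raise ValueError("all CohortConfig fields must be positive")


@dataclass
class ExclusionLog:
    """Per-rule exclusion counts; each stay is counted under the first rule
    it violates, in the fixed order age -> multi-stay -> LOS -> observations."""

    n_input: int = 0
    n_output: int = 0
    counts: dict = field(default_factory=lambda: {r: 0 for r in EXCLUSION_RULES})

    def to_dict(self) -> dict:
        return {"n_input": self.n_input, "n_output": self.n_output, "counts": dict(self.counts)}


def apply_exclusions(cohort: Cohort, config: CohortConfig = CohortConfig()):
    """Return the eligible sub-cohort and an :class:`ExclusionLog`.

    Eligibility requires: age >= ``min_age``; the stay's hospital admission
    contains no other ICU stay; ``los_hours`` strictly greater than
    ``min_los_hours``; and at least one observation inside the analysis
    window.  Rule predicates are evaluated on the *input* cohort, so two
    stays sharing an admission are both excluded even if one of them also
    fails an earlier rule.  Idempotent: an all-eligible cohort passes
    through unchanged.
    """
    stays = cohort.stays
    log = ExclusionLog(n_input=len(stays))
    if len(stays) == 0:
        return cohort, log

    young = stays["age"].to_numpy() < config.min_age
    adm_counts = stays["admission_id"].map(stays["admission_id"].value_counts())
    multi = adm_counts.to_numpy() > 1
    short = stays["los_hours"].to_numpy() <= config.min_los_hours

    obs = cohort.observations
    in_window = obs[(obs["hour"] >= 0) & (obs["hour"] < config.window_hours)]
    has_obs = stays["stay_id"].isin(in_window["stay_id"].unique()).to_numpy()
    no_obs = ~has_obs

    rule_masks = {"age": young, "multi_stay": multi, "los": short, "observations": no_obs}
    claimed = np.zeros(len(stays), dtype=bool)
    for rule in EXCLUSION_RULES:
        hits = rule_masks[rule] & ~claimed
        log.counts[rule] = int(hits.sum())
        claimed |= rule_masks[rule]

    keep = stays.loc[~claimed, "stay_id"]
    out = cohort.subset(keep)
    log.n_output = len(out)
    return out, log


# ---------------------------------------------------------------------------
# descriptive tables
# ---------------------------------------------------------------------------

_TABLE_ATTRIBUTES = ("gender", "age_band") + tuple(
    a for a in DEMOGRAPHIC_ATTRIBUTES if a != "gender"
)


def demographics_table(cohort: Cohort) -> pd.DataFrame:
    """Demographic/outcome distribution table.

    One row per level of gender, age band, ethnicity and insurance plus a
    totals row, with patient counts (distinct ``patient_id`` within the
    level), stay counts, their percentages, and the in-hospital mortality
    rate (%) over stays.  Raises :class:`SchemaError` on unknown categorical
    levels.
    """
    stays = cohort.stays
    if len(stays) == 0:
        raise ValueError("demographics_table requires a non-empty cohort")
    for attr in DEMOGRAPHIC_ATTRIBUTES:
        unknown = set(stays[attr].unique()) - set(ATTRIBUTE_LEVELS[attr])
        if unknown:
            raise SchemaError(f"unknown {attr} level(s): {sorted(unknown)!r}")

    work = stays.copy()
    work["age_band"] = age_band(work["age"]).to_numpy()
    n_stays = len(work)
    n_patients = work["patient_id"].nunique()

    rows = []
    band_levels = tuple(label for label, _, _ in AGE_BANDS)
    level_sets = dict(ATTRIBUTE_LEVELS, age_band=band_levels)
    for attr in _TABLE_ATTRIBUTES:
        present = work.groupby(attr, sort=False)
        stats = {
            lvl: (
                int(g["patient_id"].nunique()),
                len(g),
                float(100.0 * g["label"].mean()),
            )
            for lvl, g in present
        }
        for lvl in level_sets[attr]:
            pat, stay, rate = stats.get(lvl, (0, 0, float("nan")))
            rows.append(
                {
                    "attribute": attr,
                    "level": lvl,
                    "patients": pat,
                    "patients_pct": 100.0 * pat / n_patients,
                    "stays": stay,
                    "stays_pct": 100.0 * stay / n_stays,
                    "ihm_rate_pct": rate,
                }
            )
    rows.append(
        {
            "attribute": "total",
            "level": "all",
            "patients": int(n_patients),
            "patients_pct": 100.0,
            "stays": int(n_stays),
            "stays_pct": 100.0,
            "ihm_rate_pct": float(100.0 * work["label"].mean()),
        }
    )
    return pd.DataFrame(rows)


def missingness_profile(
    cohort: Cohort,
    config: CohortConfig = CohortConfig(),
    variables: tuple[str, ...] = VARIABLES,
) -> pd.DataFrame:
    """Per-variable data-coverage profile over the analysis window.

    For every catalog variable: ``pct_none`` — % of stays with no
    observation at all; ``pct_full`` — % of stays with at least one
    observation in *every* hour bucket; ``avg_points`` — mean number of hour
    buckets covered (max ``window_hours``), with ``avg_points_pct`` the same
    as % of the window.  A stay contributes one countable point per hour
    bucket holding at least one observation.
    """
    stays = cohort.stays
    if len(stays) == 0:
        raise ValueError("missingness_profile requires a non-empty cohort")
    n = len(stays)
    w = config.window_hours

    obs = cohort.observations
    obs = obs[(obs["hour"] >= 0) & (obs["hour"] < w)]
    covered = (
        obs.drop_duplicates(["stay_id", "variable_id", "hour"])
        .groupby(["variable_id", "stay_id"], sort=False)
        .size()
    )

    rows = []
    for var in variables:
        if var in covered.index.get_level_values(0):
            per_stay = covered.loc[var]
            n_any = len(per_stay)
            n_full = int((per_stay == w).sum())
            total_points = int(per_stay.sum())
        else:
            n_any = n_full = total_points = 0
        avg = total_points / n
        rows.append(
            {
                "variable_id": var,
                "pct_none": 100.0 * (n - n_any) / n,
                "pct_full": 100.0 * n_full / n,
                "avg_points": avg,
                "avg_points_pct": 100.0 * avg / w,
            }
        )
    return pd.DataFrame(rows)
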