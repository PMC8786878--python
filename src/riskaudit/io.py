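"""Delimited-text persistence for cohorts, predictions and reports.

A cohort is three UTF-8 CSV files with mandatory header rows — ``stays.csv``,
``observations.csv``, ``diagnoses.csv`` — missing values encoded as empty
fields.  The latent true risk of synthetic cohorts is deliberately not part
of the stays schema, so a write/read round-trip cannot leak it.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .exceptions import SchemaError
from .schema import DX_COLUMNS, OBS_COLUMNS, STAY_COLUMNS
from .synthetic import Cohort

__all__ = ["write_cohort", "read_cohort", "write_predictions", "read_predictions",
           "write_json", "read_json"]

_FILES = {
    "stays": ("stays.csv", STAY_COLUMNS),
    "observations": ("observations.csv", OBS_COLUMNS),
    "diagnoses": ("diagnoses.csv", DX_COLUMNS),
}


def write_cohort(cohort: Cohort, directory) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for part, (fname, cols) in _FILES.items():
        df = getattr(cohort, part)
        df.to_csv(directory / fname, index=False, columns=cols)
    return directory


def read_cohort(directory, provenance: str | None = None) -> Cohort:
    """Load a cohort from its three CSV files.

    Raises :class:`SchemaError` naming the file and the missing column on a
    header mismatch.  Loaded cohorts carry no latent true risk.
    """
    directory = Path(directory)
    frames = {}
    for part, (fname, cols) in _FILES.items():
        path = directory / fname
        if not path.exists():
            raise SchemaError(f"missing cohort file: {path}")
        df = pd.read_csv(path)
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {missing}")
        frames[part] = df[cols]
    return Cohort(
        stays=frames["stays"],
        observations=frames["observations"],
        diagnoses=frames["diagnoses"],
        provenance=provenance if provenance is not None else str(directory),
        config_digest="",
        true_risk=None,
    )


def write_predictions(scores: pd.Series, path) -> Path:
    """Write per-stay risk scores as a two-column CSV (stay_id, score)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"stay_id": scores.index, "score": scores.to_numpy()}).to_csv(
        path, index=False
    )
    return path


def read_predictions(path) -> pd.Series:
    df = pd.read_csv(path)
    for col in ("stay_id", "score"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    return pd.Series(df["score"].to_numpy(), index=df["stay_id"].to_numpy(), name="score")


def write_json(obj, path) -> Path:
    """Canonical JSON writer (sorted keys, fixed separators) so identical
    payloads serialize to identical bytes."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return path


def read_json(path):
    return json.loads(Path(path).read_text(encoding="utf-8"))
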