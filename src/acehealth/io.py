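"""Cohort (de)serialization: CSV with a YAML sidecar schema.

Cohorts travel as comma-separated text with a header row; an empty field
means missing. The sidecar records column classes and dtypes so a reader
does not need to guess.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .config import (
    ACE_COLUMNS,
    BIOMARKER_COLUMNS,
    COVARIATE_COLUMNS,
    DESIGN_COLUMNS,
    OUTCOMES,
)

__all__ = ["write_cohort", "read_cohort", "schema_path"]


def _column_class(name: str) -> str:
    if name in DESIGN_COLUMNS:
        return "design"
    if name in ACE_COLUMNS:
        return "ace"
    if name in COVARIATE_COLUMNS:
        return "covariate"
    if name in BIOMARKER_COLUMNS:
        return "biomarker"
    if name in OUTCOMES:
        return "outcome"
    if name in ("race", "sex", "age", "pregnant", "pid"):
        return "demographic"
    return "other"


def schema_path(path: str | Path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".schema.yaml")


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort CSV plus its sidecar schema file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(path, index=False, na_rep="")
    schema = {
        "format": "acehealth-cohort/1",
        "missing": "",
        "columns": [
            {"name": c, "dtype": str(cohort[c].dtype), "class": _column_class(c)}
            for c in cohort.columns
        ],
    }
    with open(schema_path(path), "w") as fh:
        yaml.safe_dump(schema, fh, sort_keys=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV; uses the sidecar schema when present."""
    path = Path(path)
    side = schema_path(path)
    if side.exists():
        with open(side) as fh:
            schema = yaml.safe_load(fh)
        names = [c["name"] for c in schema["columns"]]
        frame = pd.read_csv(path)
        missing_cols = set(names) - set(frame.columns)
        if missing_cols:
            raise ValueError(f"cohort file missing schema columns: {sorted(missing_cols)}")
        return frame[names]
    return pd.read_csv(path)
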