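"""Cohort CSV and model JSON I/O with strict validation."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ranges import NormativeModel
from .simulate import COHORT_COLUMNS

__all__ = ["CohortValidationError", "read_cohort", "validate_cohort",
           "write_cohort", "write_model", "read_model", "model_json"]


class CohortValidationError(ValueError):
    pass


def validate_cohort(df: pd.DataFrame, require_values: bool = True) -> pd.DataFrame:
    """Validate the long-format cohort schema; raises with row numbers."""
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortValidationError(f"missing columns: {missing}")
    extra = [c for c in df.columns if c not in COHORT_COLUMNS]
    if extra:
        raise CohortValidationError(f"unknown columns: {extra}")
    problems = []
    for col in ("age", "value") if require_values else ("age",):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna()].tolist()
        if bad:
            problems.append(f"non-numeric {col} at rows {bad[:10]}")
        df = df.assign(**{col: numeric})
    for col in ("sex", "hand"):
        codes = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[~codes.isin([0, 1])].tolist()
        if bad:
            problems.append(f"{col} not dummy-coded 0/1 at rows {bad[:10]}")
        df = df.assign(**{col: codes.astype("Int64")})
    if require_values and df[COHORT_COLUMNS].isna().any().any():
        bad = df.index[df[COHORT_COLUMNS].isna().any(axis=1)].tolist()
        problems.append(f"missing values at rows {bad[:10]}")
    if problems:
        raise CohortValidationError("; ".join(problems))
    dupes = df.duplicated(subset=["participant_id", "hand", "parameter"])
    if dupes.any():
        raise CohortValidationError(
            f"duplicate (participant_id, hand, parameter) at rows "
            f"{df.index[dupes].tolist()[:10]}")
    out = df.copy()
    out["sex"] = out["sex"].astype(int)
    out["hand"] = out["hand"].astype(int)
    out["age"] = out["age"].astype(float)
    if require_values:
        out["value"] = out["value"].astype(float)
    return out


def read_cohort(path, require_values: bool = True) -> pd.DataFrame:
    # pandas handles LF/CRLF transparently
    df = pd.read_csv(path, dtype={"participant_id": str, "parameter": str})
    return validate_cohort(df, require_values=require_values)


def write_cohort(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=COHORT_COLUMNS)


def model_json(nm: NormativeModel) -> str:
    """Canonical JSON serialization (sorted keys — byte-stable under a seed)."""
    return json.dumps(nm.to_dict(), sort_keys=True, indent=2)


def write_model(nm: NormativeModel, path) -> None:
    Path(path).write_text(model_json(nm) + "\n")


def read_model(path) -> NormativeModel:
    return NormativeModel.from_dict(json.loads(Path(path).read_text()))
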