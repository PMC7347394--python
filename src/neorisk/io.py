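"""Cohort CSV reading, writing and validation.

Dialect: UTF-8, comma separated, header row, one row per patient, booleans
as 0/1, enums as lowercase tokens, "." decimal point. Unknown columns are
preserved (and logged); invariant violations are reported with row numbers.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import PLAIN_DIAGNOSES, RESUSCITATION_LEVELS, SEVERE_DIAGNOSES, SEVERE_PLAIN_PAIRS
from .exceptions import SchemaError, ValidationError

logger = logging.getLogger(__name__)

__all__ = ["COHORT_COLUMNS", "read_cohort", "write_cohort", "validate_cohort"]

_BOOL_COLUMNS = (
    "chorioamnionitis", "maternal_hypertension", "multiple_pregnancy",
    "low_weight_p10", "inborn", "cesarean", "postnatal_steroids",
) + PLAIN_DIAGNOSES + SEVERE_DIAGNOSES

_ENUMS = {
    "maternal_steroids": ("none", "partial", "full"),
    "sex": ("female", "male"),
    "resuscitation": RESUSCITATION_LEVELS,
    "outcome": ("survived", "died"),
}

#: Full data dictionary: every column of a complete cohort table.
COHORT_COLUMNS = (
    ("id", str),
    ("maternal_steroids", str),
    ("chorioamnionitis", int),
    ("maternal_hypertension", int),
    ("multiple_pregnancy", int),
    ("sex", str),
    ("gestational_age", float),
    ("birth_weight", int),
    ("low_weight_p10", int),
    ("inborn", int),
    ("level_of_care", int),
    ("cesarean", int),
    ("resuscitation", str),
    ("apgar1", int),
    ("apgar5", int),
    ("admission_temp", float),
    ("crib1", int),
    ("postnatal_steroids", int),
) + tuple((c, int) for c in PLAIN_DIAGNOSES) \
  + tuple((c, int) for c in SEVERE_DIAGNOSES) + (
    ("length_of_stay", int),
    ("outcome", str),
    ("day_of_death", "Int64"),
)

_COLUMN_TYPES = dict(COHORT_COLUMNS)


def _check_range(df, col, problems, lo=None, hi=None, lo_open=False, hi_open=False):
    if col not in df.columns:
        return
    x = pd.to_numeric(df[col], errors="coerce")
    bad = x.isna()
    if lo is not None:
        bad |= (x <= lo) if lo_open else (x < lo)
    if hi is not None:
        bad |= (x >= hi) if hi_open else (x > hi)
    for idx in df.index[bad]:
        problems.append((int(idx) + 1, col, f"value {df.at[idx, col]!r} out of range"))


def validate_cohort(df: pd.DataFrame, required: Optional[Sequence] = None) -> list:
    """Check invariants; return a list of (row, column, message) problems.

    ``required`` limits which columns must be present (defaults to the full
    data dictionary minus the outcome block when absent).
    """
    problems: list = []
    present = set(df.columns)
    if required is not None:
        missing = sorted(set(required) - present)
        if missing:
            raise SchemaError(f"missing required column(s): {missing}")

    for col, tokens in _ENUMS.items():
        if col not in present:
            continue
        vals = df[col].astype(str).str.lower()
        bad = ~vals.isin(tokens)
        for idx in df.index[bad]:
            problems.append((int(idx) + 1, col,
                             f"invalid token {df.at[idx, col]!r} (allowed: {tokens})"))

    for col in _BOOL_COLUMNS:
        if col in present:
            x = pd.to_numeric(df[col], errors="coerce")
            bad = ~x.isin([0, 1])
            for idx in df.index[bad]:
                problems.append((int(idx) + 1, col, f"boolean must be 0/1, got {df.at[idx, col]!r}"))

    _check_range(df, "apgar1", problems, lo=0, hi=10)
    _check_range(df, "apgar5", problems, lo=0, hi=10)
    _check_range(df, "gestational_age", problems, lo=22.0, hi=34.0)
    _check_range(df, "birth_weight", problems, lo=300, hi=2000, lo_open=True, hi_open=True)
    _check_range(df, "length_of_stay", problems, lo=1)
    _check_range(df, "crib1", problems, lo=0)
    if "level_of_care" in present:
        x = pd.to_numeric(df["level_of_care"], errors="coerce")
        for idx in df.index[~x.isin([2, 3])]:
            problems.append((int(idx) + 1, "level_of_care",
                             f"must be 2 or 3, got {df.at[idx, 'level_of_care']!r}"))

    if "outcome" in present and "day_of_death" in present:
        died = df["outcome"].astype(str).str.lower() == "died"
        dod = pd.to_numeric(df["day_of_death"], errors="coerce")
        for idx in df.index[died & dod.isna()]:
            problems.append((int(idx) + 1, "day_of_death", "missing for a death"))
        for idx in df.index[~died & dod.notna()]:
            problems.append((int(idx) + 1, "day_of_death", "present for a survivor"))
        if "length_of_stay" in present:
            los = pd.to_numeric(df["length_of_stay"], errors="coerce")
            bad = died & dod.notna() & (dod > los)
            for idx in df.index[bad]:
                problems.append((int(idx) + 1, "day_of_death", "exceeds length_of_stay"))

    for severe, plain in SEVERE_PLAIN_PAIRS.items():
        if severe in present and plain in present:
            s = pd.to_numeric(df[severe], errors="coerce")
            p = pd.to_numeric(df[plain], errors="coerce")
            for idx in df.index[(s == 1) & (p != 1)]:
                problems.append((int(idx) + 1, severe, f"severe flag set without {plain}"))
    return problems


def read_cohort(path, required: Optional[Sequence] = None) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    ``required`` defaults to the full data dictionary; pass an explicit list
    (e.g. a model's predictor fields) to accept partial tables. Enum tokens
    are case-insensitive; unknown columns are preserved and logged. Raises
    ``SchemaError`` for missing columns and ``ValidationError`` (with row
    numbers) for invariant violations.
    """
    df = pd.read_csv(path)
    if required is None:
        required = [c for c, _ in COHORT_COLUMNS]
    missing = sorted(set(required) - set(df.columns))
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    unknown = sorted(set(df.columns) - {c for c, _ in COHORT_COLUMNS})
    if unknown:
        logger.info("read_cohort: preserving unknown column(s) %s", unknown)

    for col in df.columns:
        if col in _ENUMS:
            df[col] = df[col].astype(str).str.lower()
    problems = validate_cohort(df, required=required)
    if problems:
        shown = "; ".join(f"row {r}, {c}: {m}" for r, c, m in problems[:10])
        raise ValidationError(
            f"{len(problems)} invariant violation(s): {shown}", problems=problems
        )
    for col, typ in COHORT_COLUMNS:
        if col in df.columns:
            if typ == "Int64":
                df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
            elif typ in (int, float):
                df[col] = df[col].astype(typ)
    return df


def write_cohort(df: pd.DataFrame, path) -> None:
    """Write a cohort table in the package CSV dialect."""
    df.to_csv(path, index=False)
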