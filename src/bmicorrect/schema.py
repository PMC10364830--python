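"""Survey microdata schema: column names, category levels, validation, I/O.

A survey is a :class:`pandas.DataFrame` with one row per participant and the
columns in :data:`COLUMNS`. Missing values are ``NaN`` (numeric) or ``None``
(categorical); delimited-text round-trips preserve them as empty cells.
"""

from __future__ import annotations

import io
from typing import Iterable

import numpy as np
import pandas as pd

SEXES = ("male", "female")

AGE_GROUPS = ("18-34", "35-49", "50-64", "65+")
AGE_BREAKS = (18, 35, 50, 65)  # left edges; last group is open-ended

RACE_ETHNICITY_LEVELS = (
    "hispanic",
    "nh_asian",
    "nh_black",
    "nh_white",
    "nh_other",
)

LOCALITIES = ("metropolitan", "nonmetropolitan")

#: USPS codes for the 50 states plus the District of Columbia.
STATES = (
    "AL", "AK", "AZ", "AR", "CA", "CO", "CT", "DE", "DC", "FL", "GA", "HI",
    "ID", "IL", "IN", "IA", "KS", "KY", "LA", "ME", "MD", "MA", "MI", "MN",
    "MS", "MO", "MT", "NE", "NV", "NH", "NJ", "NM", "NY", "NC", "ND", "OH",
    "OK", "OR", "PA", "RI", "SC", "SD", "TN", "TX", "UT", "VT", "VA", "WA",
    "WV", "WI", "WY",
)

PROVENANCES = ("measured", "self_reported")

#: Ordered survey-table columns. ``bmi_true`` is synthetic ground truth
#: (the measured-scale BMI before reporting bias) and is absent on real data.
COLUMNS = (
    "id",
    "sex",
    "age_years",
    "age_group",
    "race_ethnicity",
    "state",
    "locality",
    "pregnant",
    "height_cm",
    "weight_kg",
    "bmi",
    "sample_weight",
    "provenance",
)

_STRING_COLS = ("id", "sex", "age_group", "race_ethnicity", "state",
                "locality", "provenance")


class SchemaError(ValueError):
    """A survey table violates the column schema or a field invariant."""


def strata() -> list[tuple[str, str]]:
    """All sex x age-group strata, in canonical order (8 cells)."""
    return [(s, a) for s in SEXES for a in AGE_GROUPS]


def age_group_of(age_years: np.ndarray | pd.Series) -> pd.Series:
    """Map integer ages (>=18) to the four surveillance age groups.

    NaN ages map to ``None``.
    """
    age = pd.Series(np.asarray(age_years, dtype=float))
    edges = [*AGE_BREAKS, np.inf]
    labels = list(AGE_GROUPS)
    out = pd.cut(age, bins=edges, labels=labels, right=False)
    return out.astype(object).where(age.notna(), None)


def compute_bmi(height_cm, weight_kg):
    """BMI = weight [kg] / (height [m])^2; NaN where either input is missing."""
    h = np.asarray(height_cm, dtype=float)
    w = np.asarray(weight_kg, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return w / (h / 100.0) ** 2


def validate_survey(df: pd.DataFrame, *, require_bmi: bool = False) -> None:
    """Raise :class:`SchemaError` on a malformed survey table."""
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"survey table missing columns: {missing}")
    w = df["sample_weight"].to_numpy(dtype=float)
    if not np.all(np.isfinite(w) & (w > 0)):
        raise SchemaError("sample_weight must be positive and finite")
    bad_prov = set(df["provenance"].dropna()) - set(PROVENANCES)
    if bad_prov:
        raise SchemaError(f"unknown provenance values: {sorted(bad_prov)}")
    bad_sex = set(df["sex"].dropna()) - set(SEXES)
    if bad_sex:
        raise SchemaError(f"unknown sex values: {sorted(bad_sex)}")
    if require_bmi and df["bmi"].isna().any():
        n = int(df["bmi"].isna().sum())
        raise SchemaError(f"{n} records have missing bmi")
    # BMI must agree with height/weight where all three are present
    have = df[["height_cm", "weight_kg", "bmi"]].notna().all(axis=1)
    if have.any():
        expect = compute_bmi(df.loc[have, "height_cm"], df.loc[have, "weight_kg"])
        if not np.allclose(df.loc[have, "bmi"], expect, rtol=0, atol=1e-9):
            raise SchemaError("bmi inconsistent with height_cm/weight_kg")


def write_survey(df: pd.DataFrame, path) -> None:
    """Write a survey as tab-delimited UTF-8 text, empty cell = missing."""
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_survey(path) -> pd.DataFrame:
    """Read a survey table written by :func:`write_survey`."""
    df = pd.read_csv(path, sep="\t", dtype={c: object for c in _STRING_COLS})
    for col in ("age_years", "height_cm", "weight_kg", "bmi", "sample_weight"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col])
    if "pregnant" in df.columns:
        df["pregnant"] = df["pregnant"].astype(bool)
    validate_survey(df)
    return df
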