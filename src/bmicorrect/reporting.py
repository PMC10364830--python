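"""Published-style prevalence tables: loading, ranges, threshold counts,
and state-vs-national significance screening.

Two fixture tables ship with the package under ``bmicorrect/data``:
severe-obesity prevalence by sociodemographic characteristic and by state
(the latter with sex-stratified corrected columns), each cell an estimate
with its 95% CI on the percent scale. The same operations run on tables
produced by the synthetic pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from math import inf

import numpy as np
import pandas as pd
from scipy.stats import norm

from .estimation import se_from_ci

#: (est, lo, hi) column triples a state-style table may carry.
CELL_PREFIXES = ("self", "corrected", "men", "women")

_DC_LABELS = {"District of Columbia", "DC"}


class TableSchemaError(ValueError):
    """A prevalence-table file violates the expected schema."""


@dataclass(frozen=True)
class PrevalenceTable:
    """Rows keyed by unique label; per-arm (est, lo, hi) percent cells."""

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        if "label" not in df.columns:
            raise TableSchemaError("missing 'label' column")
        if df["label"].duplicated().any():
            dups = df.loc[df["label"].duplicated(), "label"].tolist()
            raise TableSchemaError(f"duplicate labels: {dups}")
        if not len(df):
            raise TableSchemaError("table has no rows")
        for prefix in self.arms():
            est, lo, hi = (df[f"{prefix}_{s}"] for s in ("est", "lo", "hi"))
            ok = (lo <= est) & (est <= hi)
            bad = df.loc[~(ok | est.isna()), "label"].tolist()
            if bad:
                raise TableSchemaError(
                    f"{prefix}: CI does not bracket estimate for rows {bad}")

    def arms(self) -> list[str]:
        return [p for p in CELL_PREFIXES if f"{p}_est" in self.data.columns]

    def __len__(self) -> int:
        return len(self.data)

    def labels(self) -> list[str]:
        return self.data["label"].tolist()

    def cell(self, label: str, arm: str) -> tuple[float, float, float]:
        """(estimate, ci_low, ci_high) for one row and arm, percent scale."""
        row = self.data.loc[self.data["label"] == label]
        if row.empty:
            raise KeyError(f"no row labelled {label!r}")
        r = row.iloc[0]
        return tuple(float(r[f"{arm}_{s}"]) for s in ("est", "lo", "hi"))

    def _rows(self, include_dc: bool) -> pd.DataFrame:
        if include_dc:
            return self.data
        return self.data[~self.data["label"].isin(_DC_LABELS)]

    def write(self, path) -> None:
        # fixed precision so write -> load -> write round-trips bytewise
        self.data.to_csv(path, sep="\t", index=False, na_rep="",
                         float_format="%.6f")


def load_prevalence_table(path) -> PrevalenceTable:
    """Read a tab-delimited prevalence table, validating cells.

    Malformed numeric cells are rejected with their row label and column.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise TableSchemaError(f"{path}: empty file") from None
    if "label" not in df.columns:
        raise TableSchemaError(f"{path}: missing 'label' column")
    numeric = [c for c in df.columns
               if any(c.startswith(f"{p}_") for p in CELL_PREFIXES)
               or c in ("n_unweighted", "weighted_pct", "sig_above_national")]
    for col in numeric:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = df[col].notna() & parsed.isna()
        if bad.any():
            where = df.loc[bad, "label"].iloc[0]
            raise TableSchemaError(
                f"{path}: malformed numeric cell at row {where!r}, "
                f"column {col!r}")
        df[col] = parsed
    return PrevalenceTable(df)


def packaged_table(which: str) -> PrevalenceTable:
    """Load a packaged fixture: ``"by_characteristic"`` or ``"by_state"``."""
    names = {
        "by_characteristic": "table1_severe_obesity_by_characteristic.tsv",
        "by_state": "table2_severe_obesity_by_state.tsv",
    }
    if which not in names:
        raise KeyError(f"unknown packaged table {which!r}")
    ref = resources.files("bmicorrect.data").joinpath(names[which])
    with resources.as_file(ref) as path:
        return load_prevalence_table(path)


def _column(table: PrevalenceTable, column: str,
            include_dc: bool) -> pd.DataFrame:
    if column not in table.data.columns:
        raise KeyError(f"unknown column {column!r}")
    df = table._rows(include_dc)
    return df[["label", column]].dropna(subset=[column])


def count_above(table: PrevalenceTable, column: str, threshold: float,
                include_dc: bool = False) -> int:
    """Number of rows whose ``column`` value is strictly above ``threshold``.

    With ``include_dc=False`` the District of Columbia row is left out, so
    the count matches "N states" phrasing.
    """
    if threshold == inf:
        return 0
    df = _column(table, column, include_dc)
    return int((df[column] > threshold).sum())


def column_extremes(table: PrevalenceTable, column: str,
                    include_dc: bool = True):
    """((min_labels, min_value), (max_labels, max_value)); ties return all
    tied labels."""
    df = _column(table, column, include_dc)
    if df.empty:
        raise ValueError(f"column {column!r} has no values")
    vmin, vmax = df[column].min(), df[column].max()
    lo = df.loc[df[column] == vmin, "label"].tolist()
    hi = df.loc[df[column] == vmax, "label"].tolist()
    return (lo, float(vmin)), (hi, float(vmax))


def flag_above_national(table: PrevalenceTable,
                        national: tuple[float, float, float],
                        column: str = "corrected",
                        alpha: float = 0.05,
                        include_dc: bool = False) -> list[str]:
    """Rows significantly *above* the national cell.

    SEs come from the printed CIs (half-width / 1.96). The screen is
    directional: a row is flagged when its estimate exceeds the national
    estimate and the one-sided z test of that excess is significant at
    ``alpha``. Rows below the national value are never flagged, however
    narrow their CI.
    """
    nat_est, nat_lo, nat_hi = national
    nat_se = se_from_ci(nat_lo, nat_hi)
    df = table._rows(include_dc)
    flagged = []
    for _, row in df.iterrows():
        est, lo, hi = (row[f"{column}_{s}"] for s in ("est", "lo", "hi"))
        if np.isnan(est):
            continue
        if np.isnan(lo) or np.isnan(hi):
            raise ValueError(f"row {row['label']!r} has no CI")
        if est <= nat_est:
            continue
        z = (est - nat_est) / np.hypot(se_from_ci(lo, hi), nat_se)
        if norm.sf(z) < alpha:
            flagged.append(row["label"])
    return flagged


def relative_underestimation(self_reported_est: float,
                             corrected_est: float,
                             digits: int = 0) -> float:
    """Percent by which self-report underestimates the corrected value:
    100 (corrected - self_reported) / corrected, rounded for reporting."""
    if corrected_est <= 0:
        raise ValueError("corrected estimate must be positive")
    pct = 100.0 * (corrected_est - self_reported_est) / corrected_est
    return round(pct, digits) if digits else round(pct)
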