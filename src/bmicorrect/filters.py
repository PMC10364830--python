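"""Sequential cohort exclusions with an auditable log.

Mirrors the screening applied to surveillance microdata before analysis:
pregnant respondents, then records missing core demographics, then missing
or biologically implausible anthropometrics. Each record is counted at the
first criterion it fails, so the log telescopes exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_FIELD_ALIASES = {"age": "age_years", "weight": "weight_kg",
                  "height": "height_cm"}
_KNOWN_FIELDS = {"sex", "age_years", "race_ethnicity",
                 "height_cm", "weight_kg"}


@dataclass(frozen=True)
class ExclusionCriteria:
    """Exclusion rules, applied in order.

    ``required_fields`` lists demographic fields whose absence excludes a
    record (checked sequentially); missing or implausible height/weight is
    always the final step. Plausibility bounds follow the conventional
    screen: height outside [50, 300] cm or weight below 20 kg is implausible
    (strict inequalities — the boundary values are retained).
    """

    exclude_pregnant: bool = True
    required_fields: tuple = ("sex", "age_years", "race_ethnicity")
    height_min_cm: float = 50.0
    height_max_cm: float = 300.0
    weight_min_kg: float = 20.0

    def __post_init__(self):
        if not self.height_min_cm < self.height_max_cm:
            raise ValueError("height_min_cm must be < height_max_cm")
        if self.weight_min_kg <= 0:
            raise ValueError("weight_min_kg must be > 0")
        resolved = tuple(_FIELD_ALIASES.get(f, f) for f in self.required_fields)
        unknown = [f for f in resolved if f not in _KNOWN_FIELDS]
        if unknown:
            raise ValueError(f"unknown required field(s): {unknown}")
        object.__setattr__(self, "required_fields", resolved)


@dataclass
class ExclusionLog:
    """Ordered per-criterion exclusion counts; telescopes to the retained n."""

    n_input: int
    steps: list = field(default_factory=list)  # (criterion, n_excluded, n_remaining)

    def add(self, criterion: str, n_excluded: int) -> None:
        prev = self.steps[-1][2] if self.steps else self.n_input
        self.steps.append((criterion, int(n_excluded), prev - int(n_excluded)))

    @property
    def n_retained(self) -> int:
        return self.steps[-1][2] if self.steps else self.n_input

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps,
                            columns=["criterion", "n_excluded", "n_remaining"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def apply_exclusions(records: pd.DataFrame,
                     criteria: ExclusionCriteria = ExclusionCriteria()
                     ) -> tuple[pd.DataFrame, ExclusionLog]:
    """Apply the exclusion sequence; return (retained records, log).

    A record missing the pregnancy flag is treated as not pregnant — only
    identified pregnant respondents are excluded. The retained set is
    order-invariant; only the per-criterion attribution depends on order.
    """
    log = ExclusionLog(n_input=len(records))
    alive = np.ones(len(records), dtype=bool)

    def step(name: str, fails: np.ndarray) -> None:
        hit = alive & np.asarray(fails, dtype=bool)
        log.add(name, hit.sum())
        alive[hit] = False

    if criteria.exclude_pregnant:
        step("pregnant", records["pregnant"].eq(True).to_numpy(dtype=bool))
    for fld in criteria.required_fields:
        step(f"missing_{fld}", records[fld].isna().to_numpy())

    h = records["height_cm"].to_numpy(dtype=float)
    w = records["weight_kg"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        implausible = ((h < criteria.height_min_cm)
                       | (h > criteria.height_max_cm)
                       | (w < criteria.weight_min_kg))
    step("missing_or_implausible_anthropometrics",
         np.isnan(h) | np.isnan(w) | implausible)

    for name, n_exc, n_rem in log.steps:
        logger.info("exclusion %s: removed %d, %d remain", name, n_exc, n_rem)
    return records.loc[alive].copy(), log
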