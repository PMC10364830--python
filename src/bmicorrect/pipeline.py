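"""End-to-end run: generate -> filter -> fit curves -> correct -> estimate
-> report, from one declarative config, with a structured manifest.

All randomness flows from a single seed, split deterministically per stage,
so identical (config, seed) produce identical outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import schema
from .correction import SplineConfig, apply_correction, estimate_bias_curves, \
    validate_correction
from .estimation import classify_severe_obesity, weighted_prevalence
from .filters import ExclusionCriteria, apply_exclusions
from .reporting import PrevalenceTable, relative_underestimation
from .synthetic import BiasModel, PopulationConfig, make_paired_surveys

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrectionSettings:
    grid_size: int = 99
    spline: SplineConfig = field(default_factory=SplineConfig)
    tolerance: float = 0.1  # BMI units; quantile-matching check at grid points


@dataclass(frozen=True)
class ReportSettings:
    threshold_pct: float = 10.0
    include_dc: bool = False
    alpha: float = 0.05


@dataclass(frozen=True)
class RunConfig:
    """Everything one reproducible pipeline run depends on."""

    population: PopulationConfig = field(default_factory=PopulationConfig)
    bias: BiasModel = field(default_factory=BiasModel)
    exclusions: ExclusionCriteria = field(default_factory=ExclusionCriteria)
    correction: CorrectionSettings = field(default_factory=CorrectionSettings)
    report: ReportSettings = field(default_factory=ReportSettings)
    seed: int = 0
    write_surveys: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["population"]["mixtures"] = {
            f"{sex}/{age}": dataclasses.asdict(mix)
            for (sex, age), mix in self.population.mixtures.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        kwargs = {}
        if "population" in d:
            pop = dict(d["population"])
            if "mixtures" in pop:
                from .synthetic import StratumMixture
                pop["mixtures"] = {
                    tuple(k.split("/")): StratumMixture(**v)
                    for k, v in pop["mixtures"].items()}
            kwargs["population"] = PopulationConfig(**pop)
        if "bias" in d:
            kwargs["bias"] = BiasModel(**d["bias"])
        if "exclusions" in d:
            kwargs["exclusions"] = ExclusionCriteria(**{
                k: tuple(v) if k == "required_fields" else v
                for k, v in d["exclusions"].items()})
        if "correction" in d:
            corr = dict(d["correction"])
            if "spline" in corr:
                corr["spline"] = SplineConfig(**corr["spline"])
            kwargs["correction"] = CorrectionSettings(**corr)
        if "report" in d:
            kwargs["report"] = ReportSettings(**d["report"])
        for k in ("seed", "write_surveys"):
            if k in d:
                kwargs[k] = d[k]
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _prevalence_pct(df: pd.DataFrame, bmi_column: str = "bmi") -> float:
    est = weighted_prevalence(df, bmi_column=bmi_column)
    return 100.0 * est.p_hat


def _state_table(uncorrected: pd.DataFrame,
                 corrected: pd.DataFrame) -> PrevalenceTable:
    """Synthetic analogue of the published state table (percent scale)."""
    rows = []
    for st in sorted(uncorrected["state"].dropna().unique()):
        row = {"label": st}
        for prefix, df, dom in (
                ("self", uncorrected, None),
                ("corrected", corrected, None),
                ("men", corrected, corrected["sex"] == "male"),
                ("women", corrected, corrected["sex"] == "female")):
            mask = (df["state"] == st).to_numpy()
            if dom is not None:
                mask &= dom.to_numpy()
            if not mask.any():
                continue
            est = weighted_prevalence(df, domain=mask, label=st)
            row[f"{prefix}_est"], row[f"{prefix}_lo"], row[f"{prefix}_hi"] = \
                est.as_percent()
        rows.append(row)
    return PrevalenceTable(pd.DataFrame(rows))


def run_pipeline(config: RunConfig, outdir=None) -> dict:
    """Execute all stages; return the manifest (also written to outdir).

    The manifest records the seed, a config hash, per-stage row counts, the
    pooled and per-stratum KS validation, naive and corrected severe-obesity
    prevalence, and the recovery error against the generator's ground truth.
    """
    stage = "generate"
    try:
        measured_ref, sr_ref, sr_target = make_paired_surveys(
            config.population, config.bias, seed=config.seed)

        stage = "filter"
        surveys, logs = {}, {}
        for name, df in (("measured_reference", measured_ref),
                         ("selfreported_reference", sr_ref),
                         ("selfreported_target", sr_target)):
            surveys[name], logs[name] = apply_exclusions(df, config.exclusions)

        stage = "fit_curves"
        curves = estimate_bias_curves(
            surveys["selfreported_reference"], surveys["measured_reference"],
            grid_size=config.correction.grid_size,
            spline=config.correction.spline)

        stage = "correct"
        corrected = apply_correction(surveys["selfreported_target"], curves)

        stage = "validate"
        ks = validate_correction(corrected, surveys["measured_reference"])

        stage = "estimate"
        target = surveys["selfreported_target"]
        naive_pct = _prevalence_pct(target)
        corrected_pct = _prevalence_pct(corrected)
        truth_pct = _prevalence_pct(target, bmi_column="bmi_true")
        analytic_pct = 100.0 * config.population.severe_obesity_prevalence()

        stage = "report"
        table = _state_table(target, corrected)

        manifest = {
            "seed": config.seed,
            "config_hash": config.content_hash(),
            "counts": {name: {"input": lg.n_input,
                              "retained": lg.n_retained,
                              "excluded": lg.n_input - lg.n_retained}
                       for name, lg in logs.items()},
            "ks": {k: {"statistic": round(v.statistic, 10),
                       "p_value": round(v.p_value, 10)}
                   for k, v in ks.items()},
            "prevalence_pct": {
                "self_reported": round(naive_pct, 6),
                "corrected": round(corrected_pct, 6),
                "ground_truth": round(truth_pct, 6),
                "analytic_population": round(analytic_pct, 6),
            },
            "recovery_error_pp": round(abs(corrected_pct - truth_pct), 6),
            "naive_relative_underestimation_pct": relative_underestimation(
                naive_pct, truth_pct, digits=2),
        }
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        config.to_yaml(outdir / "config.yaml")
        for name, lg in logs.items():
            lg.write(outdir / f"exclusions_{name}.tsv")
        pd.concat([c.to_frame() for c in curves.values()]).to_csv(
            outdir / "bias_curves.tsv", sep="\t", index=False)
        table.write(outdir / "state_prevalence.tsv")
        if config.write_surveys:
            for name, df in surveys.items():
                schema.write_survey(df, outdir / f"{name}.tsv")
            schema.write_survey(corrected, outdir / "corrected_target.tsv")
        with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        manifest["outdir"] = str(outdir)
    return manifest
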