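"""Synthetic paired surveys with known ground truth.

Emulates the measurement setting of US obesity surveillance: a smaller
examination survey with *measured* height and weight (the NHANES role) and
large telephone surveys with *self-reported* values (the BRFSS role).
Self-report bias is injected on the BMI scale by an explicit parametric
mechanism, so every downstream stage — exclusion filtering, quantile-matching
correction, design-weighted prevalence — can be tested against analytic or
stored truth without any external microdata.

Measured BMI per sex x age-group stratum follows a two-component truncated
normal mixture: a bulk component around the population mode and a heavy
right-tail component. Tail-component weights are solved per stratum so the
population prevalence of severe obesity (BMI >= 40) is ~9% overall, higher
in women than men and lowest at ages 65+, matching the pattern reported by
national surveillance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .schema import (AGE_GROUPS, COLUMNS, RACE_ETHNICITY_LEVELS, SEXES,
                     STATES, age_group_of, compute_bmi, strata)

#: Support of the measured-BMI mixture (truncation bounds, kg/m^2).
BMI_MIN, BMI_MAX = 15.0, 75.0

SEVERE_OBESITY_BMI = 40.0


class ConfigError(ValueError):
    """A configuration field violates its invariant; the message names it."""


@dataclass(frozen=True)
class StratumMixture:
    """Two-component truncated-normal mixture for measured BMI in one stratum.

    ``tail_weight`` is the mixing proportion of the right-tail component;
    component weights are (1 - tail_weight, tail_weight) and sum to 1.
    """

    bulk_mean: float
    bulk_sd: float
    tail_mean: float
    tail_sd: float
    tail_weight: float

    def _components(self):
        out = []
        for mu, sd in ((self.bulk_mean, self.bulk_sd),
                       (self.tail_mean, self.tail_sd)):
            a, b = (BMI_MIN - mu) / sd, (BMI_MAX - mu) / sd
            out.append(truncnorm(a, b, loc=mu, scale=sd))
        return out

    def tail_mass(self, threshold: float = SEVERE_OBESITY_BMI) -> float:
        """P(BMI >= threshold) under the mixture — closed form via the
        truncated-normal survival functions."""
        bulk, tail = self._components()
        lam = self.tail_weight
        return float((1 - lam) * bulk.sf(threshold) + lam * tail.sf(threshold))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        bulk, tail = self._components()
        from_tail = rng.random(n) < self.tail_weight
        u = rng.random(n)
        return np.where(from_tail, tail.ppf(u), bulk.ppf(u))


def mixture_for_prevalence(bulk_mean: float, bulk_sd: float, tail_mean: float,
                           tail_sd: float, target: float) -> StratumMixture:
    """Solve the tail weight so the mixture's severe-obesity mass equals
    ``target`` (closed form: the mass is linear in the mixing weight)."""
    probe = StratumMixture(bulk_mean, bulk_sd, tail_mean, tail_sd, 0.0)
    t_bulk = probe.tail_mass()
    t_tail = replace(probe, tail_weight=1.0).tail_mass()
    lam = (target - t_bulk) / (t_tail - t_bulk)
    if not 0.0 <= lam <= 1.0:
        raise ConfigError(
            f"tail_weight: target prevalence {target} unattainable with the "
            f"given components (solved weight {lam:.4f})")
    return StratumMixture(bulk_mean, bulk_sd, tail_mean, tail_sd, lam)


# Severe-obesity prevalence targets per stratum = age pattern x sex ratio,
# after the sex/age profile of national surveillance estimates.
_AGE_PREVALENCE = {"18-34": 0.095, "35-49": 0.103, "50-64": 0.100, "65+": 0.049}
_SEX_RATIO = {"male": 6.5 / 8.8, "female": 11.1 / 8.8}
_BULK = {"male": (27.8, 4.1), "female": (27.0, 4.6)}
_TAIL = {"male": (39.5, 5.0), "female": (40.5, 5.5)}
#: Population age-group shares (weighted shares of US adults).
_AGE_SHARES = {"18-34": 0.296, "35-49": 0.229, "50-64": 0.251, "65+": 0.224}

_HEIGHT = {"male": (176.0, 7.0), "female": (162.0, 6.5)}  # cm
_HEIGHT_RANGE = (140.0, 210.0)  # clip to stay biologically plausible


def default_mixtures() -> dict[tuple[str, str], StratumMixture]:
    """Default measured-BMI mixtures for the 8 sex x age strata."""
    out = {}
    for sex, age in strata():
        target = _AGE_PREVALENCE[age] * _SEX_RATIO[sex]
        out[(sex, age)] = mixture_for_prevalence(
            *_BULK[sex], *_TAIL[sex], target)
    return out


@dataclass(frozen=True)
class BiasModel:
    """Parametric self-report bias on the BMI scale.

    Reported BMI = measured BMI - bias + noise, with
    bias = intercept + slope * max(0, BMI - pivot) + sex_offset + age_offset.
    With nonnegative intercept and slope the expected reported BMI never
    exceeds the measured value above the pivot, and the bias magnitude is
    non-decreasing in measured BMI — the two qualitative facts about
    self-reported anthropometrics this generator must reproduce.
    """

    intercept_kgm2: float = 0.3
    slope_per_unit: float = 0.08
    pivot_kgm2: float = 25.0
    sex_offsets: dict = field(
        default_factory=lambda: {"male": 0.0, "female": 0.3})
    age_offsets: dict = field(
        default_factory=lambda: {"18-34": 0.0, "35-49": 0.0,
                                 "50-64": 0.0, "65+": 0.2})
    noise_sd: float = 0.5

    def __post_init__(self):
        if self.slope_per_unit < 0:
            raise ConfigError("slope_per_unit must be >= 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")

    def expected_bias(self, bmi, sex, age_group) -> np.ndarray:
        """Mean (measured - reported) BMI for given covariates."""
        bmi = np.asarray(bmi, dtype=float)
        so = np.array([self.sex_offsets.get(s, 0.0) for s in np.asarray(sex)])
        ao = np.array([self.age_offsets.get(a, 0.0)
                       for a in np.asarray(age_group)])
        return (self.intercept_kgm2
                + self.slope_per_unit * np.maximum(0.0, bmi - self.pivot_kgm2)
                + so + ao)


@dataclass(frozen=True)
class PopulationConfig:
    """Generating process for one synthetic survey."""

    n: int = 100_000
    mixtures: dict = field(default_factory=default_mixtures)
    sex_shares: dict = field(
        default_factory=lambda: {"male": 0.5, "female": 0.5})
    age_shares: dict = field(default_factory=lambda: dict(_AGE_SHARES))
    state_weights: dict = field(
        default_factory=lambda: {s: 1.0 for s in STATES})
    metropolitan_share: float = 0.85
    weight_dispersion: float = 0.8  # sigma of log-normal sampling weights
    missingness_rates: dict = field(
        default_factory=lambda: {"sex": 0.0, "age_years": 0.01,
                                 "race_ethnicity": 0.01, "height_cm": 0.004,
                                 "weight_kg": 0.004})
    pregnancy_rate: float = 0.02  # among women under 50
    implausible_rate: float = 0.003
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ConfigError("n must be >= 1")
        if self.weight_dispersion < 0:
            raise ConfigError("weight_dispersion must be >= 0")
        for name in ("pregnancy_rate", "implausible_rate",
                     "metropolitan_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        for fld, rate in self.missingness_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"missingness_rates[{fld}] must be in [0, 1]")
        for name, shares in (("sex_shares", self.sex_shares),
                             ("age_shares", self.age_shares)):
            if abs(sum(shares.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1")
        if any(w < 0 for w in self.state_weights.values()):
            raise ConfigError("state_weights must be nonnegative")
        missing = [k for k in strata() if k not in self.mixtures]
        if missing:
            raise ConfigError(f"mixtures missing strata: {missing}")

    def severe_obesity_prevalence(self,
                                  threshold: float = SEVERE_OBESITY_BMI
                                  ) -> float:
        """Analytic population P(BMI >= threshold): stratum-share-weighted
        mixture tail masses. The ground truth downstream estimators chase."""
        total = 0.0
        for (sex, age), mix in self.mixtures.items():
            share = self.sex_shares[sex] * self.age_shares[age]
            total += share * mix.tail_mass(threshold)
        return total


def _draw_clean(config: PopulationConfig, rng: np.random.Generator,
                id_prefix: str) -> pd.DataFrame:
    """Fully observed measured population, before artifact injection."""
    n = config.n
    sex = rng.choice(SEXES, size=n, p=[config.sex_shares[s] for s in SEXES])
    ages_lo = {"18-34": (18, 35), "35-49": (35, 50),
               "50-64": (50, 65), "65+": (65, 95)}
    grp = rng.choice(AGE_GROUPS, size=n,
                     p=[config.age_shares[a] for a in AGE_GROUPS])
    age_years = np.empty(n, dtype=float)
    for a, (lo, hi) in ages_lo.items():
        m = grp == a
        age_years[m] = rng.integers(lo, hi, size=int(m.sum()))

    bmi = np.empty(n, dtype=float)
    height = np.empty(n, dtype=float)
    for s in SEXES:
        sm = sex == s
        mu, sd = _HEIGHT[s]
        height[sm] = np.clip(rng.normal(mu, sd, int(sm.sum())), *_HEIGHT_RANGE)
        for a in AGE_GROUPS:
            m = sm & (grp == a)
            bmi[m] = config.mixtures[(s, a)].sample(int(m.sum()), rng)
    weight = bmi * (height / 100.0) ** 2

    race = rng.choice(RACE_ETHNICITY_LEVELS, size=n,
                      p=[0.163, 0.055, 0.120, 0.631, 0.031])
    sw = np.array([config.state_weights[s] for s in STATES], dtype=float)
    state = rng.choice(STATES, size=n, p=sw / sw.sum())
    locality = np.where(rng.random(n) < config.metropolitan_share,
                        "metropolitan", "nonmetropolitan")
    if config.weight_dispersion > 0:
        w = rng.lognormal(0.0, config.weight_dispersion, n)
        w /= w.mean()
    else:
        w = np.ones(n)

    df = pd.DataFrame({
        "id": [f"{id_prefix}{i:07d}" for i in range(n)],
        "sex": sex,
        "age_years": age_years,
        "age_group": grp,
        "race_ethnicity": race,
        "state": state,
        "locality": locality,
        "pregnant": np.zeros(n, dtype=bool),
        "height_cm": height,
        "weight_kg": weight,
        "bmi": bmi,
        "sample_weight": w,
        "provenance": "measured",
    })
    return df


def _inject_artifacts(df: pd.DataFrame, config: PopulationConfig,
                      rng: np.random.Generator) -> pd.DataFrame:
    """Inject pregnancy, MCAR missingness, and implausible anthropometrics.

    Applied after bias so exclusion-triggering records exist in every survey
    regardless of provenance.
    """
    df = df.copy()
    n = len(df)
    fertile = (df["sex"] == "female") & (df["age_years"] < 50)
    df.loc[fertile & (rng.random(n) < config.pregnancy_rate),
           "pregnant"] = True

    for fld, rate in config.missingness_rates.items():
        if rate <= 0:
            continue
        hit = rng.random(n) < rate
        if fld in ("sex", "race_ethnicity"):
            df.loc[hit, fld] = None
        elif fld == "age_years":
            df.loc[hit, "age_years"] = np.nan
            df.loc[hit, "age_group"] = None
        else:
            df.loc[hit, fld] = np.nan

    if config.implausible_rate > 0:
        hit = np.flatnonzero(rng.random(n) < config.implausible_rate)
        kind = rng.integers(0, 3, size=hit.size)
        df.loc[df.index[hit[kind == 0]], "height_cm"] = 30.0
        df.loc[df.index[hit[kind == 1]], "height_cm"] = 320.0
        df.loc[df.index[hit[kind == 2]], "weight_kg"] = 15.0

    df["bmi"] = compute_bmi(df["height_cm"], df["weight_kg"])
    return df


def generate_measured_population(
        config: PopulationConfig,
        seed: int | np.random.SeedSequence | None = None,
        id_prefix: str = "M") -> pd.DataFrame:
    """Draw a measured-provenance survey of exactly ``config.n`` records.

    Deterministic given (config, seed); ``seed`` defaults to ``config.seed``.
    """
    if isinstance(seed, np.random.SeedSequence):
        ss = seed
    else:
        ss = np.random.SeedSequence(config.seed if seed is None else seed)
    draw_rng, artifact_rng = (np.random.default_rng(c) for c in ss.spawn(2))
    df = _draw_clean(config, draw_rng, id_prefix)
    return _inject_artifacts(df, config, artifact_rng)


def apply_reporting_bias(records: pd.DataFrame, bias: BiasModel,
                         seed: int = 0) -> pd.DataFrame:
    """Turn a measured survey into its self-reported counterpart.

    Bias acts on BMI directly; weight is back-solved from the reported BMI at
    unchanged height so the height/weight/BMI triple stays consistent. Ids
    and sampling weights are preserved; ``bmi_true`` keeps the measured value.
    """
    if (records["provenance"] != "measured").any():
        raise ValueError("apply_reporting_bias expects measured-provenance "
                         "records")
    if records["bmi"].isna().any():
        bad = records.loc[records["bmi"].isna(), "id"].tolist()
        raise ValueError(f"records missing bmi: {bad[:5]}"
                         + ("..." if len(bad) > 5 else ""))
    rng = np.random.default_rng(seed)
    out = records.copy()
    delta = bias.expected_bias(out["bmi"], out["sex"], out["age_group"])
    noise = rng.normal(0.0, bias.noise_sd, len(out)) if bias.noise_sd > 0 \
        else 0.0
    reported = out["bmi"].to_numpy(dtype=float) - delta + noise
    out["bmi_true"] = records["bmi"].to_numpy(dtype=float)
    out["bmi"] = reported
    out["weight_kg"] = reported * (out["height_cm"].to_numpy() / 100.0) ** 2
    out["provenance"] = "self_reported"
    return out


def make_paired_surveys(config: PopulationConfig, bias: BiasModel,
                        seed: int | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Three independent draws from one generating process.

    Returns (measured_reference, self_reported_reference,
    self_reported_target). The reference pair plays the NHANES/BRFSS
    reference-period roles; the target is an independent self-reported survey
    of the same population. Bias and artifact injection are seeded
    deterministically from ``seed``.
    """
    ss = np.random.SeedSequence(config.seed if seed is None else seed)
    kids = ss.spawn(3)

    measured_ref = generate_measured_population(
        config, seed=kids[0], id_prefix="M")

    out = [measured_ref]
    for child, prefix in zip(kids[1:], ("R", "T")):
        draw_rng, bias_seed, artifact_rng = child.spawn(3)
        clean = _draw_clean(config, np.random.default_rng(draw_rng), prefix)
        reported = apply_reporting_bias(clean, bias,
                                        seed=np.random.default_rng(bias_seed)
                                        .integers(2**31))
        out.append(_inject_artifacts(reported, config, np.random.default_rng(
            artifact_rng)))
    return tuple(out)
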