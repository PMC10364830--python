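import numpy as np
import pandas as pd
import pytest

from bmicorrect import BiasModel, PopulationConfig, make_paired_surveys
from bmicorrect.filters import apply_exclusions


def clean_population(n: int, seed: int) -> PopulationConfig:
    """A population with no exclusion-triggering artifacts."""
    return PopulationConfig(
        n=n, seed=seed,
        missingness_rates={}, pregnancy_rate=0.0, implausible_rate=0.0)


@pytest.fixture(scope="session")
def default_bias() -> BiasModel:
    return BiasModel()


@pytest.fixture(scope="session")
def paired_clean(default_bias):
    """Artifact-free paired surveys, n=20000 each, fixed seed."""
    cfg = clean_population(20_000, seed=42)
    return make_paired_surveys(cfg, default_bias, seed=42)


@pytest.fixture(scope="session")
def paired_filtered(default_bias):
    """Default-config paired surveys after exclusions, n=20000 each."""
    cfg = PopulationConfig(n=20_000, seed=7)
    out = []
    for df in make_paired_surveys(cfg, default_bias, seed=7):
        retained, _ = apply_exclusions(df)
        out.append(retained)
    return tuple(out)


@pytest.fixture(scope="session")
def reference_pair_100k(default_bias):
    """Default-condition reference pair (n=100000) after exclusions."""
    cfg = PopulationConfig(n=100_000, seed=1)
    mref, sref, _ = make_paired_surveys(cfg, default_bias, seed=1)
    return apply_exclusions(mref)[0], apply_exclusions(sref)[0]


def toy_survey(bmis, weights=None, sex="female", age_group="35-49",
               **extra) -> pd.DataFrame:
    """Minimal schema-complete survey around given BMIs."""
    n = len(bmis)
    bmis = np.asarray(bmis, dtype=float)
    height = np.full(n, 165.0)
    df = pd.DataFrame({
        "id": [f"t{i}" for i in range(n)],
        "sex": sex if isinstance(sex, str) else sex,
        "age_years": 40.0,
        "age_group": age_group,
        "race_ethnicity": "nh_white",
        "state": "OH",
        "locality": "metropolitan",
        "pregnant": False,
        "height_cm": height,
        "weight_kg": bmis * (height / 100.0) ** 2,
        "bmi": bmis,
        "sample_weight": np.ones(n) if weights is None
        else np.asarray(weights, dtype=float),
        "provenance": "measured",
    })
    for k, v in extra.items():
        df[k] = v
    return df
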