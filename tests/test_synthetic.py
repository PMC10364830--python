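"""Synthetic survey generator: determinism, bias mechanism, analytic truth."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from bmicorrect import (BiasModel, PopulationConfig, apply_reporting_bias,
                        generate_measured_population, make_paired_surveys)
from bmicorrect.synthetic import (BMI_MAX, BMI_MIN, ConfigError,
                                  StratumMixture, default_mixtures,
                                  mixture_for_prevalence)
from bmicorrect.weighted import WeightedSample, ks_compare

from conftest import clean_population


def integrate_tail_mass(mix: StratumMixture, threshold=40.0) -> float:
    """Independent oracle: numerically integrate the truncated mixture
    density above the threshold."""
    def density(x):
        total = 0.0
        for (mu, sd), wgt in (((mix.bulk_mean, mix.bulk_sd),
                               1 - mix.tail_weight),
                              ((mix.tail_mean, mix.tail_sd),
                               mix.tail_weight)):
            z = norm.pdf(x, mu, sd)
            mass = norm.cdf(BMI_MAX, mu, sd) - norm.cdf(BMI_MIN, mu, sd)
            total += wgt * z / mass
        return total
    val, _ = quad(density, threshold, BMI_MAX, limit=200)
    return val


class TestConfigValidation:
    def test_zero_population_invalid(self):
        with pytest.raises(ConfigError, match="n"):
            PopulationConfig(n=0)

    @pytest.mark.parametrize("kwargs,field", [
        (dict(pregnancy_rate=1.5), "pregnancy_rate"),
        (dict(implausible_rate=-0.1), "implausible_rate"),
        (dict(weight_dispersion=-1.0), "weight_dispersion"),
        (dict(missingness_rates={"sex": 2.0}), "missingness_rates"),
        (dict(sex_shares={"male": 0.7, "female": 0.7}), "sex_shares"),
    ])
    def test_errors_name_the_field(self, kwargs, field):
        with pytest.raises(ConfigError, match=field):
            PopulationConfig(**kwargs)

    def test_mixture_target_must_be_attainable(self):
        with pytest.raises(ConfigError):
            mixture_for_prevalence(27.0, 4.0, 38.0, 5.0, target=0.9999)


class TestGenerateMeasured:
    def test_zero_dispersion_forces_equal_weights(self):
        cfg = PopulationConfig(n=1000, weight_dispersion=0.0, seed=7)
        df = generate_measured_population(cfg)
        assert len(df) == 1000
        assert df["sample_weight"].nunique() == 1
        assert (df["provenance"] == "measured").all()

    def test_deterministic_given_seed(self):
        cfg = PopulationConfig(n=500, seed=3)
        a = generate_measured_population(cfg)
        b = generate_measured_population(cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_bmi_consistent_with_height_weight(self):
        df = generate_measured_population(clean_population(2000, seed=1))
        expect = df["weight_kg"] / (df["height_cm"] / 100) ** 2
        assert np.allclose(df["bmi"], expect, atol=1e-9)

    def test_age_group_matches_age(self):
        df = generate_measured_population(clean_population(2000, seed=2))
        bins = {"18-34": (18, 34), "35-49": (35, 49),
                "50-64": (50, 64), "65+": (65, 200)}
        for grp, (lo, hi) in bins.items():
            ages = df.loc[df["age_group"] == grp, "age_years"]
            assert ages.between(lo, hi).all()

    def test_prevalence_converges_to_analytic_tail_mass(self):
        """Empirical weighted prevalence of BMI>=40 matches the mixture's
        integrated tail mass within 0.5 percentage points at n=100000."""
        cfg = clean_population(100_000, seed=1)
        analytic = sum(
            cfg.sex_shares[s] * cfg.age_shares[a]
            * integrate_tail_mass(cfg.mixtures[(s, a)])
            for s, a in cfg.mixtures)
        # dual route: closed-form truncnorm tail inside the package
        assert cfg.severe_obesity_prevalence() == pytest.approx(
            analytic, abs=1e-8)
        df = generate_measured_population(cfg)
        w = df["sample_weight"].to_numpy()
        empirical = float(np.sum(w * (df["bmi"] >= 40)) / w.sum())
        assert abs(empirical - analytic) < 0.005


class TestReportingBias:
    def test_zero_bias_is_identity(self):
        df = generate_measured_population(clean_population(500, seed=4))
        zero = BiasModel(intercept_kgm2=0, slope_per_unit=0, noise_sd=0,
                         sex_offsets={}, age_offsets={})
        out = apply_reporting_bias(df, zero, seed=0)
        assert np.allclose(out["bmi"], df["bmi"])
        assert (out["provenance"] == "self_reported").all()

    def test_constant_shift(self):
        df = generate_measured_population(clean_population(500, seed=4))
        shift = BiasModel(intercept_kgm2=1.0, slope_per_unit=0, noise_sd=0,
                          sex_offsets={}, age_offsets={})
        out = apply_reporting_bias(df, shift, seed=0)
        assert np.allclose(out["bmi"], df["bmi"] - 1.0)

    def test_piecewise_slope_hand_example(self):
        # measured 45 with intercept .5, slope .1 above pivot 25 -> 42.5
        from conftest import toy_survey
        df = toy_survey([45.0])
        bias = BiasModel(intercept_kgm2=0.5, slope_per_unit=0.1,
                         pivot_kgm2=25.0, noise_sd=0.0,
                         sex_offsets={}, age_offsets={})
        out = apply_reporting_bias(df, bias, seed=0)
        assert out["bmi"].iloc[0] == pytest.approx(42.5)

    def test_bias_monotone_in_measured_bmi(self):
        df = generate_measured_population(clean_population(3000, seed=5))
        bias = BiasModel(noise_sd=0.0)
        out = apply_reporting_bias(df, bias, seed=0)
        sub = out[(out["sex"] == "male") & (out["age_group"] == "35-49")]
        order = np.argsort(sub["bmi_true"].to_numpy())
        gap = (sub["bmi_true"] - sub["bmi"]).to_numpy()[order]
        assert np.all(np.diff(gap) >= -1e-9)

    def test_triple_stays_consistent_and_ids_preserved(self):
        df = generate_measured_population(clean_population(400, seed=6))
        out = apply_reporting_bias(df, BiasModel(), seed=1)
        assert np.allclose(out["bmi"],
                           out["weight_kg"] / (out["height_cm"] / 100) ** 2,
                           atol=1e-9)
        assert (out["id"] == df["id"]).all()
        assert np.allclose(out["sample_weight"], df["sample_weight"])
        assert np.allclose(out["height_cm"], df["height_cm"])

    def test_missing_bmi_rejected_with_record_id(self):
        from conftest import toy_survey
        df = toy_survey([30.0, 31.0])
        df.loc[1, ["bmi", "weight_kg"]] = np.nan
        with pytest.raises(ValueError, match="t1"):
            apply_reporting_bias(df, BiasModel(), seed=0)


class TestPairedSurveys:
    def test_same_seed_bitwise_identical(self, default_bias):
        cfg = PopulationConfig(n=800, seed=9)
        a = make_paired_surveys(cfg, default_bias, seed=9)
        b = make_paired_surveys(cfg, default_bias, seed=9)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_degenerate_bias_matches_measured_in_law(self):
        cfg = clean_population(20_000, seed=10)
        zero = BiasModel(intercept_kgm2=0, slope_per_unit=0, noise_sd=0,
                         sex_offsets={}, age_offsets={})
        mref, sref, _ = make_paired_surveys(cfg, zero, seed=10)
        r = ks_compare(
            WeightedSample(mref["bmi"].to_numpy(),
                           mref["sample_weight"].to_numpy()),
            WeightedSample(sref["bmi"].to_numpy(),
                           sref["sample_weight"].to_numpy()))
        assert r.statistic < 0.02
        assert r.p_value > 0.05

    def test_reported_mean_below_measured_mean(self, paired_clean):
        mref, _, target = paired_clean
        wm = np.average(mref["bmi"], weights=mref["sample_weight"])
        wt = np.average(target["bmi"], weights=target["sample_weight"])
        assert wt < wm

    def test_tail_distortion_of_reported_prevalence(self, paired_clean):
        """Naive reported severe-obesity prevalence sits well below the
        measured population's (the headline distortion the method fixes)."""
        mref, _, target = paired_clean
        def prev(df, col):
            w = df["sample_weight"].to_numpy()
            return np.sum(w * (df[col] >= 40)) / w.sum()
        naive = prev(target, "bmi")
        truth = prev(target, "bmi_true")
        assert (truth - naive) / truth >= 0.20
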