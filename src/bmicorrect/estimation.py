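"""Design-weighted prevalence estimation and subgroup comparison.

Point estimates are Horvitz-Thompson style weighted proportions
p_hat = sum(w x) / sum(w). Variance uses the weights-only linearization of
the ratio estimator, se^2 = sum(w_i^2 (x_i - p_hat)^2) / (sum w)^2, which
reduces to the classical binomial linearization at unit weights. 95% CIs
are computed on the logit scale and mapped back to [0, 1]; degenerate
estimates (p_hat of exactly 0 or 1) get exact one-sided Clopper-Pearson
style bounds at the effective sample size. Subgroup contrasts use
large-sample two-sided z tests on the difference of estimates, without
multiplicity adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

SEVERE_OBESITY_BMI = 40.0

Z95 = 1.959963984540054  # norm.ppf(0.975)


def classify_severe_obesity(bmi) -> bool | np.ndarray:
    """Severe (class III) obesity indicator: BMI >= 40, boundary inclusive."""
    x = np.asarray(bmi, dtype=float)
    if not np.all(np.isfinite(x) & (x > 0)):
        raise ValueError("bmi must be finite and positive")
    out = x >= SEVERE_OBESITY_BMI
    return out if out.ndim else bool(out)


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Weighted proportion for one domain, with SE and 95% CI."""

    label: str
    p_hat: float
    se: float
    ci_low: float
    ci_high: float
    n_unweighted: int
    sum_weights: float

    def __post_init__(self):
        if not (0.0 <= self.ci_low <= self.p_hat <= self.ci_high <= 1.0):
            raise ValueError(
                f"{self.label}: CI bounds must bracket the estimate in [0,1]")

    def as_percent(self) -> tuple[float, float, float]:
        """(estimate, ci_low, ci_high) on the percent scale."""
        return (100 * self.p_hat, 100 * self.ci_low, 100 * self.ci_high)


@dataclass(frozen=True)
class ComparisonResult:
    """Two-sided large-sample z contrast between two prevalence estimates."""

    label_a: str
    label_b: str
    difference: float
    z: float
    p_value: float
    significant_at_05: bool


def _logit_ci(p_hat: float, se: float, n_eff: float,
              alpha: float = 0.05) -> tuple[float, float]:
    zcrit = norm.ppf(1 - alpha / 2)
    if p_hat <= 0.0:
        return 0.0, min(1.0, 1.0 - (alpha / 2) ** (1.0 / max(n_eff, 1.0)))
    if p_hat >= 1.0:
        return max(0.0, (alpha / 2) ** (1.0 / max(n_eff, 1.0))), 1.0
    logit = np.log(p_hat / (1 - p_hat))
    se_logit = se / (p_hat * (1 - p_hat))
    lo, hi = logit - zcrit * se_logit, logit + zcrit * se_logit
    return float(1 / (1 + np.exp(-lo))), float(1 / (1 + np.exp(-hi)))


def weighted_prevalence(records: pd.DataFrame,
                        indicator=None,
                        domain=None,
                        label: str = "overall",
                        bmi_column: str = "bmi",
                        alpha: float = 0.05) -> PrevalenceEstimate:
    """Weighted prevalence of a binary outcome over a survey domain.

    ``indicator`` is a boolean array aligned with ``records`` (default:
    severe obesity computed from ``bmi_column``); ``domain`` an optional
    boolean mask restricting the estimate to a subpopulation.
    """
    if indicator is None:
        indicator = classify_severe_obesity(records[bmi_column])
    x = np.asarray(indicator, dtype=float)
    w = records["sample_weight"].to_numpy(dtype=float)
    if domain is not None:
        keep = np.asarray(domain, dtype=bool)
        x, w = x[keep], w[keep]
    if x.size == 0:
        raise ValueError(f"domain {label!r} is empty")
    sw = w.sum()
    p_hat = float(np.sum(w * x) / sw)
    se = float(np.sqrt(np.sum(w ** 2 * (x - p_hat) ** 2)) / sw)
    n_eff = sw ** 2 / np.sum(w ** 2)
    ci_low, ci_high = _logit_ci(p_hat, se, n_eff, alpha)
    return PrevalenceEstimate(label=label, p_hat=p_hat, se=se,
                              ci_low=min(ci_low, p_hat),
                              ci_high=max(ci_high, p_hat),
                              n_unweighted=int(x.size),
                              sum_weights=float(sw))


def estimate_by_groups(records: pd.DataFrame,
                       grouping: list[str] | None = None,
                       indicator=None,
                       bmi_column: str = "bmi") -> pd.DataFrame:
    """One prevalence row per level of each grouping field, plus overall.

    Returns a tidy frame (group, label, p_hat, se, ci_low, ci_high,
    n_unweighted, sum_weights). Levels with no records are absent, not zero.
    """
    grouping = list(grouping or [])
    unknown = [g for g in grouping if g not in records.columns]
    if unknown:
        raise ValueError(f"unknown grouping field(s): {unknown}")
    if indicator is None:
        indicator = classify_severe_obesity(records[bmi_column])

    rows = [("overall", weighted_prevalence(records, indicator,
                                            label="overall"))]
    for g in grouping:
        col = records[g]
        for level in sorted(col.dropna().unique()):
            est = weighted_prevalence(records, indicator,
                                      domain=(col == level).to_numpy(),
                                      label=str(level))
            rows.append((g, est))
    return pd.DataFrame(
        [{"group": grp, "label": e.label, "p_hat": e.p_hat, "se": e.se,
          "ci_low": e.ci_low, "ci_high": e.ci_high,
          "n_unweighted": e.n_unweighted, "sum_weights": e.sum_weights}
         for grp, e in rows])


def compare_estimates(a: PrevalenceEstimate, b: PrevalenceEstimate,
                      alpha: float = 0.05) -> ComparisonResult:
    """Two-sided z test of p_hat_a - p_hat_b with independent SEs."""
    if a.se == 0.0 and b.se == 0.0:
        if a.p_hat == b.p_hat:
            return ComparisonResult(a.label, b.label, 0.0, 0.0, 1.0, False)
        raise ValueError("both standard errors are zero with unequal "
                         "estimates")
    diff = a.p_hat - b.p_hat
    z = diff / float(np.hypot(a.se, b.se))
    p = float(2 * norm.sf(abs(z)))
    return ComparisonResult(a.label, b.label, diff, float(z), p, p < alpha)


def se_from_ci(ci_low: float, ci_high: float) -> float:
    """Back out a standard error from a printed symmetric 95% CI:
    (ci_high - ci_low) / (2 * 1.96). Used to re-test published tables."""
    if not ci_low < ci_high:
        raise ValueError("ci_low must be < ci_high")
    return (ci_high - ci_low) / (2 * 1.96)
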