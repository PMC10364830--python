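"""Weighted order statistics: ECDF-inverse quantiles, ranks, two-sample KS.

Conventions
-----------
The weighted empirical distribution places mass ``w_i / W`` on each
observation; a weight of ``k`` is read as ``k`` replicates of the record,
the natural semantics for survey sampling weights. Quantiles invert the
ECDF with linear interpolation between order statistics at normalized
cumulative-weight Hazen positions: an observation spanning cumulative
weight ``(C - w, C]`` contributes interpolation nodes at
``(C - w + h) / W`` and ``(C - h) / W`` with ``h = min(w, 1) / 2``, so for
integer weights the quantile function is *exactly* the classical
``(i - 1/2)/n`` Hazen interpolation applied to the replicate-expanded
sample (weights above 1 produce flat stretches, as ties in the expansion
do), while unit and sub-unit weights reduce to interpolation between
cumulative-weight midpoints. Ranks collapse tied values to their average
cumulative weight, again matching the expanded-sample midpoint rank; on
tie-free samples with weights <= 1 ``rank(quantile(p)) = p`` exactly
within the interpolation range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import distributions


@dataclass(frozen=True)
class WeightedSample:
    """Values with positive sampling weights, optionally tagged by stratum."""

    values: np.ndarray
    weights: np.ndarray
    stratum: tuple[str, str] | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if v.ndim != 1 or w.shape != v.shape:
            raise ValueError("values and weights must be 1-d and equal length")
        if v.size == 0:
            raise ValueError("empty sample")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        if not np.all(np.isfinite(w) & (w > 0)):
            raise ValueError("weights must be positive and finite")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "weights", w)

    @property
    def n_effective(self) -> float:
        """Kish effective sample size (sum w)^2 / sum w^2."""
        w = self.weights
        return float(w.sum() ** 2 / np.square(w).sum())


def _sorted(sample: WeightedSample):
    order = np.argsort(sample.values, kind="stable")
    return sample.values[order], sample.weights[order]


def weighted_quantile(sample: WeightedSample, p) -> float | np.ndarray:
    """Inverse weighted ECDF at probability ``p`` (scalar or array).

    p=0 returns the minimum, p=1 the maximum; interior p interpolates
    linearly between weighted order statistics (replication semantics — see
    the module docstring).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p must be in [0, 1]")
    v, w = _sorted(sample)
    cw = np.cumsum(w)
    h = 0.5 * np.minimum(w, 1.0)
    pos = np.empty(2 * v.size)
    pos[0::2] = (cw - w + h) / cw[-1]  # enter the observation's block
    pos[1::2] = (cw - h) / cw[-1]      # leave it
    out = np.interp(p, pos, np.repeat(v, 2))  # clamps: p<=pos[0] -> min
    return out if out.ndim else float(out)


def weighted_rank(sample: WeightedSample, v) -> float | np.ndarray:
    """Weighted-ECDF position of value(s) ``v`` in [0, 1].

    Inverse of :func:`weighted_quantile` on tie-free samples; tied values get
    their average cumulative weight (midpoint convention). Values strictly
    below the sample minimum map to 0, strictly above the maximum to 1.
    """
    x = np.asarray(v, dtype=float)
    sv, sw = _sorted(sample)
    uniq, start = np.unique(sv, return_index=True)
    uw = np.add.reduceat(sw, start)
    cw = np.cumsum(uw)
    pos = (cw - 0.5 * uw) / cw[-1]
    r = np.interp(x, uniq, pos)
    r = np.where(x < uniq[0], 0.0, np.where(x > uniq[-1], 1.0, r))
    return r if r.ndim else float(r)


def weighted_ecdf(sample: WeightedSample, x) -> np.ndarray:
    """Right-continuous weighted ECDF evaluated at points ``x``."""
    v, w = _sorted(sample)
    cw = np.cumsum(w)
    cw = cw / cw[-1]
    idx = np.searchsorted(v, np.asarray(x, dtype=float), side="right")
    out = np.where(idx == 0, 0.0, cw[np.minimum(idx, v.size) - 1])
    return out


@dataclass(frozen=True)
class KSResult:
    """Two-sample Kolmogorov-Smirnov comparison of weighted ECDFs."""

    statistic: float
    p_value: float
    n_eff_a: float
    n_eff_b: float


def ks_compare(a: WeightedSample, b: WeightedSample) -> KSResult:
    """Weighted two-sample KS test.

    D is the supremum of |ECDF_a - ECDF_b| over the pooled support. The
    p-value uses the asymptotic two-sample reference distribution
    ``kstwo(round(m n/(m+n)))`` with Kish effective sample sizes in place of
    the counts; with unit weights both D and the p-value coincide with the
    classical asymptotic two-sample test (scipy's ``ks_2samp`` in
    asymptotic mode).
    """
    xs = np.concatenate([a.values, b.values])
    d = float(np.max(np.abs(weighted_ecdf(a, xs) - weighted_ecdf(b, xs))))
    na, nb = a.n_effective, b.n_effective
    en = na * nb / (na + nb)
    p = float(np.clip(distributions.kstwo.sf(d, max(int(np.round(en)), 1)),
                      0.0, 1.0))
    return KSResult(statistic=d, p_value=p, n_eff_a=na, n_eff_b=nb)
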