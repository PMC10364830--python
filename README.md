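# bmicorrect

Quantile-matching correction of self-report bias in survey body-mass
index (BMI), with design-weighted severe-obesity prevalence estimation
and published-style reporting.

## The problem

State-level obesity surveillance relies on large telephone surveys that
collect *self-reported* height and weight. People under-report weight and
over-report height, and the distortion grows with BMI, so the prevalence
of severe (class III) obesity — BMI ≥ 40, where BMI = weight [kg] /
height [m]² — is badly underestimated from self-reported data. Smaller
examination surveys measure height and weight directly but cannot support
state-level estimates. This package is for epidemiologists and
surveillance analysts who want to correct a self-reported survey's entire
BMI distribution against a measured reference and then produce
design-weighted prevalence estimates and state tables from the corrected
microdata.

## The method

Within each sex × age-group stratum, using a reference period covered by
both surveys, estimate the quantile-specific bias

    δ(p) = Q_measured(p) − Q_self-reported(p),   p ∈ {0.01, …, 0.99},

fit a cubic spline to (p, δ(p)), then shift each target-survey record by
the bias at its own sample-weighted quantile:

    bmi*_i = bmi_i + δ_s(rank_s(bmi_i)).

Because the whole distribution is matched — not a conditional mean — the
upper tail is preserved, which is what severe-obesity estimation needs. A
weighted two-sample Kolmogorov–Smirnov test (effective-sample-size
asymptotics) validates that the corrected and measured distributions are
statistically similar. Downstream, prevalence is the weighted proportion
with weights-only linearized variance and logit-scale 95% CIs, and the
reporting layer reproduces published-table logic: threshold counts,
ranges, and a directional z-test screen for states above the national
estimate. Synthetic paired surveys with known ground truth (parametric
BMI-scale bias on a two-component mixture population) make the whole
pipeline testable end to end; see `docs/methods.md` for the model and all
conventions.

## Worked example

```python
from bmicorrect import RunConfig, run_pipeline

manifest = run_pipeline(RunConfig(seed=1))   # three surveys of n=100000
print(manifest["prevalence_pct"])
print(manifest["recovery_error_pp"], manifest["ks"]["pooled"])
```

prints (exactly, given the seed):

```
{'self_reported': 6.438334, 'corrected': 8.89727,
 'ground_truth': 8.980127, 'analytic_population': 8.7783}
0.082857 {'statistic': 0.0046907159, 'p_value': 0.6271421842}
```

Read: the naive self-reported severe-obesity prevalence (6.44%) sits ~28%
below the generator's ground truth for the same people (8.98%); the
corrected estimate (8.90%) recovers it to within 0.08 percentage points;
and the weighted KS test cannot distinguish the corrected target from the
measured reference (p = 0.63, comfortably above the .05 similarity bar).

The same machinery runs from the shell:

```sh
bmicorrect all --seed 1 --out runs/demo       # full pipeline + manifest
bmicorrect report                             # packaged state-table summary
```

`bmicorrect report` applies the reporting operations to the packaged
published-style state table: 16 states above 10% corrected prevalence and
17 states significantly above the national 8.8% (8.6–9.0), with the
corrected range 5.5% (Massachusetts) to 13.2% (West Virginia).

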