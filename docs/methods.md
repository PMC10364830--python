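# Methods

`bmicorrect` implements a distribution-level correction for self-report
bias in survey body-mass index (BMI), together with the survey-weighted
estimation and reporting machinery needed to turn corrected microdata into
published-style severe-obesity prevalence tables. This note records the
model, the conventions, and the design choices, in the order the pipeline
applies them.

## The measurement problem

Large telephone surveys (the BRFSS role in this package) collect
*self-reported* height and weight; people tend to under-report weight and
over-report height, and the distortion grows with BMI. Examination surveys
(the NHANES role) measure height and weight directly but are far too small
for state-level estimation. Severe (class III) obesity — BMI ≥ 40, with
BMI = weight [kg] / height [m]² — sits in the upper tail, exactly where
self-report bias bites hardest, so naive self-reported prevalence
understates it badly. Regression-style corrections that predict measured
BMI from reported BMI shrink the tail and still underestimate high-BMI
prevalence; matching the *whole distribution* does not.

## Quantile-matching correction

Within each sex × age-group stratum (2 × 4 = 8 strata; age groups 18–34,
35–49, 50–64, ≥65):

1. From a *reference period* in which both surveys observe the same
   population, compute the weighted quantile functions `Q_meas` (measured
   reference) and `Q_self` (self-reported reference), and the
   quantile-specific bias

       δ(p) = Q_meas(p) − Q_self(p)

   on an equally spaced grid of probabilities, by default the 99
   percentiles 0.01 … 0.99.
2. Fit a cubic spline to (p, δ(p)). Outside the grid the curve is clamped
   to its endpoint values: quantile differences beyond p = 0.01/0.99 are
   not identified by the grid, and clamping prevents wild extrapolated
   tail corrections.
3. For each record of the *target* self-reported survey, compute the
   sample-weighted quantile `p_i` of its reported BMI within its own
   stratum of the target survey, and correct additively:

       bmi_corrected_i = bmi_i + δ_s(p_i).

   Signs are chosen so that δ ≥ 0 means under-reporting and zero bias is
   the identity. Ids, sampling weights and strata never change; weight in
   kg is back-solved from the corrected BMI at unchanged height so each
   record's height/weight/BMI triple stays internally consistent.
4. Validate distributional similarity with a weighted two-sample
   Kolmogorov–Smirnov test between the corrected target and the measured
   reference (similar means p > .05). Both the pooled test and per-stratum
   tests are computed, since the pooled ECDFs can agree while a stratum
   misfits.

### Spline choice

The default fit is a **natural cubic interpolating spline** through the 99
raw quantile differences. With reference surveys of realistic size the raw
differences are already stable, and interpolation makes the method's
defining guarantee exact: correcting the self-reported reference against
its own curves reproduces the measured reference's grid quantiles up to
rank discretization (observed ≲ 0.02 BMI units at the default problem
size, against a documented tolerance of 0.1). A cubic *smoothing* spline
with generalized cross-validation (`SplineConfig(kind="smoothing")`) is
available for small or noisy references; GCV smoothing can deviate from
the raw tail differences by several tenths of a BMI unit, which is why it
is not the default.

### Monotonicity

The map v → v + δ(rank(v)) need not be monotone when δ decreases steeply.
The correction counts and logs adjacent-rank order inversions per stratum;
an optional isotonic rearrangement (`isotonic=True`) restores the original
ordering within strata. It is off by default — a diagnostic that is
reported beats a silent reordering.

### Weighted quantiles and ranks

Sampling weights are treated as replication counts. An observation with
weight `w` spanning cumulative weight `(C−w, C]` contributes interpolation
nodes at `(C−w+h)/W` and `(C−h)/W`, `h = min(w, 1)/2`; for integer weights
the quantile function is then *exactly* the classical Hazen
`(i−1/2)/n` interpolation applied to the replicate-expanded sample, and
unit or sub-unit weights reduce to interpolation between cumulative-weight
midpoints. Ranks collapse ties to their average cumulative weight
(midpoint convention), matching the expanded-sample rank; p = 0 and
p = 1 return the sample minimum and maximum. On tie-free samples with
weights ≤ 1 rank∘quantile is the exact identity inside the interpolation
range; at survey scale the deviation is bounded by the largest single
weight share, far below one grid step.

### Weighted KS test

D is the supremum difference of the two weighted ECDFs over the pooled
support. The p-value uses the asymptotic two-sample reference with Kish
effective sample sizes `(Σw)²/Σw²` in place of counts; with unit weights
statistic and p-value coincide exactly with scipy's classical asymptotic
two-sample test. Effective-size asymptotics are an approximation — weights
enter the ECDF variance only through n_eff — but they reduce correctly and
are conservative in the direction that matters for a similarity check.

## Exclusion screening

Before any estimation, records pass a sequential screen in a fixed order:
pregnant → missing sex → missing age → missing race/ethnicity → missing or
biologically implausible height/weight (height < 50 cm or > 300 cm, weight
< 20 kg; strict inequalities, boundaries retained; any one condition
triggers exclusion). A record is counted at the first criterion it fails,
so the log telescopes exactly; the retained *set* is invariant to
criterion order — only attribution moves. A missing pregnancy flag is
treated as not pregnant: only identified pregnant respondents are
excluded. No imputation is attempted.

## Design-weighted estimation

Prevalence is the weighted proportion `p̂ = Σwx/Σw` with the weights-only
linearization `se² = Σw²(x−p̂)²/(Σw)²`; 95% CIs are computed on the logit
scale and mapped back, with exact one-sided Clopper–Pearson-style bounds
at the Kish effective size when p̂ is exactly 0 or 1. This is a
weights-only approximation: true design-based variance (strata, PSUs,
replicate weights, as in SUDAAN) requires design information the package
deliberately does not model. Calibration is checked empirically — on
weighted Bernoulli simulations (n = 2,000, 1,000 replicates) the CI covers
the truth ~95% of the time.

Subgroup contrasts are large-sample two-sided z tests on the difference of
estimates (survey degrees of freedom are enormous, so the t reference is
indistinguishable); no multiplicity adjustment, by design. Internally
everything is a proportion; the reporting layer formats percent with one
decimal.

## Reporting layer and published-table fixtures

Two delimited-text fixtures transcribe published-style severe-obesity
tables (overall/subgroup, and by state with sex-stratified corrected
columns, estimates with 95% CIs in percent). The reporting operations —
threshold counts, column extremes with tie handling, relative
underestimation `100(corrected − self)/corrected`, and the
above-national significance screen — run identically on these fixtures
and on tables produced by the synthetic pipeline.

The above-national screen derives SEs from printed CIs (half-width/1.96)
and flags rows whose estimate exceeds the national value with a
**one-sided** z test at α = 0.05. The screen is inherently directional
("significantly higher than national"), and with SEs reconstructed from
*rounded* printed CIs the one-sided form reproduces published footnote
markers exactly, where a two-sided form narrowly drops borderline states
whose unrounded microdata tests had been significant. District of
Columbia stays in every table but is excluded by default from "N states"
counts.

## Synthetic data: what it emulates, what it does not

The generator draws three independent surveys from one known population —
a measured reference, a self-reported reference, and a self-reported
target — so the whole pipeline is testable against stored ground truth
(each self-reported record keeps its pre-bias BMI in `bmi_true`).

* **Measured BMI** per stratum: a two-component truncated-normal mixture
  on [15, 75] — a bulk component (men 27.8 ± 4.1, women 27.0 ± 4.6) and a
  heavy right-tail component (men 39.5 ± 5.0, women 40.5 ± 5.5). Tail
  weights are solved in closed form per stratum so severe-obesity
  prevalence follows the surveillance pattern: ≈ 8.8% overall, women above
  men (ratio 11.1 : 6.5), middle ages highest and ≥65 lowest. The
  population tail mass is available analytically and is the recovery
  target for the estimators.
* **Self-report bias**, applied on the BMI scale: reported = measured −
  (0.3 + 0.08·max(0, BMI−25) + sex/age offsets) + N(0, 0.5²), with women
  +0.3 and ages ≥65 +0.2. Nonnegative intercept and slope reproduce the
  two qualitative facts the mechanism must show: reported ≤ measured in
  expectation above the pivot, and bias non-decreasing in BMI. Under
  these defaults naive severe-obesity prevalence runs ~28% relatively
  below truth — the order of distortion seen in real surveillance.
  Bias is injected on BMI directly with weight back-solved at fixed
  height, mirroring the correction's own convention.
* **Sampling weights**: log-normal with σ = 0.8 (CV ≈ 0.95, Kish design
  effect ≈ 1.9 — a realistic amount of weight dispersion for a telephone
  survey), normalized to mean 1; σ = 0 gives exactly equal weights.
* **Exclusion-triggering artifacts**: pregnancy (2% of women under 50),
  completely-at-random missingness (1% age, 1% race/ethnicity, 0.4% each
  height/weight), implausible anthropometrics (0.3%: height 30 cm or
  320 cm, or weight 15 kg). Injected after bias so they exist in every
  survey; sufficient to exercise the filter, not a model of real
  missingness (which is not MCAR).

Not emulated: the telephone-sampling design itself (strata, PSUs, raking),
pregnancy or race effects on BMI, secular drift between reference and
target periods, and informative missingness. Passing tests therefore show
that the method recovers truth *when the reference pair really measures
the same population as the target and bias acts stratum-wise on BMI
quantiles* — they cannot certify the substantive accuracy of any real
survey correction.

## Problem sizes and numerical conventions

The default study condition is n = 100,000 per survey; parameter-recovery
checks run five seeds at that size (corrected prevalence within ±0.5
percentage points of truth; naive at least 20% relatively below), KS
validation runs 20 replicates at n = 20,000 (p > .05 in ≥ 90%), and CI
calibration 1,000 replicates at n = 2,000. All randomness derives from one
seed via `numpy` `SeedSequence` splitting, so identical config + seed give
byte-identical outputs, including the JSON manifest. Ties in ECDFs use the
average-cumulative-weight convention; curve evaluation outside the grid is
clamped; prevalence tables round-trip through fixed six-decimal text.

## Known limitations

* Weights-only variance understates design effects from clustering; CIs
  are calibrated for independent weighted draws only.
* The KS p-value with effective sample sizes is asymptotic and
  approximate under strongly dispersed weights.
* Quantile-difference curves are fitted independently per stratum; no
  pooling or smoothing across strata.
* The correction assumes the reference pair and the target share the
  stratum-wise bias structure; nothing in the data can test that
  assumption from the target survey alone.
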