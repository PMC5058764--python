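# Methods

This note documents the models, parameter choices and numerical conventions
behind the package, and what the synthetic-data tests do and do not
establish about real cohorts.

## The PSA deconvolution model

Serum PSA is modelled as an additive mixture of a benign and a tumour
component. The benign component assumes a fixed epithelial fraction
(`epithelial_fraction`, default 0.1, dimensionless) of the benign gland
volume and a fixed serum contribution per cc of epithelium
(`benign_secretion`, default 0.30 ng/ml per cc). Both are population-level
constants taken from the prostate literature, not estimated per patient;
they are configurable because the literature value can also be read as a
rate per cc of whole benign tissue — either reading is expressible by
rescaling the pair. Benign volume is prostate volume minus total tumour
volume, clamped at zero (a tumour occupying the whole gland contributes all
serum PSA); clamping is recorded as a per-case flag.

Subtracting the benign estimate can leave a non-positive "cancer PSA" when
a large gland accompanies a small tumour. Such cases are retained with
`valid_for_log=False` and excluded only from log-scale analyses: flooring
at a small positive constant would bias group means downward in exactly the
strata (high benign volume, low secretion) the analysis cares about.

tPSAD is cancer PSA divided by tumour volume (total by default; the index
lesion's volume is an option, with missing index volumes skipped and
flagged). The analysis scale is the natural log, matching the proportional,
right-skewed behaviour of secretion rates.

**Eligibility filters** run sequentially with first-match-wins attribution:
missing pre-operative PSA, then PSA above 20 ng/ml (to limit contamination
by occult metastatic disease), then gland size above the cohort's own 95th
percentile (very large glands make the benign subtraction dominate). The
percentile is computed on gland weight when every remaining case has one,
otherwise on prostate volume at 1 g ≈ 1 cc, with linear interpolation
between order statistics. Because the cut is empirical, the excluded
fraction is ~5% by construction regardless of the cohort's scale.

## Volumetry

Tumour volume uses plain Cavalieri summation: section areas (mm²) times the
sectioning interval (default 3.5 mm), times a multiplicative correction for
formalin shrinkage (default 1.25), divided by 1000 to give cc. Each section
represents a full slab — terminal sections are not half-weighted — keeping
the estimate linear in every area. Gland volume uses the ellipsoid formula
π/6·L·W·H; the π/6 coefficient was chosen over the sonographic 0.52
approximation (the two differ by 0.7%).

## Survival machinery

Kaplan–Meier, the k-sample log-rank test and Cox proportional hazards are
implemented in-repo (validated in the test suite against lifelines, an
exhaustive label-permutation oracle, and direct numerical maximization of
the written-out partial likelihood).

The Cox fit maximizes the **Breslow** partial likelihood by Newton–Raphson
with step-halving; Efron tie handling is not implemented. Convergence is
declared when the largest score component falls below 10⁻⁸ or the Newton
step becomes smaller than 10⁻¹⁰ in every coordinate (at several thousand
subjects, rounding noise in the cumulative sums floors the achievable score
below any fixed absolute tolerance, so a vanishing step is the sharper
criterion). A coefficient exceeding 10 in absolute value (hazard ratio
> 2×10⁴) is treated as a monotone likelihood — perfect separation — and the
fit is flagged unconverged rather than reported. Wald 95% intervals use
z = 1.959964. The log-rank test uses the hypergeometric variance with the
(n−d)/(n−1) tie correction; with untied event times the two-group statistic
coincides with the Cox score test at β = 0, and the tests assert that
identity on tie-free data.

Quintile stratification cuts at the 20/40/60/80th percentiles (linear
interpolation); a value equal to a cut point goes to the lower stratum, and
an all-equal input collapses to one stratum with a warning. Group
comparisons use the classical pooled-variance t-test for two groups and
one-way ANOVA for three or more.

## Cross-study rank meta-analysis

Within each study a pooled-variance Student t-test (Welch is a flag)
compares high-grade samples against the comparator class, giving one-sided
p-values per direction. Genes are ranked by p-value within each study
(average ranks on ties) and rescaled to percentiles in (0, 1] so platforms
with different gene universes are commensurable; raw ranks are also kept.
The cross-study summary is the **median percentile**, tested against a null
in which each contributing study draws an independent Uniform(0, 1]
percentile: with `n_perm` draws of the null median, the reported p-value is
the smoothed tail fraction (1 + #{null ≤ observed})/(n_perm + 1), bounded
below by 1/(n_perm + 1); fewer than 100 permutations are rejected as
unstable. The median summary and the permutation null are the package's
chosen reading of "rank enrichment against a random distribution" — an
exact published null for the original database tool does not exist; both
the summary statistic and the smoothing are configurable.

One structural consequence worth knowing: a gene's best achievable p-value
decays with the size of the study gene universes (rank 1 of 100 can never
look as extreme as rank 1 of 10,000), so meaningfully powered runs need
universes much larger than the gene set of interest.

Count preprocessing follows standard RNA-seq practice. CPM is counts over
library size times 10⁶; the expression filter removes genes with CPM below
a threshold (default 1) in strictly more than a third of samples. TMM
factors are computed against a reference sample (the one whose 75th count
percentile is closest to the cohort mean), double-trimming M-values (30%)
and A-values (5%) and averaging the surviving M-values with inverse
delta-method variance weights; factors are rescaled to geometric mean 1.
The precision weights depend weakly on sequencing depth, so the weighted
factors are only asymptotically invariant to rescaling a single library;
`weighted=False` gives the exactly invariant unweighted trimmed mean. The
in-repo differential-expression path for count matrices is log-CPM + t-test;
negative-binomial GLM fitting is deliberately out of scope. Benjamini–
Hochberg adjustment is provided as a utility (delegating to statsmodels).

## IHC optical densitometry

Optical density of a stained region is OD = log₁₀(255 / mean intensity) of
an 8-bit image, measured on `n_regions` (default 3) equal-size square
regions placed uniformly at random (seeded; overlap allowed, with a
resampling no-overlap option); the summary is the arithmetic mean. The
region side defaults to 128 px and is configurable, since no canonical size
exists.

Colour deconvolution uses the standard published H-DAB absorbance vectors —
haematoxylin (0.650, 0.704, 0.286), DAB (0.269, 0.568, 0.778) — completed
to an invertible basis by the normalized cross product. The package's
absorbance convention is A = −log₁₀((I + 1)/256), chosen so a blank pixel
(I = 255) has exactly zero absorbance and the forward synthesis
I = 256·10^(−A) − 1 is its exact inverse; the +1 regularizer avoids log(0)
on saturated pixels. With the full three-stain basis, deconvolution
followed by resynthesis reproduces a quantized image exactly; recovering
*stain amounts* from an 8-bit image is, however, limited by quantization
amplified through the inverse stain matrix (the two named vectors are far
from orthogonal), so amount-level accuracy is asserted on the continuous
forward model and image/OD-level accuracy on the quantized path.

## The synthetic cohort generator

The generator emulates a single-institution prostatectomy series. Anchored
quantities (their defaults are the study conditions): grade mix
13.8/76.5/9.7% (low/intermediate/high), overall pT3 30.4%, EPE 29.4%, SVI
6%, recurrence 23.2%, prostate volume log-normal with median 32.2 cc and
IQR 24.2–43.5, tumour volume log-normal with median 2.6 cc and IQR 1.3–4.8,
and per-cc secretion anchored at 4.01 (low grade, organ-confined) and 1.71
(high grade, invasive) ng/ml per cc. Log-normal (μ, σ) come from
μ = ln median and σ = ln(Q3/Q1)/(2·0.6745).

Free choices, fixed once as realistic values and not revisited:

- **Stage gradient.** pT3 probability 0.08 for low grade and 0.70 for high
  grade, with the intermediate value solved so the grade-weighted overall
  rate hits 30.4% (infeasible combinations raise a calibration error). EPE
  and SVI are confined to pT3 disease (they are its defining features) at
  conditional rates 0.294/0.304 and 0.06/0.304; positive margins occur at
  0.20 (pT2) and 0.35 (pT3), giving ≈25% overall.
- **Grade-dependent tumour size.** Median multipliers 0.6 (low) and 2.0
  (high); the intermediate multiplier is solved so the probability-weighted
  mean log-shift is zero, preserving the overall 2.6 cc median by
  construction.
- **Secretion grid.** log s is linear in an aggressiveness score
  z = (grade index + pT3 flag)/3 ∈ [0, 1] anchored at the two printed
  values; intermediate cells interpolate geometrically (the stratum-average
  intermediate secretion is √(4.01·1.71) ≈ 2.62 ng/ml per cc).
- **Secretion noise.** Per-patient log-normal noise with σ = 0.3 (~30%
  coefficient of variation), representing combined biological and assay
  variability. Serum PSA is then built generatively as
  benign PSA + secretion·tumour volume·noise, with a 9/1228 missing-PSA
  rate.
- **Outcome model.** Exponential event times with planted log hazard ratios
  ln 1.68 (EPE), ln 1.90 (SVI), ln 2.12 (margins), ln 1.97 (intermediate
  grade), ln 5.28 (high grade) on a baseline hazard of 8×10⁻⁴ events/month;
  administrative censoring at a horizon solved by bisection so the expected
  event fraction equals 23.2% (≈98 months at the defaults; no
  loss-to-follow-up process). tPSAD itself carries no independent planted
  hazard by default — its association with recurrence flows through grade
  and stage, so the multivariable model shows HR ≈ 1 for ln(tPSAD), while
  an optional parameter plants a direct effect for sensitivity analyses.

One global seed spawns independent child streams per component (grade,
stage, features, volumes, PSA, outcome), so a stage can be regenerated
without disturbing the others; identical (parameters, seed) give
byte-identical cohort CSVs.

Because the noise-free, zero-epithelium limit of the generator makes
serum PSA / tumour volume equal the planted secretion exactly, the
deconvolution pipeline admits an exact round-trip test; with noise, the
geometric-mean tPSAD per (grade, stage) stratum equals the planted
secretion up to a small, design-inherent downward selection bias: the
PSA > 20 filter preferentially removes large-volume, high-noise patients,
shifting stratum geometric means by roughly −2 to −4% at the default noise
level. This is a property of the emulated cohort-selection design, not a
numerical artefact, and the calibration checks operate within it.

The expression generator draws Gaussian log₂ expression with gene-specific
baselines (mean 7, SD 1) and plants a mean shift of −2 on a 25-gene
cassette and +1 on AR in the high-grade class (σ = 0.5 within groups, 20
samples per class, 5 studies, 1000 genes) — effect sizes large enough that
the cassette is recovered in full, which is the point: the generator tests
machinery, not discovery power. The IHC generator emits uniform patches
whose intensity encodes a target OD (error if the implied intensity falls
below the 8-bit floor), plus an RGB variant synthesized through the forward
stain model.

**What passing tests do not show.** The generator draws covariates from the
planted marginals with a simple conditional structure; real cohorts have
correlated pathology (grade–volume–stage dependence beyond the planted
shifts), non-exponential hazards, informative censoring, measurement error
in planimetry, and secretion heterogeneity beyond a shared log-normal.
Recovery of the planted values demonstrates correctness of the estimators
and the calibration, not clinical validity of the constants.

## Problem sizes

The calibration checks use one 20,000-patient cohort for the secretion,
event-fraction and volume targets and 25 replicate 5,000-patient cohorts
for hazard-ratio recovery; the null-calibration check uses 500 genes across
5 studies with 2,000 permutations; oracle-equivalence checks run at n ≤ 8
where exhaustive enumeration is exact. These sizes put Monte-Carlo error
well inside each check's tolerance while keeping the whole suite fast.
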