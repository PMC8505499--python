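# Methods

## The trimodal radiodensity model

A mid-thigh CT cross-section yields voxel radiodensities in Hounsfield
units (HU).  Restricted to the soft-tissue window [−200, 200) and binned
(default 1 HU, half-open bins, model evaluated at bin centres), the
histogram is treated as a quasi-probability density equal to the sum of
three skew-Gaussian components — fat, loose connective/water-equivalent
tissue, and lean muscle:

φ(x; N, μ, σ, α) = N/(σ√(2π)) · exp(−(x−μ)²/2σ²) · erfc(α(x−μ)/(σ√2)).

This is N times a skew-normal density with location μ, scale σ and shape
−α.  Two analytic identities anchor the implementation and its tests:

* **Apex**: φ(μ) = N/(σ√(2π)) for any α, since erfc(0) = 1.
* **Mass**: ∫φ = N exactly, for any α — amplitudes are integrated tissue
  masses, hence proportional to voxel counts.

Sign convention: α > 0 skews the curve toward *lower* HU (sampled third
central moment has sign −α).  Muscle therefore carries positive α and fat
negative α — both peaks slope inward toward 0 HU — while the connective
component's skewness is identically zero *structurally* (it is not a free
parameter), leaving 4 + 3 + 4 = 11 free parameters.

Model assumptions worth stating: tissue classes are exhaustive within the
soft-tissue window; each class is unimodal skew-normal; partial-volume
voxels are absorbed into the component shapes rather than modelled
separately.

## Fitting

`fit_ntra` minimizes the sum over bins of squared differences between the
model curve at bin centres and the histogram heights scaled so the
histogram area equals `scale` (bounded trust-region least squares,
`scipy.optimize.least_squares`).  Choices that matter:

* **Amplitude scale.**  Absolute amplitudes are not identifiable from a
  voxel sample — only the ratios N_i/ΣN are.  `scale` (default 1.0, i.e.
  amplitudes are mass fractions) sets the histogram area in model mass
  units; pass a known total mass to work on an absolute scale.
* **Bounds.**  σ ∈ [0.5, 60] HU; |α| ≤ 10 (prevents erfc overflow and mode
  collapse); N ≥ 0 with a loose upper bound of 10·scale; locations
  confined to widened, overlapping tissue windows (fat −200…0, connective
  −60…50, muscle 30…120 HU).  The fat < connective < muscle ordering is
  asserted post-fit rather than imposed as a hard constraint.
* **Initialization.**  Count-weighted mean and SD (floored at 1 HU) within
  the canonical tissue domains (fat −200…−10, connective −9…40, muscle
  41…200 HU); amplitude from peak height × σ√(2π); α starts at −2 (fat),
  0 (connective), +2 (muscle).  An empty domain initializes with N = 0,
  μ at the domain midpoint and σ = width/6.
* **Multistart.**  Five starts by default (the moment start plus four
  multiplicative jitters, 5% relative); the best minimum whose locations
  respect the tissue ordering wins; if none does, the best overall is
  returned flagged non-converged.
* **Degenerate inputs.**  A zero-count histogram is an error; a
  single-bin histogram drives σ to its lower bound (flagged by the bound,
  not an exception); a flat histogram has undefined R² (NaN).

A variance-weighted alternative (Pearson residuals, dividing by the
per-bin sampling SD) was evaluated and rejected: the skewness information
lives in low-count tail bins whose standardized noise then dominates the
objective, and truth-started weighted fits land farther from the
generating parameters than unweighted ones.  Unweighted least squares on
area-scaled heights is the package's objective.

At 10⁵ voxels per subject the estimator recovers amplitudes and widths
within a few percent and locations within fractions of an HU; the two
skewness parameters carry a sampling-noise floor of roughly 3–8% relative
at that voxel count (verified to be a property of the least-squares
functional itself, by restarting the optimizer at the truth), which is why
recovery checks aggregate skewness error by the median across replicate
fits rather than per fit.

## The mediation pipeline

Exposure is the five-level PA score (treated as numeric 1–5, as is
standard for Likert exposures in this literature); outcomes are the four
LEF measures at follow-up; mediators are the eleven radiodensity
parameters at follow-up; covariates are age, sex (0 = female, 1 = male;
coefficient signs are coding-dependent) and BMI, plus the same-task
baseline LEF in every outcome model.  All models are OLS with intercept on
complete cases (row-wise deletion, counts logged).  Both raw and
standardized coefficients (β = b·SD(x)/SD(y)) are reported; attenuation
uses standardized β, which reproduces published % changes from published
βs.

Holm–Bonferroni stepdown families, at family-wise α = 0.05 (inclusive
boundary: p = threshold rejects):

| step | family |
|---|---|
| 1 total effect | 4 PA tests |
| 2 mediator models | 11 PA tests (selection = survivors) |
| 3 outcome models | mediators × 4 |
| 4 attenuation models | (1 + mediators) × 4 |

Indirect effects use products of coefficients: specific = a_j·b_j with a_j
from the step-2 model and b_j from the step-4 (full) model; total = Σ
specific *by construction* (published mediation tables do not always
satisfy this additivity — printed totals there differ slightly from the
sum of printed specifics; this package enforces it).  CIs come from
resampling subjects with replacement (default B = 5000 percentile;
bias-corrected available via `method="bc"`); rank-deficient replicates are
discarded and redrawn, capped at 1% of B.  An empty step-2 selection
yields a complete report with empty mediation sections, not an error.

Also documented: recomputing attenuation from published rounded
coefficients reproduces the published −18.3% (GSF), −18.5% (GSN) and
−32.1% (STR), while TUG recomputes to −20.5% against a published −20.3% —
a rounding artefact of the printed coefficients.

## The synthetic cohort generator

`generate_cohort` simulates: PA from the published five-category
frequencies (0.398/0.167/0.077/0.183/0.175); age ~ N(74.9, 4.8²); BMI ~
N(27.3, 4.2²); sex Bernoulli (58% female); baseline LEF Gaussian at the
published baseline moments; each mediator as mean + a_j·(PA − E[PA]) +
covariate terms + Gaussian noise, centred on the published follow-up
moments; follow-up LEF as c′·PA + Σ b_j·mediator + γ·baseline + covariate
terms + noise.  Path coefficients are raw-scale (per PA point, per
mediator unit).  Noise SDs left unset are solved analytically (via the
loadings on the independent sources) so each variable's marginal SD
matches its published target, floored at 5% of the target.  TUG paths are
sign-flipped (higher = worse).  The generator returns the implied truth:
specific indirects a_j·b_j, totals, directs.

`make_paper_like_scenario` plants muscle_N and muscle_mu as the only true
mediators.  Its a-paths use the published standardized PA→muscle
magnitudes (0.0841, 0.1076) converted to raw scale; its b-paths are set so
the implied products a_j·b_j equal the published raw-scale bootstrap
mediation effects (the published coefficient tables and mediation table
are not mutually consistent — deriving b from the mediation effects keeps
every planted effect detectable and matches what the scenario is meant to
mirror); direct effects and covariate effects come from the published
full-model coefficients.  Mediator noise leaves PA explaining only a small
fraction of mediator variance, the realistic regime.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: mediators are conditionally independent given PA
and covariates (diagonal residual covariance; the source reports no
mediator correlations), marginals are Gaussian rather than skewed or
heavy-tailed, baseline LEF is independent of the covariates, and there is
no attrition between visits, no missing data and no self-report
measurement error in PA.

## Problem sizes used by the test suite and acceptance script

Chosen to make every check reproducible in minutes on one CPU: voxel
recovery uses 20 replicates × 10⁵ voxels; the planted mediation run uses
n = 3000 subjects with B = 1000 bootstrap replicates (B = 5000 remains the
library default); calibration arms use 200 simulated datasets of n = 400
subjects with B = 200, giving a type-I error around 6% (accepting 1–11%
binomial spread) and CI coverage around 93–95% at nominal 95%.

## Known limitations

* The amplitude scale must be supplied externally when absolute masses are
  wanted (see above); batch fits on real data would take it from the
  segmented cross-sectional area or total voxel count.
* PA as numeric 1–5 assumes equal spacing of the Likert levels.
* Percentile bootstrap CIs for products of coefficients are slightly
  conservative near a = 0 and slightly anti-conservative for small n; the
  bias-corrected option mitigates but does not remove this.
* No exposure–mediator interaction, counterfactual decomposition,
  sensitivity analysis, multiple imputation, or survival/mixed models.
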