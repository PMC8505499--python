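# ntra

Trimodal skew-Gaussian modelling of CT soft-tissue radiodensity, and
mediation analysis of how physical activity protects lower-extremity
function in aging cohorts.

## The problem

Sarcopenia — age-related loss of muscle strength, function and mass — can be
quantified from a single mid-thigh CT cross-section.  The distribution of
voxel radiodensities (Hounsfield units, HU) over the soft-tissue window
[−200, 200] is trimodal: adipose tissue peaks far below 0 HU, loose
connective / water-equivalent tissue near 0 HU, and lean muscle well above
0 HU.  Modelling the whole histogram as a sum of three skew-Gaussian
components,

```
φ(x; N, μ, σ, α) = N / (σ√(2π)) · exp(−(x−μ)² / 2σ²) · erfc(α(x−μ) / (σ√2)),
```

one per tissue, yields eleven subject parameters (amplitude *N*, location
*μ*, width *σ* for each tissue plus skewness *α* for fat and muscle; the
connective component is symmetric by construction).  *N* tracks tissue
quantity (it is exactly the component's integrated mass, hence proportional
to voxel count); *μ*, *σ*, *α* track lean-tissue quality — myosteatosis
pushes the muscle peak toward 0 HU, widens it and skews it.

These parameters can then act as candidate *mediators* of the longitudinal
relationship between self-reported physical activity (PA, a five-level
score) and four lower-extremity-function (LEF) outcomes: fast and normal
gait speed (GSF, GSN; m/s), isometric knee-extension strength (STR; N) and
timed up-and-go (TUG; s).  The package implements the standard four-step
multiple-mediator regression procedure — total-effect models, mediator
models with Holm–Bonferroni screening, outcome models, and attenuation of
the PA coefficient — plus subject-resampling bootstrap confidence intervals
for the product-of-coefficients indirect effects `a_j·b_j`, their total,
and the direct effect `c′`.  All models adjust for age, sex, BMI and
baseline LEF.

Because the underlying cohort data are access-restricted, the package ships
a synthetic-data layer that emulates the published cohort marginals and
plants known path coefficients, so every stage can be exercised against
ground truth.

## Worked example: fitting a radiodensity histogram

Sample 100 000 voxels from known parameters, bin them at 1 HU, and recover
the parameters by bounded least squares:

```python
from ntra import TrimodalParams, sample_voxels, histogram_from_voxels, fit_ntra

truth = TrimodalParams.from_array(
    [62.0, -117.8, 8.2, -2.5, 41.6, -24.1, 25.1, 78.0, 61.5, 8.6, 2.8])
voxels = sample_voxels(truth, 100_000, seed=1)
hist = histogram_from_voxels(voxels)
result = fit_ntra(hist, scale=181.6, seed=1)
print(f"r_squared = {result.r_squared:.4f}")
for name, value in result.params.to_dict().items():
    print(f"{name:13s} {value:8.2f}")
```

```
r_squared = 0.9993
fat_N            62.14
fat_mu         -117.90
fat_sigma         8.30
fat_alpha        -2.61
conn_N           41.42
conn_mu         -24.14
conn_sigma       25.13
muscle_N         77.91
muscle_mu        61.43
muscle_sigma      8.51
muscle_alpha      2.72
```

Every parameter comes back within a few percent of the generating values
(locations within ~0.4 HU).  `scale` fixes the histogram's area in model
mass units; absolute amplitudes are only identifiable up to this scale,
since sampling sees the amplitudes only through their ratios.

## Worked example: mediation on a planted cohort

The `paper-like` scenario plants muscle amplitude (`muscle_N`) and muscle
location (`muscle_mu`) as the only true mediators, with effect sizes drawn
from the published cohort tables:

```python
from ntra import (PipelineConfig, generate_cohort, make_paper_like_scenario,
                  run_full_pipeline)

config = make_paper_like_scenario(n_subjects=3000, seed=2)
cohort, truth = generate_cohort(config)
report = run_full_pipeline(cohort, PipelineConfig(B=1000, seed=3))
print("selected mediators:", report.selected_mediators)
for task in ("gsf", "gsn", "str", "tug"):
    effects = report.bootstrap[task]
    est, lo, hi = effects.direct
    print(f"{task}: attenuation {report.attenuation[task]:6.1f}%   "
          f"direct effect {est:8.4f} [{lo:.4f}, {hi:.4f}]")
```

```
selected mediators: ['muscle_N', 'muscle_mu']
gsf: attenuation  -20.5%   direct effect   0.0215 [0.0163, 0.0268]
gsn: attenuation  -24.8%   direct effect   0.0144 [0.0106, 0.0182]
str: attenuation  -30.6%   direct effect   5.6723 [3.9281, 7.3258]
tug: attenuation  -20.8%   direct effect  -0.2713 [-0.3464, -0.1984]
```

The Holm–Bonferroni screen selects exactly the two planted mediators out of
eleven candidates; adding them attenuates the PA coefficient on every task
(negative % change = partial mediation, strongest for strength), and the
direct effects remain significant — higher activity still predicts better
function after accounting for muscle quantity and quality.  Direct effects
are on raw scales: m/s, Newtons, or seconds per PA point.

## Command line

The same pipeline is available from the shell:

```sh
ntra simulate-cohort --scenario paper-like --n-subjects 3000 --seed 2 --out-dir run/
ntra mediate run/cohort.csv --out-dir run/ --bootstrap-reps 5000 --seed 3
ntra simulate-histograms --n-subjects 10 --seed 1 --out-dir hists/
ntra fit-ntra hists/S*.csv --out fits.csv --scale 181.6
```

`mediate` writes one delimited table per pipeline stage
(`table2_total_effect` … `table6_bootstrap`) plus `summary.json`; every
output carries a header comment with the package version, seed and config
hash, and re-running with the same seed reproduces files byte-for-byte.

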