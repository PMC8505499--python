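"""Synthetic voxel samples and longitudinal cohorts with known ground truth.

The restricted AGES-Reykjavík data cannot be redistributed, so every stage of
the package is exercised against synthetic data instead.  Two generators are
provided:

* :func:`sample_voxels` inverts the trimodal radiodensity model: it draws
  voxel HU values from a mixture of skew-normals whose mixing weights are
  the component amplitudes, so a histogram of the sample can be fitted to
  recover the generating parameters.

* :func:`generate_cohort` simulates a two-timepoint elderly cohort — age,
  sex, BMI, a five-level physical-activity (PA) score, four baseline
  lower-extremity-function (LEF) measures, eleven follow-up tissue
  radiodensity parameters (the mediators) and four follow-up LEF measures —
  with *planted* linear path coefficients: PA -> mediator (a paths),
  mediator -> follow-up LEF (b paths) and a residual direct PA -> LEF path
  (c').  The generator returns the implied mediation truth (specific
  indirect effects a_j * b_j, their total, and the direct effect) so that
  estimates can be checked against it.

Marginal distributions default to the published AGES-Reykjavík summary
statistics (baseline visit for exposure/covariates/baseline LEF; 5-year
follow-up visit for mediators and outcome LEF).  Mediators are conditionally
independent given PA and covariates (no residual mediator correlation is
simulated), attrition between visits is not modelled, and self-report
measurement error in PA is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import PARAM_NAMES, TissueComponent, TrimodalParams

LEF_TASKS = ("gsf", "gsn", "str", "tug")

#: Reference trimodal parameters: cohort means at the baseline visit.
REFERENCE_BASELINE_PARAMS = TrimodalParams(
    fat=TissueComponent(N=62.0, mu=-117.8, sigma=8.2, alpha=-2.5),
    connective=TissueComponent(N=41.6, mu=-24.1, sigma=25.1, alpha=0.0),
    muscle=TissueComponent(N=78.0, mu=61.5, sigma=8.6, alpha=2.8),
)

#: Cohort (mean, SD) of each trimodal parameter at the baseline visit.
REFERENCE_BASELINE_NTRA = {
    "fat_N": (62.0, 33.1), "fat_mu": (-117.8, 3.3),
    "fat_sigma": (8.2, 6.0), "fat_alpha": (-2.5, 2.1),
    "conn_N": (41.6, 8.4), "conn_mu": (-24.1, 28.6), "conn_sigma": (25.1, 5.7),
    "muscle_N": (78.0, 17.9), "muscle_mu": (61.5, 2.7),
    "muscle_sigma": (8.6, 2.2), "muscle_alpha": (2.8, 0.8),
}

#: Cohort (mean, SD) of each trimodal parameter at the 5-year follow-up.
REFERENCE_FOLLOWUP_NTRA = {
    "fat_N": (62.3, 33.2), "fat_mu": (-117.2, 4.7),
    "fat_sigma": (8.1, 5.7), "fat_alpha": (-2.5, 2.0),
    "conn_N": (41.8, 9.3), "conn_mu": (-25.9, 28.2), "conn_sigma": (24.6, 5.6),
    "muscle_N": (72.6, 17.4), "muscle_mu": (60.9, 2.9),
    "muscle_sigma": (9.2, 2.6), "muscle_alpha": (3.0, 0.8),
}

#: LEF task (mean, SD): gait speeds in m/s, strength in N, up-and-go in s.
REFERENCE_LEF_BASELINE = {
    "gsf": (1.34, 0.25), "gsn": (0.99, 0.19),
    "str": (337.9, 115.9), "tug": (11.5, 2.7),
}
REFERENCE_LEF_FOLLOWUP = {
    "gsf": (1.26, 0.26), "gsn": (0.92, 0.20),
    "str": (279.5, 101.4), "tug": (12.7, 3.8),
}

#: Five-level PA score frequencies, never ... high.
REFERENCE_PA_PROBS = (0.398, 0.167, 0.077, 0.183, 0.175)

REFERENCE_AGE = (74.9, 4.8)
REFERENCE_BMI = (27.3, 4.2)
REFERENCE_FEMALE_FRAC = 0.58


def pa_score_moments(probs=REFERENCE_PA_PROBS) -> tuple[float, float]:
    """Mean and SD of the five-level PA score under category probabilities."""
    v = np.arange(1, 6)
    p = np.asarray(probs, dtype=float)
    mean = float(p @ v)
    var = float(p @ (v - mean) ** 2)
    return mean, np.sqrt(var)


def sample_voxels(
    params: TrimodalParams, n_voxels: int, seed=None
) -> np.ndarray:
    """Draw voxel HU values from the trimodal mixture.

    Components are chosen with probability N_i / sum(N); each draw comes
    from the skew-normal with location mu, scale sigma and shape -alpha
    (matching the erfc convention of the density), rejection-truncated to
    the soft-tissue window [-200, 200).
    """
    if n_voxels < 1:
        raise ValueError("n_voxels must be >= 1")
    comps = (params.fat, params.connective, params.muscle)
    weights = np.array([c.N for c in comps], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("all component amplitudes are zero; nothing to sample")
    weights /= weights.sum()
    rng = np.random.default_rng(seed)
    which = rng.choice(3, size=n_voxels, p=weights)
    out = np.empty(n_voxels)
    for i, comp in enumerate(comps):
        idx = np.flatnonzero(which == i)
        if idx.size == 0:
            continue
        draws = stats.skewnorm.rvs(
            a=-comp.alpha, loc=comp.mu, scale=comp.sigma,
            size=idx.size, random_state=rng,
        )
        bad = (draws < -200.0) | (draws >= 200.0)
        while np.any(bad):
            draws[bad] = stats.skewnorm.rvs(
                a=-comp.alpha, loc=comp.mu, scale=comp.sigma,
                size=int(bad.sum()), random_state=rng,
            )
            bad = (draws < -200.0) | (draws >= 200.0)
        out[idx] = draws
    return out


def sample_subject_params(rng, spread: float = 1.0) -> TrimodalParams:
    """Draw one subject's trimodal parameters around the reference means.

    Gaussian perturbations use the reference between-subject SDs scaled by
    ``spread``, clipped so components stay inside their tissue windows and
    keep the fat < connective < muscle ordering.
    """
    clip = {
        "fat_mu": (-180.0, -60.0), "conn_mu": (-55.0, 30.0),
        "muscle_mu": (45.0, 90.0),
    }
    vals = {}
    for name in PARAM_NAMES:
        mean, sd = REFERENCE_BASELINE_NTRA[name]
        v = rng.normal(mean, spread * sd)
        if name.endswith("_N"):
            v = max(v, 1.0)
        elif name.endswith("_sigma"):
            v = float(np.clip(v, 1.0, 50.0))
        elif name.endswith("_mu"):
            v = float(np.clip(v, *clip[name]))
        else:
            v = float(np.clip(v, -8.0, 8.0))
        vals[name] = v
    return TrimodalParams.from_dict(vals)


@dataclass
class CohortConfig:
    """Configuration and planted truth for the cohort generator.

    Path coefficients are on the raw measurement scales: ``a[j]`` is the
    change in mediator j per PA point, ``b[task][j]`` the change in the
    follow-up LEF measure per unit of mediator j, ``c_direct[task]`` the
    residual direct effect per PA point.  Covariate effects are per SD of
    age/BMI and per unit of the male indicator.  Noise SDs left at ``None``
    are solved so each simulated variable's marginal SD matches its target.
    """

    n_subjects: int = 1000
    seed: int = 0
    age_mean: float = REFERENCE_AGE[0]
    age_sd: float = REFERENCE_AGE[1]
    bmi_mean: float = REFERENCE_BMI[0]
    bmi_sd: float = REFERENCE_BMI[1]
    female_frac: float = REFERENCE_FEMALE_FRAC
    pa_probs: tuple = REFERENCE_PA_PROBS
    lef_baseline: dict = field(
        default_factory=lambda: dict(REFERENCE_LEF_BASELINE))
    lef_followup: dict = field(
        default_factory=lambda: dict(REFERENCE_LEF_FOLLOWUP))
    mediator_marginals: dict = field(
        default_factory=lambda: dict(REFERENCE_FOLLOWUP_NTRA))
    a: dict = field(default_factory=dict)
    b: dict = field(default_factory=lambda: {t: {} for t in LEF_TASKS})
    c_direct: dict = field(default_factory=lambda: {t: 0.0 for t in LEF_TASKS})
    baseline_effect: dict = field(
        default_factory=lambda: {t: 0.02 for t in LEF_TASKS})
    cov_effects_mediator: dict = field(default_factory=dict)
    cov_effects_outcome: dict = field(
        default_factory=lambda: {t: (0.0, 0.0, 0.0) for t in LEF_TASKS})
    mediator_noise_sd: dict = field(default_factory=dict)
    outcome_noise_sd: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if abs(sum(self.pa_probs) - 1.0) > 1e-8:
            raise ValueError(
                f"PA category probabilities must sum to 1, got {sum(self.pa_probs)}"
            )
        for name, (_, sd) in self.mediator_marginals.items():
            if sd <= 0:
                raise ValueError(f"mediator SD must be > 0 ({name})")


@dataclass(frozen=True)
class MediationTruth:
    """Planted mediation effects implied by a :class:`CohortConfig`."""

    mediators: tuple
    specific: dict  # task -> {mediator: a_j * b_j}
    total: dict     # task -> sum of specifics
    direct: dict    # task -> c'

    def as_dict(self) -> dict:
        return {
            "mediators": list(self.mediators),
            "specific": {t: dict(v) for t, v in self.specific.items()},
            "total": dict(self.total),
            "direct": dict(self.direct),
        }


def _truth_from_config(config: CohortConfig) -> MediationTruth:
    mediators = tuple(j for j, v in config.a.items() if v != 0.0)
    specific, total, direct = {}, {}, {}
    for t in LEF_TASKS:
        bt = config.b.get(t, {})
        spec = {j: config.a[j] * bt.get(j, 0.0) for j in mediators}
        specific[t] = spec
        total[t] = float(sum(spec.values()))
        direct[t] = float(config.c_direct.get(t, 0.0))
    return MediationTruth(mediators, specific, total, direct)


def generate_cohort(config: CohortConfig):
    """Simulate a longitudinal cohort table plus its mediation ground truth.

    Returns ``(cohort, truth)`` where ``cohort`` is a DataFrame with one row
    per subject and columns ``id, age, sex, bmi, pa``, baseline LEF
    (``<task>_baseline``), follow-up LEF (``<task>_followup``) and the
    eleven follow-up mediator columns named as in
    :data:`ntra.model.PARAM_NAMES`.  Sex is coded 0 = female, 1 = male.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    male_frac = 1.0 - config.female_frac

    pa = rng.choice(np.arange(1, 6), size=n, p=np.asarray(config.pa_probs))
    age = rng.normal(config.age_mean, config.age_sd, size=n)
    bmi = rng.normal(config.bmi_mean, config.bmi_sd, size=n)
    sex = (rng.random(n) < male_frac).astype(int)

    pa_mean, pa_sd = pa_score_moments(config.pa_probs)
    pa_c = pa - pa_mean
    z_age = (age - config.age_mean) / config.age_sd
    z_bmi = (bmi - config.bmi_mean) / config.bmi_sd
    sex_c = sex - male_frac
    var_pa = pa_sd**2
    var_sex = male_frac * (1.0 - male_frac)

    data = {"id": [f"S{i:05d}" for i in range(n)],
            "age": age, "sex": sex, "bmi": bmi, "pa": pa}

    baseline = {}
    for t in LEF_TASKS:
        mean, sd = config.lef_baseline[t]
        baseline[t] = rng.normal(mean, sd, size=n)
        data[f"{t}_baseline"] = baseline[t]

    mediators = {}
    med_noise_var = {}
    for j in PARAM_NAMES:
        mean, sd_target = config.mediator_marginals[j]
        a_j = config.a.get(j, 0.0)
        g_age, g_sex, g_bmi = config.cov_effects_mediator.get(j, (0.0, 0.0, 0.0))
        noise_sd = config.mediator_noise_sd.get(j)
        if noise_sd is None:
            planted = a_j**2 * var_pa + g_age**2 + g_sex**2 * var_sex + g_bmi**2
            noise_sd = np.sqrt(max(sd_target**2 - planted, (0.05 * sd_target) ** 2))
        med_noise_var[j] = noise_sd**2
        mediators[j] = (
            mean + a_j * pa_c + g_age * z_age + g_sex * sex_c + g_bmi * z_bmi
            + rng.normal(0.0, noise_sd, size=n)
        )
        data[j] = mediators[j]

    for t in LEF_TASKS:
        mean_f, sd_target = config.lef_followup[t]
        mean_b, sd_b = config.lef_baseline[t]
        c_t = config.c_direct.get(t, 0.0)
        gamma = config.baseline_effect.get(t, 0.0)
        g_age, g_sex, g_bmi = config.cov_effects_outcome.get(t, (0.0, 0.0, 0.0))
        bt = config.b.get(t, {})
        y = (
            mean_f + c_t * pa_c + gamma * (baseline[t] - mean_b)
            + g_age * z_age + g_sex * sex_c + g_bmi * z_bmi
        )
        for j, b_jt in bt.items():
            mean_j = config.mediator_marginals[j][0]
            y = y + b_jt * (mediators[j] - mean_j)
        noise_sd = config.outcome_noise_sd.get(t)
        if noise_sd is None:
            # variance of the planted linear part, over independent sources
            load_pa = c_t + sum(
                b_jt * config.a.get(j, 0.0) for j, b_jt in bt.items())
            load_age = g_age + sum(
                b_jt * config.cov_effects_mediator.get(j, (0, 0, 0))[0]
                for j, b_jt in bt.items())
            load_sex = g_sex + sum(
                b_jt * config.cov_effects_mediator.get(j, (0, 0, 0))[1]
                for j, b_jt in bt.items())
            load_bmi = g_bmi + sum(
                b_jt * config.cov_effects_mediator.get(j, (0, 0, 0))[2]
                for j, b_jt in bt.items())
            planted = (
                load_pa**2 * var_pa + load_age**2 + load_sex**2 * var_sex
                + load_bmi**2 + gamma**2 * sd_b**2
                + sum(b_jt**2 * med_noise_var[j] for j, b_jt in bt.items())
            )
            noise_sd = np.sqrt(max(sd_target**2 - planted, (0.05 * sd_target) ** 2))
        data[f"{t}_followup"] = y + rng.normal(0.0, noise_sd, size=n)

    return pd.DataFrame(data), _truth_from_config(config)


def _std_to_raw(beta: float, sd_y: float, sd_x: float) -> float:
    return beta * sd_y / sd_x


def make_paper_like_scenario(
    n_subjects: int = 3000, seed: int = 0
) -> CohortConfig:
    """Cohort scenario with muscle amplitude and location as true mediators.

    Plants nonzero a and b paths only for ``muscle_N`` and ``muscle_mu``.
    The a-paths use the standardized PA -> muscle magnitudes reported for
    the AGES-Reykjavík cohort (about 0.08-0.11), converted to raw scale via
    the reference SDs; the b-paths are then set so the implied specific
    indirect effects a_j * b_j equal the reported raw-scale bootstrap
    mediation effects, and the direct effects match the reported full-model
    PA coefficients.  All planted paths for the timed-up-and-go task are
    sign-flipped because higher times mean worse function.  The result is partial mediation on all four tasks: the
    direct effect remains nonzero, so adding the two mediators attenuates
    but does not eliminate the PA coefficient.
    """
    _, pa_sd = pa_score_moments()
    med = dict(REFERENCE_FOLLOWUP_NTRA)
    sd_nm = med["muscle_N"][1]
    sd_mm = med["muscle_mu"][1]
    sd_y = {t: REFERENCE_LEF_FOLLOWUP[t][1] for t in LEF_TASKS}
    sd_b = {t: REFERENCE_LEF_BASELINE[t][1] for t in LEF_TASKS}
    sd_sex = np.sqrt(0.42 * 0.58)

    # standardized planted a-paths and direct effects
    a_std = {"muscle_N": 0.0841, "muscle_mu": 0.1076}
    c_std = {"gsf": 0.1377, "gsn": 0.1431, "str": 0.0720, "tug": -0.1118}
    # raw-scale specific indirect effects the scenario reproduces; the
    # b-paths are derived as specific / a so the planted products match
    specific_raw = {
        "gsf": {"muscle_N": 0.0036, "muscle_mu": 0.0012},
        "gsn": {"muscle_N": 0.0026, "muscle_mu": 0.0012},
        "str": {"muscle_N": 1.5060, "muscle_mu": 0.5414},
        "tug": {"muscle_N": -0.0398, "muscle_mu": -0.0233},
    }
    cov_out_std = {
        "gsf": (-0.2716, -0.1522, -0.2853),
        "gsn": (-0.3264, -0.0261, -0.2876),
        "str": (-0.1718, -0.4192, -0.0848),
        "tug": (0.2779, -0.0622, 0.2630),
    }
    cov_med_std = {
        "muscle_N": (-0.2152, -0.5082, 0.5135),
        "muscle_mu": (-0.2434, -0.0717, 0.1242),
    }
    base_std = {"gsf": 0.0224, "gsn": 0.0135, "str": 0.0104, "tug": 0.0139}

    a = {
        "muscle_N": _std_to_raw(a_std["muscle_N"], sd_nm, pa_sd),
        "muscle_mu": _std_to_raw(a_std["muscle_mu"], sd_mm, pa_sd),
    }
    b = {
        t: {j: specific_raw[t][j] / a[j] for j in a}
        for t in LEF_TASKS
    }
    c = {t: _std_to_raw(c_std[t], sd_y[t], pa_sd) for t in LEF_TASKS}
    cov_out = {
        t: (
            _std_to_raw(cov_out_std[t][0], sd_y[t], 1.0),
            _std_to_raw(cov_out_std[t][1], sd_y[t], sd_sex),
            _std_to_raw(cov_out_std[t][2], sd_y[t], 1.0),
        )
        for t in LEF_TASKS
    }
    cov_med = {
        j: (
            _std_to_raw(v[0], med[j][1], 1.0),
            _std_to_raw(v[1], med[j][1], sd_sex),
            _std_to_raw(v[2], med[j][1], 1.0),
        )
        for j, v in cov_med_std.items()
    }
    baseline_effect = {
        t: _std_to_raw(base_std[t], sd_y[t], sd_b[t]) for t in LEF_TASKS
    }
    return CohortConfig(
        n_subjects=n_subjects,
        seed=seed,
        a=a,
        b=b,
        c_direct=c,
        baseline_effect=baseline_effect,
        cov_effects_mediator=cov_med,
        cov_effects_outcome=cov_out,
    )


def make_null_scenario(n_subjects: int = 1000, seed: int = 0) -> CohortConfig:
    """Cohort scenario with no planted paths: PA affects nothing."""
    return CohortConfig(n_subjects=n_subjects, seed=seed)
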