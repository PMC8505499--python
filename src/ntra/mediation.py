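"""Four-step multiple-mediator regression pipeline with bootstrap effects.

The pipeline tests whether soft-tissue radiodensity parameters mediate the
longitudinal association between a five-level physical-activity (PA) score
and four lower-extremity-function (LEF) outcomes, adjusting every model for
age, sex, BMI and (for LEF outcomes) the same task's baseline measure:

1. *Total effect*: ``LEF_followup ~ PA + age + sex + BMI + LEF_baseline``
   for each of the four tasks; the four PA p-values form one
   Holm-Bonferroni (HB) family.
2. *Mediator models*: ``mediator ~ PA + age + sex + BMI`` for each of the
   eleven radiodensity parameters; parameters whose PA coefficient survives
   HB across the family of eleven are the candidate mediators.
3. *Outcome models*: ``LEF_followup ~ mediators + age + sex + BMI +
   LEF_baseline`` (no PA); HB across mediators x tasks.
4. *Attenuation*: the step-1 models refitted with the mediators added; the
   relative change of the standardized PA coefficient measures how much of
   the total effect the mediators absorb.

Indirect effects are quantified by products of coefficients: the specific
indirect effect of mediator j is a_j * b_j, where a_j is the PA coefficient
from its step-2 model and b_j its coefficient in the step-4 model; the total
indirect effect is the sum over mediators, and the direct effect is the PA
coefficient of the step-4 model.  Confidence intervals come from resampling
subjects with replacement (percentile bootstrap by default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm

from .model import PARAM_NAMES
from .simulate import LEF_TASKS

logger = logging.getLogger(__name__)

COVARIATES = ("age", "sex", "bmi")


class PipelineError(RuntimeError):
    """A structural failure in one of the mediation pipeline stages."""


class RankDeficiencyError(ValueError):
    """The regression design matrix is rank deficient."""


@dataclass(frozen=True)
class RegressionModelResult:
    """One fitted OLS model: raw and standardized coefficients per predictor."""

    outcome: str
    predictors: tuple
    coef: dict          # raw-scale coefficients (excluding intercept)
    beta_std: dict      # standardized: coef * SD(x) / SD(y)
    se: dict            # raw-scale standard errors
    pvalues: dict       # two-sided t-test p-values
    intercept: float
    n: int
    n_dropped: int
    r_squared: float


def _complete_cases(df: pd.DataFrame, cols) -> tuple[pd.DataFrame, int]:
    sub = df[list(cols)].apply(pd.to_numeric, errors="coerce")
    kept = sub.dropna()
    n_dropped = len(sub) - len(kept)
    if n_dropped:
        logger.info(
            "complete-case deletion dropped %d of %d rows for columns %s",
            n_dropped, len(sub), list(cols),
        )
    return kept, n_dropped


def _collinear_columns(X: np.ndarray, names) -> list[str]:
    """Name the design columns involved in a rank deficiency (via QR)."""
    _, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps
    return [names[i] for i in np.flatnonzero(diag < max(tol, 1e-10))]


def fit_ols(
    df: pd.DataFrame, outcome: str, predictors
) -> RegressionModelResult:
    """Ordinary least squares with intercept on complete cases.

    Reports raw coefficients, standardized coefficients
    (``coef * SD(x)/SD(y)``, sample SDs with one delta degree of freedom),
    raw-scale standard errors and two-sided p-values from the t
    distribution.  Raises :class:`RankDeficiencyError` naming the collinear
    columns (a constant predictor included) if the design is singular.
    """
    predictors = list(predictors)
    data, n_dropped = _complete_cases(df, [outcome, *predictors])
    if len(data) <= len(predictors) + 1:
        raise ValueError(
            f"too few complete cases ({len(data)}) for {len(predictors)} predictors"
        )
    y = data[outcome].to_numpy(dtype=float)
    X = data[predictors].to_numpy(dtype=float)
    const = [p for p, s in zip(predictors, X.std(axis=0)) if s == 0.0]
    if const:
        raise RankDeficiencyError(f"constant predictor column(s): {const}")
    design = np.column_stack([np.ones(len(y)), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        cols = _collinear_columns(design, ["const", *predictors])
        raise RankDeficiencyError(f"collinear design columns: {cols}")
    fit = sm.OLS(y, design).fit()
    sd_y = y.std(ddof=1)
    sd_x = X.std(axis=0, ddof=1)
    coef = dict(zip(predictors, fit.params[1:]))
    return RegressionModelResult(
        outcome=outcome,
        predictors=tuple(predictors),
        coef=coef,
        beta_std={p: coef[p] * sd_x[i] / sd_y for i, p in enumerate(predictors)},
        se=dict(zip(predictors, fit.bse[1:])),
        pvalues=dict(zip(predictors, fit.pvalues[1:])),
        intercept=float(fit.params[0]),
        n=len(y),
        n_dropped=n_dropped,
        r_squared=float(fit.rsquared),
    )


@dataclass(frozen=True)
class HolmResult:
    """Holm-Bonferroni stepdown decision for one family of tests."""

    reject: np.ndarray      # in input order
    thresholds: np.ndarray  # alpha / (m - rank + 1), in input order
    alpha: float


def holm_bonferroni(p_values, alpha: float = 0.05) -> HolmResult:
    """Stepdown familywise-error control at level ``alpha``.

    Sort the m p-values ascending; the k-th smallest is rejected iff every
    p_(j) with j <= k satisfies ``p_(j) <= alpha / (m - j + 1)`` (stop at the
    first failure).  The boundary is inclusive: ``p == threshold`` rejects.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return HolmResult(np.zeros(0, bool), np.zeros(0), alpha)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    reject = np.zeros(m, dtype=bool)
    thresholds = np.empty(m)
    passing = True
    for k, idx in enumerate(order):
        thresholds[idx] = alpha / (m - k)
        passing = passing and (p[idx] <= alpha / (m - k))
        reject[idx] = passing
    return HolmResult(reject, thresholds, alpha)


def attenuation_percent(beta_full: float, beta_prior: float) -> float:
    """Relative change (%) of an exposure coefficient after adding mediators.

    ``100 * (beta_full - beta_prior) / beta_prior``; negative values mean the
    mediators attenuated the prior effect.  Undefined for ``beta_prior == 0``.
    """
    if beta_prior == 0:
        raise ValueError("attenuation undefined: prior coefficient is zero")
    return 100.0 * (beta_full - beta_prior) / beta_prior


@dataclass(frozen=True)
class StepResult:
    """Per-model results for one pipeline step plus its HB family decision."""

    models: dict  # key -> RegressionModelResult
    hb: HolmResult | None
    family: tuple  # keys of the HB family, aligned with hb arrays


def step1_total_effect(cohort: pd.DataFrame, alpha: float = 0.05) -> StepResult:
    """Total-effect models of follow-up LEF on PA (one HB family of four)."""
    models = {}
    for t in LEF_TASKS:
        models[t] = fit_ols(
            cohort, f"{t}_followup",
            ["pa", *COVARIATES, f"{t}_baseline"],
        )
    pvals = [models[t].pvalues["pa"] for t in LEF_TASKS]
    return StepResult(models, holm_bonferroni(pvals, alpha), tuple(LEF_TASKS))


def step2_mediator_models(
    cohort: pd.DataFrame, alpha: float = 0.05, mediator_names=PARAM_NAMES
) -> tuple[StepResult, list[str]]:
    """Mediator models and HB selection of candidate mediators.

    The connective-tissue skewness is structurally zero and is not among
    the eleven free parameters; if passed explicitly it is skipped.
    """
    names = [m for m in mediator_names if m != "conn_alpha"]
    models = {}
    for j in names:
        models[j] = fit_ols(cohort, j, ["pa", *COVARIATES])
    pvals = [models[j].pvalues["pa"] for j in names]
    hb = holm_bonferroni(pvals, alpha)
    selected = [j for j, rej in zip(names, hb.reject) if rej]
    return StepResult(models, hb, tuple(names)), selected


def step3_outcome_models(
    cohort: pd.DataFrame, mediators, alpha: float = 0.05
) -> StepResult:
    """Follow-up LEF on the selected mediators (no PA); HB over mediators x tasks.

    With an empty mediator set no mediation is testable and an empty result
    is returned rather than an error.
    """
    mediators = list(mediators)
    if not mediators:
        return StepResult({}, None, ())
    models, family, pvals = {}, [], []
    for t in LEF_TASKS:
        res = fit_ols(
            cohort, f"{t}_followup",
            [*mediators, *COVARIATES, f"{t}_baseline"],
        )
        models[t] = res
        for j in mediators:
            family.append((t, j))
            pvals.append(res.pvalues[j])
    return StepResult(models, holm_bonferroni(pvals, alpha), tuple(family))


def step4_attenuation_models(
    cohort: pd.DataFrame, mediators, step1: StepResult, alpha: float = 0.05
) -> tuple[StepResult, dict]:
    """Step-1 models with mediators added, plus PA-coefficient attenuation.

    Attenuation is computed on standardized coefficients; a zero step-1
    coefficient yields NaN for that task.  The HB family is every PA and
    mediator coefficient across the four tasks, ``(1 + m) * 4`` tests.
    """
    mediators = list(mediators)
    models, family, pvals = {}, [], []
    attenuation = {}
    for t in LEF_TASKS:
        res = fit_ols(
            cohort, f"{t}_followup",
            ["pa", *mediators, *COVARIATES, f"{t}_baseline"],
        )
        models[t] = res
        for key in ("pa", *mediators):
            family.append((t, key))
            pvals.append(res.pvalues[key])
        prior = step1.models[t].beta_std["pa"]
        if prior == 0:
            logger.warning("step-1 PA coefficient is zero for %s; "
                           "attenuation undefined", t)
            attenuation[t] = float("nan")
        else:
            attenuation[t] = attenuation_percent(res.beta_std["pa"], prior)
    return StepResult(models, holm_bonferroni(pvals, alpha), tuple(family)), attenuation


@dataclass(frozen=True)
class BootstrapEffects:
    """Indirect and direct effects for one LEF task with bootstrap CIs.

    ``specific`` maps each mediator to ``(estimate, lo, hi)``; the total
    indirect point estimate is the sum of the specific estimates by
    construction.  Raw-scale (unstandardized) coefficients throughout.
    """

    task: str
    mediators: tuple
    specific: dict
    total: tuple
    direct: tuple
    B: int
    ci_level: float
    seed: int
    n_discarded: int
    method: str = "percentile"


def _effects_from_sample(pa_X, med_ys, out_X, out_y, n_med):
    """a_j, b_j and direct effect from one (re)sample via least squares.

    ``pa_X`` is the mediator-model design [1, pa, age, sex, bmi]; ``out_X``
    the outcome design [1, pa, mediators..., age, sex, bmi, baseline].
    Returns None if either design is rank deficient.
    """
    rank_needed = pa_X.shape[1]
    a = np.empty(n_med)
    for j in range(n_med):
        sol, _, rank, _ = np.linalg.lstsq(pa_X, med_ys[j], rcond=None)
        if rank < rank_needed:
            return None
        a[j] = sol[1]
    sol, _, rank, _ = np.linalg.lstsq(out_X, out_y, rcond=None)
    if rank < out_X.shape[1]:
        return None
    b = sol[2:2 + n_med]
    direct = sol[1]
    return a * b, direct


def bootstrap_effects(
    cohort: pd.DataFrame,
    mediators,
    task: str,
    B: int = 5000,
    ci_level: float = 0.95,
    seed: int = 0,
    method: str = "percentile",
) -> BootstrapEffects:
    """Subject-resampling bootstrap of indirect and direct effects.

    Point estimates come from full-sample fits (products of coefficients);
    intervals from ``B`` resamples of subjects with replacement.  Replicates
    whose resampled design is rank deficient are discarded and redrawn, up
    to 1% of ``B``.  ``method`` is ``"percentile"`` (default) or ``"bc"``
    (bias-corrected percentile).
    """
    mediators = list(mediators)
    if not mediators:
        raise ValueError("mediator set is empty")
    if B < 200:
        raise ValueError("B must be >= 200")
    if method not in ("percentile", "bc"):
        raise ValueError(f"unknown bootstrap method {method!r}")
    cols = [f"{task}_followup", "pa", *mediators, *COVARIATES,
            f"{task}_baseline"]
    data, _ = _complete_cases(cohort, cols)
    n = len(data)
    n_med = len(mediators)
    arr = data.to_numpy(dtype=float)
    out_y = arr[:, 0]
    ones = np.ones(n)
    pa = arr[:, 1]
    meds = arr[:, 2:2 + n_med]
    covs = arr[:, 2 + n_med:]
    pa_X = np.column_stack([ones, pa, covs[:, :-1]])  # baseline excluded
    out_X = np.column_stack([ones, pa, meds, covs])

    point = _effects_from_sample(pa_X, meds.T, out_X, out_y, n_med)
    if point is None:
        raise RankDeficiencyError("full-sample mediation design is singular")
    spec_point, direct_point = point

    rng = np.random.default_rng(seed)
    spec_reps = np.empty((B, n_med))
    direct_reps = np.empty(B)
    discarded = 0
    max_discard = max(1, int(0.01 * B))
    filled = 0
    while filled < B:
        idx = rng.integers(0, n, size=n)
        rep = _effects_from_sample(
            pa_X[idx], [m[idx] for m in meds.T], out_X[idx], out_y[idx], n_med
        )
        if rep is None:
            discarded += 1
            if discarded > max_discard:
                raise PipelineError(
                    f"more than {max_discard} rank-deficient bootstrap "
                    f"replicates for task {task}"
                )
            continue
        spec_reps[filled], direct_reps[filled] = rep
        filled += 1
    if discarded:
        logger.info("discarded and redrew %d degenerate bootstrap "
                    "replicates for %s", discarded, task)

    def _ci(reps, est):
        if method == "bc":
            prop = np.mean(reps < est)
            prop = min(max(prop, 1.0 / (len(reps) + 1)), 1 - 1.0 / (len(reps) + 1))
            z0 = norm.ppf(prop)
            zc = norm.ppf(0.5 + ci_level / 2)
            lo_q = norm.cdf(2 * z0 - zc)
            hi_q = norm.cdf(2 * z0 + zc)
        else:
            lo_q = 0.5 - ci_level / 2
            hi_q = 0.5 + ci_level / 2
        lo, hi = np.quantile(reps, [lo_q, hi_q])
        return float(lo), float(hi)

    specific = {}
    for j, name in enumerate(mediators):
        lo, hi = _ci(spec_reps[:, j], spec_point[j])
        specific[name] = (float(spec_point[j]), lo, hi)
    total_reps = spec_reps.sum(axis=1)
    lo, hi = _ci(total_reps, spec_point.sum())
    total = (float(spec_point.sum()), lo, hi)
    lo, hi = _ci(direct_reps, direct_point)
    direct = (float(direct_point), lo, hi)
    return BootstrapEffects(
        task=task, mediators=tuple(mediators), specific=specific,
        total=total, direct=direct, B=B, ci_level=ci_level, seed=seed,
        n_discarded=discarded, method=method,
    )


@dataclass
class PipelineConfig:
    """Tunable knobs of the full mediation pipeline."""

    alpha: float = 0.05
    B: int = 5000
    ci_level: float = 0.95
    seed: int = 0
    mediator_override: list | None = None
    bootstrap_method: str = "percentile"


@dataclass
class MediationReport:
    """All artefacts of the four-step pipeline plus bootstrap effects."""

    step1: StepResult
    step2: StepResult
    selected_mediators: list
    step3: StepResult
    step4: StepResult | None
    attenuation: dict
    bootstrap: dict  # task -> BootstrapEffects, empty if nothing selected
    config: PipelineConfig

    def to_tables(self) -> dict:
        """Render the report as tidy DataFrames, one per pipeline stage."""
        def tidy(step: StepResult, label_key) -> pd.DataFrame:
            rows = []
            for key, res in step.models.items():
                for p in res.predictors:
                    rows.append({
                        label_key: key if isinstance(key, str) else str(key),
                        "predictor": p,
                        "coef_raw": res.coef[p],
                        "beta_std": res.beta_std[p],
                        "se": res.se[p],
                        "p_value": res.pvalues[p],
                        "n": res.n,
                        "r_squared": res.r_squared,
                    })
            return pd.DataFrame(rows)

        tables = {
            "table2_total_effect": tidy(self.step1, "task"),
            "table3_mediator_models": tidy(self.step2, "mediator"),
            "table4_outcome_models": tidy(self.step3, "task"),
        }
        if self.step4 is not None:
            t5 = tidy(self.step4, "task")
            att = pd.DataFrame(
                [{"task": t, "predictor": "pa_pct_change",
                  "coef_raw": v, "beta_std": v, "se": np.nan,
                  "p_value": np.nan, "n": np.nan, "r_squared": np.nan}
                 for t, v in self.attenuation.items()]
            )
            tables["table5_attenuation"] = pd.concat([t5, att], ignore_index=True)
        else:
            tables["table5_attenuation"] = pd.DataFrame()
        rows = []
        for t, eff in self.bootstrap.items():
            for name, (est, lo, hi) in eff.specific.items():
                rows.append({"task": t, "effect": f"indirect_{name}",
                             "estimate": est, "ci_lo": lo, "ci_hi": hi})
            rows.append({"task": t, "effect": "indirect_total",
                         "estimate": eff.total[0], "ci_lo": eff.total[1],
                         "ci_hi": eff.total[2]})
            rows.append({"task": t, "effect": "direct",
                         "estimate": eff.direct[0], "ci_lo": eff.direct[1],
                         "ci_hi": eff.direct[2]})
        tables["table6_bootstrap"] = pd.DataFrame(rows)
        return tables

    def summary(self) -> dict:
        return {
            "selected_mediators": list(self.selected_mediators),
            "attenuation_pct": dict(self.attenuation),
            "direct_effects": {
                t: e.direct for t, e in self.bootstrap.items()},
            "total_indirect_effects": {
                t: e.total for t, e in self.bootstrap.items()},
            "alpha": self.config.alpha,
            "B": self.config.B,
            "ci_level": self.config.ci_level,
            "seed": self.config.seed,
        }


def run_full_pipeline(
    cohort: pd.DataFrame, config: PipelineConfig | None = None
) -> MediationReport:
    """Execute steps 1-4 and the bootstrap in order on a cohort table.

    Mediator selection uses the step-2 HB family unless
    ``config.mediator_override`` names an explicit set.  A cohort in which
    step 2 selects nothing still yields a complete report with empty
    step-3/4 and bootstrap sections.
    """
    config = config or PipelineConfig()

    def _stage(name, fn, *args, **kw):
        try:
            return fn(*args, **kw)
        except (ValueError, RankDeficiencyError) as exc:
            raise PipelineError(f"{name}: {exc}") from exc

    step1 = _stage("step1_total_effect", step1_total_effect, cohort, config.alpha)
    step2, selected = _stage(
        "step2_mediator_models", step2_mediator_models, cohort, config.alpha)
    if config.mediator_override is not None:
        selected = list(config.mediator_override)
    step3 = _stage("step3_outcome_models", step3_outcome_models,
                   cohort, selected, config.alpha)
    if selected:
        step4, attenuation = _stage(
            "step4_attenuation_models", step4_attenuation_models,
            cohort, selected, step1, config.alpha)
        bootstrap = {
            t: _stage(
                f"bootstrap[{t}]", bootstrap_effects, cohort, selected, t,
                config.B, config.ci_level, config.seed,
                config.bootstrap_method)
            for t in LEF_TASKS
        }
    else:
        logger.warning("no mediators selected; mediation not testable")
        step4, attenuation, bootstrap = None, {}, {}
    return MediationReport(
        step1=step1, step2=step2, selected_mediators=list(selected),
        step3=step3, step4=step4, attenuation=attenuation,
        bootstrap=bootstrap, config=config,
    )
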