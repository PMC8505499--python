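"""Trimodal skew-Gaussian modelling of soft-tissue CT radiodensity histograms.

A mid-thigh CT cross-section yields a distribution of voxel radiodensities
(Hounsfield units, HU) over the soft-tissue window [-200, 200].  That
distribution is treated as a quasi-probability density composed of three
summed skew-Gaussian components, one per canonical tissue type:

* fat (approx. -200 to -10 HU, negatively-signed skewness),
* loose connective / water-equivalent tissue (approx. -9 to 40 HU, symmetric),
* lean muscle (approx. 41 to 200 HU, positively-signed skewness).

Each component is

    phi(x; N, mu, sigma, alpha)
        = N / (sigma sqrt(2 pi)) * exp(-(x - mu)^2 / (2 sigma^2))
          * erfc(alpha (x - mu) / (sigma sqrt(2)))

which is ``N`` times a skew-normal density with location ``mu``, scale
``sigma`` and shape ``-alpha`` — so the total mass of a component is exactly
its amplitude ``N``, tying amplitudes to voxel counts, and ``alpha > 0``
gives a longer tail toward *lower* HU.  Fitting the three-component sum to a
subject's histogram yields the eleven subject-specific parameters (four each
for fat and muscle, three for connective tissue whose skewness is fixed at
zero by construction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize
from scipy.special import erfc

HU_MIN = -200.0
HU_MAX = 200.0

#: Canonical tissue HU domains used for moment-based initialization.
FAT_DOMAIN = (-200.0, -10.0)
CONNECTIVE_DOMAIN = (-9.0, 40.0)
MUSCLE_DOMAIN = (41.0, 200.0)

#: Widened per-tissue location windows used as fit bounds.  They overlap on
#: purpose; the fat < connective < muscle ordering is asserted post-fit.
FAT_MU_BOUNDS = (-200.0, 0.0)
CONNECTIVE_MU_BOUNDS = (-60.0, 50.0)
MUSCLE_MU_BOUNDS = (30.0, 120.0)

SIGMA_BOUNDS = (0.5, 60.0)
ALPHA_MAX = 10.0

#: Canonical order of the eleven free parameters.
PARAM_NAMES = (
    "fat_N", "fat_mu", "fat_sigma", "fat_alpha",
    "conn_N", "conn_mu", "conn_sigma",
    "muscle_N", "muscle_mu", "muscle_sigma", "muscle_alpha",
)


class ParameterDomainError(ValueError):
    """A tissue-component parameter lies outside its physical domain."""


@dataclass(frozen=True)
class TissueComponent:
    """One skew-Gaussian tissue component.

    Parameters
    ----------
    N : float
        Amplitude; equals the component's total integrated mass and is
        proportional to the tissue's voxel count.
    mu : float
        Location in HU.
    sigma : float
        Width in HU, strictly positive.
    alpha : float
        Skewness; positive values skew the curve toward lower HU.
    """

    N: float
    mu: float
    sigma: float
    alpha: float = 0.0

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ParameterDomainError(f"sigma must be > 0, got {self.sigma}")
        if self.N < 0:
            raise ParameterDomainError(f"N must be >= 0, got {self.N}")
        if not (HU_MIN <= self.mu <= HU_MAX):
            raise ParameterDomainError(
                f"mu must lie in [{HU_MIN}, {HU_MAX}], got {self.mu}"
            )


@dataclass(frozen=True)
class TrimodalParams:
    """The eleven-parameter trimodal model: fat, connective and muscle.

    The connective component is symmetric by construction (its skewness is
    identically zero and is not a free parameter), and the component
    locations must satisfy fat < connective < muscle.
    """

    fat: TissueComponent
    connective: TissueComponent
    muscle: TissueComponent

    def __post_init__(self) -> None:
        if self.connective.alpha != 0.0:
            raise ParameterDomainError("connective tissue skewness must be 0")
        if not (self.fat.mu < self.connective.mu < self.muscle.mu):
            raise ParameterDomainError(
                "component locations must be ordered fat < connective < muscle, "
                f"got {self.fat.mu}, {self.connective.mu}, {self.muscle.mu}"
            )

    def to_array(self) -> np.ndarray:
        """Pack the eleven free parameters in :data:`PARAM_NAMES` order."""
        f, c, m = self.fat, self.connective, self.muscle
        return np.array([
            f.N, f.mu, f.sigma, f.alpha,
            c.N, c.mu, c.sigma,
            m.N, m.mu, m.sigma, m.alpha,
        ])

    @classmethod
    def from_array(cls, theta: np.ndarray) -> "TrimodalParams":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (11,):
            raise ValueError(f"expected 11 parameters, got shape {theta.shape}")
        return cls(
            fat=TissueComponent(*theta[0:4]),
            connective=TissueComponent(*theta[4:7], alpha=0.0),
            muscle=TissueComponent(*theta[7:11]),
        )

    def to_dict(self) -> dict[str, float]:
        return dict(zip(PARAM_NAMES, self.to_array()))

    @classmethod
    def from_dict(cls, d) -> "TrimodalParams":
        return cls.from_array(np.array([float(d[k]) for k in PARAM_NAMES]))


@dataclass(frozen=True)
class RadiodensityHistogram:
    """Binned voxel HU counts over the soft-tissue window [-200, 200).

    ``bin_edges`` define half-open bins ``[e_k, e_{k+1})``; ``counts`` holds
    non-negative voxel counts per bin.  ``n_discarded`` records how many raw
    voxel values fell outside the soft-tissue window during construction.
    """

    bin_edges: np.ndarray
    counts: np.ndarray
    n_discarded: int = 0

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)
        if edges.ndim != 1 or len(edges) < 2:
            raise ValueError("bin_edges must be a 1-d array of length >= 2")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly increasing")
        if not (math.isclose(edges[0], HU_MIN) and math.isclose(edges[-1], HU_MAX)):
            raise ValueError(
                f"bin_edges must span [{HU_MIN}, {HU_MAX}], "
                f"got [{edges[0]}, {edges[-1]}]"
            )
        if counts.shape != (len(edges) - 1,):
            raise ValueError("counts length must equal number of bins")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    @property
    def total_count(self) -> float:
        return float(self.counts.sum())

    def density(self, scale: float = 1.0) -> np.ndarray:
        """Bin heights normalized so the histogram area equals ``scale``.

        ``scale`` sets the mass units of the fitted model: with the default
        1.0 the fitted amplitudes are tissue mass *fractions*; passing a
        total soft-tissue mass puts amplitudes on that scale instead.
        """
        total = self.total_count
        if total <= 0:
            raise ValueError("histogram has zero total count")
        return self.counts / (total * self.bin_widths) * scale


def histogram_from_voxels(
    hu_values, bin_width: float = 1.0
) -> RadiodensityHistogram:
    """Bin raw voxel HU values into a :class:`RadiodensityHistogram`.

    Values outside the half-open soft-tissue window [-200, 200) are discarded
    and counted in ``n_discarded``.  Raises if no value survives.
    """
    values = np.asarray(hu_values, dtype=float).ravel()
    n_bins = int(round((HU_MAX - HU_MIN) / bin_width))
    if not math.isclose(HU_MIN + n_bins * bin_width, HU_MAX):
        raise ValueError("bin_width must divide the 400 HU window evenly")
    inside = (values >= HU_MIN) & (values < HU_MAX)
    retained = values[inside]
    if retained.size == 0:
        raise ValueError("no HU values inside [-200, 200)")
    edges = HU_MIN + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(retained, bins=edges)
    return RadiodensityHistogram(
        bin_edges=edges,
        counts=counts.astype(float),
        n_discarded=int(values.size - retained.size),
    )


def evaluate_component(x, comp: TissueComponent) -> np.ndarray:
    """Evaluate one skew-Gaussian component at HU value(s) ``x``.

    At ``x == mu`` the value is ``N / (sigma sqrt(2 pi))`` for any skewness,
    since ``erfc(0) == 1``.
    """
    x = np.asarray(x, dtype=float)
    u = (x - comp.mu) / comp.sigma
    gauss = np.exp(-0.5 * u * u) / (comp.sigma * math.sqrt(2.0 * math.pi))
    return comp.N * gauss * erfc(comp.alpha * u / math.sqrt(2.0))


def evaluate_trimodal(x, params: TrimodalParams) -> np.ndarray:
    """Evaluate the three-component sum at HU value(s) ``x``."""
    return (
        evaluate_component(x, params.fat)
        + evaluate_component(x, params.connective)
        + evaluate_component(x, params.muscle)
    )


def component_mass(comp: TissueComponent) -> float:
    """Total integrated mass of a component over the real line.

    The erfc form is ``N`` times a skew-normal density (shape ``-alpha``),
    whose integral is 1 for any skewness, so the mass equals ``N`` exactly.
    """
    return comp.N


@dataclass(frozen=True)
class NtraFitResult:
    """Outcome of fitting the trimodal model to one histogram."""

    params: TrimodalParams
    objective: float
    converged: bool
    n_iterations: int
    r_squared: float
    residuals: np.ndarray
    scale: float = 1.0


def _domain_moments(hist: RadiodensityHistogram, domain, scale: float):
    """Count-weighted moments of the histogram restricted to one HU domain."""
    lo, hi = domain
    centers = hist.bin_centers
    mask = (centers >= lo) & (centers <= hi)
    counts = hist.counts[mask]
    total = counts.sum()
    if total <= 0:
        # degenerate: empty tissue domain
        return 0.0, 0.5 * (lo + hi), (hi - lo) / 6.0
    c = centers[mask]
    mu = float(np.average(c, weights=counts))
    var = float(np.average((c - mu) ** 2, weights=counts))
    sigma = max(math.sqrt(var), 1.0)
    heights = hist.density(scale)[mask]
    n_init = float(heights.max() * sigma * math.sqrt(2.0 * math.pi))
    return n_init, mu, sigma


def initialize_params(
    hist: RadiodensityHistogram, scale: float = 1.0
) -> TrimodalParams:
    """Moment-based starting values from the canonical tissue domains.

    Each domain contributes a count-weighted mean (location), count-weighted
    SD floored at 1 HU (width) and a peak-height-derived amplitude; skewness
    starts at -2 for fat, 0 for connective, +2 for muscle.  A domain with no
    counts yields an empty component centred in its domain.
    """
    if hist.total_count <= 0:
        raise ValueError("histogram has zero total count")
    f_n, f_mu, f_s = _domain_moments(hist, FAT_DOMAIN, scale)
    c_n, c_mu, c_s = _domain_moments(hist, CONNECTIVE_DOMAIN, scale)
    m_n, m_mu, m_s = _domain_moments(hist, MUSCLE_DOMAIN, scale)
    return TrimodalParams(
        fat=TissueComponent(f_n, f_mu, f_s, -2.0),
        connective=TissueComponent(c_n, c_mu, c_s, 0.0),
        muscle=TissueComponent(m_n, m_mu, m_s, 2.0),
    )


def _model_heights(theta: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Trimodal model evaluated from the raw 11-vector (no ordering checks)."""
    out = np.zeros_like(centers)
    for (n, mu, sig, alpha) in (
        (theta[0], theta[1], theta[2], theta[3]),
        (theta[4], theta[5], theta[6], 0.0),
        (theta[7], theta[8], theta[9], theta[10]),
    ):
        u = (centers - mu) / sig
        out += (
            n
            * np.exp(-0.5 * u * u)
            / (sig * math.sqrt(2.0 * math.pi))
            * erfc(alpha * u / math.sqrt(2.0))
        )
    return out


def _fit_bounds(scale: float):
    n_hi = 10.0 * scale
    lo = np.array([
        0.0, FAT_MU_BOUNDS[0], SIGMA_BOUNDS[0], -ALPHA_MAX,
        0.0, CONNECTIVE_MU_BOUNDS[0], SIGMA_BOUNDS[0],
        0.0, MUSCLE_MU_BOUNDS[0], SIGMA_BOUNDS[0], -ALPHA_MAX,
    ])
    hi = np.array([
        n_hi, FAT_MU_BOUNDS[1], SIGMA_BOUNDS[1], ALPHA_MAX,
        n_hi, CONNECTIVE_MU_BOUNDS[1], SIGMA_BOUNDS[1],
        n_hi, MUSCLE_MU_BOUNDS[1], SIGMA_BOUNDS[1], ALPHA_MAX,
    ])
    return lo, hi


def _jitter(theta, lo, hi, rng, rel=0.05):
    spread = rel * np.maximum(np.abs(theta), 1.0)
    return np.clip(theta + rng.normal(scale=spread), lo, hi)


def fit_ntra(
    hist: RadiodensityHistogram,
    init: TrimodalParams | None = None,
    *,
    scale: float = 1.0,
    n_starts: int = 5,
    seed: int = 0,
    max_nfev: int | None = None,
) -> NtraFitResult:
    """Fit the trimodal model to a histogram by bounded least squares.

    The objective is the sum over bins of squared differences between the
    histogram heights (counts normalized so the histogram area equals
    ``scale``; see :meth:`RadiodensityHistogram.density`) and the model
    curve at the bin centres.  Widths are bounded to [0.5, 60] HU, skewness
    to [-10, 10], locations to widened per-tissue windows, and amplitudes to
    be non-negative; the connective skewness is structurally zero.

    A multistart strategy (default 5) perturbs the moment-based start and
    keeps the best minimum whose locations respect fat < connective < muscle;
    if no start respects the ordering the best overall is returned with
    ``converged=False``.
    """
    if hist.total_count <= 0:
        raise ValueError("cannot fit a histogram with zero total count")
    centers = hist.bin_centers
    target = hist.density(scale)
    lo, hi = _fit_bounds(scale)
    theta0 = (init if init is not None else initialize_params(hist, scale)).to_array()
    theta0 = np.clip(theta0, lo, hi)

    rng = np.random.default_rng(seed)
    starts = [theta0]
    starts += [_jitter(theta0, lo, hi, rng) for _ in range(max(0, n_starts - 1))]

    def residual(theta):
        return _model_heights(theta, centers) - target

    best = None  # (ordered, objective, result)
    total_nfev = 0
    any_success = False
    for start in starts:
        res = optimize.least_squares(
            residual, start, bounds=(lo, hi), method="trf", max_nfev=max_nfev
        )
        total_nfev += res.nfev
        any_success = any_success or res.success
        obj = float(2.0 * res.cost)  # least_squares cost = 0.5 * SSE
        ordered = res.x[1] < res.x[5] < res.x[8]
        key = (not ordered, obj)
        if best is None or key < best[0]:
            best = (key, res, ordered)

    _, res, ordered = best
    theta = res.x.copy()
    if not ordered:
        # push locations to a minimally valid ordering so params construct
        theta[5] = max(theta[5], theta[1] + 1e-6)
        theta[8] = max(theta[8], theta[5] + 1e-6)
    params = TrimodalParams.from_array(theta)
    resid = residual(res.x)
    sse = float(np.sum(resid**2))
    sst = float(np.sum((target - target.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else float("nan")
    return NtraFitResult(
        params=params,
        objective=sse,
        converged=bool(any_success and ordered),
        n_iterations=int(total_nfev),
        r_squared=r2,
        residuals=resid,
        scale=scale,
    )


def goodness_of_fit(
    hist: RadiodensityHistogram, params: TrimodalParams, scale: float = 1.0
) -> tuple[float, float]:
    """R-squared and RMSE of the model against histogram bin heights.

    R-squared is undefined (NaN) for a zero-variance histogram.
    """
    target = hist.density(scale)
    model = evaluate_trimodal(hist.bin_centers, params)
    resid = model - target
    sse = float(np.sum(resid**2))
    sst = float(np.sum((target - target.mean()) ** 2))
    # zero-variance histogram: SST is numerically indistinguishable from 0
    if sst <= 1e-12 * float(np.sum(target**2)):
        return float("nan"), math.sqrt(sse / len(target))
    r2 = 1.0 - sse / sst
    rmse = math.sqrt(sse / len(target))
    return r2, rmse
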