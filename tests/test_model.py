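"""Unit and property tests for the trimodal radiodensity model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from ntra.model import (
    PARAM_NAMES,
    ParameterDomainError,
    RadiodensityHistogram,
    TissueComponent,
    TrimodalParams,
    component_mass,
    evaluate_component,
    evaluate_trimodal,
    fit_ntra,
    goodness_of_fit,
    histogram_from_voxels,
    initialize_params,
)
from tests.conftest import REFERENCE_THETA, REFERENCE_TOTAL_MASS

GRID = np.arange(-199.5, 200.0, 1.0)


def components():
    return st.builds(
        TissueComponent,
        N=st.floats(0.1, 100.0),
        mu=st.floats(-150.0, 150.0),
        sigma=st.floats(1.0, 40.0),
        alpha=st.floats(-8.0, 8.0),
    )


class TestEvaluateComponent:
    def test_standard_normal_apex(self):
        comp = TissueComponent(N=1.0, mu=0.0, sigma=1.0, alpha=0.0)
        assert evaluate_component(0.0, comp) == pytest.approx(
            1.0 / math.sqrt(2 * math.pi), abs=1e-15
        )

    def test_symmetric_without_skew(self):
        comp = TissueComponent(N=3.0, mu=20.0, sigma=5.0, alpha=0.0)
        for d in (0.5, 3.0, 11.0):
            assert evaluate_component(20 + d, comp) == pytest.approx(
                float(evaluate_component(20 - d, comp)), rel=1e-14
            )

    def test_reference_muscle_apex(self):
        # closed form at x = mu: N / (sigma sqrt(2 pi)), any skewness
        comp = TissueComponent(N=78.0, mu=61.5, sigma=8.6, alpha=2.8)
        expected = 78.0 / (8.6 * math.sqrt(2 * math.pi))
        assert evaluate_component(61.5, comp) == pytest.approx(expected, rel=1e-14)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ParameterDomainError):
            TissueComponent(N=1.0, mu=0.0, sigma=0.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(comp=components(), x=st.floats(-200.0, 200.0))
    def test_density_non_negative(self, comp, x):
        assert evaluate_component(x, comp) >= 0.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(comp=components())
    def test_apex_identity_any_alpha(self, comp):
        expected = comp.N / (comp.sigma * math.sqrt(2 * math.pi))
        assert evaluate_component(comp.mu, comp) == pytest.approx(
            expected, rel=1e-12
        )


class TestTrimodal:
    def test_zero_amplitudes_vanish(self):
        params = TrimodalParams(
            fat=TissueComponent(0.0, -100.0, 10.0, -2.0),
            connective=TissueComponent(0.0, 0.0, 20.0, 0.0),
            muscle=TissueComponent(0.0, 60.0, 9.0, 2.0),
        )
        assert np.all(evaluate_trimodal(GRID, params) == 0.0)

    def test_reduces_to_single_component(self):
        muscle = TissueComponent(50.0, 60.0, 9.0, 2.0)
        params = TrimodalParams(
            fat=TissueComponent(0.0, -100.0, 10.0, -2.0),
            connective=TissueComponent(0.0, 0.0, 20.0, 0.0),
            muscle=muscle,
        )
        np.testing.assert_allclose(
            evaluate_trimodal(GRID, params), evaluate_component(GRID, muscle)
        )

    def test_reference_params_show_three_ordered_peaks(self, reference_params):
        # sum of per-component curves, with local maxima ordered
        # fat < connective < muscle in HU
        total = evaluate_trimodal(GRID, reference_params)
        parts = [
            evaluate_component(GRID, c)
            for c in (
                reference_params.fat,
                reference_params.connective,
                reference_params.muscle,
            )
        ]
        np.testing.assert_allclose(total, np.sum(parts, axis=0), rtol=1e-12)
        peak_locs = [GRID[np.argmax(p)] for p in parts]
        assert peak_locs[0] < peak_locs[1] < peak_locs[2]

    def test_connective_skew_must_be_zero(self):
        with pytest.raises(ParameterDomainError):
            TrimodalParams(
                fat=TissueComponent(1.0, -100.0, 10.0, -2.0),
                connective=TissueComponent(1.0, 0.0, 20.0, 1.0),
                muscle=TissueComponent(1.0, 60.0, 9.0, 2.0),
            )

    def test_location_ordering_enforced(self):
        with pytest.raises(ParameterDomainError):
            TrimodalParams(
                fat=TissueComponent(1.0, 10.0, 10.0, -2.0),
                connective=TissueComponent(1.0, 0.0, 20.0, 0.0),
                muscle=TissueComponent(1.0, 60.0, 9.0, 2.0),
            )

    def test_array_round_trip(self, reference_params):
        theta = reference_params.to_array()
        np.testing.assert_array_equal(
            TrimodalParams.from_array(theta).to_array(), theta
        )
        assert list(reference_params.to_dict()) == list(PARAM_NAMES)


class TestComponentMass:
    @pytest.mark.parametrize(
        "comp",
        [
            TissueComponent(1.0, 0.0, 1.0, 0.0),
            TissueComponent(62.0, -117.8, 8.2, -2.5),
            TissueComponent(5.0, 30.0, 12.0, 7.0),
        ],
    )
    def test_quadrature_agrees_with_amplitude(self, comp):
        # independent oracle: numeric quadrature of the density
        integral, _ = integrate.quad(
            lambda x: float(evaluate_component(x, comp)),
            comp.mu - 40 * comp.sigma,
            comp.mu + 40 * comp.sigma,
            limit=400,
        )
        assert component_mass(comp) == comp.N
        assert integral == pytest.approx(comp.N, rel=1e-6)

    def test_mass_is_alpha_free(self):
        masses = {
            a: component_mass(TissueComponent(5.0, 10.0, 7.0, a))
            for a in (-6.0, 0.0, 3.3)
        }
        assert set(masses.values()) == {5.0}

    def test_skew_sign_convention(self):
        # alpha > 0 must skew the curve toward lower HU: negative third moment
        for alpha in (-3.0, -1.0, 1.0, 3.0):
            draws = stats.skewnorm.rvs(
                a=-alpha, loc=0.0, scale=1.0, size=20_000,
                random_state=np.random.default_rng(7),
            )
            assert np.sign(stats.skew(draws)) == -np.sign(alpha)


class TestHistogram:
    def test_direct_binning(self):
        hist = histogram_from_voxels([-150.0, -150.0, 50.0], bin_width=1.0)
        centers = hist.bin_centers
        assert hist.counts[np.flatnonzero(centers == -149.5)[0]] == 2
        assert hist.counts[np.flatnonzero(centers == 50.5)[0]] == 1
        assert hist.total_count == 3

    def test_upper_boundary_is_excluded(self):
        hist = histogram_from_voxels([0.0, 200.0, -250.0])
        assert hist.total_count == 1
        assert hist.n_discarded == 2

    def test_empty_retained_set_errors(self):
        with pytest.raises(ValueError):
            histogram_from_voxels([250.0, -300.0])

    def test_invariants_validated(self):
        edges = np.arange(-200.0, 201.0, 1.0)
        with pytest.raises(ValueError):
            RadiodensityHistogram(edges, -np.ones(400))
        with pytest.raises(ValueError):
            RadiodensityHistogram(edges[:-1], np.ones(398))

    def test_sampled_histogram_matches_model_shape(
        self, sampled_histogram, reference_params
    ):
        # chi-square goodness of fit of the binned sample against the
        # generating density (pooling sparse tail bins)
        probs = (
            evaluate_trimodal(sampled_histogram.bin_centers, reference_params)
            / REFERENCE_TOTAL_MASS
        )
        probs = probs / probs.sum()
        expected = probs * sampled_histogram.total_count
        keep = expected >= 5.0
        f_obs = np.append(sampled_histogram.counts[keep],
                          sampled_histogram.counts[~keep].sum())
        f_exp = np.append(expected[keep], expected[~keep].sum())
        f_exp *= f_obs.sum() / f_exp.sum()
        stat, p = stats.chisquare(f_obs, f_exp)
        assert p > 1e-4  # shape consistent within sampling error


class TestInitialization:
    def test_pure_muscle_gaussian(self):
        rng = np.random.default_rng(3)
        voxels = rng.normal(70.0, 5.0, size=50_000)
        voxels = voxels[(voxels > 45) & (voxels < 190)]
        hist = histogram_from_voxels(voxels)
        init = initialize_params(hist)
        assert init.muscle.mu == pytest.approx(np.mean(voxels), abs=0.5)
        assert init.muscle.sigma == pytest.approx(np.std(voxels), rel=0.1)
        assert init.fat.N == 0.0 and init.connective.N == 0.0

    def test_empty_fat_domain_degenerate_rule(self):
        rng = np.random.default_rng(4)
        voxels = rng.normal(70.0, 5.0, size=10_000)
        hist = histogram_from_voxels(voxels[(voxels > 45) & (voxels < 190)])
        init = initialize_params(hist)
        assert init.fat.mu == pytest.approx(-105.0)
        assert init.fat.sigma == pytest.approx(190.0 / 6.0, rel=1e-6)

    def test_inits_land_in_canonical_domains(self, sampled_histogram):
        init = initialize_params(sampled_histogram, scale=REFERENCE_TOTAL_MASS)
        assert -200 <= init.fat.mu <= -10
        assert -9 <= init.connective.mu <= 40
        assert 41 <= init.muscle.mu <= 200


class TestFit:
    def test_noise_free_self_consistency(self, reference_params):
        # histogram tabulated directly from the model must be recovered
        heights = evaluate_trimodal(GRID, reference_params)
        edges = np.arange(-200.0, 201.0, 1.0)
        hist = RadiodensityHistogram(edges, heights)
        res = fit_ntra(hist, scale=REFERENCE_TOTAL_MASS, seed=0)
        truth = reference_params.to_array()
        est = res.params.to_array()
        for name, t, e in zip(PARAM_NAMES, truth, est):
            if name.endswith("_mu"):
                assert abs(e - t) < 0.2, name
            else:
                assert abs(e - t) / abs(t) < 0.01, name
        assert res.converged

    def test_refit_from_optimum_is_idempotent(self, sampled_histogram):
        first = fit_ntra(sampled_histogram, scale=REFERENCE_TOTAL_MASS, seed=0)
        second = fit_ntra(
            sampled_histogram, init=first.params,
            scale=REFERENCE_TOTAL_MASS, n_starts=1, seed=0,
        )
        assert second.objective <= first.objective * (1 + 1e-8)
        assert abs(second.objective - first.objective) < 1e-8 * first.objective

    def test_sampled_round_trip(self, sampled_histogram, reference_params):
        res = fit_ntra(sampled_histogram, scale=REFERENCE_TOTAL_MASS, seed=1)
        truth = reference_params.to_array()
        est = res.params.to_array()
        for name, t, e in zip(PARAM_NAMES, truth, est):
            if name.endswith("_mu"):
                assert abs(e - t) < 1.0, name
            elif name.endswith("_N") or name.endswith("_sigma"):
                assert abs(e - t) / abs(t) < 0.05, name
        assert res.r_squared > 0.95
        assert res.converged

    def test_single_bin_degenerates_to_width_bound(self):
        edges = np.arange(-200.0, 201.0, 1.0)
        counts = np.zeros(400)
        counts[260] = 1000.0  # one bin at 60.5 HU
        hist = RadiodensityHistogram(edges, counts)
        res = fit_ntra(hist, seed=0)
        assert res.params.muscle.sigma == pytest.approx(0.5, abs=1e-6)

    def test_zero_count_histogram_rejected(self):
        edges = np.arange(-200.0, 201.0, 1.0)
        hist = RadiodensityHistogram(edges, np.zeros(400))
        with pytest.raises(ValueError):
            fit_ntra(hist)


class TestGoodnessOfFit:
    def test_exact_model_gives_r2_one(self, reference_params):
        heights = evaluate_trimodal(GRID, reference_params)
        hist = RadiodensityHistogram(np.arange(-200.0, 201.0, 1.0), heights)
        r2, rmse = goodness_of_fit(
            hist, reference_params, scale=heights.sum()
        )
        assert r2 == pytest.approx(1.0, abs=1e-4)
        assert rmse == pytest.approx(0.0, abs=1e-3)

    def test_zero_model_has_nonpositive_r2(self, sampled_histogram):
        null = TrimodalParams(
            fat=TissueComponent(0.0, -100.0, 10.0, 0.0),
            connective=TissueComponent(0.0, 0.0, 20.0, 0.0),
            muscle=TissueComponent(0.0, 60.0, 9.0, 0.0),
        )
        r2, _ = goodness_of_fit(sampled_histogram, null)
        assert r2 <= 0.0

    def test_flat_histogram_r2_undefined(self, reference_params):
        hist = RadiodensityHistogram(
            np.arange(-200.0, 201.0, 1.0), np.ones(400)
        )
        r2, _ = goodness_of_fit(hist, reference_params)
        assert math.isnan(r2)
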