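"""Virtual populations, biomarker samples and population-level calibration."""

import numpy as np
import pytest

import virtopop as vp
from virtopop import InvalidParameterError
from virtopop.population import burden_at


@pytest.fixture(scope="module")
def small_grid():
    return vp.SpaceGrid(33, 33)


class TestGenerateVpp:
    def test_single_member_fixed_coefficients_matches_direct_solve(self, small_grid):
        n0 = vp.gaussian_initial_condition(small_grid, variance=1e-3)
        t = [0.0, 20.0, 40.0]
        rng = np.random.default_rng(3)
        vpp = vp.generate_vpp(
            n0, small_grid, t, 1, rng, D=1e-5, rho=0.2, kappa=1e6
        )
        direct = vp.solve_rde(
            vp.CoefficientSet(D=1e-5, rho=0.2, kappa=1e6), n0, small_grid, t
        )
        np.testing.assert_allclose(
            vpp.members[0].burden, vp.tumor_burden(direct), rtol=1e-10
        )

    def test_same_seed_bitwise_reproducible(self, small_grid):
        n0 = vp.gaussian_initial_condition(small_grid, variance=1e-3)
        kw = dict(
            D_prior=vp.LumpPrior(5, 1e-6, 0.04),
            rho_prior=vp.LumpPrior(20, 0.2, 2e-3),
            kappa_prior=vp.LumpPrior(20, 1e5, 0.1),
        )
        a = vp.generate_vpp(n0, small_grid, [0, 10], 3, np.random.default_rng(17), **kw)
        b = vp.generate_vpp(n0, small_grid, [0, 10], 3, np.random.default_rng(17), **kw)
        for ma, mb in zip(a.members, b.members):
            assert ma.seed == mb.seed
            np.testing.assert_array_equal(ma.coeffs.D.centers, mb.coeffs.D.centers)
            np.testing.assert_array_equal(ma.burden, mb.burden)

    def test_initial_burden_is_seed_mass(self):
        grid = vp.SpaceGrid(129, 129)
        n0 = vp.gaussian_initial_condition(grid)  # 5 cells
        vpp = vp.generate_vpp(
            n0, grid, [0.0, 5.0], 3, np.random.default_rng(0),
            D=0.0, rho=0.1, kappa=1e6,
        )
        sample = vp.biomarker_sample(vpp, burden_at(0.0, vpp.times), "N(0)")
        np.testing.assert_allclose(sample.values, 5.0, rtol=2e-3)
        assert sample.values.shape == (3,)


class TestBiomarkers:
    def test_burden_grows_with_growth_amplitude(self, small_grid):
        """Larger rho-field amplitude b0 shifts the N(100) biomarker up."""
        n0 = vp.gaussian_initial_condition(small_grid, variance=1e-3)
        means = []
        for b0 in (0.1, 0.4):
            vpp = vp.generate_vpp(
                n0, small_grid, [0.0, 100.0], 16, np.random.default_rng(8),
                D=1e-6, kappa=1e7, rho_prior=vp.LumpPrior(200, b0, 2e-3),
                rtol=1e-5,
            )
            sample = vp.biomarker_sample(vpp, burden_at(100.0, vpp.times))
            means.append(sample.summary()["mean"])
        assert means[1] > means[0]

    def test_single_member_sample(self, small_grid):
        n0 = vp.gaussian_initial_condition(small_grid, variance=1e-3)
        vpp = vp.generate_vpp(
            n0, small_grid, [0.0, 1.0], 1, np.random.default_rng(0),
            D=0.0, rho=0.0, kappa=1.0,
        )
        s = vp.biomarker_sample(vpp, burden_at(1.0, vpp.times))
        assert s.values.shape == (1,)
        assert s.values[0] == pytest.approx(vpp.members[0].burden[-1])


class TestEnsembleSummary:
    def test_identical_members_zero_band(self):
        c = np.linspace(1, 5, 10)
        mean, sd = vp.ensemble_summary(np.stack([c, c, c]))
        np.testing.assert_allclose(mean, c)
        np.testing.assert_allclose(sd, 0.0, atol=1e-14)

    def test_two_member_hand_formula(self):
        c = np.linspace(1, 4, 7)
        mean, sd = vp.ensemble_summary(np.stack([c, 3 * c]))
        np.testing.assert_allclose(mean, 2 * c)
        np.testing.assert_allclose(sd, np.sqrt(2) * c)  # sample sd, ddof=1

    def test_coverage_diagnostic_near_normal(self, rng):
        curves = 10 + rng.standard_normal((64, 20))
        mean, sd = vp.ensemble_summary(curves)
        inside = np.mean((curves > mean - sd) & (curves < mean + sd))
        assert 0.55 < inside < 0.8  # ~68% for normal spread

    def test_single_member_rejected(self):
        with pytest.raises(InvalidParameterError):
            vp.ensemble_summary(np.ones((1, 5)))


@pytest.fixture(scope="module")
def calib_system():
    return vp.ImagingSystem.planar_grid(16, blur_sigma=0.0425, gain=100.0)


class TestPopulationLikelihood:
    def test_single_draw_reduces_to_plain_loglik(self, calib_system):
        params = vp.PopulationParams(10, 1.0, 2e-3)
        g = np.full(calib_system.n_bins, 3.0)
        # same seed -> same single field draw inside and outside the estimator
        ll = vp.population_loglik(g, params, calib_system, 1, np.random.default_rng(4))
        field = vp.sample_lump_field(params.prior(), np.random.default_rng(4))
        direct = vp.poisson_loglik(g, vp.forward_mean_lumpy(calib_system, field))
        assert ll == pytest.approx(direct, rel=1e-12)

    def test_enumerable_two_realization_prior(self, calib_system, rng):
        """MC marginal converges to the exact average over an activity with
        two equally likely realizations."""
        fa = vp.LumpField([[0.4, 0.4]], [2.0], 5e-3, 1)
        fb = vp.LumpField([[0.6, 0.6]], [3.0], 5e-3, 1)
        sampler = lambda r: fa if r.uniform() < 0.5 else fb  # noqa: E731
        g = vp.sample_counts(vp.forward_mean_lumpy(calib_system, fa), rng).astype(float)
        params = vp.PopulationParams(1, 1.0, 5e-3)  # placeholder; sampler overrides
        mc = vp.population_loglik(
            g, params, calib_system, 4096, np.random.default_rng(12),
            field_sampler=sampler,
        )
        la = vp.poisson_loglik(g, vp.forward_mean_lumpy(calib_system, fa))
        lb = vp.poisson_loglik(g, vp.forward_mean_lumpy(calib_system, fb))
        exact = np.logaddexp(la, lb) - np.log(2)
        assert mc == pytest.approx(exact, abs=0.1)

    def test_mc_variance_shrinks_with_draws(self, calib_system):
        params = vp.PopulationParams(10, 1.0, 2e-3)
        truth = vp.sample_lump_field(params.prior(), np.random.default_rng(1))
        g = np.random.default_rng(2).poisson(
            vp.forward_mean_lumpy(calib_system, truth)
        ).astype(float)
        variances = []
        for n_draws in (16, 64, 256):
            vals = [
                vp.population_loglik(
                    g, params, calib_system, n_draws, np.random.default_rng(100 + r)
                )
                for r in range(15)
            ]
            variances.append(np.var(vals, ddof=1))
        assert variances[0] > variances[1] > variances[2]


class TestPopulationMle:
    def test_single_point_grid_returned(self, calib_system, rng):
        params = vp.PopulationParams(10, 1.0, 2e-3)
        g = np.full(calib_system.n_bins, 2.0)
        best, scores = vp.population_mle(g, [params], calib_system, 8, rng)
        assert best is params and scores.shape == (1,)

    def test_dominated_candidate_loses(self, calib_system, rng):
        # an absurdly bright candidate makes every observed image implausible
        g = np.full(calib_system.n_bins, 1.0)
        good = vp.PopulationParams(5, 0.01, 2e-3)
        bad = vp.PopulationParams(200, 1e4, 0.05)
        best, scores = vp.population_mle(g, [bad, good], calib_system, 16, rng)
        assert best is good
        assert scores[1] > scores[0]
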