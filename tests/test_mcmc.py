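"""Metropolis-Hastings sampler: proposal symmetry, stationarity, acceptance."""

import numpy as np
import pytest

import virtopop as vp
from virtopop import InvalidParameterError
from virtopop.bayes import UniformPrior, proposal_log_density


def toy_layout(n_lumps=1):
    """Amplitudes-only layout with arbitrary frozen centers."""
    centers = np.linspace(0.2, 0.8, n_lumps)[:, None] * np.ones((1, 2))
    return vp.amplitude_grid_layout(centers, 1e-2)


class TestLogPosterior:
    def test_outside_prior_box_minus_inf(self):
        layout = toy_layout(2)
        prior = UniformPrior(amplitude_bounds=(0.0, 10.0))
        fwd = lambda th: np.ones(3)  # noqa: E731
        assert vp.log_posterior(np.array([-1.0, 1.0]), np.ones(3), prior, layout, fwd) == -np.inf
        assert vp.log_posterior(np.array([1.0, 11.0]), np.ones(3), prior, layout, fwd) == -np.inf

    def test_flat_prior_differences_equal_loglik_differences(self, rng):
        layout = toy_layout(2)
        prior = UniformPrior(amplitude_bounds=(0.0, 1e6))
        H = rng.uniform(0.1, 1.0, (6, 2))
        g = rng.poisson(H @ [3.0, 4.0]).astype(float)
        fwd = lambda th: H @ th  # noqa: E731
        t1, t2 = np.array([2.0, 5.0]), np.array([3.5, 1.0])
        dpost = vp.log_posterior(t1, g, prior, layout, fwd) - vp.log_posterior(
            t2, g, prior, layout, fwd
        )
        dlik = vp.poisson_loglik(g, H @ t1) - vp.poisson_loglik(g, H @ t2)
        assert dpost == pytest.approx(dlik, rel=1e-12)

    def test_matches_hand_computed_density_on_grid(self):
        # one amplitude, one bin, gbar = theta: p ~ 1[0<theta<B] e^{-theta} theta^g
        layout = toy_layout(1)
        prior = UniformPrior(amplitude_bounds=(0.0, 50.0))
        g = np.array([4.0])
        fwd = lambda th: th.copy()  # noqa: E731
        for theta in [0.5, 2.0, 10.0]:
            lp = vp.log_posterior(np.array([theta]), g, prior, layout, fwd)
            assert lp == pytest.approx(4 * np.log(theta) - theta)


class TestProposal:
    def test_zero_scale_keeps_state(self, rng):
        layout = toy_layout(3)
        cfg = vp.ChainConfig(n_steps=1, lumps_per_proposal=2, amplitude_sd=0.0)
        theta = rng.uniform(0, 1, 3)
        np.testing.assert_array_equal(vp.propose(theta, layout, cfg, rng), theta)

    def test_only_selected_amplitudes_move(self, rng):
        layout = toy_layout(10)
        cfg = vp.ChainConfig(n_steps=1, lumps_per_proposal=3, amplitude_sd=1.0)
        theta = np.zeros(10)
        moved = vp.propose(theta, layout, cfg, rng) != theta
        assert moved.sum() == 3

    def test_frozen_blocks_untouched(self, rng):
        layout = vp.free_center_layout(4)
        cfg = vp.ChainConfig(
            n_steps=1, lumps_per_proposal=2, amplitude_sd=1.0, center_sd=0.0, width_sd=0.0
        )
        theta = np.concatenate([rng.uniform(0, 1, 8), [2.0, 0.01]])
        new = vp.propose(theta, layout, cfg, rng)
        np.testing.assert_array_equal(new[:8], theta[:8])  # centers frozen
        assert new[9] == theta[9]  # width frozen
        assert new[8] != theta[8]  # shared amplitude moves

    def test_transition_density_is_symmetric(self, rng):
        layout = toy_layout(5)
        cfg = vp.ChainConfig(n_steps=1, lumps_per_proposal=2, amplitude_sd=0.7)
        for _ in range(20):
            a = rng.uniform(0, 5, 5)
            b = vp.propose(a, layout, cfg, rng)
            assert proposal_log_density(a, b, layout, cfg) == pytest.approx(
                proposal_log_density(b, a, layout, cfg), rel=1e-12
            )

    def test_too_many_lumps_rejected(self, rng):
        layout = toy_layout(2)
        cfg = vp.ChainConfig(n_steps=1, lumps_per_proposal=5, amplitude_sd=1.0)
        with pytest.raises(InvalidParameterError):
            vp.propose(np.zeros(2), layout, cfg, rng)


@pytest.fixture(scope="module")
def toy_chain():
    """Long chain on the 1D conjugate-style toy: one amplitude, one bin,
    gbar = theta, g = 400 counts; posterior ~ theta^400 e^-theta on [0, 1e10]."""
    layout = toy_layout(1)
    prior = UniformPrior(amplitude_bounds=(0.0, 1e10))
    g = np.array([400.0])
    cfg = vp.ChainConfig(n_steps=20_000, lumps_per_proposal=1, amplitude_sd=30.0)
    rng = np.random.default_rng(99)
    result = vp.run_chain(
        g, np.array([400.0]), cfg, prior, layout, lambda th: th.copy(), rng
    )
    return result


class TestChain:
    def test_constant_likelihood_accepts_everything(self, rng):
        layout = toy_layout(2)
        prior = UniformPrior(amplitude_bounds=(0.0, 1e12))
        cfg = vp.ChainConfig(n_steps=500, lumps_per_proposal=1, amplitude_sd=1.0)
        res = vp.run_chain(
            np.array([1.0]),
            np.array([1e6, 1e6]),  # far from the boundary
            cfg,
            prior,
            layout,
            lambda th: np.array([5.0]),  # likelihood independent of theta
            rng,
        )
        assert res.acceptance_rate == 1.0

    def test_toy_posterior_moments_match_quadrature(self, toy_chain):
        # quadrature oracle for the posterior density theta^g e^-theta
        theta_grid = np.linspace(250, 600, 20_000)
        logp = 400 * np.log(theta_grid) - theta_grid
        w = np.exp(logp - logp.max())
        w /= w.sum()
        q_mean = np.sum(w * theta_grid)
        q_var = np.sum(w * (theta_grid - q_mean) ** 2)
        x = toy_chain.samples[:, 0]
        # batch-means standard error to account for autocorrelation
        batches = x.reshape(40, -1).mean(axis=1)
        se_mean = batches.std(ddof=1) / np.sqrt(40)
        assert abs(x.mean() - q_mean) < 3 * se_mean
        vbatch = (x.reshape(40, -1) ** 2).mean(axis=1)
        se_m2 = vbatch.std(ddof=1) / np.sqrt(40)
        assert abs(x.var() - q_var) < 3 * (se_m2 + 2 * abs(q_mean) * se_mean)

    def test_rejections_repeat_state_and_support_holds(self, toy_chain):
        x = toy_chain.samples[:, 0]
        rejected = ~toy_chain.accepted
        assert rejected.any() and toy_chain.accepted.any()
        idx = np.flatnonzero(rejected[1:]) + 1
        np.testing.assert_array_equal(x[idx], x[idx - 1])
        assert np.all((x >= 0) & (x <= 1e10))

    def test_discretized_detailed_balance(self, toy_chain):
        """Empirical one-step flows between posterior quantile bins balance."""
        x = toy_chain.samples[:, 0]
        edges = np.quantile(x, [0.25, 0.5, 0.75])
        states = np.digitize(x, edges)
        flows = np.zeros((4, 4))
        np.add.at(flows, (states[:-1], states[1:]), 1)
        for i in range(4):
            for j in range(i + 1, 4):
                diff = abs(flows[i, j] - flows[j, i])
                assert diff < 3 * np.sqrt(flows[i, j] + flows[j, i]) + 1

    def test_acceptance_monotone_in_proposal_scale(self):
        layout = toy_layout(1)
        prior = UniformPrior(amplitude_bounds=(0.0, 1e10))
        g = np.array([400.0])
        rates = []
        for sd in [3.0, 30.0, 3000.0]:
            cfg = vp.ChainConfig(n_steps=4000, lumps_per_proposal=1, amplitude_sd=sd)
            res = vp.run_chain(
                g,
                np.array([400.0]),
                cfg,
                prior,
                layout,
                lambda th: th.copy(),
                np.random.default_rng(5),
            )
            rates.append(res.acceptance_rate)
        assert rates[0] > rates[1] > rates[2]
        assert rates[0] > 0.9 and rates[2] < 0.2

    def test_start_outside_support_rejected(self, rng):
        layout = toy_layout(1)
        prior = UniformPrior(amplitude_bounds=(0.0, 1.0))
        cfg = vp.ChainConfig(n_steps=10, lumps_per_proposal=1)
        with pytest.raises(InvalidParameterError):
            vp.run_chain(
                np.array([1.0]), np.array([5.0]), cfg, prior, layout,
                lambda th: th.copy(), rng,
            )
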