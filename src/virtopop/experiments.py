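"""End-to-end in-silico experiments: ground truth, imaging, estimation, VPPs.

Experiment 1: image the cell density n(x, t0) at t0 = 100 days with a
0.021 cm-sigma (500 um FWHM) Gaussian blur and photon yield 1e-3 detected
photons per cell, Poisson-sample the counts, reconstruct n(x, t0) by MLEM
over a 25 x 25 amplitude grid of narrow lumps on [0.35, 0.65]^2, and grow a
virtual population (J = 64) from the reconstruction with the remaining
coefficients randomized.  A Metropolis-Hastings chain over the lump
amplitudes (3 lumps per proposal, amplitude sd 1e4, i.i.d. uniform [0, 1e10]
prior, 512 steps from the MLE) yields posterior samples and a posterior
virtual population (J = 512).

Experiment 2 adds a second imaging channel for the growth field rho(x)
(0.0425 cm sigma, 1 mm FWHM), reconstructs rho by box-constrained nonlinear
MLE over free lump centers with shared amplitude and width (L_max = 60,
x in [0,1]^2, b > 0, sigma^2 in (0, 0.1]), and randomizes only D and kappa.

Both experiments share the population priors
D ~ LB(20, 1e-7, 0.04), rho ~ LB(200, 0.25, 0.002), kappa ~ LB(100, 5e7, 0.1),
chosen to give a mean tumor burden of order 1e8 cells after one year.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, replace

import numpy as np

from .bayes import ChainConfig, UniformPrior, run_chain
from .estimate import mlem, nonlinear_mle, poisson_loglik
from .fields import (
    LumpPrior,
    amplitude_grid_layout,
    free_center_layout,
    sample_lump_field,
    synthesize,
    unpack,
)
from .growth import (
    CellDensityPath,
    CoefficientSet,
    SpaceGrid,
    gaussian_initial_condition,
    solve_rde,
    tumor_burden,
)
from .imaging import ImagingSystem, build_system_matrix, forward_mean, sample_counts
from .imaging import forward_mean_lumpy
from .population import ensemble_summary, generate_vpp

__all__ = [
    "ExperimentConfig",
    "make_ground_truth",
    "run_experiment1",
    "run_experiment2",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExperimentConfig:
    """All tunables of the two experiments (defaults follow the study setup)."""

    # space-time discretization
    grid_n: int = 128
    t0: float = 100.0  # imaging day
    t_end: float = 365.0  # horizon (days)
    t_step: float = 5.0  # burden-curve output cadence (days)
    rtol: float = 1e-6
    atol: float = 1e-3

    # initial condition: 5 cells in a tight Gaussian at the domain center
    ic_center: tuple = (0.5, 0.5)
    ic_variance: float = 1e-4
    ic_total_cells: float = 5.0

    # population priors LB(L_bar, b0, sigma0^2) per coefficient
    D_prior: LumpPrior = field(default_factory=lambda: LumpPrior(20, 1e-7, 0.04))
    rho_prior: LumpPrior = field(default_factory=lambda: LumpPrior(200, 0.25, 0.002))
    kappa_prior: LumpPrior = field(default_factory=lambda: LumpPrior(100, 5e7, 0.1))

    # cell-density imaging channel
    n_bins: int = 64
    blur_sigma_n: float = 0.021  # cm (500 um FWHM)
    gain_n: float = 1e-3  # detected photons per cell

    # growth-field imaging channel (experiment 2)
    blur_sigma_rho: float = 0.0425  # cm (1 mm FWHM)
    gain_rho: float = 1e3  # detected photons per unit growth rate

    # MLEM reconstruction of n(x, t0)
    recon_grid_n: int = 25
    recon_box: tuple = ((0.35, 0.65), (0.35, 0.65))
    recon_lump_variance: float = 1e-2 / 256
    mlem_iterations: int = 5000

    # nonlinear MLE of rho (experiment 2)
    rho_max_lumps: int = 60
    rho_width_max: float = 0.1
    rho_mle_starts: int = 3

    # MCMC over the amplitude reconstruction
    mcmc_steps: int = 512
    mcmc_lumps_per_proposal: int = 3
    mcmc_amplitude_sd: float = 1e4
    mcmc_prior_upper: float = 1e10

    # virtual populations
    J_mle: int = 64
    J_posterior: int = 512

    @classmethod
    def smoke(cls) -> "ExperimentConfig":
        """Coarse, fast settings exercising every stage (plumbing check)."""
        return cls(
            grid_n=48,
            t_end=160.0,
            t_step=10.0,
            rtol=1e-5,
            n_bins=32,
            recon_grid_n=9,
            mlem_iterations=200,
            rho_max_lumps=10,
            rho_mle_starts=1,
            mcmc_steps=64,
            J_mle=4,
            J_posterior=4,
        )

    def grid(self) -> SpaceGrid:
        return SpaceGrid(self.grid_n, self.grid_n)

    def truth_times(self) -> np.ndarray:
        t = np.arange(0.0, self.t_end + 0.5 * self.t_step, self.t_step)
        if not np.any(np.isclose(t, self.t0)):
            t = np.sort(np.append(t, self.t0))
        return t

    def prediction_times(self) -> np.ndarray:
        """Times of the post-imaging forward solves, offset from t0."""
        return np.arange(0.0, self.t_end - self.t0 + 0.5 * self.t_step, self.t_step)

    def density_system(self) -> ImagingSystem:
        return ImagingSystem.planar_grid(self.n_bins, self.blur_sigma_n, self.gain_n)

    def growth_system(self) -> ImagingSystem:
        return ImagingSystem.planar_grid(
            self.n_bins, self.blur_sigma_rho, self.gain_rho
        )

    def recon_centers(self) -> np.ndarray:
        (x0, x1), (y0, y1) = self.recon_box
        cx = np.linspace(x0, x1, self.recon_grid_n)
        cy = np.linspace(y0, y1, self.recon_grid_n)
        X, Y = np.meshgrid(cx, cy, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel()])


def make_ground_truth(config: ExperimentConfig, rng: np.random.Generator):
    """Sample one coefficient triple from the population priors and solve.

    Returns (CoefficientSet, CellDensityPath) with the path evaluated at
    ``config.truth_times()`` (always containing the imaging day t0).
    """
    coeffs = CoefficientSet(
        D=sample_lump_field(config.D_prior, rng),
        rho=sample_lump_field(config.rho_prior, rng),
        kappa=sample_lump_field(config.kappa_prior, rng),
    )
    grid = config.grid()
    n0 = gaussian_initial_condition(
        grid, config.ic_center, config.ic_variance, config.ic_total_cells
    )
    path = solve_rde(
        coeffs, n0, grid, config.truth_times(), rtol=config.rtol, atol=config.atol
    )
    return coeffs, path


def image_density(config: ExperimentConfig, path: CellDensityPath, rng):
    """Snapshot ECT data of n(x, t0): mean image and one Poisson count draw."""
    system = config.density_system()
    f = path.at_time(config.t0)
    gbar = forward_mean(system, f, path.grid)
    g = sample_counts(gbar, rng)
    return system, gbar, g


def reconstruct_density(config: ExperimentConfig, system: ImagingSystem, g):
    """MLEM reconstruction of n(x, t0) on the fixed lump-amplitude grid.

    Initial guess is the back-projection H^T g; returns (result, matrix,
    layout)."""
    matrix = build_system_matrix(
        system, config.recon_centers(), config.recon_lump_variance
    )
    theta0 = matrix.adjoint(np.asarray(g, dtype=float))
    result = mlem(matrix, g, theta0, config.mlem_iterations, track_loglik=False)
    return result, matrix, matrix.layout()


def sample_density_posterior(
    config: ExperimentConfig, matrix, g, theta_mle, rng: np.random.Generator
):
    """Metropolis-Hastings chain over the lump amplitudes, started at the MLE."""
    layout = matrix.layout()
    chain_config = ChainConfig(
        n_steps=config.mcmc_steps,
        lumps_per_proposal=config.mcmc_lumps_per_proposal,
        amplitude_sd=config.mcmc_amplitude_sd,
    )
    prior = UniformPrior(amplitude_bounds=(0.0, config.mcmc_prior_upper))
    # start strictly inside the support
    theta0 = np.clip(theta_mle, 0.0, config.mcmc_prior_upper)
    return run_chain(
        g, theta0, chain_config, prior, layout, lambda th: matrix @ th, rng
    )


def _stage(name, t_start):
    elapsed = time.perf_counter() - t_start
    logger.info("stage %-24s %.1f s", name, elapsed)
    return time.perf_counter()


def run_experiment1(config: ExperimentConfig, rng: np.random.Generator) -> dict:
    """Density imaging -> MLEM -> MLE-VPP, plus posterior sampling -> VPP.

    Returns an artifact bundle (plain dict of arrays and scalars); see
    :mod:`virtopop.io` for persisting it.
    """
    t = time.perf_counter()
    grid = config.grid()
    truth_coeffs, truth_path = make_ground_truth(config, rng)
    truth_burden = tumor_burden(truth_path)
    t = _stage("ground-truth", t)

    system, gbar, g = image_density(config, truth_path, rng)
    mle_result, matrix, layout = reconstruct_density(config, system, g)
    n_hat = synthesize(unpack(mle_result.theta, layout), grid.points())
    t = _stage("imaging+mlem", t)

    pred_times = config.prediction_times()
    vpp_mle = generate_vpp(
        n_hat,
        grid,
        pred_times,
        config.J_mle,
        rng,
        D_prior=config.D_prior,
        rho_prior=config.rho_prior,
        kappa_prior=config.kappa_prior,
        rtol=config.rtol,
        atol=config.atol,
    )
    mle_mean, mle_sd = ensemble_summary(vpp_mle.burden_matrix())
    t = _stage("mle-vpp", t)

    chain = sample_density_posterior(config, matrix, g, mle_result.theta, rng)
    t = _stage("mcmc", t)

    # posterior VPP: each member starts from a distinct posterior sample
    pick = rng.choice(chain.samples.shape[0], size=config.J_posterior, replace=True)
    n0_samples = [
        synthesize(unpack(chain.samples[i], layout), grid.points()) for i in pick
    ]
    vpp_post = generate_vpp(
        n0_samples[0],
        grid,
        pred_times,
        config.J_posterior,
        rng,
        D_prior=config.D_prior,
        rho_prior=config.rho_prior,
        kappa_prior=config.kappa_prior,
        n0_samples=n0_samples,
        rtol=config.rtol,
        atol=config.atol,
    )
    post_mean, post_sd = ensemble_summary(vpp_post.burden_matrix())
    t = _stage("posterior-vpp", t)

    return {
        "truth_times": truth_path.times,
        "truth_burden": truth_burden,
        "counts": g,
        "mean_counts": gbar,
        "theta_mle": mle_result.theta,
        "mle_loglik": mle_result.loglik,
        "prediction_times": config.t0 + pred_times,
        "vpp_mle_burden": vpp_mle.burden_matrix(),
        "vpp_mle_mean": mle_mean,
        "vpp_mle_sd": mle_sd,
        "chain_samples": chain.samples,
        "chain_log_posterior": chain.log_posterior,
        "acceptance_rate": chain.acceptance_rate,
        "vpp_posterior_burden": vpp_post.burden_matrix(),
        "vpp_posterior_mean": post_mean,
        "vpp_posterior_sd": post_sd,
    }


def experiment1_acceptance_rate(
    config: ExperimentConfig, rng: np.random.Generator, replicates: int = 3
) -> float:
    """Mean Metropolis-Hastings acceptance rate of the Experiment-1 chain.

    Runs the estimation pipeline (fresh ground truth, density image, MLEM,
    512-step amplitude chain from the MLE) ``replicates`` times with
    independent truths and returns the average accepted/total ratio.  The
    rate depends on the particular ground-truth draw, so averaging a few
    replicates reduces that variability without changing the estimand.
    """
    rates = []
    for _ in range(replicates):
        _, path = make_ground_truth(config, rng)
        system, _, g = image_density(config, path, rng)
        mle_result, matrix, _ = reconstruct_density(config, system, g)
        chain = sample_density_posterior(config, matrix, g, mle_result.theta, rng)
        rates.append(chain.acceptance_rate)
        logger.info("replicate acceptance rate %.3f", rates[-1])
    return float(np.mean(rates))


def reconstruct_growth(
    config: ExperimentConfig, system: ImagingSystem, g, rng: np.random.Generator
):
    """Box-constrained nonlinear MLE of rho: free centers, shared b and width.

    theta = [x_1 ... x_Lmax, b, sigma^2] with x in [0,1]^2, b > 0 and
    sigma^2 in (0, 0.1].  Started from centers spread over the domain
    interior with width at mid-range.
    """
    layout = free_center_layout(config.rho_max_lumps)
    bounds = [(0.0, 1.0)] * (2 * config.rho_max_lumps)
    bounds += [(1e-12, None), (1e-8, config.rho_width_max)]
    centers0 = rng.uniform(0.2, 0.8, size=(config.rho_max_lumps, 2))
    theta0 = np.concatenate(
        [centers0.ravel(), [np.mean(g) / max(system.gain, 1e-300), 0.01]]
    )
    forward = lambda th: forward_mean_lumpy(system, th, layout)  # noqa: E731
    result = nonlinear_mle(
        forward,
        g,
        theta0,
        bounds,
        n_starts=config.rho_mle_starts,
        rng=rng,
        options={"maxiter": 300},
    )
    return result, layout


def run_experiment2(config: ExperimentConfig, rng: np.random.Generator) -> dict:
    """Polyscopic variant: MLEs of both n(x, t0) and rho(x) feed the VPP;
    only D and kappa are randomized (J = 64)."""
    t = time.perf_counter()
    grid = config.grid()
    truth_coeffs, truth_path = make_ground_truth(config, rng)
    truth_burden = tumor_burden(truth_path)
    t = _stage("ground-truth", t)

    system_n, _, g_n = image_density(config, truth_path, rng)
    mle_n, matrix, layout_n = reconstruct_density(config, system_n, g_n)
    n_hat = synthesize(unpack(mle_n.theta, layout_n), grid.points())
    t = _stage("density-channel", t)

    system_rho = config.growth_system()
    rho_true = truth_coeffs.on_grid(grid)[1]
    gbar_rho = forward_mean(system_rho, rho_true, grid)
    g_rho = sample_counts(gbar_rho, rng)
    mle_rho, layout_rho = reconstruct_growth(config, system_rho, g_rho, rng)
    rho_hat = synthesize(unpack(mle_rho.theta, layout_rho), grid.points())
    t = _stage("growth-channel", t)

    pred_times = config.prediction_times()
    vpp = generate_vpp(
        n_hat,
        grid,
        pred_times,
        config.J_mle,
        rng,
        rho=rho_hat,
        D_prior=config.D_prior,
        kappa_prior=config.kappa_prior,
        rtol=config.rtol,
        atol=config.atol,
    )
    vpp_mean, vpp_sd = ensemble_summary(vpp.burden_matrix())
    t = _stage("vpp", t)

    return {
        "truth_times": truth_path.times,
        "truth_burden": truth_burden,
        "counts_n": g_n,
        "counts_rho": g_rho,
        "theta_mle_n": mle_n.theta,
        "theta_mle_rho": mle_rho.theta,
        "rho_mle_converged": mle_rho.converged,
        "prediction_times": config.t0 + pred_times,
        "vpp_burden": vpp.burden_matrix(),
        "vpp_mean": vpp_mean,
        "vpp_sd": vpp_sd,
    }
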