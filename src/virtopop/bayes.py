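"""Metropolis-Hastings sampling of the posterior over lumpy-field parameters.

The posterior over theta given Poisson counts g is

    p(theta | g)  ~  p0(theta) L(theta | g),

with p0 a product of independent uniform priors per parameter block and L
the Poisson likelihood.  Proposals perturb a random subset of L_mcmc lumps
with independent Gaussians (diagonal covariance) on their free blocks;
because the lump subset is drawn independently of the current state and
the Gaussian kernel is symmetric, the proposal is symmetric and the
acceptance probability reduces to the Metropolis ratio

    Q(theta', theta) = min{1, p0(theta') L(theta'|g) / (p0(theta) L(theta|g))}.

Proposals that leave the prior support (negative amplitudes, centers
outside the domain) are handled by prior rejection: the log-posterior is
-inf there, so the step is rejected and the chain repeats its state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._validation import InvalidParameterError
from .estimate import poisson_loglik
from .fields import LumpLayout

__all__ = ["ChainConfig", "ChainResult", "log_posterior", "propose", "run_chain"]


@dataclass(frozen=True)
class UniformPrior:
    """Independent uniform bounds per parameter block of a lump layout.

    ``amplitude_bounds`` apply to every free (or shared) amplitude entry,
    ``center_bounds`` to every center coordinate, ``width_bounds`` to the
    shared variance.  The log-density is 0 inside the box and -inf outside
    (the normalizing constant cancels in Metropolis ratios).
    """

    amplitude_bounds: tuple = (0.0, np.inf)
    center_bounds: tuple = (0.0, 1.0)
    width_bounds: tuple = (0.0, np.inf)

    def log_density(self, theta: np.ndarray, layout: LumpLayout) -> float:
        amp, cen, wid = layout._blocks()
        theta = np.asarray(theta, dtype=float)
        if amp is not None:
            block = theta[amp[0] : amp[1]]
            if np.any(block < self.amplitude_bounds[0]) or np.any(
                block > self.amplitude_bounds[1]
            ):
                return -np.inf
        if cen is not None:
            block = theta[cen[0] : cen[1]]
            if np.any(block < self.center_bounds[0]) or np.any(
                block > self.center_bounds[1]
            ):
                return -np.inf
        if wid is not None:
            w = theta[wid[0]]
            if not (self.width_bounds[0] < w <= self.width_bounds[1]):
                return -np.inf
        return 0.0


@dataclass
class ChainConfig:
    """Metropolis-Hastings settings.

    ``lumps_per_proposal`` lumps are redrawn per step; each free block of a
    selected lump is perturbed by a zero-mean Gaussian with the matching
    standard deviation (a zero sd freezes that block).
    """

    n_steps: int
    lumps_per_proposal: int = 3
    amplitude_sd: float = 1e4
    center_sd: float = 0.0
    width_sd: float = 0.0
    burn_in: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise InvalidParameterError("chain length must be >= 1")
        if self.lumps_per_proposal < 1:
            raise InvalidParameterError("lumps_per_proposal must be >= 1")
        if min(self.amplitude_sd, self.center_sd, self.width_sd) < 0:
            raise InvalidParameterError("proposal scales must be >= 0")


@dataclass
class ChainResult:
    """Posterior samples with log-posterior trace and acceptance bookkeeping."""

    samples: np.ndarray  # (n_kept, dim)
    log_posterior: np.ndarray
    accepted: np.ndarray  # bool per proposal (after burn-in)
    n_burn_in: int = 0

    @property
    def acceptance_rate(self) -> float:
        """Accepted proposals divided by total number of samples."""
        return float(np.mean(self.accepted))


def log_posterior(
    theta: np.ndarray, g: np.ndarray, prior: UniformPrior, layout: LumpLayout, forward
) -> float:
    """log p0(theta) + l(theta | g), up to an additive constant; -inf outside
    the prior support (the forward model is not evaluated there)."""
    lp = prior.log_density(theta, layout)
    if not np.isfinite(lp):
        return -np.inf
    return lp + poisson_loglik(g, forward(theta))


def propose(
    theta: np.ndarray,
    layout: LumpLayout,
    config: ChainConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Perturb the free blocks of ``lumps_per_proposal`` randomly chosen lumps.

    Lump indices are drawn uniformly without replacement; shared blocks
    (common amplitude / width) are perturbed once whenever any lump is
    selected.  The transition density is symmetric in (theta, theta').
    """
    if config.lumps_per_proposal > layout.max_lumps:
        raise InvalidParameterError("lumps_per_proposal exceeds the number of lumps")
    theta = np.array(theta, dtype=float).copy()
    idx = rng.choice(layout.max_lumps, size=config.lumps_per_proposal, replace=False)
    amp, cen, wid = layout._blocks()
    if amp is not None and config.amplitude_sd > 0:
        if layout.free_amplitudes:
            theta[amp[0] + idx] += config.amplitude_sd * rng.standard_normal(idx.size)
        else:  # shared amplitude
            theta[amp[0]] += config.amplitude_sd * rng.standard_normal()
    if cen is not None and config.center_sd > 0:
        for i in idx:
            sl = slice(cen[0] + i * layout.ndim, cen[0] + (i + 1) * layout.ndim)
            theta[sl] += config.center_sd * rng.standard_normal(layout.ndim)
    if wid is not None and config.width_sd > 0:
        theta[wid[0]] += config.width_sd * rng.standard_normal()
    return theta


def proposal_log_density(
    theta_from: np.ndarray,
    theta_to: np.ndarray,
    layout: LumpLayout,
    config: ChainConfig,
) -> float:
    """Log transition density of the proposal kernel (up to the shared
    combinatorial constant over index subsets).

    Exposes the symmetry of the kernel: the density depends on
    (theta_to - theta_from) only through squares, so swapping the arguments
    leaves it unchanged.  Only the amplitude block is handled (the layouts
    this is used with in tests); the Gaussian factor applies to the moved
    coordinates, and moves touching more lumps than allowed have density 0.
    """
    diff = np.asarray(theta_to, dtype=float) - np.asarray(theta_from, dtype=float)
    moved = np.flatnonzero(diff)
    if moved.size > config.lumps_per_proposal:
        return -np.inf
    sd = config.amplitude_sd
    return float(
        -0.5 * np.sum(diff[moved] ** 2) / sd**2
        - moved.size * np.log(sd * np.sqrt(2 * np.pi))
    )


def run_chain(
    g: np.ndarray,
    theta0: np.ndarray,
    config: ChainConfig,
    prior: UniformPrior,
    layout: LumpLayout,
    forward,
    rng: np.random.Generator,
) -> ChainResult:
    """Metropolis-Hastings chain of ``config.n_steps`` proposals from theta0.

    theta0 must lie in the prior support (a chain is typically started at
    the MLE, which for a uniform prior is the MAP, so no burn-in is needed
    by default).  Rejected proposals repeat the previous state exactly.
    """
    theta = np.array(theta0, dtype=float).copy()
    lp = log_posterior(theta, g, prior, layout, forward)
    if not np.isfinite(lp):
        raise InvalidParameterError("chain start is outside the prior support")
    dim = theta.shape[0]
    total = config.n_steps + config.burn_in
    kept = config.n_steps
    samples = np.empty((kept, dim))
    lps = np.empty(kept)
    accepted = np.zeros(kept, dtype=bool)
    for step in range(total):
        proposal = propose(theta, layout, config, rng)
        lp_new = log_posterior(proposal, g, prior, layout, forward)
        accept = np.log(rng.uniform()) < lp_new - lp
        if accept:
            theta, lp = proposal, lp_new
        k = step - config.burn_in
        if k >= 0:
            samples[k] = theta
            lps[k] = lp
            accepted[k] = accept
    return ChainResult(samples, lps, accepted, n_burn_in=config.burn_in)
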