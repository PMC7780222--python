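"""Virtual patient populations, biomarker samples and population calibration.

A virtual patient is a coefficient draw beta = (D, rho, kappa) plus the
forward solve n(x, t) it produces; a virtual population is an ensemble of
J such members sharing the grid and time vector.  The initial density and
growth field can be fixed (estimated from a patient's image data) while
the unmeasured coefficients are randomized from lumpy-field priors --
this is how patient-specific populations propagate parameter uncertainty
into biomarkers such as the tumor burden N(t).

Population calibration estimates the hyperparameters theta_p = (L_bar, b0,
sigma0^2) of the lumpy prior from a database of noisy count images by a
Monte-Carlo marginal likelihood,

    P(g_j | theta_p) ~= 1/J' sum_{j'} P(g_j | f_{j'}),   f_{j'} ~ LB(theta_p),

evaluated in log space with log-sum-exp and maximized over a finite grid
of candidate hyperparameters (with common random numbers across grid
points to suppress Monte-Carlo noise in the comparison).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import logsumexp

from ._validation import InvalidParameterError
from .fields import LumpPrior, sample_lump_field
from .growth import CellDensityPath, CoefficientSet, SpaceGrid, solve_rde, tumor_burden
from .imaging import ImagingSystem, forward_mean_lumpy
from .estimate import poisson_loglik

__all__ = [
    "VppMember",
    "VirtualPopulation",
    "BiomarkerSample",
    "PopulationParams",
    "generate_vpp",
    "biomarker_sample",
    "ensemble_summary",
    "population_loglik",
    "population_mle",
]


@dataclass
class VppMember:
    """One virtual patient: coefficients, burden curve, optional full path."""

    coeffs: CoefficientSet
    burden: np.ndarray
    path: CellDensityPath | None = None
    seed: int | None = None
    source: str = "randomized"
    failed: bool = False


@dataclass
class VirtualPopulation:
    """Ensemble of virtual patients on a shared grid and time vector."""

    members: list
    times: np.ndarray
    grid: SpaceGrid

    @property
    def size(self) -> int:
        return len(self.members)

    def burden_matrix(self) -> np.ndarray:
        """(J, nt) tumor-burden curves of the non-failed members."""
        return np.array([m.burden for m in self.members if not m.failed])


@dataclass
class BiomarkerSample:
    """Length-J vector of a scalar biomarker over a virtual population."""

    values: np.ndarray
    descriptor: str = ""

    def summary(self) -> dict:
        v = self.values
        return {
            "mean": float(np.mean(v)),
            "sd": float(np.std(v, ddof=1)) if v.size > 1 else 0.0,
            "min": float(np.min(v)),
            "max": float(np.max(v)),
        }


@dataclass(frozen=True)
class PopulationParams:
    """Hyperparameter triple theta_p = (L_bar, b0, sigma0^2) of one field."""

    mean_lumps: float
    amplitude: float
    lump_variance: float

    def __post_init__(self) -> None:
        if min(self.mean_lumps, self.amplitude, self.lump_variance) <= 0:
            raise InvalidParameterError("population parameters must be positive")

    def prior(self, domain=((0.0, 1.0), (0.0, 1.0))) -> LumpPrior:
        return LumpPrior(self.mean_lumps, self.amplitude, self.lump_variance, domain)


def _resolve(coef, prior, rng, name):
    """Fixed coefficient if given, else a fresh draw from its prior."""
    if coef is not None:
        return coef
    if prior is None:
        raise InvalidParameterError(f"{name}: provide either a fixed field or a prior")
    return sample_lump_field(prior, rng)


def generate_vpp(
    n0: np.ndarray,
    grid: SpaceGrid,
    t_eval,
    J: int,
    rng: np.random.Generator,
    D=None,
    rho=None,
    kappa=None,
    D_prior: LumpPrior | None = None,
    rho_prior: LumpPrior | None = None,
    kappa_prior: LumpPrior | None = None,
    n0_samples: Sequence[np.ndarray] | None = None,
    keep_paths: bool = False,
    rtol: float = 1e-6,
    atol: float = 1e-3,
) -> VirtualPopulation:
    """Generate a virtual population of J forward solves.

    Each coefficient is either fixed (pass ``D`` / ``rho`` / ``kappa``, e.g.
    an estimated growth field) or randomized per member from its lumpy
    prior.  ``n0_samples`` supplies per-member initial densities (e.g.
    posterior samples of the imaged cell density); otherwise all members
    share ``n0``.  Per-member seeds are spawned from ``rng`` and recorded,
    so a population is reproducible from its seeds.  A member whose solve
    fails is flagged and excluded from burden summaries.
    """
    if J < 1:
        raise InvalidParameterError("population size J must be >= 1")
    if n0_samples is not None and len(n0_samples) != J:
        raise InvalidParameterError("n0_samples length must equal J")
    t_eval = np.asarray(t_eval, dtype=float)
    seeds = rng.integers(0, 2**31 - 1, size=J)
    members = []
    for j in range(J):
        member_rng = np.random.default_rng(seeds[j])
        coeffs = CoefficientSet(
            D=_resolve(D, D_prior, member_rng, "D"),
            rho=_resolve(rho, rho_prior, member_rng, "rho"),
            kappa=_resolve(kappa, kappa_prior, member_rng, "kappa"),
        )
        start = n0_samples[j] if n0_samples is not None else n0
        source = "posterior-sample" if n0_samples is not None else "randomized"
        try:
            path = solve_rde(coeffs, start, grid, t_eval, rtol=rtol, atol=atol)
            member = VppMember(
                coeffs,
                tumor_burden(path),
                path=path if keep_paths else None,
                seed=int(seeds[j]),
                source=source,
            )
        except Exception:  # noqa: BLE001 - a failed member must not sink the rest
            member = VppMember(
                coeffs,
                np.full(len(t_eval), np.nan),
                seed=int(seeds[j]),
                source=source,
                failed=True,
            )
        members.append(member)
    return VirtualPopulation(members, t_eval, grid)


def biomarker_sample(
    vpp: VirtualPopulation, functional: Callable[[VppMember], float], descriptor: str = ""
) -> BiomarkerSample:
    """Apply a scalar functional (e.g. burden at day t) to every member."""
    vals = np.array([functional(m) for m in vpp.members if not m.failed])
    return BiomarkerSample(vals, descriptor)


def burden_at(t: float, times: np.ndarray) -> Callable[[VppMember], float]:
    """Functional returning the tumor burden N(t) at the stored time t."""
    times = np.asarray(times, dtype=float)
    idx = int(np.argmin(np.abs(times - t)))
    if not np.isclose(times[idx], t):
        raise InvalidParameterError(f"time {t} not in the population time vector")
    return lambda m: float(m.burden[idx])


def ensemble_summary(burden_curves: np.ndarray):
    """Pointwise empirical mean and +-1 sample-sd band over member curves.

    Returns (mean, sd), each of length nt; sd uses the J-1 denominator and
    needs at least two members.
    """
    curves = np.asarray(burden_curves, dtype=float)
    if curves.ndim != 2 or curves.shape[0] < 2:
        raise InvalidParameterError("need >= 2 member curves for an sd band")
    return curves.mean(axis=0), curves.std(axis=0, ddof=1)


def population_loglik(
    images: np.ndarray,
    params: PopulationParams,
    system: ImagingSystem,
    n_draws: int,
    rng: np.random.Generator,
    domain=((0.0, 1.0), (0.0, 1.0)),
    fresh_per_image: bool = True,
    field_sampler=None,
) -> float:
    """Monte-Carlo marginal log-likelihood of theta_p given an image database.

    sum_j log[ 1/J' sum_{j'} P(g_j | f_{j'}) ] with f_{j'} ~ LB(theta_p) and
    P the Poisson likelihood of the mean image H f_{j'}, computed in log
    space with log-sum-exp.  ``fresh_per_image=False`` reuses one set of J'
    field draws for every image (common random numbers across images).
    Returns -inf when every inner likelihood of some image underflows to
    zero probability (logged by the -inf sentinel itself).
    ``field_sampler`` (callable rng -> LumpField) overrides the prior draw,
    mainly for validation against enumerable toy priors.
    """
    if n_draws < 1:
        raise InvalidParameterError("n_draws must be >= 1")
    images = np.atleast_2d(np.asarray(images, dtype=float))
    prior = params.prior(domain)
    if field_sampler is None:
        field_sampler = lambda r: sample_lump_field(prior, r)  # noqa: E731

    def draw_means(k):
        return np.array(
            [forward_mean_lumpy(system, field_sampler(rng)) for _ in range(k)]
        )

    total = 0.0
    shared = None if fresh_per_image else draw_means(n_draws)
    for g in images:
        means = draw_means(n_draws) if fresh_per_image else shared
        lls = np.array([poisson_loglik(g, gbar) for gbar in means])
        if np.all(np.isneginf(lls)):
            return -np.inf
        total += float(logsumexp(lls) - np.log(n_draws))
    return total


def population_mle(
    images: np.ndarray,
    grid_points: Sequence[PopulationParams],
    system: ImagingSystem,
    n_draws: int,
    rng: np.random.Generator,
    domain=((0.0, 1.0), (0.0, 1.0)),
):
    """Grid-search population MLE with common random numbers across candidates.

    Every candidate theta_p is scored by :func:`population_loglik` with an
    identically seeded generator, so Monte-Carlo noise largely cancels in
    the comparison.  Ties go to the first-encountered maximum.
    """
    if len(grid_points) == 0:
        raise InvalidParameterError("empty search grid")
    seed = rng.integers(0, 2**31 - 1)
    best = None
    scores = []
    for params in grid_points:
        ll = population_loglik(
            images,
            params,
            system,
            n_draws,
            np.random.default_rng(seed),
            domain=domain,
        )
        scores.append(ll)
        if best is None or ll > best[0]:
            best = (ll, params)
    return best[1], np.asarray(scores)
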