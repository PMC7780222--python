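"""Likelihood evaluation and maximum-likelihood estimation for count data.

Binned-mode counts are Poisson with mean gbar(theta), so the log-likelihood
(dropping the theta-independent ``-sum ln g_m!`` term) is

    l(theta | g) = sum_m [ g_m ln gbar_m(theta) - gbar_m(theta) ].

For linear lumpy parameterizations (amplitudes over a fixed center grid)
the EM algorithm reduces to the multiplicative MLEM update

    theta_n <- theta_n / s_n * sum_m H_mn g_m / (H theta)_m,   s_n = sum_m H_mn,

which preserves non-negativity and never decreases the likelihood.  For
nonlinear parameterizations (free lump centers / shared amplitude and
width) the MLE is computed by box-constrained quasi-Newton optimization.

The Fisher information of the Poisson model,

    F_nn' = sum_m (d gbar_m / d theta_n)(d gbar_m / d theta_n') / gbar_m,

gives the asymptotic MLE covariance F^{-1}.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from ._validation import InvalidParameterError
from .imaging import SystemMatrix

__all__ = [
    "MleResult",
    "FisherInfo",
    "poisson_loglik",
    "mlem",
    "nonlinear_mle",
    "fisher_information",
]

logger = logging.getLogger(__name__)

_NEG_INF = -np.inf


def poisson_loglik(g: np.ndarray, gbar: np.ndarray) -> float:
    """Poisson log-likelihood sum_m [g_m ln gbar_m - gbar_m] (constant dropped).

    Conventions: a bin with g_m = 0 contributes -gbar_m (0 ln 0 := 0); a bin
    with gbar_m = 0 but g_m > 0 has zero likelihood, returned as -inf.
    """
    g = np.asarray(g, dtype=float)
    gbar = np.asarray(gbar, dtype=float)
    if g.shape != gbar.shape:
        raise InvalidParameterError("g and gbar shapes differ")
    if np.any(gbar < 0):
        raise InvalidParameterError("mean counts must be non-negative")
    impossible = (gbar == 0) & (g > 0)
    if np.any(impossible):
        logger.debug("poisson_loglik: %d bins with gbar=0, g>0", impossible.sum())
        return _NEG_INF
    pos = g > 0
    return float(np.sum(g[pos] * np.log(gbar[pos])) - np.sum(gbar))


@dataclass
class MleResult:
    """Maximum-likelihood estimate with its convergence trace."""

    theta: np.ndarray
    loglik: float
    n_iter: int
    trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True


def mlem(
    matrix: SystemMatrix | np.ndarray,
    g: np.ndarray,
    theta0: np.ndarray,
    n_iter: int,
    track_loglik: bool = True,
) -> MleResult:
    """MLEM iteration for a linear Poisson model g ~ Poi(H theta).

    Runs a fixed number of multiplicative updates from theta0 >= 0 (zero
    components stay at zero, which is an MLEM fixed point).  Columns with
    zero sensitivity are excluded from the update; a small floor guards
    zero denominators, with a warning when it is ever hit on a bin with
    counts.  The per-iteration log-likelihood trace is non-decreasing.
    """
    H = matrix.H if isinstance(matrix, SystemMatrix) else np.asarray(matrix)
    g = np.asarray(g, dtype=float)
    theta = np.array(theta0, dtype=float).copy()
    if theta.shape[0] != H.shape[1]:
        raise InvalidParameterError("theta0 length does not match H columns")
    if np.any(theta < 0):
        raise InvalidParameterError("theta0 must be non-negative")
    s = H.sum(axis=0)
    active = s > 0
    if not np.all(active):
        logger.warning("mlem: %d zero-sensitivity columns frozen", (~active).sum())
    floor = np.finfo(float).tiny
    trace = np.empty(n_iter) if track_loglik else np.empty(0)
    floored = False
    for k in range(n_iter):
        gbar = H @ theta
        denom = np.maximum(gbar, floor)
        if np.any((gbar == 0) & (g > 0)):
            floored = True
        ratio = H.T @ (g / denom)
        theta[active] *= ratio[active] / s[active]
        if track_loglik:
            trace[k] = poisson_loglik(g, H @ theta)
    if floored:
        logger.warning("mlem: zero model mean on bins with counts; floor applied")
    final = trace[-1] if track_loglik and n_iter else poisson_loglik(g, H @ theta)
    return MleResult(theta, float(final), n_iter, trace)


def nonlinear_mle(
    forward,
    g: np.ndarray,
    theta0: np.ndarray,
    bounds,
    n_starts: int = 3,
    perturb_scale: float = 0.05,
    rng: np.random.Generator | None = None,
    options: dict | None = None,
) -> MleResult:
    """Box-constrained MLE for a nonlinear forward model gbar = forward(theta).

    Minimizes -l(theta|g) with L-BFGS-B inside ``bounds`` (a sequence of
    (lo, hi) pairs).  Non-convexity is mitigated by multi-start: the first
    start is theta0 itself, the rest are theta0 with multiplicative
    perturbations of relative scale ``perturb_scale``, clipped to the
    bounds; the best likelihood wins.  A non-converged optimizer still
    returns its best iterate, flagged on the result.
    """
    g = np.asarray(g, dtype=float)
    theta0 = np.asarray(theta0, dtype=float)
    lo = np.array([b[0] if b[0] is not None else -np.inf for b in bounds])
    hi = np.array([b[1] if b[1] is not None else np.inf for b in bounds])
    if np.any(theta0 < lo) or np.any(theta0 > hi):
        raise InvalidParameterError("theta0 violates the bounds")
    if rng is None:
        rng = np.random.default_rng(0)

    trace: list[float] = []

    def negloglik(theta):
        ll = poisson_loglik(g, forward(theta))
        trace.append(ll)
        # a huge finite penalty keeps line searches alive where gbar hits 0
        return -ll if np.isfinite(ll) else 1e30

    best = None
    for start in range(n_starts):
        if start == 0:
            x0 = theta0
        else:
            x0 = theta0 * (1 + perturb_scale * rng.standard_normal(theta0.shape))
            x0 = np.clip(x0, lo, hi)
        res = minimize(
            negloglik, x0, method="L-BFGS-B", bounds=bounds, options=options or {}
        )
        if best is None or -res.fun > best[0]:
            best = (-res.fun, res.x, bool(res.success), res.nit)
    ll, theta, ok, nit = best
    if not ok:
        logger.warning("nonlinear_mle: optimizer did not report convergence")
    return MleResult(theta, float(ll), int(nit), np.asarray(trace), converged=ok)


@dataclass(frozen=True)
class FisherInfo:
    """Symmetric PSD Fisher information matrix of the Poisson count model."""

    matrix: np.ndarray

    def inverse(self) -> np.ndarray:
        """Asymptotic MLE covariance F^{-1}; pseudo-inverse if F is singular."""
        F = self.matrix
        cond = np.linalg.cond(F)
        if not np.isfinite(cond) or cond > 1e12:
            logger.warning("FisherInfo: ill-conditioned (cond=%.3g), using pinv", cond)
            return np.linalg.pinv(F)
        return np.linalg.inv(F)


def fisher_information(
    forward,
    theta: np.ndarray,
    jacobian: np.ndarray | None = None,
    fd_step: float = 1e-5,
) -> FisherInfo:
    """F_nn' = sum_m (dgbar_m/dtheta_n)(dgbar_m/dtheta_n')/gbar_m at theta.

    ``jacobian`` supplies analytic dgbar/dtheta (M, N) -- for an
    amplitudes-only model it is the system matrix itself.  Otherwise
    central finite differences with relative step ``fd_step`` are used.
    Bins with gbar = 0 are excluded (they carry no information about any
    parameter that leaves them at 0).
    """
    theta = np.asarray(theta, dtype=float)
    gbar = np.asarray(forward(theta), dtype=float)
    if jacobian is None:
        J = np.empty((gbar.shape[0], theta.shape[0]))
        for n in range(theta.shape[0]):
            step = fd_step * max(abs(theta[n]), 1.0)
            tp, tm = theta.copy(), theta.copy()
            tp[n] += step
            tm[n] -= step
            J[:, n] = (forward(tp) - forward(tm)) / (2 * step)
    else:
        J = np.asarray(jacobian, dtype=float)
    keep = gbar > 0
    Jk = J[keep]
    F = Jk.T @ (Jk / gbar[keep, None])
    F = 0.5 * (F + F.T)
    return FisherInfo(F)
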