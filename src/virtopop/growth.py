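"""Fisher-KPP reaction-diffusion tumor growth with spatially varying coefficients.

The model is

    dn/dt = div(D(x) grad n) + rho(x) n (1 - n / kappa(x)),    x in V,
    n(x, 0) = n0(x),        nu . grad n = 0 on the boundary,

with cell density n (cells/cm^2 in d=2), diffusivity D (cm^2/day), growth
rate rho (1/day) and carrying capacity kappa (cells/cm^2).  The solver is a
finite-difference method of lines: a conservative five-point stencil with
face-averaged D on a node-centered uniform grid (zero-flux Neumann
boundaries enter as vanishing boundary fluxes), integrated in time by an
adaptive embedded Runge-Kutta scheme.

Boundary nodes carry half-size control volumes, so the discrete mass
``sum_i w_i n_i`` with trapezoidal weights w is conserved exactly by the
diffusion operator; :func:`tumor_burden` uses the same weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from ._validation import InvalidParameterError, NumericalFailureError
from .fields import LumpField, synthesize

__all__ = [
    "SpaceGrid",
    "CoefficientSet",
    "CellDensityPath",
    "gaussian_initial_condition",
    "solve_rde",
    "tumor_burden",
    "integrated_log_kill",
]


@dataclass(frozen=True)
class SpaceGrid:
    """Node-centered uniform grid on an axis-aligned box (default [0,1]^2).

    ``nx`` nodes span the x side, so the spacing is side / (nx - 1).
    """

    nx: int
    ny: int
    box: tuple = ((0.0, 1.0), (0.0, 1.0))

    def __post_init__(self) -> None:
        if self.nx < 2 or self.ny < 2:
            raise InvalidParameterError("grid needs at least 2 nodes per axis")
        (x0, x1), (y0, y1) = self.box
        hx = (x1 - x0) / (self.nx - 1)
        hy = (y1 - y0) / (self.ny - 1)
        if not np.isclose(hx, hy):
            raise InvalidParameterError("grid spacing must be uniform (hx == hy)")

    @property
    def h(self) -> float:
        (x0, x1) = self.box[0]
        return (x1 - x0) / (self.nx - 1)

    @property
    def x(self) -> np.ndarray:
        x0, x1 = self.box[0]
        return np.linspace(x0, x1, self.nx)

    @property
    def y(self) -> np.ndarray:
        y0, y1 = self.box[1]
        return np.linspace(y0, y1, self.ny)

    def points(self) -> np.ndarray:
        """(nx, ny, 2) array of node coordinates (ij indexing)."""
        X, Y = np.meshgrid(self.x, self.y, indexing="ij")
        return np.stack([X, Y], axis=-1)

    def quad_weights(self) -> np.ndarray:
        """Trapezoidal quadrature weights, shape (nx, ny)."""
        wx = np.full(self.nx, self.h)
        wx[[0, -1]] = self.h / 2
        wy = np.full(self.ny, self.h)
        wy[[0, -1]] = self.h / 2
        return np.outer(wx, wy)

    def integrate(self, f: np.ndarray) -> float:
        return float(np.sum(self.quad_weights() * f))


def _as_grid_array(coef, grid: SpaceGrid, name: str) -> np.ndarray:
    if isinstance(coef, LumpField):
        return synthesize(coef, grid.points())
    arr = np.asarray(coef, dtype=float)
    if arr.ndim == 0:
        return np.full((grid.nx, grid.ny), float(arr))
    if arr.shape != (grid.nx, grid.ny):
        raise InvalidParameterError(f"{name} shape {arr.shape} does not match grid")
    return arr


@dataclass(frozen=True)
class CoefficientSet:
    """Admissible coefficient triple beta = (D, rho, kappa).

    Each entry is a LumpField, a scalar, or an (nx, ny) array.  Evaluated on
    a grid, D >= 0, rho >= 0 and kappa > 0 are enforced (membership in the
    admissible set that keeps the forward problem well-posed).
    """

    D: object
    rho: object
    kappa: object

    def on_grid(self, grid: SpaceGrid):
        D = _as_grid_array(self.D, grid, "D")
        rho = _as_grid_array(self.rho, grid, "rho")
        kappa = _as_grid_array(self.kappa, grid, "kappa")
        if np.any(D < 0):
            raise InvalidParameterError("D must be non-negative")
        if np.any(rho < 0):
            raise InvalidParameterError("rho must be non-negative")
        if np.any(kappa <= 0):
            raise InvalidParameterError("kappa must be strictly positive")
        return D, rho, kappa


@dataclass
class CellDensityPath:
    """Gridded density path n(x, t): values (nt, nx, ny) at increasing times."""

    values: np.ndarray
    times: np.ndarray
    grid: SpaceGrid
    clipped_nodes: int = 0  # negative undershoots zeroed across all outputs

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape[0] != self.times.shape[0]:
            raise InvalidParameterError("values and times lengths differ")

    def at_time(self, t: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.times - t)))
        if not np.isclose(self.times[idx], t):
            raise InvalidParameterError(f"time {t} not in the stored time vector")
        return self.values[idx]


def gaussian_initial_condition(
    grid: SpaceGrid,
    center=(0.5, 0.5),
    variance: float = 1e-4,
    total_cells: float = 5.0,
) -> np.ndarray:
    """Isotropic Gaussian seed n0(x) = A exp(-||x - x0||^2 / (2 sigma^2)).

    A = total_cells / (2 pi sigma^2), so the plane integral is exactly
    ``total_cells`` (5 cells by default, localized at the domain center).
    """
    if variance <= 0:
        raise InvalidParameterError("variance must be positive")
    if total_cells < 0:
        raise InvalidParameterError("total_cells must be non-negative")
    pts = grid.points()
    d2 = np.sum((pts - np.asarray(center, dtype=float)) ** 2, axis=-1)
    amplitude = total_cells / (2.0 * np.pi * variance)
    return amplitude * np.exp(-d2 / (2.0 * variance))


def _divergence_D_grad(n: np.ndarray, D: np.ndarray, h: float) -> np.ndarray:
    """Conservative div(D grad n) with zero-flux boundaries.

    Face diffusivities are arithmetic averages; boundary nodes divide their
    net flux by the half-size control volume.
    """
    out = np.zeros_like(n)
    # x-direction fluxes at interior faces: shape (nx-1, ny)
    Fx = 0.5 * (D[1:, :] + D[:-1, :]) * (n[1:, :] - n[:-1, :]) / h
    wx = np.full(n.shape[0], h)
    wx[[0, -1]] = h / 2
    out[1:-1, :] += (Fx[1:, :] - Fx[:-1, :]) / wx[1:-1, None]
    out[0, :] += Fx[0, :] / wx[0]
    out[-1, :] += -Fx[-1, :] / wx[-1]
    # y-direction
    Fy = 0.5 * (D[:, 1:] + D[:, :-1]) * (n[:, 1:] - n[:, :-1]) / h
    wy = np.full(n.shape[1], h)
    wy[[0, -1]] = h / 2
    out[:, 1:-1] += (Fy[:, 1:] - Fy[:, :-1]) / wy[None, 1:-1]
    out[:, 0] += Fy[:, 0] / wy[0]
    out[:, -1] += -Fy[:, -1] / wy[-1]
    return out


def solve_rde(
    coeffs: CoefficientSet,
    n0: np.ndarray,
    grid: SpaceGrid,
    t_eval,
    rtol: float = 1e-6,
    atol: float = 1e-3,
    method: str = "RK45",
) -> CellDensityPath:
    """Solve the Fisher-KPP RDE by the method of lines.

    ``t_eval`` is an increasing time vector starting at 0 (days).  Negative
    undershoots from time integration are clipped to zero in the stored
    outputs and counted on the returned path.
    """
    t_eval = np.asarray(t_eval, dtype=float)
    if t_eval.ndim != 1 or t_eval[0] != 0.0 or np.any(np.diff(t_eval) <= 0):
        raise InvalidParameterError("t_eval must increase strictly from 0")
    D, rho, kappa = coeffs.on_grid(grid)
    n0 = np.asarray(n0, dtype=float)
    if n0.shape != (grid.nx, grid.ny):
        raise InvalidParameterError("n0 shape does not match grid")
    if np.any(n0 < 0):
        raise InvalidParameterError("n0 must be non-negative")
    h = grid.h
    shape = n0.shape
    diffusive = bool(np.any(D > 0))
    reactive = bool(np.any(rho > 0))

    def rhs(t, y):
        n = y.reshape(shape)
        dn = np.zeros_like(n)
        if diffusive:
            dn += _divergence_D_grad(n, D, h)
        if reactive:
            dn += rho * n * (1.0 - n / kappa)
        return dn.ravel()

    if not diffusive and not reactive:
        values = np.repeat(n0[None], len(t_eval), axis=0)
        return CellDensityPath(values, t_eval, grid)

    sol = solve_ivp(
        rhs,
        (t_eval[0], t_eval[-1]),
        n0.ravel(),
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise NumericalFailureError(
            f"RDE integration failed: {sol.message}; "
            f"max |n| = {np.nanmax(np.abs(sol.y)):.3g}"
        )
    values = sol.y.T.reshape(len(t_eval), *shape)
    clipped = int(np.sum(values < 0))
    if clipped:
        values = np.clip(values, 0.0, None)
    return CellDensityPath(values, t_eval, grid, clipped_nodes=clipped)


def tumor_burden(path: CellDensityPath) -> np.ndarray:
    """Total cell count N(t) = integral_V n(x, t) dx per stored time."""
    w = path.grid.quad_weights()
    return np.tensordot(path.values, w, axes=([1, 2], [0, 1]))


def integrated_log_kill(
    path: CellDensityPath, n0: np.ndarray, mask: np.ndarray | None = None
) -> np.ndarray:
    """Integral of ln(n(x,t)/n0(x)) over the support where n0 > 0.

    A mass-action drug-effect metric: 0 when nothing changed, negative where
    cells were killed.  ``mask`` restricts the support further; nodes where
    n0 <= 0 are always excluded.  An empty support is an error.
    """
    n0 = np.asarray(n0, dtype=float)
    support = n0 > 0
    if mask is not None:
        support = support & np.asarray(mask, dtype=bool)
    if not np.any(support):
        raise InvalidParameterError("integrated_log_kill: empty support")
    w = path.grid.quad_weights() * support
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(support, path.values / n0, 1.0)
        logs = np.where(ratio > 0, np.log(np.where(ratio > 0, ratio, 1.0)), -np.inf)
    return np.tensordot(logs, w, axes=([1, 2], [0, 1]))
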