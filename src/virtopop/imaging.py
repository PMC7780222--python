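"""Binned-mode emission-tomography forward model with Gaussian blur.

A planar detector (intravital-microscopy style: optical or gamma images of
a thin, pseudo-2D activity distribution) sorts detected particles into M
spatial bins.  Bin m responds to emission at x through the sensitivity
function

    h_m(x) = A / (2 pi sigma_blur^2) * exp(-||x - x_m||^2 / (2 sigma_blur^2)),

i.e. gain A (detected particles per emitted unit, exposure time absorbed)
times a normalized Gaussian point-spread function.  The mean data are the
continuous-to-discrete linear operator

    gbar_m = integral_V h_m(x) f(x) dx,

and the measured counts are independent Poisson draws per bin.  Imaging is
treated as a snapshot of the activity at a single time point.

For activities that are themselves sums of Gaussian lumps the integral has
the closed form of a Gaussian-Gaussian convolution, used to assemble the
system matrix H whose columns are the mean images of unit-amplitude basis
lumps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._validation import InvalidParameterError
from .fields import LumpField, LumpLayout, synthesize, unpack
from .growth import SpaceGrid

__all__ = [
    "ImagingSystem",
    "SystemMatrix",
    "fwhm_from_variance",
    "forward_mean",
    "forward_mean_lumpy",
    "build_system_matrix",
    "sample_counts",
]

_FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


def fwhm_from_variance(blur_variance: float) -> float:
    """Full-width-half-max of a Gaussian PSF: 2 sqrt(2 ln 2) * sigma (cm)."""
    if blur_variance <= 0:
        raise InvalidParameterError("blur_variance must be positive")
    return _FWHM_FACTOR * np.sqrt(blur_variance)


@dataclass(frozen=True)
class ImagingSystem:
    """Detector-bin geometry, blur and gain of a planar binned-mode system.

    ``bins_x`` and ``bins_y`` are the 1D coordinates of the virtual pixel
    centers; the M = len(bins_x) * len(bins_y) bin centers are their tensor
    product (ij order, x fastest along rows).
    """

    bins_x: np.ndarray
    bins_y: np.ndarray
    blur_variance: float
    gain: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "bins_x", np.asarray(self.bins_x, dtype=float))
        object.__setattr__(self, "bins_y", np.asarray(self.bins_y, dtype=float))
        if self.bins_x.size < 1 or self.bins_y.size < 1:
            raise InvalidParameterError("need at least one detector bin")
        if self.blur_variance <= 0:
            raise InvalidParameterError("blur_variance must be positive")
        if self.gain <= 0:
            raise InvalidParameterError("gain must be positive")

    @classmethod
    def planar_grid(
        cls,
        n_bins: int = 64,
        blur_sigma: float = 0.021,
        gain: float = 1e-3,
        box=((0.0, 1.0), (0.0, 1.0)),
    ) -> "ImagingSystem":
        """Uniform n_bins x n_bins grid of bin centers covering the box."""
        (x0, x1), (y0, y1) = box
        bx = x0 + (np.arange(n_bins) + 0.5) * (x1 - x0) / n_bins
        by = y0 + (np.arange(n_bins) + 0.5) * (y1 - y0) / n_bins
        return cls(bx, by, blur_sigma**2, gain)

    @property
    def n_bins(self) -> int:
        return self.bins_x.size * self.bins_y.size

    @property
    def bin_centers(self) -> np.ndarray:
        """(M, 2) bin-center coordinates."""
        X, Y = np.meshgrid(self.bins_x, self.bins_y, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel()])

    @property
    def fwhm(self) -> float:
        return fwhm_from_variance(self.blur_variance)


def _blur_kernels(system: ImagingSystem, grid: SpaceGrid):
    """Separable 1D Gaussian factors Kx (mx, nx), Ky (my, ny) of h_m."""
    s2 = system.blur_variance
    kx = np.exp(-((system.bins_x[:, None] - grid.x[None, :]) ** 2) / (2 * s2))
    ky = np.exp(-((system.bins_y[:, None] - grid.y[None, :]) ** 2) / (2 * s2))
    return kx, ky


def forward_mean(system: ImagingSystem, f: np.ndarray, grid: SpaceGrid) -> np.ndarray:
    """Mean counts gbar = H f by quadrature of h_m * f on the grid.

    ``f`` is a non-negative (nx, ny) activity snapshot; the result is a
    length-M vector.  The separable Gaussian kernel keeps this at two small
    matrix products.
    """
    f = np.asarray(f, dtype=float)
    if f.shape != (grid.nx, grid.ny):
        raise InvalidParameterError("activity shape does not match grid")
    if np.any(f < 0):
        raise InvalidParameterError("activity must be non-negative")
    kx, ky = _blur_kernels(system, grid)
    pref = system.gain / (2.0 * np.pi * system.blur_variance)
    gbar = pref * (kx @ (grid.quad_weights() * f) @ ky.T)
    return gbar.ravel()


def _lumpy_closed_form(system: ImagingSystem, field: LumpField) -> np.ndarray:
    """Exact mean counts for a sum of Gaussian lumps.

    Gaussian-Gaussian convolution: a unit lump of variance s_l^2 at x_l
    contributes A * s_l^2/(s_l^2 + s_b^2) * exp(-||x_m - x_l||^2 /
    (2 (s_l^2 + s_b^2))) at bin m (integral taken over the whole plane;
    negligible truncation for interior lumps).
    """
    if field.n_lumps == 0:
        return np.zeros(system.n_bins)
    s_comb = field.lump_variance + system.blur_variance
    scale = system.gain * field.lump_variance / s_comb
    dx2 = (system.bins_x[:, None] - field.centers[None, :, 0]) ** 2
    dy2 = (system.bins_y[:, None] - field.centers[None, :, 1]) ** 2
    ex = np.exp(-dx2 / (2 * s_comb))  # (mx, L)
    ey = np.exp(-dy2 / (2 * s_comb))  # (my, L)
    # gbar(mx, my) = sum_l b_l scale ex[mx,l] ey[my,l]
    gbar = np.einsum("il,jl->ij", ex * (scale * field.amplitudes)[None, :], ey)
    return gbar.ravel()


def forward_mean_lumpy(
    system: ImagingSystem,
    field_or_theta,
    layout: LumpLayout | None = None,
    method: str = "analytic",
    grid: SpaceGrid | None = None,
) -> np.ndarray:
    """Mean counts of a lumpy activity, from a LumpField or a (theta, layout).

    ``method='analytic'`` uses the Gaussian-Gaussian closed form (exact up
    to boundary truncation); ``method='quadrature'`` synthesizes the field
    on ``grid`` and calls :func:`forward_mean` (validation path).
    """
    if isinstance(field_or_theta, LumpField):
        field = field_or_theta
    else:
        if layout is None:
            raise InvalidParameterError("theta requires a layout")
        field = unpack(field_or_theta, layout)
    if method == "analytic":
        return _lumpy_closed_form(system, field)
    if method == "quadrature":
        if grid is None:
            raise InvalidParameterError("quadrature method requires a grid")
        return forward_mean(system, synthesize(field, grid.points()), grid)
    raise InvalidParameterError(f"unknown method {method!r}")


@dataclass(frozen=True)
class SystemMatrix:
    """Discrete M x N operator whose column l is the mean image of basis lump l."""

    H: np.ndarray
    centers: np.ndarray
    lump_variance: float

    @property
    def column_sums(self) -> np.ndarray:
        """Sensitivities s_n = sum_m H_mn."""
        return self.H.sum(axis=0)

    def layout(self) -> LumpLayout:
        from .fields import amplitude_grid_layout

        return amplitude_grid_layout(self.centers, self.lump_variance)

    def __matmul__(self, theta: np.ndarray) -> np.ndarray:
        return self.H @ theta

    def adjoint(self, g: np.ndarray) -> np.ndarray:
        return self.H.T @ g


def build_system_matrix(
    system: ImagingSystem, centers: np.ndarray, lump_variance: float
) -> SystemMatrix:
    """Assemble H for an amplitudes-only lumpy basis via the closed form."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    if lump_variance <= 0:
        raise InvalidParameterError("lump_variance must be positive")
    s_comb = lump_variance + system.blur_variance
    scale = system.gain * lump_variance / s_comb
    ex = np.exp(
        -((system.bins_x[:, None] - centers[None, :, 0]) ** 2) / (2 * s_comb)
    )
    ey = np.exp(
        -((system.bins_y[:, None] - centers[None, :, 1]) ** 2) / (2 * s_comb)
    )
    # column l over the (mx, my) bin grid is an outer product ex[:,l] ey[:,l]
    H = scale * np.einsum("il,jl->ijl", ex, ey).reshape(-1, centers.shape[0])
    return SystemMatrix(H, centers, float(lump_variance))


def sample_counts(mean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Independent Poisson counts per bin given the mean data."""
    mean = np.asarray(mean, dtype=float)
    if np.any(mean < 0):
        raise InvalidParameterError("mean counts must be non-negative")
    return rng.poisson(mean)
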