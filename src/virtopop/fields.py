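"""Lumpy-type random fields used as reaction-diffusion coefficients.

A lumpy field is a finite sum of translated, isotropic, *unnormalized*
Gaussian "lumps",

    phi(x) = sum_l  b_l * exp(-||x - x_l||^2 / (2 sigma^2)),

a standard stochastic object model in image science for soft tissue with
smoothly varying characteristics.  Because the lump kernel and amplitudes
are non-negative and bounded and the number of lumps is finite, every
realization is non-negative and bounded -- which is exactly what admissible
diffusion / growth / carrying-capacity coefficients require.

Randomization follows the ``LB(L_bar, b0, sigma0^2)`` recipe: draw the lump
count L ~ Poisson(L_bar), place the L centers i.i.d. uniform in the domain
box V, and give every active lump the common amplitude b0 and width
sigma0^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._validation import InvalidParameterError

__all__ = [
    "LumpField",
    "LumpPrior",
    "LumpLayout",
    "synthesize",
    "sample_lump_field",
    "pack",
    "unpack",
]


@dataclass(frozen=True)
class LumpField:
    """One realization of a lumpy field: centers, amplitudes, shared width.

    Parameters
    ----------
    centers : (L, d) array of lump centers, cm.
    amplitudes : (L,) array of non-negative lump amplitudes (field units).
    lump_variance : shared isotropic lump variance sigma^2, cm^2.
    max_lumps : capacity of the parameterization (L <= max_lumps).
    """

    centers: np.ndarray
    amplitudes: np.ndarray
    lump_variance: float
    max_lumps: int

    def __post_init__(self) -> None:
        centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        if centers.size == 0:
            centers = centers.reshape(0, 2)
        amplitudes = np.asarray(self.amplitudes, dtype=float).ravel()
        object.__setattr__(self, "centers", centers)
        object.__setattr__(self, "amplitudes", amplitudes)
        if centers.shape[0] != amplitudes.shape[0]:
            raise InvalidParameterError(
                f"{centers.shape[0]} centers but {amplitudes.shape[0]} amplitudes"
            )
        if self.lump_variance <= 0:
            raise InvalidParameterError("lump_variance must be positive")
        if np.any(amplitudes < 0):
            raise InvalidParameterError("amplitudes must be non-negative")
        if centers.shape[0] > self.max_lumps:
            raise InvalidParameterError(
                f"{centers.shape[0]} lumps exceed max_lumps={self.max_lumps}"
            )

    @property
    def n_lumps(self) -> int:
        return self.centers.shape[0]

    @property
    def ndim(self) -> int:
        return self.centers.shape[1] if self.n_lumps else 2

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return synthesize(self, points)


def synthesize(field: LumpField, points: np.ndarray) -> np.ndarray:
    """Evaluate a lumpy field at the given points.

    ``points`` has shape (..., d); the result has shape (...,).  The value
    at x is ``sum_l b_l exp(-||x - x_l||^2 / (2 sigma^2))`` -- an empty sum
    (zero lumps) is identically zero.
    """
    pts = np.asarray(points, dtype=float)
    out_shape = pts.shape[:-1]
    if field.n_lumps == 0:
        return np.zeros(out_shape)
    flat = pts.reshape(-1, pts.shape[-1])
    # (P, L) squared distances; fields have few lumps so this stays small.
    d2 = np.sum((flat[:, None, :] - field.centers[None, :, :]) ** 2, axis=-1)
    vals = np.exp(-d2 / (2.0 * field.lump_variance)) @ field.amplitudes
    return vals.reshape(out_shape)


@dataclass(frozen=True)
class LumpPrior:
    """Hyperparameters LB(L_bar, b0, sigma0^2) of a lumpy random field.

    ``domain`` is the axis-aligned box V as ((x_lo, x_hi), (y_lo, y_hi)).
    """

    mean_lumps: float
    amplitude: float
    lump_variance: float
    domain: tuple = ((0.0, 1.0), (0.0, 1.0))
    max_lumps: int | None = None

    def __post_init__(self) -> None:
        if self.mean_lumps <= 0:
            raise InvalidParameterError("mean_lumps must be positive")
        if self.amplitude < 0:
            raise InvalidParameterError("amplitude must be non-negative")
        if self.lump_variance <= 0:
            raise InvalidParameterError("lump_variance must be positive")
        for lo, hi in self.domain:
            if not hi > lo:
                raise InvalidParameterError("domain box must have positive extent")

    @property
    def capacity(self) -> int:
        """Effective max_lumps: max(10 * L_bar, 200) unless set explicitly."""
        if self.max_lumps is not None:
            return self.max_lumps
        return int(max(10 * self.mean_lumps, 200))

    @property
    def volume(self) -> float:
        return float(np.prod([hi - lo for lo, hi in self.domain]))

    def mean_field_value(self) -> float:
        """Campbell mean of the field at a domain-interior point (d=2):
        L_bar * b0 * 2 pi sigma0^2 / |V|."""
        return (
            self.mean_lumps
            * self.amplitude
            * 2.0
            * np.pi
            * self.lump_variance
            / self.volume
        )


def sample_lump_field(prior: LumpPrior, rng: np.random.Generator) -> LumpField:
    """Draw one LB(L_bar, b0, sigma0^2) realization.

    L ~ Poisson(L_bar) truncated at the prior's capacity; centers i.i.d.
    uniform in V; all amplitudes equal b0.
    """
    cap = prior.capacity
    n = int(min(rng.poisson(prior.mean_lumps), cap))
    lows = np.array([lo for lo, _ in prior.domain])
    highs = np.array([hi for _, hi in prior.domain])
    centers = rng.uniform(lows, highs, size=(n, len(prior.domain)))
    amplitudes = np.full(n, prior.amplitude)
    return LumpField(centers, amplitudes, prior.lump_variance, cap)


@dataclass(frozen=True)
class LumpLayout:
    """Which blocks of a lump parameterization are free in the flat vector θ.

    The flat layout is ``[per-lump amplitudes?][centers?][shared
    amplitude?][shared width?]`` with

    * per-lump amplitudes when ``free_amplitudes`` (length L), or one shared
      amplitude when ``shared_amplitude``;
    * per-lump centers when ``free_centers`` (length d*L, row-major);
    * one shared variance when ``free_width``.

    Frozen blocks take their values from ``fixed_centers`` /
    ``fixed_variance`` / ``fixed_amplitude``.  Inactive lumps are encoded
    with amplitude 0, so θ always describes exactly ``max_lumps`` slots.
    """

    max_lumps: int
    ndim: int = 2
    free_amplitudes: bool = True
    shared_amplitude: bool = False
    free_centers: bool = False
    free_width: bool = False
    fixed_centers: np.ndarray | None = None
    fixed_variance: float | None = None
    fixed_amplitude: float | None = None

    def __post_init__(self) -> None:
        if self.free_amplitudes and self.shared_amplitude:
            raise InvalidParameterError(
                "amplitudes are either per-lump free or shared, not both"
            )
        if not self.free_centers:
            if self.fixed_centers is None:
                raise InvalidParameterError("frozen centers need fixed_centers")
            fc = np.atleast_2d(np.asarray(self.fixed_centers, dtype=float))
            if fc.shape != (self.max_lumps, self.ndim):
                raise InvalidParameterError(
                    f"fixed_centers shape {fc.shape} != ({self.max_lumps}, {self.ndim})"
                )
            object.__setattr__(self, "fixed_centers", fc)
        if not self.free_width and self.fixed_variance is None:
            raise InvalidParameterError("frozen width needs fixed_variance")
        if not (self.free_amplitudes or self.shared_amplitude) and (
            self.fixed_amplitude is None
        ):
            raise InvalidParameterError("frozen amplitudes need fixed_amplitude")

    @property
    def size(self) -> int:
        n = 0
        if self.free_amplitudes:
            n += self.max_lumps
        elif self.shared_amplitude:
            n += 1
        if self.free_centers:
            n += self.ndim * self.max_lumps
        if self.free_width:
            n += 1
        return n

    def _blocks(self):
        """Start indices of (amplitudes, centers, width) blocks, None if frozen.

        Order: per-lump amplitudes, then centers, then shared amplitude,
        then shared width -- so the free-center layout reads
        [x_1 ... x_Lmax, b, sigma^2].
        """
        i = 0
        amp = cen = wid = None
        if self.free_amplitudes:
            amp = (i, i + self.max_lumps)
            i += self.max_lumps
        if self.free_centers:
            cen = (i, i + self.ndim * self.max_lumps)
            i += self.ndim * self.max_lumps
        if self.shared_amplitude:
            amp = (i, i + 1)
            i += 1
        if self.free_width:
            wid = (i, i + 1)
            i += 1
        return amp, cen, wid


def amplitude_grid_layout(centers: np.ndarray, lump_variance: float) -> LumpLayout:
    """Amplitudes-only layout over a fixed center grid (linear synthesis)."""
    centers = np.atleast_2d(np.asarray(centers, dtype=float))
    return LumpLayout(
        max_lumps=centers.shape[0],
        ndim=centers.shape[1],
        free_amplitudes=True,
        fixed_centers=centers,
        fixed_variance=lump_variance,
    )


def free_center_layout(max_lumps: int, ndim: int = 2) -> LumpLayout:
    """Free centers with one shared amplitude and shared width:
    θ = [x_1 ... x_Lmax, b, sigma^2], length ndim*Lmax + 2."""
    return LumpLayout(
        max_lumps=max_lumps,
        ndim=ndim,
        free_amplitudes=False,
        shared_amplitude=True,
        free_centers=True,
        free_width=True,
    )


def pack(field: LumpField, layout: LumpLayout) -> np.ndarray:
    """Flatten a LumpField into θ for the given layout.

    Fields with fewer than ``max_lumps`` lumps are padded with amplitude-0
    lumps (centers of padded slots are arbitrary; the fixed grid is used
    when centers are frozen, the domain origin otherwise).
    """
    L = layout.max_lumps
    if field.n_lumps > L:
        raise InvalidParameterError("field has more lumps than the layout allows")
    theta = np.zeros(layout.size)
    amp, cen, wid = layout._blocks()
    amps = np.zeros(L)
    amps[: field.n_lumps] = field.amplitudes
    centers = np.zeros((L, layout.ndim))
    centers[: field.n_lumps] = field.centers
    if field.n_lumps < L and not layout.free_centers:
        centers[field.n_lumps :] = layout.fixed_centers[field.n_lumps :]
    if amp is not None:
        if layout.free_amplitudes:
            theta[amp[0] : amp[1]] = amps
        else:  # shared amplitude: use the common value
            nonzero = amps[amps > 0]
            theta[amp[0]] = nonzero[0] if nonzero.size else 0.0
    if cen is not None:
        theta[cen[0] : cen[1]] = centers.ravel()
    if wid is not None:
        theta[wid[0]] = field.lump_variance
    return theta


def unpack(theta: np.ndarray, layout: LumpLayout) -> LumpField:
    """Rebuild a LumpField from θ; inverse of :func:`pack` for its layout."""
    theta = np.asarray(theta, dtype=float).ravel()
    if theta.shape[0] != layout.size:
        raise InvalidParameterError(
            f"theta length {theta.shape[0]} != layout size {layout.size}"
        )
    L = layout.max_lumps
    amp, cen, wid = layout._blocks()
    if layout.free_amplitudes:
        amps = theta[amp[0] : amp[1]].copy()
    elif layout.shared_amplitude:
        amps = np.full(L, theta[amp[0]])
    else:
        amps = np.full(L, layout.fixed_amplitude)
    if layout.free_centers:
        centers = theta[cen[0] : cen[1]].reshape(L, layout.ndim).copy()
    else:
        centers = layout.fixed_centers.copy()
    variance = theta[wid[0]] if layout.free_width else layout.fixed_variance
    return LumpField(centers, amps, float(variance), L)
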