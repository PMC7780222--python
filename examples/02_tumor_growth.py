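"""Grow one virtual tumor: Fisher-KPP dynamics with lumpy coefficients.

Five tumor cells seeded at the domain center grow and spread under a
spatially heterogeneous diffusivity D(x), growth rate rho(x) and carrying
capacity kappa(x), each drawn from its lumpy prior.  The tumor burden
N(t) = integral of n(x,t) is the scalar readout.
"""

import numpy as np

import virtopop as vp

rng = np.random.default_rng(7)
grid = vp.SpaceGrid(65, 65)

coeffs = vp.CoefficientSet(
    D=vp.sample_lump_field(vp.LumpPrior(20, 1e-7, 0.04), rng),
    rho=vp.sample_lump_field(vp.LumpPrior(200, 0.25, 0.002), rng),
    kappa=vp.sample_lump_field(vp.LumpPrior(100, 5e7, 0.1), rng),
)
n0 = vp.gaussian_initial_condition(grid)  # 5 cells, sigma^2 = 1e-4 cm^2
print(f"initial burden: {grid.integrate(n0):.3f} cells")

times = np.arange(0.0, 366.0, 73.0)
path = vp.solve_rde(coeffs, n0, grid, times, rtol=1e-5)
for t, N in zip(path.times, vp.tumor_burden(path)):
    print(f"  day {t:5.0f}:  N = {N:.3e} cells")
# growth is initially exponential at the local rho, then saturates toward
# the local carrying capacity as the colonized area expands.
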