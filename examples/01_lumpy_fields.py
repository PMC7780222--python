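"""Sample lumpy random fields and check their first-moment statistics.

A lumpy field LB(L_bar, b0, sigma0^2) is a Poisson(L_bar) number of
Gaussian bumps of amplitude b0 and variance sigma0^2, dropped uniformly in
the unit square.  At an interior point the ensemble mean has the Campbell
closed form L_bar * b0 * 2 pi sigma0^2 / |V|.
"""

import numpy as np

import virtopop as vp

rng = np.random.default_rng(0)

# the diffusivity prior used in the growth experiments
prior = vp.LumpPrior(mean_lumps=20, amplitude=1e-7, lump_variance=0.04)

field = vp.sample_lump_field(prior, rng)
grid = vp.SpaceGrid(65, 65)
values = vp.synthesize(field, grid.points())
print(f"one realization: {field.n_lumps} lumps, "
      f"field range [{values.min():.3g}, {values.max():.3g}] cm^2/day")

draws = [vp.synthesize(vp.sample_lump_field(prior, rng), np.array([0.5, 0.5]))
         for _ in range(5000)]
print(f"Monte-Carlo mean at the domain center: {np.mean(draws):.4g}")
print(f"Campbell closed form:                  {prior.mean_field_value():.4g}")
# the two should agree to a few percent: the field's mean level is set
# entirely by (L_bar, b0, sigma0^2), which is what population calibration
# tries to recover from noisy images.
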