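"""Posterior uncertainty in the imaged density via Metropolis-Hastings.

Starting the chain at the MLEM estimate (the MAP for a flat prior), each
step perturbs the amplitudes of 3 randomly chosen lumps with a Gaussian of
sd 1e4 under an i.i.d. uniform [0, 1e10] prior, and accepts by the
Metropolis rule.  The acceptance rate and the spread of the implied
burden are the readouts.
"""

import numpy as np

import virtopop as vp
from virtopop.experiments import (
    ExperimentConfig, image_density, make_ground_truth,
    reconstruct_density, sample_density_posterior,
)
from virtopop.fields import synthesize, unpack

cfg = ExperimentConfig(grid_n=65, mlem_iterations=1000, mcmc_steps=512)
rng = np.random.default_rng(3)

_, path = make_ground_truth(cfg, rng)
system, _, g = image_density(cfg, path, rng)
mle, matrix, layout = reconstruct_density(cfg, system, g)
chain = sample_density_posterior(cfg, matrix, g, mle.theta, rng)
print(f"acceptance rate: {chain.acceptance_rate:.3f} over {cfg.mcmc_steps} proposals")

grid = path.grid
burdens = [grid.integrate(synthesize(unpack(s, layout), grid.points()))
           for s in chain.samples[::64]]
print(f"posterior burden samples: mean {np.mean(burdens):.3e}, "
      f"sd {np.std(burdens, ddof=1):.3e} cells")
# the posterior sd quantifies how much the Poisson noise in a single image
# leaves the day-100 burden uncertain.
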