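"""Patient-specific virtual population from a reconstructed tumor.

The MLEM estimate of the day-100 density becomes the initial condition;
the unmeasured coefficients D, rho, kappa are randomized from their lumpy
priors; J forward solves propagate that uncertainty into the tumor-burden
trajectory N(t).
"""

import numpy as np

import virtopop as vp
from virtopop.experiments import ExperimentConfig, image_density, make_ground_truth, reconstruct_density
from virtopop.fields import synthesize, unpack

cfg = ExperimentConfig(grid_n=65, mlem_iterations=1000, t_end=200.0)
rng = np.random.default_rng(5)

_, truth_path = make_ground_truth(cfg, rng)
system, _, g = image_density(cfg, truth_path, rng)
mle, matrix, layout = reconstruct_density(cfg, system, g)
n_hat = synthesize(unpack(mle.theta, layout), cfg.grid().points())

vpp = vp.generate_vpp(
    n_hat, cfg.grid(), cfg.prediction_times(), 16, rng,
    D_prior=cfg.D_prior, rho_prior=cfg.rho_prior, kappa_prior=cfg.kappa_prior,
    rtol=1e-5,
)
mean, sd = vp.ensemble_summary(vpp.burden_matrix())
truth_N = vp.tumor_burden(truth_path)
days = cfg.t0 + vpp.times
for k in range(0, len(days), 4):
    t = days[k]
    true_here = truth_N[np.isclose(truth_path.times, t)]
    truth_str = f"{true_here[0]:.2e}" if true_here.size else "   --  "
    print(f"  day {t:5.0f}:  VPP mean {mean[k]:.2e} +- {sd[k]:.2e}   truth {truth_str}")
# the +-1 sd band is the uncertainty a clinician would have to accept when
# predicting this patient's burden from one noisy image.
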