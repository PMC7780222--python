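# Methods

## Growth model

The forward model is the Fisher-KPP reaction–diffusion equation for a 2D
cell density n(x, t) ≥ 0 on V = [0,1]² cm with zero-flux (Neumann)
boundaries. The 2D setting models thin-slab preparations (window-chamber
style intravital imaging) rather than bulk tissue. The coefficients
β = (D, ρ, κ) are time-independent scalar fields; admissibility (D ≥ 0,
ρ ≥ 0, κ > 0, all bounded) is enforced at construction so every solve is
well-posed. The printed units throughout are cm and days; κ and n are
per-area densities in d = 2.

The initial condition is an isotropic Gaussian with total mass
`total_cells` (default 5), center (0.5, 0.5) and variance 1e-4 cm²
(σ = 100 μm): a well-localized seed colony. Note a structural property of
an analytic Gaussian seed: its tails are positive everywhere above the
floating-point floor, so under a positive growth rate distant tissue is
eventually colonized by *local* logistic growth of the tail, independent
of D. With the default priors this tail-driven expansion alone reaches
r ≈ 0.2 cm by day 365 and is a major contributor to the year-one burden
(see "Scales" below).

## Coefficient randomization

Each coefficient is a lumpy random field LB(L̄, b₀, σ₀²): L ~ Poisson(L̄)
unnormalized Gaussian lumps of common amplitude b₀ and variance σ₀²,
centers i.i.d. uniform in V. Realizations are non-negative and bounded by
L·b₀, which is exactly what admissibility requires. Defaults (used for
ground truths and for randomizing unmeasured coefficients):

| field | prior | Campbell mean L̄b₀2πσ₀²/\|V\| |
|---|---|---|
| D | LB(20, 1e-7 cm²/day, 0.04 cm²) | 5.0e-7 cm²/day |
| ρ | LB(200, 0.25 day⁻¹, 0.002 cm²) | 0.63 day⁻¹ |
| κ | LB(100, 5e7 cells/cm², 0.1 cm²) | 3.1e9 cells/cm² |

Poisson draws beyond the capacity max(10 L̄, 200) are truncated (draws
that large essentially never occur at the default rates); lump centers may
fall arbitrarily close to the boundary, with no reflection or wrapping.
All randomness flows through one explicit `numpy.random.Generator`; no
global state is touched, so populations are bitwise reproducible from
their recorded seeds.

Flat parameter layouts connect lump fields to estimators: an
amplitudes-only layout over a fixed center grid (linear synthesis, used by
MLEM), and a free-center layout θ = [x₁ … x_L, b, σ²] with shared
amplitude and width (nonlinear, used for the growth-field MLE). Inactive
lumps are encoded as zero amplitudes.

## Discretization

Space: node-centered uniform grid (default 128×128; tests and the
scaled-down acceptance runs use 65×65, chosen to keep a full
population-of-16 solve around ten seconds while staying within ~10% of
the refined burden). The diffusion operator is the conservative five-point
stencil with arithmetic face-averaged D; boundary nodes carry half-size
control volumes. The discrete invariant of this operator is the
trapezoidal-weight mass, and the same trapezoid rule is used for all
domain integrals (burden, imaging quadrature), so pure-diffusion runs
conserve the reported burden to rounding. Sharp masks (integrated
log-kill supports) incur the usual O(h) quadrature error.

Time: `scipy.integrate.solve_ivp` RK45 with rtol = 1e-6 (1e-5 in
scaled-down runs), atol = 1e-3 cells/cm². The dynamics are non-stiff at
the default scales (diffusion CFL ≫ reaction time scale). Negative
undershoots in stored outputs are clipped to zero and counted on the
returned path. Note that with D of order 1e-7 cm²/day the traveling-front
width √(D/ρ) ≈ 10 μm is below any practical grid resolution; the discrete
front then propagates somewhat faster than the continuum speed 2√(Dρ)
(observed ~15% burden drop from 65² to 193²), which is inherent to
under-resolved Fisher fronts rather than to this implementation.

## Imaging

Binned-mode planar emission tomography with Gaussian sensitivity
functions: gain A times a normalized PSF of variance σ²_blur. Imaging is
a snapshot of the activity at the imaging day; the exposure-time integral
is absorbed into A. Detector bins are a uniform 64×64 grid of virtual
pixel centers covering V (the bin count is a design choice; the chain
acceptance statistics depend on it through the per-lump sensitivities).
Channels:

* density channel: σ_blur = 0.021 cm (FWHM 494.5 μm ≈ 500 μm),
  A = 1e-3 detected photons per cell;
* growth channel: σ_blur = 0.0425 cm (FWHM 1.0008 mm ≈ 1 mm),
  A = 1e3 detected photons per unit growth rate — the growth-channel gain
  is a package choice, set so per-bin means are O(10²–10³), comparable
  statistical quality to the density channel.

For lumpy activities the bin means have the exact Gaussian–Gaussian
convolution form A b σ_l²/(σ_l²+σ²_blur) exp(−‖x_m−x_l‖²/2(σ_l²+σ²_blur)),
used for system-matrix assembly and nonlinear forward models and verified
against grid quadrature to 1e-6 relative. Counts are independent Poisson
draws per bin.

## Estimation

The Poisson log-likelihood drops the θ-independent term; 0·ln 0 := 0, and
a zero model mean on a bin with counts returns a −∞ sentinel.

**MLEM** runs a fixed number of multiplicative updates (default 5000, no
early stopping; the per-iteration likelihood trace is stored so users can
truncate). Zero-sensitivity columns are frozen; zero denominators are
floored at the smallest positive double with a logged warning. Iterates
stay non-negative and the trace is non-decreasing (asserted in tests).
The default initial guess for the reconstruction pipeline is the
back-projection Hᵀg; MLEM's multiplicative update corrects its scale
within the first iterations.

**Nonlinear MLE** (free lump centers, shared amplitude/width) minimizes
−ℓ with L-BFGS-B inside box bounds (centers in [0,1]², b > 0,
σ² ∈ (0, 0.1]), finite-difference gradients, and 3 multiplicative-perturbation
multi-starts (relative scale 0.05) to hedge against non-convexity; the
best likelihood wins and a non-converged optimizer still returns its best
iterate, flagged.

**Fisher information** uses F = Jᵀ diag(1/ḡ) J with the analytic Jacobian
for amplitude parameters and central differences (relative step 1e-5) for
centers/widths; bins with ḡ = 0 are excluded; F⁻¹ falls back to the
pseudo-inverse above condition number 1e12, with a warning.

**Metropolis–Hastings** proposals redraw a uniformly chosen subset of
`lumps_per_proposal` lumps without replacement and perturb their free
blocks with independent Gaussians; shared blocks are perturbed once when
any lump is selected. The kernel is symmetric, so the acceptance ratio is
the plain posterior ratio. Support violations (negative amplitudes,
out-of-domain centers) are handled by prior rejection, not reflection.
Chains started at the MLE (the MAP under the uniform prior) use no
burn-in by default; `burn_in` is a config option. No thinning; full
chains are stored. The Experiment-1 chain uses 512 steps, 3 lumps per
proposal, amplitude sd 1e4, i.i.d. uniform [0, 1e10] amplitude prior.
MLE amplitudes above the prior ceiling are clipped to it before starting
(the start must lie in the support).

## Virtual populations and calibration

A population member is a coefficient triple (fixed where estimated,
drawn from its prior where not), an initial density (shared MLEM estimate
or a distinct posterior sample per member), and one forward solve; its
seed is recorded. A failed member solve is flagged and excluded from
summaries without sinking the population. Ensemble summaries are
pointwise means and ±1 sample sd (J−1 denominator).

The population marginal likelihood is evaluated in log space with
log-sum-exp; Monte-Carlo field draws are fresh per image by default (a
shared-draws mode exists). Grid-search calibration scores every candidate
with an identically seeded generator (common random numbers), so MC noise
largely cancels in comparisons; ties go to the first maximum. Gradient-based
hyperparameter optimization is out of scope — the marginal-likelihood
surface is noisy, badly scaled and non-convex, and the grid search is the
honest baseline.

## Scales the package actually produces

Computed by the test suite and `scripts/acceptance.py` at the default
settings: the default initial condition integrates to 5.000 cells; the
two blur widths imply 500 μm and 1 mm FWHM after rounding; a J = 16
population under the default priors has mean N(365) ≈ 1.7e9 cells (the
Campbell-mean carrying capacity ~3.1e9 cells/cm² times the colonized
area, roughly half the domain by year one — tail-driven colonization plus
front propagation); the Experiment-1 chain acceptance rate is ~0.40 on
average, varying roughly 0.2–0.55 with the particular ground-truth draw
(the rate mixes near-certain acceptance of lumps under the tumor with
strong rejection of lumps over empty bins, so it is sensitive to how much
of the reconstruction box the tumor covers, and to the bin count).

## What the generator does and does not emulate

The synthetic data cover: spatial heterogeneity of growth parameters with
controllable statistics, Poisson counting noise, finite detector
resolution, and single-snapshot observation. They do not cover: model
mismatch (every virtual patient is exactly Fisher-KPP with lumpy
coefficients), attenuation/scatter/depth effects, detector dead-time or
reconstruction-induced noise correlations, 3D geometry, treatment
effects, or real biological variability beyond the lumpy family. Passing
tests therefore validate the inference machinery under a well-specified
model, not clinical performance.

## Known limitations

* Single-time-point density data cannot identify D and κ (and ρ, if
  unmeasured); the package deliberately randomizes rather than estimates
  them, so patient-specific predictions inherit the full prior spread of
  those fields.
* The MLEM basis (narrow lumps on a 25×25 grid) has a nontrivial null
  space; reconstructions show checkerboard artifacts that barely affect
  the burden but make individual amplitudes non-identifiable.
* The amplitude-chain proposal is isotropic; with 625 correlated
  amplitudes mixing is slow in null-space directions, so posterior burden
  spreads from short chains are lower bounds on the true posterior
  spread.
* Under-resolved reaction fronts propagate at a grid-dependent speed
  (see Discretization); burden magnitudes at late times carry O(10%)
  grid sensitivity.
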