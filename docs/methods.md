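# Methods

`movetarget` builds continuous-time movement models that are *consistent by
construction* with a parametric utilisation distribution: the same
selection coefficients describe both the short-term dynamics and the
long-run density of locations.  This note records the models, the
numerical choices, and what the test suite does and does not demonstrate.

## Targets

The utilisation distribution is log-linear in spatial covariates,

    log pi(x) = sum_k beta_k c_k(x) + const,

with the constant fixed at zero throughout: every consumer (drifts, event
rates, switching generators, likelihoods) uses only differences and
gradients of `log pi`, so normalising constants never need to be known.
Built-in covariate families: Laplace-shaped `tau exp(-|x-mu|/(2 tau))`
(peak height `tau`, gradient magnitude bounded by 1/2), the bimodal
min-Laplace `exp(-min(|x-mu_A|, |x-mu_B|)/(2 tau))` (equal unit peaks),
Gaussian bumps, and a quadratic covariate (giving Gaussian targets and
linear drifts).  Separable targets (normal, logistic, logistic-mixture
axes) carry analytic per-axis CDFs for diagnostics.  Covariate kinks
(Laplace centre, min-Laplace mid-line) report a zero gradient exactly at
the kink; the kink set has measure zero and simulated paths never evaluate
there in practice.

Some covariate-based targets are *improper on the whole plane*: the
min-Laplace selection density `exp(beta c_1(x))` tends to `exp(0) = 1` at
infinity.  Wherever such a target is normalised (diagnostics, the
interaction model), the quadrature window is the modelled domain, and
simulators that need an exact stationary law on that domain reflect at the
window boundary (see below).  For strongly selective targets (e.g. the
two-state example, whose conditional densities fall by `e^-20` within a
few home-range widths) the truncation is numerically irrelevant.

A discrete-time companion, the two-stage "local Gibbs" move, is included:
draw a latent point `z` from a symmetric homogeneous kernel around the
current location, then draw the next location from `psi(.|z) pi(.)`.  The
second stage is sampled exactly by rejection against a safety-inflated
grid maximum of `pi` over the kernel support (factor 1.2, 61 grid points
per axis, capped at 1e5 attempts).

## Targeted diffusions

* **Langevin**: `dx = (gamma/2) grad log pi dt + sqrt(gamma) dW`.  `gamma`
  (units: area/time) sets the speed of movement and cancels from the
  stationary law.
* **Kinetic (underdamped) Langevin**: position–velocity dynamics with
  friction `alpha/gamma` and velocity noise `sqrt(alpha)`; stationary
  velocity is `Normal(0, (gamma/2) I)` independent of position.  `gamma`
  controls speed, `alpha` smoothness.
* **Position-dependent rate**: diffusion rate
  `tau(x) = exp(delta_0 + sum_k delta_k c_k(x))` with drift
  `(1/2)(grad tau - tau grad U)`.  The default `delta_k = -beta_k` makes
  `tau = alpha^2 / pi`, the drift cancels, and the animal realises its
  utilisation distribution purely by moving faster in poor habitat.
* **Polar (speed/bearing)**: `dx = s cos(theta) dt, dy = s sin(theta) dt`;
  the speed follows a 1-D Langevin SDE targeting Rayleigh(sigma) — its
  drift uses `s/sigma^2 - 1/s`, the *derivative* of the Rayleigh
  potential, which is the only reading that makes Rayleigh(sigma) the
  stationary speed law — and the bearing drifts by the negative
  perpendicular dot product of velocity and `grad U` with diffusivity
  `alpha_theta` (the knob controlling sinuosity).  Bearings are stored
  wrapped to `(-pi, pi]`; the orthogonal rotation convention is +90
  degrees.  Speed is reflected at a floor of `1e-6 sigma`: the `1/s` term
  repels from zero in the continuum, but a discrete step can cross it, and
  reflection keeps the discretised chain ergodic without changing the
  model.
* **Generic builder**: any diffusion targeting `exp(-H(z))` can be written
  with drift `-(D(z)+Q(z)) grad H + Gamma(z)` and noise `sqrt(2 D)`, with
  `D` positive semi-definite (reversible part), `Q` skew-symmetric
  (irreversible part) and `Gamma_i = sum_j d(D_ij+Q_ij)/dz_j`.  The named
  models above are special cases, and the builder is cross-checked against
  them to 1e-10 in the tests.  `Gamma` falls back to central differences
  (step 1e-5) when not supplied analytically.

### Integrators

`simulate_em` is fixed-step Euler–Maruyama: `state' = state + drift dt +
noise sqrt(dt) xi`, deterministic given one seed, no adaptive stepping
(reproducibility over efficiency).  Two situations need more care:

* The inverse-density diffusion's noise grows super-linearly in the tails
  (like `1/sqrt(pi)`), where explicit Euler schemes are divergent.
  `position_dependent_spec(..., reflect=(lo, hi))` imposes no-flux
  (elastic) boundaries; the family is reversible, so reflection preserves
  exactly the window-truncated target.  The reference configuration
  reflects a standard normal target at ±4 (truncated mass ~6e-5) and uses
  dt = 0.001, at which the residual discretisation bias is below what a
  KS test at n = 2000 can see.
* For the **kinetic** model, explicit Euler pumps energy when the force is
  stiff relative to the step: at `gamma = 5, alpha = 1` it inflates the
  stationary position variance by ~30% at dt = 0.02, and the kinks of
  Laplace-covariate targets keep the bias large even at dt = 0.005.
  `simulate_baoab` therefore implements the standard BAOAB splitting
  (half-kick, half-drift, *exact* Ornstein–Uhlenbeck velocity update,
  half-drift, half-kick), whose invariant-measure error is O(dt^2) and
  which is robust at kinks; long runs on the two-state conditional target
  reproduce the quadrature variance within Monte-Carlo error at dt = 0.02.
  Kinetic specs carry the structure BAOAB needs; the switching and
  interaction simulators use it automatically ("auto"), and plain
  Euler–Maruyama remains available and is what all first-order and polar
  models use.

## Velocity-jump (piecewise deterministic) models

Straight-line motion punctuated by velocity jumps.  Three event types:

* **Bounces** at the canonical rate `max{0, grad U . v}`: BPS (exact
  reflection of the gradient-parallel component), GBPS (parallel
  reflection plus fresh Gaussian orthogonal part), and the **half-space
  bounce**, where the new parallel speed is `Rice(rho s_1,
  sigma sqrt(1-rho^2))` pointing against the gradient and the orthogonal
  coefficient updates autoregressively with coefficient `omega`; the
  post-bounce support is the entire half-plane of velocities whose
  gradient component has flipped sign.  `rho = omega = 1` recovers the
  BPS, `rho = 1, omega = 0` the GBPS; full half-space support requires the
  open ranges.  The Rice noncentrality is taken as the magnitude
  `rho s_1`, with the sign carried by the reflected direction (Rice is
  defined for non-negative noncentrality; this is exactly the correlated
  bivariate-Rayleigh conditional).
* **Reorientations** at the smooth rate `s ||grad U|| (1 + h cos theta)`,
  `theta` the bearing *relative to the gradient direction* at the event
  (the frame conversion lives inside the sampler).  The new bearing has
  density `(1 + a cos th' + b cos(th' - th))/(2 pi)`, sampled by rejection
  from a uniform envelope; speed and bearing update independently.
  Consistency with the target forces `h - a - b h/2 = 1`, positivity
  `|h| <= 1`, `|a| + |b| <= 1`; the five tabulated extremal rows are
  shipped as `TABLE1` and the balance identity
  `kappa(th) - int kappa(th') q(th|th') dth' = cos th` is verified by
  quadrature to 1e-8.  The speed update `q(s'|s)` is a scaled noncentral
  chi_3: `s' = ||rho s e + varsigma xi||` with `xi` standard normal in
  three dimensions and **`varsigma^2 = sigma^2 (1 - rho^2)`** — the unique
  scale for which the symmetric joint has size-biased
  (Maxwell–Boltzmann(sigma)) marginals, verified by the consistency
  integral `int s' q(s|s') p(s') ds' = s p(s)` to better than 1e-12 by
  quadrature and cross-checked against the noncentral-chi-square density.
* **Refreshment** on an independent exponential clock at rate `lambda_0`:
  speed via the Rice conditional of a correlated bivariate Rayleigh pair
  (parameter `eta`; preserves Rayleigh(sigma) and satisfies pointwise
  detailed balance), bearing via a von Mises turn with concentration
  `kappa` (any symmetric circular law preserves the uniform direction).

Simulation is exact uniformisation/thinning: Poisson candidates at a
dominating rate over a 1-time-unit lookahead window, accepted with
probability `rate/bound`.  The dominating rate is `||v||` (or
`s (1+|h|)`) times an analytic bound on `||grad U||` along the segment:
logistic scores are bounded by 1/scale, normal scores by the segment
endpoints times a 1.5 safety factor (the norm is convex along a segment,
so the endpoint maximum is exact and the factor is pure headroom), Laplace
covariates by `|beta|/2`.  A candidate whose true rate exceeds the bound
raises an error — exactness over generality, never silent clipping.  At an
exact mode (`grad U = 0`) bounce and reorientation rates vanish and only
the refreshment clock runs.  Half-space and reorientation models are
two-dimensional; BPS/GBPS support general dimension.  Initial velocities
in the reference configurations are drawn `Normal(0, sigma^2 I)` from the
run seed.

## Behavioural switching

Location and state evolve jointly: within state `s` the movement targets
the conditional `pi(x|s)` (any model above), and the state chain's
generator satisfies `pi(.|x) Lambda(x) = 0` at every location.  Four
constructions (symmetric square-root, Gibbs, Metropolis–Hastings, Barker)
satisfy detailed balance — for two states that is also necessary — and a
three-state parameterisation adds a circulation `epsilon` on top of the
cyclic free rates `lambda_12, lambda_23, lambda_31`:

    lambda_21 = (pi_1/pi_2) lambda_12 + eps/pi_2   (cyclically),

valid (all rates non-negative) iff `eps >= -min{pi_1 lambda_12,
pi_2 lambda_23, pi_3 lambda_31}`.  The cyclic pairing and the `min` bound
are forced by stationarity and non-negativity respectively, and
stationarity is asserted numerically at random locations rather than
assumed.  All rate formulas use unnormalised state weights (only ratios
appear).

Joint simulation is operator splitting at the integrator step: one
movement step, then a switch with probability `1 - exp(-lambda_tot dt)`.
A warning is emitted when `lambda_tot dt > 0.1`; in the two-state
reference run this fires during rare deep excursions into the opposite
state's territory, where the square-root rates are large.  The same rates
make switching *slow* overall (equilibrium switch rate ~2.5e-4 per time
unit, i.e. ~7 dwells per 3e4 time units), so a single run can leave one
state with too few samples for a conditional test.  The reference check
therefore pools four runs of 7.5e3 time units with alternating initial
states — the model parameters are untouched, both conditionals are
guaranteed coverage, and pooling independent runs improves KS calibration.
The within-state conditionals equilibrate in tens of time units, so entry
transients are negligible against the dwell lengths; the state occupancy
(quadrature value 5/8) is only constrained loosely, since ~15 pooled
dwells carry large Monte-Carlo error and the alternating starts bias the
pooled share toward 1/2 by design.

## Interacting individuals

Adding a pairwise attraction to the joint potential changes each
individual's marginal (demonstrated by quadrature: L1 distortion > 0.03
for interaction strength 1 on the bimodal reference target).  The
latent-kernel construction instead defines

    pi(x_1..x_n) = prod_i pi(x_i) * int_z [prod_{i<j} psi(x_i|z) psi(x_j|z)] / Phi(z) dz

with a Gaussian kernel `psi` of scale `varsigma`,
`Phi(z) = m_{n-1} Psi_{n-1}(z)^{n-1}`,
`Psi_{n-1}(z) = int pi(u) psi(u|z)^{n-1} du` and `m_{n-1} = int
psi(u|0)^{n-1} du` (analytic for Gaussian `psi`).  Dividing the whole
pair-product by `Phi(z)` *once* is the reading that preserves every
marginal for `n > 2` (it reduces to the pair formula at `n = 2`); the
n = 3 quadrature check confirms preservation to machine precision, and
the pair marginal on the reference bimodal target is preserved to 1e-9
over the window interior.  Near the window edge the kernel loses mass
outside the window, so marginal checks exclude a boundary layer of six
kernel scales — a pure truncation artefact of representing a non-decaying
target on a finite window.

The z-integral uses trapezoid quadrature on a uniform grid (default 2001
points spanning the target support ± 6 varsigma), log-sum-exp stabilised.
`Psi` is computed with the *same* discrete rule, which is what makes the
discrete construction exactly self-consistent.  The gradient of the joint
log-density is the exact derivative of this quadrature representation —
for a Gaussian kernel the log-sum-exp differentiates to
`grad log pi(x_i) + (n-1)(E_w[z] - x_i)/varsigma^2` with softmax weights
`w` over the grid — and agrees with central finite differences to 1e-10;
a finite-difference path is retained as a cross-check.

Simulation treats the n individuals as one point in `R^{nd}` under
Langevin or kinetic dynamics on the joint target, reflecting at the
window boundary (velocity flip for kinetic), so the window-truncated
joint density is the exact stationary law.  The reference pair
configuration (kinetic, `alpha = 0.01, gamma = 0.05`) mixes extremely
slowly — the window traversal time is ~7e4 time units — so distributional
tests use faster dynamics (`gamma = 20`, measured integrated
autocorrelation ~100 time units; the speed parameters never affect the
target) and thin to the measured decorrelation spacing; the reference
parameters themselves are exercised by shorter qualitative runs
(finiteness, confinement, determinism, positive cross-correlation).

## Inference

For a track observed at regular spacing `dt`, the Langevin increment is
approximately `Normal((gamma/2) grad L(x_t) dt, gamma dt I)`; the
pseudo-likelihood is maximised over `(beta, log gamma)` (positivity via
the log scale) with three deterministic starts around the zero-drift
moment estimate of `gamma`.  At the pinned operating point (`dt = 0.01`,
5e4 steps, quadratic covariate, `beta = 2, gamma = 1`) recovery is within
±0.2 on `beta` and ±10% on `gamma`, and the replicate-mean of `beta_hat`
is within 2 Monte-Carlo SE of the truth; bias at coarse `dt` is expected
and is not corrected here (multi-point gradient evaluation schemes exist
but are out of scope).  Only regular time grids are accepted.

## Diagnostics and test design

Stationarity checks compare thinned post-burn-in position samples against
quadrature-normalised target marginals (analytic CDFs for separable
targets; 4001-point normalisation over a stated window otherwise) with
one-sample KS tests at the 1% level, plus moment comparisons; switching
runs are checked per state, and event-driven runs report event-rate
summaries.  KS p-values on single trajectories are calibrated only when
the thinning interval comfortably exceeds the mixing time, so run lengths
and thinning in the reference checks were chosen from *measured*
integrated autocorrelation times, and the diagnostic's own calibration is
tested on i.i.d. draws (≥95% non-rejection over seeded repeats) and its
power on a one-SD shift.  Problem sizes (4e4 time units for the diffusion
runs, 2e4 for polar and half-space, 3e4 for switching, 5e4 for the
interaction run) are the package's reference choices and are recorded in
the tests and the acceptance script.

What the synthetic setups do *not* show: all covariates are smooth
analytic forms (no raster data, no measurement error, no irregular
sampling, no boundary effects other than the documented reflecting
windows), so passing tests demonstrate correctness of the constructions,
not robustness to real telemetry artefacts.

## Known limitations

* Half-space and reorientation models are restricted to two dimensions.
* The thinning engine requires an analytic segment gradient bound from the
  target; targets without one cannot be simulated event-exactly.
* Switching uses dt-splitting rather than exact thinning (rates depend on
  a diffusing position, so no linear-segment bound exists); the bias is
  flagged, not corrected.
* Interaction densities are quadrature-validated in one dimension;
  two-dimensional simulation uses the same machinery, but marginal checks
  there would be Monte-Carlo only.
* The Euler–Maruyama pseudo-likelihood is biased for coarsely sampled
  tracks; no correction is implemented.
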