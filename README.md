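# movetarget

Continuous-time animal-movement models that are **consistent by
construction** with a parametric utilisation distribution.

In movement ecology, resource selection describes *where* an animal
spends its time — a utilisation distribution π(x) over space — while step
selection describes *how* it moves in the short term.  The widely used
separable step-selection models are not consistent across timescales: the
selection function they fit is not the utilisation distribution, and the
fitted coefficients change with the sampling interval.  `movetarget`
takes the opposite route: start from a tractable parametric utilisation
distribution,

    log π(x) = Σ_k β_k c_k(x) + const,

with spatial covariates c_k and selection coefficients β_k, and construct
movement processes whose long-run location law is *exactly* π — so the
same β_k describe both the dynamics and the long-term space use, at every
timescale.

The toolkit covers:

* **Targeted diffusions** — the Langevin diffusion
  `dx = (γ/2)∇log π dt + √γ dW`; the kinetic (underdamped) Langevin model
  with velocity persistence; diffusions with covariate-dependent rate
  τ(x) (in particular τ ∝ 1/π: no drift at all, the animal attains π by
  moving faster in poor habitat); and a polar model on speed and bearing
  with Rayleigh-distributed speeds, where sinuosity is a parameter.
  A generic builder assembles any targeted diffusion from a reversible
  part D(z) and an irreversible part Q(z).
* **Velocity-jump (piecewise deterministic) processes** — bouncy-particle
  dynamics generalised for realistic movement: exact (BPS) and randomised
  (GBPS) bounces; a *half-space* bounce whose post-event velocity has
  Rice-distributed speed against the gradient and autoregressive
  orthogonal component, supported on a full half-plane; a *reorientation*
  family with smooth event rates `s‖∇U‖(1 + h cos θ)` and cosine-family
  turn densities; and autocorrelated refreshment (Rice speeds, von Mises
  turns).  Simulation is exact via uniformisation/thinning with analytic
  rate bounds.
* **Behavioural switching** — multi-state models π(x, s) where each state
  has its own selection coefficients and movement process, and the
  location-dependent switching generator Λ(x) preserves π(s|x) exactly
  (symmetric, Gibbs, Metropolis–Hastings and Barker constructions, plus a
  complete non-reversible three-state parameterisation).
* **Interacting individuals** — a latent-kernel joint distribution for n
  animals that induces attraction while preserving each individual's
  marginal π (a naive potential-sum interaction provably does not), with
  joint-space simulation.
* **Diagnostics and inference** — quadrature-normalised stationarity
  checks (KS tests per coordinate, per state), and Euler–Maruyama
  pseudo-likelihood estimation of (β, γ) for the Langevin model from
  regularly sampled tracks.

## A worked example

Build a bimodal utilisation distribution from two covariates — habitat
preference for two patches, inside a home range — simulate a Langevin
track, verify stationarity, and re-estimate the selection coefficients
from the track:

```python
import numpy as np
import movetarget as mt
from movetarget.diagnostics import diagnose
from movetarget.inference import fit_langevin

# log pi(x) = 2 * habitat(x) + 1 * home(x):
# two habitat patches at +-10 inside a home range centred at 0
habitat = mt.minlaplace_covariate([-10.0], [10.0], tau=10.0)
home = mt.quadratic_covariate([0.0], scale=10.0)
target = mt.LinExpTarget([habitat, home], beta=[2.0, 1.0])

spec = mt.langevin_spec(target, gamma=5.0)
track = mt.simulate_em(spec, x0=np.array([-10.0]), dt=0.01,
                       t_end=20_000.0, seed=1)

report = diagnose(track, target, burn_in=0.1, thin=10_000,
                  lo=-50, hi=50, min_samples=150)
c = report["coordinates"][0]
print(f"KS p = {c['ks_pvalue']:.3f}  mean = {c['mean']:.2f}  var = {c['var']:.1f}"
      f"  (target var {c['target_var']:.1f})")

fit = fit_langevin(track.times, track.states, [habitat, home])
print(f"beta_hat = {np.round(fit.beta_hat, 3)}  gamma_hat = {fit.gamma_hat:.3f}")
```

Output:

```
KS p = 0.064  mean = 1.79  var = 97.8  (target var 93.5)
beta_hat = [1.797 0.961]  gamma_hat = 4.990
```

The KS test (on samples thinned to ~100 time units, roughly the mixing
time of this bimodal target) does not reject stationarity against the
quadrature-normalised target, and the fitted selection coefficients and
speed are close to the values the track was generated with
(β = (2, 1), γ = 5); the remaining gap on the habitat coefficient is
Monte-Carlo error at this track length.

## Command line

The same functionality is scriptable:

```bash
movetarget fixtures list                 # bundled reference configurations
movetarget simulate --fixture fig3c --out run     # events + resampled track
movetarget diagnose --traj run.csv --fixture fig3c
movetarget fit --traj track.csv --target target.json
```

Fixtures `fig1`–`fig5` reproduce the package's reference setups: the 1-D
inverse-density diffusion, constant-speed polar models at three
sinuosities, four velocity-jump samplers on a bimodal logistic target,
two-state kinetic-Langevin switching, and an interacting pair.

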