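"""Utilisation-distribution targets built from spatial covariates.

An animal's long-run space use is described by a utilisation distribution,
a density pi(x) over locations x in R^d.  Habitat selection enters through
the log-linear ("linear-exponential") form

    log pi(x) = sum_k beta_k c_k(x) + const,

where the c_k are spatial covariates and the beta_k are selection
coefficients.  Everything downstream (diffusion drifts, event rates for
velocity-jump processes, switching generators) consumes only differences
and gradients of log pi, so all log-densities here are reported *up to an
additive constant*, with the constant fixed at zero.

Conventions
-----------
* Locations are plain real vectors of length ``dim``; a batch of points is
  an array of shape ``(m, dim)``.  All evaluation methods are vectorised
  over the leading axis.
* ``U(x) = -log pi(x)`` is the potential; ``grad_U`` is the gradient that
  movement models bounce off or drift down.
* Covariates with kinks (Laplace at its centre, min-Laplace on the
  mid-line) report a zero gradient exactly at the kink; the kink set has
  measure zero and simulated trajectories never evaluate there.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from scipy.special import expit, logsumexp, ndtr

__all__ = [
    "Covariate",
    "laplace_covariate",
    "minlaplace_covariate",
    "gaussian_covariate",
    "quadratic_covariate",
    "Target",
    "LinExpTarget",
    "ProductTarget",
    "UniformTarget",
    "MultiStateTarget",
    "Normal1D",
    "Logistic1D",
    "LogisticMixture1D",
    "GaussianKernel",
    "UniformBallKernel",
    "PointMassKernel",
    "LocalGibbsError",
    "local_gibbs_step",
    "target_from_config",
    "target_to_config",
]


def _points(x, dim: int):
    """Coerce ``x`` to an (m, dim) float array; report whether it was a single point."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 0:
        if dim != 1:
            raise ValueError(f"scalar location given but target dimension is {dim}")
        return x.reshape(1, 1), True
    if x.shape[-1] != dim:
        raise ValueError(f"expected locations of dimension {dim}, got shape {x.shape}")
    if x.ndim == 1:
        return x.reshape(1, dim), True
    return x.reshape(-1, dim), False


class Covariate:
    """A spatial covariate c_k(x) with an analytic gradient.

    Parameters
    ----------
    name:
        Label used in configs and reports.
    value_fn, grad_fn:
        Vectorised callables on (m, d) point arrays returning (m,) values
        and (m, d) gradients respectively.
    seg_grad_bound:
        Optional callable ``(x, v, horizon) -> float`` giving an upper
        bound on ``||grad c||`` along the segment ``{x + t v : 0 <= t <=
        horizon}``; used by the exact thinning simulator for event-rate
        bounds.
    """

    def __init__(self, name: str, value_fn, grad_fn, seg_grad_bound=None, dim: int | None = None,
                 config: dict | None = None):
        self.name = name
        self._value = value_fn
        self._grad = grad_fn
        self._bound = seg_grad_bound
        self.dim = dim
        self.config = config

    def value_at(self, x):
        dim = self.dim if self.dim is not None else np.atleast_1d(np.asarray(x)).shape[-1]
        pts, single = _points(x, dim)
        out = self._value(pts)
        return float(out[0]) if single else out

    def gradient_at(self, x):
        dim = self.dim if self.dim is not None else np.atleast_1d(np.asarray(x)).shape[-1]
        pts, single = _points(x, dim)
        out = self._grad(pts)
        return out[0] if single else out

    def seg_grad_bound(self, x, v, horizon: float) -> float:
        if self._bound is None:
            raise NotImplementedError(f"covariate {self.name!r} has no segment gradient bound")
        return float(self._bound(np.asarray(x, float), np.asarray(v, float), float(horizon)))


def _radial(pts: np.ndarray, mu: np.ndarray):
    diff = pts - mu
    r = np.linalg.norm(diff, axis=-1)
    return diff, r


def laplace_covariate(mu, tau: float) -> Covariate:
    """Laplace-shaped covariate  c(x) = tau * exp(-|x - mu| / (2 tau)).

    Peaks at ``mu`` with height ``tau``; its gradient has constant magnitude
    ``c(x)/(2 tau) <= 1/2`` away from the centre, which is what makes it a
    convenient bounded-score building block for unimodal targets.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    mu = np.atleast_1d(np.asarray(mu, float))
    tau = float(tau)

    def value(pts):
        _, r = _radial(pts, mu)
        return tau * np.exp(-r / (2.0 * tau))

    def grad(pts):
        diff, r = _radial(pts, mu)
        val = tau * np.exp(-r / (2.0 * tau))
        r_safe = np.where(r == 0.0, 1.0, r)
        unit = diff / r_safe[..., None]
        unit[r == 0.0] = 0.0
        return -unit * (val / (2.0 * tau))[..., None]

    return Covariate(
        "laplace", value, grad,
        seg_grad_bound=lambda x, v, h: 0.5,
        dim=mu.size,
        config={"family": "laplace", "mu": mu.tolist(), "tau": tau},
    )


def minlaplace_covariate(muA, muB, tau: float) -> Covariate:
    """Bimodal covariate  c(x) = exp(-min(|x - muA|, |x - muB|) / (2 tau)).

    Equal peaks of height 1 at the two centres; gradient points towards the
    nearer centre and vanishes on the equidistant mid-line.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    muA = np.atleast_1d(np.asarray(muA, float))
    muB = np.atleast_1d(np.asarray(muB, float))
    if muA.shape != muB.shape:
        raise ValueError("muA and muB must have the same dimension")
    tau = float(tau)

    def value(pts):
        _, rA = _radial(pts, muA)
        _, rB = _radial(pts, muB)
        return np.exp(-np.minimum(rA, rB) / (2.0 * tau))

    def grad(pts):
        dA, rA = _radial(pts, muA)
        dB, rB = _radial(pts, muB)
        use_a = rA < rB
        diff = np.where(use_a[..., None], dA, dB)
        r = np.where(use_a, rA, rB)
        val = np.exp(-r / (2.0 * tau))
        r_safe = np.where(r == 0.0, 1.0, r)
        unit = diff / r_safe[..., None]
        unit[r == 0.0] = 0.0
        g = -unit * (val / (2.0 * tau))[..., None]
        # zero gradient on the equidistant mid-line (measure-zero kink set)
        g[rA == rB] = 0.0
        return g

    return Covariate(
        "minlaplace", value, grad,
        seg_grad_bound=lambda x, v, h: 1.0 / (2.0 * tau),
        dim=muA.size,
        config={"family": "minlaplace", "muA": muA.tolist(), "muB": muB.tolist(), "tau": tau},
    )


def gaussian_covariate(mu, scale: float) -> Covariate:
    """Gaussian-shaped covariate  c(x) = exp(-|x - mu|^2 / (2 scale^2))."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    mu = np.atleast_1d(np.asarray(mu, float))
    scale = float(scale)

    def value(pts):
        _, r = _radial(pts, mu)
        return np.exp(-r ** 2 / (2.0 * scale ** 2))

    def grad(pts):
        diff, r = _radial(pts, mu)
        val = np.exp(-r ** 2 / (2.0 * scale ** 2))
        return -diff * (val / scale ** 2)[..., None]

    # |grad c| = (r/scale^2) exp(-r^2/2 scale^2) maximised at r = scale
    bound = np.exp(-0.5) / scale
    return Covariate(
        "gaussian", value, grad,
        seg_grad_bound=lambda x, v, h: bound,
        dim=mu.size,
        config={"family": "gaussian", "mu": mu.tolist(), "scale": scale},
    )


def quadratic_covariate(mu, scale: float = 1.0) -> Covariate:
    """Quadratic covariate  c(x) = -|x - mu|^2 / (2 scale^2).

    With coefficient beta this yields a Gaussian target with per-coordinate
    variance scale^2 / beta; useful for normal targets and for parameter
    recovery experiments where the drift is linear.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    mu = np.atleast_1d(np.asarray(mu, float))
    scale = float(scale)

    def value(pts):
        _, r = _radial(pts, mu)
        return -(r ** 2) / (2.0 * scale ** 2)

    def grad(pts):
        diff, _ = _radial(pts, mu)
        return -diff / scale ** 2

    def bound(x, v, h):
        x = np.atleast_1d(x)
        v = np.atleast_1d(v)
        r0 = np.linalg.norm(x - mu)
        r1 = np.linalg.norm(x + h * v - mu)
        return 1.5 * max(r0, r1) / scale ** 2  # ||x+tv-mu|| is convex in t

    return Covariate(
        "quadratic", value, grad, seg_grad_bound=bound, dim=mu.size,
        config={"family": "quadratic", "mu": mu.tolist(), "scale": scale},
    )


# ---------------------------------------------------------------------------
# targets


class Target:
    """A utilisation distribution known up to proportionality."""

    dim: int

    def log_density(self, x):
        raise NotImplementedError

    def grad_log_density(self, x):
        """Gradient of log pi; central finite differences unless overridden."""
        pts, single = _points(x, self.dim)
        out = np.empty_like(pts)
        step = 1e-5 * (1.0 + np.abs(pts))
        for j in range(self.dim):
            hi = pts.copy()
            lo = pts.copy()
            hi[:, j] += step[:, j]
            lo[:, j] -= step[:, j]
            out[:, j] = (np.atleast_1d(self.log_density(hi)) - np.atleast_1d(self.log_density(lo))) / (2 * step[:, j])
        return out[0] if single else out

    def grad_U(self, x):
        """Gradient of the potential U = -log pi."""
        return -np.asarray(self.grad_log_density(x))

    def grad_norm_bound(self, x, v, horizon: float) -> float:
        """Upper bound on ||grad U|| along the segment x + [0, horizon] v."""
        raise NotImplementedError(f"{type(self).__name__} has no segment gradient bound")


class UniformTarget(Target):
    """Flat (improper) target: log pi == 0 everywhere, gradient zero."""

    def __init__(self, dim: int = 2):
        self.dim = int(dim)

    def log_density(self, x):
        pts, single = _points(x, self.dim)
        out = np.zeros(pts.shape[0])
        return float(out[0]) if single else out

    def grad_log_density(self, x):
        pts, single = _points(x, self.dim)
        out = np.zeros_like(pts)
        return out[0] if single else out

    def grad_norm_bound(self, x, v, horizon):
        return 0.0


class LinExpTarget(Target):
    """Log-linear target: log pi(x) = sum_k beta_k c_k(x) (no constant)."""

    def __init__(self, covariates: Sequence[Covariate], beta, dim: int | None = None):
        self.covariates = list(covariates)
        self.beta = np.atleast_1d(np.asarray(beta, float))
        if len(self.covariates) != self.beta.size:
            raise ValueError("beta must have one coefficient per covariate")
        if dim is None:
            dims = {c.dim for c in self.covariates if c.dim is not None}
            if len(dims) != 1:
                raise ValueError("cannot infer dimension; pass dim explicitly")
            dim = dims.pop()
        self.dim = int(dim)

    def log_density(self, x):
        pts, single = _points(x, self.dim)
        out = np.zeros(pts.shape[0])
        for b, c in zip(self.beta, self.covariates):
            if b != 0.0:
                out += b * c._value(pts)
        return float(out[0]) if single else out

    def grad_log_density(self, x):
        pts, single = _points(x, self.dim)
        out = np.zeros_like(pts)
        for b, c in zip(self.beta, self.covariates):
            if b != 0.0:
                out += b * c._grad(pts)
        return out[0] if single else out

    def grad_norm_bound(self, x, v, horizon):
        return float(sum(abs(b) * c.seg_grad_bound(x, v, horizon)
                         for b, c in zip(self.beta, self.covariates)))


# -- separable (product) targets --------------------------------------------


class Axis1D:
    """One coordinate of a separable target: a univariate log-density."""

    def logpdf(self, x):
        raise NotImplementedError

    def dlogpdf(self, x):
        raise NotImplementedError

    def cdf(self, x):
        raise NotImplementedError

    def score_bound(self, x: float, v: float, horizon: float) -> float:
        raise NotImplementedError

    mean: float
    var: float


class Normal1D(Axis1D):
    def __init__(self, mu: float = 0.0, sigma: float = 1.0):
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        self.mu = float(mu)
        self.sigma = float(sigma)
        self.mean = self.mu
        self.var = self.sigma ** 2
        self.config = {"dist": "normal", "mu": self.mu, "sigma": self.sigma}

    def logpdf(self, x):
        z = (np.asarray(x, float) - self.mu) / self.sigma
        return -0.5 * z ** 2

    def dlogpdf(self, x):
        return -(np.asarray(x, float) - self.mu) / self.sigma ** 2

    def cdf(self, x):
        return ndtr((np.asarray(x, float) - self.mu) / self.sigma)

    def score_bound(self, x, v, horizon):
        r0 = abs(x - self.mu)
        r1 = abs(x + horizon * v - self.mu)
        return 1.5 * max(r0, r1) / self.sigma ** 2


class Logistic1D(Axis1D):
    def __init__(self, loc: float = 0.0, scale: float = 1.0):
        if scale <= 0:
            raise ValueError("scale must be positive")
        self.loc = float(loc)
        self.scale = float(scale)
        self.mean = self.loc
        self.var = (np.pi * self.scale) ** 2 / 3.0
        self.config = {"dist": "logistic", "loc": self.loc, "scale": self.scale}

    def logpdf(self, x):
        z = np.abs((np.asarray(x, float) - self.loc) / self.scale)
        return -z - 2.0 * np.log1p(np.exp(-z))

    def dlogpdf(self, x):
        z = (np.asarray(x, float) - self.loc) / self.scale
        return -np.tanh(z / 2.0) / self.scale

    def cdf(self, x):
        return expit((np.asarray(x, float) - self.loc) / self.scale)

    def score_bound(self, x, v, horizon):
        return 1.0 / self.scale  # logistic score is bounded by 1/scale


class LogisticMixture1D(Axis1D):
    """Finite mixture of logistic distributions on one axis."""

    def __init__(self, locs, scales, weights):
        self.locs = np.atleast_1d(np.asarray(locs, float))
        self.scales = np.atleast_1d(np.asarray(scales, float))
        self.weights = np.atleast_1d(np.asarray(weights, float))
        if not (self.locs.size == self.scales.size == self.weights.size):
            raise ValueError("locs, scales, weights must have equal length")
        if np.any(self.scales <= 0) or np.any(self.weights <= 0):
            raise ValueError("scales and weights must be positive")
        self.weights = self.weights / self.weights.sum()
        self.mean = float(np.sum(self.weights * self.locs))
        comp_var = (np.pi * self.scales) ** 2 / 3.0
        self.var = float(np.sum(self.weights * (comp_var + self.locs ** 2)) - self.mean ** 2)
        self.config = {"dist": "logistic_mixture", "locs": self.locs.tolist(),
                       "scales": self.scales.tolist(), "weights": self.weights.tolist()}

    def _comp_logpdf(self, x):
        x = np.asarray(x, float)[..., None]
        z = np.abs((x - self.locs) / self.scales)
        return -z - 2.0 * np.log1p(np.exp(-z)) - np.log(self.scales)

    def logpdf(self, x):
        return logsumexp(self._comp_logpdf(x) + np.log(self.weights), axis=-1)

    def dlogpdf(self, x):
        x_arr = np.asarray(x, float)
        lp = self._comp_logpdf(x_arr) + np.log(self.weights)
        w = np.exp(lp - logsumexp(lp, axis=-1, keepdims=True))
        z = (x_arr[..., None] - self.locs) / self.scales
        scores = -np.tanh(z / 2.0) / self.scales
        return np.sum(w * scores, axis=-1)

    def cdf(self, x):
        z = (np.asarray(x, float)[..., None] - self.locs) / self.scales
        return np.sum(self.weights * expit(z), axis=-1)

    def score_bound(self, x, v, horizon):
        # the mixture score is a pointwise convex combination of component scores
        return float(np.max(1.0 / self.scales))


class ProductTarget(Target):
    """Separable target: independent coordinates, each with its own 1-D law."""

    def __init__(self, axes: Sequence[Axis1D]):
        self.axes = list(axes)
        self.dim = len(self.axes)

    def log_density(self, x):
        pts, single = _points(x, self.dim)
        out = sum(np.atleast_1d(ax.logpdf(pts[:, j])) for j, ax in enumerate(self.axes))
        return float(out[0]) if single else out

    def grad_log_density(self, x):
        pts, single = _points(x, self.dim)
        out = np.column_stack([np.atleast_1d(ax.dlogpdf(pts[:, j])) for j, ax in enumerate(self.axes)])
        return out[0] if single else out

    def grad_norm_bound(self, x, v, horizon):
        x = np.atleast_1d(np.asarray(x, float))
        v = np.atleast_1d(np.asarray(v, float))
        b = [ax.score_bound(x[j], v[j], horizon) for j, ax in enumerate(self.axes)]
        return float(np.sqrt(np.sum(np.square(b))))


def standard_normal_target(dim: int = 1) -> ProductTarget:
    return ProductTarget([Normal1D() for _ in range(dim)])


# -- multi-state targets -----------------------------------------------------


class MultiStateTarget:
    """Joint utilisation distribution over location and behavioural state.

    pi(x, s) is log-linear per state with its own intercept beta_{s,0} and
    selection coefficients beta_{s,k}:

        log pi(x, s) = beta_{s,0} + sum_k beta_{s,k} c_k(x)   (+ const).

    ``state_posterior`` gives pi(s | x) (a softmax over states), and
    ``conditional(s)`` the within-state location target pi(x | s) as a
    plain :class:`LinExpTarget` (the intercept is an additive constant).
    """

    def __init__(self, beta0, beta, covariates: Sequence[Covariate], dim: int | None = None):
        self.beta0 = np.atleast_1d(np.asarray(beta0, float))
        self.beta = np.atleast_2d(np.asarray(beta, float))
        self.covariates = list(covariates)
        self.n_states = self.beta0.size
        if self.n_states < 2:
            raise ValueError("a multi-state target needs at least two states")
        if self.beta.shape != (self.n_states, len(self.covariates)):
            raise ValueError("beta must be (n_states, n_covariates)")
        if dim is None:
            dims = {c.dim for c in self.covariates if c.dim is not None}
            if len(dims) != 1:
                raise ValueError("cannot infer dimension; pass dim explicitly")
            dim = dims.pop()
        self.dim = int(dim)

    def state_logweights(self, x):
        """Unnormalised log pi(x, s) for every state; shape (..., S)."""
        pts, single = _points(x, self.dim)
        cvals = np.column_stack([c._value(pts) for c in self.covariates])
        out = self.beta0[None, :] + cvals @ self.beta.T
        return out[0] if single else out

    def state_posterior(self, x):
        lw = np.atleast_2d(self.state_logweights(x))
        post = np.exp(lw - logsumexp(lw, axis=-1, keepdims=True))
        return post[0] if np.asarray(x).ndim <= 1 else post

    def conditional(self, s: int) -> LinExpTarget:
        return LinExpTarget(self.covariates, self.beta[s], dim=self.dim)


# ---------------------------------------------------------------------------
# the discrete-time local Gibbs step


class LocalGibbsError(RuntimeError):
    pass


class GaussianKernel:
    """Isotropic Gaussian displacement kernel (symmetric, homogeneous)."""

    is_degenerate = False

    def __init__(self, sd: float, dim: int = 1, n_grid: int = 61, support_sds: float = 6.0):
        if sd <= 0:
            raise ValueError("sd must be positive")
        self.sd = float(sd)
        self.dim = int(dim)
        self.support_radius = support_sds * self.sd
        axes = [np.linspace(-self.support_radius, self.support_radius, n_grid)] * self.dim
        mesh = np.meshgrid(*axes, indexing="ij")
        self.grid_offsets = np.column_stack([m.ravel() for m in mesh])

    def sample(self, centre, rng, size=None):
        centre = np.atleast_1d(np.asarray(centre, float))
        if size is None:
            return centre + self.sd * rng.standard_normal(self.dim)
        return centre[None, :] + self.sd * rng.standard_normal((size, self.dim))


class UniformBallKernel:
    """Uniform displacement on a ball (interval for d=1, disc for d=2)."""

    is_degenerate = False

    def __init__(self, radius: float, dim: int = 2, n_grid: int = 41):
        if radius <= 0:
            raise ValueError("radius must be positive")
        self.radius = float(radius)
        self.dim = int(dim)
        self.support_radius = self.radius
        axes = [np.linspace(-self.radius, self.radius, n_grid)] * self.dim
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([m.ravel() for m in mesh])
        self.grid_offsets = pts[np.linalg.norm(pts, axis=1) <= self.radius]

    def sample(self, centre, rng, size=None):
        centre = np.atleast_1d(np.asarray(centre, float))
        m = 1 if size is None else size
        if self.dim == 1:
            out = centre[None, :] + rng.uniform(-self.radius, self.radius, (m, 1))
        else:
            u = rng.standard_normal((m, self.dim))
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            r = self.radius * rng.random(m) ** (1.0 / self.dim)
            out = centre[None, :] + u * r[:, None]
        return out[0] if size is None else out


class PointMassKernel:
    """Degenerate kernel concentrated at the current point."""

    is_degenerate = True

    def sample(self, centre, rng, size=None):
        centre = np.atleast_1d(np.asarray(centre, float))
        return centre if size is None else np.tile(centre, (size, 1))


def local_gibbs_step(target: Target, kernel, x, rng, max_attempts: int = 100_000,
                     safety: float = 1.2):
    """One step of the rejection-free two-stage ("local Gibbs") move.

    Stage 1 draws a latent point z from the symmetric homogeneous kernel
    psi(.|x); stage 2 draws the new location from psi(.|z) * pi(.),
    normalised over the kernel support.  If x ~ pi then the new location is
    again distributed as pi.  The second stage is sampled exactly by
    rejection: proposals from psi(.|z) are accepted with probability
    pi(x') / M_z, with M_z a safety-inflated grid maximum of pi over the
    kernel support around z.
    """
    x = np.atleast_1d(np.asarray(x, float))
    z = kernel.sample(x, rng)
    if kernel.is_degenerate:
        return z
    grid = z[None, :] + kernel.grid_offsets
    log_m = float(np.max(target.log_density(grid))) + np.log(safety)
    n_batch = 64
    attempts = 0
    while attempts < max_attempts:
        props = kernel.sample(z, rng, size=n_batch)
        logp = np.atleast_1d(target.log_density(props))
        accept = np.log(rng.random(n_batch)) < logp - log_m
        if np.any(accept):
            return props[int(np.argmax(accept))]
        attempts += n_batch
    raise LocalGibbsError(
        f"local Gibbs rejection sampler exceeded {max_attempts} attempts "
        f"(envelope log M_z = {log_m:.3f})"
    )


# ---------------------------------------------------------------------------
# JSON config plumbing


_COV_BUILDERS = {
    "laplace": lambda c: laplace_covariate(c["mu"], c["tau"]),
    "minlaplace": lambda c: minlaplace_covariate(c["muA"], c["muB"], c["tau"]),
    "gaussian": lambda c: gaussian_covariate(c["mu"], c["scale"]),
    "quadratic": lambda c: quadratic_covariate(c["mu"], c.get("scale", 1.0)),
}

_AXIS_BUILDERS = {
    "normal": lambda a: Normal1D(a.get("mu", 0.0), a.get("sigma", 1.0)),
    "logistic": lambda a: Logistic1D(a.get("loc", 0.0), a.get("scale", 1.0)),
    "logistic_mixture": lambda a: LogisticMixture1D(a["locs"], a["scales"], a["weights"]),
}


def covariate_from_config(cfg: dict) -> Covariate:
    try:
        return _COV_BUILDERS[cfg["family"]](cfg)
    except KeyError as e:
        raise ValueError(f"unknown covariate family in config: {cfg!r}") from e


def target_from_config(cfg: dict):
    """Build a target from its JSON config block."""
    kind = cfg["type"]
    if kind == "linexp":
        covs = [covariate_from_config(c) for c in cfg["covariates"]]
        return LinExpTarget(covs, cfg["beta"], dim=cfg.get("dim"))
    if kind == "product":
        axes = [_AXIS_BUILDERS[a["dist"]](a) for a in cfg["axes"]]
        return ProductTarget(axes)
    if kind == "multistate":
        covs = [covariate_from_config(c) for c in cfg["covariates"]]
        return MultiStateTarget(cfg["beta0"], cfg["beta"], covs, dim=cfg.get("dim"))
    if kind == "uniform":
        return UniformTarget(cfg.get("dim", 2))
    raise ValueError(f"unknown target type {kind!r}")


def target_to_config(target) -> dict:
    if isinstance(target, LinExpTarget):
        return {"type": "linexp", "dim": target.dim,
                "covariates": [c.config for c in target.covariates],
                "beta": target.beta.tolist()}
    if isinstance(target, ProductTarget):
        return {"type": "product", "axes": [ax.config for ax in target.axes]}
    if isinstance(target, MultiStateTarget):
        return {"type": "multistate", "dim": target.dim,
                "beta0": target.beta0.tolist(), "beta": target.beta.tolist(),
                "covariates": [c.config for c in target.covariates]}
    if isinstance(target, UniformTarget):
        return {"type": "uniform", "dim": target.dim}
    raise TypeError(f"cannot serialise target of type {type(target).__name__}")
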