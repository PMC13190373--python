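"""Speed and bearing laws for velocity-jump updates.

When the velocity of a planar movement process is Normal(0, sigma^2 I_2),
the speed s = ||v|| is Rayleigh(sigma).  The event-time updates of the
velocity-jump models need a small family of related laws:

* the Rice distribution -- the conditional of a correlated bivariate
  Rayleigh pair, used for the gradient-parallel speed at a half-space
  bounce and for autocorrelated speed refreshment;
* the size-biased speed law s p(s)/E[s], which for Rayleigh(sigma) is the
  Maxwell-Boltzmann(sigma) density (a scaled chi_3): the speed law seen at
  event times, since faster animals hit events more often;
* a symmetric bivariate law with Maxwell-Boltzmann marginals whose
  conditional q(s'|s) is a scaled noncentral chi_3 -- the speed update of
  the reorientation family.  Its scale is varsigma^2 = sigma^2 (1 - rho^2),
  the unique choice for which the chain of updates preserves the
  size-biased marginal (equivalently, for which the consistency integral
  int s' q(s|s') p(s') ds' = s p(s) holds);
* the von Mises turn for bearings.

Samplers are constructive (norms of Gaussian vectors) and therefore exact;
Bessel factors are evaluated in log space via exponentially scaled Bessel
functions so large arguments do not overflow.
"""

from __future__ import annotations

import numpy as np
from scipy.special import i0e, ive

from .diffusions import wrap_angle

__all__ = [
    "rayleigh_density",
    "rice_density",
    "rice_sample",
    "sizebiased_speed_density",
    "speed_update_scale",
    "speed_update_density",
    "speed_update_sample",
    "rice_refresh_speed",
    "vonmises_turn",
]


def rayleigh_density(s, sigma: float):
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    s = np.asarray(s, float)
    out = np.where(s >= 0, s / sigma ** 2 * np.exp(-s ** 2 / (2 * sigma ** 2)), 0.0)
    return float(out) if out.ndim == 0 else out


def rice_density(s, nu: float, b: float):
    """Rice(nu, b) density: (s/b^2) exp(-(s^2+nu^2)/(2 b^2)) I0(s nu / b^2).

    nu = 0 reduces to Rayleigh(b).  Evaluated in log space: the Bessel
    factor uses the scaled I0e so the product is stable for large s nu.
    """
    if b <= 0:
        raise ValueError("b must be positive")
    if nu < 0:
        raise ValueError("nu must be non-negative")
    s = np.asarray(s, float)
    w = s * nu / b ** 2
    # log I0(w) = log i0e(w) + w
    log_pdf = np.log(np.where(s > 0, s, 1.0)) - 2 * np.log(b) \
        - (s ** 2 + nu ** 2) / (2 * b ** 2) + np.log(i0e(w)) + w
    out = np.where(s > 0, np.exp(log_pdf), 0.0)
    return float(out) if out.ndim == 0 else out


def rice_sample(nu: float, b: float, rng: np.random.Generator, size=None):
    """Exact Rice draw as the norm of (nu + b xi1, b xi2), xi standard normal."""
    if b < 0:
        raise ValueError("b must be non-negative")
    if nu < 0:
        raise ValueError("nu must be non-negative")
    shape = (2,) if size is None else (size, 2)
    xi = rng.standard_normal(shape)
    vec = b * xi
    vec[..., 0] += nu
    out = np.linalg.norm(vec, axis=-1)
    return float(out) if size is None else out


def sizebiased_speed_density(s, sigma: float):
    """Maxwell-Boltzmann(sigma): the size-biased Rayleigh(sigma) speed law.

    p*(s) = sqrt(2/pi) s^2 / sigma^3 exp(-s^2 / (2 sigma^2))
          = s p(s) / E[s],  E[s] = sigma sqrt(pi/2).
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    s = np.asarray(s, float)
    out = np.where(
        s >= 0,
        np.sqrt(2.0 / np.pi) * s ** 2 / sigma ** 3 * np.exp(-s ** 2 / (2 * sigma ** 2)),
        0.0,
    )
    return float(out) if out.ndim == 0 else out


def speed_update_scale(sigma: float, rho: float) -> float:
    """Scale varsigma of the noncentral-chi_3 speed update.

    varsigma^2 = sigma^2 (1 - rho^2): the conditional of the symmetric
    trivariate-Gaussian-norm construction (Y | X ~ Normal(rho X,
    varsigma^2 I_3), s = ||X||, s' = ||Y||), which is the unique scale for
    which the joint has Maxwell-Boltzmann(sigma) marginals.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not 0.0 <= rho < 1.0:
        raise ValueError("require 0 <= rho < 1")
    return sigma * np.sqrt(1.0 - rho ** 2)


def speed_update_density(s_new, s: float, sigma: float, rho: float):
    """Conditional density q(s'|s) of the event-time speed update.

    A scaled noncentral chi_3: s'/varsigma has noncentrality rho s /
    varsigma, giving

        q(s'|s) = (s')^{3/2} / (varsigma^2 sqrt(rho s))
                  * exp(-((s')^2 + (rho s)^2) / (2 varsigma^2))
                  * I_{1/2}(s' s rho / varsigma^2).

    rho = 0 is the independent limit: a fresh Maxwell-Boltzmann(sigma) draw.
    """
    if s <= 0:
        raise ValueError("s must be positive")
    vs = speed_update_scale(sigma, rho)
    s_new = np.asarray(s_new, float)
    if rho == 0.0:
        out = sizebiased_speed_density(s_new, sigma)
        return out
    w = s_new * s * rho / vs ** 2
    # log I_{1/2}(w) = log ive(1/2, w) + w
    with np.errstate(divide="ignore", invalid="ignore"):
        log_pdf = 1.5 * np.log(np.where(s_new > 0, s_new, 1.0)) \
            - 2 * np.log(vs) - 0.5 * np.log(rho * s) \
            - (s_new ** 2 + (rho * s) ** 2) / (2 * vs ** 2) \
            + np.log(ive(0.5, w)) + w
    out = np.where(s_new > 0, np.exp(log_pdf), 0.0)
    return float(out) if out.ndim == 0 else out


def speed_update_sample(s: float, sigma: float, rho: float,
                        rng: np.random.Generator, size=None):
    """Exact draw from q(.|s): the norm of rho s e + varsigma xi, xi in R^3."""
    if s <= 0:
        raise ValueError("s must be positive")
    vs = speed_update_scale(sigma, rho)
    shape = (3,) if size is None else (size, 3)
    xi = rng.standard_normal(shape)
    vec = vs * xi
    vec[..., 0] += rho * s
    out = np.linalg.norm(vec, axis=-1)
    return float(out) if size is None else out


def rice_refresh_speed(s: float, sigma: float, eta: float,
                       rng: np.random.Generator, size=None):
    """Autocorrelated speed refreshment preserving Rayleigh(sigma).

    s' | s ~ Rice(s eta, sigma sqrt(1 - eta^2)): the conditional of a
    correlated bivariate Rayleigh pair with equal Rayleigh(sigma) marginals
    and correlation parameter eta.  eta = 0 gives an independent
    Rayleigh(sigma) draw; eta -> 1 concentrates at the current speed.
    """
    if not 0.0 <= eta < 1.0:
        raise ValueError("require 0 <= eta < 1")
    if s < 0:
        raise ValueError("s must be non-negative")
    return rice_sample(eta * s, sigma * np.sqrt(1.0 - eta ** 2), rng, size=size)


def vonmises_turn(theta: float, kappa: float, rng: np.random.Generator, size=None):
    """New bearing ~ von Mises(theta, kappa), wrapped to (-pi, pi].

    kappa = 0 is a uniform bearing; any symmetric circular law centred on
    the current bearing maintains detailed balance for the uniform
    direction distribution.
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if kappa == 0.0:
        draw = rng.uniform(-np.pi, np.pi, size=size)
    else:
        draw = rng.vonmises(theta, kappa, size=size)
    out = wrap_angle(draw)
    return float(out) if size is None else out
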