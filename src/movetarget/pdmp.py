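"""Velocity-jump (piecewise deterministic) movement models.

Between events the animal moves in a straight line at constant velocity;
at random event times the velocity jumps.  Event rates and post-event
velocity laws are chosen so that the long-run location law is a prescribed
utilisation distribution pi(x) with potential U = -log pi:

* **bounces** at the canonical rate max{0, grad U . v}: the classical
  bouncy particle sampler (BPS) reflects the gradient-parallel velocity
  component deterministically; the generalized BPS (GBPS) resamples the
  orthogonal part; the *half-space* bounce draws a Rice-distributed speed
  against the gradient and an autoregressive orthogonal component, giving
  post-bounce support over the whole half-space of velocities whose
  gradient component has flipped sign;
* **reorientations** at smooth non-canonical rates
  s ||grad U|| (1 + h cos theta), with theta the bearing relative to the
  gradient: full-support velocity updates with speed drawn from a
  noncentral-chi_3 conditional (size-biased marginal) and bearing from a
  low-order cosine family; the (a, b, h) coefficients must satisfy
  h - a - b h / 2 = 1 together with the positivity bounds |h| <= 1,
  |a| + |b| <= 1;
* **refreshment** at a constant rate lambda0, independent of the target:
  autocorrelated speed (Rice) and von Mises turning, preserving the
  Normal(0, sigma^2 I) velocity law.

Events are simulated exactly by uniformisation/thinning: candidate times
from a Poisson process at a dominating rate over a lookahead window, each
accepted with probability rate/bound.  The dominating rate comes from
analytic gradient-norm bounds supplied by the targets; a candidate whose
true rate exceeds the bound is a hard error, never silently clipped.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import List, Optional

import numpy as np
import pandas as pd

from .diffusions import Trajectory, wrap_angle
from .speed_distributions import rice_refresh_speed, rice_sample, speed_update_sample, vonmises_turn
from .targets import Target

__all__ = [
    "EventRecord",
    "PDMPPath",
    "BounceConfig",
    "ReorientConfig",
    "TABLE1",
    "ThinningBoundError",
    "canonical_rate",
    "bps_reflect",
    "gbps_bounce",
    "halfspace_bounce",
    "reorientation_rate",
    "reorientation_bearing_density",
    "reorientation_bearing_sample",
    "simulate_pdmp",
    "path_position_at",
]


class ThinningBoundError(RuntimeError):
    """The true event rate exceeded the dominating rate used for thinning."""


@dataclasses.dataclass
class EventRecord:
    time: float
    kind: str  # "bounce" | "reorientation" | "refresh"
    position: np.ndarray
    v_before: np.ndarray
    v_after: np.ndarray


@dataclasses.dataclass
class PDMPPath:
    """Event-indexed trajectory; the path is piecewise linear between events."""

    x0: np.ndarray
    v0: np.ndarray
    t0: float
    events: List[EventRecord]
    t_end: float
    seed: Optional[int]

    def _segments(self):
        times = [self.t0] + [e.time for e in self.events]
        pos = [self.x0] + [e.position for e in self.events]
        vel = [self.v0] + [e.v_after for e in self.events]
        return np.asarray(times), np.asarray(pos), np.asarray(vel)

    def position_at(self, t):
        single = np.ndim(t) == 0
        t_arr = np.atleast_1d(np.asarray(t, float))
        if np.any(t_arr < self.t0 - 1e-12) or np.any(t_arr > self.t_end + 1e-12):
            raise ValueError("time outside the simulated interval")
        times, pos, vel = self._segments()
        idx = np.clip(np.searchsorted(times, t_arr, side="right") - 1, 0, len(times) - 1)
        out = pos[idx] + (t_arr[:, None] - times[idx][:, None]) * vel[idx]
        return out[0] if single else out

    def velocity_at(self, t):
        single = np.ndim(t) == 0
        t_arr = np.atleast_1d(np.asarray(t, float))
        times, _, vel = self._segments()
        idx = np.clip(np.searchsorted(times, t_arr, side="right") - 1, 0, len(times) - 1)
        return vel[idx][0] if single else vel[idx]

    def sample_grid(self, dt: float) -> Trajectory:
        """Regular-grid position resampling, compatible with diffusion output."""
        times = np.arange(self.t0, self.t_end + 1e-12, dt)
        states = np.atleast_2d(self.position_at(times))
        d = self.x0.size
        names = ("x", "y", "z")[:d] if d <= 3 else tuple(f"x{i+1}" for i in range(d))
        return Trajectory(times, states, dt, self.seed, names)

    def to_csv(self, path, sidecar: dict | None = None):
        path = Path(path)
        d = self.x0.size
        cols = {"t": [e.time for e in self.events],
                "event_kind": [e.kind for e in self.events]}
        labels = ("x", "y", "z")[:d] if d <= 3 else tuple(f"x{i+1}" for i in range(d))
        for j, lab in enumerate(labels):
            cols[lab] = [e.position[j] for e in self.events]
        for j, lab in enumerate(labels):
            cols[f"v{lab}_before"] = [e.v_before[j] for e in self.events]
        for j, lab in enumerate(labels):
            cols[f"v{lab}_after"] = [e.v_after[j] for e in self.events]
        pd.DataFrame(cols).to_csv(path, index=False)
        meta = {"t0": self.t0, "t_end": self.t_end, "seed": self.seed,
                "x0": self.x0.tolist(), "v0": self.v0.tolist()}
        if sidecar:
            meta.update(sidecar)
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


@dataclasses.dataclass
class BounceConfig:
    """Parameters of the half-space bounce and the refreshment process.

    sigma is the velocity scale (stationary velocity ~ Normal(0, sigma^2 I)).
    rho correlates the gradient-parallel speeds before/after a bounce
    (rho = 1 recovers the deterministic BPS reflection of that component);
    omega is the autoregressive coefficient of the orthogonal component
    (omega = 1 keeps it, BPS; omega = 0 resamples it, GBPS).  Full support
    on the velocity half-space requires 0 <= rho < 1 and -1 < omega < 1;
    the closed endpoints are accepted as the degenerate BPS/GBPS limits.
    Refreshment occurs at rate lambda0 with Rice-autocorrelated speed
    (eta) and von Mises turning (kappa).
    """

    sigma: float = 1.0
    rho: float = 0.5
    omega: float = 0.5
    refresh_rate: float = 0.0
    refresh_eta: float = 0.0
    refresh_kappa: float = 0.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("require 0 <= rho <= 1")
        if not -1.0 <= self.omega <= 1.0:
            raise ValueError("require -1 <= omega <= 1")
        if self.refresh_rate < 0:
            raise ValueError("refresh_rate must be non-negative")
        if not 0.0 <= self.refresh_eta < 1.0:
            raise ValueError("require 0 <= refresh_eta < 1")
        if self.refresh_kappa < 0:
            raise ValueError("refresh_kappa must be non-negative")


@dataclasses.dataclass
class ReorientConfig:
    """Coefficients of the reorientation family.

    The event rate is s ||grad U|| (1 + h cos theta) and the new
    (gradient-relative) bearing has density
    (1/2pi)(1 + a cos theta' + b cos(theta' - theta)).  Consistency with
    the target requires h - a - b h/2 = 1; positivity requires |h| <= 1 and
    |a| + |b| <= 1.  rho_speed correlates speeds before/after the event.
    """

    a: float
    b: float
    h: float
    sigma: float = 1.0
    rho_speed: float = 0.0
    refresh_rate: float = 0.0
    refresh_eta: float = 0.0
    refresh_kappa: float = 0.0

    def __post_init__(self):
        if abs(self.h) > 1.0 + 1e-12:
            raise ValueError("require |h| <= 1")
        if abs(self.a) + abs(self.b) > 1.0 + 1e-12:
            raise ValueError("require |a| + |b| <= 1")
        resid = self.h - self.a - self.b * self.h / 2.0 - 1.0
        if abs(resid) > 1e-12:
            raise ValueError(f"coefficients violate h - a - b h/2 = 1 (residual {resid:.3e})")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0.0 <= self.rho_speed < 1.0:
            raise ValueError("require 0 <= rho_speed < 1")
        if self.refresh_rate < 0 or self.refresh_kappa < 0 or not 0.0 <= self.refresh_eta < 1.0:
            raise ValueError("invalid refreshment parameters")


#: The extremal (a, b, h) solutions of the consistency constraint, plus the
#: isotropic boundary case a = b = 0.
TABLE1 = {
    "i": (-1.0 / 3.0, 2.0 / 3.0, 1.0),
    "ii": (-1.0, 0.0, 0.0),
    "iii": (0.0, -1.0, 2.0 / 3.0),
    "iv": (1.0 / 3.0, -2.0 / 3.0, 1.0),
    "v": (0.0, 0.0, 1.0),
}


# ---------------------------------------------------------------------------
# event-time velocity updates


def canonical_rate(target: Target, x, v) -> float:
    """Canonical bounce rate max{0, grad U(x) . v} (units 1/time)."""
    g = np.asarray(target.grad_U(x), float)
    return max(0.0, float(g @ np.asarray(v, float)))


def bps_reflect(v, g):
    """Deterministic BPS reflection: negate the component of v along g."""
    v = np.asarray(v, float)
    g = np.asarray(g, float)
    gg = g @ g
    if gg == 0.0:
        raise ValueError("cannot reflect off a zero gradient")
    return v - 2.0 * (v @ g) / gg * g


def _orth_basis(u: np.ndarray) -> np.ndarray:
    """Orthonormal basis of {u}^perp as columns; u must be a unit vector."""
    d = u.size
    _, _, vt = np.linalg.svd(u.reshape(1, d))
    return vt[1:].T  # (d, d-1)


def gbps_bounce(v, g, sigma: float, rng: np.random.Generator):
    """Generalized-BPS bounce: reflect the parallel part, resample the rest.

    v' = -v1 + u with u ~ Normal(0, sigma^2 I_{d-1}) in the subspace
    orthogonal to g.
    """
    v = np.asarray(v, float)
    g = np.asarray(g, float)
    norm_g = np.linalg.norm(g)
    if norm_g == 0.0:
        raise ValueError("cannot bounce off a zero gradient")
    if v.size < 2:
        raise ValueError("GBPS bounce requires dimension >= 2")
    u = g / norm_g
    v1 = (v @ u) * u
    basis = _orth_basis(u)
    noise = basis @ (sigma * rng.standard_normal(v.size - 1))
    return -v1 + noise


def _perp(u: np.ndarray) -> np.ndarray:
    """u rotated by +pi/2 (the orthogonal-rotation convention)."""
    return np.array([-u[1], u[0]])


def halfspace_bounce(v, g, cfg: BounceConfig, rng: np.random.Generator):
    """Half-space bounce (d = 2): Rice parallel speed, AR orthogonal part.

    Decompose v = s1 u + c2 u_perp with u = g/||g|| (s1 > 0 at an event by
    the canonical rate).  The new parallel speed r1 has a Rice(rho s1,
    sigma sqrt(1-rho^2)) law and points against the gradient, v1' = -r1 u;
    the orthogonal coefficient updates as c2' = omega c2 +
    sqrt(1-omega^2) sigma xi.  The support of v' is the half-plane
    {v' : g . v' < 0}.
    """
    v = np.asarray(v, float)
    g = np.asarray(g, float)
    if v.size != 2:
        raise ValueError("half-space bounce is two-dimensional")
    norm_g = np.linalg.norm(g)
    if norm_g == 0.0:
        raise ValueError("cannot bounce off a zero gradient")
    u = g / norm_g
    s1 = v @ u
    if s1 <= 0:
        raise ValueError("half-space bounce requires grad U . v > 0 at the event")
    c2 = v @ _perp(u)
    r1 = rice_sample(cfg.rho * s1, cfg.sigma * np.sqrt(1.0 - cfg.rho ** 2), rng)
    c2_new = cfg.omega * c2 + np.sqrt(1.0 - cfg.omega ** 2) * cfg.sigma * rng.standard_normal()
    return -r1 * u + c2_new * _perp(u)


def reorientation_rate(target: Target, x, v, cfg: ReorientConfig) -> float:
    """Reorientation rate s ||grad U|| (1 + h cos theta), theta gradient-relative.

    Since s ||grad U|| cos theta = v . grad U, this is ||grad U|| s +
    h (v . grad U), non-negative whenever |h| <= 1.  A zero gradient (an
    exact mode) gives rate zero; only refreshment operates there.
    """
    g = np.asarray(target.grad_U(x), float)
    v = np.asarray(v, float)
    norm_g = np.linalg.norm(g)
    if norm_g == 0.0:
        return 0.0
    s = np.linalg.norm(v)
    return float(s * norm_g + cfg.h * (v @ g))


def reorientation_bearing_density(theta_new, theta, a: float, b: float):
    """Density (1/2pi)(1 + a cos th' + b cos(th' - th)) on (-pi, pi].

    Bearings are measured relative to the gradient direction at the event.
    """
    theta_new = np.asarray(theta_new, float)
    out = (1.0 + a * np.cos(theta_new) + b * np.cos(theta_new - theta)) / (2.0 * np.pi)
    return float(out) if out.ndim == 0 else out


def reorientation_bearing_sample(theta_abs: float, x, target: Target, cfg: ReorientConfig,
                                 rng: np.random.Generator, max_attempts: int = 100_000) -> float:
    """Draw the new absolute bearing at a reorientation event.

    Works in the gradient-relative frame: the incoming bearing is rotated
    by -arg(grad U(x)), a new relative bearing is drawn by rejection from
    the cosine-family density (uniform envelope (1 + |a| + |b|)/2pi), and
    the result is rotated back to the absolute frame.
    """
    g = np.asarray(target.grad_U(x), float)
    ref = np.arctan2(g[1], g[0])
    theta_rel = wrap_angle(theta_abs - ref)
    bound = (1.0 + abs(cfg.a) + abs(cfg.b)) / (2.0 * np.pi)
    for _ in range(max_attempts):
        prop = rng.uniform(-np.pi, np.pi)
        if rng.random() * bound < reorientation_bearing_density(prop, theta_rel, cfg.a, cfg.b):
            return wrap_angle(prop + ref)
    raise RuntimeError(f"bearing rejection sampler exceeded {max_attempts} attempts")


# ---------------------------------------------------------------------------
# the uniformisation/thinning simulation engine


def _refresh_velocity(v, cfg, rng):
    """Refreshment update preserving Normal(0, sigma^2 I) velocities."""
    v = np.asarray(v, float)
    d = v.size
    if d == 2:
        s = np.linalg.norm(v)
        theta = np.arctan2(v[1], v[0])
        s_new = rice_refresh_speed(s, cfg.sigma, cfg.refresh_eta, rng)
        th_new = vonmises_turn(theta, cfg.refresh_kappa, rng)
        return s_new * np.array([np.cos(th_new), np.sin(th_new)])
    if cfg.refresh_eta != 0.0 or cfg.refresh_kappa != 0.0:
        raise ValueError("autocorrelated refreshment is only defined for d = 2")
    return cfg.sigma * rng.standard_normal(d)


def simulate_pdmp(target: Target, model: str, cfg, x0, v0, t_end: float,
                  seed: int | None = None, horizon: float = 1.0,
                  rng: np.random.Generator | None = None) -> PDMPPath:
    """Exact event-time simulation of a velocity-jump model by thinning.

    Along each linear segment, candidate event times come from a Poisson
    process at a dominating rate valid over a lookahead window of length
    ``horizon``; each candidate at time t is accepted with probability
    rate(x + t v, v) / bound.  Refreshment runs on an independent
    exponential clock at ``cfg.refresh_rate``.  The dominating rate uses
    the target's analytic segment gradient bound; if the true rate ever
    exceeds it, a :class:`ThinningBoundError` is raised.

    model: "bps", "gbps", "halfspace" (canonical bounce rates) or
    "reorient" (the smooth-rate reorientation family).
    """
    if model not in ("bps", "gbps", "halfspace", "reorient"):
        raise ValueError(f"unknown model {model!r}")
    if model == "reorient" and not isinstance(cfg, ReorientConfig):
        raise TypeError("reorient model needs a ReorientConfig")
    if model in ("bps", "gbps", "halfspace") and not isinstance(cfg, BounceConfig):
        raise TypeError(f"{model} model needs a BounceConfig")
    if rng is None:
        rng = np.random.default_rng(seed)
    x = np.atleast_1d(np.asarray(x0, float)).copy()
    v = np.atleast_1d(np.asarray(v0, float)).copy()
    d = x.size
    if model in ("halfspace", "reorient") and d != 2:
        raise ValueError(f"{model} model is two-dimensional")

    if model == "reorient":
        def rate(pos, vel):
            return reorientation_rate(target, pos, vel, cfg)

        def rate_bound(pos, vel, h):
            s = np.linalg.norm(vel)
            return s * (1.0 + abs(cfg.h)) * target.grad_norm_bound(pos, vel, h)
    else:
        def rate(pos, vel):
            return canonical_rate(target, pos, vel)

        def rate_bound(pos, vel, h):
            return np.linalg.norm(vel) * target.grad_norm_bound(pos, vel, h)

    def jump(pos, vel):
        g = np.asarray(target.grad_U(pos), float)
        if model == "bps":
            return bps_reflect(vel, g), "bounce"
        if model == "gbps":
            return gbps_bounce(vel, g, cfg.sigma, rng), "bounce"
        if model == "halfspace":
            return halfspace_bounce(vel, g, cfg, rng), "bounce"
        s = np.linalg.norm(vel)
        theta = np.arctan2(vel[1], vel[0])
        s_new = speed_update_sample(s, cfg.sigma, cfg.rho_speed, rng)
        th_new = reorientation_bearing_sample(theta, pos, target, cfg, rng)
        return s_new * np.array([np.cos(th_new), np.sin(th_new)]), "reorientation"

    lam0 = cfg.refresh_rate
    events: List[EventRecord] = []
    t = 0.0
    next_refresh = t + rng.exponential(1.0 / lam0) if lam0 > 0 else np.inf

    while t < t_end:
        window_end = min(t + horizon, next_refresh, t_end)
        bound = rate_bound(x, v, window_end - t)
        accepted = None
        if bound > 0.0:
            tau = t + rng.exponential(1.0 / bound)
            while tau < window_end:
                pos = x + (tau - t) * v
                lam = rate(pos, v)
                if lam > bound * (1.0 + 1e-9):
                    raise ThinningBoundError(
                        f"event rate {lam:.6g} exceeded the dominating rate {bound:.6g} "
                        f"at t = {tau:.6g}"
                    )
                if rng.random() * bound < lam:
                    accepted = tau
                    break
                tau += rng.exponential(1.0 / bound)
        if accepted is not None:
            pos = x + (accepted - t) * v
            v_new, kind = jump(pos, v)
            events.append(EventRecord(accepted, kind, pos, v.copy(), v_new))
            t, x, v = accepted, pos, v_new
            continue
        x = x + (window_end - t) * v
        t = window_end
        if t == next_refresh and t < t_end:
            v_new = _refresh_velocity(v, cfg, rng)
            events.append(EventRecord(t, "refresh", x.copy(), v.copy(), v_new))
            v = v_new
            next_refresh = t + rng.exponential(1.0 / lam0)

    return PDMPPath(np.atleast_1d(np.asarray(x0, float)), np.atleast_1d(np.asarray(v0, float)),
                    0.0, events, t_end, seed)


def path_position_at(path: PDMPPath, t):
    """Piecewise-linear interpolation of the path position at time(s) t."""
    return path.position_at(t)
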