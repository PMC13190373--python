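"""Stationarity diagnostics: does a simulated track match its target?

The models in this package are consistent by construction: the long-run
location law of every simulator is the utilisation distribution it was
built from.  The checks here operationalise that claim.  Position samples
(after burn-in, thinned to roughly independent spacing) are compared
against the quadrature-normalised target marginal with a one-sample
Kolmogorov–Smirnov test per coordinate, alongside empirical versus target
moments; switching runs additionally report per-state conditional KS
tests and state occupancy, and PDMP paths report event-rate summaries.

A caveat inherent to single-trajectory diagnostics: consecutive samples
are autocorrelated, so KS p-values are calibrated only when the thinning
interval is comfortably larger than the mixing time.  The fixtures record
thinning choices for which the reference runs are calibrated.
"""

from __future__ import annotations

import json
from typing import Optional

import numpy as np
from scipy import stats

from .diffusions import Trajectory
from .pdmp import PDMPPath
from .targets import MultiStateTarget, ProductTarget, Target

__all__ = ["marginal_cdf", "quadrature_moments", "diagnose"]


def marginal_cdf(target, axis: int = 0, lo: float = -60.0, hi: float = 60.0, n: int = 4001):
    """CDF of one position coordinate of the target, normalised by quadrature.

    Separable targets use the analytic per-axis CDF; one-dimensional
    targets known only up to proportionality are normalised on a 4001-point
    grid over [lo, hi] (the default window comfortably covers every
    built-in fixture target).
    """
    if isinstance(target, ProductTarget):
        ax = target.axes[axis]
        return ax.cdf
    if isinstance(target, Target) and target.dim == 1:
        grid = np.linspace(lo, hi, n)
        logp = np.asarray(target.log_density(grid[:, None]), float)
        p = np.exp(logp - logp.max())
        cdf_vals = np.concatenate([[0.0], np.cumsum((p[1:] + p[:-1]) / 2 * np.diff(grid))])
        cdf_vals /= cdf_vals[-1]

        def cdf(x):
            return np.interp(np.asarray(x, float), grid, cdf_vals)

        return cdf
    raise NotImplementedError(
        "marginal CDFs are available for separable targets and 1-D targets")


def quadrature_moments(target, axis: int = 0, lo: float = -60.0, hi: float = 60.0, n: int = 4001):
    """Mean and variance of one coordinate of the (normalised) target."""
    if isinstance(target, ProductTarget):
        ax = target.axes[axis]
        return ax.mean, ax.var
    grid = np.linspace(lo, hi, n)
    logp = np.asarray(target.log_density(grid[:, None]), float)
    p = np.exp(logp - logp.max())
    p /= np.trapezoid(p, grid)
    mean = np.trapezoid(grid * p, grid)
    var = np.trapezoid((grid - mean) ** 2 * p, grid)
    return float(mean), float(var)


def _position_samples(data, position_idx=None):
    if isinstance(data, Trajectory):
        idx = position_idx
        if idx is None:
            idx = [i for i, c in enumerate(data.columns) if c in ("x", "y") or c.startswith("x")]
            if not idx:
                idx = list(range(data.states.shape[1]))
        return data.states[:, list(idx)], data
    if isinstance(data, PDMPPath):
        raise TypeError("resample a PDMPPath onto a grid first (path.sample_grid(dt))")
    arr = np.atleast_2d(np.asarray(data, float))
    return arr, None


def diagnose(data, target, burn_in: float = 0.1, thin: int = 1,
             position_idx=None, states: Optional[np.ndarray] = None,
             events=None, lo: float = -60.0, hi: float = 60.0,
             alpha: float = 0.01, min_samples: int = 500) -> dict:
    """Compare a simulated track against its target distribution.

    Parameters
    ----------
    data:
        A :class:`Trajectory`, or a raw (m, d) array of position samples.
    target:
        The target; for switching runs pass the :class:`MultiStateTarget`
        together with the per-sample ``states`` array.
    burn_in:
        Fraction of initial samples discarded.
    thin:
        Keep every ``thin``-th sample after burn-in.
    events:
        Optional event list (PDMP) for rate summaries.

    Returns a JSON-serialisable report dict.
    """
    samples, traj = _position_samples(data, position_idx)
    if states is None and traj is not None and "state" in traj.discrete:
        states = traj.discrete["state"]
    start = int(burn_in * samples.shape[0])
    kept = samples[start::thin]
    kept_states = None if states is None else np.asarray(states)[start::thin]
    if kept.shape[0] < min_samples:
        raise ValueError(
            f"only {kept.shape[0]} post-burn-in samples (< {min_samples}); "
            "lengthen the run or reduce thinning")

    report: dict = {"n_samples": int(kept.shape[0]), "burn_in": burn_in, "thin": thin,
                    "alpha": alpha, "coordinates": []}

    if isinstance(target, MultiStateTarget):
        if kept_states is None:
            raise ValueError("a multi-state target needs per-sample states")
        report["states"] = []
        post = []
        for s in range(target.n_states):
            mask = kept_states == s
            entry: dict = {"state": s, "occupancy": float(np.mean(mask))}
            if np.sum(mask) >= min_samples:
                cond = target.conditional(s)
                cdf = marginal_cdf(cond, 0, lo, hi)
                ks = stats.ks_1samp(kept[mask, 0], cdf)
                m, v = quadrature_moments(cond, 0, lo, hi)
                entry.update({"ks_stat": float(ks.statistic), "ks_pvalue": float(ks.pvalue),
                              "reject": bool(ks.pvalue < alpha),
                              "mean": float(kept[mask, 0].mean()), "target_mean": m,
                              "var": float(kept[mask, 0].var()), "target_var": v})
            report["states"].append(entry)
            post.append(np.mean(mask))
        return report

    d = kept.shape[1]
    for j in range(d):
        cdf = marginal_cdf(target, j, lo, hi)
        ks = stats.ks_1samp(kept[:, j], cdf)
        m, v = quadrature_moments(target, j, lo, hi)
        report["coordinates"].append({
            "axis": j,
            "ks_stat": float(ks.statistic),
            "ks_pvalue": float(ks.pvalue),
            "reject": bool(ks.pvalue < alpha),
            "mean": float(kept[:, j].mean()),
            "target_mean": m,
            "var": float(kept[:, j].var()),
            "target_var": v,
        })

    if events is not None:
        span = None
        kinds = {}
        for e in events:
            kinds[e.kind] = kinds.get(e.kind, 0) + 1
        if events:
            span = events[-1].time - events[0].time
        report["events"] = {
            "counts": kinds,
            "rate_per_time": {k: (c / span if span else None) for k, c in kinds.items()},
        }
    return report


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=1)
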