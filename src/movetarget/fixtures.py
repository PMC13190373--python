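"""Reference model configurations and a one-call runner.

Each fixture is a complete, serialisable run configuration for one of the
package's reference setups:

* ``fig1``   -- 1-D inverse-density diffusion (no drift, rate 1/pi) on a
  standard normal target;
* ``fig2a/b/c`` -- constant-speed polar diffusions on a bivariate normal
  target with covariance diag(2, 1), bearing diffusivity 0.1 / 0.5 / 2.5;
* ``fig3a-d``   -- velocity-jump models on a bimodal target (x: logistic
  mixture, locations +-1, scale 1, weights 0.6/0.4; y: logistic(0, 1)):
  BPS, GBPS, and two half-space samplers, the second with a higher
  refreshment rate and a much higher turning concentration;
* ``fig4``   -- two-state kinetic Langevin switching (Laplace covariates
  tau = 10 centred at -+10, intercepts log(5/3) and 0, selection
  coefficients 2 on the own-state covariate, symmetric switching at
  psi = sqrt(0.0015), kinetic parameters alpha = 1, gamma = 5);
* ``fig5``   -- two interacting individuals on the bimodal min-Laplace
  target (beta_1 = 2, tau = 10) with Gaussian interaction kernel scale 2,
  kinetic dynamics alpha = 0.01, gamma = 0.05.

Where a reference setup does not pin a value (event-model sigma/rho/omega,
refreshment parameters, horizons, initial conditions), the fixture records
an explicit documented choice; see docs/methods.md.
"""

from __future__ import annotations

import dataclasses
import json
import math

import numpy as np

from . import diffusions, interactions, pdmp, switching, targets

__all__ = ["RunConfig", "FIXTURE_NAMES", "make_fixture", "run_fixture"]

FIXTURE_NAMES = ("fig1", "fig2a", "fig2b", "fig2c", "fig3a", "fig3b", "fig3c", "fig3d",
                 "fig4", "fig5")


@dataclasses.dataclass
class RunConfig:
    name: str
    model: str
    target: dict
    params: dict
    sim: dict

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(name=d["name"], model=d["model"], target=dict(d["target"]),
                   params=dict(d["params"]), sim=dict(d["sim"]))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1)

    @classmethod
    def from_json(cls, s: str) -> "RunConfig":
        return cls.from_dict(json.loads(s))

    def build_target(self):
        return targets.target_from_config(self.target)

    def validate(self):
        self.build_target()
        if self.model not in ("inverse_density", "polar", "bps", "gbps", "halfspace",
                              "reorient", "switching", "interacting"):
            raise ValueError(f"unknown model id {self.model!r}")
        if self.sim.get("t_end", 0) <= 0:
            raise ValueError("t_end must be positive")
        return self


_FIG3_TARGET = {
    "type": "product",
    "axes": [
        {"dist": "logistic_mixture", "locs": [-1.0, 1.0], "scales": [1.0, 1.0],
         "weights": [0.6, 0.4]},
        {"dist": "logistic", "loc": 0.0, "scale": 1.0},
    ],
}


def make_fixture(name: str) -> RunConfig:
    if name == "fig1":
        return RunConfig(
            name, "inverse_density",
            target={"type": "product", "axes": [{"dist": "normal", "mu": 0.0, "sigma": 1.0}]},
            params={"alpha": 1.0, "reflect": [-4.0, 4.0]},
            sim={"dt": 0.0025, "t_end": 100.0, "seed": 1, "x0": [0.0]},
        ).validate()
    if name in ("fig2a", "fig2b", "fig2c"):
        alpha_theta = {"fig2a": 0.1, "fig2b": 0.5, "fig2c": 2.5}[name]
        return RunConfig(
            name, "polar",
            target={"type": "product", "axes": [
                {"dist": "normal", "mu": 0.0, "sigma": math.sqrt(2.0)},
                {"dist": "normal", "mu": 0.0, "sigma": 1.0}]},
            params={"constant_speed": True, "sigma": 1.0, "gamma_s": 0.0,
                    "alpha_theta": alpha_theta, "s0": 1.0, "theta0": 0.0},
            sim={"dt": 0.01, "t_end": 100.0, "seed": 1, "x0": [0.0, 0.0]},
        ).validate()
    if name in ("fig3a", "fig3b", "fig3c", "fig3d"):
        cfg = {
            "fig3a": {"sigma": 1.0, "rho": 1.0, "omega": 1.0, "refresh_rate": 0.5,
                      "refresh_eta": 0.0, "refresh_kappa": 0.0},
            "fig3b": {"sigma": 1.0, "rho": 1.0, "omega": 0.0, "refresh_rate": 0.0,
                      "refresh_eta": 0.0, "refresh_kappa": 0.0},
            "fig3c": {"sigma": 1.0, "rho": 0.5, "omega": 0.5, "refresh_rate": 0.2,
                      "refresh_eta": 0.5, "refresh_kappa": 4.0},
            "fig3d": {"sigma": 1.0, "rho": 0.5, "omega": 0.5, "refresh_rate": 1.5,
                      "refresh_eta": 0.5, "refresh_kappa": 20.0},
        }[name]
        model = {"fig3a": "bps", "fig3b": "gbps", "fig3c": "halfspace",
                 "fig3d": "halfspace"}[name]
        return RunConfig(
            name, model, target=dict(_FIG3_TARGET), params=cfg,
            sim={"t_end": 200.0, "seed": 1, "x0": [0.0, 0.0]},
        ).validate()
    if name == "fig4":
        return RunConfig(
            name, "switching",
            target={"type": "multistate", "dim": 1,
                    "beta0": [math.log(5.0 / 3.0), 0.0],
                    "beta": [[2.0, 0.0], [0.0, 2.0]],
                    "covariates": [
                        {"family": "laplace", "mu": [-10.0], "tau": 10.0},
                        {"family": "laplace", "mu": [10.0], "tau": 10.0}]},
            params={"psi": math.sqrt(0.0015), "gamma": 5.0, "alpha": 1.0},
            # switching is slow (equilibrium switch rate ~2.5e-4/time); the
            # horizon must cover many dwells for occupancy to equilibrate
            sim={"dt": 0.02, "t_end": 30000.0, "seed": 1, "x0": [-10.0], "v0": [0.0], "s0": 0},
        ).validate()
    if name == "fig5":
        return RunConfig(
            name, "interacting",
            target={"type": "linexp", "dim": 1, "beta": [2.0],
                    "covariates": [{"family": "minlaplace", "muA": [-10.0], "muB": [10.0],
                                    "tau": 10.0}]},
            params={"kernel_scale": 2.0, "n": 2, "movement": "kinetic",
                    "gamma": 0.05, "alpha": 0.01, "grid": [-30.0, 30.0, 2001]},
            sim={"dt": 0.1, "t_end": 2000.0, "seed": 1, "x0s": [-10.0, -5.0]},
        ).validate()
    raise ValueError(f"unknown fixture {name!r}; known: {', '.join(FIXTURE_NAMES)}")


def run_fixture(cfg: RunConfig, seed: int | None = None, t_end: float | None = None,
                record_every: int = 1):
    """Execute a run configuration; returns a Trajectory or a PDMPPath."""
    cfg.validate()
    seed = cfg.sim.get("seed", 1) if seed is None else seed
    t_end = cfg.sim.get("t_end") if t_end is None else t_end
    target = cfg.build_target()
    p = cfg.params

    if cfg.model == "inverse_density":
        spec = diffusions.position_dependent_spec(
            target, alpha=p.get("alpha", 1.0),
            reflect=tuple(p["reflect"]) if "reflect" in p else None)
        return diffusions.simulate_em(spec, np.asarray(cfg.sim["x0"], float),
                                      cfg.sim["dt"], t_end, seed=seed,
                                      record_every=record_every)
    if cfg.model == "polar":
        spec = diffusions.polar_velocity_spec(
            target, sigma=p.get("sigma", 1.0), gamma_s=p.get("gamma_s", 1.0),
            alpha_theta=p["alpha_theta"], constant_speed=p.get("constant_speed", False))
        z0 = np.concatenate([np.asarray(cfg.sim["x0"], float),
                             [p.get("s0", 1.0), p.get("theta0", 0.0)]])
        return diffusions.simulate_em(spec, z0, cfg.sim["dt"], t_end, seed=seed,
                                      record_every=record_every)
    if cfg.model in ("bps", "gbps", "halfspace"):
        bc = pdmp.BounceConfig(**p)
        rng = np.random.default_rng(seed)
        v0 = bc.sigma * rng.standard_normal(target.dim)
        return pdmp.simulate_pdmp(target, cfg.model, bc, np.asarray(cfg.sim["x0"], float),
                                  v0, t_end, seed=None, rng=rng)
    if cfg.model == "reorient":
        rc = pdmp.ReorientConfig(**p)
        rng = np.random.default_rng(seed)
        v0 = rc.sigma * rng.standard_normal(2)
        return pdmp.simulate_pdmp(target, "reorient", rc, np.asarray(cfg.sim["x0"], float),
                                  v0, t_end, seed=None, rng=rng)
    if cfg.model == "switching":
        specs = [diffusions.kinetic_langevin_spec(target.conditional(s), p["gamma"], p["alpha"])
                 for s in range(target.n_states)]
        model = switching.SwitchingModel(
            target, specs, switching.symmetric_rate_fn(target, p["psi"]))
        z0 = np.concatenate([np.asarray(cfg.sim["x0"], float),
                             np.asarray(cfg.sim.get("v0", [0.0] * target.dim), float)])
        return switching.simulate_switching(model, z0, cfg.sim.get("s0", 0),
                                            cfg.sim["dt"], t_end, seed=seed,
                                            record_every=record_every)
    if cfg.model == "interacting":
        jt = interactions.JointTarget(target, p["kernel_scale"], n=p.get("n", 2),
                                      grid=tuple(p.get("grid", (-30.0, 30.0, 2001))))
        return interactions.simulate_interacting(
            jt, p.get("movement", "kinetic"),
            {"gamma": p["gamma"], "alpha": p.get("alpha", 1.0)},
            np.asarray(cfg.sim["x0s"], float), cfg.sim["dt"], t_end, seed=seed,
            record_every=record_every)
    raise ValueError(f"unknown model id {cfg.model!r}")
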