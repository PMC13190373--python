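"""Velocity-jump models: bounces, reorientations, refreshment, thinning engine."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import movetarget as mt
from movetarget.pdmp import TABLE1, BounceConfig, ReorientConfig


@pytest.fixture
def bounce_cfg():
    return BounceConfig(sigma=1.0, rho=0.5, omega=0.5, refresh_rate=0.2,
                        refresh_eta=0.5, refresh_kappa=4.0)


def test_canonical_rate_examples(std_normal_2d):
    # grad U = x for the standard normal
    assert mt.canonical_rate(std_normal_2d, [1.0, 0.0], [0.0, 1.0]) == 0.0
    assert mt.canonical_rate(std_normal_2d, [1.0, 0.0], [-1.0, 0.0]) == 0.0
    assert mt.canonical_rate(std_normal_2d, [1.0, 0.0], [1.0, 0.0]) == pytest.approx(1.0)


def test_reflect_parallel_and_orthogonal():
    g = np.array([2.0, 0.0])
    assert np.allclose(mt.bps_reflect([3.0, 0.0], g), [-3.0, 0.0])
    assert np.allclose(mt.bps_reflect([0.0, 1.5], g), [0.0, 1.5])
    with pytest.raises(ValueError):
        mt.bps_reflect([1.0, 0.0], [0.0, 0.0])


@given(st.lists(st.floats(-5, 5), min_size=2, max_size=4),
       st.lists(st.floats(-5, 5), min_size=2, max_size=4))
def test_reflect_is_an_isometric_involution(v, g):
    n = min(len(v), len(g))
    v = np.asarray(v[:n])
    g = np.asarray(g[:n])
    if np.linalg.norm(g) < 1e-6:
        return
    out = mt.bps_reflect(v, g)
    assert np.linalg.norm(out) == pytest.approx(np.linalg.norm(v), abs=1e-9)
    assert np.allclose(mt.bps_reflect(out, g), v, atol=1e-9)


def test_gbps_bounce_structure(rng):
    g = np.array([1.0, 2.0])
    u = g / np.linalg.norm(g)
    v = np.array([0.8, -0.4])
    draws = np.array([mt.gbps_bounce(v, g, 1.3, rng) for _ in range(20_000)])
    # parallel component always exactly negated
    par = draws @ u
    assert np.allclose(par, -(v @ u), atol=1e-12)
    # orthogonal component ~ Normal(0, sigma^2)
    perp = draws @ np.array([-u[1], u[0]])
    assert stats.kstest(perp, "norm", args=(0, 1.3)).pvalue > 0.01


def test_gbps_zero_noise_keeps_reflected_parallel_part(rng):
    g = np.array([0.0, 1.0])
    v = np.array([0.3, 0.9])
    out = mt.gbps_bounce(v, g, 0.0, rng)
    assert np.allclose(out, [0.0, -0.9])


def test_halfspace_bounce_limits(rng):
    g = np.array([0.7, -0.3])
    v = np.array([1.0, 0.5])
    if g @ v < 0:
        v = -v
    # rho = omega = 1: the deterministic BPS reflection
    out = mt.halfspace_bounce(v, g, BounceConfig(sigma=1.0, rho=1.0, omega=1.0), rng)
    assert np.allclose(out, mt.bps_reflect(v, g), atol=1e-12)
    # rho = 1, omega = 0: GBPS (parallel part deterministic, orthogonal fresh)
    u = g / np.linalg.norm(g)
    outs = np.array([mt.halfspace_bounce(v, g, BounceConfig(sigma=1.0, rho=1.0, omega=0.0), rng)
                     for _ in range(20_000)])
    assert np.allclose(outs @ u, -(v @ u), atol=1e-12)
    perp = outs @ np.array([-u[1], u[0]])
    assert stats.kstest(perp, "norm", args=(0, 1.0)).pvalue > 0.01


def test_halfspace_bounce_flips_gradient_component(rng, bounce_cfg):
    g = np.array([1.0, 1.0])
    v = np.array([0.9, 0.2])
    draws = np.array([mt.halfspace_bounce(v, g, bounce_cfg, rng) for _ in range(10_000)])
    assert np.all(draws @ g < 0)


def test_bounce_config_validation():
    with pytest.raises(ValueError):
        BounceConfig(sigma=0.0)
    with pytest.raises(ValueError):
        BounceConfig(rho=1.2)
    with pytest.raises(ValueError):
        BounceConfig(omega=-1.5)
    with pytest.raises(ValueError):
        BounceConfig(refresh_eta=1.0)


# -- reorientation family ----------------------------------------------------


@pytest.mark.parametrize("row", list(TABLE1), ids=lambda r: f"case-{r}")
def test_reorient_coefficients_satisfy_constraint(row):
    a, b, h = TABLE1[row]
    cfg = ReorientConfig(a, b, h)  # validation runs in the constructor
    assert abs(cfg.h - cfg.a - cfg.b * cfg.h / 2 - 1.0) < 1e-12
    assert abs(cfg.h) <= 1 and abs(cfg.a) + abs(cfg.b) <= 1


@pytest.mark.parametrize("bad", [
    {"a": 0.0, "b": 0.0, "h": 0.5},     # violates the consistency constraint
    {"a": -1.5, "b": 0.5, "h": 1.0},    # violates |a| + |b| <= 1
    {"a": -1.0, "b": 0.0, "h": 2.0},    # violates |h| <= 1 (and the constraint)
])
def test_reorient_config_rejects_invalid(bad):
    with pytest.raises(ValueError):
        ReorientConfig(**bad)


def test_reorientation_rate_examples(std_normal_2d):
    # h = 0: rate independent of bearing
    cfg0 = ReorientConfig(-1.0, 0.0, 0.0)
    x = np.array([3.0, 0.0])  # ||grad U|| = 3
    r1 = mt.reorientation_rate(std_normal_2d, x, np.array([0.0, 2.0]), cfg0)
    r2 = mt.reorientation_rate(std_normal_2d, x, np.array([-2.0, 0.0]), cfg0)
    assert r1 == pytest.approx(6.0)
    assert r2 == pytest.approx(6.0)
    # h = 1, bearing opposite to the gradient: rate vanishes
    cfg1 = ReorientConfig(0.0, 0.0, 1.0)
    away = mt.reorientation_rate(std_normal_2d, x, np.array([-2.0, 0.0]), cfg1)
    assert away == pytest.approx(0.0, abs=1e-12)
    # h = 1, bearing along the gradient, s = 2, ||grad U|| = 3 -> 12
    toward = mt.reorientation_rate(std_normal_2d, x, np.array([2.0, 0.0]), cfg1)
    assert toward == pytest.approx(12.0)
    # at an exact mode the rate is zero
    assert mt.reorientation_rate(std_normal_2d, np.zeros(2), np.array([1.0, 0.0]), cfg1) == 0.0


@pytest.mark.parametrize("row", list(TABLE1), ids=lambda r: f"case-{r}")
def test_bearing_density_normalised(row):
    a, b, _ = TABLE1[row]
    grid = np.linspace(-np.pi, np.pi, 8193)
    dens = mt.reorientation_bearing_density(grid, 0.7, a, b)
    assert np.all(dens >= -1e-12)
    assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-10)


def test_bearing_density_shapes():
    grid = np.linspace(-np.pi, np.pi, 1001)
    # isotropic case
    assert np.allclose(mt.reorientation_bearing_density(grid, 0.3, 0.0, 0.0),
                       1 / (2 * np.pi))
    # a = -1, b = 0: mode opposite the gradient direction (towards higher density)
    dens = mt.reorientation_bearing_density(grid, 0.3, -1.0, 0.0)
    assert abs(abs(grid[np.argmax(dens)]) - np.pi) < 0.01


def test_bearing_sampler_matches_density(std_normal_2d, rng):
    cfg = ReorientConfig(*TABLE1["i"])
    x = np.array([2.0, 1.0])
    g = std_normal_2d.grad_U(x)
    ref = np.arctan2(g[1], g[0])
    theta_abs = 0.4
    draws = np.array([mt.reorientation_bearing_sample(theta_abs, x, std_normal_2d, cfg, rng)
                      for _ in range(30_000)])
    rel = mt.wrap_angle(draws - ref)
    theta_rel = mt.wrap_angle(theta_abs - ref)
    grid = np.linspace(-np.pi, np.pi, 2001)
    pdf = mt.reorientation_bearing_density(grid, theta_rel, cfg.a, cfg.b)
    cdf_grid = np.concatenate([[0], np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(grid))])
    cdf_grid /= cdf_grid[-1]
    assert stats.ks_1samp(rel, lambda t: np.interp(t, grid, cdf_grid)).pvalue > 0.01


@pytest.mark.parametrize("row", list(TABLE1), ids=lambda r: f"case-{r}")
def test_turn_balance_identity(row):
    """kappa(theta) - int kappa(theta') q(theta | theta') dtheta' = cos(theta):
    the condition under which reorientations leave the target invariant."""
    a, b, h = TABLE1[row]
    thetas = np.linspace(-np.pi, np.pi, 64, endpoint=False)
    grid = np.linspace(-np.pi, np.pi, 4097)
    kappa_grid = 1 + h * np.cos(grid)
    for theta in thetas:
        integral = np.trapezoid(
            kappa_grid * mt.reorientation_bearing_density(theta, grid, a, b), grid)
        resid = (1 + h * np.cos(theta)) - integral - np.cos(theta)
        assert abs(resid) < 1e-8


# -- the thinning engine -----------------------------------------------------


def test_refresh_only_dynamics_has_exponential_gaps(rng):
    """With a flat target the bounce rate vanishes; only refreshment fires,
    and the inter-event times are Exponential(lambda0)."""
    cfg = BounceConfig(sigma=1.0, rho=0.5, omega=0.5, refresh_rate=2.0,
                       refresh_eta=0.3, refresh_kappa=3.0)
    path = mt.simulate_pdmp(mt.UniformTarget(2), "halfspace", cfg,
                            [0.0, 0.0], [1.0, 0.0], 5000.0, seed=2)
    kinds = {e.kind for e in path.events}
    assert kinds == {"refresh"}
    times = np.array([e.time for e in path.events])
    gaps = np.diff(np.concatenate([[0.0], times]))
    assert gaps.size > 5000
    assert stats.kstest(gaps, "expon", args=(0, 0.5)).pvalue > 0.01


def test_rate_bound_violation_is_a_hard_error(std_normal_2d, bounce_cfg):
    """A dominating rate that under-covers the true rate must raise, never
    silently clip the event intensity."""

    class LyingTarget(mt.ProductTarget):
        def grad_norm_bound(self, x, v, horizon):
            return 0.01 * super().grad_norm_bound(x, v, horizon)

    liar = LyingTarget(std_normal_2d.axes)
    with pytest.raises(mt.pdmp.ThinningBoundError):
        mt.simulate_pdmp(liar, "halfspace", bounce_cfg, [3.0, 0.0], [1.0, 0.0],
                         200.0, seed=1)


def test_simulation_is_deterministic_given_seed(bimodal_2d, bounce_cfg):
    a = mt.simulate_pdmp(bimodal_2d, "halfspace", bounce_cfg, [0, 0], [1, 0], 50.0, seed=5)
    b = mt.simulate_pdmp(bimodal_2d, "halfspace", bounce_cfg, [0, 0], [1, 0], 50.0, seed=5)
    assert len(a.events) == len(b.events)
    for ea, eb in zip(a.events, b.events):
        assert ea.time == eb.time and ea.kind == eb.kind
        assert np.array_equal(ea.v_after, eb.v_after)


def test_half_space_property_along_path(bimodal_2d, bounce_cfg):
    path = mt.simulate_pdmp(bimodal_2d, "halfspace", bounce_cfg, [0, 0], [1, 0], 500.0, seed=7)
    n_bounce = 0
    for e in path.events:
        if e.kind == "bounce":
            g = bimodal_2d.grad_U(e.position)
            assert g @ e.v_before > 0
            assert g @ e.v_after < 0
            n_bounce += 1
    assert n_bounce > 50


def test_path_positions_consistent_with_piecewise_linear_flow(bimodal_2d, bounce_cfg):
    path = mt.simulate_pdmp(bimodal_2d, "halfspace", bounce_cfg, [0, 0], [1, 0], 200.0, seed=9)
    pos = path.x0
    t = 0.0
    v = path.v0
    for e in path.events:
        expected = pos + (e.time - t) * v
        assert np.max(np.abs(e.position - expected)) < 1e-10
        pos, t, v = e.position, e.time, e.v_after


def test_path_interpolation(bimodal_2d, bounce_cfg):
    path = mt.simulate_pdmp(bimodal_2d, "halfspace", bounce_cfg, [0, 0], [1, 0], 100.0, seed=3)
    e = path.events[10]
    assert np.allclose(mt.path_position_at(path, e.time), e.position, atol=1e-12)
    # midpoint of a segment is the mean of its endpoints
    e2 = path.events[11]
    mid = 0.5 * (e.time + e2.time)
    expected = 0.5 * (e.position + path.position_at(e2.time))
    assert np.allclose(path.position_at(mid), expected, atol=1e-10)
    with pytest.raises(ValueError):
        path.position_at(1e9)
    # grid resampling reproduces segment slopes equal to stored velocities
    grid = np.linspace(e.time, e2.time, 5)
    if e2.time - e.time > 1e-6:
        pts = path.position_at(grid)
        slopes = np.diff(pts, axis=0) / np.diff(grid)[:, None]
        assert np.allclose(slopes, e.v_after, atol=1e-8)


def test_post_refresh_velocities_are_gaussian(bimodal_2d):
    cfg = BounceConfig(sigma=1.0, rho=0.5, omega=0.5, refresh_rate=0.5,
                       refresh_eta=0.5, refresh_kappa=4.0)
    path = mt.simulate_pdmp(bimodal_2d, "halfspace", cfg, [0, 0], [1, 0], 4000.0, seed=13)
    vs = np.array([e.v_after for e in path.events if e.kind == "refresh"])
    assert vs.shape[0] > 1000
    for j in range(2):
        assert stats.kstest(vs[:, j], "norm", args=(0, 1.0)).pvalue > 0.01


def test_reorient_model_runs_and_targets_velocity_law(std_normal_2d):
    cfg = ReorientConfig(*TABLE1["i"], sigma=1.0, rho_speed=0.5,
                         refresh_rate=0.2, refresh_eta=0.3, refresh_kappa=2.0)
    path = mt.simulate_pdmp(std_normal_2d, "reorient", cfg, [0, 0], [1.0, 0.2],
                            2000.0, seed=15)
    kinds = {e.kind for e in path.events}
    assert "reorientation" in kinds and "refresh" in kinds
    # event-time speeds after reorientations follow the size-biased law
    speeds = np.array([np.linalg.norm(e.v_after) for e in path.events
                       if e.kind == "reorientation"])
    assert speeds.size > 1000
    assert stats.kstest(speeds[::3], "maxwell", args=(0, 1.0)).pvalue > 0.01


def test_pdmp_path_csv_round_trip(tmp_path, bimodal_2d, bounce_cfg):
    path = mt.simulate_pdmp(bimodal_2d, "halfspace", bounce_cfg, [0, 0], [1, 0], 50.0, seed=4)
    out = tmp_path / "events.csv"
    path.to_csv(out, sidecar={"model": "halfspace"})
    assert out.exists() and out.with_suffix(".json").exists()
    traj = path.sample_grid(0.5)
    assert traj.states.shape[1] == 2
    assert traj.times[-1] <= path.t_end
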