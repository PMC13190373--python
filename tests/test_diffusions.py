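"""Targeted diffusion builders and the Euler–Maruyama integrator."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import movetarget as mt
from movetarget.diffusions import wrap_angle


def test_langevin_drift_examples(std_normal_1d):
    spec = mt.langevin_spec(std_normal_1d, 1.0)
    assert spec.drift(np.array([0.0]))[0] == 0.0
    assert spec.drift(np.array([2.0]))[0] == pytest.approx(-1.0)
    assert spec.noise_scale(np.array([2.0]))[0] == pytest.approx(1.0)


def test_langevin_gamma_scaling(std_normal_1d):
    s1 = mt.langevin_spec(std_normal_1d, 1.0)
    s2 = mt.langevin_spec(std_normal_1d, 2.0)
    x = np.array([1.3])
    assert s2.drift(x)[0] == pytest.approx(2 * s1.drift(x)[0])
    assert s2.noise_scale(x)[0] ** 2 == pytest.approx(2 * s1.noise_scale(x)[0] ** 2)


def test_kinetic_drift_coefficients(std_normal_1d):
    # alpha = 1, gamma = 5: dv = -2.5 grad U - 0.2 v
    spec = mt.kinetic_langevin_spec(std_normal_1d, 5.0, 1.0)
    z = np.array([1.0, 2.0])  # x = 1 (grad U = 1), v = 2
    d = spec.drift(z)
    assert d[0] == pytest.approx(2.0)
    assert d[1] == pytest.approx(-2.5 * 1.0 - 0.2 * 2.0)
    assert spec.noise_scale(z)[1] == pytest.approx(1.0)
    # zero drift at a mode with zero velocity
    assert np.allclose(spec.drift(np.array([0.0, 0.0])), 0.0)


def test_kinetic_velocity_variance_flat_target():
    """With no selection pressure the velocity is an OU process with
    stationary per-coordinate variance gamma / 2."""
    flat = mt.UniformTarget(1)
    spec = mt.kinetic_langevin_spec(flat, 2.0, 1.0)
    tr = mt.simulate_em(spec, np.array([0.0, 0.0]), 0.01, 3000.0, seed=5, record_every=25)
    v = tr.states[400:, 1]
    assert abs(v.var() - 1.0) < 0.1


# -- the generic reversible/irreversible builder -----------------------------


def _ma_langevin(target, gamma):
    d = target.dim
    D = 0.5 * gamma * np.eye(d)
    Z = np.zeros((d, d))
    return mt.ma_spec(lambda z: np.asarray(target.grad_U(z)),
                      lambda z: D, lambda z: Z, d,
                      check_points=np.zeros((1, d)))


def _ma_kinetic(target, gamma, alpha):
    d = target.dim
    D = np.zeros((2 * d, 2 * d))
    D[d:, d:] = 0.5 * alpha * np.eye(d)
    Q = np.zeros((2 * d, 2 * d))
    Q[:d, d:] = -0.5 * gamma * np.eye(d)
    Q[d:, :d] = 0.5 * gamma * np.eye(d)

    def grad_H(z):
        x, v = z[:d], z[d:]
        return np.concatenate([np.asarray(target.grad_U(x)), 2.0 * v / gamma])

    return mt.ma_spec(grad_H, lambda z: D, lambda z: Q, 2 * d,
                      check_points=np.zeros((1, 2 * d)))


def test_ma_reduces_to_langevin(std_normal_2d, rng):
    gamma = 1.7
    ref = mt.langevin_spec(std_normal_2d, gamma)
    gen = _ma_langevin(std_normal_2d, gamma)
    for z in rng.uniform(-3, 3, size=(100, 2)):
        assert np.max(np.abs(ref.drift(z) - gen.drift(z))) < 1e-10
        assert np.allclose(ref.noise_scale(z), gen.noise_scale(z))


def test_ma_reduces_to_kinetic(std_normal_1d, rng):
    gamma, alpha = 5.0, 1.0
    ref = mt.kinetic_langevin_spec(std_normal_1d, gamma, alpha)
    gen = _ma_kinetic(std_normal_1d, gamma, alpha)
    for z in rng.uniform(-3, 3, size=(100, 2)):
        assert np.max(np.abs(ref.drift(z) - gen.drift(z))) < 1e-10
        assert np.allclose(ref.noise_scale(z), gen.noise_scale(z))


def test_ma_constant_coefficients_have_zero_divergence(std_normal_2d):
    gamma = 0.8
    gen = _ma_langevin(std_normal_2d, gamma)
    z = np.array([0.4, -1.1])
    # with constant D and Q the drift is exactly -(D+Q) grad H
    expected = -0.5 * gamma * np.asarray(std_normal_2d.grad_U(z))
    assert np.max(np.abs(gen.drift(z) - expected)) < 1e-9


def test_ma_validates_matrix_structure(std_normal_1d):
    bad_D = np.array([[-1.0]])
    with pytest.raises(ValueError, match="positive semi-definite"):
        mt.ma_spec(lambda z: z, lambda z: bad_D, lambda z: np.zeros((1, 1)), 1,
                   check_points=np.zeros((1, 1)))
    bad_Q = np.array([[0.0, 1.0], [1.0, 0.0]])
    with pytest.raises(ValueError, match="skew"):
        mt.ma_spec(lambda z: z, lambda z: np.eye(2), lambda z: bad_Q, 2,
                   check_points=np.zeros((1, 2)))


# -- position-dependent diffusion rate ---------------------------------------


def test_inverse_density_rate_examples():
    target = mt.LinExpTarget([mt.quadratic_covariate([0.0])], [1.0])  # standard normal
    spec = mt.position_dependent_spec(target, alpha=1.0)
    assert np.allclose(spec.drift(np.array([2.0])), 0.0)
    assert spec.noise_scale(np.array([0.0]))[0] == pytest.approx(1.0)
    # exp(-L/2) = exp(x^2 / 4) = e at x = 2
    assert spec.noise_scale(np.array([2.0]))[0] == pytest.approx(np.e)


def test_constant_rate_reduces_to_langevin(rng):
    target = mt.LinExpTarget([mt.laplace_covariate([0.0], 2.0)], [1.5])
    gamma = 0.7
    ref = mt.langevin_spec(target, gamma)
    gen = mt.position_dependent_spec(target, delta=[0.0], delta0=np.log(gamma))
    for x in rng.uniform(-5, 5, size=(50, 1)):
        assert np.allclose(gen.drift(x), ref.drift(x), atol=1e-12)
        assert np.allclose(gen.noise_scale(x), ref.noise_scale(x), atol=1e-12)


# -- polar (speed / bearing) model -------------------------------------------


def test_polar_bearing_drift_example():
    # bivariate normal, covariance diag(2, 1); at (0, 2): grad U = (0, 2)
    target = mt.ProductTarget([mt.Normal1D(0, np.sqrt(2)), mt.Normal1D(0, 1)])
    spec = mt.polar_velocity_spec(target, sigma=1.0, gamma_s=1.0, alpha_theta=0.5)
    z = np.array([0.0, 2.0, 1.0, 0.0])  # s = 1, theta = 0
    d = spec.drift(z)
    assert d[3] == pytest.approx(-2.0)  # (s sin, -s cos) . grad U
    assert d[0] == pytest.approx(1.0)
    assert d[1] == pytest.approx(0.0)


def test_polar_uniform_target_gives_brownian_bearing():
    spec = mt.polar_velocity_spec(mt.UniformTarget(2), sigma=1.0,
                                  gamma_s=0.0, alpha_theta=0.3, constant_speed=True)
    z = np.array([1.0, -2.0, 1.5, 0.7])
    assert spec.drift(z)[3] == 0.0
    assert spec.noise_scale(z)[3] == pytest.approx(np.sqrt(0.3))


@pytest.mark.parametrize("alpha_theta", [0.1, 0.5, 2.5])
def test_polar_constant_speed_is_conserved(std_normal_2d, alpha_theta):
    spec = mt.polar_velocity_spec(std_normal_2d, sigma=1.0, gamma_s=0.0,
                                  alpha_theta=alpha_theta, constant_speed=True)
    tr = mt.simulate_em(spec, np.array([0.0, 0.0, 1.0, 0.0]), 0.01, 20.0, seed=8)
    assert np.all(tr.states[:, 2] == 1.0)


def test_polar_speed_targets_rayleigh(std_normal_2d):
    from scipy import stats
    spec = mt.polar_velocity_spec(std_normal_2d, sigma=1.0, gamma_s=1.0, alpha_theta=0.5)
    tr = mt.simulate_em(spec, np.array([0.0, 0.0, 1.0, 0.0]), 0.0025, 3000.0,
                        seed=9, record_every=400)
    s = tr.states[200:, 2]
    assert stats.kstest(s, "rayleigh").pvalue > 0.01


# -- integrator --------------------------------------------------------------


def test_simulate_em_zero_dynamics_is_constant():
    spec = mt.DiffusionSpec(2, lambda z: np.zeros(2), lambda z: np.zeros(2),
                            ("x", "y"), (0, 1))
    tr = mt.simulate_em(spec, np.array([1.0, -2.0]), 0.1, 5.0, seed=1)
    assert np.all(tr.states == [1.0, -2.0])


def test_simulate_em_determinism(std_normal_1d):
    spec = mt.langevin_spec(std_normal_1d, 1.0)
    a = mt.simulate_em(spec, np.array([0.0]), 0.01, 10.0, seed=42)
    b = mt.simulate_em(spec, np.array([0.0]), 0.01, 10.0, seed=42)
    assert np.array_equal(a.states, b.states)
    c = mt.simulate_em(spec, np.array([0.0]), 0.01, 10.0, seed=43)
    assert not np.array_equal(a.states, c.states)


def test_simulate_em_aborts_on_divergence():
    spec = mt.DiffusionSpec(1, lambda z: 1e4 * z, lambda z: np.ones(1), ("x",), (0,))
    with pytest.raises(FloatingPointError, match="step"):
        mt.simulate_em(spec, np.array([1.0]), 0.1, 50.0, seed=0)


def test_langevin_em_stationary_variance(std_normal_1d):
    spec = mt.langevin_spec(std_normal_1d, 1.0)
    tr = mt.simulate_em(spec, np.array([0.0]), 0.01, 2000.0, seed=11, record_every=100)
    x = tr.states[100:, 0]
    assert abs(x.var() - 1.0) < 0.1


@given(st.floats(-50, 50))
def test_wrap_angle_range(theta):
    w = wrap_angle(theta)
    assert -np.pi < w <= np.pi
    assert np.isclose(np.sin(w), np.sin(theta), atol=1e-9)
    assert np.isclose(np.cos(w), np.cos(theta), atol=1e-9)


def test_trajectory_csv_round_trip(tmp_path, std_normal_1d):
    spec = mt.langevin_spec(std_normal_1d, 1.0)
    tr = mt.simulate_em(spec, np.array([0.0]), 0.01, 5.0, seed=2)
    path = tmp_path / "traj.csv"
    tr.to_csv(path)
    back = mt.Trajectory.from_csv(path)
    assert np.allclose(back.states, tr.states)
    assert back.dt == tr.dt
    assert back.seed == tr.seed
    assert back.columns == tr.columns
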