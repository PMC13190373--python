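"""Behavioural switching: generator constructions and joint simulation."""

import numpy as np
import pytest

import movetarget as mt
from movetarget import switching as sw


@pytest.fixture
def two_state():
    """Two states, each selecting its own Laplace covariate."""
    return mt.MultiStateTarget(
        [np.log(5 / 3), 0.0], [[2.0, 0.0], [0.0, 2.0]],
        [mt.laplace_covariate([-10.0], 10.0), mt.laplace_covariate([10.0], 10.0)],
    )


@pytest.fixture
def three_state():
    return mt.MultiStateTarget(
        [0.1, -0.2, 0.3], [[1.0], [0.5], [-0.5]],
        [mt.laplace_covariate([0.0], 5.0)],
    )


def _stationarity_residual(target, x, lam):
    pi = target.state_posterior(x)
    return np.max(np.abs(pi @ lam))


def _constructions(target, x):
    S = target.n_states
    q = np.full((S, S), 0.7)
    yield sw.rates_symmetric(target, x, 0.5)
    yield sw.rates_gibbs(target, x, 1.2)
    yield sw.rates_mh(target, x, q)
    yield sw.rates_barker(target, x, q)


@pytest.mark.parametrize("fixture_name", ["two_state", "three_state"])
def test_all_constructions_preserve_state_posterior(fixture_name, request, rng):
    target = request.getfixturevalue(fixture_name)
    for x in rng.uniform(-30, 30, size=(100, 1)):
        for lam in _constructions(target, x):
            assert np.allclose(lam.sum(axis=1), 0.0, atol=1e-12)
            assert np.all(lam - np.diag(np.diag(lam)) >= 0)
            assert _stationarity_residual(target, x, lam) < 1e-10


def test_detailed_balance_of_reversible_constructions(two_state, rng):
    for x in rng.uniform(-30, 30, size=(50, 1)):
        w = np.exp(two_state.state_logweights(x) - np.max(two_state.state_logweights(x)))
        for lam in _constructions(two_state, x):
            assert w[0] * lam[0, 1] == pytest.approx(w[1] * lam[1, 0], rel=1e-12)


def test_symmetric_rates_examples(two_state):
    # pi(x, 1) = pi(x, 2) at the location where the weights cross
    from scipy.optimize import brentq
    xc = brentq(lambda x: np.subtract(*two_state.state_logweights(np.array([x]))), -10, 10)
    lam = sw.rates_symmetric(two_state, np.array([xc]), np.sqrt(0.0015))
    assert lam[0, 1] == pytest.approx(np.sqrt(0.0015), rel=1e-9)
    assert lam[1, 0] == pytest.approx(np.sqrt(0.0015), rel=1e-9)
    with pytest.raises(ValueError):
        sw.rates_symmetric(two_state, np.array([0.0]), np.array([[0.1, 0.2], [0.3, 0.1]]))


def test_gibbs_rates_equal_weights():
    target = mt.MultiStateTarget([0.0, 0.0], [[1.0], [1.0]],
                                 [mt.laplace_covariate([0.0], 2.0)])
    lam = sw.rates_gibbs(target, np.array([1.0]), 1.0)
    assert lam[0, 1] == pytest.approx(0.5)
    assert lam[1, 0] == pytest.approx(0.5)


def test_mh_and_barker_examples(two_state):
    x = np.array([-20.0])  # state 1 strongly favoured here
    w = np.exp(two_state.state_logweights(x) - np.max(two_state.state_logweights(x)))
    lam_mh = sw.rates_mh(two_state, x, 0.7)
    # moving towards the favoured state is accepted with probability 1
    assert lam_mh[1, 0] == pytest.approx(0.7)
    assert lam_mh[0, 1] == pytest.approx(0.7 * w[1] / w[0])
    # Barker splits an equal-weight proposal in half
    eq = mt.MultiStateTarget([0.0, 0.0], [[1.0], [1.0]],
                             [mt.laplace_covariate([0.0], 2.0)])
    lam_b = sw.rates_barker(eq, np.array([3.0]), 0.8)
    assert lam_b[0, 1] == pytest.approx(0.4)


def test_one_way_proposals_are_balanced(two_state):
    q = np.array([[0.0, 0.5], [0.0, 0.0]])  # no reverse proposal
    for ctor in (sw.rates_mh, sw.rates_barker):
        lam = ctor(two_state, np.array([0.0]), q)
        assert lam[0, 1] == 0.0
        assert lam[1, 0] == 0.0
        assert _stationarity_residual(two_state, np.array([0.0]), lam) < 1e-12


# -- 3-state non-reversible parameterisation ---------------------------------


def test_three_state_reversible_case(three_state, rng):
    for x in rng.uniform(-15, 15, size=(25, 1)):
        pi = three_state.state_posterior(x)
        lam = sw.generator_3state(three_state, x, 0.4, 0.7, 1.1, eps=0.0)
        for i in range(3):
            for j in range(3):
                assert pi[i] * lam[i, j] == pytest.approx(pi[j] * lam[j, i], abs=1e-12)


def test_three_state_circulation_breaks_detailed_balance(three_state, rng):
    for x in rng.uniform(-15, 15, size=(25, 1)):
        pi = three_state.state_posterior(x)
        lam = sw.generator_3state(three_state, x, 0.4, 0.7, 1.1, eps=0.05)
        assert _stationarity_residual(three_state, x, lam) < 1e-10
        db = max(abs(pi[i] * lam[i, j] - pi[j] * lam[j, i])
                 for i in range(3) for j in range(3) if i != j)
        assert db > 1e-3


def test_three_state_uniform_unit_rates():
    target = mt.MultiStateTarget([0.0, 0.0, 0.0], [[0.0], [0.0], [0.0]],
                                 [mt.laplace_covariate([0.0], 1.0)])
    lam = sw.generator_3state(target, np.array([0.3]), 1.0, 1.0, 1.0, eps=0.0)
    off = lam[~np.eye(3, dtype=bool)]
    assert np.allclose(off, 1.0)


def test_three_state_eps_bound_enforced(three_state):
    x = np.array([2.0])
    pi = three_state.state_posterior(x)
    bound = -min(pi[0] * 0.4, pi[1] * 0.7, pi[2] * 1.1)
    # just inside the bound is fine, below it is rejected
    sw.generator_3state(three_state, x, 0.4, 0.7, 1.1, eps=bound + 1e-9)
    with pytest.raises(ValueError, match="bound"):
        sw.generator_3state(three_state, x, 0.4, 0.7, 1.1, eps=bound - 1e-6)


def test_linexp_psi_keeps_rates_loglinear(two_state):
    psi = sw.linexp_psi(np.full((2, 2), np.log(0.2)),
                        np.zeros((2, 2, 2)), two_state.covariates)
    lam = sw.rates_symmetric(two_state, np.array([3.0]), psi)
    ref = sw.rates_symmetric(two_state, np.array([3.0]), 0.2)
    assert np.allclose(lam, ref)


# -- joint simulation --------------------------------------------------------


def _switch_model(target, psi, gamma=5.0, alpha=1.0):
    specs = [mt.kinetic_langevin_spec(target.conditional(s), gamma, alpha)
             for s in range(target.n_states)]
    return sw.SwitchingModel(target, specs, sw.symmetric_rate_fn(target, psi))


def test_zero_switching_rate_gives_pure_single_state(two_state):
    model = _switch_model(two_state, 1e-300)
    tr = sw.simulate_switching(model, np.array([-10.0, 0.0]), 0, 0.02, 50.0, seed=3)
    assert np.all(tr.discrete["state"] == 0)


def _mild_two_state():
    """Two overlapping states with O(1) switching-rate ratios."""
    return mt.MultiStateTarget(
        [0.0, 0.0], [[1.0, 0.0], [0.0, 1.0]],
        [mt.laplace_covariate([-2.0], 2.0), mt.laplace_covariate([2.0], 2.0)],
    )


def test_switching_visits_both_states():
    model = _switch_model(_mild_two_state(), 0.5, gamma=1.0)
    tr = sw.simulate_switching(model, np.array([-2.0, 0.0]), 0, 0.02, 400.0, seed=4)
    states = tr.discrete["state"]
    assert set(np.unique(states)) == {0, 1}
    assert np.sum(np.diff(states) != 0) > 10


def test_switching_determinism(two_state):
    model = _switch_model(two_state, 0.5)
    a = sw.simulate_switching(model, np.array([-10.0, 0.0]), 0, 0.02, 50.0, seed=9)
    b = sw.simulate_switching(model, np.array([-10.0, 0.0]), 0, 0.02, 50.0, seed=9)
    assert np.array_equal(a.states, b.states)
    assert np.array_equal(a.discrete["state"], b.discrete["state"])


def test_switching_warns_on_coarse_splitting():
    model = _switch_model(_mild_two_state(), 20.0, gamma=1.0)
    with pytest.warns(RuntimeWarning, match="splitting"):
        sw.simulate_switching(model, np.array([-2.0, 0.0]), 0, 0.02, 20.0, seed=5)


def test_em_and_baoab_agree_on_smooth_gentle_dynamics():
    """On a smooth target with mild force the two integrators should agree
    in distribution; compare stationary moments."""
    target = mt.ProductTarget([mt.Normal1D()])
    spec = mt.kinetic_langevin_spec(target, 1.0, 1.0)
    em = mt.simulate_em(spec, np.array([0.0, 0.0]), 0.01, 2000.0, seed=6, record_every=100)
    ba = mt.simulate_baoab(spec, np.array([0.0, 0.0]), 0.01, 2000.0, seed=6, record_every=100)
    assert abs(em.states[100:, 0].var() - ba.states[100:, 0].var()) < 0.15
    assert abs(em.states[100:, 0].mean() - ba.states[100:, 0].mean()) < 0.15
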