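"""Balancing flow: convergence, conservation laws, optimality, bounds."""

import numpy as np
import pytest
from scipy.optimize import minimize

from synbal import (
    CostMatrix,
    FlowSettings,
    GainMoments,
    balance_config,
    balance_flow,
    check_balance,
    check_strongly_connected,
    cost_bounds,
    costs_at_h,
    lax_residual,
    neural_gradients,
    random_fixture,
    spectrum,
    symmetrizable_equilibrium,
    synaptic_costs,
    total_cost,
)
from synbal.transform import apply_transform


def _random_cost(n, seed, density=0.6, ensure_sc=True):
    rng = np.random.default_rng(seed)
    c = np.abs(rng.normal(size=(n, n))) * (rng.random((n, n)) < density)
    np.fill_diagonal(c, 0.0)
    if ensure_sc:
        order = rng.permutation(n)
        for src, dst in zip(order, np.roll(order, -1)):
            c[dst, src] = np.abs(rng.normal()) + 0.1
    return CostMatrix(c=c, p=2.0)


# ----------------------------------------------------------------- topology

def test_feedforward_not_strongly_connected():
    rep = check_strongly_connected(CostMatrix(c=[[0.0, 1.0], [0.0, 0.0]]))
    assert not rep.strongly_connected
    assert len(rep.components) == 2


def test_reciprocal_pair_strongly_connected():
    rep = check_strongly_connected(CostMatrix(c=[[0.0, 1.0], [4.0, 0.0]]))
    assert rep.strongly_connected


def test_ring_strongly_connected():
    n = 12
    c = np.zeros((n, n))
    for k in range(n):
        c[(k + 1) % n, k] = 1.0
        c[k, (k + 1) % n] = 1.0
    rep = check_strongly_connected(CostMatrix(c=c))
    assert rep.strongly_connected
    assert len(rep.components) == 1


# --------------------------------------------------------------------- flow

def test_symmetric_costs_already_balanced():
    c = CostMatrix(c=[[0.0, 2.0], [2.0, 0.0]])
    traj = balance_flow(c)
    assert traj.converged
    assert traj.t_grid[-1] == 0.0
    np.testing.assert_array_equal(traj.h_star, np.zeros(2))


def test_two_neuron_equilibrium_closed_form():
    """c12=1, c21=4 relaxes to the geometric-mean equilibrium (2, 2), C*=4."""
    traj = balance_flow(CostMatrix(c=[[0.0, 1.0], [4.0, 0.0]], p=2.0))
    assert traj.converged
    np.testing.assert_allclose(
        traj.h_star, [-np.log(2) / 4, np.log(2) / 4], atol=1e-8
    )
    assert traj.C_series[-1] == pytest.approx(4.0, abs=1e-8)


def test_three_cycle_equilibrium_from_conserved_product():
    """Costs (1,1,8) around a directed 3-cycle equalize at (1*1*8)^{1/3} = 2."""
    c = np.zeros((3, 3))
    c[1, 0], c[2, 1], c[0, 2] = 1.0, 1.0, 8.0
    traj = balance_flow(CostMatrix(c=c, p=2.0))
    assert traj.converged
    c_eq = costs_at_h(CostMatrix(c=c, p=2.0), traj.h_star)
    np.testing.assert_allclose(c_eq.c[c_eq.c > 0], [2.0, 2.0, 2.0], atol=1e-7)
    assert traj.C_series[-1] == pytest.approx(6.0, abs=1e-7)


def test_feedforward_algebraic_decay():
    """A single synapse has no equilibrium: c(t) = c0/(2 p c0 t + 1)."""
    c0 = CostMatrix(c=[[0.0, 1.0], [0.0, 0.0]], p=2.0)
    with pytest.warns(UserWarning, match="strongly connected"):
        traj = balance_flow(c0, FlowSettings(t_max=1.0))
    assert traj.termination_reason == "not_strongly_connected"
    c_at_1 = costs_at_h(c0, traj.h_series[:, -1])
    assert c_at_1.c[0, 1] == pytest.approx(0.2, rel=1e-6)


def test_flow_conservation_and_monotonicity():
    c0 = _random_cost(8, seed=5)
    traj = balance_flow(c0)
    assert traj.converged
    # sum of h stays zero at every sample time
    np.testing.assert_allclose(traj.h_series.sum(axis=0), 0.0, atol=1e-12)
    # cost is nonincreasing (within solver tolerance)
    assert np.all(np.diff(traj.C_series) <= 1e-9 * traj.C_series[0])
    # spectrum of J conserved along the flow
    cfg = random_fixture(8, density=1.0, seed=5)
    spec0 = spectrum(cfg.J)
    for k in range(0, traj.h_series.shape[1], max(1, traj.h_series.shape[1] // 5)):
        spec_k = spectrum(apply_transform(cfg, traj.h_series[:, k]).J)
        assert np.max(np.abs(spec_k - spec0)) <= 1e-8 * max(1.0, np.max(np.abs(spec0)))


def test_converged_flow_is_balanced():
    c0 = _random_cost(10, seed=8)
    traj = balance_flow(c0)
    assert traj.converged
    report = check_balance(costs_at_h(c0, traj.h_star), tol=10 * traj.g_tol)
    assert report.balanced


def test_exponential_convergence_of_gradient_norm():
    """log ||g(t)|| is eventually linear with negative slope (strong connectivity)."""
    c0 = _random_cost(6, seed=13)
    traj = balance_flow(c0)
    g_norm = np.linalg.norm(traj.g_series, axis=0)
    # late window where the slowest eigenmode dominates but the signal is
    # still well above solver noise
    mask = (g_norm < 1e5 * traj.g_tol) & (g_norm > 1e2 * traj.g_tol)
    assert mask.sum() >= 4
    t, lg = traj.t_grid[mask], np.log(g_norm[mask])
    coeffs = np.polyfit(t, lg, 1)
    assert coeffs[0] < 0
    resid = lg - np.polyval(coeffs, t)
    assert np.max(np.abs(resid)) < 0.3  # linear decay of log ||g||


def test_flow_matches_independent_convex_minimization():
    """C* from the flow equals direct minimization of the convex cost in h."""
    for seed in range(5):
        c0 = _random_cost(np.random.default_rng(seed).integers(3, 10), seed=seed)
        traj = balance_flow(c0)
        n = c0.n

        def objective(h):
            return total_cost(costs_at_h(c0, h))

        res = minimize(objective, np.zeros(n), method="BFGS", options={"gtol": 1e-12})
        assert traj.C_series[-1] == pytest.approx(res.fun, rel=1e-8)


def test_check_balance_examples():
    sym = CostMatrix(c=[[0.0, 2.0], [2.0, 0.0]])
    rep = check_balance(sym)
    assert rep.balanced
    np.testing.assert_array_equal(rep.residuals, [0.0, 0.0])
    rep2 = check_balance(CostMatrix(c=[[0.0, 1.0], [4.0, 0.0]]))
    assert not rep2.balanced
    np.testing.assert_allclose(rep2.residuals, [-3.0, 3.0])


# ------------------------------------------------------------------- bounds

def test_cost_bounds_two_neuron_example():
    c0 = CostMatrix(c=[[0.0, 1.0], [4.0, 0.0]])
    lower, upper = cost_bounds(c0)
    assert lower == pytest.approx(4.0)
    assert upper == pytest.approx(5.0 - 18.0 / 40.0)
    traj = balance_flow(c0)
    assert lower - 1e-9 <= traj.C_series[-1] <= upper + 1e-9


def test_bounds_equality_when_symmetric():
    c0 = CostMatrix(c=[[0.0, 3.0], [3.0, 0.0]])
    lower, upper = cost_bounds(c0)
    assert lower == pytest.approx(6.0)
    assert upper == pytest.approx(6.0)


def test_bounds_hold_on_random_instances():
    for seed in range(20):
        c0 = _random_cost(6, seed=100 + seed)
        lower, upper = cost_bounds(c0)
        traj = balance_flow(c0)
        c_star = traj.C_series[-1]
        assert lower - 1e-8 * c_star <= c_star <= upper + 1e-8 * c_star


def test_rank_one_closed_form():
    """C0 = a b^T has equilibrium a* b*^T with a*_i = b*_i = sqrt(a_i b_i)."""
    rng = np.random.default_rng(3)
    a, b = rng.uniform(0.2, 2, 5), rng.uniform(0.2, 2, 5)
    c0 = CostMatrix(c=np.outer(a, b), p=2.0)
    traj = balance_flow(c0)
    assert traj.C_series[-1] == pytest.approx(np.sum(np.sqrt(a * b)) ** 2, rel=1e-8)


def test_normal_matrix_is_equilibrium(rng):
    """Normal J with uniform sigma2 satisfies the balance condition."""
    A = rng.normal(size=(5, 5))
    Q = np.linalg.qr(A)[0]  # orthogonal, hence normal
    c = synaptic_costs(Q, moments=GainMoments(mu=np.full(5, 0.5), sigma2=np.full(5, 0.5)))
    np.testing.assert_allclose(neural_gradients(c), 0.0, atol=1e-12)


# --------------------------------------------------------- symmetrizability

def test_two_neuron_always_symmetrizable():
    res = symmetrizable_equilibrium(CostMatrix(c=[[0.0, 1.0], [4.0, 0.0]], p=2.0))
    assert res is not None
    c_hat, h = res
    np.testing.assert_allclose(c_hat.c, [[0.0, 2.0], [2.0, 0.0]], atol=1e-12)
    np.testing.assert_allclose(h, [-np.log(2) / 4, np.log(2) / 4], atol=1e-12)


def test_symmetric_input_is_its_own_equilibrium():
    c0 = CostMatrix(c=[[0.0, 2.0], [2.0, 0.0]])
    c_hat, h = symmetrizable_equilibrium(c0)
    np.testing.assert_array_equal(c_hat.c, c0.c)
    np.testing.assert_allclose(h, 0.0, atol=1e-15)


def test_perturbed_ring_not_symmetrizable():
    """Unequal forward/backward ring products obstruct symmetrizability."""
    n = 12
    c = np.zeros((n, n))
    for k in range(n):
        c[(k + 1) % n, k] = 1.0
        c[k, (k + 1) % n] = 1.0
    assert symmetrizable_equilibrium(CostMatrix(c=c, p=2.0)) is not None
    c[1, 0] = 3.0  # one direction of one pair perturbed
    assert symmetrizable_equilibrium(CostMatrix(c=c, p=2.0)) is None


def test_symmetrizable_matches_flow(rng):
    """When symmetrizable, the closed form equals the flow equilibrium."""
    # build a symmetrizable instance: symmetric base conjugated by diag scales
    base = np.abs(rng.normal(size=(5, 5))) + 0.1
    base = base + base.T
    np.fill_diagonal(base, 0.0)
    s = rng.uniform(-1, 1, 5)
    c0 = CostMatrix(c=base * np.exp(2.0 * (s[None, :] - s[:, None])), p=2.0)
    res = symmetrizable_equilibrium(c0)
    assert res is not None
    c_hat, h = res
    traj = balance_flow(c0)
    assert total_cost(c_hat) == pytest.approx(traj.C_series[-1], rel=1e-7)


# ---------------------------------------------------------------- Lax form

def test_lax_residual_along_flow():
    """Central-difference dJ/dt matches [J, diag g] to O(dt^2) along the flow."""
    c0 = _random_cost(5, seed=44)
    cfg = random_fixture(5, density=1.0, seed=44)
    traj = balance_flow(c0)
    t_mid = traj.t_grid[-1] / 20.0
    errs = []
    for dt in (1e-2, 5e-3):
        hs = []
        for t in (t_mid - dt, t_mid, t_mid + dt):
            # re-integrate to the exact sample times
            s = FlowSettings(g_tol=0.0, t_max=t, rtol=1e-10, atol=1e-12)
            hs.append(balance_flow(c0, s).h_series[:, -1])
        J = [apply_transform(cfg, h).J for h in hs]
        dJ_dt = (J[2] - J[0]) / (2 * dt)
        g = neural_gradients(costs_at_h(c0, hs[1]))
        errs.append(lax_residual(J[1], g, dJ_dt))
    assert errs[1] < errs[0]  # finite-difference error shrinks with dt
    assert errs[0] < 1e-2


def test_lax_residual_trivial_cases():
    J = np.diag([1.0, 2.0])
    g = np.array([3.0, -3.0])
    # diagonal J commutes with diag(g): residual is just ||dJ/dt||
    assert lax_residual(J, g, np.zeros((2, 2))) == 0.0
    dJ = np.ones((2, 2))
    assert lax_residual(J, np.zeros(2), dJ) == pytest.approx(np.linalg.norm(dJ))


def test_balance_config_stays_on_manifold(random_inputs):
    """Balanced weights reproduce the original outputs exactly."""
    from synbal import SimSettings, verify_preservation

    cfg = random_fixture(6, density=0.8, seed=77)
    c0 = synaptic_costs(cfg.J, moments=GainMoments.unit(6))
    balanced, traj = balance_config(cfg, c0)
    assert traj.converged
    rep = verify_preservation(
        cfg, traj.h_series[:, -1], random_inputs(), SimSettings(dt=0.1)
    )
    assert rep.max_output_dev < 1e-9
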