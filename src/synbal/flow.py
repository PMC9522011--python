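"""The synaptic-balancing gradient flow and its equilibrium theory.

Balancing is gradient descent on the convex total cost C(h) =
sum_ij c0_ij e^{p(h_j - h_i)} over the manifold coordinates h:

    dh/dt = g(h),    g_k = (incoming cost of k) - (outgoing cost of k),

initialized at h(0) = 0.  Equilibria are exactly the *balanced*
configurations (incoming cost = outgoing cost at every neuron), which are
the global minima of C on the manifold.  When the directed graph of
positive costs is strongly connected the equilibrium exists at finite h and
the flow converges to it exponentially; with embedded feedforward structure
the cost still decreases but the infimum may sit at infinite h.

The flow is integrated in h-space and weights are reconstructed through
pi_h, so trajectories stay exactly on the task-preserving manifold
regardless of solver error.  On J itself the dynamics take the Lax form
dJ/dt = [J, diag(g)], an isospectral flow: the spectrum of J and all
directed loop products are conserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.integrate import solve_ivp

from .costs import CostMatrix, costs_at_h, neural_gradients, total_cost

__all__ = [
    "ConnectivityReport",
    "BalancingTrajectory",
    "BalanceReport",
    "FlowSettings",
    "check_strongly_connected",
    "balance_flow",
    "balance_config",
    "check_balance",
    "cost_bounds",
    "symmetrizable_equilibrium",
    "lax_residual",
]


@dataclass(frozen=True)
class ConnectivityReport:
    """Strong-connectivity structure of the directed positive-cost graph."""

    strongly_connected: bool
    components: list[frozenset]
    condensation_edges: list[tuple[int, int]]


def _cost_digraph(c0: CostMatrix) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(range(c0.n))
    rows, cols = np.nonzero(c0.c > 0)
    for i, j in zip(rows, cols):
        if i != j:  # self-loops are irrelevant to connectivity
            g.add_edge(j, i)  # c_ij > 0 is a synapse j -> i
    return g


def check_strongly_connected(c0: CostMatrix) -> ConnectivityReport:
    """Strongly connected components of the graph with an edge j->i iff c_ij > 0."""
    g = _cost_digraph(c0)
    comps = [frozenset(s) for s in nx.strongly_connected_components(g)]
    cond = nx.condensation(g)
    return ConnectivityReport(
        strongly_connected=len(comps) == 1,
        components=comps,
        condensation_edges=list(cond.edges()),
    )


@dataclass(frozen=True)
class FlowSettings:
    """Solver and termination settings for the balancing flow.

    ``g_tol`` terminates when the max-norm of the neural gradient drops
    below it; the default scales with the initial cost per neuron.
    """

    rtol: float = 1e-8
    atol: float = 1e-10
    g_tol: float | None = None  # default: 1e-10 * C0 / N
    t_max: float = 1e5
    method: str = "LSODA"

    def resolve_g_tol(self, c0: CostMatrix) -> float:
        if self.g_tol is not None:
            return self.g_tol
        return 1e-10 * max(total_cost(c0), 1e-300) / c0.n


@dataclass
class BalancingTrajectory:
    """Time course of a balancing run: h, g, C and convergence diagnostics."""

    t_grid: np.ndarray
    h_series: np.ndarray  # N x L
    g_series: np.ndarray  # N x L
    C_series: np.ndarray  # L
    converged: bool
    termination_reason: str  # converged | max_time | not_strongly_connected
    h_star: np.ndarray | None = None
    g_tol: float = np.nan
    connectivity: ConnectivityReport | None = None

    def cost_at(self, k: int) -> float:
        return float(self.C_series[k])


def balance_flow(c0: CostMatrix, settings: FlowSettings | None = None) -> BalancingTrajectory:
    """Integrate dh/dt = g(h) from h(0) = 0 until balance or t_max.

    Uses an adaptive stiff-capable solver with a terminal event on
    ||g||_inf.  If the positive-cost graph is not strongly connected the
    flow is still well defined and decreases C, but a finite equilibrium
    may not exist: a warning is emitted and the run terminates at t_max
    with ``termination_reason='not_strongly_connected'`` unless the
    gradient happens to vanish (components can be individually balanced).
    """
    settings = settings or FlowSettings()
    n = c0.n
    g_tol = settings.resolve_g_tol(c0)
    conn = check_strongly_connected(c0)
    if not conn.strongly_connected:
        warnings.warn(
            "cost graph is not strongly connected; a finite balanced "
            "equilibrium may not exist (cost still decreases)",
            stacklevel=2,
        )

    def rhs(t, h):
        return neural_gradients(costs_at_h(c0, h))

    def balance_event(t, h):
        g = rhs(t, h)
        return float(np.max(np.abs(g))) - g_tol

    balance_event.terminal = True
    balance_event.direction = -1

    h0 = np.zeros(n)
    if balance_event(0.0, h0) <= 0:
        # already balanced at the start
        g0 = rhs(0.0, h0)
        return BalancingTrajectory(
            t_grid=np.array([0.0]),
            h_series=h0[:, None].copy(),
            g_series=g0[:, None],
            C_series=np.array([total_cost(c0)]),
            converged=True,
            termination_reason="converged",
            h_star=h0,
            g_tol=g_tol,
            connectivity=conn,
        )

    sol = solve_ivp(
        rhs,
        (0.0, settings.t_max),
        h0,
        method=settings.method,
        rtol=settings.rtol,
        atol=settings.atol,
        events=balance_event,
        dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(f"balancing flow failed: {sol.message}")

    t_grid = sol.t
    h_series = sol.y
    g_series = np.stack([rhs(t, h) for t, h in zip(t_grid, h_series.T)], axis=1)
    C_series = np.array([total_cost(costs_at_h(c0, h)) for h in h_series.T])

    hit_event = len(sol.t_events[0]) > 0
    if hit_event:
        reason = "converged"
    elif conn.strongly_connected:
        reason = "max_time"
    else:
        reason = "not_strongly_connected"
    return BalancingTrajectory(
        t_grid=t_grid,
        h_series=h_series,
        g_series=g_series,
        C_series=C_series,
        converged=hit_event,
        termination_reason=reason,
        h_star=h_series[:, -1].copy() if hit_event else None,
        g_tol=g_tol,
        connectivity=conn,
    )


@dataclass(frozen=True)
class BalanceReport:
    """Per-neuron in/out cost residuals and the balance verdict."""

    residuals: np.ndarray
    balanced: bool
    tol: float


def check_balance(c: CostMatrix, tol: float = 1e-10) -> BalanceReport:
    """Check the balance condition sum_i c_ik = sum_j c_kj per neuron.

    residual_k = incoming - outgoing; balanced iff
    max |residual| <= tol * max(1, C).
    """
    residuals = neural_gradients(c)
    scale = max(1.0, total_cost(c))
    return BalanceReport(
        residuals=residuals,
        balanced=bool(np.max(np.abs(residuals)) <= tol * scale),
        tol=tol,
    )


def cost_bounds(c0: CostMatrix) -> tuple[float, float]:
    """Bounds on the minimum cost C* on the manifold.

    lower = sum_ij sqrt(c0_ij c0_ji) (tight exactly for diagonally
    symmetrizable cost matrices);
    upper = C0 - ||g0||^2 / (8 C0): the further the network starts from
    balance, the more balancing is guaranteed to improve the cost.
    """
    C0 = total_cost(c0)
    if C0 == 0:
        raise ValueError("cost bounds are undefined for an all-zero cost matrix")
    lower = float(np.sum(np.sqrt(c0.c * c0.c.T)))
    g0 = neural_gradients(c0)
    upper = C0 - float(g0 @ g0) / (8.0 * C0)
    return lower, max(lower, upper)


def symmetrizable_equilibrium(
    c0: CostMatrix, tol: float = 1e-8
) -> tuple[CostMatrix, np.ndarray] | None:
    """Closed-form equilibrium when c0 is positive diagonally symmetrizable.

    A cost matrix is diagonally symmetrizable when some pi_h makes it
    symmetric — equivalently, when the forward and backward weight products
    agree around every cycle.  The minimum is then attained at the matrix
    of geometric means c^_ij = sqrt(c0_ij c0_ji), and the lower cost bound
    holds with equality.  Returns (C^, h achieving it), or None if c0 is
    not symmetrizable.

    The test solves the incidence-map least-squares system
    p (h_j - h_i) = log(c0_ji / c0_ij) / 2 over reciprocal synapse pairs
    and accepts iff the residual is below ``tol`` (relative to the log-cost
    scale); an unreciprocated positive cost rules symmetrizability out
    immediately.
    """
    c = c0.c
    n = c0.n
    off = ~np.eye(n, dtype=bool)
    pos = (c > 0) & off
    if not np.array_equal(pos, pos.T):
        return None  # some synapse has no reciprocal partner
    rows_i, rows_j = np.nonzero(pos & (np.arange(n)[:, None] < np.arange(n)[None, :]))
    h = np.zeros(n)
    if rows_i.size:
        A = np.zeros((rows_i.size, n))
        d = np.empty(rows_i.size)
        for k, (i, j) in enumerate(zip(rows_i, rows_j)):
            # want c_ij e^{p(h_j-h_i)} = c_ji e^{p(h_i-h_j)}
            A[k, j] = 1.0
            A[k, i] = -1.0
            d[k] = np.log(c[j, i] / c[i, j]) / (2.0 * c0.p)
        h, *_ = np.linalg.lstsq(A, d, rcond=None)
        resid = A @ h - d
        scale = max(1.0, float(np.max(np.abs(d))))
        if np.max(np.abs(resid)) > tol * scale:
            return None
        h = h - h.mean()  # global sum-zero convention, matching h(0) = 0
    c_hat = costs_at_h(c0, h)
    return c_hat, h


def balance_config(
    config,
    c0: CostMatrix,
    settings: FlowSettings | None = None,
):
    """Run the balancing flow and realize the result on a weight configuration.

    Integrates the flow on ``c0`` and applies pi_h at the final coordinate,
    returning ``(balanced WeightConfig, BalancingTrajectory)``.  Because
    weights are reconstructed through the transformation rather than by
    integrating dJ/dt directly, the result lies exactly on the
    task-preserving manifold of ``config``.
    """
    from .transform import apply_transform

    traj = balance_flow(c0, settings)
    h_final = traj.h_series[:, -1]
    return apply_transform(config, h_final), traj


def lax_residual(J: np.ndarray, g: np.ndarray, dJ_dt: np.ndarray) -> float:
    """Frobenius deviation of dJ/dt from the Lax form [J, diag(g)].

    Along an exact balancing trajectory dJ/dt = J diag(g) - diag(g) J, so a
    finite-difference dJ/dt from flow samples leaves only the O(dt)
    differencing error.
    """
    J = np.atleast_2d(np.asarray(J, dtype=float))
    g = np.asarray(g, dtype=float).ravel()
    commutator = J * g[None, :] - g[:, None] * J
    return float(np.linalg.norm(np.asarray(dJ_dt) - commutator))
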