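"""Closed-form and approximate balancing trajectories, and near-equilibrium
perturbation theory.

Three layers of theory sit on top of the numerical flow:

* **Two neurons** — the cost trajectories solve exactly: with both
  reciprocal costs positive they relax along hyperbolic-tangent /
  -cotangent curves to the geometric-mean equilibrium
  c^ = sqrt(c12^0 c21^0); with a single (feedforward) cost, the cost decays
  algebraically, c(t) = c^0 / (2 p c^0 t + 1), and no finite equilibrium
  exists.

* **Heat-kernel approximation** — the Hessian of the total cost in h is
  p^2 L where L is the graph Laplacian of the *conductance* matrix
  c~_ij = c_ij + c_ji.  Freezing L near a reference configuration turns
  the gradient dynamics into the heat equation dg/dt = -p L g on the cost
  graph, giving closed-form g(t), h(t), and the equilibrium
  h* = p^{-1} L^+ g^0.

* **Perturbation response** — potentiating a single synapse J_ij of a
  balanced network by a factor (1+eta) produces, to first order, a
  localized gradient eta p c_ij (e_i - e_j) whose relaxation predicts
  multiplicative heterosynaptic plasticity at the synapses of neurons i
  and j, and a fractional reversal of the perturbation equal to
  c_ij^0 R_ij^0, with R the effective-resistance (resistance-distance)
  metric of the conductance graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

from .costs import CostMatrix, neural_gradients
from .flow import check_balance

__all__ = [
    "LaplacianModel",
    "PerturbationSpec",
    "two_neuron_solution",
    "graph_laplacian",
    "heat_kernel_gradients",
    "approx_h_trajectory",
    "approx_equilibrium",
    "perturb_equilibrium",
    "heterosynaptic_response",
    "resistance_distance",
    "predicted_attenuation",
]


# --------------------------------------------------------------------------
# exact two-neuron trajectories
# --------------------------------------------------------------------------

def _two_neuron_ode(c12_0: float, c21_0: float, p: float, t_grid: np.ndarray):
    """Numeric oracle: integrate the two-neuron cost ODE directly."""

    def rhs(t, c):
        c12, c21 = c
        # g1 = c12 - c21 = -g2 ; dc12/dt = p c12 (g2 - g1), dc21/dt = -that
        diff = -2.0 * p * (c12 - c21)
        return [c12 * diff, -c21 * diff]

    sol = solve_ivp(
        rhs,
        (0.0, float(t_grid[-1])),
        [c12_0, c21_0],
        t_eval=t_grid,
        rtol=1e-10,
        atol=1e-12,
        method="LSODA",
    )
    return sol.y[0], sol.y[1]


def two_neuron_solution(
    c12_0: float,
    c21_0: float,
    p: float = 2.0,
    t_grid: np.ndarray | None = None,
    validate: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact cost trajectories c12(t), c21(t) for a two-neuron network.

    Both costs positive: c12 = c^ q(t), c21 = c^ / q(t) with
    c^ = sqrt(c12^0 c21^0) and q relaxing to 1 at rate 2 p c^ along the
    tanh branch (q(0) < 1) or the coth branch (q(0) > 1) — the two
    branches are the same Riccati solution continued through q = 1.
    Single positive cost: algebraic decay c12(t) = c12^0/(2 p c12^0 t + 1)
    while the absent reciprocal cost stays zero.

    With ``validate=True`` (default) the closed form is checked against a
    direct numerical integration of the cost ODE on the same grid.
    """
    if c12_0 < 0 or c21_0 < 0:
        raise ValueError("initial costs must be nonnegative")
    if c12_0 == 0 and c21_0 == 0:
        raise ValueError("at least one initial cost must be positive")
    if t_grid is None:
        t_grid = np.linspace(0.0, 2.0, 101)
    t_grid = np.asarray(t_grid, dtype=float)

    if c12_0 > 0 and c21_0 > 0:
        c_hat = np.sqrt(c12_0 * c21_0)
        q0 = np.sqrt(c12_0 / c21_0)
        rate = 2.0 * p * c_hat
        if np.isclose(q0, 1.0):
            q = np.ones_like(t_grid)
        elif q0 < 1.0:
            q = np.tanh(rate * t_grid + np.arctanh(q0))
        else:
            q = 1.0 / np.tanh(rate * t_grid + np.arctanh(1.0 / q0))
        c12 = c_hat * q
        c21 = c_hat / q
    elif c12_0 > 0:
        c12 = c12_0 / (2.0 * p * c12_0 * t_grid + 1.0)
        c21 = np.zeros_like(t_grid)
    else:
        c21 = c21_0 / (2.0 * p * c21_0 * t_grid + 1.0)
        c12 = np.zeros_like(t_grid)

    if validate:
        c12_num, c21_num = _two_neuron_ode(c12_0, c21_0, p, t_grid)
        scale = max(c12_0, c21_0)
        err = max(np.max(np.abs(c12 - c12_num)), np.max(np.abs(c21 - c21_num)))
        if err > 1e-6 * scale:
            raise AssertionError(
                f"closed-form two-neuron solution deviates from the numeric "
                f"flow by {err:g} (scale {scale:g})"
            )
    return c12, c21


# --------------------------------------------------------------------------
# graph Laplacian of the conductance matrix and heat-kernel dynamics
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LaplacianModel:
    """Graph Laplacian of the symmetrized (conductance) cost matrix."""

    L: np.ndarray
    conductances: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # columns, orthonormal
    pinv: np.ndarray
    zero_tol: float

    @property
    def n(self) -> int:
        return self.L.shape[0]

    @property
    def n_components(self) -> int:
        return int(np.sum(self.eigenvalues <= self.zero_tol))

    def zero_modes(self) -> np.ndarray:
        """Orthonormal basis of the Laplacian kernel (component indicators)."""
        return self.eigenvectors[:, self.eigenvalues <= self.zero_tol]


def graph_laplacian(c: CostMatrix) -> LaplacianModel:
    """Laplacian of the conductance graph c~_ij = c_ij + c_ji.

    L has off-diagonals -c~_ij and diagonal equal to each node's total
    conductance; L 1 = 0, and the multiplicity of the zero eigenvalue is
    the number of connected components.  p^2 L is the Hessian of the total
    cost in h, so L governs the linearized balancing dynamics.
    """
    cbar = c.c + c.c.T
    np.fill_diagonal(cbar, 0.0)  # self-loops never enter the gradients
    L = np.diag(cbar.sum(axis=1)) - cbar
    lam, V = np.linalg.eigh(L)
    lam = np.clip(lam, 0.0, None)
    zero_tol = 1e-10 * max(float(lam[-1]), 1.0)
    inv = np.where(lam > zero_tol, 1.0 / np.where(lam > zero_tol, lam, 1.0), 0.0)
    pinv = (V * inv[None, :]) @ V.T
    return LaplacianModel(
        L=L, conductances=cbar, eigenvalues=lam, eigenvectors=V,
        pinv=pinv, zero_tol=zero_tol,
    )


def _project_gradient(lm: LaplacianModel, g0: np.ndarray) -> np.ndarray:
    g0 = np.asarray(g0, dtype=float).ravel()
    if g0.size != lm.n:
        raise ValueError("g0 does not match the Laplacian size")
    zero = lm.zero_modes()
    overlap = zero.T @ g0
    if np.any(np.abs(overlap) > 1e-8 * max(1.0, float(np.linalg.norm(g0)))):
        warnings.warn(
            "g0 has a nonzero mean on some connected component; projecting "
            "it out (realizable neural gradients sum to zero per component)",
            stacklevel=3,
        )
        g0 = g0 - zero @ overlap
    return g0


def heat_kernel_gradients(
    lm: LaplacianModel, g0: np.ndarray, p: float, t_grid: np.ndarray
) -> np.ndarray:
    """Frozen-Laplacian gradients g(t) = e^{-p L t} g0 (heat kernel), N x L.

    Each positive Laplacian eigenmode decays at rate p * lambda_i: sharp
    (high-spatial-frequency) gradient patterns diffuse away fastest, like
    heat on the cost graph.
    """
    g0 = _project_gradient(lm, g0)
    t_grid = np.asarray(t_grid, dtype=float)
    pos = lm.eigenvalues > lm.zero_tol
    V = lm.eigenvectors[:, pos]
    lam = lm.eigenvalues[pos]
    coeff = V.T @ g0
    return V @ (np.exp(-p * lam[:, None] * t_grid[None, :]) * coeff[:, None])


def approx_h_trajectory(
    lm: LaplacianModel, g0: np.ndarray, p: float, t_grid: np.ndarray
) -> np.ndarray:
    """Integrated heat-kernel solution h(t) with h(0) = 0, shape N x L."""
    g0 = _project_gradient(lm, g0)
    t_grid = np.asarray(t_grid, dtype=float)
    pos = lm.eigenvalues > lm.zero_tol
    V = lm.eigenvectors[:, pos]
    lam = lm.eigenvalues[pos]
    coeff = V.T @ g0
    factor = (1.0 - np.exp(-p * lam[:, None] * t_grid[None, :])) / (p * lam[:, None])
    return V @ (factor * coeff[:, None])


def approx_equilibrium(lm: LaplacianModel, g0: np.ndarray, p: float) -> np.ndarray:
    """Quadratic-approximation equilibrium h* = p^{-1} L^+ g0."""
    g0 = _project_gradient(lm, g0)
    return lm.pinv @ g0 / p


# --------------------------------------------------------------------------
# single-synapse perturbations of a balanced network
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PerturbationSpec:
    """Instantaneous multiplicative perturbation of synapse J_ij by (1 + eta)."""

    i: int
    j: int
    eta: float

    def __post_init__(self):
        if self.i == self.j:
            raise ValueError("perturbation requires distinct neurons i != j")
        if abs(self.eta) > 0.2:
            warnings.warn(
                f"eta = {self.eta:g} is large; first-order perturbation "
                "predictions are only accurate for |eta| << 1",
                stacklevel=3,
            )

    @classmethod
    def from_cost_factor(cls, i: int, j: int, factor: float, p: float = 2.0):
        """Build a spec from a target *cost* scale factor: (1+eta)^p = factor."""
        if factor <= 0:
            raise ValueError("cost factor must be positive")
        return cls(i=i, j=j, eta=factor ** (1.0 / p) - 1.0)


def perturb_equilibrium(
    c_eq: CostMatrix, spec: PerturbationSpec, balance_tol: float = 1e-8
) -> tuple[CostMatrix, np.ndarray, np.ndarray]:
    """Perturb a balanced cost matrix at one synapse.

    Scaling J_ij by (1 + eta) scales c_ij by (1 + eta)^p exactly
    (first order: 1 + eta p).  Because the network starts balanced, the
    exact post-perturbation gradient is supported on neurons i and j; its
    first-order form is g0 = eta p c_ij (e_i - e_j).

    Returns (perturbed cost matrix, first-order g0, exact g0).
    """
    report = check_balance(c_eq, tol=balance_tol)
    if not report.balanced:
        raise ValueError(
            "cost matrix is not balanced within tolerance "
            f"(max residual {np.max(np.abs(report.residuals)):g})"
        )
    i, j = spec.i, spec.j
    c_new = c_eq.c.copy()
    c_new[i, j] *= (1.0 + spec.eta) ** c_eq.p
    perturbed = replace(c_eq, c=c_new)
    g_first = np.zeros(c_eq.n)
    g_first[i] += spec.eta * c_eq.p * c_eq.c[i, j]
    g_first[j] -= spec.eta * c_eq.p * c_eq.c[i, j]
    g_exact = neural_gradients(perturbed)
    return perturbed, g_first, g_exact


def heterosynaptic_response(
    J: np.ndarray, c_eq: CostMatrix, spec: PerturbationSpec
) -> np.ndarray:
    """First-order weight velocities dJ_kl/dt right after the perturbation.

    dJ_kl/dt = eta p J_kl c_ij (delta_il - delta_jl + delta_jk - delta_ik):
    a potentiation (eta > 0) of the synapse from j to i depresses the other
    incoming synapses of i and the outgoing synapses of j, and potentiates
    the outgoing synapses of i and the incoming synapses of j — all
    multiplicatively in J_kl.  Synapses touching neither neuron are
    untouched at first order.
    """
    J = np.atleast_2d(np.asarray(J, dtype=float))
    n = c_eq.n
    if J.shape != (n, n):
        raise ValueError("J does not match the cost matrix size")
    i, j = spec.i, spec.j
    # delta_il - delta_jl varies over columns l; delta_jk - delta_ik over rows k
    col = np.zeros(n)
    col[i], col[j] = 1.0, -1.0
    row = np.zeros(n)
    row[j], row[i] = 1.0, -1.0
    pattern = col[None, :] + row[:, None]
    return spec.eta * c_eq.p * c_eq.c[i, j] * J * pattern


def resistance_distance(lm: LaplacianModel) -> np.ndarray:
    """Effective-resistance matrix R_ij = L+_ii + L+_jj - 2 L+_ij.

    The resistance distance of the conductance graph is a metric; R_ij is
    large where paths of conductance between i and j are few or weak.
    Entries between different connected components are infinite.
    """
    d = np.diag(lm.pinv)
    R = d[:, None] + d[None, :] - 2.0 * lm.pinv
    R = np.maximum(R, 0.0)
    if lm.n_components > 1:
        # kernel projector is block-constant within a component, 0 across
        proj = lm.zero_modes() @ lm.zero_modes().T
        cross = ~np.isclose(proj, np.diag(proj)[:, None])
        R[cross] = np.inf
    return R


def predicted_attenuation(
    c0: CostMatrix, i: int, j: int, use_perturbed: bool = True
) -> float:
    """Predicted fractional reversal of a perturbation at synapse j -> i.

    Returns -c0_ij R_ij computed on the Laplacian of ``c0`` — by default
    the *post-perturbation* cost matrix, which is the configuration whose
    relaxation the prediction describes (set ``use_perturbed=False`` only
    if you pass pre-perturbation costs for sensitivity analysis; the
    formula is identical, only the argument changes).  The prediction is
    (1/eta) log(J_ij^final / J_ij^perturbed) = -c0_ij R_ij: the synapse
    reverts by the fraction of total i--j conductance carried by itself.
    """
    lm = graph_laplacian(c0)
    R = resistance_distance(lm)
    if not np.isfinite(R[i, j]):
        raise ValueError(f"neurons {i} and {j} are in different components")
    return float(-c0.c[i, j] * R[i, j])
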