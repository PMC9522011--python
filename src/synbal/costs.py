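"""Gain moments, the noise-sensitivity functional, and power-law synaptic costs.

Sensitivity of the neural dynamics is the trial-averaged squared Frobenius
norm of the dynamics Jacobian -I + J diag(phi'(x)).  With per-neuron gain
moments mu_i = <phi'(x_i)> and sigma2_i = <phi'(x_i)^2> it reduces to

    S = sum_ij sigma2_j J_ij^2  -  2 sum_i mu_i J_ii  +  N.

Because homogeneous nonlinearities have scale-invariant gains, the moments
are constant on the task-preserving manifold, so S restricted to the
manifold is the manifestly convex function

    S(h) = sum_ij c0_ij e^{p (h_j - h_i)} + S_const,

with robustness costs c0_ij = sigma2_j |J0_ij|^p, p = 2.  The same machinery
supports any power-law cost c_ij = alpha_ij |J_ij|^p (e.g. the l1/l2 matrix
penalties).  Throughout we adopt gamma * p = 1 for the descent rate, so the
neural gradient is simply incoming minus outgoing cost per neuron.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .network import (
    InputTrajectory,
    SimSettings,
    WeightConfig,
    activation,
    simulate,
)

__all__ = [
    "GainMoments",
    "CostMatrix",
    "SensitivityValue",
    "estimate_gain_moments",
    "sensitivity",
    "synaptic_costs",
    "costs_at_h",
    "neural_gradients",
    "total_cost",
]


@dataclass(frozen=True)
class GainMoments:
    """First and second moments of the activation derivative per neuron."""

    mu: np.ndarray
    sigma2: np.ndarray

    def __post_init__(self):
        mu = np.asarray(self.mu, dtype=float).ravel()
        sigma2 = np.asarray(self.sigma2, dtype=float).ravel()
        if mu.size != sigma2.size:
            raise ValueError("mu and sigma2 must have the same length")
        if np.any(sigma2 < 0):
            raise ValueError("sigma2 must be nonnegative")
        # variance nonnegativity: <g^2> >= <g>^2 (tolerate rounding)
        if np.any(sigma2 - mu**2 < -1e-12):
            raise ValueError("sigma2 < mu^2: not a valid moment pair")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma2", sigma2)

    @classmethod
    def unit(cls, n: int) -> "GainMoments":
        """Moments of a linear network (phi' identically 1)."""
        return cls(mu=np.ones(n), sigma2=np.ones(n))


@dataclass(frozen=True)
class CostMatrix:
    """Nonnegative per-synapse costs c_ij = alpha_ij |J_ij|^p.

    ``c[i, j]`` is the cost of the synapse from neuron j to neuron i.  The
    descent rate gamma is tied to the exponent by gamma * p = 1.  Self-loop
    costs are carried in c (they contribute to the total cost C) but cancel
    in the neural gradients.
    """

    c: np.ndarray
    p: float = 2.0
    alpha: np.ndarray | None = None
    mode: str = "custom"

    def __post_init__(self):
        c = np.atleast_2d(np.asarray(self.c, dtype=float))
        if c.shape[0] != c.shape[1]:
            raise ValueError("cost matrix must be square")
        if np.any(c < 0):
            raise ValueError("synaptic costs must be nonnegative")
        if not self.p > 0:
            raise ValueError("exponent p must be positive")
        object.__setattr__(self, "c", c)
        if self.alpha is not None:
            alpha = np.atleast_2d(np.asarray(self.alpha, dtype=float))
            if np.any(alpha < 0):
                raise ValueError("alpha must be nonnegative")
            if alpha.shape != c.shape:
                raise ValueError("alpha must match the shape of c")
            object.__setattr__(self, "alpha", alpha)

    @property
    def n(self) -> int:
        return self.c.shape[0]

    @property
    def gamma(self) -> float:
        return 1.0 / self.p


@dataclass(frozen=True)
class SensitivityValue:
    """Sensitivity S and its h-independent offset S_const."""

    S: float
    S_const: float


def estimate_gain_moments(
    config: WeightConfig,
    inputs: Sequence[InputTrajectory],
    sim: SimSettings,
) -> GainMoments:
    """Empirical gain moments over task activity.

    Simulates each input (noiselessly by default — a noisy ``sim`` is
    honoured but estimation on the deterministic trajectories is the
    recommended and default protocol) and averages phi'(x_i) and
    phi'(x_i)^2 over all recorded time points and trials.  The t=0 sample
    is excluded: x(0)=0 is the imposed initial condition, not task
    activity.
    """
    if not inputs:
        raise ValueError("need at least one input trajectory")
    n = config.n_neurons
    s1 = np.zeros(n)
    s2 = np.zeros(n)
    count = 0
    for inp in inputs:
        traj = simulate(config, inp, sim)
        _, gains = activation(config.activation, traj.x[:, 1:])
        s1 += gains.sum(axis=1)
        s2 += (gains**2).sum(axis=1)
        count += gains.shape[1]
    return GainMoments(mu=s1 / count, sigma2=s2 / count)


def sensitivity(J: np.ndarray, moments: GainMoments) -> SensitivityValue:
    """Noise sensitivity S = sum_ij sigma2_j J_ij^2 - 2 sum_i mu_i J_ii + N."""
    J = np.atleast_2d(np.asarray(J, dtype=float))
    n = J.shape[0]
    if moments.mu.size != n:
        raise ValueError("moments do not match the network size")
    quad = float(np.sum(moments.sigma2[None, :] * J**2))
    s_const = float(-2.0 * np.sum(moments.mu * np.diag(J)) + n)
    return SensitivityValue(S=quad + s_const, S_const=s_const)


def synaptic_costs(
    J: np.ndarray,
    moments: GainMoments | None = None,
    alpha: np.ndarray | None = None,
    p: float = 2.0,
) -> CostMatrix:
    """Power-law synaptic costs c_ij = alpha_ij |J_ij|^p.

    Robustness mode (pass ``moments``): alpha_ij = sigma2_j, the
    *presynaptic* second gain moment, with p = 2 — minimizing the total of
    these costs on the manifold minimizes the sensitivity S.  Generic mode
    (pass ``alpha``): user-supplied coefficients and exponent; alpha = 1,
    p = 2 gives the l2 cost J_ij^2.
    """
    J = np.atleast_2d(np.asarray(J, dtype=float))
    n = J.shape[0]
    if (moments is None) == (alpha is None):
        raise ValueError("pass exactly one of moments (robustness) or alpha")
    if moments is not None:
        if p != 2.0:
            raise ValueError("robustness costs require p = 2")
        alpha_mat = np.broadcast_to(moments.sigma2[None, :], (n, n)).copy()
        mode = "robustness"
    else:
        alpha_mat = np.broadcast_to(np.asarray(alpha, dtype=float), (n, n)).copy()
        mode = "custom"
    return CostMatrix(c=alpha_mat * np.abs(J) ** p, p=p, alpha=alpha_mat, mode=mode)


def costs_at_h(c0: CostMatrix, h: np.ndarray) -> CostMatrix:
    """Costs after moving to manifold coordinate h: c_ij = c0_ij e^{p(h_j - h_i)}.

    Zero entries stay exactly zero; this is the image of the cost matrix
    under pi_h with frozen gain moments.
    """
    h = np.asarray(h, dtype=float).ravel()
    if not np.all(np.isfinite(h)):
        raise ValueError("h must be finite")
    if h.size != c0.n:
        raise ValueError("h does not match the cost matrix size")
    factor = np.exp(c0.p * (h[None, :] - h[:, None]))
    return replace(c0, c=c0.c * factor)


def neural_gradients(c: CostMatrix) -> np.ndarray:
    """Per-neuron gradient g_k = (incoming cost sum) - (outgoing cost sum).

    This is -gamma dC/dh under gamma p = 1, the locally computable descent
    direction dh/dt = g.  Self-loop costs appear in both sums and cancel;
    the gradients always sum to zero exactly (each c_ij appears once with
    each sign).
    """
    return c.c.sum(axis=1) - c.c.sum(axis=0)


def total_cost(c: CostMatrix) -> float:
    """Total cost C = sum_ij c_ij, the convex objective on the manifold."""
    return float(c.c.sum())
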