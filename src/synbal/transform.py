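"""The task-preserving transformation pi_h and its conserved quantities.

For h in R^N with H = diag(h), the map

    pi_h(W_in, J, W_out) = (e^{-H} W_in,  e^{-H} J e^{H},  W_out e^{H})

rescales each neuron's inputs while reciprocally rescaling its outputs.
With a homogeneous nonlinearity this leaves the network's entire temporal
input-output map unchanged (the hidden states transform as e^{-H} x), while
acting on J by a positive diagonal similarity — so the spectrum of J and
the product of weights around every directed closed loop are conserved.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .network import InputTrajectory, SimSettings, WeightConfig, simulate

__all__ = [
    "TransformCoords",
    "apply_transform",
    "verify_preservation",
    "PreservationReport",
    "spectrum",
    "loop_product",
]


@dataclass(frozen=True)
class TransformCoords:
    """Coordinates h on the task-preserving manifold (H = diag(h))."""

    h: np.ndarray

    def __post_init__(self):
        h = np.asarray(self.h, dtype=float).ravel()
        if not np.all(np.isfinite(h)):
            raise ValueError("h must be finite")
        object.__setattr__(self, "h", h)


def _as_h(coords: "TransformCoords | np.ndarray") -> np.ndarray:
    if isinstance(coords, TransformCoords):
        return coords.h
    return TransformCoords(np.asarray(coords)).h


def apply_transform(
    config: WeightConfig, coords: "TransformCoords | np.ndarray"
) -> WeightConfig:
    """Apply pi_h to a weight configuration.

    Rows of W_in are scaled by e^{-h_i}, J_ij by e^{h_j - h_i}, and columns
    of W_out by e^{h_j}.  Sign and zero patterns are unchanged: the
    transformation rescales existing synapses but never creates, removes,
    or sign-flips one.
    """
    h = _as_h(coords)
    if h.size != config.n_neurons:
        raise ValueError(
            f"h has length {h.size} but the network has {config.n_neurons} neurons"
        )
    e_neg = np.exp(-h)
    e_pos = np.exp(h)
    return config.with_weights(
        W_in=e_neg[:, None] * config.W_in,
        J=e_neg[:, None] * config.J * e_pos[None, :],
        W_out=config.W_out * e_pos[None, :],
    )


@dataclass(frozen=True)
class PreservationReport:
    """Deviations between a network and its pi_h image over a batch of inputs."""

    max_output_dev: float
    max_scaled_state_dev: float

    def to_dict(self) -> dict:
        return {
            "max_output_dev": self.max_output_dev,
            "max_scaled_state_dev": self.max_scaled_state_dev,
        }


def verify_preservation(
    config: WeightConfig,
    coords: "TransformCoords | np.ndarray",
    inputs: Sequence[InputTrajectory],
    sim: SimSettings,
) -> PreservationReport:
    """Check that pi_h(config) reproduces the outputs of config.

    Both networks are simulated on the identical Euler grid, under which the
    symmetry is exact in discrete time: the transformed hidden states equal
    e^{-H} x step by step, and the outputs agree up to rounding.  Reports
    max |y' - y| and max |x' - e^{-H} x| over all inputs and times.
    """
    if sim.noise_std != 0:
        raise ValueError("preservation is defined for noiseless dynamics")
    h = _as_h(coords)
    transformed = apply_transform(config, h)
    scale = np.exp(-h)[:, None]
    max_y = 0.0
    max_x = 0.0
    for inp in inputs:
        base = simulate(config, inp, sim)
        other = simulate(transformed, inp, sim)
        max_y = max(max_y, float(np.max(np.abs(other.y - base.y))))
        max_x = max(max_x, float(np.max(np.abs(other.x - scale * base.x))))
    return PreservationReport(max_output_dev=max_y, max_scaled_state_dev=max_x)


def spectrum(J: np.ndarray) -> np.ndarray:
    """Eigenvalues of J sorted by (real, imag) for stable comparison."""
    J = np.atleast_2d(np.asarray(J, dtype=float))
    if J.shape[0] != J.shape[1]:
        raise ValueError("J must be square")
    ev = np.linalg.eigvals(J)
    order = np.lexsort((ev.imag, ev.real))
    return ev[order]


def loop_product(J: np.ndarray, cycle: Sequence[int]) -> float:
    """Product of synaptic weights along a directed closed loop.

    ``cycle`` lists neuron indices with first == last; the synapse from
    ``cycle[k]`` to ``cycle[k+1]`` must be present (nonzero).  Loop
    products are invariant under pi_h because the e^{h_j - h_i} factors
    telescope around any closed loop.
    """
    J = np.atleast_2d(np.asarray(J, dtype=float))
    cycle = list(cycle)
    if len(cycle) < 2 or cycle[0] != cycle[-1]:
        raise ValueError("cycle must be closed (first index == last index)")
    prod = 1.0
    for src, dst in zip(cycle[:-1], cycle[1:]):
        w = J[dst, src]
        if w == 0:
            raise ValueError(f"missing synapse {src}->{dst} on cycle")
        prod *= w
    return float(prod)
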