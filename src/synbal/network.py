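"""Nonlinear recurrent rate-network model and its input-output map.

The model is the standard continuous-time rate network

    tau * dx/dt = -x + J phi(x) + W_in u,        y = W_out x,

with activity initialized at the origin and integrated by explicit forward
Euler on a uniform grid.  ``phi`` is restricted to *homogeneous* scalar
nonlinearities (phi(a x) = a phi(x) for a > 0): linear and rectified-linear.
Homogeneity is what makes the per-neuron rescaling symmetry of
:mod:`synbal.transform` exact, and under a shared Euler grid the symmetry
holds exactly step by step, not just in the continuum limit.

Optional additive Gaussian noise (per-step standard deviation ``noise_std``)
models fluctuations in the hidden dynamics; the deterministic input-output
map requires ``noise_std = 0``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "Activation",
    "WeightConfig",
    "InputTrajectory",
    "SimSettings",
    "Trajectory",
    "SimulationError",
    "activation",
    "simulate",
    "input_output_map",
]


class SimulationError(RuntimeError):
    """Raised when the hidden state diverges (non-finite values)."""

    def __init__(self, message: str, time_index: int | None = None):
        super().__init__(message)
        self.time_index = time_index


class Activation(str, Enum):
    """Homogeneous scalar nonlinearities."""

    LINEAR = "linear"
    RELU = "relu"


def activation(kind: Activation | str, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise activation value and derivative (the neuronal gain).

    The ReLU derivative at exactly 0 is defined as 0 (subgradient
    convention; the point is measure zero under task activity).

    Returns
    -------
    (value, derivative) : pair of arrays with the shape of ``x``.
    """
    kind = Activation(kind)
    x = np.asarray(x, dtype=float)
    if kind is Activation.LINEAR:
        return x, np.ones_like(x)
    if kind is Activation.RELU:
        deriv = (x > 0).astype(float)
        return x * deriv, deriv
    raise ValueError(f"unknown activation kind: {kind!r}")  # pragma: no cover


@dataclass(frozen=True)
class WeightConfig:
    """Weight configuration W = (W_in, J, W_out) plus activation and tau.

    ``J[i, j]`` is the synapse from neuron ``j`` to neuron ``i``.
    """

    W_in: np.ndarray
    J: np.ndarray
    W_out: np.ndarray
    activation: Activation = Activation.RELU
    tau: float = 1.0

    def __post_init__(self):
        object.__setattr__(self, "W_in", np.atleast_2d(np.asarray(self.W_in, dtype=float)))
        object.__setattr__(self, "J", np.atleast_2d(np.asarray(self.J, dtype=float)))
        object.__setattr__(self, "W_out", np.atleast_2d(np.asarray(self.W_out, dtype=float)))
        object.__setattr__(self, "activation", Activation(self.activation))
        n = self.J.shape[0]
        if self.J.shape != (n, n):
            raise ValueError(f"J must be square, got {self.J.shape}")
        if self.W_in.shape[0] != n:
            raise ValueError(
                f"W_in has {self.W_in.shape[0]} rows but J is {n}x{n}"
            )
        if self.W_out.shape[1] != n:
            raise ValueError(
                f"W_out has {self.W_out.shape[1]} columns but J is {n}x{n}"
            )
        if not self.tau > 0:
            raise ValueError("tau must be positive")

    @property
    def n_neurons(self) -> int:
        return self.J.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.W_in.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.W_out.shape[0]

    def with_weights(self, W_in=None, J=None, W_out=None) -> "WeightConfig":
        return replace(
            self,
            W_in=self.W_in if W_in is None else W_in,
            J=self.J if J is None else J,
            W_out=self.W_out if W_out is None else W_out,
        )


@dataclass(frozen=True)
class InputTrajectory:
    """A time-gridded input series u(t), shape M x L on a grid starting at 0."""

    times: np.ndarray
    u: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        u = np.atleast_2d(np.asarray(self.u, dtype=float))
        if times.ndim != 1 or times.size < 2:
            raise ValueError("times must be a 1-D grid with at least two points")
        if not np.isclose(times[0], 0.0):
            raise ValueError("input grid must start at 0")
        dts = np.diff(times)
        if np.any(dts <= 0):
            raise ValueError("input grid must be strictly increasing")
        if not np.allclose(dts, dts[0], rtol=1e-9, atol=1e-12):
            raise ValueError("input grid must be uniform")
        if u.shape[1] != times.size:
            raise ValueError(
                f"u has {u.shape[1]} columns but the grid has {times.size} points"
            )
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "u", u)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @classmethod
    def from_series(cls, u: np.ndarray, dt: float) -> "InputTrajectory":
        u = np.atleast_2d(np.asarray(u, dtype=float))
        return cls(times=np.arange(u.shape[1]) * dt, u=u)


@dataclass(frozen=True)
class SimSettings:
    """Euler step, hidden-state noise level and seed.

    ``noise_std`` is the *per-step* standard deviation of the i.i.d.
    Gaussian perturbation added to x after each Euler step.  (An
    alternative sqrt(dt) diffusion scaling would only relabel the noise
    axis; the per-step convention is adopted and documented.)
    """

    dt: float = 0.1
    noise_std: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.noise_std < 0:
            raise ValueError("noise_std must be nonnegative")


@dataclass(frozen=True)
class Trajectory:
    """Simulated trial: input, hidden state and output on a shared grid."""

    times: np.ndarray
    u: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def to_frame(self):
        """Long-format (time, series, index, value) table for CSV export."""
        import pandas as pd

        rows = []
        for name, arr in (("u", self.u), ("x", self.x), ("y", self.y)):
            for idx in range(arr.shape[0]):
                rows.append(
                    pd.DataFrame(
                        {
                            "time": self.times,
                            "series": name,
                            "index": idx,
                            "value": arr[idx],
                        }
                    )
                )
        return pd.concat(rows, ignore_index=True)


def simulate(
    config: WeightConfig, input: InputTrajectory, sim: SimSettings
) -> Trajectory:
    """Forward-Euler integration of the rate dynamics from x(0) = 0.

    The input grid spacing must be an integer multiple of ``sim.dt``
    (the input is held constant between grid points); states are recorded
    at the input grid points.  When ``sim.noise_std > 0``, i.i.d.
    N(0, noise_std^2) noise is added to every neuron after each Euler
    step; the run is deterministic given ``sim.seed``.
    """
    if config.n_inputs != input.u.shape[0]:
        raise ValueError(
            f"config expects {config.n_inputs} inputs, got {input.u.shape[0]}"
        )
    grid_dt = input.dt
    n_sub = int(round(grid_dt / sim.dt))
    if n_sub < 1 or not np.isclose(n_sub * sim.dt, grid_dt, rtol=1e-9):
        raise ValueError(
            f"input grid spacing {grid_dt} is not an integer multiple of dt={sim.dt}"
        )
    n, L = config.n_neurons, input.times.size
    alpha = sim.dt / config.tau
    rng = np.random.default_rng(sim.seed)

    x = np.zeros(n)
    xs = np.empty((n, L))
    xs[:, 0] = x
    for k in range(L - 1):
        u_k = input.u[:, k]
        drive = config.W_in @ u_k
        for _ in range(n_sub):
            phi, _ = activation(config.activation, x)
            x = x + alpha * (-x + config.J @ phi + drive)
            if sim.noise_std > 0:
                x = x + rng.normal(0.0, sim.noise_std, size=n)
        if not np.all(np.isfinite(x)):
            raise SimulationError(
                f"hidden state diverged at time index {k + 1} "
                f"(t={input.times[k + 1]:g})",
                time_index=k + 1,
            )
        xs[:, k + 1] = x
    ys = config.W_out @ xs
    return Trajectory(times=input.times.copy(), u=input.u.copy(), x=xs, y=ys)


def input_output_map(
    config: WeightConfig,
    inputs: Sequence[InputTrajectory],
    sim: SimSettings,
) -> list[np.ndarray]:
    """The deterministic input-output map: y-series for each input trajectory.

    This is the object the task-preserving transformation conserves; it is
    only defined for noiseless dynamics.
    """
    if sim.noise_std != 0:
        raise ValueError("the input-output map is defined for noise_std = 0")
    return [simulate(config, inp, sim).y for inp in inputs]
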