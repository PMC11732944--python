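"""Fixed random leaky-integrator reservoirs.

An echo state network keeps its input and recurrent weights frozen at random
values; only a readout is ever trained.  This module builds those weights and
drives them with input sequences to produce internal-state trajectories.  The
state update is the leaky tanh recurrence

    x[t+1] = (1 - a) * x[t] + a * tanh(W_in @ u[t+1] + W_res @ x[t])

with leakage rate ``a`` in [0, 1] and the recurrent matrix rescaled to a
target spectral radius so that the echo state (fading memory) property holds.
No output-feedback term is used: for classification the label only exists at
the end of the series, so feeding an output back into the dynamics is neither
meaningful nor wanted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

__all__ = [
    "ReservoirSpec",
    "ReservoirWeights",
    "StateTrajectory",
    "build_reservoir",
    "update_state",
    "run_sequence",
    "iterate_batch_states",
]


@dataclass(frozen=True)
class ReservoirSpec:
    """Hyperparameters and RNG seed defining one fixed random reservoir.

    Parameters
    ----------
    M : int
        Number of reservoir neurons.
    a : float
        Leakage rate in [0, 1]; the convex-combination weight between the
        previous state and the new tanh-driven state.
    rho : float
        Target spectral radius of the recurrent matrix (> 0).  Values below
        1 preserve the echo state property.
    k : int
        Input feature count.
    seed : int
        Seed for the generator that draws the weights.  Identical specs
        reproduce bit-identical weights.
    input_scale : float
        Multiplier applied to the standard-normal input weights.
    sparsity : float or None
        If set, fraction of recurrent entries zeroed out (Bernoulli mask)
        before spectral-radius rescaling.  Dense by default.
    """

    M: int = 50
    a: float = 0.9
    rho: float = 0.95
    k: int = 1
    seed: int = 0
    input_scale: float = 1.0
    sparsity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError(f"M must be >= 1, got {self.M}")
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if not 0.0 <= self.a <= 1.0:
            raise ValueError(f"leakage rate a must lie in [0, 1], got {self.a}")
        if self.rho <= 0.0:
            raise ValueError(f"spectral radius rho must be > 0, got {self.rho}")
        if self.sparsity is not None and not 0.0 <= self.sparsity < 1.0:
            raise ValueError(f"sparsity must lie in [0, 1), got {self.sparsity}")


@dataclass(frozen=True)
class ReservoirWeights:
    """Immutable input and recurrent weight matrices of one reservoir."""

    W_in: np.ndarray  # (M, k)
    W_res: np.ndarray  # (M, M)

    def __post_init__(self) -> None:
        self.W_in.setflags(write=False)
        self.W_res.setflags(write=False)

    @property
    def M(self) -> int:
        return self.W_res.shape[0]

    @property
    def k(self) -> int:
        return self.W_in.shape[1]


@dataclass
class StateTrajectory:
    """Per-sample sequence of internal states, one row per driven input."""

    states: np.ndarray  # (n, M)
    sample_id: object = None

    @property
    def n(self) -> int:
        return self.states.shape[0]

    @property
    def M(self) -> int:
        return self.states.shape[1]


def spectral_radius(W: np.ndarray) -> float:
    """Largest eigenvalue magnitude of a square matrix."""
    return float(np.max(np.abs(np.linalg.eigvals(W))))


def build_reservoir(spec: ReservoirSpec) -> ReservoirWeights:
    """Draw the fixed random weights of one reservoir.

    Both matrices are i.i.d. standard normal from the seeded generator;
    the recurrent matrix is then rescaled so its spectral radius equals
    ``spec.rho`` (to floating-point accuracy).
    """
    rng = np.random.default_rng(spec.seed)
    W_in = rng.standard_normal((spec.M, spec.k)) * spec.input_scale
    W_res = rng.standard_normal((spec.M, spec.M))
    if spec.sparsity:
        mask = rng.random((spec.M, spec.M)) >= spec.sparsity
        W_res = W_res * mask
    raw = spectral_radius(W_res)
    if raw < 1e-12:
        raise ValueError(
            "recurrent matrix has (numerically) zero spectral radius and "
            "cannot be rescaled; use a different seed or larger M"
        )
    W_res = W_res * (spec.rho / raw)
    return ReservoirWeights(W_in=W_in, W_res=W_res)


def update_state(
    x: np.ndarray, u: np.ndarray, weights: ReservoirWeights, a: float
) -> np.ndarray:
    """One step of the leaky tanh recurrence."""
    x = np.asarray(x, dtype=float)
    u = np.asarray(u, dtype=float)
    if x.shape != (weights.M,):
        raise ValueError(f"state has shape {x.shape}, expected ({weights.M},)")
    if u.shape != (weights.k,):
        raise ValueError(f"input has shape {u.shape}, expected ({weights.k},)")
    return (1.0 - a) * x + a * np.tanh(weights.W_in @ u + weights.W_res @ x)


def run_sequence(
    seq: np.ndarray,
    weights: ReservoirWeights,
    spec: ReservoirSpec,
    x0: Optional[np.ndarray] = None,
    sample_id: object = None,
) -> StateTrajectory:
    """Drive the reservoir with one sequence from a zero initial state.

    The state is reset (to ``x0``, zero by default) for every sequence so
    that no dependence is carried across samples.
    """
    seq = np.atleast_2d(np.asarray(seq, dtype=float))
    if seq.shape[0] < 1 or seq.size == 0:
        raise ValueError("cannot drive the reservoir with an empty sequence")
    if seq.shape[1] != spec.k:
        raise ValueError(
            f"sequence has {seq.shape[1]} features, reservoir expects {spec.k}"
        )
    x = np.zeros(spec.M) if x0 is None else np.asarray(x0, dtype=float).copy()
    states = np.empty((seq.shape[0], spec.M))
    for j in range(seq.shape[0]):
        x = update_state(x, seq[j], weights, spec.a)
        states[j] = x
    return StateTrajectory(states=states, sample_id=sample_id)


def iterate_batch_states(
    seqs: np.ndarray, weights: ReservoirWeights, a: float
) -> Iterator[np.ndarray]:
    """Drive many equal-length sequences at once, yielding states per step.

    ``seqs`` has shape (N, T, k); each yielded array has shape (N, M) and is
    the internal state of every sample after step t.  All samples start from
    the zero state.  Equivalent to N independent :func:`run_sequence` calls
    but vectorised across the batch.
    """
    seqs = np.asarray(seqs, dtype=float)
    N, T, k = seqs.shape
    if k != weights.k:
        raise ValueError(f"batch has {k} features, reservoir expects {weights.k}")
    X = np.zeros((N, weights.M))
    for t in range(T):
        X = (1.0 - a) * X + a * np.tanh(seqs[:, t, :] @ weights.W_in.T + X @ weights.W_res.T)
        yield X
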