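"""Random Boolean Network reservoirs with fixed in-degree and Gaussian weights.

A reservoir is a network of ``N`` binary threshold neurons updated
synchronously.  Each neuron *i* receives exactly ``K`` recurrent connections
with weights drawn i.i.d. from a Normal distribution, plus (optionally) a
scalar input ``u(t)`` coupled through a per-neuron input weight:

    x_i(t) = theta( w_i^in u(t) + sum_j w_ij x_j(t-1) )

where ``theta`` is the Heaviside step function with the convention
``theta(0) = 0``.  Because ``theta(lam * x) = theta(x)`` for any ``lam > 0``,
the free-running dynamics depend on the weight distribution ``N(mu, sigma)``
only through the ratio ``sigma_star = sigma / mu`` (for ``mu != 0``), so all
simulations run at the canonical form ``(mu, sigma) = (sign(sigma_star),
|sigma_star|)``.  The perfectly balanced case ``mu = 0`` is scale-free and is
represented by the distinguished token :data:`BALANCED`, simulated at
``(0, 1)``.

Half of the neurons are coupled to the input, the other (disjoint) half is
exposed to the readout.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np

__all__ = [
    "BALANCED",
    "ReservoirConfig",
    "Reservoir",
    "ActivityTrace",
    "canonical_params",
    "generate_reservoir",
    "toss_input_weights",
    "init_state",
    "step",
    "run_free",
    "run_driven",
    "save_reservoir",
    "load_reservoir",
]

#: Token for the zero-mean ("perfect balance") weight distribution, for which
#: sigma_star = sigma/mu is undefined and the dynamics are independent of sigma.
BALANCED = "balanced"

SigmaStar = Union[float, str]


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def canonical_params(sigma_star: SigmaStar) -> tuple[float, float]:
    """Canonical (mu, sigma) of the weight distribution for a given sigma_star.

    Positive rescaling of all weights leaves the binary dynamics unchanged,
    so ``(mu, sigma)`` can always be reduced to ``(sign(sigma_star),
    |sigma_star|)``; the balanced case maps to ``(0, 1)``.

    Raises
    ------
    ValueError
        If ``sigma_star`` is zero, non-finite, or an unknown token.
    """
    if isinstance(sigma_star, str):
        if sigma_star == BALANCED:
            return 0.0, 1.0
        raise ValueError(f"unknown sigma_star token: {sigma_star!r}")
    ss = float(sigma_star)
    if not math.isfinite(ss) or ss == 0.0:
        raise ValueError(f"sigma_star must be finite and nonzero, got {ss}")
    return math.copysign(1.0, ss), abs(ss)


@dataclass(frozen=True)
class ReservoirConfig:
    """Parameters of a reservoir: size, in-degree, sigma_star and seed."""

    n_neurons: int = 10_000
    in_degree: int = 16
    sigma_star: SigmaStar = -0.66
    seed: int = 0

    def __post_init__(self):
        if self.n_neurons < 1:
            raise ValueError("n_neurons must be >= 1")
        if not (1 <= self.in_degree <= self.n_neurons - 1):
            raise ValueError("in_degree must satisfy 1 <= K <= N - 1")
        canonical_params(self.sigma_star)  # validates

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class Reservoir:
    """A generated reservoir: recurrent wiring, input weights and masks.

    Attributes
    ----------
    pre_indices : (N, K) int array
        Presynaptic partner of each incoming connection; row *i* lists the
        K distinct neurons feeding neuron *i* (self-connections excluded).
    weights : (N, K) float array
        The corresponding recurrent weights, i.i.d. Normal(mu, sigma) at the
        canonical parameters of ``config.sigma_star``.
    input_weights : (N,) float array
        Input coupling w_i^in; nonzero exactly on ``input_indices``.
    input_indices, readout_indices : (N/2,) int arrays
        Disjoint equal halves: neurons driven by the input, and neurons
        visible to the readout.
    """

    pre_indices: np.ndarray
    weights: np.ndarray
    input_weights: np.ndarray
    input_indices: np.ndarray
    readout_indices: np.ndarray
    config: ReservoirConfig

    @property
    def n_neurons(self) -> int:
        return self.config.n_neurons

    @property
    def in_degree(self) -> int:
        return self.config.in_degree

    def validate(self) -> None:
        """Check structural invariants; raise ValueError on violation."""
        n, k = self.config.n_neurons, self.config.in_degree
        if self.pre_indices.shape != (n, k) or self.weights.shape != (n, k):
            raise ValueError("recurrent tables must have shape (N, K)")
        rows = np.arange(n)[:, None]
        if np.any(self.pre_indices == rows):
            raise ValueError("self-connections are not allowed")
        sorted_pre = np.sort(self.pre_indices, axis=1)
        if np.any(sorted_pre[:, 1:] == sorted_pre[:, :-1]):
            raise ValueError("each neuron needs K distinct presynaptic partners")
        both = np.concatenate([self.input_indices, self.readout_indices])
        if len(self.input_indices) != n // 2 or len(np.unique(both)) != n:
            raise ValueError("input and readout halves must partition the neurons")
        nz = np.flatnonzero(self.input_weights)
        if not np.all(np.isin(nz, self.input_indices)):
            raise ValueError("input weights must be zero outside the input half")
        if np.any(np.abs(self.input_weights) > 0.5):
            raise ValueError("input weights must lie in [-0.5, 0.5]")


def _sample_pre_indices(n: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """K distinct presynaptic partners per neuron, self excluded.

    Rejection sampling on rows with duplicates; with K << N only a few
    percent of rows need redrawing, and the loop is deterministic given rng.
    """
    rows = np.arange(n)
    pre = rng.integers(0, n - 1, size=(n, k))
    pre += pre >= rows[:, None]  # shift past the diagonal -> no self loops
    while True:
        s = np.sort(pre, axis=1)
        bad = np.flatnonzero((s[:, 1:] == s[:, :-1]).any(axis=1))
        if bad.size == 0:
            return pre.astype(np.int64)
        redraw = rng.integers(0, n - 1, size=(bad.size, k))
        redraw += redraw >= rows[bad, None]
        pre[bad] = redraw


def _draw_input_weights(n: int, input_indices: np.ndarray,
                        rng: np.random.Generator) -> np.ndarray:
    w = np.zeros(n)
    w[input_indices] = rng.uniform(-0.5, 0.5, size=len(input_indices))
    return w


def generate_reservoir(config: ReservoirConfig) -> Reservoir:
    """Generate a reservoir from its config, deterministically given the seed.

    Requires an even number of neurons so the input/readout halves are equal.
    """
    n, k = config.n_neurons, config.in_degree
    if n % 2 != 0:
        raise ValueError("n_neurons must be even (equal input/readout halves)")
    mu, sigma = canonical_params(config.sigma_star)
    rng = np.random.default_rng(config.seed)
    pre = _sample_pre_indices(n, k, rng)
    weights = rng.normal(mu, sigma, size=(n, k))
    perm = rng.permutation(n)
    input_idx = np.sort(perm[: n // 2])
    readout_idx = np.sort(perm[n // 2:])
    input_w = _draw_input_weights(n, input_idx, rng)
    return Reservoir(pre, weights, input_w, input_idx, readout_idx, config)


def toss_input_weights(reservoir: Reservoir, seed_or_rng) -> Reservoir:
    """Redraw the input weight values on the same input half (a "tossing")."""
    rng = _as_rng(seed_or_rng)
    new_w = _draw_input_weights(reservoir.n_neurons, reservoir.input_indices, rng)
    return dataclasses.replace(reservoir, input_weights=new_w)


def init_state(n_neurons: int, active_fraction: float, seed_or_rng) -> np.ndarray:
    """Random binary state with round(active_fraction * N) active neurons.

    The count uses round-half-up, so e.g. 20% of 10 neurons is exactly 2.
    """
    if not 0.0 <= active_fraction <= 1.0:
        raise ValueError("active_fraction must lie in [0, 1]")
    rng = _as_rng(seed_or_rng)
    n_active = math.floor(active_fraction * n_neurons + 0.5)
    state = np.zeros(n_neurons, dtype=np.uint8)
    if n_active:
        state[rng.choice(n_neurons, size=n_active, replace=False)] = 1
    return state


@dataclass
class ActivityTrace:
    """Population activity A(t) over a run, split into transient and steady parts.

    Activity is stored as the exact integer count of active neurons so
    periodicity can be tested with integer equality; ``activity`` divides
    by N on access.
    """

    counts: np.ndarray  # int64, length n_transient + n_steady
    n_neurons: int
    n_transient: int

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) <= self.n_transient:
            raise ValueError("steady window must be nonempty")
        if self.counts.min() < 0 or self.counts.max() > self.n_neurons:
            raise ValueError("activity counts out of range")

    @property
    def activity(self) -> np.ndarray:
        return self.counts / self.n_neurons

    @property
    def steady_counts(self) -> np.ndarray:
        return self.counts[self.n_transient:]

    @property
    def steady_activity(self) -> np.ndarray:
        return self.steady_counts / self.n_neurons


def _check_state(reservoir: Reservoir, state: np.ndarray) -> np.ndarray:
    state = np.asarray(state)
    if state.shape != (reservoir.n_neurons,):
        raise ValueError("state length must equal n_neurons")
    return state.astype(np.float64)


def step(reservoir: Reservoir, state: np.ndarray,
         input_value: float = 0.0) -> np.ndarray:
    """One synchronous update of every neuron; theta(0) = 0 exactly."""
    s = _check_state(reservoir, state)
    total = np.einsum("nk,nk->n", reservoir.weights, s[reservoir.pre_indices])
    if input_value != 0.0:
        total = total + reservoir.input_weights * input_value
    return (total > 0).astype(np.uint8)


def _simulate(reservoir: Reservoir, state: np.ndarray, inputs: np.ndarray,
              record_indices: np.ndarray | None = None):
    """Inner loop shared by run_free / run_driven.  Returns (counts, history)."""
    w, pre, win = reservoir.weights, reservoir.pre_indices, reservoir.input_weights
    s = _check_state(reservoir, state)
    n_steps = len(inputs)
    counts = np.empty(n_steps, dtype=np.int64)
    history = None
    if record_indices is not None:
        history = np.empty((n_steps, len(record_indices)), dtype=np.uint8)
    for t in range(n_steps):
        total = np.einsum("nk,nk->n", w, s[pre])
        u = inputs[t]
        if u != 0.0:
            total += win * u
        s = (total > 0).astype(np.float64)
        counts[t] = int(s.sum())
        if history is not None:
            history[t] = s[record_indices]
    return counts, history


def run_free(reservoir: Reservoir, initial_state: np.ndarray,
             n_transient: int = 1000, n_steady: int = 1000) -> ActivityTrace:
    """Free evolution (u = 0) for n_transient + n_steady steps."""
    if n_transient < 1 or n_steady < 1:
        raise ValueError("n_transient and n_steady must be >= 1")
    inputs = np.zeros(n_transient + n_steady)
    counts, _ = _simulate(reservoir, initial_state, inputs)
    return ActivityTrace(counts, reservoir.n_neurons, n_transient)


def run_driven(reservoir: Reservoir, initial_state: np.ndarray,
               input_series: Sequence[float], n_transient: int = 0):
    """Drive the reservoir with u(t) and record the readout-half states.

    Returns
    -------
    trace : ActivityTrace
        Activity over the whole run (``n_transient`` marks the split; with
        the default 0 the steady window is the whole run).
    readout_history : (L, N/2) uint8 array
        State of the readout half at each step, row t aligned with
        ``input_series[t]``.
    """
    inputs = np.asarray(input_series, dtype=np.float64)
    if inputs.ndim != 1 or len(inputs) == 0:
        raise ValueError("input_series must be a nonempty 1-d sequence")
    counts, history = _simulate(reservoir, initial_state, inputs,
                                record_indices=reservoir.readout_indices)
    trace = ActivityTrace(counts, reservoir.n_neurons, n_transient)
    return trace, history


def save_reservoir(reservoir: Reservoir, path) -> None:
    """Write a reservoir as a compressed array archive plus a JSON sidecar."""
    path = Path(path)
    np.savez_compressed(
        path,
        pre_indices=reservoir.pre_indices,
        weights=reservoir.weights,
        input_weights=reservoir.input_weights,
        input_indices=reservoir.input_indices,
        readout_indices=reservoir.readout_indices,
    )
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(reservoir.config.to_dict(), indent=2))


def load_reservoir(path) -> Reservoir:
    """Load a reservoir archive written by :func:`save_reservoir`; validates."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(".npz")
    with np.load(path) as npz:
        arrays = {k: npz[k] for k in npz.files}
    cfg = json.loads(path.with_suffix(".json").read_text())
    res = Reservoir(config=ReservoirConfig(**cfg), **arrays)
    res.validate()
    return res
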