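"""Sigmoid linear readout: training, evaluation, and full task runs.

The readout is a single unit y(t) = f(W_out x(t) + c) with f the logistic
sigmoid, applied to the binary states x(t) of the readout half of a
reservoir.  Training minimizes the mean-squared error against the target
T(t) by full-batch ADAM from zero-initialized weights (learning rate 0.001,
4000 epochs by default).  Performance is the Pearson correlation
Corr(y, T): 1 for a perfect match, 0 for an unrelated output.

A closed-form ridge regression on the logit of the target is included as a
fast alternative and as an independent cross-check of the gradient trainer;
it is not part of the benchmark protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attractors import classify_trace, dominant_attractor
from .reservoir import (Reservoir, init_state, run_driven, run_free,
                        toss_input_weights)
from .signals import Series, TaskSpec, make_target, mackey_glass, white_noise

__all__ = ["ReadoutModel", "PerformanceRecord", "train_readout",
           "ridge_readout", "evaluate", "pearson", "run_task"]


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class ReadoutModel:
    """Trained readout: weights over the readout half, bias, and hyperparams."""

    weights: np.ndarray
    bias: float
    hyperparams: dict = field(default_factory=dict)
    loss_curve: np.ndarray | None = None

    def predict(self, states: np.ndarray) -> np.ndarray:
        return _sigmoid(states @ self.weights + self.bias)


@dataclass(frozen=True)
class PerformanceRecord:
    """Task score of one reservoir, averaged over input-weight tossings."""

    reservoir_id: int
    sigma_star: float | str
    dominant_attractor: str
    task: TaskSpec
    corr: float
    corr_sd: float
    n_tossings: int

    def __post_init__(self):
        if not -1.0 <= self.corr <= 1.0:
            raise ValueError("corr must lie in [-1, 1]")


def train_readout(states: np.ndarray, targets: np.ndarray,
                  learning_rate: float = 0.001, epochs: int = 4000,
                  beta1: float = 0.9, beta2: float = 0.999,
                  eps: float = 1e-8) -> ReadoutModel:
    """Full-batch ADAM on the sigmoid readout's MSE loss, zero-initialized.

    Deterministic given its inputs (no stochastic minibatching, no random
    initialization).  Raises FloatingPointError if the loss diverges.
    """
    x = np.asarray(states, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    if x.shape[0] != len(t):
        raise ValueError("states rows must align one-to-one with targets")
    n, d = x.shape
    w = np.zeros(d)
    c = 0.0
    m = np.zeros(d + 1)
    v = np.zeros(d + 1)
    losses = np.empty(epochs)
    for epoch in range(epochs):
        y = _sigmoid(x @ w + c)
        err = y - t
        losses[epoch] = np.mean(err ** 2)
        if not np.isfinite(losses[epoch]):
            raise FloatingPointError(
                "readout training diverged; try a lower learning rate")
        dz = 2.0 / n * err * y * (1.0 - y)     # dMSE/dz through the sigmoid
        g = np.concatenate([x.T @ dz, [dz.sum()]])
        m = beta1 * m + (1 - beta1) * g
        v = beta2 * v + (1 - beta2) * g ** 2
        mhat = m / (1 - beta1 ** (epoch + 1))
        vhat = v / (1 - beta2 ** (epoch + 1))
        upd = learning_rate * mhat / (np.sqrt(vhat) + eps)
        w -= upd[:-1]
        c -= upd[-1]
    return ReadoutModel(w, float(c),
                        {"optimizer": "adam", "learning_rate": learning_rate,
                         "epochs": epochs}, losses)


def ridge_readout(states: np.ndarray, targets: np.ndarray,
                  alpha: float = 1e-6) -> ReadoutModel:
    """Closed-form ridge regression on logit(T); cross-check for the trainer.

    Solves (X'X + alpha I) w = X' logit(T) with an intercept; the sigmoid of
    the linear fit then approximates T directly.  Targets must lie strictly
    inside (0, 1).
    """
    x = np.asarray(states, dtype=np.float64)
    t = np.asarray(targets, dtype=np.float64)
    if np.any(t <= 0) or np.any(t >= 1):
        raise ValueError("ridge oracle needs targets strictly inside (0, 1)")
    z = np.log(t / (1.0 - t))
    xm = x.mean(axis=0)
    zm = z.mean()
    xc = x - xm
    d = x.shape[1]
    w = np.linalg.solve(xc.T @ xc + alpha * np.eye(d), xc.T @ (z - zm))
    c = zm - xm @ w
    return ReadoutModel(w, float(c), {"optimizer": "ridge", "alpha": alpha})


def pearson(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation; defined as 0 when either side has zero variance."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return 0.0
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def evaluate(model: ReadoutModel, states: np.ndarray,
             targets: np.ndarray) -> float:
    """Corr(y, T) of the model's output against the target."""
    return pearson(model.predict(states), targets)


def _task_input(task: TaskSpec, seed) -> Series:
    if task.kind == "memory":
        return white_noise(task.total_length, seed)
    return mackey_glass(task.total_length, task.mg_tau, seed)


def run_task(reservoir: Reservoir, task: TaskSpec, n_tossings: int = 5,
             seed=0, trainer=train_readout, score_on_train: bool = False,
             attractor_runs: int = 10, dominant_label: str | None = None,
             **trainer_kwargs) -> PerformanceRecord:
    """Benchmark one reservoir on one task, averaged over input tossings.

    For each tossing: redraw the input weights on the same input half,
    generate a fresh input series, drive the reservoir, train the readout
    on the training segment and score Corr(y, T) on the held-out test
    segment (set ``score_on_train`` to score the training segment instead).
    The record is tagged with the reservoir's dominant free-run attractor
    over ``attractor_runs`` random initial conditions, or with
    ``dominant_label`` when the caller has already classified it.
    """
    root = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    toss_seeds = root.spawn(n_tossings)
    scores = []
    for toss_ss in toss_seeds:
        toss_rng_ss, sig_ss, init_ss = toss_ss.spawn(3)
        tossed = toss_input_weights(reservoir, np.random.default_rng(toss_rng_ss))
        series = _task_input(task, np.random.default_rng(sig_ss))
        u, targets, _ = make_target(series, task.delta)
        state0 = init_state(reservoir.n_neurons, 0.2,
                            np.random.default_rng(init_ss))
        # drive with the aligned input so row t of the history matches T(t)
        _, history = run_driven(tossed, state0, u, n_transient=0)
        x = history.astype(np.float64)
        w0, tr = task.washout, task.n_train
        model = trainer(x[w0:w0 + tr], targets[w0:w0 + tr], **trainer_kwargs)
        if score_on_train:
            seg = slice(w0, w0 + tr)
        else:
            seg = slice(w0 + tr, w0 + tr + task.n_test)
        scores.append(evaluate(model, x[seg], targets[seg]))
    scores = np.asarray(scores)
    if dominant_label is None:
        att_labels = []
        att_root = root.spawn(1)[0]
        for init_ss in att_root.spawn(attractor_runs):
            st = init_state(reservoir.n_neurons, 0.2,
                            np.random.default_rng(init_ss))
            att_labels.append(classify_trace(run_free(reservoir, st)))
        dominant_label = dominant_attractor(att_labels).label
    return PerformanceRecord(
        reservoir_id=reservoir.config.seed,
        sigma_star=reservoir.config.sigma_star,
        dominant_attractor=dominant_label, task=task,
        corr=float(scores.mean()), corr_sd=float(scores.std()),
        n_tossings=n_tossings)
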