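"""Task input signals: white noise, Mackey-Glass series, and shifted targets.

The benchmarks drive a reservoir with a scalar series u(t) and train the
readout on the shifted target T(t) = u(t + delta): delta < 0 is a memory
task (recall past input), delta > 0 a prediction task.  Two generators are
provided:

* uncorrelated white noise (i.i.d. uniform), the memory-task input — with
  no autocorrelation, only memory can solve it;
* the Mackey-Glass delay differential equation

      dx/dt = beta * x(t - tau) / (1 + x(t - tau)^n) - gamma * x(t)

  with the standard benchmark constants beta = 0.2, gamma = 0.1, n = 10,
  whose delay tau tunes regularity from periodic (tau = 5) to chaotic
  (tau = 28); the prediction-task input.

All task series are affinely placed in [0.1, 0.9] so they are reachable by
the sigmoid readout with margin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Series", "TaskSpec", "white_noise", "mackey_glass", "make_target",
           "detect_period_approx"]


@dataclass
class Series:
    """A scalar time series with generator provenance (unit sampling step)."""

    values: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("series values must be finite")

    def __len__(self):
        return len(self.values)

    def save(self, path) -> None:
        import json
        from pathlib import Path
        path = Path(path)
        arr = np.column_stack([np.arange(len(self.values)), self.values])
        np.savetxt(path, arr, delimiter=",", header="t,value", comments="")
        path.with_suffix(".json").write_text(json.dumps(self.provenance, indent=2))


@dataclass(frozen=True)
class TaskSpec:
    """A memory or prediction task: shift delta, and tau for Mackey-Glass.

    Lengths are in reservoir ticks; the washout segment is excluded from
    both training and scoring.
    """

    kind: str                  # "memory" | "prediction"
    delta: int
    mg_tau: float | None = None
    washout: int = 1000
    n_train: int = 4000
    n_test: int = 1000

    def __post_init__(self):
        if self.kind not in ("memory", "prediction"):
            raise ValueError("kind must be 'memory' or 'prediction'")
        if self.kind == "memory" and self.delta > 0:
            raise ValueError("memory tasks need delta <= 0")
        if self.kind == "prediction":
            if self.delta <= 0:
                raise ValueError("prediction tasks need delta > 0")
            if self.mg_tau is None:
                raise ValueError("prediction tasks need mg_tau")

    @property
    def total_length(self) -> int:
        return self.washout + self.n_train + self.n_test + abs(self.delta)


def white_noise(length: int, seed) -> Series:
    """I.i.d. uniform noise on [0.1, 0.9]; zero autocorrelation by construction."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    vals = rng.uniform(0.1, 0.9, size=length)
    return Series(vals, provenance={"generator": "white_noise",
                                    "length": length, "low": 0.1, "high": 0.9,
                                    "seed": repr(seed)})


def _mg_integrate(n_samples: int, tau: float, history: np.ndarray,
                  beta: float, gamma: float, n_exp: float,
                  dt: float, per_sample: int) -> np.ndarray:
    """RK4 integration of the Mackey-Glass DDE with linear lag interpolation.

    ``history`` holds x on [-tau, 0] at step dt (lag+1 points, last = x(0)).
    Returns x at unit sampling times 1..n_samples.
    """
    lag = int(round(tau / dt))
    if abs(lag * dt - tau) > 1e-9:
        raise ValueError("tau must be a multiple of the internal step")
    total_steps = n_samples * per_sample
    buf = np.empty(lag + 1 + total_steps)
    buf[: lag + 1] = history

    def f(x, x_lag):
        return beta * x_lag / (1.0 + x_lag ** n_exp) - gamma * x

    for i in range(total_steps):
        j = lag + i              # index of x(t) in buf
        x = buf[j]
        xl0 = buf[j - lag]                       # x(t - tau)
        xl1 = buf[j - lag + 1]                   # x(t + dt - tau)
        xlh = 0.5 * (xl0 + xl1)                  # x(t + dt/2 - tau), linear
        k1 = f(x, xl0)
        k2 = f(x + 0.5 * dt * k1, xlh)
        k3 = f(x + 0.5 * dt * k2, xlh)
        k4 = f(x + dt * k3, xl1)
        buf[j + 1] = x + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
    if not np.all(np.isfinite(buf)):
        raise FloatingPointError("Mackey-Glass integration diverged")
    return buf[lag + per_sample::per_sample][:n_samples]


def mackey_glass(length: int, tau: float, seed=None, *,
                 history: float | np.ndarray | None = None,
                 beta: float = 0.2, gamma: float = 0.1, n_exp: float = 10.0,
                 dt: float = 0.1, warmup: int = 1000,
                 rescale: tuple[float, float] | None = (0.1, 0.9)) -> Series:
    """Mackey-Glass series sampled at unit intervals.

    Integrates by fourth-order Runge-Kutta at internal step ``dt``, samples
    every 1.0, discards ``warmup`` samples, then rescales affinely into
    ``rescale`` (pass None for the raw trajectory).  The initial history is
    constant 1.2 with a small seeded perturbation when ``seed`` is given;
    pass ``history`` explicitly to override (a constant history of exactly
    1.0 is the equation's equilibrium and is preserved exactly).
    """
    if length < 1 or tau < 1:
        raise ValueError("length and tau must be >= 1")
    per_sample = int(round(1.0 / dt))
    lag = int(round(tau / dt))
    if history is None:
        hist = np.full(lag + 1, 1.2)
        if seed is not None:
            hist += np.random.default_rng(seed).uniform(-0.1, 0.1, lag + 1)
    elif np.isscalar(history):
        hist = np.full(lag + 1, float(history))
    else:
        hist = np.asarray(history, dtype=np.float64)
        if len(hist) != lag + 1:
            raise ValueError(f"history must have tau/dt + 1 = {lag + 1} points")
    raw = _mg_integrate(length + warmup, tau, hist, beta, gamma, n_exp,
                        dt, per_sample)
    vals = raw[warmup:]
    prov = {"generator": "mackey_glass", "tau": tau, "beta": beta,
            "gamma": gamma, "n": n_exp, "dt": dt, "warmup": warmup,
            "length": length, "seed": repr(seed)}
    if rescale is not None:
        lo, hi = rescale
        vmin, vmax = vals.min(), vals.max()
        if vmax > vmin:
            vals = lo + (hi - lo) * (vals - vmin) / (vmax - vmin)
        else:
            vals = np.full_like(vals, 0.5 * (lo + hi))
        prov["rescale"] = {"target": [lo, hi],
                           "source_min": float(vmin), "source_max": float(vmax)}
    return Series(vals, provenance=prov)


def detect_period_approx(values, tol: float = 0.01,
                         min_period: int = 2) -> int | None:
    """Smallest near-period of a real-valued series, or None.

    Returns the smallest lag p with min_period <= p <= len/2 whose RMS
    self-mismatch sqrt(mean((x(t+p) - x(t))^2)) is below ``tol``.  Sampled
    limit cycles are rarely exactly periodic at integer lags (the intrinsic
    period is incommensurate with the sampling step), so a tolerance is
    required; chaotic series stay far above any small tolerance at all lags
    beyond the smoothness scale.
    """
    x = np.asarray(values, dtype=np.float64)
    w = len(x)
    if w < 2 * min_period:
        raise ValueError("series too short for period detection")
    for p in range(min_period, w // 2 + 1):
        if np.sqrt(np.mean((x[:-p] - x[p:]) ** 2)) < tol:
            return p
    return None


def make_target(series: Series, delta: int):
    """Align input u(t) with the shifted target T(t) = u(t + delta).

    Returns ``(u_aligned, target, t_index)`` where ``t_index`` gives the
    original time index of each aligned row; |delta| samples are trimmed.
    """
    u = series.values if isinstance(series, Series) else np.asarray(series)
    n = len(u)
    if abs(delta) >= n:
        raise ValueError("|delta| must be smaller than the series length")
    t = np.arange(max(0, -delta), n - max(0, delta))
    return u[t], u[t + delta], t
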