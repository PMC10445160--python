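"""Free-run ensemble statistics and criticality detection.

For each value of the control parameter sigma_star, an ensemble of reservoirs
is run freely from a 20%-active initial state.  Per reservoir we measure the
time mean and time variance of the steady activity, and the BiEntropy of the
steady activity binarized at its own time mean.  Across reservoirs we form
the ensemble aggregates <A>, <dA^2>, <H_b> and the BiEntropy variance
<dH_b^2>; the peak of <dH_b^2> over a sigma_star grid locates the critical
point, and the contiguous interval where it exceeds a small fraction of the
peak is the critical region ("edge of chaos").

BiEntropy is Croll's weighted entropy of a binary string and its successive
binary (XOR) derivatives: 0 for fully ordered streams, 1 for fully
disordered ones.  The power-weighted form (BiEn) is used up to 32 bits and
the logarithmic-weight form (TBiEn) above, following Croll's prescription
for long strings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import xlogy

from .reservoir import (ActivityTrace, ReservoirConfig, SigmaStar,
                        generate_reservoir, init_state, run_free)

__all__ = [
    "SteadyStats", "EnsembleStats", "CriticalityReport",
    "steady_stats", "binarize_trace", "bientropy",
    "ensemble_stats", "locate_critical", "NoTransitionError",
]

#: Fraction of initially active neurons in every free run.
INITIAL_ACTIVITY = 0.2

#: Critical region = contiguous interval with <dH_b^2> above this fraction
#: of its peak (a finite-sample proxy for "nonzero variance").
REGION_THRESHOLD = 0.01


class NoTransitionError(RuntimeError):
    """Raised when a scan shows no BiEntropy-variance signal anywhere."""


@dataclass(frozen=True)
class SteadyStats:
    mean_activity: float
    activity_variance: float
    bientropy: float


@dataclass(frozen=True)
class EnsembleStats:
    """Per-sigma_star aggregates over an ensemble of reservoirs."""

    sigma_star: SigmaStar
    n_reservoirs: int
    mean_activity: float          # <A-bar>
    activity_variance: float      # <dA^2-bar>
    mean_bientropy: float         # <H_b>
    bientropy_variance: float     # <dH_b^2>, population convention


@dataclass(frozen=True)
class CriticalityReport:
    critical_point: float
    region_low: float
    region_high: float
    peak_variance: float
    tie: bool = False

    def to_dict(self) -> dict:
        return {"critical_point": self.critical_point,
                "critical_region": [self.region_low, self.region_high],
                "peak_variance": self.peak_variance, "tie": self.tie}


def steady_stats(trace: ActivityTrace) -> tuple[float, float]:
    """Time mean and (population) time variance of the steady activity."""
    a = trace.steady_activity
    mean = float(a.mean())
    return mean, float(np.mean((a - mean) ** 2))


def binarize_trace(trace: ActivityTrace) -> np.ndarray:
    """Binarize the steady activity at its own time mean.

    s(t) = 1 where A(t) > A-bar.  Parameter-free: fixed points map to the
    all-zero string, oscillations to alternating strings.  Thresholding is
    done on exact integer counts to avoid float ties.
    """
    c = trace.steady_counts
    # A(t) > mean(A)  <=>  c(t) * W > sum(c)  in exact integer arithmetic
    w = len(c)
    return (c * w > c.sum()).astype(np.uint8)


def _entropy(p: float) -> float:
    return float(-(xlogy(p, p) + xlogy(1.0 - p, 1.0 - p)) / np.log(2.0))


def bientropy(bits) -> float:
    """Croll's BiEntropy of a binary string, in [0, 1].

    Uses the power-weighted BiEn for strings of <= 32 bits and the
    logarithmic-weight TBiEn for longer strings (power weights overflow and
    concentrate all mass on the last derivative).  Invariant under bitwise
    complement, since the entropy term is symmetric in p <-> 1-p and XOR
    derivatives of order >= 1 are unchanged.
    """
    d = np.asarray(bits, dtype=np.uint8) if not isinstance(bits, str) \
        else np.frombuffer(bits.encode(), dtype=np.uint8) - ord("0")
    n = len(d)
    if n < 2:
        raise ValueError("bientropy needs at least 2 bits")
    if np.any(d > 1):
        raise ValueError("input must be binary")
    use_power = n <= 32
    num = 0.0
    den = 0.0
    for k in range(n - 1):
        weight = 2.0 ** k if use_power else np.log2(k + 2.0)
        num += _entropy(float(d.mean())) * weight
        den += weight
        d = d[1:] ^ d[:-1]
    return num / den


def free_run_stats(config: ReservoirConfig, init_seed,
                   n_transient: int = 1000, n_steady: int = 1000) -> SteadyStats:
    """Generate one reservoir, free-run it, and compute its steady statistics."""
    res = generate_reservoir(config)
    state = init_state(config.n_neurons, INITIAL_ACTIVITY, init_seed)
    trace = run_free(res, state, n_transient, n_steady)
    mean, var = steady_stats(trace)
    return SteadyStats(mean, var, bientropy(binarize_trace(trace)))


def ensemble_stats(sigma_star: SigmaStar, n_reservoirs: int,
                   n_neurons: int = 2000, in_degree: int = 16,
                   seed=0, n_transient: int = 1000,
                   n_steady: int = 1000) -> EnsembleStats:
    """Aggregate free-run statistics over an ensemble at one sigma_star.

    Each reservoir is generated and run once from its own seeded 20%-active
    initial state; seeds derive deterministically from ``seed`` via a
    SeedSequence spawn per reservoir.  The BiEntropy variance uses the
    population convention (divide by n).
    """
    if n_reservoirs < 2:
        raise ValueError("need at least 2 reservoirs for ensemble variance")
    root = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    children = root.spawn(n_reservoirs)
    per = []
    for child in children:
        gen_ss, init_ss = child.spawn(2)
        cfg = ReservoirConfig(n_neurons, in_degree, sigma_star,
                              seed=int(gen_ss.generate_state(1)[0] % (2**31)))
        per.append(free_run_stats(cfg, np.random.default_rng(init_ss),
                                  n_transient, n_steady))
    means = np.array([s.mean_activity for s in per])
    avars = np.array([s.activity_variance for s in per])
    hb = np.array([s.bientropy for s in per])
    return EnsembleStats(
        sigma_star=sigma_star, n_reservoirs=n_reservoirs,
        mean_activity=float(means.mean()),
        activity_variance=float(avars.mean()),
        mean_bientropy=float(hb.mean()),
        bientropy_variance=float(np.mean((hb - hb.mean()) ** 2)),
    )


def stats_table(stats: list[EnsembleStats]) -> pd.DataFrame:
    """Long-format table of ensemble statistics (one row per sigma_star)."""
    return pd.DataFrame([{
        "sigma_star": s.sigma_star, "n_reservoirs": s.n_reservoirs,
        "mean_activity": s.mean_activity,
        "activity_variance": s.activity_variance,
        "mean_bientropy": s.mean_bientropy,
        "bientropy_variance": s.bientropy_variance,
    } for s in stats])


def locate_critical(stats: list[EnsembleStats],
                    region_threshold: float = REGION_THRESHOLD) -> CriticalityReport:
    """Critical point and region from a grid of ensemble statistics.

    The critical point is the grid argmax of the BiEntropy variance
    (leftmost on ties, flagged); the critical region is the maximal
    contiguous grid interval containing it where the variance exceeds
    ``region_threshold`` times the peak.
    """
    if len(stats) < 3:
        raise ValueError("need at least 3 grid points")
    grid = np.array([float(s.sigma_star) for s in stats])
    order = np.argsort(grid)
    grid = grid[order]
    var = np.array([s.bientropy_variance for s in stats])[order]
    if np.all(var == 0):
        raise NoTransitionError("BiEntropy variance is zero on the whole grid")
    peak = int(np.argmax(var))
    tie = bool(np.count_nonzero(var == var[peak]) > 1)
    above = var > region_threshold * var[peak]
    lo = peak
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = peak
    while hi < len(grid) - 1 and above[hi + 1]:
        hi += 1
    return CriticalityReport(critical_point=float(grid[peak]),
                             region_low=float(grid[lo]),
                             region_high=float(grid[hi]),
                             peak_variance=float(var[peak]), tie=tie)
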