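"""Attractor classification of free-running steady-state activity.

The steady activity sequence A(t) of a free-running reservoir is assigned to
one of four categories:

* ``extinguished`` -- A(t) = 0 throughout the steady window (the activity
  died during the transient);
* ``fixed``        -- A(t) constant and nonzero (includes saturation A = 1);
* ``cyclic``       -- A(t) periodic with minimal period 2 <= p <= W/2;
* ``irregular``    -- no period up to W/2 within the observation window.

Classification operates on the activity (the fraction of active neurons),
not on the full state vector, stored as exact integer active-counts so
periodicity is tested with integer equality.  Because the network is finite
and deterministic every state sequence is eventually periodic; ``irregular``
therefore means "period longer than the window can certify", and a cyclic
activity can in principle alias a longer state cycle (quantified in the
test-suite against exhaustive state-space enumeration on tiny networks).

Running a reservoir from many random initial conditions and taking the modal
category gives its *dominant attractor*.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reservoir import ActivityTrace

__all__ = ["CATEGORIES", "AttractorLabel", "DominantAttractor",
           "detect_period", "classify_trace", "dominant_attractor",
           "attractor_distribution"]

#: Category order, also the tie-break priority (increasing dynamical
#: complexity): ties in the dominant-attractor vote resolve to the earlier.
CATEGORIES = ("extinguished", "fixed", "cyclic", "irregular")


@dataclass(frozen=True)
class AttractorLabel:
    category: str
    period: int | None = None  # minimal period, present iff cyclic

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if (self.category == "cyclic") != (self.period is not None):
            raise ValueError("period must be present iff cyclic")
        if self.period is not None and self.period < 2:
            raise ValueError("cyclic period must be >= 2")


@dataclass(frozen=True)
class DominantAttractor:
    label: str
    dominance: float            # fraction of runs yielding the modal label
    counts: dict
    tie: bool = False


def detect_period(counts) -> int | None:
    """Smallest p with 1 <= p <= W/2 such that A(t) = A(t+p) for all t.

    ``counts`` must be the exact integer active-counts of the steady window;
    equality is exact.  Returns None when no period up to W/2 fits.
    """
    c = np.asarray(counts)
    if not np.issubdtype(c.dtype, np.integer):
        raise TypeError("detect_period needs exact integer activity counts")
    w = len(c)
    if w < 4:
        raise ValueError("window too short for period detection")
    for p in range(1, w // 2 + 1):
        if np.array_equal(c[:-p], c[p:]):
            return p
    return None


def classify_trace(trace: ActivityTrace) -> AttractorLabel:
    """Assign the steady window of a trace to one of the four categories."""
    c = trace.steady_counts
    if not c.any():
        return AttractorLabel("extinguished")
    p = detect_period(c)
    if p == 1:
        return AttractorLabel("fixed")
    if p is not None:
        return AttractorLabel("cyclic", period=p)
    return AttractorLabel("irregular")


def dominant_attractor(labels) -> DominantAttractor:
    """Modal category over runs; ties resolve to the lower-complexity category.

    Ties are rare and flagged in the result.
    """
    labels = list(labels)
    if not labels:
        raise ValueError("need at least one label")
    counts = Counter(lab.category for lab in labels)
    best = max(counts.values())
    winners = [cat for cat in CATEGORIES if counts.get(cat, 0) == best]
    return DominantAttractor(
        label=winners[0], dominance=best / len(labels),
        counts={cat: counts.get(cat, 0) for cat in CATEGORIES},
        tie=len(winners) > 1)


def attractor_distribution(labels) -> dict:
    """Pooled category fractions over (reservoir x initial condition) runs."""
    labels = list(labels)
    if not labels:
        raise ValueError("need at least one label")
    counts = Counter(lab.category for lab in labels)
    n = len(labels)
    return {cat: counts.get(cat, 0) / n for cat in CATEGORIES}


def labels_table(rows) -> pd.DataFrame:
    """Long-format table (sigma_star, reservoir_id, init_id, category, period)."""
    return pd.DataFrame(rows, columns=["sigma_star", "reservoir_id",
                                       "init_id", "category", "period"])
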