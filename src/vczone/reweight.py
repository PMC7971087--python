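"""Thermodynamic reweighting of stored snapshots into a canonical ensemble.

A snapshot stored in RC bin b was visited c(b) times in total while the
canonical probability of b is Q(b); assigning each snapshot the weight
w ∝ Q(b)/c(b) therefore turns the biased zone-sampling store into a
thermally equilibrated (canonical) ensemble at the simulation temperature:
weighted averages over snapshots estimate equilibrium expectations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import HistogramStack, QGrid
from .errors import (EmptyDistributionError, InconsistentStoreError,
                     InvalidSpecError)
from .rc import Snapshot

__all__ = ["CanonicalEnsemble", "snapshot_weights", "reweighted_distribution"]

#: snapshots in bins whose Q falls below this fraction of the peak get zero
#: weight and are flagged (their canonical probability is statistically
#: indistinguishable from zero)
Q_FLOOR_FRACTION = 1e-8


@dataclass
class CanonicalEnsemble:
    """Snapshots plus normalized nonnegative thermodynamic weights."""

    snapshots: list[Snapshot]
    weights: np.ndarray
    temperature: float
    q_iteration: int = 0
    n_zero_weight: int = 0

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape[0] != len(self.snapshots):
            raise InvalidSpecError("one weight per snapshot required")
        if np.any(self.weights < 0):
            raise InvalidSpecError("weights must be nonnegative")
        total = self.weights.sum()
        if abs(total - 1.0) > 1e-12 and total > 0:
            self.weights = self.weights / total


def snapshot_weights(snapshots: list[Snapshot], q: QGrid,
                     raw_counts: np.ndarray, temperature: float = 300.0,
                     q_floor_fraction: float = Q_FLOOR_FRACTION) -> CanonicalEnsemble:
    """Weights w_i ∝ Q(b(λ_i)) / raw_counts(b(λ_i)), normalized to sum 1.

    ``raw_counts`` are the total per-bin snapshot counts over all states and
    iterations.  A snapshot in a zero-count bin means the store and the
    histograms disagree and raises :class:`InconsistentStoreError`.
    """
    qs = q.as_mode("sum1")
    raw_counts = np.asarray(raw_counts)
    floor = q_floor_fraction * qs.values.max()
    w = np.empty(len(snapshots))
    n_zero = 0
    for i, snap in enumerate(snapshots):
        b = qs.grid.bin_of(snap.rc)
        c = raw_counts[b]
        if c <= 0:
            raise InconsistentStoreError(
                f"snapshot {i} maps to bin {b} with zero recorded counts")
        qb = qs.values[b]
        if qb <= floor:
            w[i] = 0.0
            n_zero += 1
        else:
            w[i] = qb / c
    total = w.sum()
    if total <= 0:
        raise EmptyDistributionError("all snapshot weights vanished")
    return CanonicalEnsemble(list(snapshots), w / total, temperature,
                             q_iteration=q.iteration, n_zero_weight=n_zero)


def reweighted_distribution(ensemble: CanonicalEnsemble, observable,
                            bins: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted histogram of a per-snapshot observable, unit integral.

    ``observable`` is either an array of per-snapshot values or a callable
    applied to each snapshot.  Returns (density, edges).
    """
    if callable(observable):
        values = np.array([observable(s) for s in ensemble.snapshots])
    else:
        values = np.asarray(observable, dtype=float)
    if not np.all(np.isfinite(values)):
        raise InvalidSpecError("observable must be finite for all snapshots")
    edges = np.asarray(bins, dtype=float)
    hist, edges = np.histogram(values, bins=edges, weights=ensemble.weights)
    total = hist.sum()
    if total <= 0:
        raise EmptyDistributionError("no weight falls inside the bin range")
    widths = np.diff(edges)
    density = hist / (total * widths)
    return density, edges
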