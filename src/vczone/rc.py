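"""Reaction coordinates and the overlapping-zone virtual system.

An RC is the distance between the centers (geometric or mass-weighted) of
two bead groups.  The virtual system discretizes the joint RC space into a
Cartesian product of per-RC overlapping intervals ("zones"); a virtual
state is one zone index per RC.  Zone boundaries always coincide with
histogram bin edges so overlap regions contain whole bins — the stitching
estimator requires this.

Interval convention: zones and bins are closed on the left, open on the
right, except the last one on each axis which is closed on both ends.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidGroupError, InvalidGridError, OutOfRangeError

__all__ = [
    "RCDefinition",
    "ZoneAxis",
    "ZoneGrid",
    "Snapshot",
    "group_center",
    "rc_values",
    "build_zone_grid",
    "states_containing",
]

#: how far (Å) beyond a zone/grid boundary a value may sit and still count
#: as inside — matches the soft half-harmonic wall penetration scale
WALL_TOL = 0.5


def group_center(coords: np.ndarray, ids, weighting: str = "geometric",
                 masses: np.ndarray | None = None) -> np.ndarray:
    """Geometric or mass-weighted center of a bead group."""
    ids = np.asarray(ids, dtype=np.intp)
    if ids.size == 0:
        raise InvalidGroupError("cannot take the center of an empty group")
    pts = np.asarray(coords, dtype=float)[ids]
    if weighting == "geometric":
        return pts.mean(axis=0)
    if weighting == "mass":
        if masses is None:
            raise InvalidGroupError("mass weighting requires masses")
        w = np.asarray(masses, dtype=float)[ids]
        return (w[:, None] * pts).sum(axis=0) / w.sum()
    raise InvalidGroupError(f"unknown weighting {weighting!r}")


@dataclass
class RCDefinition:
    """Distance between the centers of two bead groups."""

    name: str
    group_A: np.ndarray
    group_B: np.ndarray
    weighting: str = "geometric"     # applied to both groups
    range: tuple[float, float] = (0.0, 20.0)

    def __post_init__(self):
        self.group_A = np.asarray(self.group_A, dtype=np.intp)
        self.group_B = np.asarray(self.group_B, dtype=np.intp)
        if self.group_A.size == 0 or self.group_B.size == 0:
            raise InvalidGroupError(f"RC {self.name!r}: groups must be nonempty")
        if set(self.group_A.tolist()) & set(self.group_B.tolist()):
            raise InvalidGroupError(f"RC {self.name!r}: groups must be disjoint")
        if not self.range[0] < self.range[1]:
            raise InvalidGridError(f"RC {self.name!r}: empty range")

    def value(self, coords: np.ndarray, masses: np.ndarray | None = None) -> float:
        ca = group_center(coords, self.group_A, self.weighting, masses)
        cb = group_center(coords, self.group_B, self.weighting, masses)
        return float(np.linalg.norm(ca - cb))


def rc_values(rc_defs: Sequence[RCDefinition], coords: np.ndarray,
              masses: np.ndarray | None = None) -> np.ndarray:
    """λ value per RC (Å)."""
    return np.array([rc.value(coords, masses) for rc in rc_defs])


# ----------------------------------------------------------------------
# Zone grid
# ----------------------------------------------------------------------

@dataclass
class ZoneAxis:
    """Overlapping zones along one RC, integer-aligned on a shared bin grid."""

    lo: float
    hi: float
    n_zones: int
    bins_per_zone: int
    overlap_bins: int

    def __post_init__(self):
        if self.n_zones < 1:
            raise InvalidGridError("need at least one zone")
        if not 0 < self.overlap_bins < self.bins_per_zone:
            raise InvalidGridError("overlap must be a proper fraction of a zone")
        if not self.hi > self.lo:
            raise InvalidGridError("axis range is empty")

    @property
    def stride_bins(self) -> int:
        return self.bins_per_zone - self.overlap_bins

    @property
    def n_bins(self) -> int:
        return (self.n_zones - 1) * self.stride_bins + self.bins_per_zone

    @property
    def bin_width(self) -> float:
        return (self.hi - self.lo) / self.n_bins

    @property
    def bin_edges(self) -> np.ndarray:
        return self.lo + self.bin_width * np.arange(self.n_bins + 1)

    @property
    def bin_centers(self) -> np.ndarray:
        return self.lo + self.bin_width * (np.arange(self.n_bins) + 0.5)

    @property
    def intervals(self) -> list[tuple[float, float]]:
        w = self.bin_width
        out = []
        for i in range(self.n_zones):
            a = self.lo + i * self.stride_bins * w
            out.append((a, a + self.bins_per_zone * w))
        return out

    def zone_bin_range(self, zone: int) -> tuple[int, int]:
        """Half-open global-bin index range covered by ``zone``."""
        start = zone * self.stride_bins
        return start, start + self.bins_per_zone

    def clamp(self, value: float, tol: float = WALL_TOL) -> float:
        if value < self.lo - tol or value > self.hi + tol:
            raise OutOfRangeError(
                f"value {value:.3f} outside axis [{self.lo}, {self.hi}] ± {tol}"
            )
        return float(min(max(value, self.lo), np.nextafter(self.hi, -np.inf)))

    def bin_index(self, value: float, tol: float = WALL_TOL) -> int:
        v = self.clamp(value, tol)
        return min(int((v - self.lo) / self.bin_width), self.n_bins - 1)

    def zones_containing(self, value: float, tol: float = WALL_TOL) -> list[int]:
        v = self.clamp(value, tol)
        out = []
        for i, (a, b) in enumerate(self.intervals):
            last = i == self.n_zones - 1
            if (a <= v < b) or (last and a <= v <= b):
                out.append(i)
        return out


@dataclass
class ZoneGrid:
    """Cartesian product of per-RC zone axes over the joint RC space."""

    axes: list[ZoneAxis]

    @property
    def ndim(self) -> int:
        return len(self.axes)

    @property
    def shape(self) -> tuple[int, ...]:
        return tuple(ax.n_bins for ax in self.axes)

    @property
    def n_states(self) -> int:
        return int(np.prod([ax.n_zones for ax in self.axes]))

    @property
    def bin_volume(self) -> float:
        return float(np.prod([ax.bin_width for ax in self.axes]))

    def all_states(self) -> Iterable[tuple[int, ...]]:
        return itertools.product(*[range(ax.n_zones) for ax in self.axes])

    def states_containing(self, lam, tol: float = WALL_TOL) -> list[tuple[int, ...]]:
        lam = np.atleast_1d(np.asarray(lam, dtype=float))
        per_axis = [ax.zones_containing(v, tol) for ax, v in zip(self.axes, lam)]
        return [tuple(s) for s in itertools.product(*per_axis)]

    def state_contains(self, state, lam, tol: float = WALL_TOL) -> bool:
        lam = np.atleast_1d(np.asarray(lam, dtype=float))
        for ax, z, v in zip(self.axes, state, lam):
            a, b = ax.intervals[z]
            if not (a - tol <= v <= b + tol):
                return False
        return True

    def state_bounds(self, state) -> tuple[np.ndarray, np.ndarray]:
        los, his = [], []
        for ax, z in zip(self.axes, state):
            a, b = ax.intervals[z]
            los.append(a)
            his.append(b)
        return np.array(los), np.array(his)

    def state_bin_slices(self, state) -> tuple[slice, ...]:
        return tuple(
            slice(*ax.zone_bin_range(z)) for ax, z in zip(self.axes, state)
        )

    def bin_of(self, lam, tol: float = WALL_TOL) -> tuple[int, ...]:
        lam = np.atleast_1d(np.asarray(lam, dtype=float))
        return tuple(ax.bin_index(v, tol) for ax, v in zip(self.axes, lam))

    def state_center(self, state) -> np.ndarray:
        lo, hi = self.state_bounds(state)
        return 0.5 * (lo + hi)

    def normalized(self, lam) -> np.ndarray:
        """λ mapped into [0, 1] per axis (used by the GA seed matcher)."""
        lam = np.atleast_1d(np.asarray(lam, dtype=float))
        return np.array([
            (v - ax.lo) / (ax.hi - ax.lo) for ax, v in zip(self.axes, lam)
        ])


def build_zone_grid(ranges, n_vs, overlap_fraction: float = 0.5,
                    bins_per_zone: int = 4) -> ZoneGrid:
    """Uniform overlapping zones covering each RC range exactly.

    Zone width w solves span = w·((n−1)(1−overlap_fraction) + 1); the bin
    width is chosen so a zone holds ``bins_per_zone`` whole bins and the
    overlap region holds ``round(bins_per_zone · overlap_fraction)`` of
    them — zone boundaries therefore always sit on bin edges.

    ``ranges`` may be one (lo, hi) pair or a sequence of them; ``n_vs``
    likewise a single count or one per RC.
    """
    if not 0 < overlap_fraction < 1:
        raise InvalidGridError("overlap_fraction must be in (0, 1)")
    rng_list = [ranges] if np.isscalar(ranges[0]) else list(ranges)
    n_list = [n_vs] * len(rng_list) if np.isscalar(n_vs) else list(n_vs)
    if len(n_list) != len(rng_list):
        raise InvalidGridError("n_vs must match number of RC ranges")
    overlap_bins = int(round(bins_per_zone * overlap_fraction))
    if not 0 < overlap_bins < bins_per_zone:
        raise InvalidGridError(
            "bins_per_zone too small to realize the requested overlap"
        )
    axes = []
    for (lo, hi), n in zip(rng_list, n_list):
        if n < 2:
            raise InvalidGridError("need n_vs >= 2 zones per RC")
        span = hi - lo
        if span <= 0:
            raise InvalidGridError("range too narrow for the requested zones")
        axes.append(ZoneAxis(float(lo), float(hi), int(n),
                             bins_per_zone, overlap_bins))
    return ZoneGrid(axes)


def states_containing(lam, grid: ZoneGrid, tol: float = WALL_TOL):
    """Module-level convenience wrapper for :meth:`ZoneGrid.states_containing`."""
    return grid.states_containing(lam, tol)


# ----------------------------------------------------------------------
# Snapshot
# ----------------------------------------------------------------------

@dataclass
class Snapshot:
    """One stored frame: coordinates, its RC triplet and virtual state."""

    coords: np.ndarray
    rc: np.ndarray
    state: tuple[int, ...]
    iteration: int = 0
    run_id: int = 0
    step: int = 0
    #: False when the RC leaked past the state's bins (histogram skipped it)
    counted: bool = True

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.rc = np.atleast_1d(np.asarray(self.rc, dtype=float))
        self.state = tuple(int(s) for s in self.state)
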