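"""The GA-guided virtual-system-coupled sampling loop.

One iteration runs many short wall-confined Langevin stretches in parallel
replicas.  Each replica carries a discrete virtual state (one zone per RC);
between stretches it may hop to any other state whose zone also contains
the current RC value.  Per-state RC histograms accumulate over all
iterations and are stitched into a single canonical distribution estimate
Q_cano over the RC space; Q_cano in turn steers the transitions (toward
poorly covered zones) and supplies the per-snapshot thermodynamic weights.

Seeds for the next iteration mix an evenness pass over visited zones with
genetic-algorithm targets (crossover of zone indices of low-count parents
plus ±1 mutation), so coverage expands toward unexplored RC regions.

Transition rule: independence sampling over the candidate states with
probability ∝ 1/Ẑ_v, Ẑ_v the current Q_cano mass of zone v (floored for
unvisited zones).  This flattens the virtual-state marginal; the validity
of the final estimate rests only on within-zone canonical sampling, which
the zero-inside-zone walls preserve, so the estimator is robust to the
exact rule used here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components

from .dynamics import DynamicsParams, RCWall, langevin_segment, maxwell_velocities
from .errors import (EmptyEstimateError, GeometryError, InvalidSpecError,
                     OutOfRangeError, SeedingError, StitchingError)
from .rc import RCDefinition, Snapshot, ZoneGrid, rc_values
from .system import ToySystem

logger = logging.getLogger(__name__)

__all__ = [
    "IterationSchedule",
    "HistogramStack",
    "QGrid",
    "schedule_totals",
    "generate_initial_seeds",
    "attempt_transition",
    "run_vcmd_iteration",
    "stitch_histograms",
    "select_seeds_next",
    "convergence_metric",
    "run_ga_vcmd",
    "SamplingResult",
]

#: floor on a zone's estimated mass when steering transitions (fraction of
#: the total Q mass); keeps unvisited zones strongly attractive without
#: dividing by zero
EPS_Z_FRACTION = 1e-6


@dataclass
class IterationSchedule:
    n_iterations: int
    n_runs_per_iteration: int
    steps_per_run: int
    dt: float                        # fs
    snapshot_interval_steps: int
    transition_interval_steps: int = 0

    def __post_init__(self):
        if self.transition_interval_steps == 0:
            self.transition_interval_steps = self.snapshot_interval_steps
        for name in ("n_iterations", "n_runs_per_iteration", "steps_per_run",
                     "dt", "snapshot_interval_steps", "transition_interval_steps"):
            if getattr(self, name) <= 0:
                raise InvalidSpecError(f"{name} must be positive")
        if self.steps_per_run % self.snapshot_interval_steps:
            raise InvalidSpecError(
                "snapshot_interval_steps must divide steps_per_run")


def schedule_totals(schedule: IterationSchedule) -> dict:
    """Total snapshot count and simulated time implied by a schedule."""
    per_run = schedule.steps_per_run // schedule.snapshot_interval_steps
    snaps = schedule.n_iterations * schedule.n_runs_per_iteration * per_run
    time_fs = (schedule.n_iterations * schedule.n_runs_per_iteration
               * schedule.steps_per_run * schedule.dt)
    return {
        "snapshots_total": int(snaps),
        "simulated_time_fs": float(time_fs),
        "simulated_time_us": float(time_fs) * 1e-9,
    }


# ----------------------------------------------------------------------
# Histograms and Q grids
# ----------------------------------------------------------------------

class HistogramStack:
    """Per-virtual-state RC-bin counts sharing the zone grid's bin geometry."""

    def __init__(self, grid: ZoneGrid):
        self.grid = grid
        self.counts: dict[tuple, np.ndarray] = {}
        self.dropped = 0   # snapshots whose RC leaked past their zone's bins

    def _array(self, state) -> np.ndarray:
        if state not in self.counts:
            self.counts[state] = np.zeros(self.grid.shape, dtype=np.int64)
        return self.counts[state]

    def add(self, state: tuple, lam) -> bool:
        """Count one snapshot into its state's bins; False if it leaked."""
        try:
            b = self.grid.bin_of(lam)
        except OutOfRangeError:
            self.dropped += 1
            return False
        for ax_idx, (ax, z) in enumerate(zip(self.grid.axes, state)):
            start, stop = ax.zone_bin_range(z)
            if not start <= b[ax_idx] < stop:
                self.dropped += 1
                return False
        self._array(state)[b] += 1
        return True

    def visited_states(self) -> list[tuple]:
        return [s for s, c in self.counts.items() if c.sum() > 0]

    def state_total(self, state) -> int:
        c = self.counts.get(state)
        return int(c.sum()) if c is not None else 0

    def visit_counts(self) -> dict[tuple, int]:
        return {s: int(c.sum()) for s, c in self.counts.items() if c.sum() > 0}

    def total_per_bin(self) -> np.ndarray:
        out = np.zeros(self.grid.shape, dtype=np.int64)
        for c in self.counts.values():
            out += c
        return out

    def copy(self) -> "HistogramStack":
        new = HistogramStack(self.grid)
        new.counts = {s: c.copy() for s, c in self.counts.items()}
        new.dropped = self.dropped
        return new


@dataclass
class QGrid:
    """Binned estimate of the canonical distribution over the RC space."""

    values: np.ndarray
    grid: ZoneGrid
    mode: str = "max1"               # "max1" (reporting) | "sum1" (weights)
    iteration: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise GeometryError("Q values do not match the zone grid shape")
        if np.any(self.values < 0):
            raise InvalidSpecError("Q values must be nonnegative")

    def as_mode(self, mode: str) -> "QGrid":
        if mode == self.mode:
            return self
        total = self.values.sum() if mode == "sum1" else self.values.max()
        if total <= 0:
            raise EmptyEstimateError("cannot normalize an all-zero Q grid")
        return QGrid(self.values / total, self.grid, mode, self.iteration)


# ----------------------------------------------------------------------
# Seeding
# ----------------------------------------------------------------------

def _assign_state(grid: ZoneGrid, lam, rng: np.random.Generator,
                  prefer: tuple | None = None) -> tuple:
    """A starting state containing λ; ``prefer`` wins if it qualifies."""
    cands = grid.states_containing(lam)
    if prefer is not None:
        if prefer in cands:
            return prefer
        # nearest containing state to the preferred zone (index L1 distance)
        dists = [sum(abs(a - b) for a, b in zip(c, prefer)) for c in cands]
        return cands[int(np.argmin(dists))]
    return cands[int(rng.integers(len(cands)))]


def generate_initial_seeds(
    system: ToySystem,
    rc_defs: list[RCDefinition],
    windows: list[tuple[float, float]],
    n_runs: int,
    params: DynamicsParams,
    seed: int,
    grid: ZoneGrid | None = None,
    steps_per_attempt: int = 2000,
    max_attempts: int = 10,
) -> list[Snapshot]:
    """Window-restrained relaxation runs; returns each run's final frame.

    Every returned frame satisfies lo < λ < hi on all RCs.  The restraint
    walls sit on a slightly shrunken inner window: a soft wall equilibrates
    with an O(sqrt(kT/k)) tail just outside its boundary, so restraining to
    the nominal window would leave a sizable chance of ending each stretch
    marginally outside it.
    """
    walls = []
    for rc, (lo, hi) in zip(rc_defs, windows):
        margin = 0.15 * (hi - lo)
        walls.append(RCWall(rc, lo + margin, hi - margin, params.wall_k))
    seeds = []
    for run in range(n_runs):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0, run)))
        x, v = system.coords.copy(), None
        ok = False
        for _ in range(max_attempts):
            seg = langevin_segment(system, (x, v), steps_per_attempt, params,
                                   walls=walls, rng=rng, run_id=run)
            x, v = seg.final_coords, seg.final_velocities
            lam = rc_values(rc_defs, x, system.masses)
            if all(lo < l < hi for l, (lo, hi) in zip(lam, windows)):
                ok = True
                break
        if not ok:
            raise SeedingError(
                f"run {run}: RC window not reached after "
                f"{max_attempts * steps_per_attempt} steps")
        state = (_assign_state(grid, lam, rng) if grid is not None else ())
        seeds.append(Snapshot(coords=x, rc=lam, state=state,
                              iteration=0, run_id=run, step=0))
    return seeds


# ----------------------------------------------------------------------
# Transitions
# ----------------------------------------------------------------------

def attempt_transition(current: tuple, lam, q_est: QGrid | None,
                       grid: ZoneGrid, rng: np.random.Generator) -> tuple:
    """Draw the next virtual state among those whose zones contain λ."""
    cands = grid.states_containing(lam)
    if len(cands) == 1:
        return cands[0]
    if q_est is None:
        return cands[int(rng.integers(len(cands)))]
    q = q_est.as_mode("sum1").values
    floor = EPS_Z_FRACTION
    masses = np.array([
        max(float(q[grid.state_bin_slices(c)].sum()), floor) for c in cands
    ])
    p = (1.0 / masses)
    p /= p.sum()
    return cands[int(rng.choice(len(cands), p=p))]


# ----------------------------------------------------------------------
# One iteration
# ----------------------------------------------------------------------

def run_vcmd_iteration(
    seeds: list[Snapshot],
    system: ToySystem,
    rc_defs: list[RCDefinition],
    grid: ZoneGrid,
    q_est: QGrid | None,
    schedule: IterationSchedule,
    params: DynamicsParams,
    iteration: int = 1,
    stack: HistogramStack | None = None,
    root_seed: int | None = None,
) -> tuple[list[Snapshot], HistogramStack]:
    """Zone-confined runs with inter-state transitions; accumulates ``stack``.

    Each run alternates ``transition_interval_steps`` of wall-confined
    Langevin propagation with one transition attempt.  Snapshots are stored
    every ``snapshot_interval_steps`` with their current state and counted
    into that state's histogram.
    """
    if len(seeds) != schedule.n_runs_per_iteration:
        raise InvalidSpecError("seed count must equal n_runs_per_iteration")
    if stack is None:
        stack = HistogramStack(grid)
    if root_seed is None:
        root_seed = params.rng_seed
    sum1 = q_est.as_mode("sum1") if q_est is not None else None

    stored: list[Snapshot] = []
    for run_id, seed_snap in enumerate(seeds):
        rng = np.random.default_rng(
            np.random.SeedSequence(root_seed, spawn_key=(iteration, run_id)))
        state = seed_snap.state or _assign_state(grid, seed_snap.rc, rng)
        x = seed_snap.coords.copy()
        v = maxwell_velocities(system, params.temperature, rng)
        step = 0
        while step < schedule.steps_per_run:
            chunk = min(schedule.transition_interval_steps,
                        schedule.steps_per_run - step)
            lo, hi = grid.state_bounds(state)
            walls = [RCWall(rc, float(a), float(b), params.wall_k)
                     for rc, a, b in zip(rc_defs, lo, hi)]
            seg = langevin_segment(
                system, (x, v), chunk, params, walls=walls,
                snapshot_interval=schedule.snapshot_interval_steps,
                rng=rng, rc_defs=rc_defs, run_id=run_id,
                iteration=iteration, step_offset=step)
            x, v = seg.final_coords, seg.final_velocities
            step += chunk
            for snap in seg.snapshots:
                snap.state = state
                snap.counted = stack.add(state, snap.rc)
                stored.append(snap)
            lam = rc_values(rc_defs, x, system.masses)
            try:
                state = attempt_transition(state, lam, sum1, grid, rng)
            except OutOfRangeError:
                pass   # rare deep wall excursion: keep the current state
    return stored, stack


# ----------------------------------------------------------------------
# Stitching
# ----------------------------------------------------------------------

def stitch_histograms(stack: HistogramStack, min_overlap_count: int = 1,
                      on_disconnected: str = "error") -> QGrid:
    """Combine per-state histograms into one global Q estimate (max1).

    Per-state densities h_v(b) = c_v(b)/(N_v·vol) are matched on shared
    bins by solving weighted least squares for log scale factors g_v
    (equations g_v + ln h_v = g_w + ln h_w, gauge g_ref = 0), then averaged
    per bin with normalized-count weights c_v(b)/N_v.  Both the equation
    weights and the final average use per-state *normalized* counts, which
    makes the estimate exactly invariant under rescaling any one zone's
    counts.

    A disconnected zone-overlap graph has no common gauge; the default is
    to raise :class:`StitchingError` listing the components, while
    ``on_disconnected="largest"`` stitches the component holding the most
    counts (the early-iteration fallback used by the campaign driver).
    """
    grid = stack.grid
    states = sorted(stack.visited_states())
    if not states:
        raise EmptyEstimateError("histogram stack holds no counts")
    vol = grid.bin_volume
    index = {s: i for i, s in enumerate(states)}
    dens = {}
    norm_counts = {}
    for s in states:
        c = stack.counts[s]
        n = c.sum()
        norm_counts[s] = c / n
        dens[s] = c / (n * vol)

    # overlap equations
    rows, rhs, wts = [], [], []
    adj = np.zeros((len(states), len(states)), dtype=bool)
    for i, v in enumerate(states):
        for j in range(i + 1, len(states)):
            w = states[j]
            both = (stack.counts[v] >= min_overlap_count) & \
                   (stack.counts[w] >= min_overlap_count)
            if not both.any():
                continue
            adj[i, j] = adj[j, i] = True
            bv = norm_counts[v][both]
            bw = norm_counts[w][both]
            weight = 2.0 * bv * bw / (bv + bw)       # harmonic mean
            rows.append((i, j, np.log(dens[w][both]) - np.log(dens[v][both]),
                         weight))

    n_comp, labels = connected_components(adj, directed=False)
    if len(states) > 1 and n_comp > 1:
        comps = [
            [states[k] for k in range(len(states)) if labels[k] == c]
            for c in range(n_comp)
        ]
        if on_disconnected != "largest":
            raise StitchingError(
                f"zone-overlap graph has {n_comp} components", components=comps)
        totals = [sum(stack.state_total(s) for s in comp) for comp in comps]
        keep = set(comps[int(np.argmax(totals))])
        logger.debug("stitching largest of %d components (%d states)",
                     n_comp, len(keep))
        sub = stack.copy()
        sub.counts = {s: c for s, c in sub.counts.items() if s in keep}
        return stitch_histograms(sub, min_overlap_count, "error")

    g = np.zeros(len(states))
    if rows and len(states) > 1:
        n_eq = sum(r[2].shape[0] for r in rows)
        amat = np.zeros((n_eq, len(states) - 1))   # gauge: g[0] = 0
        bvec = np.empty(n_eq)
        pos = 0
        for i, j, diff, weight in rows:
            m = diff.shape[0]
            sw = np.sqrt(weight)
            if i > 0:
                amat[pos:pos + m, i - 1] = sw
            if j > 0:
                amat[pos:pos + m, j - 1] = -sw
            bvec[pos:pos + m] = sw * diff
            pos += m
        sol, *_ = np.linalg.lstsq(amat, bvec, rcond=None)
        g[1:] = sol
    scale = np.exp(g - g.max())

    num = np.zeros(grid.shape)
    den = np.zeros(grid.shape)
    for s in states:
        w = norm_counts[s]
        num += w * scale[index[s]] * dens[s]
        den += w
    q = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    peak = q.max()
    if peak <= 0:
        raise EmptyEstimateError("stitched estimate is identically zero")
    return QGrid(q / peak, grid, mode="max1")


# ----------------------------------------------------------------------
# Seed selection for the next iteration
# ----------------------------------------------------------------------

def select_seeds_next(
    snapshots: list[Snapshot],
    grid: ZoneGrid,
    visit_counts: dict[tuple, int],
    n_runs: int,
    rng: np.random.Generator,
    ga_fraction: float = 0.5,
    p_mut: float = 0.1,
) -> list[Snapshot]:
    """Seeds for the next iteration: evenness half + GA-target half.

    Evenness slots cycle round-robin through visited zones in ascending
    visit count.  GA slots cross zone indices of two inverse-count-sampled
    parents (±1 mutation with probability ``p_mut``, clipped to the grid)
    and map each target to the stored snapshot whose zone-normalized λ is
    nearest the target zone's center, earliest-stored winning ties.
    """
    if not snapshots:
        raise EmptyEstimateError("snapshot store is empty")
    visited = sorted(visit_counts)
    by_state: dict[tuple, list[int]] = {}
    for idx, s in enumerate(snapshots):
        by_state.setdefault(s.state, []).append(idx)

    n_ga = int(round(n_runs * ga_fraction))
    n_even = n_runs - n_ga
    seeds: list[Snapshot] = []

    order = sorted(visited, key=lambda s: (visit_counts[s], s))
    order = [s for s in order if s in by_state] or list(by_state)
    i = 0
    while len(seeds) < n_even:
        state = order[i % len(order)]
        pool = by_state[state]
        pick = snapshots[pool[int(rng.integers(len(pool)))]]
        seeds.append(Snapshot(pick.coords.copy(), pick.rc.copy(), state,
                              run_id=len(seeds)))
        i += 1

    # GA targets
    inv = np.array([1.0 / max(visit_counts[s], 1) for s in visited])
    inv /= inv.sum()
    norm_lams = np.array([grid.normalized(s.rc) for s in snapshots])
    n_zones = [ax.n_zones for ax in grid.axes]
    for _ in range(n_ga):
        pa = visited[int(rng.choice(len(visited), p=inv))]
        pb = visited[int(rng.choice(len(visited), p=inv))]
        child = []
        for d in range(grid.ndim):
            z = pa[d] if rng.random() < 0.5 else pb[d]
            if rng.random() < p_mut:
                z += int(rng.choice([-1, 1]))
            child.append(int(np.clip(z, 0, n_zones[d] - 1)))
        child = tuple(child)
        target = grid.normalized(grid.state_center(child))
        d2 = np.sum((norm_lams - target[None, :]) ** 2, axis=1)
        pick = snapshots[int(np.argmin(d2))]   # argmin is stable: earliest wins
        state = _assign_state(grid, pick.rc, rng, prefer=child)
        seeds.append(Snapshot(pick.coords.copy(), pick.rc.copy(), state,
                              run_id=len(seeds)))
    return seeds


# ----------------------------------------------------------------------
# Convergence
# ----------------------------------------------------------------------

def convergence_metric(q_m: QGrid, q_prev: QGrid,
                       support_threshold: float = 0.001) -> float:
    """Relative L1 change of Q between iterations on its significant support.

    d = Σ|Q_M − Q_{M−1}| / ΣQ_M over bins where either max-normalized grid
    exceeds ``support_threshold``.
    """
    if q_m.grid.shape != q_prev.grid.shape:
        raise GeometryError("Q grids have different bin geometry")
    a = q_m.as_mode("max1").values
    b = q_prev.as_mode("max1").values
    mask = np.maximum(a, b) > support_threshold
    denom = a[mask].sum()
    if denom <= 0:
        return 0.0
    return float(np.abs(a[mask] - b[mask]).sum() / denom)


# ----------------------------------------------------------------------
# Full loop
# ----------------------------------------------------------------------

@dataclass
class SamplingResult:
    snapshots: list[Snapshot]
    stack: HistogramStack
    qgrids: list[QGrid]
    convergence: list[float]
    schedule: IterationSchedule
    grid: ZoneGrid
    converged_at: int | None = None


def run_ga_vcmd(
    system: ToySystem,
    rc_defs: list[RCDefinition],
    grid: ZoneGrid,
    windows: list[tuple[float, float]],
    schedule: IterationSchedule,
    params: DynamicsParams,
    root_seed: int,
    convergence_threshold: float = 0.1,
    ga_fraction: float = 0.5,
    p_mut: float = 0.1,
) -> SamplingResult:
    """Seed, iterate, stitch and track convergence for a full campaign.

    Convergence is declared when the iteration-to-iteration metric stays
    below ``convergence_threshold`` for two consecutive iterations; the
    schedule's full iteration budget is always executed (histograms keep
    accumulating over all iterations).
    """
    seeds = generate_initial_seeds(
        system, rc_defs, windows, schedule.n_runs_per_iteration, params,
        root_seed, grid=grid)
    stack = HistogramStack(grid)
    all_snaps: list[Snapshot] = []
    qgrids: list[QGrid] = []
    conv: list[float] = []
    converged_at = None
    q_est = None
    below = 0
    for m in range(1, schedule.n_iterations + 1):
        stored, stack = run_vcmd_iteration(
            seeds, system, rc_defs, grid, q_est, schedule, params,
            iteration=m, stack=stack, root_seed=root_seed)
        all_snaps.extend(stored)
        q = stitch_histograms(stack, on_disconnected="largest")
        q.iteration = m
        if qgrids:
            d = convergence_metric(q, qgrids[-1])
            conv.append(d)
            below = below + 1 if d < convergence_threshold else 0
            if below >= 2 and converged_at is None:
                converged_at = m
        qgrids.append(q)
        logger.info("iteration %d: %d zones visited, d=%s", m,
                    len(stack.visited_states()),
                    f"{conv[-1]:.4f}" if conv else "n/a")
        if m < schedule.n_iterations:
            rng = np.random.default_rng(
                np.random.SeedSequence(root_seed, spawn_key=(m, 1 << 20)))
            seeds = select_seeds_next(
                all_snaps, grid, stack.visit_counts(),
                schedule.n_runs_per_iteration, rng,
                ga_fraction=ga_fraction, p_mut=p_mut)
        q_est = q
    return SamplingResult(all_snaps, stack, qgrids, conv, schedule, grid,
                          converged_at)
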