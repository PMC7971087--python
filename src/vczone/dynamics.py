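"""BAOAB Langevin propagation of toy systems, with optional RC walls.

The BAOAB splitting samples the configurational canonical distribution
exactly in the harmonic limit, which is what every downstream estimate
(zone stitching, reweighting) relies on.  Half-harmonic walls on reaction
coordinates implement both zone confinement during sampling and the
flat-bottom windows used to prepare initial conformations; inside the
window the wall contributes nothing, so within-zone statistics stay
canonical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import KB, KCAL_PER_MOL
from .errors import IntegrationError, InvalidSpecError
from .rc import RCDefinition, Snapshot, group_center
from .system import ToySystem, potential_energy

__all__ = ["DynamicsParams", "RCWall", "TrajectorySegment", "langevin_segment",
           "maxwell_velocities"]


@dataclass
class DynamicsParams:
    """Thermostat and integration settings (K, fs, 1/ps, kcal/mol/Å²)."""

    temperature: float = 300.0
    dt: float = 8.0
    friction: float = 1.0
    rng_seed: int = 0
    wall_k: float = 10.0

    def __post_init__(self):
        if self.temperature <= 0 or self.dt <= 0 or self.friction <= 0:
            raise InvalidSpecError("temperature, dt and friction must be positive")
        if self.wall_k < 0:
            raise InvalidSpecError("wall_k must be nonnegative")


@dataclass
class RCWall:
    """Half-harmonic confinement k·(λ − bound)² outside [lo, hi] on one RC."""

    rc: RCDefinition
    lo: float
    hi: float
    k: float

    def energy_forces(self, coords: np.ndarray, masses: np.ndarray):
        ca = group_center(coords, self.rc.group_A, self.rc.weighting, masses)
        cb = group_center(coords, self.rc.group_B, self.rc.weighting, masses)
        diff = ca - cb
        lam = float(np.linalg.norm(diff))
        if self.lo <= lam <= self.hi:
            return 0.0, None
        bound = self.lo if lam < self.lo else self.hi
        delta = lam - bound
        energy = self.k * delta * delta
        # dU/dλ · dλ/dx distributed over group members by their center weight
        dU_dlam = 2.0 * self.k * delta
        u = diff / max(lam, 1e-12)
        grads = []
        for ids, sign in ((self.rc.group_A, 1.0), (self.rc.group_B, -1.0)):
            if self.rc.weighting == "mass":
                w = masses[ids] / masses[ids].sum()
            else:
                w = np.full(ids.shape[0], 1.0 / ids.shape[0])
            grads.append((ids, -dU_dlam * sign * w[:, None] * u[None, :]))
        return energy, grads


@dataclass
class TrajectorySegment:
    """Ordered snapshots from one propagation stretch."""

    snapshots: list
    run_id: int
    iteration: int
    n_steps: int
    final_coords: np.ndarray = None
    final_velocities: np.ndarray = None
    final_energy: float = 0.0


def maxwell_velocities(system: ToySystem, temperature: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Maxwell–Boltzmann draw (Å/fs); frozen beads get zero velocity."""
    kt = KB * temperature * KCAL_PER_MOL
    sigma = np.sqrt(kt / system.masses)[:, None]
    v = rng.normal(size=(system.n_beads, 3)) * sigma
    v[system.frozen] = 0.0
    return v


def _total_force(system, x, walls):
    energy, forces = potential_energy(system, x)
    if walls:
        for wall in walls:
            e, grads = wall.energy_forces(x, system.masses)
            energy += e
            if grads is not None:
                for ids, f in grads:
                    forces[ids] += f
    return energy, forces


def langevin_segment(
    system: ToySystem,
    start,
    n_steps: int,
    params: DynamicsParams,
    walls=None,
    snapshot_interval: int | None = None,
    rng: np.random.Generator | None = None,
    rc_defs=None,
    run_id: int = 0,
    iteration: int = 0,
    step_offset: int = 0,
) -> TrajectorySegment:
    """Propagate ``n_steps`` BAOAB steps from ``start`` = (coords, velocities).

    ``velocities`` may be None (drawn from Maxwell–Boltzmann).  Snapshots are
    recorded every ``snapshot_interval`` steps (never the start frame, except
    for the degenerate ``n_steps == 0`` call which returns only the start
    state).  Identical ``rng`` state gives identical snapshot streams.
    """
    if n_steps < 0:
        raise InvalidSpecError("n_steps must be >= 0")
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    coords, velocities = start
    x = np.array(coords, dtype=float)
    v = (maxwell_velocities(system, params.temperature, rng)
         if velocities is None else np.array(velocities, dtype=float))

    mobile = np.ones(system.n_beads, dtype=bool)
    mobile[system.frozen] = False
    inv_m = np.where(mobile, 1.0 / system.masses, 0.0)[:, None]

    dt = params.dt
    gamma = params.friction / 1000.0          # 1/ps -> 1/fs
    c1 = np.exp(-gamma * dt)
    kt = KB * params.temperature * KCAL_PER_MOL
    c2 = np.sqrt(kt * (1.0 - c1 * c1) / system.masses)[:, None]

    def record(step):
        lam = (np.array([rc.value(x, system.masses) for rc in rc_defs])
               if rc_defs else np.zeros(0))
        snaps.append(Snapshot(coords=x.copy(), rc=lam, state=(),
                              iteration=iteration, run_id=run_id,
                              step=step_offset + step))

    snaps: list[Snapshot] = []
    energy, forces = _total_force(system, x, walls)
    if n_steps == 0:
        record(0)
        return TrajectorySegment(snaps, run_id, iteration, 0, x, v, energy)

    half = 0.5 * dt
    for step in range(1, n_steps + 1):
        v += half * forces * inv_m * KCAL_PER_MOL
        x += half * v
        noise = rng.normal(size=x.shape)
        v = c1 * v + c2 * noise
        v[~mobile] = 0.0
        x += half * v
        energy, forces = _total_force(system, x, walls)
        v += half * forces * inv_m * KCAL_PER_MOL
        if not np.isfinite(energy) or not np.all(np.isfinite(x)):
            raise IntegrationError(
                f"non-finite energy/coordinates at step {step_offset + step}"
                f" (run {run_id})", step=step_offset + step, run_id=run_id)
        if snapshot_interval and step % snapshot_interval == 0:
            record(step)

    return TrajectorySegment(snaps, run_id, iteration, n_steps, x, v, energy)
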