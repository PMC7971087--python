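"""Self-validation benchmarks against independent oracles.

Two end-to-end checks quantify the correctness of the sampling/stitching/
reweighting machinery on systems with known answers:

* canonical recovery — the full zone-sampling loop on the reduced
  two-group system must reproduce the quadrature Boltzmann density of its
  RC, and so must a plain long Langevin run (two independent routes);
* stitching recovery — multinomial per-zone counts drawn from a known 3-D
  density must stitch back to that density, and the estimate must be
  exactly invariant under rescaling any single zone's counts.

Problem sizes default to desk-scale settings (about a minute of CPU).
"""

from __future__ import annotations

import numpy as np

from .analytic import analytic_bin_probabilities
from .dynamics import DynamicsParams, langevin_segment
from .engine import HistogramStack, IterationSchedule, run_ga_vcmd, stitch_histograms
from .rc import RCDefinition, build_zone_grid
from .reweight import snapshot_weights
from .system import build_reduced_pair_system

__all__ = ["canonical_recovery", "stitching_recovery"]


def canonical_recovery(
    seed: int,
    n_iterations: int = 4,
    n_runs: int = 16,
    steps_per_run: int = 12_500,
    temperature: float = 300.0,
) -> dict:
    """L1 distance between recovered and analytic RC densities.

    Runs the full GA-guided loop (3 zones on one RC, harmonic-tether
    reduced system) and, as a second oracle route, a plain unconfined
    Langevin run of the same total length.  Returns the L1 distances of
    (a) the reweighted RC marginal and (b) the plain-run histogram from
    the quadrature Boltzmann density, plus the step budget used.
    """
    system = build_reduced_pair_system(r0=6.0, k_tether=1.0)
    rc = [RCDefinition("r", [0], [1], range=(3.5, 8.5))]
    grid = build_zone_grid((3.5, 8.5), 3)
    schedule = IterationSchedule(
        n_iterations=n_iterations, n_runs_per_iteration=n_runs,
        steps_per_run=steps_per_run, dt=10.0,
        snapshot_interval_steps=125, transition_interval_steps=500)
    params = DynamicsParams(temperature=temperature, dt=10.0, friction=1.0,
                            rng_seed=seed)
    result = run_ga_vcmd(system, rc, grid, [(7.0, 8.2)], schedule, params,
                         root_seed=seed)

    edges = grid.axes[0].bin_edges
    truth = analytic_bin_probabilities(system, temperature, edges)

    counted = [s for s in result.snapshots if s.counted]
    ens = snapshot_weights(counted, result.qgrids[-1],
                           result.stack.total_per_bin(), temperature)
    marginal = np.zeros(truth.shape[0])
    width = grid.axes[0].bin_width
    for snap, w in zip(ens.snapshots, ens.weights):
        b = min(int((snap.rc[0] - edges[0]) / width), truth.shape[0] - 1)
        marginal[max(b, 0)] += w
    l1_vcmd = float(np.abs(marginal - truth).sum())

    # independent route: one long unconfined Langevin trajectory
    total_steps = n_iterations * n_runs * steps_per_run // 2
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(9,)))
    seg = langevin_segment(system, (system.coords, None), total_steps, params,
                           snapshot_interval=100, rng=rng, rc_defs=rc)
    lams = np.array([s.rc[0] for s in seg.snapshots])
    hist, _ = np.histogram(lams, bins=edges)
    l1_plain = float(np.abs(hist / hist.sum() - truth).sum())

    return {
        "l1_vcmd": l1_vcmd,
        "l1_plain": l1_plain,
        "total_steps": n_iterations * n_runs * steps_per_run,
        "convergence": result.convergence,
    }


def _blob_density(grid):
    centers = np.stack(
        np.meshgrid(*[ax.bin_centers for ax in grid.axes], indexing="ij"),
        axis=-1)
    mid = np.array([0.5 * (ax.lo + ax.hi) for ax in grid.axes])
    p = np.exp(-np.sum((centers - mid) ** 2, axis=-1) / (2 * 2.0 ** 2))
    return p / p.sum()


def stitching_recovery(seed: int, counts_per_zone: int = 10_000) -> dict:
    """Stitch multinomial per-zone draws from a known 3-D density.

    Returns the maximum deviation between the max-normalized stitched and
    true grids, and the maximum change caused by multiplying one zone's
    counts by 10 (exact-invariance check).
    """
    rng = np.random.default_rng(seed)
    grid = build_zone_grid([(0.0, 6.0)] * 3, 2, bins_per_zone=2)
    p = _blob_density(grid)
    stack = HistogramStack(grid)
    for state in grid.all_states():
        sl = grid.state_bin_slices(state)
        local = p[sl].ravel()
        counts = rng.multinomial(counts_per_zone, local / local.sum())
        arr = np.zeros(grid.shape, dtype=np.int64)
        arr[sl] = counts.reshape(p[sl].shape)
        stack.counts[state] = arr
    q = stitch_histograms(stack).values
    max_dev = float(np.abs(q - p / p.max()).max())

    rescaled = stack.copy()
    first = next(iter(rescaled.counts))
    rescaled.counts[first] = rescaled.counts[first] * 10
    q2 = stitch_histograms(rescaled).values
    rescale_change = float(np.abs(q2 - q).max())

    return {
        "max_deviation": max_dev,
        "rescale_change": rescale_change,
        "counts_per_zone": counts_per_zone,
        "n_zones": grid.n_states,
    }
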