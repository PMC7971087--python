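"""Zone-sampling engine: scheduling, transitions, stitching, seeding."""

import numpy as np
import pytest

from vczone.dynamics import DynamicsParams
from vczone.engine import (HistogramStack, IterationSchedule, QGrid,
                           attempt_transition, convergence_metric,
                           generate_initial_seeds, run_vcmd_iteration,
                           schedule_totals, select_seeds_next,
                           stitch_histograms)
from vczone.errors import (EmptyEstimateError, GeometryError, InvalidSpecError,
                           StitchingError)
from vczone.rc import Snapshot, build_zone_grid
from vczone.system import build_reduced_pair_system


class TestSchedule:
    @pytest.mark.parametrize(
        "n_iter, snaps, time_us",
        [(14, 107_520, 21.504), (13, 99_840, 19.968), (27, 207_360, 41.472)],
    )
    def test_published_campaign_totals(self, n_iter, snaps, time_us):
        """256 runs x 3e6 steps per iteration, snapshot every 1e5 steps, 2 fs."""
        schedule = IterationSchedule(
            n_iterations=n_iter, n_runs_per_iteration=256,
            steps_per_run=3_000_000, dt=2.0, snapshot_interval_steps=100_000)
        totals = schedule_totals(schedule)
        assert totals["snapshots_total"] == snaps
        assert totals["simulated_time_us"] == pytest.approx(time_us, rel=1e-12)

    def test_degenerate_single_snapshot(self):
        schedule = IterationSchedule(1, 1, 100, 2.0, 100)
        assert schedule_totals(schedule)["snapshots_total"] == 1

    def test_snapshot_interval_must_divide_steps(self):
        with pytest.raises(InvalidSpecError):
            IterationSchedule(1, 1, 100, 2.0, 33)


def _grid1d(n_vs=3, rng=(0.0, 6.0)):
    # two bins per zone: zone i covers bins (i, i+1)
    return build_zone_grid(rng, n_vs, bins_per_zone=2)


class TestTransitions:
    def test_single_candidate_returns_current(self, rng):
        grid = _grid1d()
        state = attempt_transition((0,), [0.2], None, grid, rng)
        assert state == (0,)

    def test_uniform_without_estimate(self, rng):
        grid = _grid1d()
        lam = [2.5]  # overlap of zones 0 and 1
        assert len(grid.states_containing(lam)) == 2
        draws = [attempt_transition((0,), lam, None, grid, rng)
                 for _ in range(10_000)]
        frac = np.mean([d == (0,) for d in draws])
        assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(10_000)

    def test_inverse_mass_weighting(self, rng):
        grid = build_zone_grid([(0.0, 6.0)] * 2, 2)
        lam = [2.9, 2.9]  # inside every zone along both axes -> 4 candidates
        cands = grid.states_containing(lam)
        assert len(cands) == 4
        values = np.zeros(grid.shape)
        masses = {(0, 0): 0.4, (0, 1): 0.2, (1, 0): 0.1, (1, 1): 0.3}
        # paint disjoint non-overlap corners so per-state zone masses differ
        corners = {(0, 0): (0, 0), (0, 1): (0, 5), (1, 0): (5, 0), (1, 1): (5, 5)}
        for s, m in masses.items():
            values[corners[s]] = m
        q = QGrid(values / values.sum(), grid, mode="sum1")
        inv = np.array([1 / masses[c] for c in cands])
        expected = inv / inv.sum()
        draws = np.array([cands.index(attempt_transition((0, 0), lam, q, grid, rng))
                          for _ in range(20_000)])
        freq = np.bincount(draws, minlength=4) / draws.size
        sigma = np.sqrt(expected * (1 - expected) / draws.size)
        assert np.all(np.abs(freq - expected) < 4 * sigma)


def _stack_from_counts(grid, counts_by_state):
    stack = HistogramStack(grid)
    for state, arr in counts_by_state.items():
        stack.counts[state] = np.asarray(arr, dtype=np.int64)
    return stack


class TestStitching:
    def test_single_state_returns_normalized_histogram(self):
        grid = _grid1d(2, (0.0, 3.0))   # zones of 2 bins, 3 bins total
        counts = np.array([8, 2, 0])
        q = stitch_histograms(_stack_from_counts(grid, {(0,): counts}))
        expected = counts / counts.max()
        assert np.allclose(q.values, expected)

    def test_exact_scale_invariance(self):
        grid = _grid1d(2, (0.0, 3.0))
        base = {(0,): np.array([40, 25, 0]), (1,): np.array([0, 55, 80])}
        q1 = stitch_histograms(_stack_from_counts(grid, base))
        scaled = {(0,): base[(0,)] * 10, (1,): base[(1,)]}
        q2 = stitch_histograms(_stack_from_counts(grid, scaled))
        assert np.allclose(q1.values, q2.values, atol=1e-14)

    def test_consistent_histograms_recover_exactly(self):
        """Counts proportional to one density stitch back to that density."""
        grid = _grid1d(3, (0.0, 4.0))   # 4 bins, zones (0,1),(1,2),(2,3)
        p = np.array([1.0, 3.0, 4.0, 2.0])
        counts = {
            (0,): np.array([10, 30, 0, 0]),
            (1,): np.array([0, 300, 400, 0]),    # 100x sampling of same p
            (2,): np.array([0, 0, 40, 20]),
        }
        q = stitch_histograms(_stack_from_counts(grid, counts))
        assert np.allclose(q.values, p / p.max(), atol=1e-12)

    def test_disconnected_graph_reports_components(self):
        grid = _grid1d(3, (0.0, 4.0))
        counts = {
            (0,): np.array([10, 0, 0, 0]),
            (2,): np.array([0, 0, 0, 20]),
        }
        with pytest.raises(StitchingError) as err:
            stitch_histograms(_stack_from_counts(grid, counts))
        assert len(err.value.components) == 2

    def test_empty_stack_rejected(self):
        with pytest.raises(EmptyEstimateError):
            stitch_histograms(HistogramStack(_grid1d()))


class TestConvergence:
    def test_identical_grids_give_zero(self):
        grid = _grid1d()
        values = np.linspace(0.1, 1.0, grid.shape[0])
        q = QGrid(values / values.max(), grid)
        assert convergence_metric(q, q) == 0.0

    def test_hand_computed_three_bin_case(self):
        grid = _grid1d(2, (0.0, 3.0))
        a = QGrid(np.array([1.0, 0.5, 0.0005]), grid)
        b = QGrid(np.array([0.8, 0.7, 0.0002]), grid)
        # support excludes the third bin (both below 0.001)
        expected = (0.2 + 0.2) / (1.0 + 0.5)
        assert convergence_metric(a, b) == pytest.approx(expected, rel=1e-12)

    def test_nonnegative_for_random_pairs(self, rng):
        grid = _grid1d()
        for _ in range(20):
            a = rng.uniform(size=grid.shape)
            b = rng.uniform(size=grid.shape)
            qa = QGrid(a / a.max(), grid)
            qb = QGrid(b / b.max(), grid)
            assert convergence_metric(qa, qb) >= 0.0

    def test_mismatched_geometry_rejected(self):
        qa = QGrid(np.ones(_grid1d(3).shape), _grid1d(3))
        qb = QGrid(np.ones(_grid1d(4).shape), _grid1d(4))
        with pytest.raises(GeometryError):
            convergence_metric(qa, qb)


def _fake_snapshots(grid, per_zone, rng):
    """A few stored snapshots in each requested zone (1-D grid)."""
    snaps = []
    for state, n in per_zone.items():
        lo, hi = grid.state_bounds(state)
        for _ in range(n):
            lam = rng.uniform(lo[0] + 0.1, hi[0] - 0.1)
            snaps.append(Snapshot(np.zeros((1, 3)), [lam], state))
    return snaps


class TestSeedSelection:
    def test_deterministic_given_rng_seed(self, rng):
        grid = _grid1d()
        snaps = _fake_snapshots(grid, {(0,): 5, (1,): 5, (2,): 5}, rng)
        counts = {(0,): 50, (1,): 10, (2,): 40}
        picks = []
        for _ in range(2):
            sel = select_seeds_next(snaps, grid, counts, 8,
                                    np.random.default_rng(3))
            picks.append([(s.state, s.rc[0]) for s in sel])
        assert picks[0] == picks[1]

    def test_round_robin_balances_equal_counts(self, rng):
        grid = _grid1d()
        snaps = _fake_snapshots(grid, {(0,): 10, (1,): 10, (2,): 10}, rng)
        counts = {(0,): 20, (1,): 20, (2,): 20}
        sel = select_seeds_next(snaps, grid, counts, 9,
                                np.random.default_rng(0), ga_fraction=0.0)
        per_zone = {s: 0 for s in counts}
        for seed in sel:
            per_zone[seed.state] += 1
        assert max(per_zone.values()) <= int(np.ceil(9 / 3))

    def test_ga_targets_reach_toward_unvisited_zone(self, rng):
        """With zone 2 unvisited, crossover+mutation should repeatedly pick
        donor snapshots from the adjacent (upper) part of zone 1."""
        grid = _grid1d()
        snaps = _fake_snapshots(grid, {(0,): 20, (1,): 20}, rng)
        counts = {(0,): 500, (1,): 50}
        upper_zone1 = 0
        for trial in range(100):
            sel = select_seeds_next(snaps, grid, counts, 4,
                                    np.random.default_rng(trial),
                                    ga_fraction=1.0)
            zone1_hi = grid.state_bounds((1,))[1][0]
            upper_zone1 += any(s.rc[0] > 0.6 * zone1_hi for s in sel)
        assert upper_zone1 > 0


class TestIterationContracts:
    def _setup(self):
        system = build_reduced_pair_system(r0=3.0, k_tether=0.0)  # flat U
        from vczone.rc import RCDefinition
        rc = [RCDefinition("r", [0], [1], range=(2.0, 8.0))]
        grid = build_zone_grid((2.0, 8.0), 3)
        schedule = IterationSchedule(1, 6, 3000, 10.0, 100, 500)
        params = DynamicsParams(temperature=300.0, dt=10.0, friction=1.0,
                                rng_seed=5)
        return system, rc, grid, schedule, params

    def test_confinement_and_bookkeeping(self):
        system, rc, grid, schedule, params = self._setup()
        seeds = generate_initial_seeds(system, rc, [(4.0, 6.0)], 6, params,
                                       seed=5, grid=grid)
        assert len(seeds) == 6
        assert all(4.0 < s.rc[0] < 6.0 for s in seeds)
        snaps, stack = run_vcmd_iteration(seeds, system, rc, grid, None,
                                          schedule, params)
        assert len(snaps) == 6 * 3000 // 100
        for snap in snaps:
            lo, hi = grid.state_bounds(snap.state)
            assert lo[0] - 0.5 <= snap.rc[0] <= hi[0] + 0.5

    def test_seed_generation_deterministic(self):
        system, rc, grid, schedule, params = self._setup()
        a = generate_initial_seeds(system, rc, [(4.0, 6.0)], 4, params, seed=9)
        b = generate_initial_seeds(system, rc, [(4.0, 6.0)], 4, params, seed=9)
        assert all(np.array_equal(x.coords, y.coords) for x, y in zip(a, b))
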