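"""Persistent snapshot store (HDF5) and ensemble weight tables.

Layout (schema version 1):

    /meta                 attrs: schema_version, package_version, config (JSON)
    /grid                 per-axis lo/hi/n_zones/bins_per_zone/overlap_bins
    /snapshots            coords (N,n,3), rc (N,d), state (N,d), iteration,
                          run_id, step, counted
    /histograms/<i_j_k>   per-state bin counts
    /qgrid/iter_%03d      stitched Q per iteration (attrs: mode, iteration)
    /convergence          per-iteration metric d

Numeric payloads round-trip bit-exact.  Reading a store written with a
different schema version raises :class:`StoreVersionError`; missing
payloads raise :class:`StoreIntegrityError`.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .engine import HistogramStack, IterationSchedule, QGrid, SamplingResult
from .errors import StoreIntegrityError, StoreVersionError
from .rc import Snapshot, ZoneAxis, ZoneGrid

__all__ = ["save_store", "load_store", "save_weights", "load_weights",
           "STORE_SCHEMA_VERSION"]

STORE_SCHEMA_VERSION = 1


def _ds(group, name, data):
    group.create_dataset(name, data=data, track_times=False)


def _grid_to_h5(g: h5py.Group, grid: ZoneGrid) -> None:
    _ds(g, "lo", [ax.lo for ax in grid.axes])
    _ds(g, "hi", [ax.hi for ax in grid.axes])
    _ds(g, "n_zones", [ax.n_zones for ax in grid.axes])
    _ds(g, "bins_per_zone", [ax.bins_per_zone for ax in grid.axes])
    _ds(g, "overlap_bins", [ax.overlap_bins for ax in grid.axes])


def _grid_from_h5(g: h5py.Group) -> ZoneGrid:
    los, his = g["lo"][:], g["hi"][:]
    nz, bpz, ob = g["n_zones"][:], g["bins_per_zone"][:], g["overlap_bins"][:]
    return ZoneGrid([
        ZoneAxis(float(lo), float(hi), int(n), int(b), int(o))
        for lo, hi, n, b, o in zip(los, his, nz, bpz, ob)
    ])


def save_store(path, result: SamplingResult, config_echo: dict | None = None) -> None:
    from . import __version__

    with h5py.File(path, "w") as fh:
        meta = fh.create_group("meta")
        meta.attrs["schema_version"] = STORE_SCHEMA_VERSION
        meta.attrs["package_version"] = __version__
        meta.attrs["config"] = json.dumps(config_echo or {}, sort_keys=True)
        sched = result.schedule
        meta.attrs["schedule"] = json.dumps({
            "n_iterations": sched.n_iterations,
            "n_runs_per_iteration": sched.n_runs_per_iteration,
            "steps_per_run": sched.steps_per_run,
            "dt": sched.dt,
            "snapshot_interval_steps": sched.snapshot_interval_steps,
            "transition_interval_steps": sched.transition_interval_steps,
        })

        _grid_to_h5(fh.create_group("grid"), result.grid)

        snaps = result.snapshots
        g = fh.create_group("snapshots")
        _ds(g, "coords", np.array([s.coords for s in snaps]))
        _ds(g, "rc", np.array([s.rc for s in snaps]))
        _ds(g, "state", np.array([s.state for s in snaps],
                                                dtype=np.int32))
        _ds(g, "iteration", np.array([s.iteration for s in snaps],
                                                    dtype=np.int32))
        _ds(g, "run_id", np.array([s.run_id for s in snaps],
                                                 dtype=np.int32))
        _ds(g, "step", np.array([s.step for s in snaps],
                                               dtype=np.int64))
        _ds(g, "counted", np.array([s.counted for s in snaps],
                                                  dtype=bool))

        h = fh.create_group("histograms")
        for state, counts in result.stack.counts.items():
            h.create_dataset("_".join(map(str, state)), data=counts,
                             track_times=False)
        h.attrs["dropped"] = result.stack.dropped

        qg = fh.create_group("qgrid")
        for q in result.qgrids:
            d = qg.create_dataset(f"iter_{q.iteration:03d}", data=q.values,
                                  track_times=False)
            d.attrs["mode"] = q.mode
            d.attrs["iteration"] = q.iteration

        _ds(fh, "convergence", np.asarray(result.convergence))
        if result.converged_at is not None:
            fh.attrs["converged_at"] = result.converged_at


def load_store(path) -> SamplingResult:
    with h5py.File(path, "r") as fh:
        if "meta" not in fh:
            raise StoreIntegrityError("store has no /meta group")
        version = int(fh["meta"].attrs.get("schema_version", -1))
        if version != STORE_SCHEMA_VERSION:
            raise StoreVersionError(
                f"store schema {version} != {STORE_SCHEMA_VERSION}; "
                "no migration path")
        for key in ("grid", "snapshots", "histograms", "qgrid"):
            if key not in fh:
                raise StoreIntegrityError(f"store is missing /{key}")
        grid = _grid_from_h5(fh["grid"])
        g = fh["snapshots"]
        coords, rcs = g["coords"][:], g["rc"][:]
        states, its = g["state"][:], g["iteration"][:]
        runs, steps, counted = g["run_id"][:], g["step"][:], g["counted"][:]
        snaps = [
            Snapshot(coords[i], rcs[i], tuple(int(v) for v in states[i]),
                     int(its[i]), int(runs[i]), int(steps[i]), bool(counted[i]))
            for i in range(coords.shape[0])
        ]
        stack = HistogramStack(grid)
        for name, ds in fh["histograms"].items():
            state = tuple(int(v) for v in name.split("_"))
            stack.counts[state] = ds[:]
        stack.dropped = int(fh["histograms"].attrs.get("dropped", 0))
        qgrids = []
        for name in sorted(fh["qgrid"]):
            ds = fh["qgrid"][name]
            qgrids.append(QGrid(ds[:], grid, mode=str(ds.attrs["mode"]),
                                iteration=int(ds.attrs["iteration"])))
        conv = fh["convergence"][:].tolist() if "convergence" in fh else []
        sched = json.loads(fh["meta"].attrs["schedule"])
        schedule = IterationSchedule(**sched)
        converged_at = (int(fh.attrs["converged_at"])
                        if "converged_at" in fh.attrs else None)
    return SamplingResult(snaps, stack, qgrids, conv, schedule, grid,
                          converged_at)


def save_weights(path, ensemble) -> None:
    """Two-column table: snapshot index, normalized thermodynamic weight."""
    with open(path, "w") as fh:
        fh.write("# snapshot_id\tweight\n")
        fh.write(f"# temperature_K\t{ensemble.temperature}\n")
        for i, w in enumerate(ensemble.weights):
            fh.write(f"{i}\t{w:.17e}\n")


def load_weights(path) -> np.ndarray:
    ids, ws = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            i, w = line.split()
            ids.append(int(i))
            ws.append(float(w))
    out = np.empty(len(ws))
    out[np.array(ids, dtype=int)] = np.array(ws)
    return out
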