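"""Binding-mode analyses on a weighted snapshot ensemble.

All real-space quantities are computed in a receptor-fixed frame obtained
by least-squares (Kabsch) superposition of the receptor-core beads onto a
reference structure.  The toolbox mirrors the standard repertoire for
ligand–receptor ensembles:

* spatial probability density ρ(r) of a selection's geometric center on a
  voxel grid, with contour levels quoted as multiples of ρ0 = 0.001;
* connected high-density clusters above a ρ0 multiple;
* the distribution of the minimum bead distance between the ligand and a
  named pocket residue (the "RDF" of this analysis, a normalized
  minimum-distance distribution without volume correction);
* a strict r < 4.0 Å contact rule and weighted contact fractions;
* intramolecular distance distributions (DDF) with the length-normalized
  flexibility sd = SD/⟨r⟩;
* the per-voxel mean tail→head unit vector ⟨e(r)⟩, voxels classified
  aligned when |⟨e⟩| ≥ 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .errors import (DegenerateSuperpositionError, EmptyDistributionError,
                     EmptyGridError, InvalidGroupError, InvalidSpecError,
                     ZeroLengthVectorError)
from .reweight import CanonicalEnsemble
from .rc import Snapshot, group_center

__all__ = [
    "GridSpec",
    "DensityGrid",
    "OrientationField",
    "DistanceDistribution",
    "Cluster",
    "ClusterReport",
    "kabsch_superpose",
    "align_ensemble",
    "spatial_density",
    "density_clusters",
    "min_group_distance",
    "contact_indicator",
    "contact_fraction",
    "distance_distribution",
    "flexibility_sd",
    "orientation_field",
]

RHO0 = 0.001
CONTACT_CUTOFF = 4.0  # Å


# ----------------------------------------------------------------------
# Superposition
# ----------------------------------------------------------------------

def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray,
                     selection) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid transform of ``mobile`` onto ``reference``.

    The rotation/translation minimizing the RMSD of ``selection`` beads is
    found and returned as (R, t, rmsd); apply it as ``x @ R.T + t``.
    """
    sel = np.asarray(selection, dtype=np.intp)
    if sel.size < 3:
        raise DegenerateSuperpositionError("selection must hold >= 3 beads")
    mob = np.asarray(mobile, dtype=float)[sel]
    ref = np.asarray(reference, dtype=float)[sel]
    cm, cr = mob.mean(axis=0), ref.mean(axis=0)
    a, b = mob - cm, ref - cr
    svals = np.linalg.svd(a.T @ b, compute_uv=False)
    if svals[1] <= 1e-8 * max(svals[0], 1e-30):
        raise DegenerateSuperpositionError("selection is (near-)collinear")
    rot, _ = Rotation.align_vectors(b, a)
    r = rot.as_matrix()
    t = cr - cm @ r.T
    rmsd = float(np.sqrt(np.mean(np.sum((mob @ r.T + t - ref) ** 2, axis=1))))
    return r, t, rmsd


def align_ensemble(ensemble: CanonicalEnsemble, reference: np.ndarray,
                   selection) -> CanonicalEnsemble:
    """Superpose every snapshot onto the reference frame (new ensemble)."""
    snaps = []
    for s in ensemble.snapshots:
        r, t, _ = kabsch_superpose(s.coords, reference, selection)
        snaps.append(Snapshot(s.coords @ r.T + t, s.rc.copy(), s.state,
                              s.iteration, s.run_id, s.step))
    return CanonicalEnsemble(snaps, ensemble.weights.copy(),
                             ensemble.temperature, ensemble.q_iteration,
                             ensemble.n_zero_weight)


# ----------------------------------------------------------------------
# Grids
# ----------------------------------------------------------------------

@dataclass
class GridSpec:
    """Voxel geometry for real-space grids.

    With ``origin``/``shape`` unset the grid is fitted to the data
    ("grow"); with a fixed geometry, ``out_of_grid`` picks between growing
    the grid and dropping (and logging) outside points.
    """

    spacing: float = 1.0
    origin: np.ndarray | None = None
    shape: tuple[int, int, int] | None = None
    out_of_grid: str = "grow"        # "grow" | "drop"

    def __post_init__(self):
        if self.spacing <= 0:
            raise InvalidSpecError("voxel spacing must be positive")
        if self.out_of_grid not in ("grow", "drop"):
            raise InvalidSpecError("out_of_grid must be 'grow' or 'drop'")


def _fit_grid(points: np.ndarray, spec: GridSpec):
    if spec.origin is not None and spec.shape is not None:
        return np.asarray(spec.origin, dtype=float), tuple(spec.shape)
    lo = points.min(axis=0) - 0.5 * spec.spacing
    hi = points.max(axis=0) + 0.5 * spec.spacing
    shape = tuple(np.maximum(np.ceil((hi - lo) / spec.spacing).astype(int), 1))
    return lo, shape


def _voxelize(points: np.ndarray, weights: np.ndarray, spec: GridSpec):
    """Common accumulation: returns (origin, shape, idx, keep_mask)."""
    origin, shape = _fit_grid(points, spec)
    idx = np.floor((points - origin[None, :]) / spec.spacing).astype(int)
    inside = np.all((idx >= 0) & (idx < np.array(shape)[None, :]), axis=1)
    if not inside.all():
        if spec.out_of_grid == "grow" and (spec.origin is None or spec.shape is None):
            pass  # fitted grid always contains the data
        elif spec.out_of_grid == "grow":
            lo = np.minimum(origin, points.min(axis=0) - 0.5 * spec.spacing)
            hi = np.maximum(origin + np.array(shape) * spec.spacing,
                            points.max(axis=0) + 0.5 * spec.spacing)
            origin = lo
            shape = tuple(np.ceil((hi - lo) / spec.spacing).astype(int))
            idx = np.floor((points - origin[None, :]) / spec.spacing).astype(int)
            inside = np.ones(points.shape[0], dtype=bool)
    if not inside.any():
        raise EmptyGridError("every point fell outside the grid")
    return origin, shape, idx, inside


@dataclass
class DensityGrid:
    """Per-voxel probability of a selection center (values sum to 1)."""

    origin: np.ndarray               # Å, corner of voxel (0,0,0)
    spacing: float                   # Å
    values: np.ndarray               # (nx, ny, nz), sums to 1
    rho0: float = RHO0
    label: str = "ligand_gc"
    n_dropped: int = 0

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.spacing <= 0:
            raise InvalidSpecError("voxel spacing must be positive")

    def voxel_centers(self) -> np.ndarray:
        axes = [self.origin[d] + self.spacing * (np.arange(self.values.shape[d]) + 0.5)
                for d in range(3)]
        g = np.meshgrid(*axes, indexing="ij")
        return np.stack(g, axis=-1)


def spatial_density(ensemble: CanonicalEnsemble, target_selection,
                    grid_spec: GridSpec | None = None,
                    label: str = "ligand_gc") -> DensityGrid:
    """Weighted voxel histogram of the selection's geometric center.

    Snapshots are assumed already superposed to the reference frame (see
    :func:`align_ensemble`).
    """
    sel = np.asarray(target_selection, dtype=np.intp)
    if sel.size == 0:
        raise InvalidGroupError("target selection is empty")
    spec = grid_spec or GridSpec()
    centers = np.array([s.coords[sel].mean(axis=0) for s in ensemble.snapshots])
    origin, shape, idx, inside = _voxelize(centers, ensemble.weights, spec)
    values = np.zeros(shape)
    np.add.at(values, tuple(idx[inside].T), ensemble.weights[inside])
    total = values.sum()
    if total <= 0:
        raise EmptyGridError("no weight accumulated on the grid")
    return DensityGrid(origin, spec.spacing, values / total, label=label,
                       n_dropped=int((~inside).sum()))


# ----------------------------------------------------------------------
# Clusters
# ----------------------------------------------------------------------

@dataclass
class Cluster:
    voxels: np.ndarray               # (m, 3) integer voxel indices
    mass: float                      # total probability
    peak_voxel: tuple[int, int, int]
    centroid: np.ndarray             # Å, probability-weighted


@dataclass
class ClusterReport:
    clusters: list[Cluster]
    threshold: float                 # absolute density threshold used
    level_multiplier: float
    rho0: float

    def __len__(self):
        return len(self.clusters)


def density_clusters(grid: DensityGrid, level_multiplier: float = 0.5,
                     rho0: float | None = None) -> ClusterReport:
    """26-connected components of voxels above level_multiplier·ρ0.

    Clusters are sorted by probability mass, largest first.
    """
    if level_multiplier <= 0:
        raise InvalidSpecError("level_multiplier must be positive")
    rho0 = grid.rho0 if rho0 is None else rho0
    thr = level_multiplier * rho0
    mask = grid.values > thr
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
    clusters = []
    centers = grid.voxel_centers()
    for lab in range(1, n + 1):
        m = labels == lab
        vox = np.argwhere(m)
        vals = grid.values[m]
        mass = float(vals.sum())
        peak = tuple(int(v) for v in vox[np.argmax(vals)])
        centroid = (vals[:, None] * centers[m]).sum(axis=0) / mass
        clusters.append(Cluster(vox, mass, peak, centroid))
    clusters.sort(key=lambda c: -c.mass)
    return ClusterReport(clusters, thr, level_multiplier, rho0)


# ----------------------------------------------------------------------
# Distances and contacts
# ----------------------------------------------------------------------

def min_group_distance(coords: np.ndarray, group1, group2) -> float:
    """Minimum pairwise Euclidean distance between two bead groups (Å)."""
    g1 = np.asarray(group1, dtype=np.intp)
    g2 = np.asarray(group2, dtype=np.intp)
    if g1.size == 0 or g2.size == 0:
        raise InvalidGroupError("groups must be nonempty")
    x = np.asarray(coords, dtype=float)
    return float(cdist(x[g1], x[g2]).min())


def contact_indicator(r: float, cutoff: float = CONTACT_CUTOFF) -> bool:
    """Strict contact rule r < cutoff."""
    if cutoff <= 0:
        raise InvalidSpecError("cutoff must be positive")
    return bool(r < cutoff)


def contact_fraction(ensemble: CanonicalEnsemble, group1, group2,
                     cutoff: float = CONTACT_CUTOFF) -> float:
    """Weighted fraction of snapshots with min group distance < cutoff."""
    if cutoff <= 0:
        raise InvalidSpecError("cutoff must be positive")
    total = 0.0
    for snap, w in zip(ensemble.snapshots, ensemble.weights):
        if min_group_distance(snap.coords, group1, group2) < cutoff:
            total += float(w)
    return total


# ----------------------------------------------------------------------
# Distance distributions (RDF / DDF)
# ----------------------------------------------------------------------

@dataclass
class DistanceSpec:
    """Which distance to histogram: group minimum (RDF) or atom pair (DDF)."""

    kind: str                        # "group_min" | "atom_pair"
    group_A: Sequence[int] | None = None
    group_B: Sequence[int] | None = None
    atom_i: int | None = None
    atom_j: int | None = None

    def evaluate(self, coords: np.ndarray) -> float:
        if self.kind == "group_min":
            return min_group_distance(coords, self.group_A, self.group_B)
        if self.kind == "atom_pair":
            return float(np.linalg.norm(coords[self.atom_i] - coords[self.atom_j]))
        raise InvalidSpecError(f"unknown distance kind {self.kind!r}")

    @property
    def tag(self) -> str:
        return "group-minimum" if self.kind == "group_min" else "atom-pair"


@dataclass
class DistanceDistribution:
    edges: np.ndarray                # Å
    density: np.ndarray              # integrates to 1
    mean: float                      # ⟨r⟩, Å (weighted, unbinned)
    sd_abs: float                    # SD(r), Å
    sd: float                        # SD/⟨r⟩, dimensionless
    definition: str = "group-minimum"


def distance_distribution(ensemble: CanonicalEnsemble, spec: DistanceSpec,
                          bin_width: float = 0.2) -> DistanceDistribution:
    """Weighted distance histogram plus unbinned weighted mean/SD/sd.

    The moments are computed from the raw per-snapshot distances, never
    from binned values, so they are invariant under bin-width changes.
    """
    if bin_width <= 0:
        raise InvalidSpecError("bin_width must be positive")
    r = np.array([spec.evaluate(s.coords) for s in ensemble.snapshots])
    w = ensemble.weights
    total = w.sum()
    if total <= 0:
        raise EmptyDistributionError("ensemble carries no weight")
    mean = float(np.sum(w * r) / total)
    var = float(np.sum(w * (r - mean) ** 2) / total)
    sd_abs = float(np.sqrt(max(var, 0.0)))
    sd = sd_abs / mean if mean > 0 else 0.0
    lo = np.floor(r.min() / bin_width) * bin_width
    n_bins = max(int(np.ceil((r.max() - lo) / bin_width)), 1)
    edges = lo + bin_width * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], r.max() + 1e-12)
    hist, edges = np.histogram(r, bins=edges, weights=w)
    density = hist / (hist.sum() * np.diff(edges))
    return DistanceDistribution(edges, density, mean, sd_abs, sd, spec.tag)


def flexibility_sd(mean: float, sd_abs: float) -> float:
    """Length-normalized flexibility sd = SD/⟨r⟩, to 3 significant figures."""
    if mean <= 0:
        raise InvalidSpecError("mean distance must be positive")
    if sd_abs < 0:
        raise InvalidSpecError("SD must be nonnegative")
    return float(f"{sd_abs / mean:.3g}")


# ----------------------------------------------------------------------
# Orientation field
# ----------------------------------------------------------------------

@dataclass
class OrientationField:
    """Per-voxel weighted mean of the ligand tail→head unit vector."""

    origin: np.ndarray
    spacing: float
    vectors: np.ndarray              # (nx, ny, nz, 3): ⟨e(r)⟩
    weight: np.ndarray               # (nx, ny, nz): supporting weight
    classify_threshold: float = 0.5
    head_label: str = "ligand_head"
    tail_label: str = "ligand_tail"

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)

    def aligned_mask(self) -> np.ndarray:
        """Occupied voxels with |⟨e⟩| ≥ threshold."""
        return (self.weight > 0) & (self.magnitude() >= self.classify_threshold)

    def occupied_mask(self) -> np.ndarray:
        return self.weight > 0

    def voxel_centers(self) -> np.ndarray:
        axes = [self.origin[d] + self.spacing * (np.arange(self.weight.shape[d]) + 0.5)
                for d in range(3)]
        return np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)


def orientation_field(ensemble: CanonicalEnsemble, head_group, tail_group,
                      grid_spec: GridSpec | None = None,
                      masses: np.ndarray | None = None,
                      ligand_group=None,
                      classify_threshold: float = 0.5) -> OrientationField:
    """⟨e(r)⟩ on a voxel grid.

    Per snapshot, e is the unit vector from the tail-group geometric center
    to the head-group geometric center; the snapshot is assigned to the
    voxel holding the ligand's center of mass (center of geometry when no
    masses are given) and contributes its thermodynamic weight.
    """
    head = np.asarray(head_group, dtype=np.intp)
    tail = np.asarray(tail_group, dtype=np.intp)
    if head.size == 0 or tail.size == 0:
        raise InvalidGroupError("head and tail groups must be nonempty")
    if set(head.tolist()) & set(tail.tolist()):
        raise InvalidGroupError("head and tail groups must be disjoint")
    lig = (np.asarray(ligand_group, dtype=np.intp) if ligand_group is not None
           else np.union1d(head, tail))
    spec = grid_spec or GridSpec(spacing=2.0)

    n = len(ensemble.snapshots)
    evecs = np.empty((n, 3))
    anchors = np.empty((n, 3))
    for i, s in enumerate(ensemble.snapshots):
        hc = s.coords[head].mean(axis=0)
        tc = s.coords[tail].mean(axis=0)
        d = hc - tc
        norm = np.linalg.norm(d)
        if norm < 1e-9:
            raise ZeroLengthVectorError(
                f"snapshot {i} (run {s.run_id}, step {s.step}): head and "
                "tail centers coincide")
        evecs[i] = d / norm
        if masses is not None:
            anchors[i] = group_center(s.coords, lig, "mass", masses)
        else:
            anchors[i] = s.coords[lig].mean(axis=0)

    origin, shape, idx, inside = _voxelize(anchors, ensemble.weights, spec)
    vec = np.zeros(shape + (3,))
    wgt = np.zeros(shape)
    ii = tuple(idx[inside].T)
    np.add.at(wgt, ii, ensemble.weights[inside])
    for d in range(3):
        np.add.at(vec[..., d], ii, ensemble.weights[inside] * evecs[inside, d])
    mean_vec = np.divide(vec, wgt[..., None],
                         out=np.zeros_like(vec), where=wgt[..., None] > 0)
    return OrientationField(origin, spec.spacing, mean_vec, wgt,
                            classify_threshold)
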