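"""Synthetic coarse-grained ligand–receptor systems.

A :class:`ToySystem` is a bead model: a rigid concave receptor whose pocket
lining ("cleft") beads can be given a deeper Lennard-Jones well with the
ligand head beads than ordinary surface beads, a weakly restrained
C-terminal-tail analog, and a short bead-chain ligand with named head/tail
groups.  The Hamiltonian is

    U = Σ_bonds k_b (r - r0)²  +  Σ_angles k_a (θ - θ0)²
      + Σ_pairs 4ε[(σ/r)¹² - (σ/r)⁶]  +  Σ_restraints k_r |x - x_ref|²

(harmonic terms carry no 1/2 factor).  Units: Å, kcal/mol, K, fs, amu.
There is no nonbonded cutoff — systems are tens of beads and the analytic
references require an exact Hamiltonian.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .errors import InvalidSpecError, OverlapError, InvalidGroupError

__all__ = [
    "Restraint",
    "ToySystem",
    "ToySpec",
    "build_toy_complex",
    "build_reduced_pair_system",
    "potential_energy",
    "save_system",
    "load_system",
    "system_to_pdb",
    "demo_binder_spec",
    "demo_rod_spec",
]

_R_FLOOR = 1e-6  # Å; below this a nonbonded pair is considered coincident

SCHEMA_VERSION = 1


@dataclass
class Restraint:
    """Harmonic position restraint k_r·|x − x_ref|² applied to a bead set."""

    indices: np.ndarray
    anchors: np.ndarray  # (len(indices), 3) reference positions, Å
    k: float             # kcal/mol/Å²

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.intp)
        self.anchors = np.asarray(self.anchors, dtype=float).reshape(-1, 3)
        if self.anchors.shape[0] != self.indices.shape[0]:
            raise InvalidSpecError("restraint anchors must match bead indices")
        if self.k < 0:
            raise InvalidSpecError("restraint stiffness must be nonnegative")


@dataclass
class ToySystem:
    coords: np.ndarray                  # (n, 3) Å
    masses: np.ndarray                  # (n,) amu
    bead_types: list[str]
    bonds: np.ndarray                   # (nb, 2) int
    bond_k: np.ndarray                  # kcal/mol/Å²
    bond_r0: np.ndarray                 # Å
    angles: np.ndarray                  # (na, 3) int, middle bead is the vertex
    angle_k: np.ndarray                 # kcal/mol/rad²
    angle_theta0: np.ndarray            # rad
    nonbonded: dict                     # (type_a, type_b) sorted tuple -> (ε, σ)
    groups: dict                        # name -> index array
    restraints: list = field(default_factory=list)
    frozen: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.intp))
    extra_exclusions: set = field(default_factory=set)
    meta: dict = field(default_factory=dict)

    # -- derived, cached pair tables ------------------------------------
    _pair_cache: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        n = self.coords.shape[0]
        self.masses = np.asarray(self.masses, dtype=float)
        self.bonds = np.asarray(self.bonds, dtype=np.intp).reshape(-1, 2)
        self.bond_k = np.asarray(self.bond_k, dtype=float)
        self.bond_r0 = np.asarray(self.bond_r0, dtype=float)
        self.angles = np.asarray(self.angles, dtype=np.intp).reshape(-1, 3)
        self.angle_k = np.asarray(self.angle_k, dtype=float)
        self.angle_theta0 = np.asarray(self.angle_theta0, dtype=float)
        self.frozen = np.asarray(self.frozen, dtype=np.intp)
        self.groups = {k: np.asarray(v, dtype=np.intp) for k, v in self.groups.items()}
        self.validate()

    # ------------------------------------------------------------------
    @property
    def n_beads(self) -> int:
        return self.coords.shape[0]

    def validate(self):
        n = self.n_beads
        if len(self.bead_types) != n or self.masses.shape[0] != n:
            raise InvalidSpecError("bead_types/masses length mismatch")
        for name, ids in self.groups.items():
            if ids.size and (ids.min() < 0 or ids.max() >= n):
                raise InvalidGroupError(f"group {name!r} has out-of-range indices")
        if np.any(self.bond_k < 0) or np.any(self.angle_k < 0):
            raise InvalidSpecError("force constants must be nonnegative")
        for (ta, tb), (eps, sig) in self.nonbonded.items():
            if eps < 0 or sig <= 0:
                raise InvalidSpecError(f"bad LJ parameters for pair ({ta}, {tb})")
        lig = set(self.groups.get("ligand", np.empty(0, dtype=np.intp)).tolist())
        for sub in ("ligand_head", "ligand_tail", "ligand_ringA"):
            if sub in self.groups and not set(self.groups[sub].tolist()) <= lig:
                raise InvalidGroupError(f"{sub} must be a subset of ligand")
        rec = set(self.groups.get("receptor_core", np.empty(0, dtype=np.intp)).tolist())
        if rec & lig:
            raise InvalidGroupError("receptor and ligand bead sets must be disjoint")

    def group(self, name: str) -> np.ndarray:
        try:
            ids = self.groups[name]
        except KeyError:
            raise InvalidGroupError(f"unknown group {name!r}") from None
        if ids.size == 0:
            raise InvalidGroupError(f"group {name!r} is empty")
        return ids

    # ------------------------------------------------------------------
    def nonbonded_pairs(self):
        """Pair tables (i, j, ε, σ): all pairs minus 1-2/1-3 and explicit
        exclusions.  Cached; invalidate by setting ``_pair_cache = None``."""
        if self._pair_cache is not None:
            return self._pair_cache
        n = self.n_beads
        excl = set(self.extra_exclusions)
        for i, j in self.bonds:
            excl.add((min(i, j), max(i, j)))
        for i, j, k in self.angles:
            excl.add((min(i, k), max(i, k)))
            excl.add((min(i, j), max(i, j)))
            excl.add((min(j, k), max(j, k)))
        ii, jj = np.triu_indices(n, k=1)
        keep = np.array(
            [(a, b) not in excl for a, b in zip(ii.tolist(), jj.tolist())], dtype=bool
        )
        ii, jj = ii[keep], jj[keep]
        eps = np.empty(ii.shape[0])
        sig = np.empty(ii.shape[0])
        for m, (a, b) in enumerate(zip(ii.tolist(), jj.tolist())):
            key = tuple(sorted((self.bead_types[a], self.bead_types[b])))
            e, s = self.nonbonded.get(key, (0.0, 1.0))
            eps[m] = e
            sig[m] = s
        live = eps > 0.0
        self._pair_cache = (ii[live], jj[live], eps[live], sig[live])
        return self._pair_cache


# ----------------------------------------------------------------------
# Energy and forces
# ----------------------------------------------------------------------

def potential_energy(system: ToySystem, coords: np.ndarray | None = None):
    """Total potential energy (kcal/mol) and forces (kcal/mol/Å).

    Plain vectorized evaluation of the toy Hamiltonian; no cutoff, no
    periodicity.  Raises :class:`OverlapError` when a nonbonded pair sits
    below the numeric distance floor.
    """
    x = system.coords if coords is None else np.asarray(coords, dtype=float)
    if x.shape != system.coords.shape:
        raise InvalidSpecError("coords shape does not match system")
    energy = 0.0
    forces = np.zeros_like(x)

    if system.bonds.shape[0]:
        i, j = system.bonds[:, 0], system.bonds[:, 1]
        d = x[i] - x[j]
        r = np.linalg.norm(d, axis=1)
        dr = r - system.bond_r0
        energy += float(np.sum(system.bond_k * dr * dr))
        f = (-2.0 * system.bond_k * dr / np.maximum(r, _R_FLOOR))[:, None] * d
        np.add.at(forces, i, f)
        np.add.at(forces, j, -f)

    if system.angles.shape[0]:
        ai, aj, ak = system.angles[:, 0], system.angles[:, 1], system.angles[:, 2]
        u = x[ai] - x[aj]
        v = x[ak] - x[aj]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        c = np.einsum("ij,ij->i", u, v) / np.maximum(nu * nv, _R_FLOOR)
        c = np.clip(c, -1.0, 1.0)
        theta = np.arccos(c)
        dtheta = theta - system.angle_theta0
        energy += float(np.sum(system.angle_k * dtheta * dtheta))
        s = np.sqrt(np.maximum(1.0 - c * c, 1e-12))
        uh = u / nu[:, None]
        vh = v / nv[:, None]
        # dθ/du = -(v̂ - cos·û) / (|u| sinθ), symmetric in u↔v for the k bead
        pref = (2.0 * system.angle_k * dtheta / s)
        fi = (pref / nu)[:, None] * (vh - c[:, None] * uh)
        fk = (pref / nv)[:, None] * (uh - c[:, None] * vh)
        np.add.at(forces, ai, fi)
        np.add.at(forces, ak, fk)
        np.add.at(forces, aj, -(fi + fk))

    ii, jj, eps, sig = system.nonbonded_pairs()
    if ii.shape[0]:
        d = x[ii] - x[jj]
        r2 = np.einsum("ij,ij->i", d, d)
        if np.any(r2 < _R_FLOOR * _R_FLOOR):
            bad = int(np.argmin(r2))
            raise OverlapError(
                f"beads {int(ii[bad])} and {int(jj[bad])} are coincident"
            )
        sr2 = sig * sig / r2
        sr6 = sr2 * sr2 * sr2
        sr12 = sr6 * sr6
        energy += float(np.sum(4.0 * eps * (sr12 - sr6)))
        # dU/dr · (1/r) = -24 ε (2 (σ/r)^12 - (σ/r)^6) / r²
        g = 24.0 * eps * (2.0 * sr12 - sr6) / r2
        f = g[:, None] * d
        np.add.at(forces, ii, f)
        np.add.at(forces, jj, -f)

    for rest in system.restraints:
        dx = x[rest.indices] - rest.anchors
        energy += float(rest.k * np.sum(dx * dx))
        np.add.at(forces, rest.indices, -2.0 * rest.k * dx)

    return energy, forces


# ----------------------------------------------------------------------
# Generator
# ----------------------------------------------------------------------

@dataclass
class ToySpec:
    """Generator parameters for the synthetic receptor–ligand complex.

    Defaults describe the shipped "binder" system: a cup-shaped receptor of
    ~27 beads with a three-bead hydrophobic pocket lining, a weakly
    restrained three-bead tail analog, and a four-bead ligand whose head
    bead sees a ``cleft_eps_multiplier`` deeper LJ well with the pocket
    lining than with ordinary surface beads.
    """

    # receptor shape
    cleft_radius: float = 2.2        # radius of the 3 pocket-bottom beads, Å
    mid_radius: float = 3.4          # pocket wall ring radius, Å
    rim_radius: float = 4.8          # pocket rim ring radius, Å
    n_mid: int = 8
    n_rim: int = 8
    n_surface: int = 6
    n_tail: int = 3
    # ligand
    n_ligand_beads: int = 4
    head_size: int = 1
    tail_size: int = 1
    bond_length: float = 2.0         # Å
    bond_k: float = 20.0             # kcal/mol/Å²
    angle_k: float = 6.0             # kcal/mol/rad² (framework flexibility)
    # interactions
    base_eps: float = 0.2            # kcal/mol
    sigma: float = 3.0               # Å
    cleft_eps_multiplier: float = 10.0
    # restraints
    receptor_restraint_k: float = 10.0   # kcal/mol/Å²
    tail_restraint_k: float = 0.5        # kcal/mol/Å²
    mass: float = 40.0               # amu per bead (united-group beads)


def _ring(n: int, radius: float, z: float, phase: float = 0.0) -> np.ndarray:
    ang = phase + 2.0 * np.pi * np.arange(n) / n
    return np.column_stack([radius * np.cos(ang), radius * np.sin(ang), np.full(n, z)])


def build_toy_complex(spec: ToySpec, seed: int) -> ToySystem:
    """Deterministically build a receptor+ligand bead system from ``spec``.

    The receptor pocket opens along +z with its lining beads at z ≈ 0; the
    ligand chain starts above the pocket.  ``seed`` only jitters the
    decorative outer-surface beads, so the binding-relevant geometry is
    identical across seeds.
    """
    if spec.n_ligand_beads < 2:
        raise InvalidSpecError("ligand needs at least 2 beads (head/tail undefined)")
    if spec.head_size < 1 or spec.tail_size < 1:
        raise InvalidSpecError("head/tail group sizes must be >= 1")
    if spec.head_size + spec.tail_size > spec.n_ligand_beads:
        raise InvalidSpecError("head and tail groups exceed ligand size")

    rng = np.random.default_rng(seed)

    blocks = []
    types: list[str] = []

    cleft = _ring(3, spec.cleft_radius, 0.0, phase=np.pi / 2)
    blocks.append(cleft)
    types += ["C"] * 3
    base = np.array([[0.0, 0.0, -2.2]])
    blocks.append(base)
    types += ["R"]
    # under-ring shields the pocket lining from below, so the deep LJ well
    # with the head is only reachable through the pocket opening
    under = _ring(8, 3.0, -1.8)
    blocks.append(under)
    types += ["R"] * 8
    mid = _ring(spec.n_mid, spec.mid_radius, 1.6)
    blocks.append(mid)
    types += ["R"] * spec.n_mid
    rim = _ring(spec.n_rim, spec.rim_radius, 3.4, phase=np.pi / spec.n_rim)
    blocks.append(rim)
    types += ["R"] * spec.n_rim
    # decorative outer surface beads (jittered)
    ang = 2.0 * np.pi * np.arange(spec.n_surface) / max(spec.n_surface, 1)
    surf = np.column_stack([
        6.5 * np.cos(ang),
        6.5 * np.sin(ang),
        np.linspace(-1.5, 1.5, max(spec.n_surface, 1)),
    ]) + rng.normal(scale=0.3, size=(spec.n_surface, 3))
    blocks.append(surf)
    types += ["R"] * spec.n_surface
    # C-terminal tail analog: short chain off the rim, weakly restrained
    tail0 = np.array([spec.rim_radius + 1.8, 0.0, 3.4])
    tail = tail0 + np.column_stack([
        2.0 * np.arange(spec.n_tail),
        np.zeros(spec.n_tail),
        np.zeros(spec.n_tail),
    ])
    blocks.append(tail)
    types += ["T"] * spec.n_tail

    n_receptor = sum(b.shape[0] for b in blocks)

    # ligand chain above the pocket, slight offset to break symmetry
    lig = np.column_stack([
        np.full(spec.n_ligand_beads, 0.4),
        np.full(spec.n_ligand_beads, 0.2),
        8.0 + spec.bond_length * np.arange(spec.n_ligand_beads),
    ])
    blocks.append(lig)
    lig_types = ["L"] * spec.n_ligand_beads
    for i in range(spec.head_size):
        lig_types[i] = "H"
    for i in range(spec.tail_size):
        lig_types[-1 - i] = "E"
    types += lig_types

    coords = np.vstack(blocks)
    n = coords.shape[0]
    masses = np.full(n, spec.mass)

    # bonds: tail chain + ligand chain
    bonds, bk, br0 = [], [], []
    tail_start = n_receptor - spec.n_tail
    for i in range(spec.n_tail - 1):
        bonds.append((tail_start + i, tail_start + i + 1))
        bk.append(10.0)
        br0.append(2.0)
    lig_start = n_receptor
    for i in range(spec.n_ligand_beads - 1):
        bonds.append((lig_start + i, lig_start + i + 1))
        bk.append(spec.bond_k)
        br0.append(spec.bond_length)

    # angles along the ligand chain
    angles, ak, at0 = [], [], []
    for i in range(spec.n_ligand_beads - 2):
        angles.append((lig_start + i, lig_start + i + 1, lig_start + i + 2))
        ak.append(spec.angle_k)
        at0.append(np.pi)

    # LJ table: geometric-mean ε, arithmetic-mean σ per type pair, then the
    # pocket override deepening head–cleft wells
    all_types = sorted(set(types))
    per_type_eps = {t: spec.base_eps for t in all_types}
    per_type_sig = {t: spec.sigma for t in all_types}
    nonbonded = {}
    for a in all_types:
        for b in all_types:
            key = tuple(sorted((a, b)))
            eps = float(np.sqrt(per_type_eps[a] * per_type_eps[b]))
            sig = 0.5 * (per_type_sig[a] + per_type_sig[b])
            nonbonded[key] = (eps, sig)
    nonbonded[tuple(sorted(("C", "H")))] = (
        spec.base_eps * spec.cleft_eps_multiplier,
        spec.sigma,
    )

    rim_ids = np.arange(12 + spec.n_mid, 12 + spec.n_mid + spec.n_rim)
    rim_x = coords[rim_ids, 0]
    groups = {
        "receptor_core": np.arange(0, tail_start),
        "tail": np.arange(tail_start, n_receptor),
        "cleft_V75": np.array([0]),
        "cleft_F93": np.array([1]),
        "cleft_F96": np.array([2]),
        "cleft": np.arange(0, 3),
        "rim": rim_ids,
        "alpha_A": rim_ids[np.argsort(rim_x)[:2]],       # -x side of the rim
        "alpha_B": rim_ids[np.argsort(rim_x)[-2:]],      # +x side of the rim
        "ligand": np.arange(lig_start, n),
        "ligand_head": np.arange(lig_start, lig_start + spec.head_size),
        "ligand_tail": np.arange(n - spec.tail_size, n),
        "ligand_ringA": np.arange(lig_start, lig_start + spec.head_size),
    }

    restraints = [
        Restraint(groups["receptor_core"], coords[groups["receptor_core"]],
                  spec.receptor_restraint_k),
        Restraint(groups["tail"], coords[groups["tail"]], spec.tail_restraint_k),
    ]

    # receptor-internal nonbonded pairs are dropped: the receptor frame is
    # held by position restraints, its internal LJ terms only add cost
    rec_all = np.arange(0, n_receptor)
    extra_exclusions = {
        (int(a), int(b))
        for idx, a in enumerate(rec_all)
        for b in rec_all[idx + 1:]
    }

    return ToySystem(
        coords=coords,
        masses=masses,
        bead_types=types,
        bonds=np.array(bonds, dtype=np.intp).reshape(-1, 2),
        bond_k=np.array(bk),
        bond_r0=np.array(br0),
        angles=np.array(angles, dtype=np.intp).reshape(-1, 3),
        angle_k=np.array(ak),
        angle_theta0=np.array(at0),
        nonbonded=nonbonded,
        groups=groups,
        restraints=restraints,
        extra_exclusions=extra_exclusions,
        meta={"spec": asdict(spec), "seed": int(seed)},
    )


def demo_binder_spec() -> ToySpec:
    """The shipped head-attractive ligand (sertraline-like behavior)."""
    return ToySpec()


def demo_rod_spec() -> ToySpec:
    """The shipped stiff rod ligand with uniform affinity (acitretin-like).

    Longer chain, stiff angles, no pocket preference."""
    return ToySpec(
        n_ligand_beads=7,
        angle_k=50.0,
        cleft_eps_multiplier=1.0,
    )


def build_reduced_pair_system(
    r0: float = 6.0,
    k_tether: float = 1.0,
    mass: float = 40.0,
    eps: float = 0.0,
    sigma: float = 3.0,
) -> ToySystem:
    """Two-group reference system with a separable radial potential.

    Bead 0 is frozen at the origin; bead 1 is tethered by a harmonic bond
    U(r) = k_tether (r − r0)² (plus an optional LJ term when ``eps`` > 0).
    Its RC Boltzmann density has the closed form p(r) ∝ r² e^{−U(r)/k_BT},
    which :func:`vczone.analytic.analytic_rc_boltzmann` evaluates by
    quadrature — the oracle the sampled ensembles must recover.
    """
    coords = np.array([[0.0, 0.0, 0.0], [r0, 0.0, 0.0]])
    nonbonded = {("A", "B"): (eps, sigma), ("A", "A"): (0.0, sigma),
                 ("B", "B"): (0.0, sigma)}
    return ToySystem(
        coords=coords,
        masses=np.array([mass, mass]),
        bead_types=["A", "B"],
        bonds=np.array([[0, 1]]),
        bond_k=np.array([k_tether]),
        bond_r0=np.array([r0]),
        angles=np.empty((0, 3), dtype=np.intp),
        angle_k=np.empty(0),
        angle_theta0=np.empty(0),
        nonbonded=nonbonded,
        groups={"receptor_core": np.array([0]), "ligand": np.array([1])},
        restraints=[],
        frozen=np.array([0]),
        meta={"reduced": True, "r0": r0, "k_tether": k_tether},
    )


# ----------------------------------------------------------------------
# Serialization
# ----------------------------------------------------------------------

def save_system(system: ToySystem, path) -> None:
    """Write the documented structured-text (JSON) schema.

    Top level: schema_version, beads (coords/masses/types), bond/angle
    tables, nonbonded LJ table, groups, restraints, frozen set, meta.
    """
    payload = {
        "schema_version": SCHEMA_VERSION,
        "beads": {
            "coords": system.coords.tolist(),
            "masses": system.masses.tolist(),
            "types": list(system.bead_types),
        },
        "bonds": {
            "index": system.bonds.tolist(),
            "k": system.bond_k.tolist(),
            "r0": system.bond_r0.tolist(),
        },
        "angles": {
            "index": system.angles.tolist(),
            "k": system.angle_k.tolist(),
            "theta0": system.angle_theta0.tolist(),
        },
        "nonbonded": [
            {"types": list(key), "eps": eps, "sigma": sig}
            for key, (eps, sig) in sorted(system.nonbonded.items())
        ],
        "groups": {k: v.tolist() for k, v in system.groups.items()},
        "restraints": [
            {"indices": r.indices.tolist(), "anchors": r.anchors.tolist(), "k": r.k}
            for r in system.restraints
        ],
        "frozen": system.frozen.tolist(),
        "exclusions": sorted([list(p) for p in system.extra_exclusions]),
        "meta": system.meta,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def load_system(path) -> ToySystem:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("schema_version") != SCHEMA_VERSION:
        from .errors import StoreVersionError
        raise StoreVersionError(
            f"system schema {payload.get('schema_version')} != {SCHEMA_VERSION}"
        )
    return ToySystem(
        coords=np.array(payload["beads"]["coords"]),
        masses=np.array(payload["beads"]["masses"]),
        bead_types=list(payload["beads"]["types"]),
        bonds=np.array(payload["bonds"]["index"], dtype=np.intp).reshape(-1, 2),
        bond_k=np.array(payload["bonds"]["k"]),
        bond_r0=np.array(payload["bonds"]["r0"]),
        angles=np.array(payload["angles"]["index"], dtype=np.intp).reshape(-1, 3),
        angle_k=np.array(payload["angles"]["k"]),
        angle_theta0=np.array(payload["angles"]["theta0"]),
        nonbonded={
            tuple(entry["types"]): (entry["eps"], entry["sigma"])
            for entry in payload["nonbonded"]
        },
        groups={k: np.array(v, dtype=np.intp) for k, v in payload["groups"].items()},
        restraints=[
            Restraint(np.array(r["indices"], dtype=np.intp),
                      np.array(r["anchors"]), r["k"])
            for r in payload["restraints"]
        ],
        frozen=np.array(payload["frozen"], dtype=np.intp),
        extra_exclusions={tuple(p) for p in payload.get("exclusions", [])},
        meta=payload.get("meta", {}),
    )


def system_to_pdb(system: ToySystem, path, coords: np.ndarray | None = None) -> None:
    """Export beads as pseudo-atoms; group membership encoded as residue names."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    x = system.coords if coords is None else np.asarray(coords)
    n = system.n_beads
    arr = struc.AtomArray(n)
    arr.coord = np.asarray(x, dtype=np.float32)
    lig = set(system.groups.get("ligand", np.empty(0, dtype=np.intp)).tolist())
    tail = set(system.groups.get("tail", np.empty(0, dtype=np.intp)).tolist())
    cleft = set(system.groups.get("cleft", np.empty(0, dtype=np.intp)).tolist())
    res_names = []
    for i in range(n):
        if i in lig:
            res_names.append("LIG")
        elif i in tail:
            res_names.append("TAI")
        elif i in cleft:
            res_names.append("CLF")
        else:
            res_names.append("REC")
    arr.res_name = np.array(res_names)
    arr.res_id = np.arange(1, n + 1)
    arr.atom_name = np.array([f"B{i%100:02d}" for i in range(n)])
    arr.chain_id = np.array(["L" if i in lig else "R" for i in range(n)])
    arr.element = np.array(["C"] * n)
    arr.hetero = np.full(n, True)
    f = pdb.PDBFile()
    f.set_structure(arr)
    f.write(str(path))
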