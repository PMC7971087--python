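import numpy as np
import pytest

from vczone.reweight import CanonicalEnsemble
from vczone.rc import Snapshot
from vczone.system import (Restraint, ToySpec, ToySystem, build_reduced_pair_system,
                           build_toy_complex)


@pytest.fixture
def toy_system():
    return build_toy_complex(ToySpec(), seed=7)


@pytest.fixture
def reduced_system():
    return build_reduced_pair_system(r0=6.0, k_tether=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_generic_system(rng, n=20):
    """A random bonded/nonbonded bead system for brute-force oracles."""
    coords = rng.uniform(0, 12, size=(n, 3))
    # spread beads so no pair starts deep inside the LJ core
    for _ in range(50):
        d = coords[:, None, :] - coords[None, :, :]
        r = np.linalg.norm(d, axis=-1) + np.eye(n) * 99
        i, j = np.unravel_index(np.argmin(r), r.shape)
        if r[i, j] > 1.8:
            break
        coords[i] += rng.normal(scale=1.0, size=3)
    bonds = np.array([[i, i + 1] for i in range(0, n - 1, 2)])
    angles = np.array([[i, i + 1, i + 2] for i in range(0, n - 2, 3)])
    return ToySystem(
        coords=coords,
        masses=np.full(n, 20.0),
        bead_types=["A"] * (n // 2) + ["B"] * (n - n // 2),
        bonds=bonds,
        bond_k=rng.uniform(5, 30, size=bonds.shape[0]),
        bond_r0=rng.uniform(1.5, 2.5, size=bonds.shape[0]),
        angles=angles,
        angle_k=rng.uniform(1, 10, size=angles.shape[0]),
        angle_theta0=rng.uniform(1.5, 2.8, size=angles.shape[0]),
        nonbonded={("A", "A"): (0.3, 2.0), ("A", "B"): (0.5, 2.2),
                   ("B", "B"): (0.2, 2.4)},
        groups={"receptor_core": np.arange(0, 3), "ligand": np.arange(3, 6)},
        restraints=[Restraint(np.arange(0, 3), coords[:3], 2.0)],
    )


def point_ensemble(points, weights, temperature=300.0):
    """Snapshots that are single beads at given points (for grid analyses)."""
    snaps = [Snapshot(np.asarray(p, dtype=float).reshape(1, 3),
                      np.zeros(1), (0,)) for p in points]
    return CanonicalEnsemble(snaps, np.asarray(weights, dtype=float), temperature)
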