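"""Toy-system generator and Hamiltonian."""

import json

import numpy as np
import pytest

from vczone.errors import InvalidSpecError, OverlapError, StoreVersionError
from vczone.system import (ToySpec, build_toy_complex, load_system,
                           potential_energy, save_system, system_to_pdb)

from conftest import random_generic_system


class TestBuilder:
    def test_counts_and_groups_follow_spec(self):
        spec = ToySpec(n_ligand_beads=5, head_size=2, tail_size=1)
        system = build_toy_complex(spec, seed=7)
        assert system.group("ligand").size == 5
        assert system.group("ligand_head").size == 2
        assert system.group("ligand_tail").size == 1
        lig = set(system.group("ligand").tolist())
        rec = set(system.group("receptor_core").tolist())
        assert not lig & rec
        assert set(system.group("ligand_head").tolist()) <= lig

    def test_same_seed_bitwise_identical(self):
        a = build_toy_complex(ToySpec(), seed=11)
        b = build_toy_complex(ToySpec(), seed=11)
        assert np.array_equal(a.coords, b.coords)
        c = build_toy_complex(ToySpec(), seed=12)
        assert not np.array_equal(a.coords, c.coords)

    def test_unit_multiplier_removes_pocket_preference(self):
        system = build_toy_complex(ToySpec(cleft_eps_multiplier=1.0), seed=7)
        eps_cleft = system.nonbonded[("C", "H")][0]
        eps_surface = system.nonbonded[("H", "R")][0]
        assert eps_cleft == pytest.approx(eps_surface)

    def test_pocket_preference_deepens_head_cleft_well(self, toy_system):
        assert (toy_system.nonbonded[("C", "H")][0]
                > toy_system.nonbonded[("H", "R")][0])

    def test_tiny_ligand_rejected(self):
        with pytest.raises(InvalidSpecError):
            build_toy_complex(ToySpec(n_ligand_beads=1), seed=7)


class TestPotential:
    def test_lj_minimum_is_minus_epsilon(self):
        import vczone.system as vs
        system = vs.ToySystem(
            coords=np.array([[0.0, 0, 0], [2 ** (1 / 6), 0, 0]]),
            masses=np.array([1.0, 1.0]),
            bead_types=["A", "B"],
            bonds=np.empty((0, 2)), bond_k=np.empty(0), bond_r0=np.empty(0),
            angles=np.empty((0, 3)), angle_k=np.empty(0), angle_theta0=np.empty(0),
            nonbonded={("A", "B"): (1.0, 1.0), ("A", "A"): (0, 1), ("B", "B"): (0, 1)},
            groups={},
        )
        energy, forces = potential_energy(system)
        assert energy == pytest.approx(-1.0, abs=1e-12)
        assert np.allclose(forces, 0.0, atol=1e-9)

    def test_bond_at_rest_length_zero_energy(self):
        import vczone.system as vs
        system = vs.ToySystem(
            coords=np.array([[0.0, 0, 0], [2.0, 0, 0]]),
            masses=np.array([1.0, 1.0]),
            bead_types=["A", "A"],
            bonds=np.array([[0, 1]]), bond_k=np.array([10.0]),
            bond_r0=np.array([2.0]),
            angles=np.empty((0, 3)), angle_k=np.empty(0), angle_theta0=np.empty(0),
            nonbonded={("A", "A"): (0.0, 1.0)},
            groups={},
        )
        energy, _ = potential_energy(system)
        assert energy == pytest.approx(0.0, abs=1e-14)

    def test_energy_matches_naive_double_loop(self, rng):
        system = random_generic_system(rng)
        energy, _ = potential_energy(system)

        ref = 0.0
        x = system.coords
        for (i, j), k, r0 in zip(system.bonds, system.bond_k, system.bond_r0):
            r = np.linalg.norm(x[i] - x[j])
            ref += k * (r - r0) ** 2
        for (i, j, k_), ka, t0 in zip(system.angles, system.angle_k,
                                      system.angle_theta0):
            u, v = x[i] - x[j], x[k_] - x[j]
            th = np.arccos(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
            ref += ka * (th - t0) ** 2
        ii, jj, eps, sig = system.nonbonded_pairs()
        for i, j, e, s in zip(ii, jj, eps, sig):
            r = np.linalg.norm(x[i] - x[j])
            ref += 4 * e * ((s / r) ** 12 - (s / r) ** 6)
        for rest in system.restraints:
            ref += rest.k * np.sum((x[rest.indices] - rest.anchors) ** 2)
        assert energy == pytest.approx(ref, rel=1e-10)

    def test_forces_match_central_differences(self, rng):
        system = random_generic_system(rng)
        x = system.coords + rng.normal(scale=0.02, size=system.coords.shape)
        _, forces = potential_energy(system, x)
        h = 1e-5
        num = np.zeros_like(forces)
        for i in range(x.shape[0]):
            for d in range(3):
                xp, xm = x.copy(), x.copy()
                xp[i, d] += h
                xm[i, d] -= h
                num[i, d] = -(potential_energy(system, xp)[0]
                              - potential_energy(system, xm)[0]) / (2 * h)
        scale = np.abs(forces).max()
        assert np.abs(num - forces).max() / scale < 1e-5

    def test_coincident_beads_raise_overlap(self, toy_system):
        x = toy_system.coords.copy()
        lig = toy_system.group("ligand")
        x[lig[0]] = x[0]  # ligand head onto a cleft bead
        with pytest.raises(OverlapError):
            potential_energy(toy_system, x)


class TestSerialization:
    def test_roundtrip_preserves_everything(self, toy_system, tmp_path):
        path = tmp_path / "system.json"
        save_system(toy_system, path)
        back = load_system(path)
        assert np.array_equal(back.coords, toy_system.coords)
        assert back.bead_types == toy_system.bead_types
        assert back.nonbonded == toy_system.nonbonded
        assert set(back.groups) == set(toy_system.groups)
        for name in toy_system.groups:
            assert np.array_equal(back.groups[name], toy_system.groups[name])
        e0, _ = potential_energy(toy_system)
        e1, _ = potential_energy(back)
        assert e0 == pytest.approx(e1, rel=1e-14)

    def test_wrong_schema_version_rejected(self, toy_system, tmp_path):
        path = tmp_path / "system.json"
        save_system(toy_system, path)
        payload = json.loads(path.read_text())
        payload["schema_version"] = 99
        path.write_text(json.dumps(payload))
        with pytest.raises(StoreVersionError):
            load_system(path)

    def test_pdb_export_readable(self, toy_system, tmp_path):
        import biotite.structure.io.pdb as pdb
        path = tmp_path / "system.pdb"
        system_to_pdb(toy_system, path)
        arr = pdb.PDBFile.read(str(path)).get_structure(model=1)
        assert arr.array_length() == toy_system.n_beads
        assert "LIG" in set(arr.res_name)
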