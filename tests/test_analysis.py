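"""Ensemble analyses: superposition, densities, distances, orientation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from vczone.analysis import (DistanceSpec, GridSpec, contact_fraction,
                             contact_indicator, density_clusters,
                             distance_distribution, flexibility_sd,
                             kabsch_superpose, min_group_distance,
                             orientation_field, spatial_density)
from vczone.errors import (DegenerateSuperpositionError, InvalidGroupError,
                           InvalidSpecError, ZeroLengthVectorError)
from vczone.reweight import CanonicalEnsemble
from vczone.rc import Snapshot

from conftest import point_ensemble


class TestKabsch:
    def test_self_superposition_is_identity(self, rng):
        x = rng.uniform(-5, 5, size=(10, 3))
        r, t, rmsd = kabsch_superpose(x, x, np.arange(10))
        assert np.allclose(r, np.eye(3), atol=1e-10)
        assert np.allclose(t, 0, atol=1e-10)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_known_rotation_recovered(self, rng):
        x = rng.uniform(-5, 5, size=(12, 3))
        rot = Rotation.random(random_state=5).as_matrix()
        shift = np.array([1.0, -2.0, 3.0])
        mobile = x @ rot.T + shift
        r, t, rmsd = kabsch_superpose(mobile, x, np.arange(12))
        assert rmsd < 1e-8
        assert np.allclose(mobile @ r.T + t, x, atol=1e-8)

    def test_optimal_among_random_rotations(self, rng):
        ref = rng.uniform(-5, 5, size=(8, 3))
        mobile = ref + rng.normal(scale=0.5, size=ref.shape)
        _, _, best = kabsch_superpose(mobile, ref, np.arange(8))
        cm, cr = mobile.mean(axis=0), ref.mean(axis=0)
        for k in range(1000):
            rot = Rotation.random(random_state=k).as_matrix()
            trial = (mobile - cm) @ rot.T + cr
            rmsd = np.sqrt(np.mean(np.sum((trial - ref) ** 2, axis=1)))
            assert best <= rmsd + 1e-12

    def test_collinear_selection_rejected(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(DegenerateSuperpositionError):
            kabsch_superpose(line, line + 0.1, np.arange(5))


class TestSpatialDensity:
    def test_point_mass_single_voxel(self):
        ens = point_ensemble([[1.2, 3.4, 5.6]] * 5, np.full(5, 0.2))
        grid = spatial_density(ens, [0], GridSpec(spacing=1.0))
        assert grid.values.max() == pytest.approx(1.0)
        assert grid.values.sum() == pytest.approx(1.0)

    def test_two_clusters_split_weight(self):
        pts = [[0.0, 0, 0]] * 3 + [[10.0, 0, 0]] * 3
        ens = point_ensemble(pts, np.full(6, 1 / 6))
        grid = spatial_density(ens, [0], GridSpec(spacing=1.0))
        flat = np.sort(grid.values.ravel())
        assert flat[-1] == pytest.approx(0.5)
        assert flat[-2] == pytest.approx(0.5)

    def test_normalized_for_random_ensembles(self, rng):
        pts = rng.uniform(0, 20, size=(100, 3))
        w = rng.uniform(size=100)
        ens = point_ensemble(pts, w / w.sum())
        grid = spatial_density(ens, [0], GridSpec(spacing=2.0))
        assert grid.values.sum() == pytest.approx(1.0, abs=1e-12)

    def test_region_mass_is_weighted_fraction(self, rng):
        """Exact bookkeeping: mass in a half-space equals the weight there."""
        pts = rng.uniform(0, 10, size=(60, 3))
        w = rng.uniform(size=60)
        w /= w.sum()
        ens = point_ensemble(pts, w)
        spec = GridSpec(spacing=1.0, origin=np.zeros(3), shape=(10, 10, 10))
        grid = spatial_density(ens, [0], spec)
        region = grid.values[:5].sum()     # voxels with x in [0, 5)
        assert region == pytest.approx(w[pts[:, 0] < 5.0].sum(), abs=1e-12)


class TestClusters:
    def test_single_blob(self):
        ens = point_ensemble([[5.0, 5, 5], [5.4, 5, 5]], [0.5, 0.5])
        grid = spatial_density(ens, [0], GridSpec(spacing=1.0))
        report = density_clusters(grid, level_multiplier=0.5)
        assert len(report) == 1

    def test_two_separated_blobs_masses(self):
        pts = [[0.0, 0, 0]] * 2 + [[12.0, 0, 0]] * 3
        ens = point_ensemble(pts, np.full(5, 0.2))
        grid = spatial_density(ens, [0], GridSpec(spacing=1.0))
        report = density_clusters(grid, level_multiplier=0.5)
        assert len(report) == 2
        assert report.clusters[0].mass == pytest.approx(0.6)
        assert report.clusters[1].mass == pytest.approx(0.4)

    def test_threshold_above_peak_empty(self):
        ens = point_ensemble([[0.0, 0, 0]], [1.0])
        grid = spatial_density(ens, [0], GridSpec(spacing=1.0))
        report = density_clusters(grid, level_multiplier=2000.0)
        assert len(report) == 0


class TestDistances:
    def test_known_pair_distance(self):
        x = np.array([[0.0, 0, 0], [4.2, 0, 0]])
        assert min_group_distance(x, [0], [1]) == pytest.approx(4.2)

    def test_shared_bead_zero(self):
        x = np.random.default_rng(0).uniform(size=(5, 3))
        assert min_group_distance(x, [0, 1], [1, 2]) == 0.0

    def test_matches_exhaustive_double_loop(self, rng):
        x = rng.uniform(0, 10, size=(20, 3))
        g1, g2 = np.arange(10), np.arange(10, 20)
        expected = min(np.linalg.norm(x[i] - x[j]) for i in g1 for j in g2)
        assert min_group_distance(x, g1, g2) == pytest.approx(expected)

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidGroupError):
            min_group_distance(np.zeros((3, 3)), [], [0])


class TestContacts:
    @pytest.mark.parametrize("r, expected",
                             [(3.9, True), (4.1, False), (4.0, False)])
    def test_strict_cutoff(self, r, expected):
        assert contact_indicator(r) is expected

    def test_all_contact_fraction_one(self):
        snaps = [Snapshot(np.array([[0.0, 0, 0], [3.0, 0, 0]]), [0.0], (0,))
                 for _ in range(4)]
        ens = CanonicalEnsemble(snaps, np.full(4, 0.25), 300.0)
        assert contact_fraction(ens, [0], [1]) == pytest.approx(1.0)


class TestDistanceDistribution:
    def _pair_ensemble(self, distances, weights):
        snaps = [Snapshot(np.array([[0.0, 0, 0], [d, 0, 0]]), [0.0], (0,))
                 for d in distances]
        return CanonicalEnsemble(snaps, np.asarray(weights, dtype=float), 300.0)

    def test_degenerate_all_equal(self):
        ens = self._pair_ensemble([5.0] * 6, np.full(6, 1 / 6))
        dist = distance_distribution(ens, DistanceSpec("atom_pair", atom_i=0,
                                                       atom_j=1), 0.2)
        assert dist.sd_abs == 0.0 and dist.sd == 0.0
        assert np.count_nonzero(dist.density) == 1

    def test_hand_weighted_moments(self):
        r = np.array([2.0, 3.0, 4.0, 5.0, 6.0])
        w = np.array([0.1, 0.2, 0.4, 0.2, 0.1])
        ens = self._pair_ensemble(r, w)
        dist = distance_distribution(ens, DistanceSpec("atom_pair", atom_i=0,
                                                       atom_j=1), 0.5)
        mean = np.sum(w * r)
        sd = np.sqrt(np.sum(w * (r - mean) ** 2))
        assert dist.mean == pytest.approx(mean, rel=1e-12)
        assert dist.sd_abs == pytest.approx(sd, rel=1e-12)
        assert dist.sd == pytest.approx(sd / mean, rel=1e-12)

    def test_moments_invariant_under_binning(self, rng):
        r = rng.uniform(2, 8, size=50)
        w = rng.uniform(size=50)
        ens = self._pair_ensemble(r, w / w.sum())
        spec = DistanceSpec("atom_pair", atom_i=0, atom_j=1)
        a = distance_distribution(ens, spec, 0.1)
        b = distance_distribution(ens, spec, 0.7)
        assert a.mean == b.mean and a.sd_abs == b.sd_abs

    def test_density_integrates_to_one(self, rng):
        r = rng.uniform(2, 8, size=30)
        ens = self._pair_ensemble(r, np.full(30, 1 / 30))
        dist = distance_distribution(ens, DistanceSpec("atom_pair", atom_i=0,
                                                       atom_j=1), 0.3)
        assert np.sum(dist.density * np.diff(dist.edges)) == pytest.approx(1.0)


class TestFlexibility:
    @pytest.mark.parametrize("mean, sd_abs, expected", [
        (7.12, 0.37, 5.20e-2),     # flexible chloro-ring compound
        (6.01, 0.14, 2.33e-2),     # stiffest rod
        (13.15, 0.47, 3.57e-2),    # long stiff rod
    ])
    def test_published_flexibility_values(self, mean, sd_abs, expected):
        assert flexibility_sd(mean, sd_abs) == pytest.approx(expected, rel=1e-9)

    @given(st.floats(0.01, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, c):
        assert flexibility_sd(7.12 * c, 0.37 * c) == flexibility_sd(7.12, 0.37)

    def test_invalid_mean_rejected(self):
        with pytest.raises(InvalidSpecError):
            flexibility_sd(0.0, 0.1)


def _oriented_snaps(directions, anchor=(5.0, 5.0, 5.0)):
    """Two-bead snapshots: bead 0 = tail, bead 1 = head = tail + direction."""
    anchor = np.asarray(anchor)
    snaps = []
    for d in directions:
        tail = anchor - 0.5 * np.asarray(d)
        head = anchor + 0.5 * np.asarray(d)
        snaps.append(Snapshot(np.array([tail, head]), [0.0], (0,)))
    return snaps


class TestOrientation:
    def test_identical_orientations_unit_magnitude(self):
        snaps = _oriented_snaps([[0, 0, 2.0]] * 8)
        ens = CanonicalEnsemble(snaps, np.full(8, 1 / 8), 300.0)
        fld = orientation_field(ens, head_group=[1], tail_group=[0],
                                grid_spec=GridSpec(spacing=2.0))
        mags = fld.magnitude()[fld.occupied_mask()]
        assert np.allclose(mags, 1.0, atol=1e-12)

    def test_antiparallel_cancellation(self):
        snaps = _oriented_snaps([[0, 0, 2.0], [0, 0, -2.0]] * 4)
        ens = CanonicalEnsemble(snaps, np.full(8, 1 / 8), 300.0)
        fld = orientation_field(ens, [1], [0], GridSpec(spacing=4.0))
        mags = fld.magnitude()[fld.occupied_mask()]
        assert np.allclose(mags, 0.0, atol=1e-12)

    def test_isotropic_orientations_below_null_quantile(self, rng):
        n = 200
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        snaps = _oriented_snaps(2.0 * dirs)
        ens = CanonicalEnsemble(snaps, np.full(n, 1 / n), 300.0)
        fld = orientation_field(ens, [1], [0], GridSpec(spacing=50.0))
        mag = fld.magnitude()[fld.occupied_mask()][0]
        # Monte-Carlo null for the resultant length of n isotropic unit vectors
        null = []
        for _ in range(400):
            v = rng.normal(size=(n, 3))
            v /= np.linalg.norm(v, axis=1)[:, None]
            null.append(np.linalg.norm(v.mean(axis=0)))
        assert mag < np.quantile(null, 0.99)

    def test_magnitude_never_exceeds_one(self, rng):
        n = 100
        dirs = rng.normal(size=(n, 3))
        dirs /= np.linalg.norm(dirs, axis=1)[:, None]
        snaps = _oriented_snaps(2.0 * dirs,)
        w = rng.uniform(size=n)
        ens = CanonicalEnsemble(snaps, w / w.sum(), 300.0)
        fld = orientation_field(ens, [1], [0], GridSpec(spacing=1.0))
        assert fld.magnitude().max() <= 1.0 + 1e-12

    def test_zero_length_vector_rejected(self):
        snaps = [Snapshot(np.zeros((2, 3)), [0.0], (0,))]
        ens = CanonicalEnsemble(snaps, np.array([1.0]), 300.0)
        with pytest.raises(ZeroLengthVectorError):
            orientation_field(ens, [1], [0], GridSpec(spacing=1.0))

    def test_overlapping_head_tail_rejected(self):
        snaps = _oriented_snaps([[0, 0, 2.0]])
        ens = CanonicalEnsemble(snaps, np.array([1.0]), 300.0)
        with pytest.raises(InvalidGroupError):
            orientation_field(ens, [0, 1], [0], GridSpec(spacing=1.0))
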