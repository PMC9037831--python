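"""Bead-envelope reconstruction, NSD metrics, clustering, voxelization."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from flexsaxs.core import AtomicModel
from flexsaxs.envelope_modeling import (
    BeadModel,
    DensityGrid,
    align_models,
    anneal_envelope,
    average_envelopes,
    cluster_envelopes,
    hcp_lattice,
    nsd,
    read_mrc,
    voxelize,
    write_mrc,
)

from conftest import make_profile, sphere_intensity


def _sphere_target(R=30.0, i0=1e5, rel=0.01, qmax=0.30, n=120):
    q = np.linspace(0.01, qmax, n)
    return make_profile(q, sphere_intensity(q, R, i0), rel_sigma=rel)


@pytest.fixture(scope="module")
def sphere_envelope():
    return anneal_envelope(_sphere_target(), dmax=60.0, bead_radius=60.0 / 16, seed=1)


class TestNSD:
    def test_identity_and_symmetry(self, rng):
        A = rng.normal(0, 10, (100, 3))
        B = rng.normal(0, 10, (100, 3))
        assert nsd(A, A) == pytest.approx(0.0, abs=1e-12)
        assert nsd(A, B) == pytest.approx(nsd(B, A), rel=1e-12)
        assert nsd(A, B) > 0

    def test_offset_lattice_brute_force_oracle(self):
        # two unit cubic lattices offset by half a lattice vector
        g = np.arange(4, dtype=float)
        X, Y, Z = np.meshgrid(g, g, g, indexing="ij")
        A = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
        B = A + np.array([0.5, 0.0, 0.0])
        # direct enumeration of the defining formula
        dA = np.mean([np.sort(np.linalg.norm(A - a, axis=1))[1] for a in A])
        dB = np.mean([np.sort(np.linalg.norm(B - b, axis=1))[1] for b in B])
        a2b = np.mean([np.min(np.sum((B - a) ** 2, axis=1)) for a in A])
        b2a = np.mean([np.min(np.sum((A - b) ** 2, axis=1)) for b in B])
        expected = np.sqrt(0.5 * (a2b / dB**2 + b2a / dA**2))
        assert nsd(A, B) == pytest.approx(expected, rel=1e-12)

    def test_single_point_fails(self):
        with pytest.raises(ValueError):
            nsd(np.zeros((1, 3)), np.ones((5, 3)))

    def test_metric_properties_random_sets(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @given(st.integers(0, 2**31 - 1))
        @settings(deadline=None, derandomize=True, max_examples=25)
        def check(seed):
            g = np.random.default_rng(seed)
            A = g.normal(0, 5, (20, 3))
            B = g.normal(0, 5, (25, 3))
            ab = nsd(A, B)
            assert ab >= 0
            assert ab == pytest.approx(nsd(B, A), rel=1e-9)
            assert nsd(A, A) == pytest.approx(0.0, abs=1e-12)

        check()


class TestAlign:
    def test_rotated_copy_recovered(self, rng):
        ref = rng.normal(0, 12, (150, 3)) * np.array([2.0, 1.0, 0.6])
        R = Rotation.random(random_state=3).as_matrix()
        mobile = ref @ R.T + np.array([20.0, -5.0, 3.0])
        assert nsd(align_models(mobile, ref), ref) < 0.05

    def test_mirrored_copy_recovered_via_enantiomer_branch(self, rng):
        ref = rng.normal(0, 12, (150, 3)) * np.array([2.0, 1.0, 0.6])
        mirrored = ref * np.array([1.0, 1.0, -1.0])
        assert nsd(align_models(mirrored, ref), ref) < 0.05

    def test_alignment_never_worse_than_com_superposition(self, rng):
        A = rng.normal(0, 10, (80, 3))
        B = rng.normal(0, 10, (80, 3)) * np.array([1.5, 1.0, 0.7])
        com_only = A - A.mean(axis=0) + B.mean(axis=0)
        assert nsd(align_models(A, B), B) <= nsd(com_only, B) + 1e-12


class TestAnneal:
    def test_sphere_envelope_quality(self, sphere_envelope):
        env = sphere_envelope
        assert env.rg() == pytest.approx(np.sqrt(3.0 / 5.0) * 30.0, rel=0.05)
        ref = BeadModel(hcp_lattice(30.0, 60.0 / 16), 60.0 / 16)
        assert nsd(align_models(env, ref), ref) < 0.7

    def test_seed_determinism(self):
        t = _sphere_target(n=60)
        kw = dict(dmax=60.0, bead_radius=5.0)
        a = anneal_envelope(t, seed=3, **kw)
        b = anneal_envelope(t, seed=3, **kw)
        assert np.array_equal(a.occupancy, b.occupancy)

    def test_objective_trace_non_increasing(self, sphere_envelope):
        assert np.all(np.diff(sphere_envelope.objective_trace) <= 1e-9)

    def test_dumbbell_two_lobes(self, rng):
        # target: two spheres of radius 15 with centres 60 apart
        a = rng.normal(0, 1, (200, 3))
        a = 15 * a / np.linalg.norm(a, axis=1)[:, None] * rng.random((200, 1)) ** (1 / 3)
        cloud = np.concatenate([a, a + [60.0, 0, 0]])
        from flexsaxs.forward_scattering import debye_profile

        q = np.linspace(0.01, 0.3, 100)
        prof = debye_profile(AtomicModel(cloud), q, form_factor_mode="uniform")
        target = make_profile(q, prof.I, rel_sigma=0.01)
        env = anneal_envelope(target, dmax=95.0, bead_radius=95.0 / 20, seed=2)
        from sklearn.cluster import KMeans

        km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(env.centers)
        sep = np.linalg.norm(km.cluster_centers_[0] - km.cluster_centers_[1])
        assert sep > 15.0  # the lobe radius


class TestClusterAverage:
    def _blob(self, rng, shift=0.0):
        return BeadModel(rng.normal(0, 8, (60, 3)) + [shift, 0, 0], 2.0)

    def test_two_well_separated_groups(self, rng):
        x = self._blob(rng)
        y = self._blob(rng, shift=200.0)
        # copies with tiny jitter so NSD within groups is near zero
        models = [BeadModel(x.centers + rng.normal(0, 0.01, x.centers.shape), 2.0)
                  for _ in range(3)]
        models += [BeadModel(y.centers + rng.normal(0, 0.01, y.centers.shape), 2.0)
                   for _ in range(3)]
        res = cluster_envelopes(models, linkage_threshold=0.5)
        assert len(res.cluster_members) == 2
        assert sorted(len(v) for v in res.cluster_members.values()) == [3, 3]
        assert res.isolated == []

    def test_threshold_below_everything_isolates_all(self, rng):
        models = [self._blob(rng, shift=50.0 * i) for i in range(4)]
        res = cluster_envelopes(models, linkage_threshold=1e-9)
        assert len(res.isolated) == 4
        assert res.cluster_members == {}

    def test_average_of_identical_members_is_member(self):
        lat = hcp_lattice(20.0, 3.0)
        occ = np.linalg.norm(lat, axis=1) < 15.0
        member = BeadModel(lat[occ], 3.0, lattice=lat, occupancy=occ)
        avg, grid = average_envelopes([member, member, member])
        assert np.allclose(np.sort(avg.centers, axis=0), np.sort(member.centers, axis=0))
        assert grid.rho_max > 0

    def test_minority_noise_bead_excluded(self):
        lat = hcp_lattice(20.0, 3.0)
        occ = np.linalg.norm(lat, axis=1) < 12.0
        noise_site = int(np.argmax(np.linalg.norm(lat, axis=1)))
        occ_noise = occ.copy()
        occ_noise[noise_site] = True
        members = [BeadModel(lat[occ], 3.0, lattice=lat, occupancy=occ)] * 2
        members += [BeadModel(lat[occ_noise], 3.0, lattice=lat, occupancy=occ_noise)]
        avg, _ = average_envelopes(members)  # 1/3 < 0.5 cut
        assert not np.any(np.all(np.isclose(avg.centers, lat[noise_site]), axis=1))


class TestVoxelize:
    def test_single_bead_peak_at_its_voxel(self):
        m = BeadModel(np.array([[5.2, 4.9, 5.1]]), 2.0)
        g = voxelize(m, spacing=1.0, blur_sigma=1.5)
        peak = np.unravel_index(np.argmax(g.values), g.values.shape)
        centre = g.origin + g.spacing * np.array(peak)
        assert np.linalg.norm(centre - [5.2, 4.9, 5.1]) < 1.0

    def test_mass_conservation(self, rng):
        pts = rng.uniform(-10, 10, (40, 3))
        g = voxelize(BeadModel(pts, 2.0), spacing=1.0, blur_sigma=2.0)
        assert g.values.sum() == pytest.approx(40.0, rel=0.01)

    def test_blur_lowers_peak_conserves_mass(self):
        m = BeadModel(np.zeros((1, 3)), 2.0)
        g1 = voxelize(m, spacing=1.0, blur_sigma=2.0)
        g2 = voxelize(m, spacing=1.0, blur_sigma=4.0)
        assert g2.rho_max < g1.rho_max
        assert g1.values.sum() == pytest.approx(g2.values.sum(), rel=0.01)

    def test_density_grid_invariants(self):
        with pytest.raises(ValueError):
            DensityGrid(np.zeros(3), -1.0, np.zeros((2, 2, 2)))
        with pytest.raises(ValueError):
            DensityGrid(np.zeros(3), 1.0, -np.ones((2, 2, 2)))


class TestMrcIO:
    def test_roundtrip(self, tmp_path, rng):
        from scipy.ndimage import gaussian_filter

        vals = gaussian_filter(rng.random((12, 14, 10)), 1.5)
        vals -= vals.min()
        g = DensityGrid(np.array([-5.0, 2.0, 1.0]), 2.5, vals)
        path = tmp_path / "m.mrc"
        write_mrc(path, g)
        back = read_mrc(path)
        assert back.spacing == pytest.approx(2.5, rel=1e-6)
        assert np.allclose(back.origin, g.origin, atol=1e-5)
        assert np.allclose(back.values, g.values, atol=1e-6 * g.rho_max)
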