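"""Envelope potential, restraint networks, and restrained refinement."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter
from scipy.spatial.distance import pdist
from scipy.spatial.transform import Rotation

from flexsaxs.core import AtomicModel, DomainPartition
from flexsaxs.envelope_modeling import DensityGrid, voxelize
from flexsaxs.flexible_fitting import (
    EnvelopePotentialParams,
    Trajectory,
    build_restraint_network,
    envelope_correlation,
    envelope_energy_force,
    restrained_refine,
    select_best_model,
)
from flexsaxs.synthetic_data import NoiseSpec, build_antibody_surrogate, simulate_profile


def _ramp_grid(L=20.0, n=21):
    vals = np.zeros((n, n, n))
    vals[:] = (np.arange(n) / L)[:, None, None]
    return DensityGrid(np.zeros(3), 1.0, vals)


class TestEnvelopePotential:
    def test_limits_of_the_potential(self):
        vals = np.zeros((5, 5, 5))
        vals[2, 2, 2] = 3.0
        g = DensityGrid(np.zeros(3), 1.0, vals)
        p = EnvelopePotentialParams(k=0.1)
        e_max, _ = envelope_energy_force(g, p, np.array([[2.0, 2.0, 2.0]]))
        assert e_max == pytest.approx(0.0, abs=1e-12)  # V = 0 at rho_max
        e_out, f_out = envelope_energy_force(g, p, np.array([[50.0, 50.0, 50.0]]))
        assert e_out == pytest.approx(0.1)  # V = k at rho = 0
        assert np.all(f_out == 0.0)

    def test_linear_ramp_force_is_k_over_L(self, rng):
        g = _ramp_grid(L=20.0)
        p = EnvelopePotentialParams(k=0.1)
        pts = rng.uniform(2, 18, (50, 3))
        _, f = envelope_energy_force(g, p, pts)
        assert np.allclose(f[:, 0], 0.1 / 20.0, rtol=1e-9)
        assert np.max(np.abs(f[:, 1:])) < 1e-14

    def test_force_matches_finite_differences(self, rng):
        vals = gaussian_filter(rng.random((20, 20, 20)), 2.0)
        vals -= vals.min()
        g = DensityGrid(np.zeros(3), 1.5, vals)
        p = EnvelopePotentialParams(k=0.7)
        pts = rng.uniform(4, 24, (120, 3))
        u = (pts - g.origin) / g.spacing
        frac = u - np.floor(u)
        pts = pts[np.all((frac > 0.05) & (frac < 0.95), axis=1)][:100]
        _, f = envelope_energy_force(g, p, pts)
        eps = 1e-6
        for i in range(len(pts)):
            for d in range(3):
                dp = np.zeros(3)
                dp[d] = eps
                ep, _ = envelope_energy_force(g, p, pts[i : i + 1] + dp)
                em, _ = envelope_energy_force(g, p, pts[i : i + 1] - dp)
                num = -(ep - em) / (2 * eps)
                assert abs(num - f[i, d]) <= 1e-5 * max(np.abs(f[i]).max(), 1e-9)

    def test_empty_grid_rejected(self):
        g = DensityGrid(np.zeros(3), 1.0, np.zeros((4, 4, 4)))
        with pytest.raises(ValueError, match="rho_max"):
            envelope_energy_force(g, EnvelopePotentialParams(), np.zeros((1, 3)))


class TestRestraintNetwork:
    def test_hand_counts(self):
        m = AtomicModel([[0, 0, 0], [0, 0, 5], [0, 0, 100]])
        same = DomainPartition({"A": [0, 1], "B": [2]})
        net = build_restraint_network(m, same, cutoff=12.0)
        assert len(net) == 1
        split = DomainPartition({"A": [0], "B": [1, 2]})
        net2 = build_restraint_network(m, split, cutoff=12.0)
        assert len(net2) == 0  # pair 0-1 crosses domains; 1-2 beyond cutoff

    def test_matches_brute_force_enumeration(self, rng):
        coords = rng.uniform(0, 30, (100, 3))
        part = DomainPartition({"A": np.arange(50), "B": np.arange(50, 100)})
        m = AtomicModel(coords)
        net = build_restraint_network(m, part, cutoff=10.0)
        expected = 0
        for idx in (part["A"], part["B"]):
            d = pdist(coords[idx])
            expected += int(np.sum(d <= 10.0))
        assert len(net) == expected
        assert np.allclose(
            net.rest, np.linalg.norm(coords[net.j] - coords[net.i], axis=1)
        )


@pytest.fixture(scope="module")
def recovery():
    """30-degree hinge-perturbed surrogate refined into the truth envelope."""
    model, part = build_antibody_surrogate()
    pert = model.coords.copy()
    idx = part["Fa"]
    piv = model.hinge_pivots["Fa"]
    u = pert[idx].mean(axis=0) - piv
    u /= np.linalg.norm(u)
    axis = np.cross(u, [0.0, 1.0, 0.0])
    axis /= np.linalg.norm(axis)
    R = Rotation.from_rotvec(np.radians(30.0) * axis).as_matrix()
    pert[idx] = (pert[idx] - piv) @ R.T + piv
    perturbed = model.with_coords(pert)
    q = np.linspace(0.01, 0.25, 60)
    profile = simulate_profile(model, q, NoiseSpec(seed=5))
    net = build_restraint_network(perturbed, part, cutoff=12.0, spring_k=1.0)
    trajs = []
    cur = perturbed
    for blur, k, steps in ((12.0, 5.0, 1500), (6.0, 3.0, 1500)):
        grid = voxelize(model, spacing=3.0, blur_sigma=blur)
        traj = restrained_refine(
            cur, grid, net, EnvelopePotentialParams(k=k), steps=steps,
            step_size=0.3, seed=0, profile=profile, stride=100,
            rigid_domains=part,
        )
        trajs.append(traj)
        cur = model.with_coords(traj.snapshots[-1])
    return model, part, perturbed, trajs, profile


class TestRecovery:
    def test_stationarity_in_own_grid(self, surrogate):
        model, part = surrogate
        grid = voxelize(model, spacing=3.0, blur_sigma=6.0)
        net = build_restraint_network(model, part)
        traj = restrained_refine(
            model, grid, net, EnvelopePotentialParams(k=0.1),
            steps=300, step_size=0.3, stride=300, rigid_domains=part,
        )
        drift = np.sqrt(np.mean(np.sum((traj.snapshots[-1] - model.coords) ** 2, axis=1)))
        assert drift < 0.1

    def test_hinge_perturbation_recovered(self, recovery):
        model, part, perturbed, trajs, _ = recovery
        rmsd0 = np.sqrt(np.mean(np.sum((perturbed.coords - model.coords) ** 2, axis=1)))
        final = trajs[-1].snapshots[-1]
        rmsd1 = np.sqrt(np.mean(np.sum((final - model.coords) ** 2, axis=1)))
        assert rmsd1 <= 0.5 * rmsd0
        score_grid = voxelize(model, spacing=3.0, blur_sigma=6.0)
        corr = envelope_correlation(model.with_coords(final), score_grid, 6.0)
        assert corr >= 0.9

    def test_domains_stay_rigid_throughout(self, recovery):
        model, part, perturbed, trajs, _ = recovery
        for lab in ("Fa", "Fb", "Fc"):
            ref = pdist(perturbed.coords[part[lab]])
            for traj in trajs:
                for snap in traj.snapshots[:: max(1, len(traj) // 4)]:
                    assert np.max(np.abs(pdist(snap[part[lab]]) - ref)) < 0.5

    def test_selection_improves_chi2(self, recovery):
        _, _, _, trajs, profile = recovery
        merged = Trajectory(
            snapshots=trajs[0].snapshots + trajs[1].snapshots,
            step_index=np.arange(len(trajs[0]) + len(trajs[1])),
            rg=np.concatenate([t.rg for t in trajs]),
            envelope_corr=np.concatenate([t.envelope_corr for t in trajs]),
            chi2=np.concatenate([t.chi2 for t in trajs]),
            energy=np.concatenate([t.energy for t in trajs]),
        )
        _, frame, best_chi2 = select_best_model(merged, profile)
        assert best_chi2 <= merged.chi2[0]

    def test_correlation_best_so_far_increases(self, recovery):
        _, _, _, trajs, _ = recovery
        corr = np.concatenate([t.envelope_corr for t in trajs])
        running_best = np.maximum.accumulate(corr)
        assert np.all(np.diff(running_best) >= -1e-12)
        assert running_best[-1] > running_best[0]


class TestSelection:
    def _traj(self, chis):
        n = len(chis)
        return Trajectory(
            snapshots=[np.full((2, 3), i, float) for i in range(n)],
            step_index=np.arange(n),
            rg=np.zeros(n),
            envelope_corr=np.zeros(n),
            chi2=np.asarray(chis, float),
            energy=np.zeros(n),
        )

    def test_monotone_series_selects_last(self):
        _, frame, _ = select_best_model(self._traj([5.0, 4.0, 3.0, 2.0]))
        assert frame == 3

    def test_tie_broken_by_earliest(self):
        _, frame, chi2 = select_best_model(self._traj([3.0, 1.0, 2.0, 1.0]))
        assert frame == 1 and chi2 == 1.0

    def test_empty_trajectory_fails(self):
        t = self._traj([1.0])
        t.snapshots = []
        with pytest.raises(ValueError):
            select_best_model(t)


class TestEnvelopeCorrelation:
    def test_self_correlation_is_one(self, surrogate):
        model, _ = surrogate
        grid = voxelize(model, spacing=3.0, blur_sigma=5.0)
        assert envelope_correlation(model, grid, blur_sigma=5.0) > 0.99

    def test_displaced_model_uncorrelated(self, surrogate):
        model, _ = surrogate
        grid = voxelize(model, spacing=3.0, blur_sigma=5.0)
        far = model.with_coords(model.coords + 1e4)
        assert abs(envelope_correlation(far, grid, blur_sigma=5.0)) < 0.05
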