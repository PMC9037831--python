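"""Envelope-restrained flexible fitting (MDFF-style).

Atoms are driven into an experimental density envelope by the potential

    V(r) = k [1 - rho(r) / rho_max]

summed over the selected atoms (C-alpha / bead level throughout), with
rho(r) obtained by trilinear interpolation on the density grid and the
force (k / rho_max) grad rho from the analytic gradient of the trilinear
form.  Internal structure is preserved by a harmonic elastic network built
within rigid domains only; the dynamics is overdamped Langevin (pure
gradient descent at temperature zero).  The best model along a trajectory
is the frame with the lowest reciprocal-space chi^2 against the measured
profile — the same direct-space/reciprocal-space trade-off rule the full
workflow uses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import AtomicModel, DomainPartition, ScatteringProfile
from .envelope_modeling import DensityGrid, voxelize
from .forward_scattering import debye_profile, fit_chi2

__all__ = [
    "EnvelopePotentialParams",
    "RestraintNetwork",
    "Trajectory",
    "envelope_energy_force",
    "build_restraint_network",
    "restrained_refine",
    "select_best_model",
    "envelope_correlation",
]

log = logging.getLogger(__name__)


@dataclass
class EnvelopePotentialParams:
    """Strength and atom selection of the envelope restraint.

    ``k`` is the energy scale of the restraint per atom (arbitrary units;
    0.1 by default).  ``selection`` restricts the restraint to a subset of
    atoms (indices); None means all points, which at the C-alpha/bead
    resolution used here is the C-alpha-only convention.
    """

    k: float = 0.1
    selection: np.ndarray | None = None

    def validate(self) -> None:
        if self.k < 0:
            raise ValueError("k must be >= 0")


@dataclass
class RestraintNetwork:
    """Harmonic pairs (i, j, rest length, spring constant), intra-domain only."""

    i: np.ndarray
    j: np.ndarray
    rest: np.ndarray
    spring_k: np.ndarray

    def __len__(self) -> int:
        return len(self.i)


@dataclass
class Trajectory:
    """Snapshots plus per-frame metrics of a restrained refinement run."""

    snapshots: list[np.ndarray]
    step_index: np.ndarray
    rg: np.ndarray
    envelope_corr: np.ndarray
    chi2: np.ndarray  # NaN when no profile was supplied
    energy: np.ndarray

    def __len__(self) -> int:
        return len(self.snapshots)


def _trilinear(grid: DensityGrid, pos: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Density and analytic gradient at arbitrary points.

    Points outside the grid clamp to rho = 0 with zero gradient.
    """
    vals = grid.values
    nx, ny, nz = vals.shape
    u = (pos - grid.origin) / grid.spacing
    inside = np.all((u >= 0) & (u <= np.array([nx, ny, nz]) - 1.000001), axis=1)
    rho = np.zeros(len(pos))
    grad = np.zeros((len(pos), 3))
    if not np.any(inside):
        return rho, grad
    ui = u[inside]
    i0 = np.floor(ui).astype(int)
    i0 = np.minimum(i0, np.array([nx, ny, nz]) - 2)
    t = ui - i0
    x0, y0, z0 = i0[:, 0], i0[:, 1], i0[:, 2]
    tx, ty, tz = t[:, 0], t[:, 1], t[:, 2]
    c = np.empty((len(ui), 2, 2, 2))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                c[:, dx, dy, dz] = vals[x0 + dx, y0 + dy, z0 + dz]
    wx = np.stack([1 - tx, tx], axis=1)
    wy = np.stack([1 - ty, ty], axis=1)
    wz = np.stack([1 - tz, tz], axis=1)
    dwx = np.stack([-np.ones_like(tx), np.ones_like(tx)], axis=1)
    dwy = np.stack([-np.ones_like(ty), np.ones_like(ty)], axis=1)
    dwz = np.stack([-np.ones_like(tz), np.ones_like(tz)], axis=1)
    rho[inside] = np.einsum("nxyz,nx,ny,nz->n", c, wx, wy, wz)
    s = grid.spacing
    grad_in = np.stack(
        [
            np.einsum("nxyz,nx,ny,nz->n", c, dwx, wy, wz) / s,
            np.einsum("nxyz,nx,ny,nz->n", c, wx, dwy, wz) / s,
            np.einsum("nxyz,nx,ny,nz->n", c, wx, wy, dwz) / s,
        ],
        axis=1,
    )
    grad[inside] = grad_in
    return rho, grad


def envelope_energy_force(
    grid: DensityGrid,
    params: EnvelopePotentialParams,
    positions: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Energy and per-atom forces of V = k [1 - rho/rho_max].

    The force is +(k/rho_max) grad rho (downhill in V), analytic from the
    trilinear interpolant and consistent with finite differences.
    """
    params.validate()
    rho_max = grid.rho_max
    if rho_max <= 0:
        raise ValueError("empty density grid (rho_max = 0)")
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    sel = params.selection
    pts = positions if sel is None else positions[sel]
    rho, grad = _trilinear(grid, pts)
    energy = float(params.k * np.sum(1.0 - rho / rho_max))
    forces = np.zeros_like(positions)
    f_sel = (params.k / rho_max) * grad
    if sel is None:
        forces[:] = f_sel
    else:
        forces[sel] = f_sel
    return energy, forces


def build_restraint_network(
    model: AtomicModel,
    partition: DomainPartition,
    cutoff: float = 12.0,
    spring_k: float = 1.0,
) -> RestraintNetwork:
    """All intra-domain atom pairs within ``cutoff`` restrained at their
    current separation; no inter-domain pairs, so hinge motion stays free."""
    if partition.n_atoms() != len(model):
        raise ValueError("partition must cover every atom exactly once")
    ii, jj, rr = [], [], []
    for lab in partition.labels:
        idx = partition[lab]
        if len(idx) < 2:
            continue
        d = squareform(pdist(model.coords[idx]))
        a, b = np.where(np.triu(d <= cutoff, k=1))
        ii.append(idx[a])
        jj.append(idx[b])
        rr.append(d[a, b])
    i = np.concatenate(ii) if ii else np.array([], int)
    j = np.concatenate(jj) if jj else np.array([], int)
    rest = np.concatenate(rr) if rr else np.array([])
    return RestraintNetwork(i, j, rest, np.full(len(i), float(spring_k)))


def _network_energy_force(
    net: RestraintNetwork, pos: np.ndarray
) -> tuple[float, np.ndarray]:
    if len(net) == 0:
        return 0.0, np.zeros_like(pos)
    dvec = pos[net.j] - pos[net.i]
    d = np.linalg.norm(dvec, axis=1)
    d = np.maximum(d, 1e-12)
    stretch = d - net.rest
    energy = float(0.5 * np.sum(net.spring_k * stretch**2))
    fpair = (net.spring_k * stretch / d)[:, None] * dvec  # force on i toward j
    forces = np.zeros_like(pos)
    np.add.at(forces, net.i, fpair)
    np.add.at(forces, net.j, -fpair)
    return energy, forces


def restrained_refine(
    model: AtomicModel,
    grid: DensityGrid,
    network: RestraintNetwork,
    params: EnvelopePotentialParams | None = None,
    steps: int = 2000,
    step_size: float = 0.5,
    temperature: float = 0.0,
    seed: int = 0,
    profile: ScatteringProfile | None = None,
    stride: int = 25,
    corr_blur: float | None = None,
    divergence_patience: int = 50,
    rigid_domains: DomainPartition | None = None,
) -> Trajectory:
    """Overdamped Langevin refinement under envelope + network potentials.

    Coordinates advance by Euler-Maruyama,
    x += step_size * F + sqrt(2 T step_size) * N(0, 1); at temperature 0
    this is pure gradient descent.  Snapshots and per-frame metrics
    (envelope Pearson correlation, Rg, optional chi^2 vs ``profile``) are
    recorded every ``stride`` steps.  Sustained energy increase aborts with
    diagnostics (step size too large).

    When ``rigid_domains`` is given, each step is followed by a SHAKE-like
    projection of every domain onto its rigid-body manifold (Kabsch fit of
    the starting domain geometry onto the updated positions).  This is the
    stiff-spring limit of the elastic network: domains move with the net
    force and torque of their atoms, intra-domain distances are preserved
    exactly, and step sizes far beyond the elastic stability limit become
    usable.  The soft network then only matters for any atoms left outside
    ``rigid_domains``.
    """
    params = params or EnvelopePotentialParams()
    params.validate()
    rng = np.random.default_rng(seed)
    pos = model.coords.copy()
    snaps: list[np.ndarray] = []
    idx_rec, rgs, corrs, chis, energies = [], [], [], [], []
    blur = corr_blur if corr_blur is not None else 2.0 * grid.spacing

    def record(step: int, energy: float) -> None:
        snaps.append(pos.copy())
        idx_rec.append(step)
        m = model.with_coords(pos)
        rgs.append(m.rg())
        corrs.append(envelope_correlation(m, grid, blur_sigma=blur))
        if profile is not None:
            calc = debye_profile(m, profile.q, form_factor_mode="model")
            chis.append(fit_chi2(calc, profile).chi2_reduced)
        else:
            chis.append(np.nan)
        energies.append(energy)

    n_bad = 0
    e_prev = np.inf
    for step in range(steps + 1):
        e_env, f_env = envelope_energy_force(grid, params, pos)
        e_net, f_net = _network_energy_force(network, pos)
        energy = e_env + e_net
        if step % stride == 0:
            record(step, energy)
        if step == steps:
            break
        if energy > e_prev + 1e-12:
            n_bad += 1
            if n_bad > divergence_patience:
                raise RuntimeError(
                    f"energy increased for {n_bad} consecutive steps at step "
                    f"{step} (E={energy:.4g}); reduce step_size"
                )
        else:
            n_bad = 0
        e_prev = energy
        pos = pos + step_size * (f_env + f_net)
        if temperature > 0:
            pos = pos + np.sqrt(2.0 * temperature * step_size) * rng.normal(
                size=pos.shape
            )
        if rigid_domains is not None:
            for lab in rigid_domains.labels:
                di = rigid_domains[lab]
                if len(di) < 3:
                    continue
                ref = model.coords[di]
                ref_c = ref - ref.mean(axis=0)
                cur_mean = pos[di].mean(axis=0)
                R = _kabsch_rot(ref_c, pos[di] - cur_mean)
                pos[di] = ref_c @ R.T + cur_mean
    return Trajectory(
        snapshots=snaps,
        step_index=np.array(idx_rec),
        rg=np.array(rgs),
        envelope_corr=np.array(corrs),
        chi2=np.array(chis),
        energy=np.array(energies),
    )


def _kabsch_rot(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing |P R^T - Q| for centred paired sets."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    return Vt.T @ np.diag([1.0, 1.0, d]) @ U.T


def select_best_model(
    traj: Trajectory, profile: ScatteringProfile | None = None
) -> tuple[np.ndarray, int, float]:
    """Frame with the lowest chi^2 vs the profile (earliest on ties)."""
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    chis = traj.chi2
    if np.all(np.isnan(chis)):
        raise ValueError("trajectory carries no chi^2 metrics; pass a profile "
                         "to restrained_refine")
    best = int(np.nanargmin(chis))  # argmin returns the first minimum
    return traj.snapshots[best], best, float(chis[best])


def envelope_correlation(model, grid: DensityGrid, blur_sigma: float) -> float:
    """Pearson correlation between the grid and the model voxelized onto it."""
    if grid.values.size == 0 or grid.rho_max <= 0:
        raise ValueError("empty or zero-variance grid")
    from .envelope_modeling import _points_of

    pts = _points_of(model)
    calc = np.zeros_like(grid.values)
    nx, ny, nz = grid.values.shape
    idx = np.rint((pts - grid.origin) / grid.spacing).astype(int)
    inside = np.all((idx >= 0) & (idx < [nx, ny, nz]), axis=1)
    if np.any(inside):
        ii = idx[inside]
        np.add.at(calc, (ii[:, 0], ii[:, 1], ii[:, 2]), 1.0)
    if blur_sigma > 0:
        from scipy.ndimage import gaussian_filter

        calc = gaussian_filter(calc, sigma=blur_sigma / grid.spacing, mode="constant")
    a = grid.values.ravel()
    b = calc.ravel()
    if a.std() == 0:
        raise ValueError("zero-variance reference grid")
    if b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])
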