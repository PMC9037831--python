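"""Ab initio dummy-atom envelope reconstruction and envelope handling.

A shape is represented by equal beads occupying sites of a hexagonal
close-packed lattice inside a search sphere of diameter Dmax.  Simulated
annealing over occupancy flips minimizes

    E = chi2[ I_beads(q), I_target(q) ]  +  lambda_c (n_components - 1)
        + lambda_p <fraction of empty neighbour sites>,

i.e. agreement with the (P(r)-smoothed) scattering target plus connectivity
and compactness penalties, as dummy-atom modelling programs do.  Ensembles
of reconstructions are compared by the normalized spatial discrepancy
(NSD), clustered by average linkage, and averaged site-wise into a
consensus envelope whose occupancy map feeds the flexible-fitting stage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import gaussian_filter
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform

from .core import AtomicModel, ScatteringProfile
from .forward_scattering import _sinc
from .profile_analysis import PairDistribution

__all__ = [
    "BeadModel",
    "DensityGrid",
    "EnvelopeClustering",
    "AnnealSchedule",
    "hcp_lattice",
    "anneal_envelope",
    "nsd",
    "align_models",
    "cluster_envelopes",
    "average_envelopes",
    "voxelize",
    "write_mrc",
    "read_mrc",
]

log = logging.getLogger(__name__)


@dataclass
class BeadModel:
    """Dummy-atom model: occupied bead centres on a search lattice."""

    centers: np.ndarray  # (n_occupied, 3)
    bead_radius: float
    lattice: np.ndarray | None = None  # (n_sites, 3) full search lattice
    occupancy: np.ndarray | None = None  # bool over lattice sites
    objective_trace: np.ndarray = field(default_factory=lambda: np.array([]))
    converged: bool = True

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))

    def __len__(self) -> int:
        return len(self.centers)

    def as_model(self) -> AtomicModel:
        return AtomicModel(self.centers, bead_radius=self.bead_radius)

    def rg(self) -> float:
        return self.as_model().rg()


@dataclass
class DensityGrid:
    """Voxelized density: origin (A), isotropic voxel spacing (A), values."""

    origin: np.ndarray
    spacing: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        if np.any(self.values < 0):
            raise ValueError("density must be non-negative")

    @property
    def rho_max(self) -> float:
        return float(self.values.max())

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def voxel_centers(self) -> np.ndarray:
        nx, ny, nz = self.values.shape
        ax = [self.origin[i] + self.spacing * np.arange(n) for i, n in enumerate((nx, ny, nz))]
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)


@dataclass
class EnvelopeClustering:
    nsd_matrix: np.ndarray
    assignments: np.ndarray  # cluster label per model, -1 for isolated
    isolated: list[int]
    cluster_members: dict[int, list[int]]
    averaged: dict[int, BeadModel] = field(default_factory=dict)


@dataclass
class AnnealSchedule:
    t_initial: float = 2.0
    cooling: float = 0.88
    n_sweeps: int = 60
    moves_per_sweep: int | None = None  # default: one proposal per site
    patience: int = 12

    def validate(self) -> None:
        if self.t_initial <= 0 or not (0 < self.cooling < 1):
            raise ValueError("need t_initial > 0 and 0 < cooling < 1")


def hcp_lattice(radius: float, bead_radius: float) -> np.ndarray:
    """Hexagonal close-packed sites inside a sphere of given radius."""
    a = 2.0 * bead_radius
    nmax = int(math.ceil(radius / a)) + 2
    pts = []
    c = a * math.sqrt(8.0 / 3.0) / 2.0  # inter-layer separation
    row = a * math.sqrt(3.0) / 2.0
    for k in range(-nmax * 2, nmax * 2 + 1):
        z = k * c
        if abs(z) > radius + a:
            continue
        for j in range(-nmax * 2, nmax * 2 + 1):
            y = j * row + (a / (2 * math.sqrt(3.0)) if k % 2 else 0.0)
            if abs(y) > radius + a:
                continue
            for i in range(-nmax * 2, nmax * 2 + 1):
                x = i * a + (a / 2.0 if (j + k) % 2 else 0.0)
                if x * x + y * y + z * z <= radius * radius:
                    pts.append((x, y, z))
    return np.array(pts, dtype=float)


def _chi2_scaled(I_obs: np.ndarray, w: np.ndarray, I_calc: np.ndarray) -> float:
    den = float(np.sum(w * I_calc * I_calc))
    if den <= 0:
        return float(np.sum(w * I_obs * I_obs))
    c = float(np.sum(w * I_obs * I_calc)) / den
    r = I_obs - c * I_calc
    return float(np.sum(w * r * r) / max(len(I_obs) - 1, 1))


def _n_components(adj: csr_matrix, occ_idx: np.ndarray) -> int:
    if occ_idx.size == 0:
        return 0
    sub = adj[occ_idx][:, occ_idx]
    n, _ = connected_components(sub, directed=False)
    return n


def _n_components_bfs(nbr_lists: list[np.ndarray], occ: np.ndarray) -> int:
    """Connected components of the occupied subgraph by plain BFS.

    Much faster than sparse-matrix slicing for the small occupied sets the
    annealer works with (called once per proposed move)."""
    visited = ~occ  # treat empty sites as already done
    count = 0
    stack: list[int] = []
    for start in np.flatnonzero(occ):
        if visited[start]:
            continue
        count += 1
        visited[start] = True
        stack.append(int(start))
        while stack:
            k = stack.pop()
            for nb in nbr_lists[k]:
                if not visited[nb]:
                    visited[nb] = True
                    stack.append(int(nb))
    return count


def anneal_envelope(
    target: ScatteringProfile | PairDistribution,
    bead_radius: float | None = None,
    dmax: float | None = None,
    weights: tuple[float, float] = (1e5, 2.0),
    schedule: AnnealSchedule | None = None,
    seed: int = 0,
    n_q: int = 40,
) -> BeadModel:
    """Reconstruct a bead envelope from scattering data by simulated
    annealing over lattice-site occupancy.

    Parameters
    ----------
    target : ScatteringProfile or PairDistribution
        Fitting target.  A PairDistribution uses its regularized
        (IFT-smoothed) intensity — the standard practice of fitting the
        smoothed curve rather than raw data — and supplies Dmax.
    bead_radius : float, optional
        Defaults to Dmax / 24 (about two dozen beads across the particle).
    dmax : float, optional
        Search-sphere diameter; required if target is a raw profile and no
        better estimate exists.
    weights : (lambda_c, lambda_p)
        Connectivity and looseness penalty weights.  The connectivity
        default is large enough to act as a hard constraint (chi^2 against
        a 1%-error target is O(10^2-10^4), so breaking the model apart can
        never pay); elongated targets then grow necks instead of splitting.
    """
    schedule = schedule or AnnealSchedule()
    schedule.validate()
    if isinstance(target, PairDistribution):
        profile = target.regularized_profile()
        dmax = dmax or float(target.Dmax)
    else:
        profile = target
        if dmax is None:
            raise ValueError("dmax is required when the target is a raw profile")
    if bead_radius is None:
        bead_radius = dmax / 24.0

    # thin the q grid for speed; annealing needs ~tens of channels
    stride = max(1, len(profile) // n_q)
    q = profile.q[::stride]
    I_obs = profile.I[::stride]
    w = 1.0 / profile.sigma[::stride] ** 2

    sites = hcp_lattice(dmax / 2.0, bead_radius)
    m = len(sites)
    if m < 8:
        raise ValueError("lattice too small; decrease bead_radius")
    tree = cKDTree(sites)
    pairs = tree.query_pairs(2.0 * bead_radius * 1.15, output_type="ndarray")
    rows = np.concatenate([pairs[:, 0], pairs[:, 1]])
    cols = np.concatenate([pairs[:, 1], pairs[:, 0]])
    adj = csr_matrix((np.ones(len(rows), bool), (rows, cols)), shape=(m, m))
    nbr_lists = [adj.indices[adj.indptr[k] : adj.indptr[k + 1]] for k in range(m)]
    degree = np.asarray(adj.sum(axis=1)).ravel().astype(float)
    degree[degree == 0] = 1.0
    dist = np.linalg.norm(sites[:, None, :] - sites[None, :, :], axis=2)

    rng = np.random.default_rng(seed)
    # start from a compact connected blob in the centre
    occ = np.linalg.norm(sites, axis=1) <= 0.55 * (dmax / 2.0)
    if occ.sum() < 4:
        occ[np.argsort(np.linalg.norm(sites, axis=1))[:8]] = True
    occ_nbr = np.asarray(adj[:, occ].sum(axis=1)).ravel().astype(float)

    sinc_cache: dict[int, np.ndarray] = {}
    cache_ok = m * m * len(q) * 8 < 2e8  # cap cache at ~200 MB

    def site_sinc(k: int) -> np.ndarray:
        # sinc(q * d_k.) rows cached lazily per site
        if k in sinc_cache:
            return sinc_cache[k]
        row = _sinc(np.outer(q, dist[k]))
        if cache_ok:
            sinc_cache[k] = row
        return row

    def full_intensity(o: np.ndarray) -> np.ndarray:
        idx = np.where(o)[0]
        s = np.zeros_like(q)
        for k in idx:
            s += site_sinc(k)[:, o].sum(axis=1)
        return s  # includes diagonal terms (sinc(0)=1 per bead)

    I_calc = full_intensity(occ)

    lam_c, lam_p = weights

    def objective(o: np.ndarray, I_c: np.ndarray, nc: int) -> float:
        loose = float(np.mean(1.0 - occ_nbr[o] / degree[o])) if o.any() else 1.0
        return _chi2_scaled(I_obs, w, I_c) + lam_c * (nc - 1) + lam_p * loose

    ncomp = _n_components_bfs(nbr_lists, occ)
    E = objective(occ, I_calc, ncomp)
    best = (occ.copy(), I_calc.copy(), E)
    trace = [E]
    T = schedule.t_initial
    moves = schedule.moves_per_sweep or m
    stall = 0
    for _ in range(schedule.n_sweeps):
        improved = False
        for k in rng.integers(0, m, size=moves):
            k = int(k)
            row = site_sinc(k)
            if occ[k]:
                delta = -(1.0 + 2.0 * (row[:, occ].sum(axis=1) - 1.0))
                occ[k] = False
            else:
                delta = 1.0 + 2.0 * row[:, occ].sum(axis=1)
                occ[k] = True
            if not occ.any():
                occ[k] = True
                continue
            I_new = I_calc + delta
            nbrs = nbr_lists[k]
            occ_nbr[nbrs] += 1.0 if occ[k] else -1.0
            occ_nbr_k = int(occ[nbrs].sum())
            if occ[k]:
                # addition: isolated bead adds a component; otherwise a
                # recount is needed only to detect merges
                nc = ncomp + 1 if occ_nbr_k == 0 else _n_components_bfs(nbr_lists, occ)
            else:
                # removal: can split only if the bead bridged >= 2 neighbours
                nc = ncomp - (1 if occ_nbr_k == 0 else 0) if occ_nbr_k <= 1 \
                    else _n_components_bfs(nbr_lists, occ)
            E_new = objective(occ, I_new, nc)
            if E_new <= E or rng.random() < math.exp(-(E_new - E) / T):
                E = E_new
                I_calc = I_new
                ncomp = nc
                if E < best[2]:
                    best = (occ.copy(), I_calc.copy(), E)
                    improved = True
            else:  # revert
                occ_nbr[nbrs] -= 1.0 if occ[k] else -1.0
                occ[k] = not occ[k]
        trace.append(best[2])
        T *= schedule.cooling
        stall = 0 if improved else stall + 1
        if stall >= schedule.patience:
            break
    converged = stall < schedule.patience
    if not converged:
        log.warning("annealing stalled for %d sweeps; returning best-so-far", stall)

    occ_best = best[0]
    occ_idx = np.where(occ_best)[0]
    # enforce connectivity of the final model: keep the largest component
    sub = adj[occ_idx][:, occ_idx]
    ncomp, labels = connected_components(sub, directed=False)
    if ncomp > 1:
        biggest = np.argmax(np.bincount(labels))
        occ_idx = occ_idx[labels == biggest]
        occ_best = np.zeros(m, bool)
        occ_best[occ_idx] = True
        log.warning("final envelope had %d components; kept the largest", ncomp)
    return BeadModel(
        centers=sites[occ_idx],
        bead_radius=bead_radius,
        lattice=sites,
        occupancy=occ_best,
        objective_trace=np.array(trace),
        converged=converged,
    )


# ------------------------------------------------------------------- NSD


def _points_of(x) -> np.ndarray:
    if isinstance(x, BeadModel):
        return x.centers
    if isinstance(x, AtomicModel):
        return x.coords
    return np.atleast_2d(np.asarray(x, dtype=float))


def nsd(A, B) -> float:
    """Normalized spatial discrepancy between two point sets.

    NSD^2 = 1/2 [ (1/(N_A d_B^2)) sum_i min_j |a_i - b_j|^2
                + (1/(N_B d_A^2)) sum_j min_i |b_j - a_i|^2 ],

    where d_X is the mean nearest-neighbour distance within X.  Zero for
    identical sets; ~1 when the sets differ by about one bead spacing.
    """
    A, B = _points_of(A), _points_of(B)
    if len(A) < 2 or len(B) < 2:
        raise ValueError("NSD needs at least two points per set")
    tA, tB = cKDTree(A), cKDTree(B)
    dA = float(np.mean(tA.query(A, k=2)[0][:, 1]))
    dB = float(np.mean(tB.query(B, k=2)[0][:, 1]))
    if dA <= 0 or dB <= 0:
        raise ValueError("degenerate point set (duplicate points)")
    a2b = tB.query(A, k=1)[0]
    b2a = tA.query(B, k=1)[0]
    val = 0.5 * (np.mean(a2b**2) / dB**2 + np.mean(b2a**2) / dA**2)
    return float(np.sqrt(val))


def _kabsch(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Proper rotation minimizing |P R^T - Q| for paired points."""
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    return Vt.T @ D @ U.T


def _principal_axes(X: np.ndarray) -> np.ndarray:
    c = X - X.mean(axis=0)
    _, vecs = np.linalg.eigh(c.T @ c)
    R = vecs[:, ::-1]  # descending variance
    if np.linalg.det(R) < 0:
        R[:, 2] = -R[:, 2]
    return R


def align_models(mobile, reference, refine_iter: int = 12):
    """Rigidly align ``mobile`` onto ``reference`` minimizing NSD.

    Searches the four proper principal-axis flips and the enantiomer
    (point inversion) branch, each followed by ICP-style local refinement,
    and keeps the transform with the lowest NSD.  Returns an object of the
    same type as ``mobile`` with transformed coordinates.
    """
    Xm = _points_of(mobile)
    Xr = _points_of(reference)
    cm, cr = Xm.mean(axis=0), Xr.mean(axis=0)
    Rr = _principal_axes(Xr)
    best_pts, best_val = None, np.inf
    for mirror in (False, True):
        X0 = -(Xm - cm) if mirror else (Xm - cm)
        Rm = _principal_axes(X0)
        for fx, fy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
            F = np.diag([fx, fy, fx * fy])  # proper flips only
            R = Rr @ F @ Rm.T
            pts = X0 @ R.T + cr
            # local ICP refinement
            tree = cKDTree(Xr)
            for _ in range(refine_iter):
                nn = tree.query(pts, k=1)[1]
                R2 = _kabsch(pts - pts.mean(axis=0), Xr[nn] - Xr[nn].mean(axis=0))
                pts = (pts - pts.mean(axis=0)) @ R2.T + Xr[nn].mean(axis=0)
            val = nsd(pts, Xr)
            if val < best_val:
                best_val, best_pts = val, pts
    return _with_points(mobile, best_pts)


def _with_points(template, pts: np.ndarray):
    if isinstance(template, BeadModel):
        return BeadModel(
            centers=pts,
            bead_radius=template.bead_radius,
            lattice=template.lattice,
            occupancy=None,
            converged=template.converged,
        )
    if isinstance(template, AtomicModel):
        return template.with_coords(pts)
    return pts


def cluster_envelopes(models: list, linkage_threshold: float = 0.7) -> EnvelopeClustering:
    """Average-linkage clustering of envelopes on the aligned-NSD matrix.

    Models are mutually aligned pairwise; singleton clusters are reported
    as isolated (label -1), as DAMCLUST-style screening does.
    """
    n = len(models)
    if n < 2:
        raise ValueError("need at least two models to cluster")
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            aligned = align_models(models[j], models[i])
            D[i, j] = D[j, i] = nsd(aligned, models[i])
    Z = linkage(squareform(D, checks=False), method="average")
    raw = fcluster(Z, t=linkage_threshold, criterion="distance")
    assignments = np.full(n, -1)
    members: dict[int, list[int]] = {}
    next_label = 0
    for lab in np.unique(raw):
        idx = np.where(raw == lab)[0]
        if len(idx) == 1:
            continue
        assignments[idx] = next_label
        members[next_label] = list(map(int, idx))
        next_label += 1
    isolated = [int(i) for i in np.where(assignments == -1)[0]]
    return EnvelopeClustering(D, assignments, isolated, members)


def average_envelopes(
    members: list[BeadModel],
    occupancy_cut: float = 0.5,
    grid_spacing: float | None = None,
) -> tuple[BeadModel, DensityGrid]:
    """Site-wise average of aligned envelopes.

    Each member's bead centres are snapped to the nearest site of the
    reference lattice (the first member's); the averaged model keeps sites
    whose occupancy frequency reaches ``occupancy_cut``.  The frequency
    field is also returned as a DensityGrid for voxel-level use.
    """
    if not members:
        raise ValueError("no members to average")
    ref = members[0]
    lattice = ref.lattice if ref.lattice is not None else ref.centers
    tree = cKDTree(lattice)
    freq = np.zeros(len(lattice))
    for mem in members:
        site_idx = np.unique(tree.query(mem.centers, k=1)[1])
        freq[site_idx] += 1.0
    freq /= len(members)
    keep = freq >= occupancy_cut
    if not np.any(keep):
        raise ValueError(f"no lattice site reaches occupancy {occupancy_cut}")
    avg = BeadModel(
        centers=lattice[keep],
        bead_radius=ref.bead_radius,
        lattice=lattice,
        occupancy=keep,
    )
    spacing = grid_spacing or ref.bead_radius
    grid = voxelize(
        BeadModel(lattice, ref.bead_radius),
        spacing=spacing,
        blur_sigma=ref.bead_radius,
        weights=freq,
    )
    return avg, grid


def voxelize(
    model,
    spacing: float,
    blur_sigma: float = 0.0,
    weights: np.ndarray | None = None,
) -> DensityGrid:
    """Deposit point masses on a regular grid and blur with a Gaussian.

    Each centre contributes its weight (default 1, or the model's
    scattering lengths for an AtomicModel); the Gaussian kernel of width
    ``blur_sigma`` conserves total mass on the interior (grid padded by
    3 sigma).
    """
    if spacing <= 0 or blur_sigma < 0:
        raise ValueError("spacing > 0 and blur_sigma >= 0 required")
    pts = _points_of(model)
    if weights is None:
        if isinstance(model, AtomicModel):
            weights = model.f
        else:
            weights = np.ones(len(pts))
    weights = np.asarray(weights, dtype=float)
    pad = 3.0 * blur_sigma + spacing
    lo = pts.min(axis=0) - pad
    hi = pts.max(axis=0) + pad
    shape = np.maximum(np.ceil((hi - lo) / spacing).astype(int) + 1, 1)
    values = np.zeros(shape)
    idx = np.rint((pts - lo) / spacing).astype(int)
    np.add.at(values, (idx[:, 0], idx[:, 1], idx[:, 2]), weights)
    if blur_sigma > 0:
        values = gaussian_filter(values, sigma=blur_sigma / spacing, mode="constant")
    values = np.clip(values, 0.0, None)
    return DensityGrid(origin=lo, spacing=spacing, values=values)


# ------------------------------------------------------------------- MRC


def write_mrc(path: str | Path, grid: DensityGrid) -> None:
    """Write a DensityGrid as a CCP4/MRC map (orthogonal cell)."""
    import gemmi

    nx, ny, nz = grid.values.shape
    g = gemmi.FloatGrid(nx, ny, nz)
    g.set_unit_cell(
        gemmi.UnitCell(nx * grid.spacing, ny * grid.spacing, nz * grid.spacing, 90, 90, 90)
    )
    np.asarray(g, dtype=np.float32)[...] = grid.values.astype(np.float32)
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    m.set_header_float(50, float(grid.origin[0]))
    m.set_header_float(51, float(grid.origin[1]))
    m.set_header_float(52, float(grid.origin[2]))
    m.write_ccp4_map(str(path))


def read_mrc(path: str | Path) -> DensityGrid:
    import gemmi

    m = gemmi.read_ccp4_map(str(path))
    values = np.array(m.grid, dtype=float)
    spacing = m.grid.unit_cell.a / m.grid.nu
    origin = np.array(
        [m.header_float(50), m.header_float(51), m.header_float(52)], dtype=float
    )
    return DensityGrid(origin=origin, spacing=float(spacing), values=np.clip(values, 0, None))
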