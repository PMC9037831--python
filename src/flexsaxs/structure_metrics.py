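"""Geometric descriptors of multi-domain antibody models.

Implements the comparison layer used to tell conformers apart: centres of
mass and their mutual distances/angles, inertia-plane angles, per-domain
radius of gyration and solvent-accessible surface area (Shrake-Rupley),
the Fab elbow angle (angle between the pseudo-two-fold axes of the
variable and constant modules), and Kabsch-superposition RMSD.

Naming convention: of the two Fab arms, ``Fa`` is the one whose centre of
mass lies farther from the Fc centre of mass, ``Fb`` the closer one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .core import AtomicModel, DomainPartition

__all__ = [
    "GeometryFeatures",
    "assign_domains",
    "geometry_features",
    "shrake_rupley_sasa",
    "elbow_angle",
    "superpose_rmsd",
]

log = logging.getLogger(__name__)


@dataclass
class GeometryFeatures:
    com_whole: np.ndarray
    com: dict[str, np.ndarray]
    com_distances: dict[str, float]  # "Fa-Fb" etc.
    center_angles: dict[str, float]  # "Fa-Fb" = angle Fa-COM-Fb, degrees
    plane_angles: dict[str, float]  # acute angle between inertia planes
    domain_rg: dict[str, float]
    domain_sasa: dict[str, float]
    elbow: dict[str, float] | None = None

    def as_row(self) -> dict[str, float]:
        """Flatten to one scalar row for feature matrices."""
        row: dict[str, float] = {}
        for k, v in self.com_distances.items():
            row[f"dist_{k}"] = v
        for k, v in self.center_angles.items():
            row[f"angle_{k}"] = v
        for k, v in self.plane_angles.items():
            row[f"plane_{k}"] = v
        for k, v in self.domain_rg.items():
            row[f"rg_{k}"] = v
        for k, v in self.domain_sasa.items():
            row[f"sasa_{k}"] = v
        if self.elbow:
            for k, v in self.elbow.items():
                row[f"elbow_{k}"] = v
        return row


def assign_domains(
    model: AtomicModel,
    partition: DomainPartition,
    arm_labels: tuple[str, str] = ("Fa", "Fb"),
    fc_label: str = "Fc",
    tie_tol: float = 1e-6,
) -> DomainPartition:
    """Relabel the two arms so Fa is the arm farther from the Fc COM.

    Ties (within ``tie_tol`` Angstrom) are broken by current label order,
    which is deterministic and logged.
    """
    a1, a2 = arm_labels
    w = model.f
    com = {
        lab: np.average(model.coords[partition[lab]], axis=0,
                        weights=w[partition[lab]])
        for lab in (a1, a2, fc_label)
    }
    d1 = float(np.linalg.norm(com[a1] - com[fc_label]))
    d2 = float(np.linalg.norm(com[a2] - com[fc_label]))
    if abs(d1 - d2) <= tie_tol:
        log.info("equidistant arms (%.6f vs %.6f A); keeping label order", d1, d2)
        return partition
    if d1 >= d2:
        return partition
    return partition.relabel({a1: a2, a2: a1})


def _gyration_plane_normal(coords: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Unit normal of the inertia plane (span of the two largest-variance
    principal axes of the gyration tensor)."""
    if len(coords) < 3:
        raise ValueError("inertia plane needs at least 3 atoms")
    c = coords - np.average(coords, axis=0, weights=weights)
    T = (c * weights[:, None]).T @ c / weights.sum()
    vals, vecs = np.linalg.eigh(T)
    return vecs[:, 0]  # smallest-variance axis = plane normal


def shrake_rupley_sasa(
    coords: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area by the Shrake-Rupley
    construction: test points on each atom's expanded sphere are counted
    accessible when inside no other expanded sphere."""
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float) + probe_radius
    n = len(coords)
    # deterministic quasi-uniform sphere points (golden-spiral)
    k = np.arange(n_points) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n_points)
    theta = np.pi * (1.0 + 5.0**0.5) * k
    sphere = np.stack(
        [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)],
        axis=1,
    )
    tree = cKDTree(coords)
    rmax = radii.max()
    areas = np.zeros(n)
    for i in range(n):
        pts = coords[i] + radii[i] * sphere
        nbr = [j for j in tree.query_ball_point(coords[i], radii[i] + rmax) if j != i]
        if nbr:
            d = np.linalg.norm(pts[:, None, :] - coords[nbr][None, :, :], axis=2)
            buried = np.any(d < radii[nbr][None, :], axis=1)
            acc = int(np.sum(~buried))
        else:
            acc = n_points
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * acc / n_points
    return areas


def geometry_features(
    model: AtomicModel,
    partition: DomainPartition,
    probe_radius: float = 1.4,
    atom_radius: float | None = None,
    mass_weighted: bool = True,
    sasa_points: int = 960,
) -> GeometryFeatures:
    """All scalar geometry descriptors of a partitioned model.

    Angles at the whole-molecule COM are between domain-COM vectors;
    inertia-plane angles are the acute angles between plane normals; SASA
    is computed per domain in isolation (each domain's own surface).
    """
    w = model.f if mass_weighted else np.ones(len(model))
    com_whole = np.average(model.coords, axis=0, weights=w)
    labels = partition.labels
    com = {}
    rg = {}
    sasa = {}
    normals = {}
    radius = atom_radius if atom_radius is not None else (model.bead_radius or 1.9)
    for lab in labels:
        idx = partition[lab]
        cw = w[idx]
        com[lab] = np.average(model.coords[idx], axis=0, weights=cw)
        d2 = np.sum((model.coords[idx] - com[lab]) ** 2, axis=1)
        rg[lab] = float(np.sqrt(np.average(d2, weights=cw)))
        sasa[lab] = float(
            np.sum(
                shrake_rupley_sasa(
                    model.coords[idx],
                    np.full(len(idx), radius),
                    probe_radius=probe_radius,
                    n_points=sasa_points,
                )
            )
        )
        if len(idx) >= 3:
            normals[lab] = _gyration_plane_normal(model.coords[idx], cw)
    dists = {}
    angles = {}
    planes = {}
    for i, la in enumerate(labels):
        for lb in labels[i + 1 :]:
            key = f"{la}-{lb}"
            dists[key] = float(np.linalg.norm(com[la] - com[lb]))
            va = com[la] - com_whole
            vb = com[lb] - com_whole
            na, nb = np.linalg.norm(va), np.linalg.norm(vb)
            if na > 1e-9 and nb > 1e-9:
                cosang = np.clip(va @ vb / (na * nb), -1.0, 1.0)
                angles[key] = float(np.degrees(np.arccos(cosang)))
            if la in normals and lb in normals:
                c = abs(float(normals[la] @ normals[lb]))
                planes[key] = float(np.degrees(np.arccos(np.clip(c, 0.0, 1.0))))
    return GeometryFeatures(
        com_whole=com_whole,
        com=com,
        com_distances=dists,
        center_angles=angles,
        plane_angles=planes,
        domain_rg=rg,
        domain_sasa=sasa,
    )


def _rotation_axis(R: np.ndarray) -> tuple[np.ndarray, float]:
    """Axis (unit) and angle in (0, 180] of a proper rotation."""
    rot = Rotation.from_matrix(R)
    vec = rot.as_rotvec()
    angle = float(np.linalg.norm(vec))
    if angle < 1e-12:
        raise ValueError("identity rotation has no defined axis")
    return vec / angle, float(np.degrees(angle))


def elbow_angle(
    model: AtomicModel,
    variable_pair: tuple[np.ndarray, np.ndarray],
    constant_pair: tuple[np.ndarray, np.ndarray],
    min_rotation: float = 5.0,
) -> float:
    """Fab elbow angle from the pseudo-two-fold axes of the variable and
    constant modules.

    ``variable_pair`` holds equal-length index lists (VL, VH) of
    corresponding atoms; superposing VL onto VH yields the variable
    module's pseudo-dyad (rotation axis).  Likewise (CL, CH1) for the
    constant module.  A pseudo-two-fold axis is only defined up to sign,
    so both dyads are first brought to a canonical orientation (the
    variable dyad points toward the constant module; the constant dyad
    into the same hemisphere), giving an inter-dyad angle theta in
    [0, 90].  The elbow is then 180 - theta or 180 + theta — parallel
    dyads give 180 — with the reflex branch chosen by the sign of
    (u_V x u_C) . (COM_C - COM_V), so results lie in (90, 270) degrees.
    """
    uv, com_v = _module_dyad(model, *variable_pair, min_rotation)
    uc, com_c = _module_dyad(model, *constant_pair, min_rotation)
    d = com_c - com_v
    nd = np.linalg.norm(d)
    if nd < 1e-9:
        raise ValueError("coincident module centres; elbow undefined")
    d = d / nd
    uv = _canonical_axis(uv, d)
    if uv @ uc < 0:
        uc = -uc
    theta = np.degrees(np.arccos(np.clip(uv @ uc, -1.0, 1.0)))  # in [0, 90]
    sign = float(np.cross(uv, uc) @ d)
    elbow = 180.0 - theta if sign >= 0 else 180.0 + theta
    return float(elbow)


def _canonical_axis(u: np.ndarray, d: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Fix the sign of an axis: along +d where possible, else by the
    largest-magnitude component."""
    proj = float(u @ d)
    if abs(proj) > tol:
        return u if proj > 0 else -u
    j = int(np.argmax(np.abs(u)))
    return u if u[j] > 0 else -u


def _module_dyad(
    model: AtomicModel, idx_l: np.ndarray, idx_h: np.ndarray, min_rotation: float
) -> tuple[np.ndarray, np.ndarray]:
    A = model.coords[np.asarray(idx_l, int)]
    B = model.coords[np.asarray(idx_h, int)]
    if len(A) != len(B) or len(A) < 3:
        raise ValueError("correspondence lists must be equal length >= 3")
    _, (R, _t) = superpose_rmsd(A, B)
    try:
        axis, angle = _rotation_axis(R)
    except ValueError as err:
        raise ValueError("superposition rotation is the identity; dyad undefined") from err
    if angle < min_rotation:
        raise ValueError(
            f"superposition rotation {angle:.2f} deg < {min_rotation} deg; "
            "pseudo-dyad ill-defined"
        )
    com = 0.5 * (A.mean(axis=0) + B.mean(axis=0))
    return axis, com


def superpose_rmsd(
    A: np.ndarray, B: np.ndarray, correspondence: np.ndarray | None = None
) -> tuple[float, tuple[np.ndarray, np.ndarray]]:
    """Optimal rigid superposition of A onto B (Kabsch, proper rotation).

    Returns (RMSD after superposition, (R, t)) with B ~ A @ R.T + t.
    ``correspondence`` maps rows of A onto rows of B (identity when None).
    Collinear/degenerate sets superpose with a warning (rotation about the
    degenerate axis is arbitrary but the RMSD is still optimal).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if correspondence is not None:
        B = B[np.asarray(correspondence, int)]
    if A.shape != B.shape or len(A) < 3:
        raise ValueError("need equal-shape coordinate sets with >= 3 points")
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    P = A - ca
    Q = B - cb
    H = P.T @ Q
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-9 * max(S[0], 1.0):
        log.warning("degenerate (collinear) point set: rotation not unique")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = cb - R @ ca
    diff = P @ R.T - Q
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1)))), (R, t)
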