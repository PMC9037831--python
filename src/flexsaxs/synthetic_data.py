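"""Synthetic antibody-like structures and SAXS profiles with known truth.

The surrogate emulates a ~150 kDa IgG at SAXS resolution: three rigid
ellipsoidal domains (two Fab arms and one Fc stem) built from uniform dummy
scatterers on a jittered lattice, joined by two flexible hinges.  Each hinge
is parameterized by a bend angle (interior angle at the pivot between the Fc
axis and the arm axis, 180 deg = arm collinear with the stem) and a twist
about the arm axis.  Conformers are generated by rigid rotations of whole
arms about fixed pivot points, so intra-domain geometry is preserved exactly.

Noise follows a photon-statistics-like model
sigma(q) = I(q) * (floor + growth * q) / sqrt(counts_scale): relative errors
grow towards high q as they do on real detectors.

Temperature series mix a folded state with an isotropically expanded one via
a logistic unfolded fraction; concentration series mix monomer with a
side-by-side dimer to emulate aggregation above a threshold concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .core import AtomicModel, DomainPartition, ScatteringProfile
from .forward_scattering import debye_profile

__all__ = [
    "SurrogateSpec",
    "NoiseSpec",
    "build_antibody_surrogate",
    "sample_conformers",
    "simulate_profile",
    "simulate_temperature_series",
    "simulate_concentration_series",
]


class ClashError(RuntimeError):
    """Raised when clash-free geometry cannot be found."""


@dataclass
class SurrogateSpec:
    """Geometry of the three-domain antibody surrogate.

    Defaults approximate an IgG: Fab arms ~80 x 50 x 40 Angstrom ellipsoids,
    a slightly smaller Fc, ~18 Angstrom hinges, and an asymmetric resting
    conformation (the two arms bend differently, as the antibody studied
    here does in solution).
    """

    beads_per_domain: Mapping[str, int] = field(
        default_factory=lambda: {"arm1": 110, "arm2": 110, "Fc": 100}
    )
    # semi-axes (long, mid, short) in Angstrom; long axis along the domain axis
    domain_shape: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "arm1": (40.0, 25.0, 20.0),
            "arm2": (40.0, 25.0, 20.0),
            "Fc": (33.0, 25.0, 21.0),
        }
    )
    hinge_lengths: Mapping[str, float] = field(
        default_factory=lambda: {"arm1": 18.0, "arm2": 18.0}
    )
    # template (bend, twist) in degrees per arm; bend 180 = collinear with stem
    hinge_angles: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"arm1": (118.0, 0.0), "arm2": (142.0, 0.0)}
    )
    # sampling half-widths used by sample_conformers when none are given
    hinge_angle_ranges: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            "Fa": {"bend": (-35.0, 35.0), "twist": (-60.0, 60.0)},
            "Fb": {"bend": (-35.0, 35.0), "twist": (-60.0, 60.0)},
        }
    )
    bead_scattering_length: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if sum(self.beads_per_domain.values()) <= 0:
            raise ValueError("total bead count must be positive")
        for name, n in self.beads_per_domain.items():
            if n < 1:
                raise ValueError(f"beads_per_domain[{name!r}] must be >= 1")
        for name, ax in self.domain_shape.items():
            if any(a < 0 for a in ax):
                raise ValueError(f"negative semi-axis for domain {name!r}")


@dataclass
class NoiseSpec:
    """Gaussian noise model sigma(q) = I(q)*(floor + growth*q)/sqrt(counts)."""

    relative_error_floor: float = 0.01
    error_growth: float = 0.15
    counts_scale: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.relative_error_floor <= 0:
            raise ValueError("relative_error_floor must be > 0 (sigma must stay positive)")
        if self.error_growth < 0 or self.counts_scale <= 0:
            raise ValueError("error_growth >= 0 and counts_scale > 0 required")

    def sigma(self, q: np.ndarray, intensity: np.ndarray) -> np.ndarray:
        return np.abs(intensity) * (
            self.relative_error_floor + self.error_growth * np.asarray(q)
        ) / math.sqrt(self.counts_scale)


def _fill_ellipsoid(
    semi_axes: tuple[float, float, float], n: int, rng: np.random.Generator
) -> np.ndarray:
    """n points on a jittered cubic lattice inside an ellipsoid.

    Long axis along y (the domain axis); degenerate axes collapse to points.
    """
    a, b, c = semi_axes  # a = long (y), b = mid (x), c = short (z)
    if n == 1 or max(semi_axes) <= 0:
        return np.zeros((1, 3))
    vol = 4.0 / 3.0 * math.pi * max(a, 1e-6) * max(b, 1e-6) * max(c, 1e-6)
    spacing = (vol / n) ** (1.0 / 3.0)
    for _ in range(8):
        nx = np.arange(-b, b + spacing, spacing)
        ny = np.arange(-a, a + spacing, spacing)
        nz = np.arange(-c, c + spacing, spacing)
        X, Y, Z = np.meshgrid(nx, ny, nz, indexing="ij")
        pts = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)
        pts = pts + rng.uniform(-0.3 * spacing, 0.3 * spacing, size=pts.shape)
        inside = (
            (pts[:, 0] / max(b, 1e-9)) ** 2
            + (pts[:, 1] / max(a, 1e-9)) ** 2
            + (pts[:, 2] / max(c, 1e-9)) ** 2
        ) <= 1.0
        pts = pts[inside]
        if len(pts) >= n:
            sel = rng.choice(len(pts), size=n, replace=False)
            return pts[np.sort(sel)]
        spacing *= 0.93  # densify until enough lattice sites fall inside
    raise RuntimeError("could not fill ellipsoid with requested bead count")


def _arm_direction(bend_deg: float, azimuth_deg: float) -> np.ndarray:
    """Unit vector at interior angle ``bend`` from the stem axis (-y)."""
    th = math.radians(bend_deg)
    ph = math.radians(azimuth_deg)
    return np.array(
        [math.sin(th) * math.cos(ph), -math.cos(th), math.sin(th) * math.sin(ph)]
    )


def _rotation_aligning(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Proper rotation matrix taking unit vector a onto unit vector b."""
    v = np.cross(a, b)
    cos = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if cos > 0:
            return np.eye(3)
        # 180 degrees: rotate about any axis perpendicular to a
        perp = np.array([1.0, 0.0, 0.0])
        if abs(a[0]) > 0.9:
            perp = np.array([0.0, 0.0, 1.0])
        axis = np.cross(a, perp)
        axis /= np.linalg.norm(axis)
        return Rotation.from_rotvec(math.pi * axis).as_matrix()
    axis = v / np.linalg.norm(v)
    angle = math.atan2(float(np.linalg.norm(v)), cos)
    return Rotation.from_rotvec(angle * axis).as_matrix()


def _min_interdomain_distance(groups: Sequence[np.ndarray]) -> float:
    best = np.inf
    for i in range(len(groups)):
        tree = cKDTree(groups[i])
        for j in range(i + 1, len(groups)):
            d, _ = tree.query(groups[j], k=1)
            best = min(best, float(d.min()))
    return best


def build_antibody_surrogate(
    spec: SurrogateSpec | None = None, max_attempts: int = 25
) -> tuple[AtomicModel, DomainPartition]:
    """Build the three-domain surrogate; deterministic for a fixed seed.

    Returns the model (with hinge pivots attached) and a DomainPartition
    labelling the arms Fa/Fb by the farther-from-Fc convention.
    """
    spec = spec or SurrogateSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    a_fc = spec.domain_shape["Fc"][0]
    b_fc = spec.domain_shape["Fc"][1]
    bead_counts = spec.beads_per_domain

    for _ in range(max_attempts):
        # Fc: long axis along y, top face at y = 0
        fc = _fill_ellipsoid(spec.domain_shape["Fc"], bead_counts["Fc"], rng)
        fc = fc + np.array([0.0, -a_fc, 0.0])
        groups: dict[str, np.ndarray] = {"Fc": fc}
        pivots: dict[str, np.ndarray] = {}
        for arm, sign, azim in (("arm1", +1.0, 0.0), ("arm2", -1.0, 180.0)):
            bend, twist = spec.hinge_angles[arm]
            pivot = np.array([sign * 0.3 * b_fc, 0.0, 0.0])
            d = _arm_direction(bend, azim)
            a_arm = spec.domain_shape[arm][0]
            center = pivot + d * (spec.hinge_lengths[arm] + a_arm)
            local = _fill_ellipsoid(spec.domain_shape[arm], bead_counts[arm], rng)
            R = _rotation_aligning(np.array([0.0, 1.0, 0.0]), d)
            if twist:
                R = Rotation.from_rotvec(math.radians(twist) * d).as_matrix() @ R
            groups[arm] = local @ R.T + center
            pivots[arm] = pivot

        # clash filter: domains must not interpenetrate
        spacing_proxy = _bead_radius(spec)
        if (
            _min_interdomain_distance(list(groups.values())) > 2.0 * spacing_proxy
            or sum(bead_counts.values()) == len(bead_counts)  # point domains
        ):
            coords = np.concatenate([groups["arm1"], groups["arm2"], groups["Fc"]])
            idx: dict[str, np.ndarray] = {}
            off = 0
            for name in ("arm1", "arm2", "Fc"):
                idx[name] = np.arange(off, off + len(groups[name]))
                off += len(groups[name])
            model = AtomicModel(
                coords,
                f=np.full(len(coords), spec.bead_scattering_length),
                hinge_pivots=pivots,
                bead_radius=spacing_proxy,
            )
            # Fa = arm whose COM is farther from the Fc COM
            com_fc = groups["Fc"].mean(axis=0)
            d1 = np.linalg.norm(groups["arm1"].mean(axis=0) - com_fc)
            d2 = np.linalg.norm(groups["arm2"].mean(axis=0) - com_fc)
            fa, fb = ("arm1", "arm2") if d1 >= d2 else ("arm2", "arm1")
            part = DomainPartition({"Fa": idx[fa], "Fb": idx[fb], "Fc": idx["Fc"]})
            model.hinge_pivots = {"Fa": pivots[fa], "Fb": pivots[fb]}
            return model, part
    raise ClashError("no clash-free surrogate geometry found")


def _bead_radius(spec: SurrogateSpec) -> float:
    """Half the typical lattice spacing; used as contact distance proxy."""
    name = max(spec.beads_per_domain, key=spec.beads_per_domain.get)
    a, b, c = spec.domain_shape[name]
    n = spec.beads_per_domain[name]
    vol = 4.0 / 3.0 * math.pi * max(a, 1e-6) * max(b, 1e-6) * max(c, 1e-6)
    return 0.5 * (vol / n) ** (1.0 / 3.0)


def sample_conformers(
    template: AtomicModel,
    partition: DomainPartition,
    hinge_ranges: Mapping[str, Mapping[str, tuple[float, float]]],
    n: int,
    seed: int = 0,
    max_attempts: int = 50,
) -> list[AtomicModel]:
    """Sample n clash-filtered conformers by rigid arm rotations.

    ``hinge_ranges`` gives per-arm uniform sampling intervals (degrees) for
    the bend and twist deltas relative to the template, e.g.
    ``{"Fa": {"bend": (-30, 30), "twist": (-60, 60)}}``.  Domains remain
    internally rigid (rotations are exactly distance-preserving).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not template.hinge_pivots:
        raise ValueError("template has no hinge pivots")
    rng = np.random.default_rng(seed)
    clash_dist = 2.0 * (template.bead_radius or 1.0)
    unknown = set(hinge_ranges) - set(template.hinge_pivots)
    if unknown:
        raise ValueError(f"hinge_ranges for unknown arms: {sorted(unknown)}")
    arm_labels = [lab for lab in partition.labels if lab in template.hinge_pivots]
    fixed_labels = [lab for lab in partition.labels if lab not in template.hinge_pivots]
    out: list[AtomicModel] = []
    for _ in range(n):
        for _try in range(max_attempts):
            coords = template.coords.copy()
            for lab in arm_labels:
                rg_ = hinge_ranges.get(lab, {})
                db = rng.uniform(*rg_["bend"]) if "bend" in rg_ else 0.0
                dt = rng.uniform(*rg_["twist"]) if "twist" in rg_ else 0.0
                idx = partition[lab]
                pivot = template.hinge_pivots[lab]
                u = coords[idx].mean(axis=0) - pivot
                nu = np.linalg.norm(u)
                u = u / nu if nu > 1e-9 else np.array([0.0, 1.0, 0.0])
                e_b = np.cross(u, [0.0, 1.0, 0.0])
                nb = np.linalg.norm(e_b)
                e_b = e_b / nb if nb > 1e-9 else np.array([1.0, 0.0, 0.0])
                R = (
                    Rotation.from_rotvec(math.radians(dt) * u).as_matrix()
                    @ Rotation.from_rotvec(math.radians(db) * e_b).as_matrix()
                )
                coords[idx] = (coords[idx] - pivot) @ R.T + pivot
            groups = [coords[partition[lab]] for lab in arm_labels + fixed_labels]
            if len(groups) < 2 or _min_interdomain_distance(groups) > clash_dist:
                out.append(template.with_coords(coords))
                break
        else:
            raise ClashError(
                f"no clash-free conformer found in {max_attempts} attempts "
                f"(ranges too wide or clash distance {clash_dist:.2f} A too large)"
            )
    return out


def simulate_profile(
    model: AtomicModel,
    q_grid: np.ndarray,
    noise: NoiseSpec | None = None,
    metadata: dict | None = None,
) -> ScatteringProfile:
    """Noisy Debye profile of a model: I = I_debye + N(0, sigma(q))."""
    noise = noise or NoiseSpec()
    noise.validate()
    clean = debye_profile(model, q_grid, form_factor_mode="model")
    sig = noise.sigma(clean.q, clean.I)
    rng = np.random.default_rng(noise.seed)
    intensity = clean.I + rng.normal(0.0, 1.0, size=len(clean)) * sig
    md = dict(metadata or {})
    md.setdefault("source", "synthetic")
    return ScatteringProfile(clean.q, intensity, sig, md)


def _mix_profiles(
    q: np.ndarray,
    curves: Sequence[np.ndarray],
    weights: Sequence[float],
    noise: NoiseSpec,
    rng: np.random.Generator,
    metadata: dict,
) -> ScatteringProfile:
    mixed = np.zeros_like(q)
    for w, c in zip(weights, curves):
        mixed = mixed + w * c
    sig = noise.sigma(q, mixed)
    intensity = mixed + rng.normal(0.0, 1.0, size=len(q)) * sig
    return ScatteringProfile(q, intensity, sig, metadata)


def unfolded_fraction(temperature: float, midpoint: float, width: float = 4.0) -> float:
    """Logistic unfolded population; 0.5 exactly at the midpoint."""
    return 1.0 / (1.0 + math.exp(-(temperature - midpoint) / width))


def simulate_temperature_series(
    template: AtomicModel,
    temperatures: Sequence[float],
    q_grid: np.ndarray,
    unfold_midpoint: float = 75.0,
    transition_width: float = 4.0,
    expansion_factor: float = 1.6,
    noise: NoiseSpec | None = None,
    seed: int = 0,
) -> list[ScatteringProfile]:
    """Temperature series mixing folded and isotropically expanded states.

    The folded state is stable far below the midpoint; above it the
    population shifts to a coil-like state modelled by scaling all
    coordinates about the centre of mass by ``expansion_factor``.
    """
    temps = list(temperatures)
    if any(b < a for a, b in zip(temps, temps[1:])):
        raise ValueError("temperatures must be sorted ascending")
    if expansion_factor <= 1.0:
        raise ValueError("expansion_factor must exceed 1 (expanded state is larger)")
    noise = noise or NoiseSpec()
    noise.validate()
    com = template.coords.mean(axis=0)
    expanded = template.with_coords(com + expansion_factor * (template.coords - com))
    I_fold = debye_profile(template, q_grid, form_factor_mode="model").I
    I_exp = debye_profile(expanded, q_grid, form_factor_mode="model").I
    rng = np.random.default_rng(seed)
    out = []
    for T in temps:
        f = unfolded_fraction(T, unfold_midpoint, transition_width)
        out.append(
            _mix_profiles(
                np.asarray(q_grid, float),
                [I_fold, I_exp],
                [1.0 - f, f],
                noise,
                rng,
                {"temperature": T, "unfolded_fraction": f, "source": "synthetic"},
            )
        )
    return out


def make_dimer(template: AtomicModel, gap: float = 2.0) -> AtomicModel:
    """Clash-free side-by-side dimer: second copy shifted along x."""
    x = template.coords[:, 0]
    shift = (x.max() - x.min()) + 2.0 * (template.bead_radius or 1.0) + gap
    coords = np.concatenate([template.coords, template.coords + [shift, 0.0, 0.0]])
    return AtomicModel(coords, f=np.concatenate([template.f, template.f]))


def default_dimer_fraction(
    c: float, onset: float = 4.0, slope: float = 0.12, fmax: float = 0.72
) -> float:
    """Aggregation stand-in: no dimer below the onset concentration, then a
    linear rise (mg/ml units)."""
    return float(np.clip(slope * (c - onset), 0.0, fmax))


def simulate_concentration_series(
    template: AtomicModel,
    concentrations: Sequence[float],
    q_grid: np.ndarray,
    dimer_fraction_fn: Callable[[float], float] = default_dimer_fraction,
    noise: NoiseSpec | None = None,
    seed: int = 0,
) -> list[ScatteringProfile]:
    """Concentration series with an aggregating (dimer) fraction.

    Each profile is I = (1-f) I_monomer + f I_dimer with f = f(c); the whole
    curve is additionally scaled by the concentration (intensity per volume
    is proportional to particle number).
    """
    if any(c <= 0 for c in concentrations):
        raise ValueError("concentrations must be positive")
    noise = noise or NoiseSpec()
    noise.validate()
    dimer = make_dimer(template)
    I_mono = debye_profile(template, q_grid, form_factor_mode="model").I
    I_dim = debye_profile(dimer, q_grid, form_factor_mode="model").I
    rng = np.random.default_rng(seed)
    out = []
    for c in concentrations:
        f = float(dimer_fraction_fn(c))
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"dimer fraction {f} outside [0, 1] at c={c}")
        prof = _mix_profiles(
            np.asarray(q_grid, float),
            [c * I_mono, c * I_dim],
            [1.0 - f, f],
            noise,
            rng,
            {"concentration": c, "dimer_fraction": f, "source": "synthetic"},
        )
        out.append(prof)
    return out
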