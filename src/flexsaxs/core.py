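"""Core data containers shared across the package.

The package works at coarse (bead / C-alpha) resolution throughout: an
:class:`AtomicModel` is a cloud of point scatterers with per-point scattering
lengths, optionally labelled by rigid domain.  A :class:`ScatteringProfile`
is a 1-D SAXS curve I(q) with experimental uncertainties.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = ["ScatteringProfile", "AtomicModel", "DomainPartition"]


@dataclass
class ScatteringProfile:
    """A 1-D scattering curve.

    Parameters
    ----------
    q : ndarray
        Momentum transfer grid in 1/Angstrom, strictly increasing, q > 0.
    I : ndarray
        Scattered intensity, arbitrary units.
    sigma : ndarray
        One-standard-deviation uncertainty on ``I``, same units.
    metadata : dict
        Free-form sample annotations (concentration in mg/ml, temperature in
        degrees C, buffer id, additive id, ...).
    """

    q: np.ndarray
    I: np.ndarray
    sigma: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.I = np.asarray(self.I, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (self.q.shape == self.I.shape == self.sigma.shape):
            raise ValueError("q, I, sigma must have identical shapes")
        if self.q.ndim != 1 or self.q.size == 0:
            raise ValueError("profile must be a non-empty 1-D curve")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q grid must be strictly increasing")
        finite = np.isfinite(self.sigma)
        if np.any(self.sigma[finite] <= 0):
            raise ValueError("sigma must be positive where defined")

    def __len__(self) -> int:
        return self.q.size

    def copy(self) -> "ScatteringProfile":
        return ScatteringProfile(
            self.q.copy(), self.I.copy(), self.sigma.copy(), dict(self.metadata)
        )

    def restrict(self, qmin: float = -np.inf, qmax: float = np.inf) -> "ScatteringProfile":
        """Return the sub-profile with qmin <= q <= qmax."""
        m = (self.q >= qmin) & (self.q <= qmax)
        if not np.any(m):
            raise ValueError("empty q range after restriction")
        return ScatteringProfile(self.q[m], self.I[m], self.sigma[m], dict(self.metadata))


@dataclass
class DomainPartition:
    """Mapping of rigid-domain labels to atom index arrays.

    Labels are free-form but the antibody convention used throughout the
    package is ``Fa``/``Fb`` for the two Fab arms (Fa being the arm whose
    centre of mass lies farther from the Fc) and ``Fc`` for the stem.
    Optional sub-module selectors (VL/VH/CL/CH1) may be nested per arm.
    """

    domains: Mapping[str, np.ndarray]
    submodules: Mapping[str, Mapping[str, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.domains = {k: np.asarray(v, dtype=int) for k, v in self.domains.items()}
        all_idx = np.concatenate([v for v in self.domains.values()]) if self.domains else np.array([], int)
        if all_idx.size != np.unique(all_idx).size:
            raise ValueError("domain index sets must be disjoint")

    @property
    def labels(self) -> list[str]:
        return list(self.domains)

    def __getitem__(self, label: str) -> np.ndarray:
        return self.domains[label]

    def n_atoms(self) -> int:
        return sum(v.size for v in self.domains.values())

    def relabel(self, mapping: Mapping[str, str]) -> "DomainPartition":
        return DomainPartition(
            {mapping.get(k, k): v for k, v in self.domains.items()},
            {mapping.get(k, k): v for k, v in self.submodules.items()},
        )


@dataclass
class AtomicModel:
    """A point-scatterer model (beads or C-alpha traces).

    ``coords`` are Cartesian positions in Angstrom; ``f`` are per-point
    scattering lengths (arbitrary units, all equal for bead models);
    ``elements`` are optional element symbols used when a per-element form
    factor table is requested.
    """

    coords: np.ndarray
    f: np.ndarray | None = None
    elements: list[str] | None = None
    hinge_pivots: Mapping[str, np.ndarray] = field(default_factory=dict)
    bead_radius: float | None = None

    def __post_init__(self) -> None:
        self.coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if self.coords.shape[1] != 3 or self.coords.shape[0] == 0:
            raise ValueError("coords must be a non-empty (N, 3) array")
        if self.f is None:
            self.f = np.ones(len(self.coords))
        else:
            self.f = np.asarray(self.f, dtype=float)
            if self.f.shape != (len(self.coords),):
                raise ValueError("f must have one entry per coordinate")
        self.hinge_pivots = {k: np.asarray(v, dtype=float) for k, v in self.hinge_pivots.items()}

    def __len__(self) -> int:
        return len(self.coords)

    def copy(self) -> "AtomicModel":
        return replace(
            self,
            coords=self.coords.copy(),
            f=self.f.copy(),
            elements=list(self.elements) if self.elements is not None else None,
            hinge_pivots={k: v.copy() for k, v in self.hinge_pivots.items()},
        )

    def with_coords(self, coords: np.ndarray) -> "AtomicModel":
        out = self.copy()
        out.coords = np.asarray(coords, dtype=float)
        if out.coords.shape != self.coords.shape:
            raise ValueError("replacement coordinates must keep the shape")
        return out

    def com(self, weights: np.ndarray | None = None) -> np.ndarray:
        w = self.f if weights is None else weights
        return np.average(self.coords, axis=0, weights=w)

    def rg(self, mass_weighted: bool = True) -> float:
        """Radius of gyration, sqrt(sum w |r - rbar|^2 / sum w)."""
        w = self.f if mass_weighted else np.ones(len(self))
        c = np.average(self.coords, axis=0, weights=w)
        d2 = np.sum((self.coords - c) ** 2, axis=1)
        return float(np.sqrt(np.average(d2, weights=w)))

    def dmax(self) -> float:
        """Maximum intra-particle distance (exact over all pairs)."""
        from scipy.spatial.distance import pdist

        if len(self) == 1:
            return 0.0
        return float(pdist(self.coords).max())
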