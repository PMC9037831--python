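"""PCA and hierarchical clustering over profile and feature matrices, plus
condition-trend statistics (size vs concentration correlations).

Profiles are compared as rows of log I(q); geometric features (mixed units:
Angstrom, degrees, square Angstrom) are z-scored before PCA.  Component
signs follow a fixed convention — the largest-magnitude loading of each
component is positive — so score plots are reproducible run to run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import pearsonr
from sklearn.decomposition import PCA as _SKPCA

from .core import ScatteringProfile

__all__ = [
    "PCAResult",
    "pca",
    "profile_matrix",
    "hierarchical_cluster",
    "size_vs_concentration",
]

log = logging.getLogger(__name__)


@dataclass
class PCAResult:
    loadings: np.ndarray  # (n_features, n_components)
    scores: np.ndarray  # (n_obs, n_components)
    explained: np.ndarray  # variance fractions, non-increasing
    preprocessing: dict

    def reconstruct(self) -> np.ndarray:
        """Centered (and scaled, if requested) data from all components."""
        return self.scores @ self.loadings.T


def pca(
    matrix: np.ndarray,
    center: bool = True,
    scale: bool = False,
    n_components: int | None = None,
) -> PCAResult:
    """Principal component analysis of rows-as-observations data.

    ``scale=True`` autoscales columns (correlation-matrix PCA), which is
    the default choice for feature matrices with mixed units; profile
    matrices are typically centered only.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows and columns")
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix contains non-finite entries")
    mean = X.mean(axis=0) if center else np.zeros(X.shape[1])
    Xc = X - mean
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant column: cannot autoscale")
        Xc = Xc / sd
    else:
        sd = np.ones(X.shape[1])
    k = n_components or min(Xc.shape[0] - 1, Xc.shape[1])
    model = _SKPCA(n_components=k, svd_solver="full")
    scores = model.fit_transform(Xc)
    loadings = model.components_.T  # (n_features, k)
    # deterministic sign: largest-|loading| element of each PC positive
    for c in range(loadings.shape[1]):
        j = int(np.argmax(np.abs(loadings[:, c])))
        if loadings[j, c] < 0:
            loadings[:, c] = -loadings[:, c]
            scores[:, c] = -scores[:, c]
    return PCAResult(
        loadings=loadings,
        scores=scores,
        explained=model.explained_variance_ratio_,
        preprocessing={"center": center, "scale": scale, "mean": mean, "sd": sd},
    )


def profile_matrix(
    profiles: list[ScatteringProfile],
    q_range: tuple[float, float] | None = None,
) -> tuple[np.ndarray, list[dict], list[int]]:
    """Stack log-intensity rows for profile PCA.

    Returns (matrix, metadata per kept row, indices of excluded profiles).
    Rows with non-positive intensities in range are excluded with a log
    message (they cannot be log-transformed), mirroring the practice of
    dropping wildly deviating samples before comparative analysis.
    """
    if not profiles:
        raise ValueError("no profiles")
    q0 = profiles[0].q
    mask = np.ones_like(q0, bool)
    if q_range is not None:
        mask = (q0 >= q_range[0]) & (q0 <= q_range[1])
        if not np.any(mask):
            raise ValueError("empty q range")
    rows, meta, excluded = [], [], []
    for i, p in enumerate(profiles):
        if not np.array_equal(p.q, q0):
            raise ValueError("profiles must share one q grid")
        sub = p.I[mask]
        if np.any(sub <= 0):
            log.info("profile %d excluded: non-positive intensities in range", i)
            excluded.append(i)
            continue
        rows.append(np.log(sub))
        meta.append(dict(p.metadata))
    if not rows:
        raise ValueError("all profiles excluded")
    return np.stack(rows), meta, excluded


def hierarchical_cluster(
    distance_matrix: np.ndarray,
    linkage_method: str = "average",
    threshold: float = 1.0,
) -> np.ndarray:
    """Agglomerative clustering of a precomputed distance matrix, cut at
    ``threshold``; returns integer labels (0-based)."""
    D = np.asarray(distance_matrix, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("need a square distance matrix")
    if np.any(D < 0) or np.any(np.abs(np.diag(D)) > 1e-12):
        raise ValueError("need a non-negative matrix with zero diagonal")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    Z = linkage(squareform(D, checks=False), method=linkage_method)
    return fcluster(Z, t=threshold, criterion="distance") - 1


def size_vs_concentration(
    series: list[dict],
) -> dict[str, float | None]:
    """Pearson correlation of each size metric against concentration.

    ``series`` rows are dicts with 'concentration' plus any of 'rg',
    'dmax'.  Zero-variance metrics yield None (flagged undefined).
    """
    if len(series) < 3:
        raise ValueError("need at least 3 points for a trend")
    conc = np.array([row["concentration"] for row in series], dtype=float)
    out: dict[str, float | None] = {}
    for key in ("rg", "dmax"):
        if not all(key in row for row in series):
            continue
        vals = np.array([row[key] for row in series], dtype=float)
        if np.std(vals) == 0 or np.std(conc) == 0:
            out[key] = None
            continue
        out[key] = float(pearsonr(conc, vals)[0])
    return out
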