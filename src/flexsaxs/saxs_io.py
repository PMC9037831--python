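"""Profile and model I/O plus the data-reduction steps: frame averaging
with outlier rejection, buffer subtraction, and concentration-series
merging.

Profiles are 3-column whitespace-delimited text (q, I, sigma) with
"#"-prefixed comment headers; ``key = value`` header lines are parsed into
metadata.  Models travel as PDB through biotite, one chain per domain
(A = Fa, B = Fb, C = Fc).

Reduction never resamples: q grids must match exactly, so no hidden
smoothing enters the data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .core import AtomicModel, DomainPartition, ScatteringProfile

__all__ = [
    "FrameSet",
    "read_profile",
    "write_profile",
    "read_model_pdb",
    "write_model_pdb",
    "average_frames",
    "subtract_buffer",
    "merge_concentration_series",
]

log = logging.getLogger(__name__)

SIGMA_FALLBACK_FRACTION = 0.03  # imputed sigma = 3% of I for 2-column files


@dataclass
class FrameSet:
    """Repeated exposures of one sample on a shared q grid."""

    frames: list[ScatteringProfile]
    exposure: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("FrameSet needs at least one frame")
        q0 = self.frames[0].q
        for fr in self.frames[1:]:
            if not np.array_equal(fr.q, q0):
                raise ValueError("all frames must share one q grid")

    def __len__(self) -> int:
        return len(self.frames)


def read_profile(path: str | Path, dialect: str = "generic-dat") -> ScatteringProfile:
    """Read a 3-column text profile (SASBDB ".dat" style).

    Header/comment lines (starting with '#' or non-numeric) are skipped;
    ``# key = value`` lines populate metadata.  Rows with non-finite values
    are dropped (count logged).  Two-column files get sigma imputed as
    ``SIGMA_FALLBACK_FRACTION * |I|`` with a warning.
    """
    if dialect not in ("generic-dat", "sasbdb-dat"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    metadata: dict = {}
    rows: list[list[float]] = []
    ncol = None
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                k, _, v = body.partition("=")
                k, v = k.strip(), v.strip()
                try:
                    metadata[k] = float(v)
                except ValueError:
                    metadata[k] = v
            continue
        parts = line.split()
        try:
            vals = [float(p) for p in parts]
        except ValueError:
            continue  # textual header without '#'
        if len(vals) < 2:
            raise ValueError(f"{path}: fewer than 2 numeric columns")
        if ncol is None:
            ncol = min(len(vals), 3)
        rows.append(vals[:ncol])
    if not rows:
        raise ValueError(f"{path}: no numeric data")
    arr = np.array(rows, dtype=float)
    finite = np.all(np.isfinite(arr), axis=1)
    dropped = int((~finite).sum())
    if dropped:
        log.info("%s: dropped %d rows with non-finite values", path, dropped)
    arr = arr[finite]
    q, intensity = arr[:, 0], arr[:, 1]
    if arr.shape[1] >= 3:
        sigma = arr[:, 2]
    else:
        warnings.warn(
            f"{path}: no sigma column; imputing "
            f"{SIGMA_FALLBACK_FRACTION:.0%} of |I|",
            stacklevel=2,
        )
        sigma = SIGMA_FALLBACK_FRACTION * np.abs(intensity)
    if np.any(np.diff(q) <= 0):
        raise ValueError(f"{path}: q not strictly increasing")
    return ScatteringProfile(q, intensity, sigma, metadata)


def write_profile(path: str | Path, profile: ScatteringProfile) -> None:
    """Write q, I, sigma as whitespace-delimited text with metadata header."""
    path = Path(path)
    lines = ["# flexsaxs scattering profile"]
    for k, v in profile.metadata.items():
        lines.append(f"# {k} = {v}")
    for qi, ii, si in zip(profile.q, profile.I, profile.sigma):
        lines.append(f"{qi:.17e} {ii:.17e} {si:.17e}")
    path.write_text("\n".join(lines) + "\n")


_CHAIN_FOR_DOMAIN = {"Fa": "A", "Fb": "B", "Fc": "C"}


def write_model_pdb(
    path: str | Path,
    model: AtomicModel,
    partition: DomainPartition | None = None,
) -> None:
    """Write a bead/C-alpha model as PDB, one chain per domain."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = len(model)
    atoms = struc.AtomArray(n)
    atoms.coord = model.coords.astype(np.float32)
    atoms.atom_name = np.full(n, "CA")
    atoms.res_name = np.full(n, "GLY")
    atoms.element = np.full(n, "C")
    atoms.res_id = np.arange(1, n + 1)
    chain = np.full(n, "A", dtype="U4")
    if partition is not None:
        for lab, idx in partition.domains.items():
            chain[idx] = _CHAIN_FOR_DOMAIN.get(lab, lab[:1].upper())
    atoms.chain_id = chain
    f = pdb.PDBFile()
    f.set_structure(atoms)
    f.write(str(path))


def read_model_pdb(path: str | Path) -> tuple[AtomicModel, DomainPartition]:
    """Read a PDB into an AtomicModel; chains become domain labels."""
    import biotite.structure.io.pdb as pdb

    f = pdb.PDBFile.read(str(path))
    atoms = f.get_structure(model=1)
    coords = np.asarray(atoms.coord, dtype=float)
    elements = [str(e).capitalize() for e in atoms.element]
    inv = {v: k for k, v in _CHAIN_FOR_DOMAIN.items()}
    domains = {}
    for ch in np.unique(atoms.chain_id):
        domains[inv.get(str(ch), str(ch))] = np.where(atoms.chain_id == ch)[0]
    return AtomicModel(coords, elements=elements), DomainPartition(domains)


def average_frames(
    frames: FrameSet | Sequence[ScatteringProfile],
    reject_threshold: float = 0.995,
) -> ScatteringProfile:
    """Average repeated frames, rejecting radiation-damaged outliers.

    A frame is kept if the Pearson correlation between its intensities and
    the pointwise-median frame is >= ``reject_threshold``.  The average is
    the plain mean over kept frames with propagated uncertainty
    sigma = sqrt(sum sigma_i^2) / n_kept.
    """
    if not isinstance(frames, FrameSet):
        frames = FrameSet(list(frames))
    I_mat = np.stack([fr.I for fr in frames.frames])
    S_mat = np.stack([fr.sigma for fr in frames.frames])
    if len(frames) == 1:
        return frames.frames[0].copy()
    ref = np.median(I_mat, axis=0)
    keep = []
    for i, row in enumerate(I_mat):
        r = np.corrcoef(row, ref)[0, 1]
        if not np.isfinite(r) or r < reject_threshold:
            log.info("frame %d rejected (correlation %.5f)", i, r)
        else:
            keep.append(i)
    if not keep:
        raise ValueError("all frames rejected by the correlation filter")
    kept_I = I_mat[keep]
    kept_S = S_mat[keep]
    nk = len(keep)
    md = dict(frames.frames[0].metadata)
    md["n_frames_kept"] = nk
    md["n_frames_rejected"] = len(frames) - nk
    return ScatteringProfile(
        frames.frames[0].q,
        kept_I.mean(axis=0),
        np.sqrt(np.sum(kept_S**2, axis=0)) / nk,
        md,
    )


def subtract_buffer(
    sample: ScatteringProfile, buffer: ScatteringProfile
) -> ScatteringProfile:
    """Background subtraction: I = I_s - I_b, sigma = sqrt(s_s^2 + s_b^2).

    Grids must match exactly; no interpolation is performed.
    """
    if not np.array_equal(sample.q, buffer.q):
        raise ValueError("sample and buffer q grids differ; refusing to interpolate")
    return ScatteringProfile(
        sample.q,
        sample.I - buffer.I,
        np.sqrt(sample.sigma**2 + buffer.sigma**2),
        dict(sample.metadata),
    )


def _fit_scale(I_low: np.ndarray, I_high: np.ndarray, sigma_high: np.ndarray) -> float:
    """Error-weighted least-squares scale s minimizing |I_high - s I_low|.

    s is the ratio of the higher-concentration profile to the lower one;
    the merged curve divides the high-concentration data by s.
    """
    w = 1.0 / (sigma_high**2 + 1e-300)
    den = float(np.sum(w * I_low**2))
    if den <= 0:
        raise ValueError("degenerate overlap window")
    return float(np.sum(w * I_high * I_low)) / den


def merge_concentration_series(
    profiles: Sequence[ScatteringProfile],
    overlap_window: tuple[float, float] | None = None,
    crossover_q: float | None = None,
) -> ScatteringProfile:
    """Merge a low-to-high concentration series into one profile.

    Consecutive pairs are merged iteratively: a scale factor between the
    current merged (low-concentration) curve and the next profile is fitted
    on the overlapping q window by error-weighted least squares; the merged
    curve keeps the low-concentration data below a crossover q and the
    scaled high-concentration data above it.  The crossover is chosen where
    the smoothed scaled discrepancy across the window is smallest, or can
    be fixed via ``crossover_q``.

    Low concentrations contribute the low-q region (weakest inter-particle
    interference); high concentrations the high-q region (best statistics).
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("need at least two profiles to merge")
    merged = profiles[0].copy()
    for nxt in profiles[1:]:
        qlo = max(merged.q[0], nxt.q[0])
        qhi = min(merged.q[-1], nxt.q[-1])
        if overlap_window is not None:
            qlo, qhi = max(qlo, overlap_window[0]), min(qhi, overlap_window[1])
        m_low = (merged.q >= qlo) & (merged.q <= qhi)
        if not np.any(m_low):
            raise ValueError("empty overlap window between consecutive profiles")
        qs = merged.q[m_low]
        if not np.array_equal(qs, nxt.q[(nxt.q >= qlo) & (nxt.q <= qhi)]):
            raise ValueError("profiles must share the q grid on the overlap")
        m_high = (nxt.q >= qlo) & (nxt.q <= qhi)
        scale = _fit_scale(merged.I[m_low], nxt.I[m_high], nxt.sigma[m_high])
        disc = np.abs(merged.I[m_low] - nxt.I[m_high] / scale) / merged.sigma[m_low]
        k = min(5, len(disc))
        smooth = np.convolve(disc, np.ones(k) / k, mode="same")
        if crossover_q is not None:
            if not (qlo <= crossover_q <= qhi):
                raise ValueError("crossover_q outside the overlap window")
            xq = crossover_q
        else:
            xq = float(qs[int(np.argmin(smooth))])
        lo_part = merged.q <= xq
        hi_part = nxt.q > xq
        md = dict(merged.metadata)
        md.setdefault("merge_scales", []).append(scale)
        md.setdefault("merge_crossovers", []).append(xq)
        merged = ScatteringProfile(
            np.concatenate([merged.q[lo_part], nxt.q[hi_part]]),
            np.concatenate([merged.I[lo_part], nxt.I[hi_part] / scale]),
            np.concatenate([merged.sigma[lo_part], nxt.sigma[hi_part] / scale]),
            md,
        )
    return merged
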