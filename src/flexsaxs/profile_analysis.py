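"""Model-free SAXS invariants: Guinier fit, normalized Kratky curve,
regularized indirect Fourier transform to P(r), Dmax scanning, peaks.

The indirect Fourier transform expands the pair distance distribution in a
Moore-type sine basis applied to P(r)/r,

    P(r) = r * sum_n a_n sin(n pi r / Dmax),        0 <= r <= Dmax,

(the division by r is what makes the Debye-transform of each basis function
elementary); the reciprocal-space image is then available in closed form,

    I(q) = 4 pi sum_n a_n psi_n(q),
    psi_n(q) = (-1)^(n+1) sin(q D) (n pi / D) / (q ((n pi / D)^2 - q^2)).

The coefficients (plus an optional constant background) minimize

    sum_k [(I_obs - I_model - b) / sigma]^2 + alpha * sum_i |D2 P|_i,

where D2 is the discrete second derivative of P on the r grid.  The L1
smoothness penalty is minimized by iteratively reweighted least squares,
which is deterministic and keeps P(r) piecewise-smooth without forcing it
positive.  P(0) = P(Dmax) = 0 hold by construction of the basis.

Derived invariants:  Rg^2 = int r^2 P dr / (2 int P dr),
I(0) = 4 pi int P dr.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .core import ScatteringProfile

__all__ = [
    "GuinierResult",
    "PairDistribution",
    "DmaxScanResult",
    "guinier_fit",
    "kratky_normalized",
    "ift_pr",
    "scan_dmax",
    "pr_peaks",
]

log = logging.getLogger(__name__)


@dataclass
class GuinierResult:
    """Result of the self-consistent Guinier fit ln I = ln I0 - (q Rg)^2/3."""

    Rg: float
    I0: float
    Rg_stderr: float
    i_min: int
    i_max: int  # inclusive window [i_min, i_max]
    qmin_Rg: float
    qmax_Rg: float
    residuals: np.ndarray  # standardized residuals over the window


@dataclass
class PairDistribution:
    """P(r) on [0, Dmax] with regularization metadata and derived invariants."""

    r: np.ndarray
    P: np.ndarray
    Dmax: float
    alpha: float
    background: float
    Rg: float
    I0: float
    coefficients: np.ndarray = field(default_factory=lambda: np.array([]))
    chi2_reduced: float = float("nan")
    # the reciprocal-space fit used to produce P(r); reusable as a smoothed
    # (regularized) version of the input data
    q: np.ndarray = field(default_factory=lambda: np.array([]))
    I_fit: np.ndarray = field(default_factory=lambda: np.array([]))
    sigma: np.ndarray = field(default_factory=lambda: np.array([]))

    def regularized_profile(self) -> ScatteringProfile:
        """The IFT-smoothed intensity, on the grid the fit used."""
        if self.q.size == 0:
            raise ValueError("this PairDistribution carries no fit curve")
        return ScatteringProfile(
            self.q, self.I_fit, self.sigma, {"source": "ift-regularized"}
        )


@dataclass
class DmaxScanResult:
    dmax_grid: np.ndarray
    scores: np.ndarray  # per-Dmax max-over-alpha score in [0, 1]
    best_alpha: np.ndarray
    optimal_dmax: float
    suggested_qmax: float


# ---------------------------------------------------------------- Guinier


def guinier_fit(
    profile: ScatteringProfile,
    qRg_limit: float = 1.3,
    min_points: int = 10,
    max_low_q_trim: int = 5,
    max_iter: int = 60,
    chi2_window_limit: float = 2.0,
) -> GuinierResult:
    """Weighted linear fit of ln I vs q^2 on a self-consistent window.

    Starting from the first ``min_points`` points, Rg is estimated and the
    window grown/shrunk to the widest range with q*Rg <= ``qRg_limit``,
    iterating to a fixed point.  Two guards keep the window honest: a low-q
    guard trims up to ``max_low_q_trim`` leading points while the first
    point's standardized residual exceeds +3 (the upturn signature of
    aggregation), and a linearity guard shrinks the window from the high-q
    side while the fit's reduced chi^2 exceeds ``chi2_window_limit`` (so
    systematic curvature beyond the Guinier regime cannot bias Rg when the
    statistical errors are small).
    """
    pos = profile.I > 0
    if pos[: min_points + 2].sum() <= min_points:
        raise ValueError("not enough positive low-q points for a Guinier fit")
    q, intensity, sigma = profile.q, profile.I, profile.sigma

    def _fit(i0: int, i1: int) -> tuple[float, float, float, np.ndarray]:
        sl = slice(i0, i1 + 1)
        x = q[sl] ** 2
        y = np.log(intensity[sl])
        w = (intensity[sl] / sigma[sl]) ** 2  # var(ln I) = (sigma/I)^2
        W = np.sum(w)
        xb = np.sum(w * x) / W
        yb = np.sum(w * y) / W
        sxx = np.sum(w * (x - xb) ** 2)
        slope = np.sum(w * (x - xb) * (y - yb)) / sxx
        inter = yb - slope * xb
        resid = (y - (inter + slope * x)) * np.sqrt(w)
        slope_var = 1.0 / sxx
        return slope, inter, slope_var, resid

    i0 = 0
    i1 = min_points - 1
    history: list[tuple[int, int]] = []
    for _ in range(max_iter):
        window = slice(i0, i1 + 1)
        if np.any(intensity[window] <= 0):
            raise ValueError("non-positive intensity inside the Guinier window")
        slope, inter, slope_var, resid = _fit(i0, i1)
        if slope >= 0:
            raise ValueError("positive Guinier slope: Rg^2 < 0 (check the data)")
        rg = float(np.sqrt(-3.0 * slope))
        # low-q aggregation guard
        if i0 < max_low_q_trim and resid[0] > 3.0:
            i0 += 1
            continue
        i1_new = int(np.searchsorted(q, qRg_limit / rg, side="right")) - 1
        i1_new = max(i1_new, i0 + min_points - 1)
        i1_new = min(i1_new, len(q) - 1)
        # linearity guard: shrink from high q while curvature dominates
        while i1_new > i0 + min_points - 1:
            sl, it, sv, rs = _fit(i0, i1_new)
            if sl < 0 and np.sum(rs**2) / max(i1_new - i0 - 1, 1) <= chi2_window_limit:
                break
            i1_new -= 1
        if (i0, i1_new) == (i0, i1):
            stderr = float(np.sqrt(slope_var) * 3.0 / (2.0 * rg))
            return GuinierResult(
                Rg=rg,
                I0=float(np.exp(inter)),
                Rg_stderr=stderr,
                i_min=i0,
                i_max=i1,
                qmin_Rg=float(q[i0] * rg),
                qmax_Rg=float(q[i1] * rg),
                residuals=resid,
            )
        if (i0, i1_new) in history:  # limit-cycle: accept the smaller window
            i1 = min(i1, i1_new)
            slope, inter, slope_var, resid = _fit(i0, i1)
            rg = float(np.sqrt(-3.0 * slope))
            stderr = float(np.sqrt(slope_var) * 3.0 / (2.0 * rg))
            return GuinierResult(
                rg, float(np.exp(inter)), stderr, i0, i1,
                float(q[i0] * rg), float(q[i1] * rg), resid,
            )
        history.append((i0, i1))
        i1 = i1_new
    raise ValueError("Guinier window iteration did not converge")


def kratky_normalized(
    profile: ScatteringProfile, Rg: float, I0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Dimensionless Kratky curve: ((q Rg)^2 I/I0) vs (q Rg).

    Compact globular particles peak at q Rg = sqrt(3) with height 3/e;
    shifts of the first peak to larger q Rg flag elongation/flexibility.
    """
    if Rg <= 0 or I0 <= 0:
        raise ValueError("Rg and I0 must be positive")
    x = profile.q * Rg
    return x, x**2 * profile.I / I0


# ---------------------------------------------------------------- Moore IFT


def _moore_design(q: np.ndarray, dmax: float, n_basis: int) -> np.ndarray:
    """Closed-form reciprocal image of the sine basis: columns psi_n(q)."""
    n = np.arange(1, n_basis + 1)
    kn = n * np.pi / dmax  # (n,)
    Q = q[:, None]
    denom = kn[None, :] ** 2 - Q**2
    sign = (-1.0) ** (n + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        psi = sign[None, :] * np.sin(Q * dmax) * kn[None, :] / (Q * denom)
    # resonance q -> kn limit: integral = dmax / (2 q)
    bad = ~np.isfinite(psi) | (np.abs(denom) < 1e-9 * kn[None, :] ** 2)
    if np.any(bad):
        iq, im = np.where(bad)
        psi[iq, im] = dmax / (2.0 * q[iq])
    return 4.0 * np.pi * psi


def _second_diff_matrix(m: int, dr: float) -> np.ndarray:
    D2 = np.zeros((m - 2, m))
    for i in range(m - 2):
        D2[i, i] = 1.0
        D2[i, i + 1] = -2.0
        D2[i, i + 2] = 1.0
    return D2 / dr**2


def ift_pr(
    profile: ScatteringProfile,
    Dmax: float,
    n_basis: int | None = None,
    alpha: float | None = None,
    fit_background: bool = False,
    n_r: int = 201,
    irls_iter: int = 40,
) -> PairDistribution:
    """Regularized indirect Fourier transform to P(r) (Moore basis, L1
    second-derivative smoothness, optional constant background).

    ``alpha = None`` selects the regularization weight at the corner of the
    chi^2-vs-penalty L-curve.  The fit is performed on internally
    normalized intensities, so the result is exactly equivariant under
    global rescaling of the data.
    """
    if Dmax <= 0:
        raise ValueError("Dmax must be positive")
    if alpha is not None and alpha < 0:
        raise ValueError("alpha must be >= 0")
    q = profile.q
    if n_basis is None:
        # Shannon-channel count plus a small margin; the smoothness penalty
        # keeps the extra coefficients from ringing
        n_basis = max(4, int(np.ceil(q[-1] * Dmax / np.pi)) + 2)
    n_free = n_basis + (1 if fit_background else 0)
    if n_free >= len(q):
        raise ValueError(
            f"underdetermined IFT: {n_free} free parameters vs {len(q)} points"
        )
    scale = float(np.max(np.abs(profile.I)))
    if scale <= 0:
        raise ValueError("profile has no signal")
    y = profile.I / scale
    sig = profile.sigma / scale

    X = _moore_design(q, Dmax, n_basis)
    if fit_background:
        X = np.hstack([X, np.ones((len(q), 1))])
    r = np.linspace(0.0, Dmax, n_r)
    S = r[:, None] * np.sin(np.outer(r, np.arange(1, n_basis + 1)) * np.pi / Dmax)
    L = _second_diff_matrix(n_r, r[1] - r[0]) @ S
    if fit_background:
        L = np.hstack([L, np.zeros((L.shape[0], 1))])
    # scale the penalty operator so alpha is dimensionless-ish across Dmax
    L = L * (Dmax**2 / n_r)

    Xw = X / sig[:, None]
    yw = y / sig

    def _solve(alpha_: float) -> np.ndarray:
        beta = np.linalg.lstsq(Xw, yw, rcond=None)[0]
        if alpha_ == 0:
            return beta
        XtX = Xw.T @ Xw
        Xty = Xw.T @ yw
        eps = 1e-8
        for _ in range(irls_iter):
            w = 1.0 / np.maximum(np.abs(L @ beta), eps)
            A = XtX + alpha_ * (L.T * w) @ L
            beta_new = np.linalg.solve(A, Xty)
            if np.max(np.abs(beta_new - beta)) < 1e-10 * max(1.0, np.max(np.abs(beta))):
                beta = beta_new
                break
            beta = beta_new
        return beta

    if alpha is None:
        alphas = np.logspace(-4, 3, 22)
        pts = []
        for a in alphas:
            b = _solve(a)
            chi2 = float(np.sum((yw - Xw @ b) ** 2))
            pen = float(np.sum(np.abs(L @ b)))
            pts.append((chi2, pen))
        alpha = float(alphas[_lcurve_corner(np.array(pts))])
    beta = _solve(alpha)

    bg = float(beta[-1]) * scale if fit_background else 0.0
    coef = (beta[:-1] if fit_background else beta) * scale
    P = S @ (coef / scale) * scale  # = S @ coef; kept explicit for clarity
    I_fit = (X @ beta) * scale

    trapz = np.trapezoid if hasattr(np, "trapezoid") else np.trapz
    area = trapz(P, r)
    if area <= 0:
        raise ValueError("non-positive total P(r) area; IFT failed")
    rg = float(np.sqrt(trapz(r**2 * P, r) / (2.0 * area)))
    i0 = float(4.0 * np.pi * area)
    dof = max(len(q) - n_free, 1)
    chi2_red = float(np.sum(((profile.I - I_fit - bg) / profile.sigma) ** 2) / dof)
    return PairDistribution(
        r=r,
        P=P,
        Dmax=Dmax,
        alpha=alpha,
        background=bg,
        Rg=rg,
        I0=i0,
        coefficients=coef,
        chi2_reduced=chi2_red,
        q=q.copy(),
        I_fit=I_fit + bg,
        sigma=profile.sigma.copy(),
    )


def _lcurve_corner(pts: np.ndarray) -> int:
    """Index of maximum curvature on the log-log L-curve."""
    x = np.log10(np.maximum(pts[:, 0], 1e-300))
    y = np.log10(np.maximum(pts[:, 1], 1e-300))
    if len(x) < 3:
        return 0
    dx = np.gradient(x)
    dy = np.gradient(y)
    ddx = np.gradient(dx)
    ddy = np.gradient(dy)
    curv = (dx * ddy - dy * ddx) / np.power(dx * dx + dy * dy, 1.5) \
        if np.all(dx * dx + dy * dy > 0) else np.zeros_like(x)
    return int(np.argmax(curv))


# ---------------------------------------------------------------- Dmax scan


def scan_dmax(
    profile: ScatteringProfile,
    dmax_grid: np.ndarray,
    alpha_grid: np.ndarray | None = None,
    negativity_weight: float = 20.0,
    occam_weight: float = 0.25,
    sn_threshold: float = 2.0,
    **ift_kwargs,
) -> DmaxScanResult:
    """Score candidate Dmax values by IFT fit quality.

    For each (Dmax, alpha) the IFT is run and scored

        exp(-chi2_red / 2) * exp(-w_neg * f_neg) * exp(-w_occam * n_basis),

    where f_neg is the fraction of |P| area that is negative and n_basis
    the number of Shannon channels the candidate Dmax requires.  The last
    factor is an evidence-like parsimony term: without it every Dmax above
    the true one fits equally well and the score plateaus; with it the
    smallest Dmax the data support wins.  The per-Dmax score is the max
    over alpha, rescaled so the best candidate scores <= 1.
    The suggested qmax is the largest q at which the smoothed q*I(q)
    signal-to-noise ratio still exceeds ``sn_threshold``.
    """
    dmax_grid = np.asarray(dmax_grid, dtype=float)
    if alpha_grid is None:
        alpha_grid = np.logspace(-2, 2, 5)
    if dmax_grid.size == 0 or len(alpha_grid) == 0:
        raise ValueError("empty scan grids")
    scores = np.zeros(len(dmax_grid))
    best_alpha = np.full(len(dmax_grid), np.nan)
    any_ok = False
    for i, dm in enumerate(dmax_grid):
        for a in alpha_grid:
            try:
                pr = ift_pr(profile, dm, alpha=float(a), **ift_kwargs)
            except (ValueError, np.linalg.LinAlgError):
                continue
            any_ok = True
            neg = float(np.sum(np.abs(pr.P[pr.P < 0])) / max(np.sum(np.abs(pr.P)), 1e-300))
            nb = len(pr.coefficients)
            s = float(
                np.exp(-pr.chi2_reduced / 2.0)
                * np.exp(-negativity_weight * neg)
                * np.exp(-occam_weight * nb)
            )
            if s > scores[i]:
                scores[i] = s
                best_alpha[i] = a
    if not any_ok:
        raise ValueError("all IFT fits failed on the scan grids")
    if scores.max() > 0:
        scores = scores / scores.max()
    sn =(profile.q * profile.I) / (profile.q * profile.sigma)
    k = min(11, len(sn))
    sn_smooth = np.convolve(sn, np.ones(k) / k, mode="same")
    above = np.where(sn_smooth > sn_threshold)[0]
    qmax_sugg = float(profile.q[above[-1]]) if above.size else float(profile.q[-1])
    return DmaxScanResult(
        dmax_grid=dmax_grid,
        scores=scores,
        best_alpha=best_alpha,
        optimal_dmax=float(dmax_grid[int(np.argmax(scores))]),
        suggested_qmax=qmax_sugg,
    )


def pr_peaks(pr: PairDistribution, min_prominence: float = 0.05) -> np.ndarray:
    """Positions (Angstrom) of P(r) local maxima, sorted by r.

    ``min_prominence`` is relative to max(P).
    """
    scale = float(np.max(pr.P))
    if scale <= 0:
        return np.array([])
    idx, _ = find_peaks(pr.P, prominence=min_prominence * scale)
    return pr.r[idx]
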