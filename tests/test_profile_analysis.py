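"""Model-free invariants: Guinier, Kratky, IFT P(r), Dmax scan, peaks."""

import numpy as np
import pytest

from flexsaxs.core import AtomicModel, ScatteringProfile
from flexsaxs.forward_scattering import debye_profile, model_rg
from flexsaxs.profile_analysis import (
    guinier_fit,
    ift_pr,
    kratky_normalized,
    pr_peaks,
    scan_dmax,
)
from flexsaxs.synthetic_data import NoiseSpec, simulate_profile

from conftest import make_profile, sphere_intensity, sphere_pr

RG_SPHERE = np.sqrt(3.0 / 5.0) * 50.0


class TestGuinier:
    def test_sphere_rg_within_half_percent(self, sphere50):
        g = guinier_fit(sphere50)
        assert g.Rg == pytest.approx(RG_SPHERE, rel=0.005)
        assert g.I0 == pytest.approx(1e6, rel=0.01)
        assert g.qmax_Rg <= 1.3 + 1e-9

    def test_scale_invariance(self, sphere50):
        scaled = ScatteringProfile(sphere50.q, 7 * sphere50.I, 7 * sphere50.sigma)
        g1, g7 = guinier_fit(sphere50), guinier_fit(scaled)
        assert g7.Rg == pytest.approx(g1.Rg, rel=1e-12)
        assert g7.I0 == pytest.approx(7 * g1.I0, rel=1e-12)

    def test_surrogate_rg_within_two_percent(self, surrogate):
        model, _ = surrogate
        q = np.linspace(0.002, 0.25, 180)
        prof = simulate_profile(model, q, NoiseSpec(counts_scale=1e30, seed=0))
        g = guinier_fit(prof)
        assert g.Rg == pytest.approx(model_rg(model), rel=0.02)

    def test_rising_low_q_fails_cleanly(self):
        q = np.linspace(0.004, 0.1, 60)
        increasing = make_profile(q, np.exp(+(q * 30) ** 2))
        with pytest.raises(ValueError, match="positive Guinier slope"):
            guinier_fit(increasing)


class TestKratky:
    def test_guinier_limit_identity(self):
        # the dimensionless Kratky peak identity (sqrt(3), 3/e) holds
        # exactly for the Guinier curve I = I0 exp(-(q Rg)^2 / 3)
        q = np.linspace(0.001, 0.2, 2000)
        rg = RG_SPHERE
        prof = make_profile(q, 1e6 * np.exp(-((q * rg) ** 2) / 3.0))
        x, y = kratky_normalized(prof, rg, 1e6)
        i = np.argmax(y)
        assert x[i] == pytest.approx(np.sqrt(3.0), rel=0.02)
        assert y[i] == pytest.approx(3.0 / np.e, rel=0.02)

    def test_flat_profile_gives_parabola(self):
        q = np.linspace(0.01, 0.3, 50)
        prof = make_profile(q, np.full(50, 8.0))
        x, y = kratky_normalized(prof, 20.0, 8.0)
        assert np.allclose(y, x**2)

    def test_dumbbell_peak_beyond_sqrt3(self):
        # two well-separated compact clusters: flexibility/elongation
        # shifts the first normalized-Kratky peak right of sqrt(3)
        rng = np.random.default_rng(0)
        a = rng.normal(0, 8, (150, 3))
        b = rng.normal(0, 8, (150, 3)) + [80, 0, 0]
        m = AtomicModel(np.concatenate([a, b]))
        q = np.linspace(0.002, 0.3, 400)
        prof = debye_profile(m, q, form_factor_mode="uniform")
        prof = ScatteringProfile(prof.q, prof.I, 1e-5 * np.abs(prof.I))
        g = guinier_fit(prof)
        x, y = kratky_normalized(prof, g.Rg, g.I0)
        first_peak = x[np.argmax(y[x < 3.5])]
        assert first_peak > np.sqrt(3.0)


class TestIFT:
    def test_sphere_pr_recovery(self, sphere50):
        pr = ift_pr(sphere50, Dmax=100.0)
        truth = sphere_pr(pr.r, 50.0)
        truth *= np.trapezoid(pr.P, pr.r) / np.trapezoid(truth, pr.r)
        nrmsd = np.sqrt(np.mean((pr.P - truth) ** 2)) / truth.max()
        assert nrmsd < 0.02
        assert pr.Rg == pytest.approx(RG_SPHERE, rel=0.01)
        assert pr.P[0] == 0.0 and pr.P[-1] == pytest.approx(0.0, abs=1e-9)

    def test_endpoints_vanish_by_construction(self, sphere50):
        pr = ift_pr(sphere50, Dmax=120.0, alpha=1.0)
        assert pr.P[0] == 0.0
        assert abs(pr.P[-1]) < 1e-9 * np.max(np.abs(pr.P))

    def test_scale_equivariance(self, sphere50):
        pr1 = ift_pr(sphere50, Dmax=100.0, alpha=0.1)
        scaled = ScatteringProfile(sphere50.q, 7 * sphere50.I, 7 * sphere50.sigma)
        pr7 = ift_pr(scaled, Dmax=100.0, alpha=0.1)
        assert np.max(np.abs(pr7.P - 7 * pr1.P)) < 1e-7 * np.max(np.abs(7 * pr1.P))
        assert pr7.Rg == pytest.approx(pr1.Rg, rel=1e-8)

    def test_invalid_inputs_rejected(self, sphere50):
        with pytest.raises(ValueError):
            ift_pr(sphere50, Dmax=-5.0)
        with pytest.raises(ValueError):
            ift_pr(sphere50, Dmax=100.0, alpha=-1.0)
        with pytest.raises(ValueError, match="underdetermined"):
            ift_pr(sphere50.restrict(qmax=0.02), Dmax=500.0, n_basis=50)

    def test_roundtrip_surrogate_invariants(self, surrogate):
        # Debye profile -> IFT at the true Dmax -> Rg and I0 match the
        # direct-sum values
        model, _ = surrogate
        q = np.linspace(0.002, 0.25, 180)
        prof = simulate_profile(model, q, NoiseSpec(counts_scale=1e30, seed=0))
        pr = ift_pr(prof, Dmax=model.dmax())
        assert pr.Rg == pytest.approx(model_rg(model), rel=0.02)
        assert pr.I0 == pytest.approx(float(np.sum(model.f)) ** 2, rel=0.02)
        # Guinier and P(r) estimates of Rg agree
        g = guinier_fit(prof)
        assert g.Rg == pytest.approx(pr.Rg, rel=0.03)


class TestScanDmax:
    def test_sphere_argmax_at_diameter(self):
        # 1% counting errors: at much tighter errors the score becomes
        # limited by sine-basis truncation rather than by Dmax itself
        q = np.linspace(0.004, 0.30, 400)
        prof = make_profile(q, sphere_intensity(q, 50.0, 1e6), rel_sigma=0.01)
        grid = np.arange(80.0, 130.0, 5.0)
        res = scan_dmax(prof, grid)
        assert abs(res.optimal_dmax - 100.0) <= 5.0
        assert np.all((res.scores >= 0) & (res.scores <= 1.0 + 1e-12))

    def test_noise_broadens_the_score_peak(self, rng):
        q = np.linspace(0.004, 0.3, 300)
        I = sphere_intensity(q, 50.0, 1e6)
        grid = np.arange(80.0, 135.0, 5.0)

        def width(rel):
            sig = rel * I
            prof = ScatteringProfile(q, I + rng.normal(0, sig), sig)
            s = scan_dmax(prof, grid).scores
            return np.sum(s > 0.5 * s.max())

        assert width(0.002) <= width(0.05)

    def test_empty_grid_rejected(self, sphere50):
        with pytest.raises(ValueError):
            scan_dmax(sphere50, np.array([]))


class TestPrPeaks:
    def test_sphere_single_peak_position(self, sphere50):
        pr = ift_pr(sphere50, Dmax=100.0)
        peaks = pr_peaks(pr)
        assert len(peaks) == 1
        # analytic maximum of r^2 gamma(r) sits near 1.05 R
        r_dense = np.linspace(0, 100, 5001)
        expected = r_dense[np.argmax(sphere_pr(r_dense, 50.0))]
        assert peaks[0] == pytest.approx(expected, abs=1.5)

    def test_two_gaussian_fixture(self):
        from flexsaxs.profile_analysis import PairDistribution

        r = np.linspace(0, 150, 301)
        P = np.exp(-((r - 40) ** 2) / 50) + 0.8 * np.exp(-((r - 95) ** 2) / 80)
        pr = PairDistribution(r=r, P=P, Dmax=150, alpha=0, background=0, Rg=0, I0=0)
        peaks = pr_peaks(pr)
        assert len(peaks) == 2
        assert peaks[0] == pytest.approx(40.0, abs=r[1] - r[0])
        assert peaks[1] == pytest.approx(95.0, abs=r[1] - r[0])

    def test_surrogate_two_maxima(self, surrogate):
        # three well-separated domains produce an intra-domain and an
        # inter-domain distance peak
        model, _ = surrogate
        q = np.linspace(0.002, 0.25, 180)
        prof = simulate_profile(model, q, NoiseSpec(counts_scale=1e30, seed=0))
        pr = ift_pr(prof, Dmax=model.dmax())
        peaks = pr_peaks(pr, min_prominence=0.03)
        assert len(peaks) >= 2
        assert peaks[0] < 60 < peaks[-1]
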