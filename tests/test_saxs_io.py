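"""I/O round trips and the data-reduction operations."""

import numpy as np
import pytest

from flexsaxs.core import ScatteringProfile
from flexsaxs.saxs_io import (
    FrameSet,
    average_frames,
    merge_concentration_series,
    read_model_pdb,
    read_profile,
    subtract_buffer,
    write_model_pdb,
    write_profile,
)


def _profile(q, I, s, **md):
    return ScatteringProfile(np.asarray(q, float), np.asarray(I, float),
                             np.asarray(s, float), md)


class TestProfileIO:
    def test_roundtrip_full_precision(self, tmp_path, rng):
        q = np.sort(rng.uniform(0.01, 0.4, 50))
        prof = _profile(q, rng.normal(10, 1, 50), rng.uniform(0.1, 1, 50),
                        concentration=2.0, buffer="PBS")
        path = tmp_path / "p.dat"
        write_profile(path, prof)
        back = read_profile(path)
        assert np.array_equal(back.q, prof.q)
        assert np.array_equal(back.I, prof.I)
        assert np.array_equal(back.sigma, prof.sigma)
        assert back.metadata["concentration"] == 2.0
        assert back.metadata["buffer"] == "PBS"

    def test_toy_file_and_headers(self, tmp_path):
        body = "0.01 10 1\n0.02 9 1\n0.03 8 1\n"
        plain = tmp_path / "a.dat"
        plain.write_text(body)
        headed = tmp_path / "b.dat"
        headed.write_text("# Sample description: test\n# exposure = 1.0\n" + body)
        pa, pb = read_profile(plain), read_profile(headed)
        assert len(pa) == 3
        assert np.array_equal(pa.I, pb.I)
        assert pb.metadata["exposure"] == 1.0

    def test_two_column_sigma_imputed_with_warning(self, tmp_path):
        f = tmp_path / "c.dat"
        f.write_text("0.01 10\n0.02 9\n")
        with pytest.warns(UserWarning, match="imputing"):
            p = read_profile(f)
        assert np.allclose(p.sigma, 0.03 * p.I)

    def test_bad_files_rejected(self, tmp_path):
        one_col = tmp_path / "one.dat"
        one_col.write_text("0.01\n0.02\n")
        with pytest.raises(ValueError):
            read_profile(one_col)
        dec = tmp_path / "dec.dat"
        dec.write_text("0.02 9 1\n0.01 10 1\n")
        with pytest.raises(ValueError, match="increasing"):
            read_profile(dec)

    def test_pdb_roundtrip(self, tmp_path, surrogate):
        model, part = surrogate
        path = tmp_path / "m.pdb"
        write_model_pdb(path, model, part)
        back, bpart = read_model_pdb(path)
        assert len(back) == len(model)
        # PDB stores 3 decimals
        assert np.allclose(back.coords, model.coords, atol=1e-3)
        for lab in ("Fa", "Fb", "Fc"):
            assert np.array_equal(np.sort(bpart[lab]), np.sort(part[lab]))


class TestAverageFrames:
    Q = np.linspace(0.01, 0.3, 60)

    def _smooth(self):
        return np.exp(-40 * self.Q**2) * 100 + 1.0

    def test_error_propagation_identical_frames(self):
        I = self._smooth()
        frames = [_profile(self.Q, I, np.full_like(I, 0.5)) for _ in range(9)]
        avg = average_frames(frames)
        assert np.allclose(avg.I, I)
        assert np.allclose(avg.sigma, 0.5 / 3.0)

    def test_damaged_frame_rejected(self, rng):
        I = self._smooth()
        frames = [
            _profile(self.Q, I + rng.normal(0, 0.01, len(I)), np.ones_like(I))
            for _ in range(27)
        ]
        # radiation-damage signature: an aggregation bump that changes the
        # curve shape (pure rescaling would not move a correlation score)
        damaged = I + 50 * np.exp(-(((self.Q - 0.15) / 0.02) ** 2))
        frames.append(_profile(self.Q, damaged, np.ones_like(I)))
        avg = average_frames(frames, reject_threshold=0.99)
        assert avg.metadata["n_frames_rejected"] == 1
        assert avg.metadata["n_frames_kept"] == 27
        assert np.allclose(avg.I, I, atol=0.05)

    def test_single_frame_passthrough(self):
        f = _profile(self.Q, self._smooth(), np.ones_like(self.Q))
        avg = average_frames([f])
        assert np.array_equal(avg.I, f.I)

    def test_permutation_invariance(self, rng):
        I = self._smooth()
        frames = [
            _profile(self.Q, I + rng.normal(0, 0.1, len(I)), np.ones_like(I))
            for _ in range(6)
        ]
        a = average_frames(frames)
        b = average_frames(frames[::-1])
        assert np.allclose(a.I, b.I)
        assert np.allclose(a.sigma, b.sigma)

    def test_all_rejected_fails(self):
        with pytest.raises(ValueError, match="rejected"):
            # anticorrelated frames cannot all match the median
            f1 = _profile(self.Q, self._smooth(), np.ones_like(self.Q))
            f2 = _profile(self.Q, self._smooth()[::-1], np.ones_like(self.Q))
            average_frames([f1, f2], reject_threshold=1.1)


class TestSubtractBuffer:
    Q = np.linspace(0.01, 0.3, 40)

    def test_identical_buffer_zeroes_signal(self):
        s = _profile(self.Q, np.full(40, 5.0), np.full(40, 0.3))
        out = subtract_buffer(s, s)
        assert np.allclose(out.I, 0.0)
        assert np.allclose(out.sigma, np.sqrt(2) * 0.3)

    def test_recovers_signal_within_errors(self, rng):
        signal = np.exp(-30 * self.Q**2) * 50
        background = 5.0 + 10 * self.Q
        sig = 0.4 * np.ones_like(self.Q)
        sample = _profile(self.Q, signal + background + rng.normal(0, sig), sig)
        buffer = _profile(self.Q, background + rng.normal(0, sig), sig)
        out = subtract_buffer(sample, buffer)
        assert np.all(np.abs(out.I - signal) < 3.0 * out.sigma)

    def test_grid_mismatch_fails(self):
        s = _profile(self.Q, np.ones(40), np.ones(40))
        b = _profile(self.Q + 1e-4, np.ones(40), np.ones(40))
        with pytest.raises(ValueError, match="grids differ"):
            subtract_buffer(s, b)


class TestMerge:
    Q = np.linspace(0.01, 0.4, 100)

    def _truth(self):
        return 100 * np.exp(-60 * self.Q**2) + 2.0

    def test_identical_profiles_merge_to_themselves(self):
        p = _profile(self.Q, self._truth(), 0.01 * self._truth(), concentration=1)
        merged = merge_concentration_series([p, p.copy()])
        assert np.allclose(merged.I, p.I)
        assert np.array_equal(merged.q, p.q)

    def test_exact_scale_recovered(self):
        I = self._truth()
        lo = _profile(self.Q, I, 0.01 * I)
        hi = _profile(self.Q, 3.0 * I, 0.03 * I)
        merged = merge_concentration_series([lo, hi])
        assert merged.metadata["merge_scales"][0] == pytest.approx(3.0, abs=1e-9)
        assert np.allclose(merged.I, I, rtol=1e-9)

    def test_merged_beats_both_inputs(self, rng):
        I = self._truth()
        # low concentration: very noisy at high q
        noise_lo = 0.002 * I[0] * (1 + 20 * self.Q**2)
        lo = _profile(self.Q, I + rng.normal(0, noise_lo), noise_lo)
        # high concentration: structure-factor dip at low q, clean high q
        sf = 1.0 - 0.25 * np.exp(-(self.Q / 0.03) ** 2)
        noise_hi = 0.001 * I
        hi = _profile(self.Q, 4 * I * sf + rng.normal(0, noise_hi), noise_hi)
        merged = merge_concentration_series([lo, hi], overlap_window=(0.08, 0.25))

        def msd_log(p):
            scale = np.sum(p.I * I) / np.sum(p.I**2)
            good = (scale * p.I > 0)
            return np.mean((np.log(scale * p.I[good]) - np.log(I[good])) ** 2)

        assert msd_log(merged) < msd_log(lo)
        assert msd_log(merged) < msd_log(hi)

    def test_empty_overlap_fails(self):
        a = _profile(self.Q[:40], self._truth()[:40], np.ones(40))
        b = _profile(self.Q[60:], self._truth()[60:], np.ones(40))
        with pytest.raises(ValueError, match="overlap"):
            merge_concentration_series([a, b])
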