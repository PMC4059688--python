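"""MEMD core: direction sampling, projections, envelopes, sifting."""

import numpy as np
import pytest
from scipy.signal import welch

from imfsieve import (
    DirectionSet,
    MultichannelSeries,
    ResidueReached,
    SiftConfig,
    envelope_mean,
    hammersley_directions,
    memd,
    project,
    sift,
)


def _tone(freq, n=512, fs=1000.0, n_series=3, amp=1.0):
    t = np.arange(n) / fs
    x = amp * np.sin(2 * np.pi * freq * t)
    return MultichannelSeries(np.tile(x[:, None], (1, n_series)), fs)


class TestHammersleyDirections:
    def test_unit_norm_by_construction(self):
        d = hammersley_directions(2, 4)
        assert d.K == 4
        np.testing.assert_allclose(np.linalg.norm(d.vectors, axis=1), 1.0,
                                   atol=1e-12)

    def test_quasi_uniformity_near_zero_mean(self):
        # a balanced sphere sample has a small resultant vector
        d = hammersley_directions(3, 64)
        assert np.linalg.norm(d.vectors.mean(axis=0)) < 0.2

    def test_deterministic(self):
        a = hammersley_directions(5, 32).vectors
        b = hammersley_directions(5, 32).vectors
        np.testing.assert_array_equal(a, b)

    def test_univariate_rejected(self):
        with pytest.raises(ValueError, match="multivariate"):
            hammersley_directions(1, 8)


class TestProject:
    def test_basis_direction_selects_series(self, rng):
        vals = rng.normal(size=(64, 2))
        sig = MultichannelSeries(vals, 1.0)
        np.testing.assert_array_equal(project(sig, np.array([1.0, 0.0])),
                                      vals[:, 0])

    def test_negated_direction_negates(self, rng):
        vals = rng.normal(size=(64, 3))
        d = np.array([0.6, 0.8, 0.0])
        np.testing.assert_allclose(project(vals, d), -project(vals, -d))

    def test_dimension_mismatch(self, rng):
        with pytest.raises(ValueError, match="does not match"):
            project(rng.normal(size=(64, 3)), np.array([1.0, 0.0]))


class TestEnvelopeMean:
    def test_symmetric_oscillation_has_small_mean(self):
        sig = _tone(20.0, n=1000)
        dirs = hammersley_directions(3, 32)
        m, _ = envelope_mean(sig, dirs)
        assert np.abs(m).max() < 0.05  # < 5% of unit amplitude

    def test_translation_equivariance(self, rng):
        vals = np.sin(2 * np.pi * 20 * np.arange(1000) / 1000.0)[:, None]
        vals = np.tile(vals, (1, 2)) + 0.1 * rng.normal(size=(1000, 2))
        dirs = hammersley_directions(2, 16)
        offset = np.array([1.5, -2.0])
        m0, _ = envelope_mean(vals, dirs)
        m1, _ = envelope_mean(vals + offset, dirs)
        # interpolation through shifted points shifts the envelope mean
        np.testing.assert_allclose(m1 - m0, np.broadcast_to(offset, m0.shape),
                                   atol=0.15)

    def test_monotone_ramp_is_residue(self):
        vals = np.linspace(0.0, 1.0, 64)[:, None] * np.array([1.0, 2.0])
        with pytest.raises(ResidueReached):
            envelope_mean(vals, hammersley_directions(2, 8))


class TestSift:
    def test_clean_tone_is_already_an_imf(self):
        sig = _tone(50.0, n=1000)
        imf, residue = sift(sig, hammersley_directions(3, 16))
        rel = np.linalg.norm(imf - sig.values) / np.linalg.norm(sig.values)
        assert rel < 0.05
        assert np.abs(residue.values).max() < 0.2

    def test_additive_identity(self, rng):
        vals = rng.normal(size=(300, 2)).cumsum(axis=0)
        vals -= vals.mean(axis=0)
        sig = MultichannelSeries(vals, 1.0)
        imf, residue = sift(sig, hammersley_directions(2, 16))
        # definitional identity, up to one rounding of the subtraction
        np.testing.assert_allclose(imf + residue.values, sig.values,
                                   rtol=1e-12, atol=1e-12)

    def test_two_tone_fast_mode_first(self):
        t = np.arange(2000) / 1000.0
        x = np.sin(2 * np.pi * 12 * t) + np.sin(2 * np.pi * 50 * t)
        sig = MultichannelSeries(np.tile(x[:, None], (1, 2)), 1000.0)
        imf, _ = sift(sig, hammersley_directions(2, 32))
        f, p = welch(imf[:, 0], fs=1000.0, nperseg=2000)
        assert abs(f[np.argmax(p)] - 50.0) <= 1.0


class TestMemd:
    def test_reconstruction_and_alignment(self, rng):
        vals = rng.normal(size=(512, 3))
        sig = MultichannelSeries(vals, 1000.0)
        dec = memd(sig, K=16)
        recon = dec.reconstruction()
        rel = np.abs(recon - vals).max() / np.abs(vals).max()
        assert rel < 1e-8
        assert dec.imfs.shape[2] == 3  # joint: one scale count for all series

    def test_deterministic_bitwise(self, rng):
        vals = rng.normal(size=(256, 2))
        sig = MultichannelSeries(vals, 1.0)
        a = memd(sig, K=8)
        b = memd(MultichannelSeries(vals.copy(), 1.0), K=8)
        np.testing.assert_array_equal(a.imfs, b.imfs)
        np.testing.assert_array_equal(a.residue, b.residue)

    def test_white_noise_scales_slow_down_monotonically(self):
        rng = np.random.default_rng(3)
        sig = MultichannelSeries(rng.normal(size=(1024, 4)), 1000.0)
        dec = memd(sig, K=32)
        freqs = []
        for s in range(4):
            psd = None
            for c in range(4):
                f, p = welch(dec.imfs[s, :, c], fs=1000.0, nperseg=256)
                psd = p if psd is None else psd + p
            freqs.append(f[1:][np.argmax(psd[1:])])
        assert all(f2 < f1 for f1, f2 in zip(freqs, freqs[1:]))

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="8 time points"):
            MultichannelSeries(np.zeros((5, 2)), 1.0)

    def test_max_imfs_cap(self, rng):
        vals = rng.normal(size=(512, 2))
        sig = MultichannelSeries(vals, 1.0)
        dec = memd(sig, K=8, cfg=SiftConfig(max_imfs=3))
        assert dec.n_scales == 3


class TestEnvelopeAgainstScipyOracle:
    def test_matches_independent_spline_implementation(self, rng):
        # the compiled kernel must agree with a SciPy-built natural-spline
        # envelope to float precision
        from scipy.interpolate import CubicSpline
        from scipy.signal import find_peaks

        vals = np.cumsum(rng.normal(size=(300, 3)), axis=0)
        vals -= vals.mean(axis=0)
        dirs = hammersley_directions(3, 16)
        m, amp = envelope_mean(vals, dirs)

        n = vals.shape[0]
        env_sum = np.zeros_like(vals)
        amp_sum = np.zeros(n)
        live = 0
        for k in range(dirs.K):
            mx, _ = find_peaks(vals @ dirs.vectors[k])
            if len(mx) < 4:  # oracle covers the cubic branch
                continue
            ml = min(2, len(mx))
            t = np.concatenate([-mx[:ml][::-1], mx, 2 * (n - 1) - mx[-ml:][::-1]])
            y = np.concatenate([vals[mx[:ml][::-1]], vals[mx], vals[mx[-ml:][::-1]]])
            e = CubicSpline(t, y, axis=0, bc_type="natural")(np.arange(n))
            env_sum += e
            amp_sum += np.linalg.norm(e, axis=1)
            live += 1
        assert live == dirs.K  # random walk: every projection oscillates
        np.testing.assert_allclose(m, env_sum / live, atol=1e-10)
        np.testing.assert_allclose(amp, amp_sum / live, atol=1e-10)
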