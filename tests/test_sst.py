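"""Synchrosqueezed transform: CWT, IF, squeezing, ridges, inversion."""

import numpy as np
import pytest

from jwave import sst


@pytest.fixture(scope="module")
def wavelet():
    return sst.WaveletSpec()


@pytest.fixture(scope="module")
def tone_10hz(fs):
    t = np.arange(int(0.5 * fs)) / fs
    return np.cos(2 * np.pi * 10 * t), t


@pytest.fixture(scope="module")
def two_tone(fs):
    t = np.arange(int(0.5 * fs)) / fs
    return np.cos(2 * np.pi * 5 * t) + 0.5 * np.cos(2 * np.pi * 20 * t), t


def cwt_quadrature_oracle(x_func, a, b, wavelet, t_span=4.0, n=40001):
    """Direct numerical quadrature of the CWT integral at one (a, b)."""
    t = np.linspace(b - t_span, b + t_span, n)
    integrand = x_func(t) * np.conj(wavelet.time_domain((t - b) / a))
    return np.trapezoid(integrand, t) / np.sqrt(a)


class TestCwt:
    def test_zero_window_zero_plane(self, fs, wavelet):
        plane = sst.cwt(np.zeros(128), fs, wavelet)
        assert np.allclose(plane.coefficients, 0)

    def test_tone_peaks_at_matching_scale(self, fs, wavelet, tone_10hz):
        x, _ = tone_10hz
        plane = sst.cwt(x, fs, wavelet)
        mid = x.size // 2
        peak_scale = plane.scales[np.argmax(np.abs(plane.coefficients[:, mid]))]
        expected = wavelet.center_frequency / 10.0
        # within one voice step of a = f_c / f
        assert abs(np.log2(peak_scale / expected)) <= 1.5 / wavelet.n_voices

    def test_matches_quadrature_oracle(self, fs, wavelet, tone_10hz):
        """FFT evaluation equals direct integration of the CWT integral."""
        x, t = tone_10hz
        plane = sst.cwt(x, fs, wavelet)
        b = t[x.size // 2]
        target = wavelet.center_frequency / 10.0
        scale_sel = np.argsort(np.abs(plane.scales - target))[:5]
        for i in scale_sel:
            a = plane.scales[i]
            oracle = cwt_quadrature_oracle(
                lambda tt: np.cos(2 * np.pi * 10 * tt), a, b, wavelet)
            got = plane.coefficients[i, x.size // 2]
            assert abs(abs(got) - abs(oracle)) <= 0.02 * abs(oracle) + 1e-6

    def test_linearity(self, fs, wavelet):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(128)
        y = rng.standard_normal(128)
        pxy = sst.cwt(x + y, fs, wavelet).coefficients
        px = sst.cwt(x, fs, wavelet).coefficients
        py = sst.cwt(y, fs, wavelet).coefficients
        np.testing.assert_allclose(pxy, px + py, atol=1e-10)

    def test_short_window_rejected(self, fs, wavelet):
        with pytest.raises(ValueError):
            sst.cwt(np.ones(16), fs, wavelet)


class TestInstantaneousFrequency:
    def test_tone_frequency_recovered(self, fs, wavelet, tone_10hz):
        x, _ = tone_10hz
        plane = sst.cwt(x, fs, wavelet)
        ifr = sst.instantaneous_frequency(plane)
        interior = slice(x.size // 4, 3 * x.size // 4)
        est_hz = ifr.w_f[:, interior] / (2 * np.pi)
        # where the wavelet genuinely responds (not just boundary leakage),
        # the phase derivative of W ~ e^{iwb} is exactly the tone frequency
        absW = np.abs(plane.coefficients[:, interior])
        strong = ~ifr.mask[:, interior] & (absW > 0.2 * absW.max())
        vals = est_hz[strong]
        assert vals.size > 100
        assert np.max(np.abs(vals - 10.0)) < 0.5

    def test_gamma_above_max_masks_everything(self, fs, wavelet, tone_10hz):
        x, _ = tone_10hz
        plane = sst.cwt(x, fs, wavelet)
        gamma = 2.0 * np.abs(plane.coefficients).max()
        ifr = sst.instantaneous_frequency(plane, gamma=gamma)
        assert ifr.mask.all()

    def test_chirp_tracked_along_ridge(self, fs, wavelet):
        """IF along the max-|W| ridge follows the analytic phase derivative."""
        t = np.arange(int(0.5 * fs)) / fs
        x = np.cos(2 * np.pi * (5 * t + 10 * t ** 2))
        plane = sst.cwt(x, fs, wavelet)
        ifr = sst.instantaneous_frequency(plane, gamma_rel=1e-2)
        mid = range(x.size // 4, 3 * x.size // 4)
        errs = []
        for j in mid:
            i = int(np.argmax(np.abs(plane.coefficients[:, j])))
            if not ifr.mask[i, j]:
                errs.append(abs(ifr.w_f[i, j] / (2 * np.pi) - (5 + 20 * t[j])))
        assert len(errs) > 50
        assert np.max(errs) < 1.0


class TestSynchrosqueeze:
    def test_energy_concentration_beats_cwt(self, fs, wavelet, tone_10hz):
        x, _ = tone_10hz
        plane = sst.cwt(x, fs, wavelet)
        ifr = sst.instantaneous_frequency(plane)
        sq = sst.synchrosqueeze(plane, ifr)
        e_sst = np.abs(sq.T_f) ** 2
        in_band = np.abs(sq.freq_bins - 10.0) <= 1.0
        conc_sst = e_sst[in_band].sum() / e_sst.sum()
        e_cwt = np.abs(plane.coefficients) ** 2
        in_band_cwt = np.abs(plane.scale_frequencies - 10.0) <= 1.0
        conc_cwt = e_cwt[in_band_cwt].sum() / e_cwt.sum()
        assert conc_sst >= 0.90
        assert conc_sst > conc_cwt

    def test_all_masked_gives_zero_plane(self, fs, wavelet, tone_10hz):
        x, _ = tone_10hz
        plane = sst.cwt(x, fs, wavelet)
        ifr = sst.instantaneous_frequency(
            plane, gamma=2.0 * np.abs(plane.coefficients).max())
        sq = sst.synchrosqueeze(plane, ifr)
        assert np.allclose(sq.T_f, 0)

    def test_two_tones_form_disjoint_ridges(self, fs, wavelet):
        # equal amplitudes so each tone carries ~half the squared energy
        t = np.arange(int(0.5 * fs)) / fs
        x = np.cos(2 * np.pi * 5 * t) + np.cos(2 * np.pi * 20 * t)
        plane = sst.cwt(x, fs, wavelet)
        sq = sst.synchrosqueeze(plane, sst.instantaneous_frequency(plane))
        e = np.abs(sq.T_f) ** 2
        total = e.sum()
        for f0 in (5.0, 20.0):
            band = np.abs(sq.freq_bins - f0) <= 1.0
            assert e[band].sum() / total >= 0.40


class TestRidges:
    def test_two_tone_ridges_recovered(self, fs, two_tone):
        x, _ = two_tone
        sq, modes = sst.analyze_window(x, fs, k=2)
        means = np.sort(modes.ridges.mean(axis=1))
        assert abs(means[0] - 5.0) <= sq.dw
        assert abs(means[1] - 20.0) <= sq.dw

    def test_single_tone_ridge(self, fs, wavelet, tone_10hz):
        x, _ = tone_10hz
        plane = sst.cwt(x, fs, wavelet)
        sq = sst.synchrosqueeze(plane, sst.instantaneous_frequency(plane))
        ridges, captured = sst.extract_ridges(sq, k=1)
        interior = slice(x.size // 8, 7 * x.size // 8)
        assert np.all(np.abs(ridges[0][interior] - 10.0) <= sq.dw)
        assert captured[0] > 0

    def test_zero_signal_degenerate_ridge(self, fs, wavelet):
        plane = sst.cwt(np.zeros(128), fs, wavelet)
        sq = sst.synchrosqueeze(plane, sst.instantaneous_frequency(plane))
        ridges, captured = sst.extract_ridges(sq, k=1)
        assert captured[0] == 0.0

    def test_ridges_ordered_by_captured_energy(self, fs, two_tone):
        x, _ = two_tone
        sq, modes = sst.analyze_window(x, fs, k=2)
        assert modes.captured_energy[0] >= modes.captured_energy[1]
        # the 1.0-amplitude 5 Hz tone must dominate the 0.5-amplitude one
        assert abs(modes.ridges[0].mean() - 5.0) < 2.0


class TestRPsi:
    def test_quadrature_converges(self, wavelet):
        coarse = sst.compute_r_psi(wavelet, n_points=10001)
        fine = sst.compute_r_psi(wavelet, n_points=20001)
        assert abs(fine - coarse) / fine < 1e-3
        assert fine > 0

    def test_matches_adaptive_quadrature_oracle(self, wavelet):
        assert sst.compute_r_psi(wavelet) == pytest.approx(
            sst.r_psi_quad(wavelet), rel=1e-3)

    def test_linear_in_spectrum_scale(self, wavelet):
        """Doubling the wavelet spectrum doubles the admissibility constant."""

        class Doubled(sst.WaveletSpec):
            def spectrum(self, xi):
                return 2.0 * super().spectrum(xi)

        doubled = Doubled()
        assert sst.compute_r_psi(doubled) == pytest.approx(
            2.0 * sst.compute_r_psi(wavelet), rel=1e-9)

    def test_inadmissible_wavelet_rejected(self):
        broad = sst.WaveletSpec(center_frequency=5.0, reference_time=0.01)
        with pytest.raises(ValueError):
            sst.compute_r_psi(broad)


class TestReconstruction:
    def test_two_tone_modes_match_components(self, fs, two_tone):
        x, t = two_tone
        _, modes = sst.analyze_window(x, fs, k=2)
        central = slice(int(0.1 * x.size), int(0.9 * x.size))
        for f0, amp in ((5.0, 1.0), (20.0, 0.5)):
            k = int(np.argmin(np.abs(modes.ridges.mean(axis=1) - f0)))
            ref = amp * np.cos(2 * np.pi * f0 * t)
            err = np.sqrt(np.mean((modes.modes[k][central]
                                   - ref[central]) ** 2))
            assert err / np.sqrt(np.mean(ref[central] ** 2)) < 0.1

    def test_mode_sum_recovers_single_tone(self, fs, tone_10hz):
        x, _ = tone_10hz
        _, modes = sst.analyze_window(x, fs, k=3)
        recon = modes.modes.sum(axis=0)
        central = slice(int(0.1 * x.size), int(0.9 * x.size))
        err = np.sqrt(np.mean((recon[central] - x[central]) ** 2))
        assert err / np.sqrt(np.mean(x[central] ** 2)) < 0.1

    def test_zero_plane_zero_modes(self, fs, wavelet):
        plane = sst.cwt(np.zeros(128), fs, wavelet)
        sq = sst.synchrosqueeze(plane, sst.instantaneous_frequency(plane))
        ridges, _ = sst.extract_ridges(sq, k=2)
        modes = sst.reconstruct_modes(sq, ridges)
        assert np.allclose(modes.modes, 0)

    def test_mode_lengths_match_window(self, fs, two_tone):
        x, _ = two_tone
        _, modes = sst.analyze_window(x, fs, k=5)
        assert modes.modes.shape == (5, x.size)
        assert modes.ridges.shape == (5, x.size)


class TestWaveletRobustness:
    def test_ridges_insensitive_to_center_frequency(self, fs, two_tone):
        """Unlike the raw CWT, squeezed ridge frequencies barely move when
        the Morlet center frequency changes."""
        x, _ = two_tone
        recovered = {}
        dw = None
        for fc in (25.0, 35.0, 45.0):
            sq, modes = sst.analyze_window(
                x, fs, wavelet=sst.WaveletSpec(center_frequency=fc), k=2)
            recovered[fc] = np.sort(modes.ridges.mean(axis=1))
            dw = sq.dw
        for fc in (25.0, 45.0):
            assert np.all(np.abs(recovered[fc] - recovered[35.0]) <= dw)
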