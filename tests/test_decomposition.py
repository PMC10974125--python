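"""VMD/EMD decomposers and Hilbert spectral analysis.

Oracles: analytically known tone components (a pure tone's center frequency
and instantaneous frequency are its oscillation frequency) and an
independent FFT periodogram estimate that the VMD solver does not use.
"""

import numpy as np
import pytest
from scipy.signal import periodogram

from mmgmotion import (
    VMDConfig,
    ValidationError,
    emd_decompose,
    hilbert_envelope,
    marginal_hilbert_spectrum,
    vmd_decompose,
)


def periodogram_peak_hz(x, rate):
    """Independent spectral oracle: frequency of the periodogram maximum."""
    f, p = periodogram(x, rate)
    return f[np.argmax(p)]


class TestVMD:
    def test_single_tone_recovery(self, tone_30hz, rate):
        res = vmd_decompose(tone_30hz, rate, VMDConfig(K=1, alpha=2000))
        assert res.center_freqs_hz[0] == pytest.approx(30.0, abs=0.5)
        assert np.corrcoef(res.imfs[0], tone_30hz)[0, 1] >= 0.99

    def test_two_tone_separation(self, two_tone, rate):
        x, low, high = two_tone
        res = vmd_decompose(x, rate, VMDConfig(K=2, alpha=2000))
        assert res.center_freqs_hz[0] == pytest.approx(2.0, abs=1.0)
        assert res.center_freqs_hz[1] == pytest.approx(30.0, abs=1.0)
        assert np.corrcoef(res.imfs[0], low)[0, 1] >= 0.99
        assert np.corrcoef(res.imfs[1], high)[0, 1] >= 0.99
        # cross-check the solver's internal frequency estimate against an
        # independent FFT-based estimate of each recovered mode
        assert abs(periodogram_peak_hz(res.imfs[0], rate) - res.center_freqs_hz[0]) <= 0.5
        assert abs(periodogram_peak_hz(res.imfs[1], rate) - res.center_freqs_hz[1]) <= 0.5

    def test_zero_signal_degenerate(self):
        res = vmd_decompose(np.zeros(1024), 1000.0, VMDConfig(K=3))
        assert res.converged
        assert np.array_equal(res.imfs, np.zeros((3, 1024)))

    @pytest.mark.parametrize("alpha", [200.0, 2000.0, 20000.0])
    def test_tone_frequency_robust_to_alpha(self, tone_30hz, rate, alpha):
        res = vmd_decompose(tone_30hz, rate, VMDConfig(K=1, alpha=alpha))
        assert res.center_freqs_hz[0] == pytest.approx(30.0, abs=0.5)

    def test_center_freqs_sorted_and_bounded(self, rate):
        rng = np.random.default_rng(3)
        x = rng.normal(size=2000)
        res = vmd_decompose(x, rate, VMDConfig(K=4, alpha=500))
        f = res.center_freqs_hz
        assert np.all(np.diff(f) >= 0)
        assert np.all((f >= 0) & (f <= rate / 2))
        assert np.isfinite(res.reconstruction_error)

    def test_fixed_point_at_converged_solution(self, two_tone, rate):
        x, _, _ = two_tone
        cfg = VMDConfig(K=2, alpha=2000)
        first = vmd_decompose(x, rate, cfg)
        again = vmd_decompose(x, rate, cfg, omega_init_hz=first.center_freqs_hz)
        np.testing.assert_allclose(
            again.center_freqs_hz, first.center_freqs_hz, atol=0.1
        )
        rel = np.linalg.norm(again.imfs - first.imfs) / np.linalg.norm(first.imfs)
        assert rel < 1e-3

    def test_mirror_boundary_agreement_in_center(self, rate):
        # decomposition of a signal and of its explicitly mirror-extended
        # version agree in the central half within 2% RMS
        t = np.arange(2000) / rate
        x = np.sin(2 * np.pi * 7 * t) + 0.5 * np.sin(2 * np.pi * 40 * t)
        ext = np.concatenate([x[:500][::-1], x, x[1500:][::-1]])
        cfg = VMDConfig(K=2, alpha=2000)
        res_x = vmd_decompose(x, rate, cfg)
        res_ext = vmd_decompose(ext, rate, cfg)
        mid_x = res_x.imfs[:, 500:1500]
        mid_ext = res_ext.imfs[:, 1000:2000]
        rms = np.sqrt(np.mean((mid_x - mid_ext) ** 2))
        assert rms / np.sqrt(np.mean(mid_x**2)) < 0.02

    def test_nan_rejected(self):
        x = np.ones(100)
        x[3] = np.nan
        with pytest.raises(ValidationError):
            vmd_decompose(x, 1000.0, VMDConfig(K=2))


class TestEMD:
    def test_tone_plus_trend_separation(self, rate):
        t = np.arange(int(4 * rate)) / rate
        tone = np.sin(2 * np.pi * 30 * t)
        trend = np.linspace(0, 1, t.size)
        res = emd_decompose(tone + trend)
        assert res.n_imfs >= 1
        assert np.corrcoef(res.imfs[0], tone)[0, 1] >= 0.95
        assert np.corrcoef(res.residual, trend)[0, 1] >= 0.95

    def test_constant_signal_no_imfs(self):
        res = emd_decompose(np.full(100, 3.0))
        assert res.n_imfs == 0
        np.testing.assert_array_equal(res.residual, np.full(100, 3.0))

    @pytest.mark.parametrize("seed", range(10))
    def test_additivity_exact_on_random_signals(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=600)
        res = emd_decompose(x)
        recon = res.imfs.sum(axis=0) + res.residual
        assert np.linalg.norm(recon - x) <= 1e-9 * np.linalg.norm(x)


class TestHilbert:
    def test_pure_tone_envelope_is_one(self, rate):
        t = np.arange(int(8 * rate)) / rate
        env = hilbert_envelope(np.sin(2 * np.pi * 20 * t))
        interior = env[1000:-1000]
        assert abs(interior.mean() - 1.0) <= 0.02

    def test_zero_signal_zero_envelope(self):
        assert np.all(hilbert_envelope(np.zeros(64)) == 0)

    def test_envelope_homogeneity(self, tone_30hz):
        np.testing.assert_allclose(
            hilbert_envelope(2.0 * tone_30hz), 2.0 * hilbert_envelope(tone_30hz),
            rtol=1e-12,
        )


class TestMarginalSpectrum:
    def test_tone_energy_concentrated_at_tone_frequency(self, tone_30hz, rate):
        spec = marginal_hilbert_spectrum(tone_30hz[None, :], rate, n_freq_bins=250)
        band = (spec.freqs_hz >= 28) & (spec.freqs_hz <= 32)
        assert spec.energy[band].sum() / spec.energy.sum() >= 0.9

    def test_zero_imf_zero_energy(self, tone_30hz, rate):
        spec = marginal_hilbert_spectrum(
            np.vstack([tone_30hz, np.zeros_like(tone_30hz)]), rate
        )
        solo = marginal_hilbert_spectrum(tone_30hz[None, :], rate)
        np.testing.assert_allclose(spec.energy, solo.energy)

    def test_time_reversal_invariance(self, tone_30hz, rate):
        fwd = marginal_hilbert_spectrum(tone_30hz[None, :], rate)
        rev = marginal_hilbert_spectrum(tone_30hz[None, ::-1], rate)
        assert abs(fwd.energy.sum() - rev.energy.sum()) / fwd.energy.sum() < 0.01

    def test_single_sample_rejected(self):
        with pytest.raises(ValidationError):
            marginal_hilbert_spectrum(np.ones((1, 1)), 1000.0)
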