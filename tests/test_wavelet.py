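"""Wavelet shrinkage: transform round-trip, noise estimation, thresholds,
and the denoiser's contraction properties."""

import numpy as np
import pytest

from brispec import (
    Spectrum,
    WaveletDenoiser,
    WAOptions,
    estimate_noise,
    soft_threshold,
    universal_threshold,
    wa_denoise,
)
from brispec.wavelet import decompose, reconstruct


def make_spectrum(intensity, sigma=1.0):
    intensity = np.asarray(intensity, dtype=float)
    return Spectrum(
        frequency_ghz=np.arange(intensity.size, dtype=float),
        intensity=intensity,
        noise_sigma=sigma,
    )


class TestTransformRoundTrip:
    @pytest.mark.parametrize("wavelet", ["sym8", "db4", "haar"])
    def test_perfect_reconstruction(self, rng, wavelet):
        x = rng.normal(size=120)
        d = decompose(x, wavelet_name=wavelet, levels=3)
        np.testing.assert_allclose(reconstruct(d), x, rtol=1e-9, atol=1e-9)

    def test_levels_auto_reduced_for_short_signals(self, rng):
        d = decompose(rng.normal(size=32), wavelet_name="sym8", levels=6)
        assert d.levels < 6
        np.testing.assert_allclose(reconstruct(d), reconstruct(d))


class TestNoiseEstimate:
    def test_recovers_gaussian_sigma(self):
        hits = 0
        for seed in range(40):
            x = np.random.default_rng(seed).normal(0.0, 1.0, 1024)
            est = estimate_noise(decompose(x))
            hits += 0.9 <= est <= 1.1
        assert hits >= 38  # >= 95% of seeds

    def test_zero_for_zero_input(self):
        assert estimate_noise(decompose(np.zeros(128))) == 0.0

    def test_small_for_smooth_signal(self, truth):
        est = estimate_noise(decompose(truth.intensity))
        assert est < 0.01 * truth.intensity.max()


class TestUniversalThreshold:
    def test_single_sample_gives_zero(self):
        assert universal_threshold(1.0, 1) == 0.0

    def test_zero_noise_gives_zero(self):
        assert universal_threshold(0.0, 120) == 0.0

    def test_canonical_value(self):
        assert universal_threshold(1.0, 120) == pytest.approx(np.sqrt(2 * np.log(120)), rel=1e-12)
        assert universal_threshold(1.0, 120) == pytest.approx(3.094, abs=2e-3)

    def test_literal_dialect(self):
        assert universal_threshold(1.0, 120, literal_dialect=True) == pytest.approx(
            2 * np.log(120) / 120
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            universal_threshold(1.0, 0)
        with pytest.raises(ValueError):
            universal_threshold(-1.0, 10)


class TestSoftThreshold:
    def test_zero_threshold_is_identity(self, rng):
        c = rng.normal(size=50)
        np.testing.assert_array_equal(soft_threshold(c, 0.0), c)

    def test_shrinks_by_threshold(self):
        np.testing.assert_allclose(soft_threshold([3.0, -3.0], 1.0), [2.0, -2.0])

    def test_all_below_threshold_zeroed(self, rng):
        c = rng.uniform(-0.5, 0.5, 30)
        np.testing.assert_array_equal(soft_threshold(c, 1.0), np.zeros(30))

    def test_hard_variant_keeps_survivors_intact(self):
        np.testing.assert_allclose(
            soft_threshold([3.0, 0.5, -2.0], 1.0, soft=False), [3.0, 0.0, -2.0]
        )


class TestDenoise:
    def test_manual_zero_threshold_returns_input(self, noisy_snr5):
        options = WAOptions(threshold_rule="manual", threshold=0.0)
        out = wa_denoise(noisy_snr5, options)
        np.testing.assert_allclose(out.intensity, noisy_snr5.intensity, rtol=1e-9, atol=1e-6)

    def test_energy_non_increase(self, noisy_snr5):
        centred = noisy_snr5.intensity - noisy_snr5.intensity.mean()
        spec = noisy_snr5.with_intensity(centred)
        out = wa_denoise(spec)
        # soft thresholding shrinks every coefficient, and the approximation
        # band carries the (removed) mean
        assert np.sum(out.intensity**2) <= np.sum(centred**2) * (1 + 1e-9)

    def test_shrinkage_contracts_on_repeat(self, noisy_snr5):
        t = 200.0
        once = wa_denoise(noisy_snr5, WAOptions(threshold_rule="manual", threshold=t))
        twice = wa_denoise(once, WAOptions(threshold_rule="manual", threshold=t))
        first_change = np.linalg.norm(once.intensity - noisy_snr5.intensity)
        second_change = np.linalg.norm(twice.intensity - once.intensity)
        assert second_change <= first_change * (1 + 1e-9)

    def test_linearity_in_joint_scale(self, noisy_snr5):
        options = WAOptions(noise_level=200.0)
        out1 = wa_denoise(noisy_snr5, options)
        scaled = noisy_snr5.with_intensity(noisy_snr5.intensity * 7.0)
        out2 = wa_denoise(scaled, WAOptions(noise_level=200.0 * 7.0))
        np.testing.assert_allclose(out2.intensity, 7.0 * out1.intensity, rtol=1e-9, atol=1e-8)

    def test_removes_broadband_noise_from_baseline(self, truth, noisy_snr5):
        # shrinkage nulls the noise in the feature-free baseline; near the
        # sharp peaks it trades noise for bias, so the pointwise test
        # belongs where the signal is smooth
        out = wa_denoise(noisy_snr5)
        sel = np.abs(truth.frequency_ghz) > 15.0
        err_before = np.linalg.norm((noisy_snr5.intensity - truth.intensity)[sel])
        err_after = np.linalg.norm((out.intensity - truth.intensity)[sel])
        assert err_after < 0.5 * err_before

    def test_per_level_rule_runs(self, noisy_snr5):
        out = wa_denoise(noisy_snr5, WAOptions(threshold_rule="universal_per_level"))
        assert out.intensity.shape == noisy_snr5.intensity.shape

    def test_manual_rule_requires_threshold(self):
        with pytest.raises(ValueError):
            WAOptions(threshold_rule="manual")


class TestTransformer:
    def test_rowwise_matches_functional(self, noisy_snr5):
        den = WaveletDenoiser()
        out = den.fit_transform(np.vstack([noisy_snr5.intensity, noisy_snr5.intensity]))
        ref = wa_denoise(noisy_snr5)
        np.testing.assert_allclose(out[0], ref.intensity)
        np.testing.assert_allclose(out[1], out[0])

    def test_sklearn_pipeline_compatibility(self, noisy_snr5):
        pytest.importorskip("sklearn")
        from sklearn.pipeline import Pipeline

        pipe = Pipeline([("wa", WaveletDenoiser())])
        out = pipe.fit_transform(noisy_snr5.intensity[None, :])
        assert out.shape == (1, len(noisy_snr5))
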