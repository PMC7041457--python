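"""Maximum-entropy reconstruction: entropy/chi-squared algebra, gradients,
termination geometry, existence criterion, and the full solver contract."""

import numpy as np
import pytest

from brispec import (
    MaximumEntropyReconstruction,
    MEROptions,
    PeakSet,
    Spectrum,
    add_noise,
    build_spectrometer,
    chi_squared,
    entropy,
    gradients,
    me_solution_exists,
    mer_reconstruct,
    synth_truth,
    termination_metric,
)


def make_spectrum(intensity, sigma=1.0, axis=None, mask=None):
    intensity = np.asarray(intensity, dtype=float)
    if axis is None:
        axis = np.arange(intensity.size, dtype=float)
    return Spectrum(frequency_ghz=axis, intensity=intensity, noise_sigma=sigma, mask=mask)


class TestEntropy:
    def test_uniform_is_maximal_log_n(self):
        assert entropy(np.ones(4)) == pytest.approx(np.log(4))
        # any perturbation lowers the entropy
        assert entropy([1.0, 1.1, 0.9, 1.0]) < np.log(4)

    def test_one_hot_is_zero(self):
        assert entropy([0.0, 5.0, 0.0]) == pytest.approx(0.0)

    def test_hand_evaluated_case(self):
        # p = (1/2, 1/4, 1/4)
        expected = -(0.5 * np.log(0.5) + 2 * 0.25 * np.log(0.25))
        assert entropy([2.0, 1.0, 1.0]) == pytest.approx(expected)
        assert expected == pytest.approx(1.0397, abs=1e-4)

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            entropy([1.0, -0.1, 1.0])

    def test_relative_entropy_vanishes_when_p_equals_prior(self, rng):
        m = rng.uniform(0.5, 2.0, 16)
        assert entropy(3.0 * m, prior=m) == pytest.approx(0.0, abs=1e-12)


class TestChiSquared:
    def test_zero_at_exact_fit(self):
        spec = make_spectrum([1.0, 2.0, 3.0])
        assert chi_squared(spec.intensity, spec) == 0.0

    def test_unit_residual_everywhere_gives_one(self):
        d = np.array([1.0, 2.0, 3.0, 4.0])
        spec = make_spectrum(d, sigma=0.5)
        assert chi_squared(d + 0.5, spec) == pytest.approx(1.0)

    def test_matches_brute_force_double_loop(self, rng):
        n = 6
        model = build_spectrometer(n_pixels=n, bandwidth_ghz=3.0, response_fwhm_ghz=0.8)
        f = rng.uniform(0.5, 2.0, n)
        d = rng.uniform(0.5, 2.0, n)
        sigma = rng.uniform(0.1, 1.0, n)
        spec = Spectrum(
            frequency_ghz=model.frequency_axis_ghz, intensity=d, noise_sigma=sigma
        )
        r = model.response
        total = 0.0
        for j in range(n):
            rf_j = 0.0
            for k in range(n):
                rf_j += r[j, k] * f[k]
            total += (rf_j - d[j]) ** 2 / sigma[j] ** 2
        assert chi_squared(f, spec, model) == pytest.approx(total / n, rel=1e-12)

    def test_all_masked_rejected(self):
        spec = make_spectrum([1.0, 2.0], mask=[False, False])
        with pytest.raises(ValueError):
            chi_squared(np.ones(2), spec)

    def test_masked_pixels_do_not_contribute(self):
        d = np.array([1.0, 2.0, 100.0])
        spec = make_spectrum(d, mask=[True, True, False])
        assert chi_squared(np.array([1.0, 2.0, 0.0]), spec) == 0.0


class TestGradients:
    def test_finite_difference_agreement(self, rng):
        n = 8
        model = build_spectrometer(n_pixels=n, bandwidth_ghz=4.0, response_fwhm_ghz=1.0)
        spec = Spectrum(
            frequency_ghz=model.frequency_axis_ghz,
            intensity=rng.uniform(1.0, 3.0, n),
            noise_sigma=rng.uniform(0.2, 0.5, n),
        )
        f = rng.uniform(0.5, 2.0, n)
        grad_s, grad_c = gradients(f, spec, model)
        eps = 1e-7
        for i in range(n):
            up, dn = f.copy(), f.copy()
            up[i] += eps
            dn[i] -= eps
            fd_s = (entropy(up) - entropy(dn)) / (2 * eps)
            fd_c = (chi_squared(up, spec, model) - chi_squared(dn, spec, model)) / (2 * eps)
            assert grad_s[i] == pytest.approx(fd_s, rel=1e-5, abs=1e-9)
            assert grad_c[i] == pytest.approx(fd_c, rel=1e-5, abs=1e-9)

    def test_chi_gradient_zero_at_exact_fit(self):
        d = np.array([1.0, 2.0, 3.0])
        spec = make_spectrum(d)
        _, grad_c = gradients(d, spec)
        np.testing.assert_allclose(grad_c, 0.0, atol=1e-14)

    def test_entropy_gradient_vanishes_at_uniform(self):
        spec = make_spectrum(np.ones(5))
        grad_s, _ = gradients(np.full(5, 2.0), spec)
        # uniform p is the entropy maximum under normalization
        np.testing.assert_allclose(grad_s, 0.0, atol=1e-10)


class TestTerminationMetric:
    def test_parallel_gradients_give_zero(self, rng):
        g = rng.normal(size=10)
        assert termination_metric(g, 2.0 * g) == pytest.approx(0.0, abs=1e-14)

    def test_antiparallel_gives_two(self, rng):
        g = rng.normal(size=10)
        assert termination_metric(g, -g) == pytest.approx(2.0)

    def test_orthogonal_gives_one(self):
        assert termination_metric([1.0, 0.0], [0.0, 3.0]) == pytest.approx(1.0)

    def test_both_zero_counts_as_converged(self):
        assert termination_metric(np.zeros(3), np.zeros(3)) == 0.0

    def test_single_zero_gradient_is_an_error(self):
        with pytest.raises(FloatingPointError):
            termination_metric(np.zeros(3), np.ones(3))


class TestExistence:
    def test_clean_structured_data_has_solution(self, truth, spectrometer):
        spec = truth.copy()
        spec.noise_sigma = 10.0  # tiny vs the 1e4 peak
        assert me_solution_exists(spec, spectrometer)

    def test_uniform_data_with_matching_sigma_has_none(self):
        rng = np.random.default_rng(3)
        d = 100.0 + rng.normal(0.0, 1.0, 64)
        spec = make_spectrum(d, sigma=2.0)  # uniform model within ~0.5 chi^2
        assert not me_solution_exists(spec)

    def test_failure_rate_increases_with_noise(self, truth, spectrometer):
        # the uniform spectrum satisfies chi^2 <= 1 only once noise swamps structure
        fails_low = fails_high = 0
        for k in range(50):
            lo = add_noise(truth, snr=1.0, seed=k)
            hi = add_noise(truth, snr=1.0, seed=k, snr_reference="rayleigh")
            fails_low += not me_solution_exists(lo, spectrometer)
            fails_high += not me_solution_exists(hi, spectrometer)
        assert fails_low <= fails_high
        assert fails_high > 25  # sigma=1e4 drowns the spectrum


class TestReconstruct:
    def test_low_noise_consistency(self, truth, spectrometer, peaks):
        spec = truth.copy()
        spec.noise_sigma = 100.0  # 1% of the Rayleigh peak
        spec.meta["snr"] = 10.0
        res = mer_reconstruct(spec, spectrometer, MEROptions(prior=peaks))
        assert res.exists and res.converged
        assert res.chi_sq <= 1.0 + 1e-6
        assert np.all(np.abs(res.f - truth.intensity) < 3.0 * 100.0)
        assert np.all(res.f > 0)

    def test_termination_geometry_at_convergence(self, noisy_snr5, spectrometer, peaks):
        res = mer_reconstruct(noisy_snr5, spectrometer, MEROptions(prior=peaks))
        assert res.converged
        assert res.term_metric < 0.01
        grad_s, grad_c = gradients(res.f, noisy_snr5, spectrometer,
                                   MEROptions(prior=peaks))
        cos = np.dot(grad_s, grad_c) / (np.linalg.norm(grad_s) * np.linalg.norm(grad_c))
        assert cos > 0.99

    def test_chi_squared_near_target_under_default_schedule(self, truth, spectrometer, peaks):
        # the solution sits on (or within) the chi^2 = chi0^2 boundary;
        # with a fixed lambda per SNR the converged value stays in a band
        for snr in (1.0, 5.0, 10.0):
            spec = add_noise(truth, snr=snr, seed=11)
            res = mer_reconstruct(spec, spectrometer, MEROptions())
            assert res.converged
            assert 0.5 <= res.chi_sq <= 1.5, f"chi^2 {res.chi_sq} out of band at snr={snr}"
        # an informative prior can only improve the fit to the data
        res_prior = mer_reconstruct(
            add_noise(truth, snr=1.0, seed=11), spectrometer, MEROptions(prior=peaks)
        )
        assert res_prior.converged
        assert res_prior.chi_sq <= 1.5

    def test_deterministic(self, noisy_snr5, spectrometer, peaks):
        a = mer_reconstruct(noisy_snr5, spectrometer, MEROptions(prior=peaks))
        b = mer_reconstruct(noisy_snr5, spectrometer, MEROptions(prior=peaks))
        np.testing.assert_array_equal(a.f, b.f)

    def test_scale_invariance(self, noisy_snr5, spectrometer, peaks):
        res1 = mer_reconstruct(noisy_snr5, spectrometer, MEROptions(prior=peaks))
        scaled = noisy_snr5.copy()
        scaled.intensity = scaled.intensity * 1000.0
        scaled.noise_sigma = scaled.noise_sigma * 1000.0
        res2 = mer_reconstruct(scaled, spectrometer, MEROptions(prior=peaks))
        np.testing.assert_allclose(
            res1.f / res1.f.sum(), res2.f / res2.f.sum(), rtol=1e-9, atol=1e-15
        )

    def test_masked_pixels_do_not_influence_result(self, truth, spectrometer, peaks):
        spec = add_noise(truth, snr=5.0, seed=9).mask_frequency_range(-2.0, 2.0)
        res1 = mer_reconstruct(spec, spectrometer, MEROptions(prior=peaks))
        perturbed = spec.copy()
        perturbed.intensity[~spec.mask] += 5.0e4
        res2 = mer_reconstruct(perturbed, spectrometer, MEROptions(prior=peaks))
        np.testing.assert_array_equal(res1.f, res2.f)

    def test_no_solution_returns_without_iterating(self, truth, spectrometer):
        hopeless = add_noise(truth, snr=1.0, seed=2, snr_reference="rayleigh")
        if me_solution_exists(hopeless, spectrometer):
            pytest.skip("this seed happens to admit a solution")
        res = mer_reconstruct(hopeless, spectrometer)
        assert not res.exists
        assert res.n_iters == 0

    def test_tune_lambda_hits_constraint_boundary(self, noisy_snr5, spectrometer, peaks):
        res = mer_reconstruct(
            noisy_snr5, spectrometer,
            MEROptions(prior=peaks, tune_lambda=True),
        )
        assert res.chi_sq == pytest.approx(1.0, abs=0.05)


class TestTransformer:
    def test_transform_matches_functional_api(self, noisy_snr5, spectrometer, peaks):
        rec = MaximumEntropyReconstruction(
            spectrometer=spectrometer, noise_sigma=noisy_snr5.noise_sigma,
            prior=peaks, snr=5.0,
        )
        out = rec.fit_transform(noisy_snr5.intensity[None, :])
        res = mer_reconstruct(noisy_snr5, spectrometer, MEROptions(prior=peaks))
        np.testing.assert_allclose(out[0], res.f)
        assert rec.results_[0].converged

    def test_get_set_params_roundtrip(self):
        rec = MaximumEntropyReconstruction()
        params = rec.get_params()
        rec.set_params(**params)
        with pytest.raises(ValueError):
            rec.set_params(nonsense=1)
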