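"""AR model fitting, spectra, autocovariances, and simulation."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iriscap import (
    ARModel,
    DegenerateSignalError,
    PowerSpectrum,
    StabilityError,
    aic_sweep,
    ar_autocovariance,
    ar_psd,
    burg_fit,
    random_stable_ar,
    relative_entropy,
    sample_spectral_realizations,
    select_order,
    simulate_ar,
)


class TestBurgFit:
    @pytest.mark.parametrize(
        "coeffs, n, tol",
        [((0.5,), 100_000, 0.01), ((0.75, -0.5), 100_000, 0.02)],
    )
    def test_recovers_known_coefficients(self, coeffs, n, tol):
        truth = ARModel(order=len(coeffs), coeffs=coeffs, noise_variance=1.0)
        x = simulate_ar(truth, n, 1, seed=1)[0]
        fit = burg_fit(x, truth.order)
        assert np.allclose(fit.coeffs, coeffs, atol=tol)
        assert fit.noise_variance == pytest.approx(1.0, rel=0.02)
        assert fit.is_stable()

    def test_white_noise_has_negligible_serial_coefficient(self, rng):
        x = rng.standard_normal(10_000)
        assert abs(burg_fit(x, 1).coeffs[0]) < 0.05

    def test_matches_statsmodels_burg(self, ar2_model):
        """Independent lattice implementation agrees with statsmodels."""
        from statsmodels.regression.linear_model import burg as sm_burg

        x = simulate_ar(ar2_model, 5_000, 1, seed=3)[0]
        ours = burg_fit(x, 4)
        theirs, sigma2 = sm_burg(x, order=4, demean=False)
        assert np.allclose(ours.coeffs, theirs, atol=1e-8)
        # residual-power normalization conventions differ slightly
        assert ours.noise_variance == pytest.approx(sigma2, rel=1e-3)

    def test_levinson_durbin_cross_check(self, ar2_model):
        """Burg coefficients approach the Yule-Walker solution on long data."""
        x = simulate_ar(ar2_model, 200_000, 1, seed=9)[0]
        fit = burg_fit(x, 2)
        # Levinson-Durbin on the sample autocovariance
        r = np.array([np.dot(x[: x.size - k], x[k:]) / x.size for k in range(3)])
        yw = np.linalg.solve([[r[0], r[1]], [r[1], r[0]]], r[1:])
        assert np.allclose(fit.coeffs, yw, atol=5e-3)

    def test_rejects_degenerate_and_infeasible_input(self):
        with pytest.raises(DegenerateSignalError):
            burg_fit(np.ones(100), 1)
        with pytest.raises(ValueError):
            burg_fit(np.random.default_rng(0).standard_normal(10), 6)
        with pytest.raises(ValueError):
            burg_fit(np.random.default_rng(0).standard_normal(10), 0)


class TestPowerSpectrum:
    def test_white_noise_spectrum_is_flat(self):
        s = ar_psd(ARModel(0, (), 2.0), 64)
        assert np.allclose(s.values, 2.0)

    def test_ar1_closed_form_at_zero_frequency(self, ar1_model):
        s = ar_psd(ar1_model, 256)
        assert s.values[0] == pytest.approx(4.0)

    def test_conjugate_symmetry(self, ar2_model):
        s = ar_psd(ar2_model, 1024)
        assert np.allclose(s.values[1:], s.values[1:][::-1], rtol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_parseval_mean_equals_process_variance(self, seed):
        # grid long relative to the correlation length, so aliasing is nil
        model = random_stable_ar(5, seed=seed, max_pole_radius=0.5)
        s = ar_psd(model, 2048)
        r0 = ar_autocovariance(model, 0)[0]
        assert s.process_variance == pytest.approx(r0, rel=1e-6)

    def test_unstable_model_is_rejected(self):
        bad = ARModel(1, (1.05,), 1.0)
        with pytest.raises(StabilityError):
            ar_psd(bad, 64)

    def test_positivity_validation(self):
        with pytest.raises(ValueError):
            PowerSpectrum(3, np.array([1.0, -1.0, 1.0]))


class TestAutocovariance:
    def test_white_noise(self):
        r = ar_autocovariance(ARModel(0, (), 3.0), 4)
        assert r[0] == pytest.approx(3.0) and np.allclose(r[1:], 0.0)

    def test_ar1_closed_form(self, ar1_model):
        r = ar_autocovariance(ar1_model, 3)
        expected = [1 / 0.75 * 0.5**k for k in range(4)]
        assert np.allclose(r, expected)

    def test_matches_long_simulation(self, ar2_model):
        x = simulate_ar(ar2_model, 1_000_000, 1, seed=11)[0]
        r_hat = [np.dot(x[: x.size - k], x[k:]) / x.size for k in range(4)]
        r = ar_autocovariance(ar2_model, 3)
        assert np.allclose(r, r_hat, rtol=0.01)

    def test_bounded_by_lag_zero(self):
        model = random_stable_ar(6, seed=4, max_pole_radius=0.9)
        r = ar_autocovariance(model, 50)
        assert r[0] > 0 and np.all(np.abs(r[1:]) <= r[0])


class TestOrderSelection:
    def test_white_noise_selects_smallest_order(self, rng):
        curve = aic_sweep(rng.standard_normal(4_800), range(1, 9))
        assert select_order(curve) == 1

    def test_tolerance_zero_is_argmin_with_parsimony_ties(self):
        from iriscap.ar import AICCurve

        curve = AICCurve(orders=(1, 2, 3), scores=(5.0, 4.0, 4.0))
        assert select_order(curve, tol=0.0) == 2
        assert select_order(curve, tol=1.5) == 1

    def test_infeasible_orders_rejected(self, rng):
        with pytest.raises(ValueError):
            aic_sweep(rng.standard_normal(20), [15])


class TestSimulation:
    def test_same_seed_is_bit_identical(self, ar2_model):
        a = simulate_ar(ar2_model, 500, 3, seed=77)
        b = simulate_ar(ar2_model, 500, 3, seed=77)
        assert np.array_equal(a, b)

    def test_sample_variance_matches_theory(self, ar1_model):
        x = simulate_ar(ar1_model, 100_000, 1, seed=5)[0]
        assert x.var() == pytest.approx(4.0 / 3.0, rel=0.02)

    def test_zero_noise_variance_gives_zeros(self):
        silent = ARModel(1, (0.5,), 0.0)
        assert np.all(simulate_ar(silent, 100, 2, seed=0) == 0.0)


class TestRandomStableAR:
    @settings(derandomize=True, max_examples=25)
    @given(p=st.integers(1, 8), radius=st.floats(0.1, 0.98), seed=st.integers(0, 10_000))
    def test_always_stable_with_finite_spectrum(self, p, radius, seed):
        model = random_stable_ar(p, seed=seed, max_pole_radius=radius)
        assert model.is_stable()
        assert np.isfinite(ar_psd(model, 256).values).all()

    def test_first_order_coefficient_bounded_by_radius(self):
        model = random_stable_ar(1, seed=2, max_pole_radius=0.6)
        assert abs(model.coeffs[0]) < 0.6

    def test_distinct_seeds_give_distinct_spectra(self):
        s1 = ar_psd(random_stable_ar(4, seed=1), 512)
        s2 = ar_psd(random_stable_ar(4, seed=2), 512)
        assert relative_entropy(s1, s2) > 0


class TestSpectralSampler:
    def test_periodogram_mean_matches_target_spectrum(self, ar2_model):
        from iriscap import periodogram

        s = ar_psd(ar2_model, 256)
        x = sample_spectral_realizations(s, 4_000, seed=8)
        mean_per = periodogram(x).mean(axis=0)
        assert np.allclose(mean_per, s.values, rtol=0.1)

    def test_output_is_real_and_deterministic(self, ar1_model):
        s = ar_psd(ar1_model, 128)
        a = sample_spectral_realizations(s, 5, seed=3)
        b = sample_spectral_realizations(s, 5, seed=3)
        assert a.shape == (5, 128) and np.array_equal(a, b)


class TestSerialization:
    def test_armodel_json_round_trip(self, ar2_model):
        assert ARModel.from_json(ar2_model.to_json()) == ar2_model

    def test_spectrum_json_and_csv_round_trip(self, ar1_model, tmp_path):
        s = ar_psd(ar1_model, 64)
        restored = PowerSpectrum.from_json(s.to_json())
        assert restored.n_grid == 64 and np.array_equal(restored.values, s.values)
        path = tmp_path / "psd.csv"
        s.to_csv(path)
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        assert np.array_equal(arr[:, 1], s.values)
        assert json.loads(s.to_json())["n_grid"] == 64
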