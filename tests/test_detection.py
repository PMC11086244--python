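"""Pairwise class discrimination: Whittle LLR, exact LLR, relative entropy."""

import numpy as np
import pytest
from scipy import linalg, stats

from iriscap import (
    ARModel,
    GridMismatchError,
    PowerSpectrum,
    ar_autocovariance,
    ar_psd,
    decide,
    erlang_component_params,
    exact_gaussian_llr,
    pairwise_error_mc,
    random_stable_ar,
    relative_entropy,
    sample_lambda_component,
    simulate_ar,
    union_bound,
    whittle_llr,
)


def _spectrum(values):
    values = np.asarray(values, dtype=float)
    return PowerSpectrum(n_grid=values.size, values=values)


class TestWhittleLLR:
    def test_identical_spectra_give_zero(self, rng):
        s = _spectrum(rng.uniform(0.5, 2.0, 64))
        queries = [rng.standard_normal(64) for _ in range(3)]
        stat = whittle_llr(s, s, queries)
        assert stat.lambda_total == pytest.approx(0.0, abs=1e-12)

    def test_single_term_closed_form(self):
        # |y|^2 = S_m, ratio r = 2: Lambda = r - 1 - ln r
        stat = whittle_llr(_spectrum([2.0]), _spectrum([1.0]), [np.array([np.sqrt(2.0)])])
        assert stat.lambda_total == pytest.approx(2 - 1 - np.log(2), rel=1e-12)

    def test_total_is_negated_component_sum(self, rng):
        s_m = _spectrum(rng.uniform(0.5, 2.0, 32))
        s_k = _spectrum(rng.uniform(0.5, 2.0, 32))
        stat = whittle_llr(s_m, s_k, [rng.standard_normal(32)])
        assert stat.lambda_total == pytest.approx(-stat.lambda_components.sum())
        assert stat.n_images == 1

    def test_grid_mismatch_raises(self, rng):
        with pytest.raises(GridMismatchError):
            whittle_llr(_spectrum(np.ones(8)), _spectrum(np.ones(16)), [np.zeros(8)])
        with pytest.raises(GridMismatchError):
            whittle_llr(_spectrum(np.ones(8)), _spectrum(np.ones(8)), [np.zeros(9)])


class TestExactLLR:
    def test_identical_models_give_zero(self, ar2_model, rng):
        q = [rng.standard_normal(64)]
        assert exact_gaussian_llr(ar2_model, ar2_model, q) == pytest.approx(0.0, abs=1e-9)

    def test_two_by_two_brute_force(self, ar1_model):
        other = ARModel(1, (-0.3,), 2.0)
        y = np.array([0.7, -1.2])
        result = exact_gaussian_llr(ar1_model, other, [y])
        K_m = linalg.toeplitz(ar_autocovariance(ar1_model, 1))
        K_k = linalg.toeplitz(ar_autocovariance(other, 1))
        expected = -(
            y @ np.linalg.inv(K_m) @ y - y @ np.linalg.inv(K_k) @ y
        ) - np.log(np.linalg.det(K_m) / np.linalg.det(K_k))
        assert result == pytest.approx(expected, abs=1e-12)

    def test_whittle_agreement_improves_with_length(self, ar1_model, ar2_model):
        """The asymptotic statistic approaches the exact one as n grows."""
        rels = []
        for n in (128, 512):
            q = simulate_ar(ar1_model, n, 100, seed=13)
            exact = exact_gaussian_llr(ar1_model, ar2_model, list(q))
            approx = whittle_llr(ar_psd(ar1_model, n), ar_psd(ar2_model, n), list(q))
            rels.append(abs(exact - approx.lambda_total) / abs(exact))
        assert rels[1] < rels[0]


class TestRelativeEntropy:
    def test_zero_iff_identical(self, rng):
        s = _spectrum(rng.uniform(0.5, 2.0, 128))
        assert relative_entropy(s, s) == 0.0

    def test_single_frequency_closed_form(self):
        assert relative_entropy(_spectrum([2.0]), _spectrum([1.0])) == pytest.approx(
            2 - np.log(2) - 1
        )

    @pytest.mark.parametrize("seed", range(5))
    def test_nonnegative_on_random_spectra(self, seed):
        r = np.random.default_rng(seed)
        s_m = _spectrum(r.uniform(0.1, 5.0, 64))
        s_k = _spectrum(r.uniform(0.1, 5.0, 64))
        assert relative_entropy(s_m, s_k) >= 0

    def test_matches_toeplitz_gaussian_kl(self):
        """d equals the matrix KL on the two-sided spectral-sum scale (2x)."""
        m = ARModel(1, (0.3,), 1.0)
        k = ARModel(1, (0.6,), 1.0)
        n = 256
        K_m = linalg.toeplitz(ar_autocovariance(m, n - 1))
        K_k = linalg.toeplitz(ar_autocovariance(k, n - 1))
        kl = 0.5 * (
            np.trace(np.linalg.solve(K_k, K_m))
            - n
            + np.linalg.slogdet(K_k)[1]
            - np.linalg.slogdet(K_m)[1]
        )
        d = relative_entropy(ar_psd(m, n), ar_psd(k, n))
        assert d == pytest.approx(2 * kl, rel=0.05)


class TestErlangComponents:
    def test_equal_ratio_is_degenerate(self):
        p = erlang_component_params(_spectrum([1.0, 2.0]), _spectrum([1.0, 2.0]), 0)
        assert p.a == 0.0 and p.sigma2 == 0.0

    def test_ratio_two_closed_form(self):
        p = erlang_component_params(_spectrum([2.0]), _spectrum([1.0]), 0)
        assert p.a == pytest.approx(np.log(2)) and p.sigma2 == pytest.approx(-1.0)

    def test_sign_coupling(self, rng):
        s_m = _spectrum(rng.uniform(0.2, 4.0, 16))
        s_k = _spectrum(rng.uniform(0.2, 4.0, 16))
        for i in range(16):
            p = erlang_component_params(s_m, s_k, i)
            assert np.sign(p.sigma2) == pytest.approx(np.sign(-(np.exp(p.a) - 1)))

    def test_component_samples_follow_shifted_gamma(self):
        s_m = _spectrum([1.0, 0.5])
        s_k = _spectrum([1.0, 1.0])
        n_images = 8
        lam = sample_lambda_component(s_m, s_k, 1, n_images, reps=4_000, seed=21)
        p = erlang_component_params(s_m, s_k, 1, n_images)
        z = (lam - p.a) / p.sigma2
        ks = stats.kstest(z, stats.gamma(a=n_images, scale=1 / n_images).cdf)
        assert ks.pvalue > 0.01


class TestDecision:
    def test_rule_and_tie_convention(self, rng):
        s = _spectrum(rng.uniform(0.5, 2.0, 4))

        def stat_with_total(total):
            from iriscap import PairStatistic

            return PairStatistic("m", "k", 1, total, np.array([-total]))

        assert decide(stat_with_total(1.0)) == "m"
        assert decide(stat_with_total(-1.0)) == "k"
        assert decide(stat_with_total(0.0)) == "k"
        assert decide(stat_with_total(0.5), threshold=1.0) == "k"


class TestPairwiseErrorMC:
    def test_identical_classes_are_degenerate_at_the_tie(self, ar1_model):
        # S_m == S_k makes Lambda identically 0; the tie rule picks class k
        out = pairwise_error_mc(ar1_model, ar1_model, n_images=1, n=64, reps=400, seed=5)
        assert out["p_k_given_m"] == 1.0 and out["p_m_given_k"] == 0.0

    def test_nearly_identical_classes_approach_coin_flip(self, ar1_model):
        near = ARModel(1, (0.505,), 1.0)
        out = pairwise_error_mc(ar1_model, near, n_images=1, n=64, reps=400, seed=5)
        assert out["p_k_given_m"] == pytest.approx(0.5, abs=0.1)
        assert out["p_m_given_k"] == pytest.approx(0.5, abs=0.1)

    def test_separated_classes_have_tiny_error(self):
        m = random_stable_ar(3, seed=10, max_pole_radius=0.9)
        k = random_stable_ar(3, seed=20, max_pole_radius=0.9)
        d = relative_entropy(ar_psd(m, 256), ar_psd(k, 256))
        assert d > 50  # widely separated pair by construction
        out = pairwise_error_mc(m, k, n_images=1, n=256, reps=1_000, seed=6)
        assert out["p_k_given_m"] < 0.01 and out["p_m_given_k"] < 0.01

    def test_fixed_seed_is_reproducible(self, ar1_model, ar2_model):
        a = pairwise_error_mc(ar1_model, ar2_model, n_images=2, n=64, reps=200, seed=3)
        b = pairwise_error_mc(ar1_model, ar2_model, n_images=2, n=64, reps=200, seed=3)
        assert a == b


class TestUnionBound:
    def test_two_class_average(self):
        assert union_bound(np.array([[0.0, 0.1], [0.1, 0.0]])) == pytest.approx(0.1)

    def test_zero_matrix(self):
        assert union_bound(np.zeros((4, 4))) == 0.0

    def test_three_class_sum(self):
        m = np.full((3, 3), 0.2)
        np.fill_diagonal(m, 0.0)
        assert union_bound(m) == pytest.approx(0.4)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            union_bound(np.zeros((2, 3)))
        with pytest.raises(ValueError):
            union_bound(np.array([[0.0, 1.5], [0.2, 0.0]]))
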