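"""Closed-form theory: effective parameters, NegBin SFS, summary statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate
from scipy.special import gammaln

from spatialsfs.params import PopulationParams, SamplingKernel
from spatialsfs.theory import (
    EffectiveParams,
    afd_distribution,
    characteristic_length,
    effective_params,
    exp_scaled_e1,
    expected_summary_stats,
    population_afd_density,
    sampling_effect_scalar,
    sfs_pmf,
    sfs_small_theta,
)

EULER_GAMMA = 0.5772156649015329


def e1_quadrature(x: float) -> float:
    """Independent E1 oracle: E1(x) = int_1^inf exp(-x t)/t dt."""
    val, _ = integrate.quad(lambda t: math.exp(-x * t) / t, 1.0, np.inf, limit=200)
    return val


def e1_series(x: float) -> float:
    """Independent small-x oracle: E1(x) = -gamma - ln x + x - x^2/4 + ..."""
    acc = -EULER_GAMMA - math.log(x)
    for k in range(1, 12):
        acc += (-1) ** (k + 1) * x**k / (k * math.factorial(k))
    return acc


def mixture_pmf_quadrature(theta, gamma, n, k) -> float:
    """Gamma-Poisson mixture oracle: int Pois(k; n x) Gamma(x; theta, gamma) dx.

    After substituting ``y = (n + gamma) x`` the integral is
    ``C * int y**(alpha-1) exp(-y) dy`` with ``alpha = theta + k``; the
    endpoint singularity goes into an algebraic quadrature weight and the
    remaining factor ``exp(-y)`` is bounded, so adaptive quadrature gets
    full relative precision, combined with the prefactor in log space.
    """
    alpha = theta + k
    beta = n + gamma
    B = max(40.0, 20.0 * (k + 1.0), 3.0 * alpha)
    if alpha <= 1.0:
        # true endpoint singularity: algebraic-weight quadrature
        head, _ = integrate.quad(lambda y: math.exp(-y), 0.0, B, weight="alg",
                                 wvar=(alpha - 1.0, 0.0), epsabs=0.0, epsrel=1e-13,
                                 limit=400)
    else:
        head, _ = integrate.quad(
            lambda y: math.exp((alpha - 1.0) * math.log(y) - y), 0.0, B,
            points=[max(alpha - 1.0, 1e-3)], epsabs=0.0, epsrel=1e-13, limit=400)
    tail, _ = integrate.quad(
        lambda y: math.exp((alpha - 1.0) * math.log(y) - y), B, np.inf,
        epsabs=1e-300, epsrel=1e-13, limit=400)
    logpref = (theta * math.log(gamma) - gammaln(theta) - gammaln(k + 1)
               + k * math.log(n) - alpha * math.log(beta))
    return math.exp(logpref + math.log(head + tail))


class TestCharacteristicLength:
    def test_scaling(self):
        # ell_c = sigma / (2 sqrt(s)): doubling sigma doubles it, 4x s halves it
        base = characteristic_length(10.0, 0.01)
        assert base == pytest.approx(50.0)
        assert characteristic_length(20.0, 0.01) == pytest.approx(2 * base)
        assert characteristic_length(10.0, 0.04) == pytest.approx(base / 2)
        assert characteristic_length(2.0, 0.1) == pytest.approx(2.0 / (2 * math.sqrt(0.1)))

    @pytest.mark.parametrize("sigma,s", [(-1.0, 0.01), (0.0, 0.01), (1.0, 0.0),
                                         (1.0, 1.0), (1.0, -0.2)])
    def test_domain_errors(self, sigma, s):
        with pytest.raises(ValueError):
            characteristic_length(sigma, s)


class TestSamplingEffectScalar:
    def test_matches_e1_oracles(self):
        # x = 1: E1 by quadrature of the defining integral
        lam = sampling_effect_scalar(1.0, 1.0)
        expected = 4 * math.pi / (math.e * e1_quadrature(1.0))
        assert lam == pytest.approx(expected, rel=1e-9)
        assert lam == pytest.approx(21.073, rel=1e-3)
        # x = 0.01: E1 by alternating series
        lam = sampling_effect_scalar(0.1, 1.0)
        expected = 4 * math.pi / (math.exp(0.01) * e1_series(0.01))
        assert lam == pytest.approx(expected, rel=1e-9)
        assert lam == pytest.approx(3.081, rel=1e-3)

    def test_strictly_increasing_and_asymptotic(self):
        w = np.geomspace(1e-3, 1e3, 301)
        lam = sampling_effect_scalar(w, 1.0)
        assert np.all(np.diff(lam) > 0)
        assert np.all(np.isfinite(lam))
        # lambda -> 4 pi (w/ell_c)^2 for broad kernels
        broad = w >= 30
        rel = np.abs(lam[broad] / (4 * math.pi * w[broad] ** 2) - 1.0)
        assert rel.max() < 0.01

    def test_no_overflow_huge_argument(self):
        lam = sampling_effect_scalar(1e3, 1.0)  # x = 1e6
        assert math.isfinite(lam)
        assert lam == pytest.approx(4 * math.pi * 1e6, rel=1e-5)

    @pytest.mark.parametrize("x", [99.5, 100.5, 150.0])
    def test_scaled_e1_branches_agree(self, x):
        # both evaluation routes must agree through the switchover
        from scipy.special import exp1

        direct = math.exp(x) * exp1(x)
        assert exp_scaled_e1(x) == pytest.approx(direct, rel=1e-12)

    @pytest.mark.parametrize("w,ell", [(0.0, 1.0), (-1.0, 1.0), (1.0, 0.0)])
    def test_domain_errors(self, w, ell):
        with pytest.raises(ValueError):
            sampling_effect_scalar(w, ell)


class TestEffectiveParams:
    def test_uniform_equals_population_scaled(self, pop_reference, uniform_kernel):
        eff = effective_params(pop_reference, uniform_kernel)
        assert eff.theta_E == pytest.approx(2e7 * 1e-9)  # N mu with N = rho L^2
        assert eff.gamma_E == pytest.approx(2e7 * 0.01)  # N s

    def test_gaussian_composition(self, pop_reference):
        kern = SamplingKernel.gaussian(width=30.0)
        eff = effective_params(pop_reference, kern)
        ell = characteristic_length(10.0, 0.01)
        lam = sampling_effect_scalar(30.0, ell)
        assert eff.theta_E == pytest.approx(1e-9 * 20.0 * ell**2 * lam, rel=1e-12)
        assert eff.gamma_E == pytest.approx(0.01 * 20.0 * ell**2 * lam, rel=1e-12)

    @pytest.mark.parametrize("width", [1.0, 10.0, 50.0, 120.0])
    def test_theta_gamma_ratio_is_mu_over_s(self, pop_reference, width):
        eff = effective_params(pop_reference, SamplingKernel.gaussian(width=width))
        assert eff.theta_E / eff.gamma_E == pytest.approx(1e-9 / 0.01, rel=1e-12)

    def test_warns_outside_validity_domain(self, pop_reference):
        # effective population above N: w not << L
        with pytest.warns(RuntimeWarning, match="exceeds N"):
            effective_params(pop_reference, SamplingKernel.gaussian(width=900.0))

    def test_mu_zero_rejected(self):
        pop = PopulationParams(sigma=10.0, rho=20.0, mu=0.0, s=0.01, L=1000.0)
        with pytest.raises(ValueError, match="mu > 0"):
            effective_params(pop, SamplingKernel.uniform())


class TestSfsPmf:
    def test_geometric_special_case(self):
        # theta_E = 1, gamma_E = n: success prob 1/2 -> geometric
        eff = EffectiveParams(ell_c=1.0, lam=1.0, theta_E=1.0, gamma_E=100.0)
        assert sfs_pmf(eff, 100, 0) == pytest.approx(0.5)
        assert sfs_pmf(eff, 100, 1) == pytest.approx(0.25)
        assert sfs_pmf(eff, 100, 5) == pytest.approx(0.5**6)

    @pytest.mark.parametrize("theta,gamma,n", [(0.02, 2e5, 10_000), (1.0, 1e2, 1_000)])
    def test_matches_gamma_poisson_mixture(self, theta, gamma, n):
        eff = EffectiveParams(ell_c=1.0, lam=1.0, theta_E=theta, gamma_E=gamma)
        for k in (0, 1, 2, 5, 17, 50):
            assert sfs_pmf(eff, n, k) == pytest.approx(
                mixture_pmf_quadrature(theta, gamma, n, k), abs=1e-10)

    @settings(max_examples=40, deadline=None)
    @given(theta=st.floats(1e-4, 50.0), gamma=st.floats(1.0, 1e7),
           n=st.integers(1, 10**6))
    def test_normalizes(self, theta, gamma, n):
        # Scoped to the rare-variant regime E[K] = theta*n/gamma small that
        # the model targets; beyond it, accumulated gammaln rounding
        # (~E[K]*1e-15) exceeds the 1e-12 budget regardless of algorithm.
        from hypothesis import assume

        assume(theta * n / gamma <= 500)
        eff = EffectiveParams(ell_c=1.0, lam=1.0, theta_E=theta, gamma_E=gamma)
        # adaptive truncation: extend until a whole block adds < 1e-16
        from scipy import stats as sps

        p = gamma / (gamma + n)
        kmax = int(sps.nbinom(theta, p).ppf(1 - 1e-13)) + 10
        total = sfs_pmf(eff, n, np.arange(kmax + 1)).sum()
        while True:
            block = sfs_pmf(eff, n, np.arange(kmax + 1, kmax + 2049)).sum()
            total += block
            kmax += 2048
            if block < 1e-16:
                break
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_vectorized_and_domain_errors(self):
        eff = EffectiveParams(ell_c=1.0, lam=1.0, theta_E=0.1, gamma_E=50.0)
        vals = sfs_pmf(eff, 100, np.arange(5))
        assert vals.shape == (5,)
        with pytest.raises(ValueError):
            sfs_pmf(eff, 0, 1)
        with pytest.raises(ValueError):
            sfs_pmf(eff, 100, -1)
        with pytest.raises(ValueError):
            sfs_pmf(eff, 100, 1.5)


class TestSmallThetaSfs:
    def test_singleton_formula(self):
        eff = EffectiveParams(ell_c=1.0, lam=1.0, theta_E=1e-3, gamma_E=300.0)
        n = 1000
        assert sfs_small_theta(eff, n, 1) == pytest.approx(1e-3 * n / (300.0 + n))

    @pytest.mark.parametrize("theta", [1e-3, 5e-3, 1e-2])
    def test_relative_error_bounded_by_2_theta(self, theta):
        # The O(theta) error coefficient is |ln(1 + n/gamma) - H_{k-1}|,
        # so a uniform 2*theta bound over k <= 20 holds when n/gamma puts
        # ln(1 + n/gamma) mid-way through the harmonic range (~5 here).
        n = 10_000
        eff = EffectiveParams(ell_c=1.0, lam=1.0, theta_E=theta, gamma_E=n / 5.0)
        ks = np.arange(1, 21)
        rel = np.abs(sfs_small_theta(eff, n, ks) / sfs_pmf(eff, n, ks) - 1.0)
        assert rel.max() <= 2.0 * theta

    @pytest.mark.parametrize("gamma", [1e2, 1e4, 1e6])
    def test_relative_error_follows_log_harmonic_form(self, gamma):
        # General first-order error: theta * |ln(1 + n/gamma) - H_{k-1}|
        theta, n = 1e-3, 10_000
        eff = EffectiveParams(ell_c=1.0, lam=1.0, theta_E=theta, gamma_E=gamma)
        ks = np.arange(1, 21)
        rel = np.abs(sfs_small_theta(eff, n, ks) / sfs_pmf(eff, n, ks) - 1.0)
        harm = np.concatenate([[0.0], np.cumsum(1.0 / np.arange(1, 20))])
        bound = theta * np.abs(math.log1p(n / gamma) - harm)
        np.testing.assert_array_less(rel, bound * (1 + 20 * theta) + 1e-9)

    def test_strong_selection_limit(self):
        eff = EffectiveParams(ell_c=1.0, lam=1.0, theta_E=1e-3, gamma_E=1e12)
        assert sfs_small_theta(eff, 100, 1) < 1e-12
        with pytest.raises(ValueError):
            sfs_small_theta(eff, 100, 0)


class TestSummaryExpectations:
    def test_mean_frequency_is_mutation_selection_balance(self, pop_reference):
        for kern in (SamplingKernel.uniform(), SamplingKernel.gaussian(width=40.0)):
            eff = effective_params(pop_reference, kern)
            st_ = expected_summary_stats(eff, pop_reference, 10_000, M=100)
            assert st_.mean_freq_all == pop_reference.mu / pop_reference.s
            assert st_.cmaf == pytest.approx(100 * pop_reference.mu / pop_reference.s)
            assert st_.het == pytest.approx(2 * pop_reference.mu / pop_reference.s)

    def test_variant_and_singleton_probabilities(self, pop_reference):
        eff = effective_params(pop_reference, SamplingKernel.gaussian(width=40.0))
        n = 10_000
        st_ = expected_summary_stats(eff, pop_reference, n)
        assert st_.p_variant == pytest.approx(1.0 - float(sfs_pmf(eff, n, 0)), rel=1e-12)
        # cross-check by summing the pmf over k >= 1
        ks = np.arange(1, 2000)
        assert st_.p_variant == pytest.approx(float(sfs_pmf(eff, n, ks).sum()), rel=1e-6)
        assert 0.0 <= st_.p_singleton <= st_.p_variant <= 1.0
        assert st_.mean_freq_variant >= st_.mean_freq_all
        assert st_.het_exact == pytest.approx(st_.het, rel=0.02)  # rare-allele regime

    def test_inconsistent_eff_pop_rejected(self, pop_reference):
        eff = EffectiveParams(ell_c=1.0, lam=1.0, theta_E=1.0, gamma_E=1.0)
        with pytest.raises(ValueError, match="inconsistent"):
            expected_summary_stats(eff, pop_reference, 100)


class TestAfdDensity:
    def test_gamma_mean_and_exponential_case(self):
        eff = EffectiveParams(ell_c=1.0, lam=1.0, theta_E=0.5, gamma_E=100.0)
        dist = afd_distribution(eff)
        assert dist.mean() == pytest.approx(0.5 / 100.0)
        # theta_E = 1 reduces to exponential with rate gamma_E
        eff1 = EffectiveParams(ell_c=1.0, lam=1.0, theta_E=1.0, gamma_E=50.0)
        x = np.array([1e-4, 1e-3, 1e-2])
        np.testing.assert_allclose(
            population_afd_density(eff1, x), 50.0 * np.exp(-50.0 * x), rtol=1e-12)
        with pytest.raises(ValueError):
            population_afd_density(eff1, 0.0)
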