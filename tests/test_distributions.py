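"""Distribution kernels: closed-form values, normalization, samplers."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import invgauss, kstest

from rdex.distributions import (
    DegenerateTruncationError,
    GoRunnerParams,
    StopRunnerParams,
    exg_cdf,
    exg_density,
    trunc_exg_density,
    trunc_exg_moments,
    trunc_exg_sample,
    trunc_exg_survival,
    wald_density,
    wald_sample,
    wald_survival,
)


class TestWald:
    def test_spot_value(self):
        # independent evaluation of the first-passage density at td=1, v=2, b=1
        assert wald_density(1.0, 2.0, 1.0) == pytest.approx(0.24197, abs=1e-5)

    def test_zero_at_origin_and_negative_time(self):
        assert wald_density(0.0, 2.0, 1.0) == 0.0
        assert wald_density(-0.5, 2.0, 1.0) == 0.0
        assert wald_density(1e-12, 5.0, 2.0) == 0.0

    def test_density_normalizes(self):
        total, _ = quad(wald_density, 0, np.inf, args=(2.0, 1.0))
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_survival_limits_and_spot(self):
        assert wald_survival(0.0, 2.0, 1.0) == 1.0
        assert wald_survival(1e4, 2.0, 1.0) == pytest.approx(0.0, abs=1e-12)
        # complement of the integrated density over (0, 0.5]
        assert wald_survival(0.5, 2.0, 1.0) == pytest.approx(0.372, abs=2e-3)

    def test_survival_matches_quadrature(self):
        for td in (0.2, 0.5, 1.0, 2.5):
            integral, _ = quad(wald_density, 0, td, args=(1.5, 1.2))
            assert wald_survival(td, 1.5, 1.2) == pytest.approx(1 - integral, abs=1e-8)

    def test_survival_monotone_nonincreasing(self):
        grid = np.linspace(0.0, 5.0, 200)
        vals = wald_survival(grid, 2.0, 1.0)
        assert np.all(np.diff(vals) <= 1e-12)

    @pytest.mark.parametrize("v,b", [(-1.0, 1.0), (2.0, 0.0), (0.0, 1.0)])
    def test_invalid_parameters_raise(self, v, b):
        with pytest.raises(ValueError):
            wald_density(1.0, v, b)

    def test_matches_scipy_invgauss(self):
        # inverse-Gaussian with mean b/v and shape b^2
        v, b = 2.0, 1.5
        mu_ig = b / v / (b * b)
        t = np.array([0.3, 0.7, 1.5])
        expected = invgauss.pdf(t, mu_ig, scale=b * b)
        np.testing.assert_allclose(wald_density(t, v, b), expected, rtol=1e-10)
        np.testing.assert_allclose(
            wald_survival(t, v, b), invgauss.sf(t, mu_ig, scale=b * b), rtol=1e-9
        )

    def test_sampler_mean_and_support(self, rng):
        params = GoRunnerParams(v=2.0, B=1.0, A=0.0, t0=0.3)
        draws = wald_sample(200_000, params, rng)
        assert np.all(draws > params.t0)
        # mean = t0 + b/v = 0.8; SE of the mean ~ sd/sqrt(n)
        se = draws.std() / np.sqrt(draws.size)
        assert abs(draws.mean() - 0.8) < 3 * se

    def test_sampler_matches_density(self, rng):
        v, b = 2.0, 1.0
        params = GoRunnerParams(v=v, B=b, A=0.0, t0=0.0)
        draws = wald_sample(200_000, params, rng)
        mu_ig = b / v / (b * b)
        stat = kstest(draws, lambda x: invgauss.cdf(x, mu_ig, scale=b * b))
        assert stat.statistic < 0.005

    def test_start_point_variability_shrinks_mean(self, rng):
        fixed = wald_sample(100_000, GoRunnerParams(v=2.0, B=1.0), rng).mean()
        varied = wald_sample(
            100_000, GoRunnerParams(v=2.0, B=0.5, A=0.5), rng
        ).mean()
        assert varied < fixed  # barrier distance b - U(0, A) <= b


class TestExGaussian:
    def test_spot_values(self):
        # 10 e^0.5 Phi(-1) and the matching CDF value at the Gaussian mean
        assert exg_density(0.5, 0.5, 0.1, 0.1) == pytest.approx(2.616, abs=2e-3)
        assert exg_cdf(0.5, 0.5, 0.1, 0.1) == pytest.approx(0.2384, abs=2e-4)

    def test_density_normalizes_and_vanishes(self):
        total, _ = quad(exg_density, -2, 8, args=(0.5, 0.1, 0.2))
        assert total == pytest.approx(1.0, abs=1e-7)
        assert exg_density(1e3, 0.5, 0.1, 0.1) == 0.0

    def test_cdf_limits_and_quadrature(self):
        assert exg_cdf(-np.inf, 0.5, 0.1, 0.1) == 0.0
        assert exg_cdf(np.inf, 0.5, 0.1, 0.1) == 1.0
        integral, _ = quad(exg_density, -2, 0.5, args=(0.5, 0.1, 0.1))
        assert exg_cdf(0.5, 0.5, 0.1, 0.1) == pytest.approx(integral, abs=1e-7)

    @pytest.mark.parametrize("sigma,tau", [(1e-4, 0.1), (0.1, 1e-4), (1e-4, 1e-4), (10, 10)])
    def test_log_space_stability(self, sigma, tau):
        t = np.array([-40 * sigma, 0.0, 0.5, 40 * sigma + 5 * tau]) + 0.2
        dens = exg_density(t, 0.2, sigma, tau)
        cdf = exg_cdf(t, 0.2, sigma, tau)
        assert np.all(np.isfinite(dens)) and np.all(dens >= 0)
        assert np.all(np.isfinite(cdf)) and np.all((cdf >= 0) & (cdf <= 1))
        assert np.all(np.diff(cdf) >= -1e-12)

    def test_invalid_scale_raises(self):
        with pytest.raises(ValueError):
            exg_density(0.5, 0.5, -0.1, 0.1)
        with pytest.raises(ValueError):
            exg_cdf(0.5, 0.5, 0.1, 0.0)


class TestTruncatedExGaussian:
    params = StopRunnerParams(mu=0.2, sigma=0.05, tau=0.08)

    def test_zero_below_support(self):
        assert trunc_exg_density(0.04, self.params) == 0.0
        assert trunc_exg_density(-1.0, self.params) == 0.0

    def test_untruncated_identity(self):
        p = StopRunnerParams(mu=0.2, sigma=0.05, tau=0.08, lower=-np.inf, upper=np.inf)
        for t in (0.0, 0.1, 0.3, 0.7):
            assert trunc_exg_density(t, p) == pytest.approx(
                exg_density(t, 0.2, 0.05, 0.08), rel=1e-12
            )

    def test_normalizes_over_support(self):
        total, _ = quad(lambda t: trunc_exg_density(t, self.params), 0.05, 10)
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_survival_limits(self):
        assert trunc_exg_survival(0.05, self.params) == 1.0
        assert trunc_exg_survival(0.0, self.params) == 1.0
        assert trunc_exg_survival(50.0, self.params) == pytest.approx(0.0, abs=1e-12)
        bounded = StopRunnerParams(mu=0.2, sigma=0.05, tau=0.08, upper=0.6)
        assert trunc_exg_survival(0.6, bounded) == 0.0

    def test_survival_matches_quadrature(self):
        t_mid = 0.3
        tail, _ = quad(lambda t: trunc_exg_density(t, self.params), t_mid, 10)
        assert trunc_exg_survival(t_mid, self.params) == pytest.approx(tail, abs=1e-7)

    def test_sampler_support_and_distribution(self, rng):
        draws = trunc_exg_sample(200_000, self.params, rng)
        assert draws.min() >= 0.05
        stat = kstest(draws, lambda x: 1 - trunc_exg_survival(x, self.params))
        assert stat.statistic < 0.005

    def test_sampler_rejection_fallback(self, rng):
        # heavy truncation (< 1% acceptance) exercises the bisection path
        p = StopRunnerParams(mu=0.0, sigma=0.1, tau=0.05, lower=0.5, upper=0.8)
        draws = trunc_exg_sample(20_000, p, rng)
        assert np.all((draws >= 0.5) & (draws <= 0.8))
        stat = kstest(draws, lambda x: 1 - trunc_exg_survival(x, p))
        assert stat.statistic < 0.02

    def test_degenerate_truncation_raises(self, rng):
        p = StopRunnerParams(mu=0.0, sigma=0.01, tau=0.01, lower=5.0, upper=5.1)
        with pytest.raises(DegenerateTruncationError):
            trunc_exg_sample(10, p, rng)

    def test_moments_untruncated_closed_form(self):
        p = StopRunnerParams(mu=0.2, sigma=0.05, tau=0.1, lower=-np.inf, upper=np.inf)
        mean, sd = trunc_exg_moments(p, n_mc=400_000, seed=1)
        assert mean == pytest.approx(0.3, abs=3 * 0.112 / np.sqrt(400_000) + 1e-4)
        assert sd == pytest.approx(np.sqrt(0.05**2 + 0.1**2), abs=1e-3)

    def test_moments_match_quadrature(self):
        mean, _ = trunc_exg_moments(self.params, n_mc=400_000, seed=2)
        exact, _ = quad(lambda t: t * trunc_exg_density(t, self.params), 0.05, 10)
        assert mean == pytest.approx(exact, abs=1e-3)

    def test_moments_reproducible(self):
        m1 = trunc_exg_moments(self.params, n_mc=10_000, seed=7)
        m2 = trunc_exg_moments(self.params, n_mc=10_000, seed=7)
        assert m1 == m2


class TestParamValidation:
    def test_go_runner_invariants(self):
        with pytest.raises(ValueError):
            GoRunnerParams(v=0.0, B=1.0)
        with pytest.raises(ValueError):
            GoRunnerParams(v=1.0, B=-0.1)
        with pytest.raises(ValueError):
            GoRunnerParams(v=1.0, B=0.0, A=0.0)  # b = 0
        p = GoRunnerParams(v=1.0, B=0.7, A=0.3)
        assert p.b == pytest.approx(1.0)

    def test_stop_runner_invariants(self):
        with pytest.raises(ValueError):
            StopRunnerParams(mu=0.2, sigma=0.0, tau=0.1)
        with pytest.raises(ValueError):
            StopRunnerParams(mu=0.2, sigma=0.1, tau=0.1, lower=0.5, upper=0.4)
        defaults = StopRunnerParams(mu=0.2, sigma=0.1, tau=0.1)
        assert defaults.lower == 0.05 and np.isinf(defaults.upper)
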