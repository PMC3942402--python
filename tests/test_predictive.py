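"""Posterior grid, predictive density, moments and intervals."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import integrate

from eesurv import (
    PredictiveModel,
    build_posterior_grid,
    log_likelihood,
    log_unnorm_posterior,
    predictive_cdf,
    predictive_interval,
    predictive_pdf,
    predictive_quantile,
    predictive_raw_moments,
    raw_to_central,
    shape_measures,
)
from eesurv.predictive import sample_predictive


class TestLogUnnormPosterior:
    def test_unit_case(self):
        # n=1, x={1}, alpha=lam=1: 0*ln1 + 2*ln1 - 2 + 0
        assert log_unnorm_posterior(1.0, 1.0, [1.0]) == pytest.approx(-2.0)

    def test_factorizes_into_likelihood_plus_prior(self, ee_cohort):
        # posterior kernel = EE likelihood * lam*exp(-lam)/alpha
        rng = np.random.default_rng(0)
        for _ in range(5):
            a = rng.uniform(0.5, 3.0)
            lam = rng.uniform(0.005, 0.05)
            lhs = log_unnorm_posterior(a, lam, ee_cohort)
            rhs = (
                log_likelihood("ee", (a, lam), ee_cohort)
                + np.log(lam)
                - lam
                - np.log(a)
            )
            assert lhs == pytest.approx(rhs, rel=1e-12, abs=1e-8)

    def test_finite_at_cohort_scale(self, ee_cohort):
        val = log_unnorm_posterior(1.2, 0.016, ee_cohort)
        assert np.isfinite(val)
        assert val < 0

    def test_invalid_arguments(self):
        assert log_unnorm_posterior(-1.0, 1.0, [1.0]) == -np.inf
        assert log_unnorm_posterior(1.0, 0.0, [1.0]) == -np.inf


class TestPosteriorGrid:
    def test_weights_normalized(self, posterior_grid):
        assert posterior_grid.weights.sum() == pytest.approx(1.0, abs=1e-10)
        assert np.all(posterior_grid.weights >= 0)

    def test_grid_brackets_mode(self, posterior_grid):
        a_mode, l_mode = posterior_grid.mode
        sd_a, sd_l = posterior_grid.laplace_sd
        assert posterior_grid.alpha[0] <= a_mode - 5.9 * sd_a
        assert posterior_grid.alpha[-1] >= a_mode + 5.9 * sd_a
        assert posterior_grid.lam[0] <= l_mode - 5.9 * sd_l
        assert posterior_grid.lam[-1] >= l_mode + 5.9 * sd_l

    def test_marginal_means_match_independent_sampler(self, ee_cohort, posterior_grid):
        # emcee ensemble sampling of the same unnormalized posterior
        # (in log-parameters, hence the +rho Jacobian) as a second route
        import emcee

        def log_prob(v):
            if np.any(np.abs(v) > 20):
                return -np.inf
            a, lam = np.exp(v)
            return log_unnorm_posterior(a, lam, ee_cohort) + v.sum()

        rng = np.random.default_rng(1)
        p0 = np.log([posterior_grid.mode[0], posterior_grid.mode[1]]) + 0.01 * rng.standard_normal((16, 2))
        sampler = emcee.EnsembleSampler(16, 2, log_prob)
        sampler.random_state = np.random.RandomState(7).get_state()
        sampler.run_mcmc(p0, 2_000)
        chain = np.exp(sampler.get_chain(discard=500, flat=True))
        from eesurv import mc_error

        for idx, grid_mean in enumerate(
            (posterior_grid.marginal_alpha_mean, posterior_grid.marginal_lam_mean)
        ):
            mcse = mc_error(chain[:, idx])
            assert abs(chain[:, idx].mean() - grid_mean) < 4 * mcse

    def test_resolution_convergence(self, ee_cohort, posterior_grid):
        fine = build_posterior_grid(ee_cohort, grid_size=401)
        m_coarse = predictive_raw_moments(posterior_grid, kmax=1)[0]
        m_fine = predictive_raw_moments(fine, kmax=1)[0]
        assert abs(m_fine - m_coarse) / m_coarse < 1e-3


class TestPredictiveDensity:
    def test_normalization(self, posterior_grid):
        total, _ = integrate.quad(
            lambda z: predictive_pdf(z, posterior_grid), 0, np.inf, limit=300
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_unimodal_right_skewed(self, ee_cohort, posterior_grid):
        z = np.linspace(1.0, 600.0, 600)
        dens = predictive_pdf(z, posterior_grid)
        peak = int(np.argmax(dens))
        diffs = np.diff(dens)
        assert np.all(diffs[: max(peak - 1, 1)] > -1e-12)
        assert np.all(diffs[peak + 1:] < 1e-12)
        m1, m2, m3 = predictive_raw_moments(posterior_grid, kmax=3)
        mu2 = m2 - m1**2
        mu3 = m3 - 3 * m1 * m2 + 2 * m1**3
        assert mu3 / mu2**1.5 > 0  # gamma1 > 0

    def test_domain_errors(self, posterior_grid):
        with pytest.raises(ValueError):
            predictive_pdf(0.0, posterior_grid)
        with pytest.raises(ValueError):
            predictive_pdf(-3.0, posterior_grid)
        with pytest.raises(ValueError):
            predictive_cdf(-1.0, posterior_grid)
        assert predictive_cdf(0.0, posterior_grid) == 0.0


@pytest.fixture(scope="module")
def lomax_setup(ee_cohort):
    grid = build_posterior_grid(
        ee_cohort, grid_size=401, span_sd=10.0, alpha_fixed=1.0
    )
    S = float(np.sum(ee_cohort) + 1.0)
    return grid, S, len(ee_cohort)


class TestLomaxOracle:
    """With alpha frozen at 1 the lam-integral is conjugate: the predictive
    is Lomax with shape n+2 and scale S = sum(x) + 1."""

    def test_density_matches_closed_form(self, lomax_setup):
        grid, S, n = lomax_setup
        z = np.linspace(1e-3, 5 * S, 500)
        closed = np.exp(
            np.log(n + 2) + (n + 2) * np.log(S) - (n + 3) * np.log(S + z)
        )
        assert np.max(np.abs(predictive_pdf(z, grid) - closed)) < 1e-8

    def test_quantiles_match_closed_form(self, lomax_setup):
        grid, S, n = lomax_setup
        for p in (0.05, 0.5, 0.95, 0.975):
            q_true = S * ((1 - p) ** (-1.0 / (n + 2)) - 1.0)
            assert predictive_quantile(grid, p) == pytest.approx(q_true, rel=1e-6)

    def test_moments_match_closed_form(self, lomax_setup):
        grid, S, n = lomax_setup
        m1, m2 = predictive_raw_moments(grid, kmax=2)
        assert m1 == pytest.approx(S / (n + 1), rel=1e-6)
        assert m2 == pytest.approx(2 * S**2 / ((n + 1) * n), rel=1e-6)


class TestMomentPipeline:
    def test_raw_to_central_identity_case(self):
        assert raw_to_central(0.0, 1.0, 0.0, 3.0) == (0.0, 1.0, 0.0, 3.0)

    def test_inconsistent_moments_rejected(self):
        with pytest.raises(ValueError):
            raw_to_central(2.0, 1.0, 0.0, 0.0)

    @given(c=st.sampled_from([1.0, 100.0]), seed=st.integers(0, 10))
    def test_shift_invariance(self, c, seed):
        rng = np.random.default_rng(seed)
        x = rng.exponential(10.0, 500)
        def raws(v):
            return tuple(np.mean(v**k) for k in range(1, 5))
        _, mu2a, mu3a, mu4a = raw_to_central(*raws(x))
        _, mu2b, mu3b, mu4b = raw_to_central(*raws(x + c))
        assert mu2b == pytest.approx(mu2a, rel=1e-9)
        assert mu3b == pytest.approx(mu3a, rel=1e-6, abs=1e-6)
        assert mu4b == pytest.approx(mu4a, rel=1e-6)

    def test_shape_measures_normal_case(self):
        assert shape_measures(1.0, 0.0, 3.0) == (0.0, 3.0, 0.0, 0.0)

    @given(
        mu2=st.floats(0.1, 1e4),
        mu3=st.floats(-1e5, 1e5),
        mu4=st.floats(0.1, 1e8),
    )
    def test_shape_measure_identities(self, mu2, mu3, mu4):
        beta1, beta2, gamma1, gamma2 = shape_measures(mu2, mu3, mu4)
        assert gamma1**2 == pytest.approx(beta1, rel=1e-9, abs=1e-12)
        assert gamma2 == pytest.approx(beta2 - 3.0, rel=1e-12, abs=1e-12)
        assert beta1 >= 0

    def test_shape_measures_rejects_degenerate(self):
        with pytest.raises(ValueError):
            shape_measures(0.0, 1.0, 1.0)


class TestIntervalsAndModel:
    def test_interval_nesting(self, ee_cohort):
        model = PredictiveModel(random_state=0).fit(ee_cohort)
        i90 = model.interval(0.90)
        i95 = model.interval(0.95)
        i99 = model.interval(0.99)
        assert i99[0] < i95[0] < i90[0] < i90[1] < i95[1] < i99[1]

    def test_level_validation(self, posterior_grid):
        for level in (0.0, 1.0, -0.1):
            with pytest.raises(ValueError):
                predictive_interval(posterior_grid, level=level)

    def test_monte_carlo_cross_check_of_mean(self, ee_cohort):
        model = PredictiveModel(random_state=5).fit(ee_cohort)
        m1 = model.raw_moments(1)[0]
        draws = model.sample(200_000, random_state=9)
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - m1) < 3 * se

    def test_summary_internal_consistency(self, ee_cohort):
        model = PredictiveModel(random_state=2).fit(ee_cohort)
        s = model.summary()
        assert s["mu1"] == s["m1"] == s["mean"]
        assert s["gamma1"] == pytest.approx(np.sqrt(s["beta1"]), rel=1e-12)
        assert s["gamma2"] == pytest.approx(s["beta2"] - 3.0, rel=1e-12)
        assert s["mu2"] >= 0
        assert s["gamma1"] > 0  # right-skewed predictive
        lo90, hi90 = s["intervals"]["0.9"]
        lo99, hi99 = s["intervals"]["0.99"]
        assert lo99 < lo90 and hi90 < hi99
        assert s["mean_mc_se"] > 0

    def test_sampler_validation(self, posterior_grid):
        with pytest.raises(ValueError):
            sample_predictive(posterior_grid, 0)
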