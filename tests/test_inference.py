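"""Likelihoods, log-scale posteriors, Metropolis sampling and summaries."""

import numpy as np
import pytest

from eesurv import (
    McmcConfig,
    PriorBox,
    default_prior_box,
    log_likelihood,
    log_posterior_rho,
    mc_error,
    run_mcmc,
    summarize,
)
from eesurv.families import FAMILIES, log_pdf
from eesurv.inference import BayesianSurvivalFit, check_survival_times

from conftest import TRUE_ALPHA, TRUE_LAM


class TestLogLikelihood:
    def test_unit_case(self):
        assert log_likelihood("ee", (1.0, 1.0), [1.0]) == pytest.approx(-1.0)

    def test_two_point_closed_form(self):
        expected = 2 * np.log(2) + np.log(1 - np.exp(-1)) + np.log(1 - np.exp(-2)) - 3
        assert log_likelihood("ee", (2.0, 1.0), [1.0, 2.0]) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(-2.217794, abs=1e-6)

    def test_nonpositive_data_rejected(self):
        with pytest.raises(ValueError):
            log_likelihood("ee", (2.0, 1.0), [1.0, 2.0, -1.0])

    def test_invalid_params_give_neg_inf_not_exception(self):
        assert log_likelihood("ee", (-1.0, 1.0), [1.0]) == -np.inf
        assert log_likelihood("ee", (np.nan, 1.0), [1.0]) == -np.inf

    @pytest.mark.parametrize("fam", list(FAMILIES))
    def test_equals_sum_of_log_pdf(self, fam, ee_cohort):
        rng = np.random.default_rng(3)
        params = rng.uniform(0.5, 2.0, FAMILIES[fam].n_params)
        if fam in ("ee", "ew", "bge"):
            params[-1] = 0.02  # month-scale rate
        expected = float(np.sum(log_pdf(fam, params, ee_cohort)))
        assert log_likelihood(fam, params, ee_cohort) == pytest.approx(
            expected, rel=1e-12, abs=1e-10
        )


class TestLogPosteriorRho:
    def test_reduces_to_loglik_inside_box(self):
        box = PriorBox.wide(2)
        val = log_posterior_rho("ee", (0.0, 0.0), [1.0], box)
        assert val == pytest.approx(log_likelihood("ee", (1.0, 1.0), [1.0]))

    def test_outside_box_is_neg_inf(self):
        box = PriorBox.wide(2)
        assert log_posterior_rho("ee", (11.0, 0.0), [1.0], box) == -np.inf

    def test_flat_prior_difference_property(self, ee_cohort):
        box = PriorBox.wide(2)
        rng = np.random.default_rng(5)
        for _ in range(5):
            ra, rb = rng.uniform(-1, 1, 2), rng.uniform(-1, 1, 2)
            d_post = log_posterior_rho("ee", ra, ee_cohort, box) - log_posterior_rho(
                "ee", rb, ee_cohort, box
            )
            d_lik = log_likelihood("ee", np.exp(ra), ee_cohort) - log_likelihood(
                "ee", np.exp(rb), ee_cohort
            )
            assert d_post == pytest.approx(d_lik, rel=1e-12, abs=1e-9)

    def test_prior_box_validation(self):
        with pytest.raises(ValueError):
            PriorBox(((1.0, 1.0),))
        box = default_prior_box("ew")
        assert box.n_components == 3


class TestMcmc:
    def test_parameter_recovery(self, ee_mcmc_draws):
        summ = summarize(ee_mcmc_draws)
        for node, truth in (("alpha", TRUE_ALPHA), ("lam", TRUE_LAM)):
            mean, sd = summ.loc[node, "mean"], summ.loc[node, "sd"]
            assert abs(mean - truth) < 3 * sd

    def test_seed_determinism(self, ee_cohort):
        cfg = McmcConfig(iterations=1_200, burn_in=200, seed=99)
        a = run_mcmc("ee", ee_cohort, box=PriorBox.wide(2), config=cfg)
        b = run_mcmc("ee", ee_cohort, box=PriorBox.wide(2), config=cfg)
        np.testing.assert_array_equal(a.rho, b.rho)

    def test_draws_stay_inside_box(self, ee_mcmc_draws):
        box = ee_mcmc_draws.box
        assert np.all(ee_mcmc_draws.rho >= box.low)
        assert np.all(ee_mcmc_draws.rho <= box.high)
        assert ee_mcmc_draws.n_retained == 4_000

    def test_box_excluding_mle_piles_at_nearest_boundary(self, ee_cohort):
        # log(lam) of the data sits near -4.1; a (5, 6) box forces the chain
        # against the lower edge, where the likelihood is largest
        box = PriorBox(((-10.0, 10.0), (5.0, 6.0)))
        draws = run_mcmc(
            "ee", ee_cohort, box=box,
            config=McmcConfig(iterations=2_000, burn_in=500, seed=3),
        )
        rho2 = draws.rho[:, 1]
        assert np.percentile(rho2, 99) < 5.05

    def test_jensen_gap_between_scales(self, ee_mcmc_draws):
        # E[log alpha] <= log E[alpha] by concavity of the logarithm
        summ = summarize(ee_mcmc_draws)
        assert summ.loc["rho_1", "mean"] <= np.log(summ.loc["alpha", "mean"])

    def test_acceptance_rate_adapted_into_band(self, ee_mcmc_draws):
        assert np.all(ee_mcmc_draws.acceptance_rate > 0.10)
        assert np.all(ee_mcmc_draws.acceptance_rate < 0.60)

    def test_interval_coverage_over_replicates(self):
        """95% credible intervals cover the generating values in >= 90/100
        scaled-down replicate chains."""
        from eesurv import sample

        cov_a = cov_l = 0
        for child in np.random.SeedSequence(2024).spawn(100):
            s = int(child.generate_state(1)[0] % 2**31)
            xs = sample("ee", (TRUE_ALPHA, TRUE_LAM), 298, seed=s)
            d = run_mcmc(
                "ee", xs, box=PriorBox.wide(2),
                config=McmcConfig(iterations=5_000, burn_in=1_000, seed=s + 1),
            )
            su = summarize(d)
            cov_a += su.loc["alpha", "ci_low"] <= TRUE_ALPHA <= su.loc["alpha", "ci_high"]
            cov_l += su.loc["lam", "ci_low"] <= TRUE_LAM <= su.loc["lam", "ci_high"]
        assert cov_a >= 90
        assert cov_l >= 90

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            McmcConfig(iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            BayesianSurvivalFit("ee", iterations=500, burn_in=100,
                                proposal_scale=-1.0).fit([1.0, 2.0])


class TestSummaries:
    def test_constant_chain(self):
        chain = np.full(500, 5.0)
        assert mc_error(chain) == 0.0

    def test_median_of_range(self):
        assert float(np.median(np.arange(1, 101))) == 50.5

    def test_iid_mc_error_matches_analytic_se(self):
        rng = np.random.default_rng(0)
        chain = rng.standard_normal(50_000)
        expected = 1.0 / np.sqrt(50_000)
        assert mc_error(chain) == pytest.approx(expected, rel=0.20)

    def test_autocorrelated_chain_inflates_mc_error(self):
        rng = np.random.default_rng(1)
        n, phi = 50_000, 0.9
        e = rng.standard_normal(n) * np.sqrt(1 - phi**2)
        ar = np.empty(n)
        ar[0] = e[0]
        for t in range(1, n):
            ar[t] = phi * ar[t - 1] + e[t]
        iid = rng.standard_normal(n) * ar.std(ddof=1)
        assert mc_error(ar) > mc_error(iid)

    def test_short_chain_rejected(self):
        with pytest.raises(ValueError):
            mc_error(np.arange(40))

    def test_summary_contract(self, ee_mcmc_draws):
        summ = summarize(ee_mcmc_draws)
        assert list(summ.index) == ["alpha", "lam", "rho_1", "rho_2"]
        assert (summ["ci_low"] <= summ["median"]).all()
        assert (summ["median"] <= summ["ci_high"]).all()
        assert (summ["mc_error"] <= summ["sd"] + 1e-15).all()
        assert (summ["n"] == 4000).all()

    def test_draws_csv_round_trip(self, ee_mcmc_draws, tmp_path):
        import pandas as pd

        path = tmp_path / "draws.csv"
        ee_mcmc_draws.to_csv(path)
        back = pd.read_csv(path)
        assert list(back.columns) == ["alpha", "lam", "rho_1", "rho_2"]
        np.testing.assert_allclose(back["alpha"], ee_mcmc_draws.natural[:, 0])

    def test_survival_times_validation(self):
        with pytest.raises(ValueError):
            check_survival_times([1.0, np.inf])
        with pytest.raises(ValueError):
            check_survival_times([], min_n=1)
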