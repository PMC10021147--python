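"""Likelihood and prior kernels, the Gibbs sampler, and posterior summaries."""

import numpy as np
import pytest
from scipy.special import gammaln

from neomap.areal_data import AdjacencyGraph
from neomap.bym_models import (
    BymGibbsSampler,
    McmcConfig,
    ModelSpec,
    fit_spatial_bym,
    fit_spatiotemporal,
    icar_log_kernel,
    poisson_loglik,
    posterior_summaries,
    rr_from_coefficient,
    rw1_log_kernel,
)
from neomap.survey_aggregation import ArealPanel
from neomap.synthetic_data import (
    SimConfig,
    simulate_effects,
    simulate_geography,
    simulate_panel,
)
from .conftest import random_connected_graph


class TestPoissonLoglik:
    def test_zero_count_unit_exposure(self):
        assert poisson_loglik(0.0, 1.0, 0.0) == pytest.approx(-1.0)

    def test_direct_formula(self):
        assert poisson_loglik(2.0, 1.0, 0.0) == pytest.approx(-1.0 - np.log(2))

    def test_maximized_at_log_rate(self):
        y, e = 7.0, 3.0
        opt = np.log(y / e)
        grid = opt + np.linspace(-0.5, 0.5, 101)
        vals = [poisson_loglik(y, e, p) for p in grid]
        assert np.argmax(vals) == 50

    def test_degenerate_cells_and_errors(self):
        assert poisson_loglik(0.0, 0.0, 3.0) == 0.0
        with pytest.raises(ValueError, match="E > 0"):
            poisson_loglik(1.0, 0.0, 0.0)
        with pytest.raises(ValueError, match="finite"):
            poisson_loglik(1.0, 1.0, np.inf)

    def test_weighted_counts_via_log_gamma(self):
        # non-integer Y admissible; continuous in Y
        v = poisson_loglik(2.5, 1.0, 0.1)
        expected = 2.5 * 0.1 - np.exp(0.1) - gammaln(3.5)
        assert v == pytest.approx(expected)


class TestPriorKernels:
    def test_icar_constant_field(self):
        g = random_connected_graph(6, np.random.default_rng(0))
        tau = 2.5
        val = icar_log_kernel(np.full(6, 3.3), g, tau)
        assert val == pytest.approx(0.5 * (6 - 1) * np.log(tau))

    def test_icar_two_node_hand_value(self):
        g = AdjacencyGraph(["a", "b"], [{1}, {0}])
        assert icar_log_kernel([0.0, 1.0], g, 1.0) == pytest.approx(-0.5)

    def test_icar_translation_invariance(self, rng):
        g = random_connected_graph(9, rng)
        mu = rng.normal(size=9)
        a = icar_log_kernel(mu, g, 3.0)
        b = icar_log_kernel(mu + 17.2, g, 3.0)
        assert a == pytest.approx(b, abs=1e-12)

    def test_rw1_hand_value_and_invariance(self, rng):
        assert rw1_log_kernel([0.0, 1.0, 3.0], 1.0) == pytest.approx(0.0 - 2.5 + np.log(1.0))
        g = rng.normal(size=5)
        assert rw1_log_kernel(g, 4.0) == pytest.approx(rw1_log_kernel(g + 3.0, 4.0), abs=1e-12)
        with pytest.raises(ValueError, match="2 time points"):
            rw1_log_kernel([1.0], 1.0)


class TestSummaries:
    def test_mean_of_small_draws(self):
        table = posterior_summaries({"x": np.array([1.0, 2.0, 3.0])})
        assert table.loc["x", "mean"] == pytest.approx(2.0)

    def test_constant_draws_zero_width(self):
        table = posterior_summaries({"x": np.full(10, 4.2)})
        assert table.loc["x", "lower_2.5"] == table.loc["x", "upper_97.5"] == 4.2

    def test_normal_quantiles(self, rng):
        table = posterior_summaries({"z": rng.standard_normal(100_000)})
        assert table.loc["z", "lower_2.5"] == pytest.approx(-1.96, abs=0.02)
        assert table.loc["z", "upper_97.5"] == pytest.approx(1.96, abs=0.02)


def test_rr_from_coefficient_values():
    assert round(rr_from_coefficient(0.003), 3) == 1.003
    assert rr_from_coefficient(0.0) == 1.0
    assert round(rr_from_coefficient(-0.12), 3) == 0.887


def _null_panel(I=16, E_value=500.0):
    cfg = SimConfig(n_units=I, n_periods=1, seed=3)
    _, graph = simulate_geography(cfg)
    E = np.full((I, 1), E_value)
    panel = ArealPanel(cfg.unit_ids, ["P1"], E.copy(), E / 0.03, E=E)
    return panel, graph


class TestSpatialFit:
    def test_null_data_limit(self):
        # Y = E exactly at large exposure: alpha ~ 0, all RR ~ 1
        panel, graph = _null_panel()
        fit = fit_spatial_bym(panel, graph, mcmc=McmcConfig.smoke(), seed=5)
        assert abs(fit.summary().loc["intercept", "mean"]) < 0.05
        assert np.all(np.abs(fit.rr_mean - 1) < 0.05)

    def test_isolated_unit_rejected(self):
        panel, _ = _null_panel(I=4)
        g = AdjacencyGraph(["U000", "U001", "U002", "U003"], [{1}, {0}, {3}, {2}])
        iso = AdjacencyGraph(
            ["U000", "U001", "U002", "U003"], [{1, 2}, {0, 2}, {0, 1}, set()]
        )
        with pytest.raises(ValueError, match="U003"):
            fit_spatial_bym(panel, iso, mcmc=McmcConfig.smoke(500, 100), seed=0)
        # components of size >= 2 are allowed
        fit_spatial_bym(panel, g, mcmc=McmcConfig.smoke(300, 100), seed=0)

    def test_degenerate_random_effects_match_poisson_glm(self):
        """With enormous forced precisions the fit collapses to the pooled GLM."""
        import statsmodels.api as sm

        cfg = SimConfig(n_units=16, n_periods=1, seed=11,
                        covariates={"x": ("standard_normal", {})})
        _, graph = simulate_geography(cfg)
        truth = simulate_effects(cfg, graph, alpha=0.2, beta={"x": 0.3},
                                 tau_mu=1e8, tau_upsilon=1e8)
        panel = simulate_panel(truth, graph, cfg)
        spec = ModelSpec(
            covariates=["x"], temporal=False,
            tau_mu_prior=(1e10, 100.0), tau_upsilon_prior=(1e10, 100.0),
        )
        fit = fit_spatial_bym(panel, graph, spec, McmcConfig.smoke(4000, 1500), seed=2)

        x = panel.X[:, 0, 0]
        glm = sm.GLM(
            panel.Y[:, 0], sm.add_constant(x),
            family=sm.families.Poisson(), offset=np.log(panel.E[:, 0]),
        ).fit()
        s = fit.summary()
        assert s.loc["intercept", "mean"] == pytest.approx(glm.params[0], abs=0.03)
        assert s.loc["beta:x", "mean"] == pytest.approx(glm.params[1], abs=0.03)
        glm_rr = np.exp(glm.params[0] + glm.params[1] * x)
        np.testing.assert_allclose(fit.rr_mean[:, 0], glm_rr, rtol=0.05)


class TestSpatiotemporalFit:
    def test_temporal_trend_recovery(self):
        """A pure RW1 ramp in time is recovered in the gamma profile."""
        cfg = SimConfig(n_units=30, n_periods=5, mean_exposure=100.0, seed=21)
        _, graph = simulate_geography(cfg)
        truth = simulate_effects(cfg, graph, tau_mu=1e8, tau_upsilon=1e8, tau_phi=1e8)
        ramp = np.linspace(-0.4, 0.4, 5)
        truth.gamma = ramp - ramp.mean()
        panel = simulate_panel(truth, graph, cfg)
        fit = fit_spatiotemporal(panel, graph, mcmc=McmcConfig.smoke(), seed=1)
        gamma_hat = fit.samples.draws["gamma"].mean(axis=0)
        assert np.corrcoef(gamma_hat, truth.gamma)[0, 1] > 0.9

    def test_null_data_flat_rr(self):
        I, T = 12, 3
        cfg = SimConfig(n_units=I, n_periods=T, seed=4)
        _, graph = simulate_geography(cfg)
        E = np.full((I, T), 400.0)
        panel = ArealPanel(cfg.unit_ids, cfg.periods, E.copy(), E / 0.03, E=E)
        fit = fit_spatiotemporal(panel, graph, mcmc=McmcConfig.smoke(), seed=6)
        inside = (fit.rr_lower <= 1.0) & (1.0 <= fit.rr_upper)
        assert inside.mean() > 0.9
        assert np.abs(fit.rr_mean - 1).max() < 0.15

    def test_sum_to_zero_constraints_every_retained_draw(self):
        cfg = SimConfig(n_units=9, n_periods=3, seed=8)
        _, graph = simulate_geography(cfg)
        truth = simulate_effects(cfg, graph, alpha=-0.1)
        panel = simulate_panel(truth, graph, cfg)
        fit = fit_spatiotemporal(panel, graph, mcmc=McmcConfig.smoke(600, 200), seed=3)
        mu = fit.samples.draws["mu"]
        gamma = fit.samples.draws["gamma"]
        assert np.abs(mu.sum(axis=1)).max() < 1e-10
        assert np.abs(gamma.sum(axis=1)).max() < 1e-10

    def test_single_period_rejected(self):
        panel, graph = _null_panel()
        with pytest.raises(ValueError, match="2 periods"):
            fit_spatiotemporal(panel, graph, mcmc=McmcConfig.smoke(200, 100), seed=0)


class TestSamplerConsistency:
    def test_geweke_style_prior_posterior_agreement(self):
        """Marginal-conditional vs successive-conditional simulator means.

        With counts resimulated from the model each sweep, the chain's
        stationary distribution is the prior; sample means of alpha and the
        precisions must agree between the two simulators (|z| < 3).
        """
        I, T = 6, 3
        cfg = SimConfig(n_units=I, n_periods=T, seed=0)
        _, graph = simulate_geography(cfg)
        # small exposures keep the resimulated counts weakly informative, so
        # the successive-conditional chain can traverse the prior; proper,
        # moderately informative priors give every marginal testable moments
        E = np.full((I, T), 0.3)
        spec = ModelSpec(
            temporal=True,
            tau_mu_prior=(3.0, 2.0), tau_upsilon_prior=(3.0, 2.0),
            tau_gamma_prior=(3.0, 2.0), tau_phi_prior=(3.0, 2.0),
            tau0=1.0,
        )
        mc = McmcConfig.smoke(100, 10)

        n_draws = 8000
        # marginal-conditional: independent prior draws
        s1 = BymGibbsSampler(E.copy(), E, None, graph, spec, mc, seed=101)
        prior_alpha, prior_tau = np.empty(n_draws), np.empty(n_draws)
        for k in range(n_draws):
            s1.draw_state_from_prior()
            prior_alpha[k] = s1.alpha
            prior_tau[k] = s1.tau_mu

        # successive-conditional: one posterior sweep then resimulate counts
        s2 = BymGibbsSampler(E.copy(), E, None, graph, spec, mc, seed=202)
        s2.draw_state_from_prior()
        s2.set_counts(s2.draw_counts())
        chain_alpha, chain_tau = np.empty(n_draws), np.empty(n_draws)
        for k in range(n_draws + 500):
            s2.sweep(adapt=k < 500)
            s2.set_counts(s2.draw_counts())
            if k >= 500:
                chain_alpha[k - 500] = s2.alpha
                chain_tau[k - 500] = s2.tau_mu

        def batch_se(x, n_batches=20):
            means = x[: (len(x) // n_batches) * n_batches].reshape(n_batches, -1).mean(axis=1)
            return means.std(ddof=1) / np.sqrt(n_batches)

        for prior, chain in [(prior_alpha, chain_alpha), (prior_tau, chain_tau)]:
            se = np.sqrt((prior.std(ddof=1) / np.sqrt(n_draws)) ** 2 + batch_se(chain) ** 2)
            z = (prior.mean() - chain.mean()) / se
            assert abs(z) < 3.0, f"prior/posterior drift: z = {z:.2f}"

    def test_acceptance_rates_adapt_toward_target(self):
        cfg = SimConfig(n_units=16, n_periods=3, seed=2)
        _, graph = simulate_geography(cfg)
        truth = simulate_effects(cfg, graph)
        panel = simulate_panel(truth, graph, cfg)
        fit = fit_spatiotemporal(panel, graph, mcmc=McmcConfig.smoke(3000, 1500), seed=0)
        rates = fit.samples.meta["acceptance_rates"][0]
        for name, r in rates.items():
            assert 0.1 < r < 0.8, f"{name} acceptance {r}"
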