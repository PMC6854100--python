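"""Sampler correctness: conjugate updates, MH blocks, reversible jump."""

import numpy as np
import pytest

from tweediepop.mcmc import (
    ChainConfig, ChainResult, TweedieSampler, bayes_factor, format_bf,
    gibbs_update_hypers, mh_update_block, run_chain, summarize,
)
from tweediepop.model import ModelSpec, PriorSettings, prepare_panel
from tweediepop.synthetic import SyntheticTruth, simulate_panel


class TestBayesFactor:
    @pytest.mark.parametrize("q,r,expect", [
        (0.5, 0.5, 1.0),            # indifference
        (0.75, 0.5, 3.0),           # the significance threshold
        (0.9, 0.5, 9.0),
        (0.75, 0.25, 9.0),
    ])
    def test_odds_algebra(self, q, r, expect):
        assert bayes_factor(q, r) == pytest.approx(expect)

    def test_certain_inclusion_is_infinite_and_capped_in_reports(self):
        assert bayes_factor(1.0, 0.5) == np.inf
        assert format_bf(np.inf) == ">10"
        assert format_bf(42.0) == ">10"
        assert format_bf(2.5) == "2.5"

    def test_degenerate_prior_rejected(self):
        with pytest.raises(ValueError):
            bayes_factor(0.5, 0.0)
        with pytest.raises(ValueError):
            bayes_factor(1.2, 0.5)


class TestGibbsHypers:
    def test_alpha_conditional_matches_closed_form(self, rng):
        # no site covariates: alpha | eps ~ N((n*ebar/s2)/(n/s2 + 1/0.01), .)
        pr = PriorSettings()
        eps = rng.normal(0.3, 0.1, size=40)
        s2 = 0.04
        n = len(eps)
        prec = n / s2 + 1.0 / pr.coef_var
        mean = (eps.sum() / s2) / prec
        draws = np.array([
            gibbs_update_hypers(eps, None, pr, s2, rng=rng)[0]
            for _ in range(20000)])
        assert draws.mean() == pytest.approx(mean, abs=4 * np.sqrt(1 / prec / 20000) + 1e-4)
        assert draws.var() == pytest.approx(1 / prec, rel=0.1)

    def test_degenerate_limit_concentrates_at_common_value(self, rng):
        pr = PriorSettings()
        eps = np.full(200, 0.25)
        a = np.array([gibbs_update_hypers(eps, None, pr, 1e-6, rng=rng)[0]
                      for _ in range(200)])
        assert a.mean() == pytest.approx(0.25, abs=0.005)

    def test_sigma2_conditional_moments(self, rng):
        # n=10 residuals with SSE ~= 4 around a tightly-determined mean:
        # sigma2 | . ~ InvGamma(0.001 + 5, 0.001 + SSE/2), mean b/(a-1)
        pr = PriorSettings()
        eps = np.sqrt(4.0 / 10) * np.array([1, -1] * 5, dtype=float)
        draws = np.array([
            gibbs_update_hypers(eps, None, pr, 0.4, rng=rng)[2]
            for _ in range(40000)])
        a, b = 0.001 + 5.0, 0.001 + 2.0
        assert draws.mean() == pytest.approx(b / (a - 1.0), rel=0.05)


class TestMhBlocks:
    def test_zero_scale_leaves_state_unchanged(self, small_panel):
        panel, state, truth = small_panel
        spec = truth.model_spec()
        out = mh_update_block(state, "gamma", panel, spec, 3,
                              proposal_scales={"gamma": 0.0})
        assert np.array_equal(out.gamma, state.gamma)

    def test_invalid_proposals_auto_reject(self, small_panel):
        panel, state, truth = small_panel
        spec = truth.model_spec()
        # a colossal proposal scale drives means out of range; never raises
        out = mh_update_block(state, "eps", panel, spec, 3,
                              proposal_scales={"eps": 1e4})
        assert np.isfinite(out.eps).all()

    def test_acceptance_decision_matches_manual_ratio(self, small_panel):
        """Replay the RNG stream and hand-evaluate the MH ratio."""
        from tweediepop.model import log_likelihood, log_prior
        panel, state, truth = small_panel
        spec = truth.model_spec()
        prep = prepare_panel(panel, spec)
        cfg = ChainConfig(n_iter=2, n_burn=0, seed=99, adapt=False, log_every=0)
        s = TweedieSampler(prep, spec, cfg)
        s.state = state.copy()
        s._refresh_all()
        scale = s.scales["gamma_dd"]
        shadow = np.random.default_rng(99)
        z = shadow.standard_normal()
        u = shadow.random()
        g_new = state.gamma_dd + scale * z
        if g_new > 0:
            g_new = -g_new
        trial = state.copy()
        trial.gamma_dd = g_new
        delta = (log_likelihood(trial, prep) - log_likelihood(state, prep)
                 + log_prior(trial, spec) - log_prior(state, spec))
        expect_accept = np.log(u) <= delta
        s.update_gamma_dd()
        got_accept = s.state.gamma_dd == g_new
        assert got_accept == expect_accept


class TestRunChain:
    def test_exactly_reproducible(self, small_panel):
        panel, _, truth = small_panel
        spec = truth.model_spec()
        cfg = ChainConfig(n_iter=300, n_burn=100, seed=5, log_every=0)
        a = run_chain(panel, spec, cfg)
        b = run_chain(panel, spec, cfg)
        for field in ("alpha", "gamma", "sigma2", "phi", "p", "eps",
                      "inclusion_trace", "log_posterior_trace"):
            assert np.array_equal(getattr(a, field), getattr(b, field))

    def test_flat_likelihood_inclusion_near_half(self):
        from tweediepop.experiments import prior_recovery_chain
        chain, _ = prior_recovery_chain(seed=3, n_iter=20000, thin=5)
        q = chain.inclusion_trace.mean(axis=0)
        assert np.all(np.abs(q - 0.5) < 0.05)

    def test_acceptance_rates_are_rates(self, small_panel):
        panel, _, truth = small_panel
        spec = truth.model_spec()
        chain = run_chain(panel, spec,
                          ChainConfig(n_iter=200, n_burn=50, seed=1, log_every=0))
        for v in chain.acceptance_rates.values():
            assert 0.0 <= v <= 1.0


class TestSummarize:
    def _chain(self, gamma_col, inc_col, spec):
        M = len(gamma_col)
        return ChainResult(
            spec=spec, config=ChainConfig(n_iter=M + 1, n_burn=0, log_every=0),
            selectable=("sparrowhawk",),
            alpha=np.zeros(M), beta=np.zeros((M, 3)),
            gamma=np.asarray(gamma_col)[:, None], gamma_dd=np.zeros(M),
            sigma2=np.full(M, 0.01), phi=np.full(M, 0.5), p=np.full(M, 1.3),
            eps=None, mu0=None,
            inclusion_trace=np.asarray(inc_col)[:, None],
            log_posterior_trace=np.zeros(M), acceptance_rates={},
        )

    def test_always_included_constant(self):
        spec = ModelSpec(covariate_names=("sparrowhawk",),
                         include_density_dependence=False)
        chain = self._chain([0.02] * 10, [1] * 10, spec)
        d = summarize(chain, spec)["decisions"][0]
        assert d.posterior_mean == pytest.approx(0.02)
        assert d.inclusion_probability == 1.0
        assert d.bayes_factor == np.inf and d.significant

    def test_half_included_averages_with_zeros(self):
        spec = ModelSpec(covariate_names=("sparrowhawk",),
                         include_density_dependence=False)
        chain = self._chain([0.04, 0.0] * 5, [1, 0] * 5, spec)
        d = summarize(chain, spec)["decisions"][0]
        assert d.posterior_mean == pytest.approx(0.02)
        assert d.inclusion_probability == pytest.approx(0.5)
        assert d.bayes_factor == pytest.approx(1.0)
        assert not d.significant

    def test_matches_direct_recomputation(self, small_panel):
        panel, _, truth = small_panel
        spec = truth.model_spec()
        chain = run_chain(panel, spec,
                          ChainConfig(n_iter=400, n_burn=100, seed=2, log_every=0))
        out = summarize(chain, spec)
        d = {x.name: x for x in out["decisions"]}
        assert d["sparrowhawk"].posterior_mean == pytest.approx(
            float(chain.gamma[:, 0].mean()))
        assert out["scalars"]["phi"]["mean"] == pytest.approx(float(chain.phi.mean()))
        assert out["scalars"]["sigma2"]["ci_lower"] == pytest.approx(
            float(np.quantile(chain.sigma2, 0.025)))

    def test_empty_chain_rejected(self):
        spec = ModelSpec(covariate_names=("sparrowhawk",),
                         include_density_dependence=False)
        chain = self._chain([], [], spec)
        with pytest.raises(ValueError, match="empty"):
            summarize(chain, spec)
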