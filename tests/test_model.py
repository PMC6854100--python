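"""Mean structures, likelihood and priors of the two formulations."""

from math import lgamma, log, pi

import numpy as np
import pytest

from tweediepop import tweedie
from tweediepop.errors import PanelValidationError
from tweediepop.model import (
    ModelSpec, ParameterState, PriorSettings, PreparedPanel, SIGMA2_HI,
    SIGMA2_LO, log_eps_density, log_likelihood, log_prior, means_change,
    means_standard, prepare_panel,
)
from tweediepop.panel import ObservationPanel


def make_prep(S=3, T=4, K=1, formulation="standard", design=None, y=None,
              mask=None, dd_scale=10.0, include_dd=True):
    """Hand-built prepared panel: full control over the design array."""
    if y is None:
        y = np.full((S, T), 2.0)
    if mask is None:
        mask = np.ones((S, T), dtype=bool)
    if design is None:
        design = np.zeros((S, T, K))
    panel = ObservationPanel(
        site_ids=np.array([f"s{i}" for i in range(S)]),
        years=np.arange(2000, 2000 + T),
        y=np.where(mask, y, np.nan), mask=mask,
        x_site=np.column_stack([np.arange(S, dtype=float),
                                np.arange(S, dtype=float)[::-1],
                                np.where(np.arange(S) % 2 == 0, -1.0, 1.0)]),
        v_time=np.zeros((S, T, 3)) + np.arange(T)[None, :, None],
    )
    spec = ModelSpec(
        formulation=formulation,
        include_density_dependence=include_dd and formulation == "standard",
        covariate_names=tuple(f"c{k}" for k in range(K)),
        dd_scale=dd_scale,
    )
    from tweediepop.panel import ScalingRecord
    return PreparedPanel(
        panel=panel, spec=spec, x_norm=panel.x_site.copy(), design=design,
        record=ScalingRecord(), dd_scale=dd_scale, first_t=panel.first_t,
        mask=mask, y=panel.y,
    )


def make_state(S=3, K=1, **kw):
    base = dict(
        alpha=0.0, beta=np.zeros(3), gamma=np.zeros(K), gamma_dd=0.0,
        eps=np.zeros(S), sigma2=0.01, phi=0.7, p=1.4,
        mu0=np.full(S, 5.0), inc_beta=np.ones(3, bool),
        inc_gamma=np.ones(K, bool), inc_dd=True,
    )
    base.update(kw)
    return ParameterState(**base)


class TestMeansStandard:
    def test_no_change_case(self):
        prep = make_prep()
        st = make_state()
        mu = means_standard(st, prep)
        assert np.allclose(mu, 5.0)

    def test_constant_multiplicative_growth(self):
        prep = make_prep(design=np.ones((3, 4, 1)))
        st = make_state(gamma=np.array([np.log(2.0)]))
        mu = means_standard(st, prep)
        # t years after entry the mean has doubled t+1 times
        expect = 5.0 * 2.0 ** (np.arange(4) + 1)
        assert np.allclose(mu, expect[None, :])

    def test_telescoping_identity(self, rng):
        S, T, K = 3, 4, 2
        design = rng.normal(size=(S, T, K))
        prep = make_prep(S, T, K, design=design, include_dd=False)
        st = make_state(S, K, gamma=rng.normal(scale=0.1, size=K),
                        eps=rng.normal(scale=0.1, size=S))
        mu = means_standard(st, prep)
        lhs = np.log(mu[:, -1]) - np.log(st.mu0)
        rhs = (design @ st.gamma).sum(axis=1) + T * st.eps
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_density_dependence_pulls_down(self):
        prep = make_prep(dd_scale=5.0)
        hi = means_standard(make_state(), prep)
        lo = means_standard(make_state(gamma_dd=-0.1), prep)
        assert (lo < hi).all()

    def test_positive_and_finite_for_bounded_inputs(self, rng):
        for _ in range(10):
            S, T, K = 4, 40, 2
            design = rng.uniform(-1, 1, size=(S, T, K))
            prep = make_prep(S, T, K, design=design, include_dd=False,
                             y=np.full((S, T), 2.0))
            st = make_state(S, K, gamma=rng.uniform(-0.05, 0.05, K),
                            eps=rng.uniform(-0.05, 0.05, S))
            mu = means_standard(st, prep)
            assert np.isfinite(mu).all() and (mu > 0).all()


class TestMeansChange:
    def test_constant_when_covariates_unchanged(self):
        prep = make_prep(formulation="change", include_dd=False)
        st = make_state(eps=np.full(3, 0.3))
        mu = means_change(st, prep)
        assert np.allclose(mu[:, 0], 5.0)                 # augmented baseline
        assert np.allclose(mu[:, 1:], 5.0 * np.exp(0.3))  # e^eps ratio

    def test_doubling_reduction_matches_published_effect(self):
        # one covariate doubles relative to baseline; gamma = -0.0325
        design = np.zeros((3, 4, 1))
        design[:, 1:, 0] = np.log(2.0)
        prep = make_prep(formulation="change", design=design, include_dd=False)
        st = make_state(gamma=np.array([-0.0325]))
        mu = means_change(st, prep)
        ratio = mu[:, 1] / mu[:, 0]
        assert np.allclose(ratio, 2.0 ** -0.0325)
        assert ratio[0] == pytest.approx(0.9777, abs=5e-5)

    def test_null_coefficients_flatten(self):
        design = np.random.default_rng(0).normal(size=(3, 4, 1))
        prep = make_prep(formulation="change", design=design, include_dd=False)
        mu = means_change(make_state(), prep)
        assert np.allclose(mu, mu[:, :1])


class TestLogLikelihood:
    def test_each_cell_contributes_its_density(self):
        mask = np.zeros((3, 4), dtype=bool)
        mask[0, 0] = mask[1, 2] = mask[2, 3] = True
        y = np.full((3, 4), 3.0)
        prep = make_prep(y=y, mask=mask)
        st = make_state()
        mu = means_standard(st, prep)
        expect = sum(
            tweedie.log_density(3.0, tweedie.TweedieParams(mu[i, t], st.phi, st.p))
            for i, t in zip(*np.nonzero(mask)))
        assert log_likelihood(st, prep) == pytest.approx(expect)

    def test_empty_panel_gives_zero(self):
        prep = make_prep(mask=np.zeros((3, 4), dtype=bool))
        assert log_likelihood(make_state(), prep) == 0.0

    def test_matches_brute_force_sum(self, rng):
        y = rng.uniform(0, 8, size=(3, 3))
        y[rng.random((3, 3)) < 0.2] = 0.0
        prep = make_prep(T=3, y=y, design=rng.normal(size=(3, 3, 1)))
        st = make_state(gamma=np.array([0.05]), eps=rng.normal(scale=0.05, size=3),
                        gamma_dd=-0.02)
        mu = means_standard(st, prep)
        brute = sum(
            tweedie.log_density(y[i, t], tweedie.TweedieParams(mu[i, t], st.phi, st.p))
            for i in range(3) for t in range(3))
        assert log_likelihood(st, prep) == pytest.approx(brute, rel=1e-10)

    def test_excluded_covariate_bit_identical_to_zero(self):
        prep = make_prep(design=np.random.default_rng(1).normal(size=(3, 4, 1)))
        a = make_state(gamma=np.array([0.3]), inc_gamma=np.zeros(1, bool))
        b = make_state(gamma=np.array([0.0]))
        assert log_likelihood(a, prep) == log_likelihood(b, prep)

    def test_likelihood_peaks_at_observed_counts(self):
        y = np.full((3, 4), 4.0)
        prep = make_prep(y=y)
        at_y = make_state(mu0=np.full(3, 4.0))
        off = make_state(mu0=np.full(3, 5.5))
        assert log_likelihood(at_y, prep) > log_likelihood(off, prep)


class TestLogPrior:
    def test_support_violations(self):
        spec = ModelSpec(covariate_names=("c0",))
        st = make_state(mu0=np.array([250.0, 5.0, 5.0]))
        assert log_prior(st, spec) == -np.inf
        st = make_state(gamma_dd=0.1)
        assert log_prior(st, spec) == -np.inf
        st = make_state(phi=6.0)
        assert log_prior(st, spec) == -np.inf

    def test_matches_hand_summed_closed_form(self):
        spec = ModelSpec(covariate_names=("c0",))
        pr = spec.priors
        st = make_state(alpha=0.05, beta=np.array([0.1, -0.2, 0.0]),
                        gamma=np.array([0.02]), gamma_dd=-0.03,
                        sigma2=0.5, phi=1.2, p=1.4, mu0=np.full(3, 10.0))

        def lognorm(x, var):
            return -0.5 * log(2 * pi * var) - 0.5 * x * x / var

        from tweediepop.model import P_HI, P_LO
        expect = lognorm(0.05, 0.01)
        expect += sum(lognorm(b, 0.01) for b in (0.1, -0.2, 0.0))
        expect += lognorm(0.02, 0.01)
        expect += log(2) + lognorm(-0.03, 0.01)         # half-normal, negative
        expect += -log(5.0)                              # phi ~ U[0,5]
        expect += -log(P_HI - P_LO)                      # p, restricted uniform
        a, b = 0.001, 0.001                              # sigma2 ~ InvGamma
        expect += (a * log(b) - lgamma(a) - (a + 1) * log(0.5) - b / 0.5
                   - pr.sigma2_lognorm)
        expect += -3 * log(200.0)                        # mu0 ~ U[0,200]
        expect += 5 * log(0.5)                           # 5 inclusion indicators
        assert log_prior(st, spec) == pytest.approx(expect, rel=1e-12)

    def test_eps_density_is_separate_and_gaussian(self):
        prep = make_prep()
        st = make_state(alpha=0.1, eps=np.array([0.1, 0.2, 0.0]),
                        beta=np.zeros(3), sigma2=0.04)
        expect = sum(-0.5 * log(2 * pi * 0.04) - 0.5 * (e - 0.1) ** 2 / 0.04
                     for e in st.eps)
        assert log_eps_density(st, prep) == pytest.approx(expect)


class TestPreparePanel:
    def test_single_site_rejected(self, small_panel):
        panel, _, _ = small_panel
        from dataclasses import replace
        one = replace(panel, site_ids=panel.site_ids[:1], y=panel.y[:1],
                      mask=panel.mask[:1], x_site=panel.x_site[:1],
                      v_time=panel.v_time[:1])
        with pytest.raises(PanelValidationError, match="2 sites"):
            prepare_panel(one, ModelSpec())

    def test_change_design_zero_baseline_guard(self, small_panel):
        panel, _, _ = small_panel
        spec = ModelSpec(formulation="change", include_density_dependence=False,
                         ratio_offsets={})
        with pytest.raises(PanelValidationError, match="offset"):
            prepare_panel(panel, spec)

    def test_change_design_no_change_is_zero(self, small_panel):
        panel, _, _ = small_panel
        spec = ModelSpec(formulation="change", include_density_dependence=False)
        prep = prepare_panel(panel, spec)
        S = panel.n_site
        first = prep.design[np.arange(S), panel.first_t, :]
        assert np.allclose(first, 0.0)

    def test_sigma2_support_constants(self):
        assert SIGMA2_LO < 1e-100 < 1e100 < SIGMA2_HI
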