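"""Synthetic panel generator: turnover process, covariates, observation model."""

import numpy as np
import pytest
from scipy.stats import skew

from tweediepop.errors import DivergentStateError
from tweediepop.synthetic import (
    CovariateProcess, SyntheticTruth, generate_design, simulate_panel,
)


class TestDesign:
    def test_no_turnover_means_full_panels(self):
        skel = generate_design(20, 8, 0.0, 0.4, seed=1)
        assert skel.n_site == 20
        assert skel.mask.all()

    def test_same_seed_identical_skeleton(self):
        a = generate_design(30, 10, 0.08, 0.4, seed=5)
        b = generate_design(30, 10, 0.08, 0.4, seed=5)
        assert np.array_equal(a.mask, b.mask)
        assert np.array_equal(a.x_site, b.x_site)
        assert np.array_equal(a.v_time, b.v_time)

    def test_turnover_matches_retirement_process_expectation(self):
        """Active sites are constant, so the expected number of distinct
        sites is n*(1 + r*(T-1)) and the mean observed fraction per site
        is 1/(1 + r*(T-1))."""
        n, T, r = 150, 36, 0.08
        fracs = []
        for seed in range(50):
            skel = generate_design(n, T, r, 0.4, seed=seed)
            fracs.append(skel.mask.sum() / (skel.n_site * T))
        expect = 1.0 / (1.0 + r * (T - 1))
        got = np.mean(fracs)
        se = np.std(fracs) / np.sqrt(len(fracs))
        assert abs(got - expect) < max(3 * se, 0.005)

    def test_replacement_sites_share_habitat_and_neighbourhood(self):
        skel = generate_design(50, 20, 0.2, 0.5, seed=3)
        assert skel.n_site > 50
        # every replacement keeps the habitat class of some earlier site
        assert set(np.unique(skel.x_site[:, 2])) <= {-1.0, 1.0}
        spans = [(m.argmax(), len(m) - m[::-1].argmax() - 1) for m in skel.mask]
        # contiguous observation runs
        for i, (s, e) in enumerate(spans):
            assert skel.mask[i, s:e + 1].all()

    def test_covariates_in_valid_ranges(self):
        skel = generate_design(40, 15, 0.08, 0.4, seed=2)
        frost = skel.v_time[:, :, 2]
        assert ((frost >= 0) & (frost <= 183)).all()
        assert (skel.v_time[:, :, :2] >= 0).all()

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            generate_design(1, 8, 0.08, 0.4, seed=0)
        with pytest.raises(ValueError):
            generate_design(10, 8, 0.9, 0.4, seed=0)


class TestSimulatePanel:
    def test_regenerate_bit_exact(self):
        truth = SyntheticTruth(n_site=20, T=8, seed=13)
        a, _ = simulate_panel(truth)
        b, _ = simulate_panel(truth)
        assert np.array_equal(a.y[a.mask], b.y[b.mask])

    def test_low_dispersion_limit_tracks_means(self):
        truth = SyntheticTruth(n_site=30, T=8, seed=4, phi=0.01,
                               include_density_dependence=False, gamma_dd=0.0,
                               mu0_band=(5.0, 50.0))
        panel, state = simulate_panel(truth)
        from tweediepop.model import _logmu, prepare_panel
        prep = prepare_panel(panel, truth.model_spec())
        logmu, _ = _logmu(state, prep)
        mu = np.exp(logmu[panel.mask])
        y = panel.y[panel.mask]
        sel = mu > 5
        rel = np.abs(y[sel] - mu[sel]) / mu[sel]
        assert rel.mean() < 0.05

    def test_zero_fraction_matches_zero_mass_formula(self):
        truth = SyntheticTruth(n_site=120, T=12, seed=8, phi=0.7, p=1.3,
                               include_density_dependence=False, gamma_dd=0.0,
                               gamma=(0.0, 0.0, 0.0), alpha=0.0, sigma2=1e-4,
                               mu0_band=(1.0, 3.0))
        panel, state = simulate_panel(truth)
        from tweediepop.model import _logmu, prepare_panel
        prep = prepare_panel(panel, truth.model_spec())
        logmu, _ = _logmu(state, prep)
        mu = np.exp(logmu[panel.mask])
        lam = mu ** (2 - truth.p) / (truth.phi * (2 - truth.p))
        expect = np.exp(-lam).mean()
        got = (panel.y[panel.mask] == 0).mean()
        n = panel.n_obs
        se = np.sqrt(expect * (1 - expect) / n)
        assert abs(got - expect) < 3 * se

    def test_skewed_zero_inflated_regime(self):
        """Low-abundance settings reach the observed-survey zero regime."""
        truth = SyntheticTruth(n_site=150, T=20, seed=21, mu0_band=(0.3, 4.0),
                               include_density_dependence=False, gamma_dd=0.0)
        panel, _ = simulate_panel(truth)
        y = panel.y[panel.mask]
        assert skew(y) > 1.0
        assert 0.05 <= (y == 0).mean() <= 0.35

    def test_divergent_effects_raise_helpfully(self):
        truth = SyntheticTruth(n_site=10, T=30, seed=1, alpha=2.5,
                               include_density_dependence=False, gamma_dd=0.0)
        with pytest.raises(DivergentStateError, match="smaller"):
            simulate_panel(truth)

    def test_change_formulation_generation(self):
        truth = SyntheticTruth(n_site=25, T=8, seed=6, formulation="change",
                               gamma=(-0.1, 0.05, 0.02))
        panel, state = simulate_panel(truth)
        assert panel.n_obs > 0
        assert (panel.y[panel.mask] >= 0).all()


def test_save_synthetic_writes_csv_and_truth(tmp_path):
    from tweediepop.synthetic import save_synthetic
    truth = SyntheticTruth(n_site=10, T=6, seed=2)
    panel, _ = simulate_panel(truth)
    save_synthetic(panel, truth, tmp_path / "demo")
    assert (tmp_path / "demo.csv").exists()
    import json
    meta = json.loads((tmp_path / "demo.truth.json").read_text())
    assert meta["seed"] == 2 and meta["n_site"] == 10
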