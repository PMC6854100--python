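import numpy as np
import pytest

from tweediepop.experiments import gof_calibration, gof_misspecified
from tweediepop.synthetic import SyntheticTruth, simulate_panel


@pytest.fixture(scope="session")
def small_panel():
    """A small realistic panel with turnover and a known truth."""
    truth = SyntheticTruth(n_site=15, T=10, seed=7)
    panel, state = simulate_panel(truth)
    return panel, state, truth


@pytest.fixture(scope="session")
def strong_effect_panel():
    """Panel with a strong negative predator effect, no density dependence."""
    truth = SyntheticTruth(
        n_site=50, T=12, seed=11, include_density_dependence=False,
        gamma_dd=0.0, gamma=(-0.12, 0.05, 0.04),
    )
    panel, state = simulate_panel(truth)
    return panel, state, truth


@pytest.fixture(scope="session")
def gof_pvalues_wellspec():
    """Posterior-predictive p-values for 20 well-specified fits."""
    return gof_calibration(n_rep=20, base_seed=1)


@pytest.fixture(scope="session")
def gof_pvalues_misspec():
    """p-values for 20 fits of heavy-tailed lognormal data at fixed p=1.9."""
    return gof_misspecified(n_rep=20, base_seed=1, sdlog=2.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
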