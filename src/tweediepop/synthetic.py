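"""Synthetic garden-bird panels with known generating truth.

Emulates the structure of a winter feeding-station survey: a roughly
constant number of active sites per year with ~8% annual turnover
(replacement sites appear near the retired ones with the same habitat
class), an urban/rural mix, weather and predator covariates that vary by
year with site-level noise, and right-skewed zero-inflated counts drawn
from the Tweedie observation model driven through the multiplicative
growth recursion.  Every stage of the modelling machinery is testable
against these panels without any real survey download.

What it deliberately does not emulate: the within-winter weekly-maximum
protocol (counts are generated directly at the site-winter level) and
spatial correlation beyond the site covariates.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np

from . import tweedie
from .errors import DivergentStateError
from .model import ModelSpec, ParameterState, _logmu, prepare_panel
from .panel import DEFAULT_TIME_COVARIATES, ObservationPanel, write_panel_csv


@dataclass(frozen=True)
class CovariateProcess:
    """First-order autoregressive year-level covariate processes."""

    frost_mean: float = 40.0
    frost_year_sd: float = 8.0
    frost_site_sd: float = 5.0
    hawk_log_base: float = -0.7      # national log-rate at year 0
    hawk_trend: float = 1.2          # total log-rate rise over the study
    hawk_ar: float = 0.6
    hawk_year_sd: float = 0.15
    hawk_site_sd: float = 0.4
    dove_log_base: float = 0.8
    dove_trend: float = 0.8
    dove_ar: float = 0.6
    dove_year_sd: float = 0.15
    dove_site_sd: float = 0.4


@dataclass(frozen=True)
class SyntheticTruth:
    """Design settings plus the generating parameters, all reproducible."""

    n_site: int = 150                # active sites per year
    T: int = 36
    turnover_rate: float = 0.08
    urban_fraction: float = 0.4
    start_year: int = 1970
    seed: int = 0
    formulation: str = "standard"
    include_density_dependence: bool = True
    alpha: float = 0.01
    beta: tuple = (0.01, -0.01, -0.01)        # northing, easting, habitat
    gamma: tuple = (-0.03, 0.01, 0.02)        # sparrowhawk, dove, frost
    gamma_dd: float = -0.02
    sigma2: float = 0.01
    phi: float = 0.7
    p: float = 1.35
    mu0_band: tuple = (2.0, 50.0)
    dd_scale: float = 15.0
    covariates: CovariateProcess = field(default_factory=CovariateProcess)

    def model_spec(self, **overrides) -> ModelSpec:
        kw = dict(
            formulation=self.formulation,
            include_density_dependence=(self.include_density_dependence
                                        and self.formulation == "standard"),
            dd_scale=self.dd_scale,
        )
        kw.update(overrides)
        return ModelSpec(**kw)


def generate_design(n_site: int, T: int, turnover_rate: float,
                    urban_fraction: float, seed: int,
                    covariates: CovariateProcess | None = None,
                    start_year: int = 1970) -> ObservationPanel:
    """Panel skeleton: sites, turnover mask and covariates, no counts.

    ``n_site`` is the number of *active* sites per year; retired sites are
    replaced by fresh ones nearby with the same habitat, so the total
    number of distinct sites grows with the turnover rate.  Observed y is
    set to 0.0 as a placeholder (the generator overwrites it).
    """
    if n_site < 2 or T < 3:
        raise ValueError("require n_site >= 2 and T >= 3")
    if not (0.0 <= turnover_rate <= 0.5):
        raise ValueError("turnover_rate must lie in [0, 0.5]")
    if not (0.0 <= urban_fraction <= 1.0):
        raise ValueError("urban_fraction must lie in [0, 1]")
    cov = covariates or CovariateProcess()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 11]))

    coords = list(rng.uniform(0.0, 1000.0, size=(n_site, 2)))
    habitat = list(np.where(rng.random(n_site) < urban_fraction, 1.0, -1.0))
    spans = [[0, T - 1] for _ in range(n_site)]
    active = list(range(n_site))
    for t in range(1, T):
        n_ret = rng.binomial(len(active), turnover_rate)
        if n_ret == 0:
            continue
        retired = rng.choice(len(active), size=n_ret, replace=False)
        for pos in sorted(retired, reverse=True):
            i = active[pos]
            spans[i][1] = t - 1
            # replacement: similar location and habitat
            coords.append(coords[i] + rng.normal(0.0, 20.0, 2))
            habitat.append(habitat[i])
            spans.append([t, T - 1])
            active[pos] = len(spans) - 1

    S = len(spans)
    coords = np.asarray(coords)
    habitat = np.asarray(habitat)
    spans = np.asarray(spans)
    mask = np.zeros((S, T), dtype=bool)
    for i, (s, e) in enumerate(spans):
        mask[i, s:e + 1] = True

    v = np.empty((S, T, 3))
    # frost days: year-level level shift plus site noise, integer, in range
    year_frost = cov.frost_mean + rng.normal(0.0, cov.frost_year_sd, T)
    frost = year_frost[None, :] + rng.normal(0.0, cov.frost_site_sd, (S, T))
    v[:, :, 2] = np.clip(np.round(frost), 0.0, 183.0)
    # predator / pseudo-predator: AR(1) national log index with trend,
    # site-level lognormal heterogeneity, Poisson counts
    for k, (base, trend, ar, ysd, ssd) in enumerate([
        (cov.hawk_log_base, cov.hawk_trend, cov.hawk_ar, cov.hawk_year_sd, cov.hawk_site_sd),
        (cov.dove_log_base, cov.dove_trend, cov.dove_ar, cov.dove_year_sd, cov.dove_site_sd),
    ]):
        z = np.empty(T)
        z[0] = rng.normal(0.0, ysd)
        for t in range(1, T):
            z[t] = ar * z[t - 1] + rng.normal(0.0, ysd)
        log_rate = base + trend * np.arange(T) / max(T - 1, 1) + z
        site_eff = rng.normal(0.0, ssd, S)
        lam = np.exp(log_rate[None, :] + site_eff[:, None])
        v[:, :, k] = rng.poisson(lam).astype(float)

    y = np.where(mask, 0.0, np.nan)
    return ObservationPanel(
        site_ids=np.array([f"S{i:04d}" for i in range(S)]),
        years=start_year + np.arange(T),
        y=y, mask=mask,
        x_site=np.column_stack([coords, habitat]),
        v_time=v, time_covariates=DEFAULT_TIME_COVARIATES,
    )


def simulate_panel(truth: SyntheticTruth) -> tuple[ObservationPanel, ParameterState]:
    """Generate a panel from ``truth``; returns it with the realized state.

    The generating coefficients apply to the covariates exactly as the
    model sees them (normalized, or scaled log-ratios for the change
    formulation), so recovery experiments compare like with like.
    """
    skeleton = generate_design(
        truth.n_site, truth.T, truth.turnover_rate, truth.urban_fraction,
        truth.seed, truth.covariates, truth.start_year)
    spec = truth.model_spec()
    prep = prepare_panel(skeleton, spec)
    rng = np.random.default_rng(np.random.SeedSequence([int(truth.seed), 29]))

    S = skeleton.n_site
    m = truth.alpha + prep.x_norm @ np.asarray(truth.beta)
    eps = m + np.sqrt(truth.sigma2) * rng.standard_normal(S)
    mu0 = rng.uniform(*truth.mu0_band, size=S)
    state = ParameterState(
        alpha=truth.alpha, beta=np.asarray(truth.beta, float),
        gamma=np.asarray(truth.gamma, float),
        gamma_dd=truth.gamma_dd if spec.include_density_dependence else 0.0,
        eps=eps, sigma2=truth.sigma2, phi=truth.phi, p=truth.p, mu0=mu0,
        inc_beta=np.ones(3, bool), inc_gamma=np.ones(len(truth.gamma), bool),
        inc_dd=spec.include_density_dependence,
    )
    logmu, ok = _logmu(state, prep)
    if not ok:
        raise DivergentStateError(
            "synthetic means diverged (|log mu| > 50); use smaller effect "
            "sizes, variance or horizon")
    y = skeleton.y.copy()
    mu_obs = np.exp(logmu[skeleton.mask])
    y[skeleton.mask] = tweedie.sample_matrix(mu_obs, truth.phi, truth.p, rng)
    panel = replace(skeleton, y=y)
    return panel, state


def save_synthetic(panel: ObservationPanel, truth: SyntheticTruth, prefix) -> None:
    """Write the panel CSV plus a JSON sidecar of the generating truth."""
    write_panel_csv(panel, f"{prefix}.csv")
    with open(f"{prefix}.truth.json", "w") as fh:
        json.dump(asdict(truth), fh, indent=2, default=list)
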