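"""The two hierarchical Tweedie mean structures and their priors.

Standard model (recursive growth-rate form, hierarchically centred):

    y_it ~ Tw(mu_it, phi, p)
    log(mu_it / mu_i,t-1) = v_itT gamma + gamma_DD * d_i,t-1 + eps_i
    eps_i ~ N(alpha + x_iT beta, sigma2)

anchored at an augmented pre-survey mean mu_i0 ~ U[0,200] in the year
before each site's first observation.  d_i,t-1 is the lagged expected
count divided by a fixed scale (the species' overall observed mean by
default) so the negative-restricted density-dependence coefficient lives
on the same scale as the normalized covariates.

Change-change model (Newson-style):

    log(mu_it / mu_i,first) = log(v_it / v_i,first)T gamma + eps'_i,  t > first
    eps'_i ~ N(alpha + x_iT beta, sigma2)

with mu_i,first an augmented baseline ~ U[0,200].  Count covariates that
can be zero get a +1 offset inside the ratio so "no change" stays exactly
zero; the log-ratio columns are scaled to unit variance (not centred) so
their coefficients stay interpretable per log-unit of change.

Excluded covariates (inclusion indicator 0) contribute exactly zero to
every mean, which is what the reversible-jump moves toggle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import lgamma

import numpy as np
from scipy.special import gammaincc

from . import tweedie
from ._kernels import standard_logmu
from .errors import DivergentStateError, PanelValidationError
from .panel import ObservationPanel, ScalingRecord, normalize_covariates

#: sampler support for the index parameter, kept clear of (1, 2) boundaries
P_LO = 1.0 + tweedie.P_EDGE
P_HI = 2.0 - tweedie.P_EDGE
#: sampler support for the random-effect variance; the exact
#: InvGamma(0.001, 0.001) prior puts roughly half its mass beyond double
#: precision, so the sampler works with the prior truncated to this range
SIGMA2_LO = 1e-300
SIGMA2_HI = 1e300


@dataclass(frozen=True)
class PriorSettings:
    """Hyperparameters of the prior specification.

    ``coef_var`` is the *variance* of the N(0, .) coefficient priors
    (0.01, i.e. sd 0.1, on normalized covariates).
    """

    coef_var: float = 0.01
    dd_var: float = 0.01
    phi_max: float = 5.0
    sigma2_shape: float = 0.001
    sigma2_rate: float = 0.001
    mu0_max: float = 200.0

    @property
    def sigma2_lognorm(self) -> float:
        """log of the truncated-InvGamma normalising constant."""
        a, b = self.sigma2_shape, self.sigma2_rate
        z = gammaincc(a, b / SIGMA2_HI) - gammaincc(a, b / SIGMA2_LO)
        return float(np.log(z))


@dataclass(frozen=True)
class ModelSpec:
    """Which formulation to fit, with what covariates and priors."""

    formulation: str = "standard"          # "standard" | "change"
    include_density_dependence: bool = True
    covariate_names: tuple = ("sparrowhawk", "collared_dove", "frost_days")
    priors: PriorSettings = field(default_factory=PriorSettings)
    inclusion_prior: float = 0.5
    select_covariates: bool = True         # reversible-jump selection on/off
    dd_scale: float | None = None          # None -> overall observed mean
    fixed_p: float | None = None
    ratio_offsets: dict | None = None      # change model; default +1 on counts

    def __post_init__(self) -> None:
        if self.formulation not in ("standard", "change"):
            raise ValueError(f"unknown formulation {self.formulation!r}")
        if self.formulation == "change" and self.include_density_dependence:
            raise ValueError("the change model has no density-dependence term")
        if not (0.0 < self.inclusion_prior < 1.0):
            raise ValueError("inclusion prior must be in (0, 1)")

    def offsets(self) -> dict:
        if self.ratio_offsets is not None:
            return self.ratio_offsets
        return {"sparrowhawk": 1.0, "collared_dove": 1.0}


@dataclass
class ParameterState:
    """One MCMC state of the full parameter vector."""

    alpha: float
    beta: np.ndarray          # (3,) site-covariate coefficients
    gamma: np.ndarray         # (K,) time-covariate coefficients
    gamma_dd: float           # <= 0
    eps: np.ndarray           # (S,) site random effects
    sigma2: float
    phi: float
    p: float
    mu0: np.ndarray           # (S,) augmented pre-survey / baseline means
    inc_beta: np.ndarray      # (3,) bool
    inc_gamma: np.ndarray     # (K,) bool
    inc_dd: bool = True

    def copy(self) -> "ParameterState":
        return ParameterState(
            alpha=self.alpha, beta=self.beta.copy(), gamma=self.gamma.copy(),
            gamma_dd=self.gamma_dd, eps=self.eps.copy(), sigma2=self.sigma2,
            phi=self.phi, p=self.p, mu0=self.mu0.copy(),
            inc_beta=self.inc_beta.copy(), inc_gamma=self.inc_gamma.copy(),
            inc_dd=self.inc_dd,
        )

    def effective_beta(self) -> np.ndarray:
        return np.where(self.inc_beta, self.beta, 0.0)

    def effective_gamma(self) -> np.ndarray:
        return np.where(self.inc_gamma, self.gamma, 0.0)

    def effective_gamma_dd(self) -> float:
        return self.gamma_dd if self.inc_dd else 0.0


def initial_state(panel: ObservationPanel, spec: ModelSpec) -> ParameterState:
    """A data-informed starting state.

    mu0 anchors at each site's first observed count and eps at the site's
    crude log growth rate (standard) or mean log change from its baseline
    (change formulation), which puts the chain near the likelihood ridge
    these parameters share.
    """
    S = panel.n_site
    K = len(spec.covariate_names)
    ft = panel.first_t
    mu0 = np.empty(S)
    eps = np.zeros(S)
    for i in range(S):
        t_obs = np.nonzero(panel.mask[i])[0]
        if len(t_obs) == 0:
            mu0[i] = 0.5 * spec.priors.mu0_max
            continue
        yi = panel.y[i, t_obs]
        mu0[i] = np.clip(yi[0], 0.5, 199.0)
        if len(t_obs) > 1:
            span = t_obs[-1] - t_obs[0]
            lr = np.log((yi + 0.5) / (yi[0] + 0.5))
            if spec.formulation == "standard":
                eps[i] = lr[-1] / max(span, 1)
            else:
                eps[i] = lr[1:].mean()
    alpha = float(np.clip(eps.mean(), -0.3, 0.3))
    return ParameterState(
        alpha=alpha, beta=np.zeros(3), gamma=np.zeros(K), gamma_dd=-0.01,
        eps=eps, sigma2=max(float(eps.var()), 1e-4), phi=0.7,
        p=1.4 if spec.fixed_p is None else spec.fixed_p,
        mu0=mu0, inc_beta=np.ones(3, bool), inc_gamma=np.ones(K, bool),
        inc_dd=spec.include_density_dependence,
    )


# -- prepared design -------------------------------------------------------

@dataclass
class PreparedPanel:
    """Panel with the formulation-specific design arrays precomputed."""

    panel: ObservationPanel        # raw panel (for back-reference / IO)
    spec: ModelSpec
    x_norm: np.ndarray             # (S, 3) normalized site covariates
    design: np.ndarray             # (S, T, K): normalized v, or scaled log-ratios
    record: ScalingRecord
    dd_scale: float
    first_t: np.ndarray
    mask: np.ndarray
    y: np.ndarray


def prepare_panel(panel: ObservationPanel, spec: ModelSpec) -> PreparedPanel:
    if panel.n_site < 2:
        raise PanelValidationError(
            "at least 2 sites are required (the random-effect variance is "
            "unidentifiable from a single site)"
        )
    names = list(panel.time_covariates)
    for c in spec.covariate_names:
        if c not in names:
            raise PanelValidationError(f"panel lacks time covariate {c!r}")
    cols = [names.index(c) for c in spec.covariate_names]

    norm, record = normalize_covariates(panel)
    if spec.formulation == "standard":
        design = norm.v_time[:, :, cols]
    else:
        design = _change_design(panel, spec, cols, record)

    yobs = panel.y[panel.mask]
    dd_scale = spec.dd_scale
    if dd_scale is None:
        dd_scale = float(yobs.mean()) if yobs.size else 1.0
        if dd_scale <= 0:
            raise PanelValidationError("all-zero panel: cannot scale density dependence")
    return PreparedPanel(
        panel=panel, spec=spec, x_norm=norm.x_site, design=design,
        record=record, dd_scale=dd_scale, first_t=panel.first_t,
        mask=panel.mask, y=panel.y,
    )


def _change_design(panel, spec, cols, record) -> np.ndarray:
    """Scaled log-ratio covariates log((v_it+off)/(v_i,first+off)) / sd."""
    offsets = spec.offsets()
    S, T = panel.mask.shape
    ft = panel.first_t
    out = np.zeros((S, T, len(cols)))
    live = np.zeros((S, T), dtype=bool)
    for i in range(S):
        live[i, ft[i]:] = True
    for j, (k, name) in enumerate(zip(cols, spec.covariate_names)):
        off = offsets.get(name, 0.0)
        v = panel.v_time[:, :, k] + off
        base = v[np.arange(S), ft]
        if (base[np.isfinite(base)] <= 0).any():
            raise PanelValidationError(
                f"covariate {name!r} has a non-positive baseline value and no "
                "offset; set ratio_offsets to keep the log-ratio finite"
            )
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.log(v / base[:, None])
        after = live & (np.arange(T)[None, :] > ft[:, None])
        sd = float(np.nanstd(r[after]))
        if sd == 0:
            raise PanelValidationError(f"log-ratio of covariate {name!r} is constant")
        record.means[f"logratio_{name}"] = 0.0
        record.sds[f"logratio_{name}"] = sd
        out[:, :, j] = np.where(live, r / sd, 0.0)
    return out


def _as_prepared(panel, spec) -> PreparedPanel:
    if isinstance(panel, PreparedPanel):
        return panel
    return prepare_panel(panel, spec)


# -- mean structures -------------------------------------------------------

def _logmu_standard(state: ParameterState, prep: PreparedPanel):
    drive = prep.design @ state.effective_gamma() + state.eps[:, None]
    with np.errstate(divide="ignore"):
        logmu0 = np.log(state.mu0)
    logmu = np.zeros(prep.mask.shape)
    standard_logmu(
        logmu0, drive, state.effective_gamma_dd(), prep.dd_scale,
        prep.first_t.astype(np.int64), logmu,
    )
    # divergence only matters where the likelihood looks
    ok = not np.any(np.abs(logmu[prep.mask]) >= 50.0)
    return logmu, bool(ok)


def _logmu_change(state: ParameterState, prep: PreparedPanel):
    with np.errstate(divide="ignore"):
        logmu0 = np.log(state.mu0)
    shift = prep.design @ state.effective_gamma() + state.eps[:, None]
    logmu = logmu0[:, None] + shift
    # the first observed year is the augmented baseline itself
    S = prep.mask.shape[0]
    logmu[np.arange(S), prep.first_t] = logmu0
    obs = logmu[prep.mask]
    ok = bool(np.all(np.abs(obs) < 50.0)) and bool(np.isfinite(obs).all())
    return logmu, ok


def _logmu(state, prep):
    if prep.spec.formulation == "standard":
        return _logmu_standard(state, prep)
    return _logmu_change(state, prep)


def means_standard(state: ParameterState, panel, spec: ModelSpec | None = None) -> np.ndarray:
    """Site-by-year expected counts under the standard model.

    Entries before a site's first observed year are returned as NaN.
    Raises :class:`DivergentStateError` if any log-mean leaves [-50, 50].
    """
    spec = spec or ModelSpec()
    prep = _as_prepared(panel, spec)
    logmu, ok = _logmu_standard(state, prep)
    if not ok:
        raise DivergentStateError("divergent means: |log mu| exceeded 50")
    return _mask_leading(logmu, prep.first_t)


def means_change(state: ParameterState, panel, spec: ModelSpec | None = None) -> np.ndarray:
    """Site-by-year expected counts under the change-change model."""
    spec = spec or ModelSpec(formulation="change", include_density_dependence=False)
    prep = _as_prepared(panel, spec)
    logmu, ok = _logmu_change(state, prep)
    if not ok:
        raise DivergentStateError("divergent means: |log mu| exceeded 50")
    return _mask_leading(logmu, prep.first_t)


def _mask_leading(logmu, first_t):
    mu = np.exp(logmu)
    T = mu.shape[1]
    mu[np.arange(T)[None, :] < first_t[:, None]] = np.nan
    return mu


# -- likelihood and priors -------------------------------------------------

def log_likelihood(state: ParameterState, panel, spec: ModelSpec | None = None) -> float:
    """Sum of Tweedie log-densities over the observed site-years."""
    spec = spec or ModelSpec()
    prep = _as_prepared(panel, spec)
    if prep.mask.sum() == 0:
        return 0.0
    logmu, ok = _logmu(state, prep)
    if not ok:
        return -np.inf
    mu = np.exp(logmu[prep.mask])
    y = prep.y[prep.mask]
    logc = tweedie.log_normalizer(y, state.phi, state.p)
    return float(_tilt_loglik(y, mu, logc, state.phi, state.p).sum())


def _tilt_loglik(y, mu, logc, phi, p):
    """Per-cell log density given the cached series factor."""
    return logc + (y * mu ** (1.0 - p) / (1.0 - p) - mu ** (2.0 - p) / (2.0 - p)) / phi


def log_prior(state: ParameterState, spec: ModelSpec) -> float:
    """Joint log prior of one state (Table-2-style specification).

    Returns -inf (never raises) outside the prior support.  The site
    random effects are part of the hierarchical model, not the prior; see
    :func:`log_eps_density`.
    """
    pr = spec.priors
    lp = 0.0
    # regression coefficients, included components only
    const = -0.5 * np.log(2 * np.pi * pr.coef_var)
    lp += const - 0.5 * state.alpha ** 2 / pr.coef_var
    for v, inc in ((state.beta, state.inc_beta), (state.gamma, state.inc_gamma)):
        k = int(inc.sum())
        lp += k * const - 0.5 * float((v[inc] ** 2).sum()) / pr.coef_var
    if spec.include_density_dependence and state.inc_dd:
        if state.gamma_dd > 0:
            return -np.inf
        lp += (np.log(2.0) - 0.5 * np.log(2 * np.pi * pr.dd_var)
               - 0.5 * state.gamma_dd ** 2 / pr.dd_var)
    # dispersion and index
    if not (0.0 < state.phi <= pr.phi_max):
        return -np.inf
    lp += -np.log(pr.phi_max)
    if not (P_LO <= state.p <= P_HI):
        return -np.inf
    lp += -np.log(P_HI - P_LO)
    # random-effect variance: truncated inverse-gamma (shape-rate)
    if not (SIGMA2_LO <= state.sigma2 <= SIGMA2_HI):
        return -np.inf
    a, b = pr.sigma2_shape, pr.sigma2_rate
    lp += (a * np.log(b) - lgamma(a) - (a + 1.0) * np.log(state.sigma2)
           - b / state.sigma2 - pr.sigma2_lognorm)
    # augmented means
    if ((state.mu0 < 0) | (state.mu0 > pr.mu0_max)).any():
        return -np.inf
    lp += -len(state.mu0) * np.log(pr.mu0_max)
    # inclusion indicators
    r = spec.inclusion_prior
    n_on = int(state.inc_beta.sum() + state.inc_gamma.sum())
    n_tot = len(state.inc_beta) + len(state.inc_gamma)
    if spec.include_density_dependence:
        n_on += int(state.inc_dd)
        n_tot += 1
    lp += n_on * np.log(r) + (n_tot - n_on) * np.log(1.0 - r)
    return float(lp)


def log_eps_density(state: ParameterState, prep: PreparedPanel) -> float:
    """log N(eps_i; alpha + x_iT beta, sigma2) summed over sites."""
    m = state.alpha + prep.x_norm @ state.effective_beta()
    r = state.eps - m
    n = len(r)
    return float(-0.5 * n * np.log(2 * np.pi * state.sigma2)
                 - 0.5 * (r ** 2).sum() / state.sigma2)
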