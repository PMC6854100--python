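"""Metropolis-within-Gibbs sampler with reversible-jump covariate selection.

Hierarchical centering makes (alpha, beta, sigma2) conjugate given the
site effects, so those are Gibbs updates; everything that touches the
Tweedie likelihood is random-walk Metropolis (log-scale walk for phi, a
logit-type walk for p inside its (1+d, 2-d) support, a reflected walk in
[0, mu0_max] for the augmented means, and a sign-reflected walk for the
negative density-dependence coefficient).  Covariate inclusion is sampled
by reversible-jump birth/death moves whose coefficient proposal is the
prior, so prior and proposal cancel and the acceptance ratio is the
likelihood ratio times the prior inclusion odds.

One extra kernel component, a joint (sigma2, eps) independence proposal
from the hierarchical prior accepted with the likelihood ratio, lets the
chain traverse the enormous dynamic range of the InvGamma(0.001, 0.001)
variance prior when the data are weak or absent; with informative data it
almost never accepts and is merely a valid extra move.

Because the density normaliser c(y; phi, p) does not depend on the means,
it is cached and only recomputed when (phi, p) moves - every other block
costs a handful of vector operations per sweep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _kernels as _k
from . import tweedie
from .model import (
    P_HI,
    P_LO,
    SIGMA2_HI,
    SIGMA2_LO,
    ModelSpec,
    ParameterState,
    PreparedPanel,
    PriorSettings,
    _logmu,
    initial_state,
    log_eps_density,
    log_prior,
    prepare_panel,
)
from .errors import DivergentStateError

logger = logging.getLogger(__name__)

_DEFAULT_SCALES = {
    "eps": 0.05, "mu0": 3.0, "gamma": 0.02, "gamma_dd": 0.02,
    "phi": 0.08, "p": 0.12, "shear_eps": 0.03, "shear_gamma": 0.01,
    "shear_dd": 0.02,
}

#: chain lengths used in the study this reimplements, per formulation
DEFAULT_ITERATIONS = {"standard": (20_000, 5_000), "change": (100_000, 60_000)}


@dataclass(frozen=True)
class ChainConfig:
    n_iter: int
    n_burn: int
    seed: int = 0
    proposal_scales: dict = field(default_factory=dict)
    adapt: bool = True
    thin: int = 1
    store_site_params: bool = True
    log_every: int = 1000

    def __post_init__(self) -> None:
        if not (0 <= self.n_burn < self.n_iter):
            raise ValueError("require 0 <= n_burn < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @classmethod
    def default_for(cls, formulation: str, seed: int = 0) -> "ChainConfig":
        n_iter, n_burn = DEFAULT_ITERATIONS[formulation]
        return cls(n_iter=n_iter, n_burn=n_burn, seed=seed)


@dataclass
class ChainResult:
    """Post-burn-in draws plus selection and diagnostic traces."""

    spec: ModelSpec
    config: ChainConfig
    selectable: tuple                  # names of RJ-selectable terms
    alpha: np.ndarray                  # (M,)
    beta: np.ndarray                   # (M, 3) model-averaged (0 when excluded)
    gamma: np.ndarray                  # (M, K)
    gamma_dd: np.ndarray               # (M,)
    sigma2: np.ndarray
    phi: np.ndarray
    p: np.ndarray
    eps: np.ndarray | None             # (M, S)
    mu0: np.ndarray | None             # (M, S)
    inclusion_trace: np.ndarray        # (M, n_selectable) 0/1
    log_posterior_trace: np.ndarray
    acceptance_rates: dict

    @property
    def n_samples(self) -> int:
        return len(self.alpha)


@dataclass(frozen=True)
class CovariateDecision:
    name: str
    posterior_mean: float              # model-averaged (zeros when excluded)
    inclusion_probability: float
    bayes_factor: float                # may be inf
    significant: bool
    posterior_mean_per_unit: float | None = None


def bayes_factor(inclusion_probability: float, prior_probability: float) -> float:
    """Posterior odds of inclusion over prior odds; q = 1 maps to +inf."""
    q, r = inclusion_probability, prior_probability
    if not (0.0 <= q <= 1.0):
        raise ValueError(f"inclusion probability {q} outside [0, 1]")
    if not (0.0 < r < 1.0):
        raise ValueError(f"prior probability {r} outside (0, 1)")
    if q == 1.0:
        return np.inf
    return (q / (1.0 - q)) / (r / (1.0 - r))


def format_bf(bf: float, cap: float = 10.0) -> str:
    """Render a Bayes factor the way the summary tables print it (">10")."""
    return f">{cap:g}" if bf > cap else f"{bf:.4g}"


def gibbs_update_hypers(eps, x_site, priors: PriorSettings, sigma2, inc_beta=None, rng=None):
    """Draw (alpha, beta_included, sigma2) from their full conditionals.

    The site effects follow eps_i ~ N(alpha + x_iT beta, sigma2); with
    N(0, coef_var) priors this is a conjugate Bayesian linear model, and
    sigma2 has an inverse-gamma full conditional (shape-rate convention),
    truncated to the sampler support.
    """
    rng = rng or np.random.default_rng()
    eps = np.asarray(eps, float)
    n = len(eps)
    if inc_beta is None:
        inc_beta = np.ones(x_site.shape[1], dtype=bool) if x_site is not None else np.zeros(0, bool)
    cols = [] if x_site is None else [x_site[:, j] for j in np.nonzero(inc_beta)[0]]
    X = np.column_stack([np.ones(n), *cols])
    k = X.shape[1]
    prec = X.T @ X / sigma2 + np.eye(k) / priors.coef_var
    try:
        cov = np.linalg.inv(prec)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular design in hyperparameter update (collinear included "
            "site covariates)") from exc
    mean = cov @ (X.T @ eps) / sigma2
    theta = rng.multivariate_normal(mean, cov, method="cholesky")
    alpha = float(theta[0])
    beta = np.zeros(0 if x_site is None else x_site.shape[1])
    beta[np.nonzero(inc_beta)[0]] = theta[1:]
    resid = eps - X @ theta
    a = priors.sigma2_shape + 0.5 * n
    b = priors.sigma2_rate + 0.5 * float(resid @ resid)
    prop = b / rng.gamma(a)
    new_sigma2 = prop if SIGMA2_LO <= prop <= SIGMA2_HI else sigma2
    return alpha, beta, float(new_sigma2)


class TweedieSampler:
    """One chain on one prepared panel.  Use :func:`run_chain` normally."""

    def __init__(self, panel, spec: ModelSpec, config: ChainConfig):
        self.prep: PreparedPanel = panel if isinstance(panel, PreparedPanel) else prepare_panel(panel, spec)
        self.spec = self.prep.spec
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self.scales = dict(_DEFAULT_SCALES, **config.proposal_scales)

        mask = self.prep.mask
        self.rows, self.cols = np.nonzero(mask)
        self.col_f = self.cols.astype(np.int64)
        self.y_f = self.prep.y[mask]
        self.counts = np.bincount(self.rows, minlength=self.prep.y.shape[0]).astype(np.int64)
        self.site_starts = np.concatenate([[0], np.cumsum(self.counts)[:-1]]).astype(np.int64)
        self.first_t64 = self.prep.first_t.astype(np.int64)
        self.has_obs = self.y_f.size > 0
        self.K = len(self.spec.covariate_names)
        self.selectable = self._selectable_names()
        self.acc = {}
        self.n_prop = {}

        self._build_shear_weights()
        self.state = initial_state(self.prep.panel, self.spec)
        if self.spec.fixed_p is not None:
            self.state.p = float(np.clip(self.spec.fixed_p, P_LO, P_HI))
        self._refresh_all()

    def _build_shear_weights(self):
        """Fixed, data-derived weights for the joint coefficient-eps moves.

        In the recursive model a site effect acts cumulatively, so it is
        strongly correlated with the baseline mean and with every
        coefficient.  The shear proposals move a coefficient together
        with the compensating shift of each site's effect (and the
        baseline for the eps move); fixed weights keep the map symmetric
        with a known Jacobian.
        """
        prep = self.prep
        S, T = prep.y.shape
        ft = prep.first_t
        mask = prep.mask
        tgrid = np.arange(T)[None, :]
        if self.spec.formulation == "standard":
            age = np.where(tgrid >= ft[:, None], tgrid - ft[:, None] + 1.0, 0.0)
            live = (tgrid >= ft[:, None])[:, :, None]
            cumv = np.where(live, prep.design, 0.0).cumsum(axis=1)
            # forward-filled observed counts approximate the lagged means
            cumd = np.zeros((S, T))
            for i in range(S):
                prev = max(prep.y[i, ft[i]], 0.1) / prep.dd_scale
                acc = 0.0
                for t in range(ft[i], T):
                    acc += prev
                    cumd[i, t] = acc
                    if mask[i, t]:
                        prev = max(prep.y[i, t], 0.1) / prep.dd_scale
        else:
            age = np.where(tgrid > ft[:, None], 1.0, 0.0)
            cumv = prep.design
            cumd = np.zeros((S, T))
        def site_mean(v):
            return np.array([v[i, mask[i]].mean() if mask[i].any() else 0.0
                             for i in range(S)])

        self.shear_age = site_mean(age)
        safe_age = np.maximum(self.shear_age, 1e-9)
        G = np.stack([site_mean(cumv[:, :, k])
                      for k in range(prep.design.shape[2])], axis=1)
        self.shear_gamma_w = np.where(self.shear_age[:, None] > 0,
                                      G / safe_age[:, None], 0.0)
        self.shear_dd_w = np.where(self.shear_age > 0,
                                   site_mean(cumd) / safe_age, 0.0)

    # -- bookkeeping -------------------------------------------------------

    def _selectable_names(self):
        names = []
        if self.spec.select_covariates:
            names += [f"site:{n}" for n in ("northing", "easting", "habitat")]
            names += list(self.spec.covariate_names)
            if self.spec.include_density_dependence:
                names.append("density_dep")
        return tuple(names)

    def _count(self, block, accepted, n=1):
        self.acc[block] = self.acc.get(block, 0.0) + accepted
        self.n_prop[block] = self.n_prop.get(block, 0) + n

    def acceptance_rates(self):
        return {k: self.acc[k] / max(self.n_prop[k], 1) for k in self.n_prop}

    # -- likelihood cache --------------------------------------------------

    def _refresh_all(self):
        st = self.state
        tilt, logmu, ok = self._site_tilt_for(st)
        if not ok:
            raise DivergentStateError("initial state has divergent means")
        self.logmu = logmu
        self.site_tilt = tilt
        if self.has_obs:
            self.logc_f = tweedie.log_normalizer(self.y_f, st.phi, st.p)
            self.site_logc = self._site_sums(self.logc_f)
        else:
            self.logc_f = np.zeros(0)
            S = self.prep.y.shape[0]
            self.site_logc = np.zeros(S)

    def _tilt(self, mu_f, phi, p):
        return (self.y_f * mu_f ** (1.0 - p) / (1.0 - p)
                - mu_f ** (2.0 - p) / (2.0 - p)) / phi

    def _site_sums(self, cell_vals):
        return np.add.reduceat(cell_vals, self.site_starts) if self.has_obs \
            else np.zeros(self.prep.y.shape[0])

    def total_loglik(self) -> float:
        return float(self.site_tilt.sum() + self.site_logc.sum())

    def log_posterior(self) -> float:
        return (self.total_loglik() + log_prior(self.state, self.spec)
                + log_eps_density(self.state, self.prep))

    def _site_tilt_for(self, state):
        """(per-site tilt sums, log-mean field, ok) for a trial state."""
        S, T = self.prep.y.shape
        logmu = np.zeros((S, T))
        site_tilt = np.empty(S)
        if self.spec.formulation == "standard":
            ok = _k.standard_site_tilt(
                state.mu0, self.prep.design, state.effective_gamma(),
                state.eps, state.effective_gamma_dd(), self.prep.dd_scale,
                self.first_t64, self.y_f, self.col_f, self.site_starts,
                self.counts, state.phi, state.p, logmu, site_tilt)
        else:
            ok = _k.change_site_tilt(
                state.mu0, self.prep.design, state.effective_gamma(),
                state.eps, self.first_t64, self.y_f, self.col_f,
                self.site_starts, self.counts, state.phi, state.p,
                logmu, site_tilt)
        if not ok:
            return None, None, False
        return site_tilt, logmu, True

    # -- update blocks -----------------------------------------------------

    def update_hypers(self):
        st = self.state
        st.alpha, beta, st.sigma2 = gibbs_update_hypers(
            st.eps, self.prep.x_norm, self.spec.priors, st.sigma2,
            inc_beta=st.inc_beta, rng=self.rng)
        st.beta[st.inc_beta] = beta[st.inc_beta]

    def update_eps(self):
        """Per-site random-walk update (sites are conditionally independent)."""
        st = self.state
        S = len(st.eps)
        z = self.rng.standard_normal(S)
        logu = np.log(self.rng.random(S))
        prop = st.eps + self.scales["eps"] * z
        trial = st.copy()
        trial.eps = prop
        tilt_p, logmu_p, ok = self._site_tilt_for(trial)
        if not ok:
            self._count("eps", 0.0, S)
            return
        m = st.alpha + self.prep.x_norm @ st.effective_beta()
        dprior = (-0.5 * (prop - m) ** 2 + 0.5 * (st.eps - m) ** 2) / st.sigma2
        accept = logu <= (tilt_p - self.site_tilt) + dprior
        st.eps[accept] = prop[accept]
        self.logmu[accept] = logmu_p[accept]
        self.site_tilt[accept] = tilt_p[accept]
        self._count("eps", float(accept.sum()), S)

    def update_mu0(self):
        st = self.state
        S = len(st.mu0)
        hi = self.spec.priors.mu0_max
        prop = st.mu0 + self.scales["mu0"] * self.rng.standard_normal(S)
        # reflect into [0, mu0_max] (handles arbitrarily many folds)
        prop = np.abs(prop) % (2.0 * hi)
        prop = np.where(prop > hi, 2.0 * hi - prop, prop)
        logu = np.log(self.rng.random(S))
        prop = np.maximum(prop, 1e-12)
        trial = st.copy()
        trial.mu0 = prop
        tilt_p, logmu_p, ok = self._site_tilt_for(trial)
        if not ok:
            self._count("mu0", 0.0, S)
            return
        accept = logu <= tilt_p - self.site_tilt
        st.mu0[accept] = prop[accept]
        self.logmu[accept] = logmu_p[accept]
        self.site_tilt[accept] = tilt_p[accept]
        self._count("mu0", float(accept.sum()), S)

    def _try_global(self, block, trial, dlogprior):
        """Shared accept/reject for moves that shift the whole mean field."""
        tilt_p, logmu_p, ok = self._site_tilt_for(trial)
        if not ok:
            self._count(block, 0.0)
            return False
        delta = float(tilt_p.sum() - self.site_tilt.sum()) + dlogprior
        if np.log(self.rng.random()) <= delta:
            self.state = trial
            self.logmu = logmu_p
            self.site_tilt = tilt_p
            self._count(block, 1.0)
            return True
        self._count(block, 0.0)
        return False

    def update_gamma(self):
        pr = self.spec.priors
        for k in range(self.K):
            if not self.state.inc_gamma[k]:
                continue
            trial = self.state.copy()
            g_new = trial.gamma[k] + self.scales["gamma"] * self.rng.standard_normal()
            dprior = -0.5 * (g_new ** 2 - trial.gamma[k] ** 2) / pr.coef_var
            trial.gamma[k] = g_new
            self._try_global("gamma", trial, dprior)

    def update_gamma_dd(self):
        if not (self.spec.include_density_dependence and self.state.inc_dd):
            return
        pr = self.spec.priors
        trial = self.state.copy()
        g_new = trial.gamma_dd + self.scales["gamma_dd"] * self.rng.standard_normal()
        if g_new > 0:            # sign-reflected walk keeps the support
            g_new = -g_new
        dprior = -0.5 * (g_new ** 2 - trial.gamma_dd ** 2) / pr.dd_var
        trial.gamma_dd = g_new
        self._try_global("gamma_dd", trial, dprior)

    def update_shear_eps_mu0(self):
        """Per-site joint (eps_i, mu0_i) move along the slope-level ridge.

        eps_i shifts by delta and the baseline compensates on the log
        scale (mu0 -> mu0*exp(-delta*age_i)), so the fitted trajectory
        pivots instead of translating; the log-scale baseline change
        contributes a -delta*age_i Jacobian term against the uniform
        mu0 prior.
        """
        st = self.state
        S = len(st.eps)
        hi = self.spec.priors.mu0_max
        delta = self.scales["shear_eps"] * self.rng.standard_normal(S)
        logu = np.log(self.rng.random(S))
        eps_p = st.eps + delta
        mu0_p = st.mu0 * np.exp(-delta * self.shear_age)
        trial = st.copy()
        trial.eps = eps_p
        trial.mu0 = mu0_p
        tilt_p, logmu_p, ok = self._site_tilt_for(trial)
        if not ok:
            self._count("shear_eps", 0.0, S)
            return
        m = st.alpha + self.prep.x_norm @ st.effective_beta()
        dprior = (-0.5 * (eps_p - m) ** 2 + 0.5 * (st.eps - m) ** 2) / st.sigma2
        jac = -delta * self.shear_age
        delta_lp = (tilt_p - self.site_tilt) + dprior + jac
        delta_lp[(mu0_p <= 0) | (mu0_p > hi)] = -np.inf
        accept = logu <= delta_lp
        st.eps[accept] = eps_p[accept]
        st.mu0[accept] = mu0_p[accept]
        self.logmu[accept] = logmu_p[accept]
        self.site_tilt[accept] = tilt_p[accept]
        self._count("shear_eps", float(accept.sum()), S)

    def _shear_coef(self, block, assign, weights, cur, prior_var, scale_key,
                    support=None):
        """Joint coefficient + compensating-eps move (symmetric shear)."""
        st = self.state
        delta = self.scales[scale_key] * self.rng.standard_normal()
        new = cur + delta
        if support is not None and not support(new):
            self._count(block, 0.0)
            return
        trial = st.copy()
        assign(trial, new)
        trial.eps = st.eps - delta * weights
        tilt_p, logmu_p, ok = self._site_tilt_for(trial)
        if not ok:
            self._count(block, 0.0)
            return
        m = st.alpha + self.prep.x_norm @ st.effective_beta()
        dprior = float((-0.5 * (trial.eps - m) ** 2
                        + 0.5 * (st.eps - m) ** 2).sum()) / st.sigma2
        dprior += -0.5 * (new ** 2 - cur ** 2) / prior_var
        d = float(tilt_p.sum() - self.site_tilt.sum()) + dprior
        if np.log(self.rng.random()) <= d:
            self.state = trial
            self.logmu = logmu_p
            self.site_tilt = tilt_p
            self._count(block, 1.0)
        else:
            self._count(block, 0.0)

    def update_shear_gamma(self):
        pr = self.spec.priors
        for k in range(self.K):
            if not self.state.inc_gamma[k]:
                continue

            def assign(tr, val, k=k):
                tr.gamma[k] = val

            self._shear_coef("shear_gamma", assign, self.shear_gamma_w[:, k],
                             self.state.gamma[k], pr.coef_var, "shear_gamma")

    def update_shear_dd(self):
        if not (self.spec.include_density_dependence and self.state.inc_dd):
            return
        cur = self.state.gamma_dd

        def assign(tr, val):
            tr.gamma_dd = val

        self._shear_coef("shear_dd", assign, self.shear_dd_w, cur,
                         self.spec.priors.dd_var, "shear_dd",
                         support=lambda v: v <= 0)

    def update_tweedie(self):
        """Joint (phi, p) move; this is the only block that re-runs the series."""
        st = self.state
        pr = self.spec.priors
        lphi = np.log(st.phi) + self.scales["phi"] * self.rng.standard_normal()
        phi_new = float(np.exp(lphi))
        if phi_new > pr.phi_max:
            self._count("tweedie", 0.0)
            return
        if self.spec.fixed_p is None:
            u = np.log((st.p - P_LO) / (P_HI - st.p))
            u += self.scales["p"] * self.rng.standard_normal()
            p_new = float((P_HI * np.exp(u) + P_LO) / (1.0 + np.exp(u)))
        else:
            p_new = st.p
        try:
            logc_new = tweedie.log_normalizer(self.y_f, phi_new, p_new) \
                if self.has_obs else self.logc_f
        except Exception:
            self._count("tweedie", 0.0)
            return
        if self.has_obs:
            mu_f = np.exp(self.logmu[self.rows, self.cols])
            tilt_new = self._site_sums(self._tilt(mu_f, phi_new, p_new))
            logc_site_new = self._site_sums(logc_new)
        else:
            tilt_new, logc_site_new = self.site_tilt, self.site_logc
        delta = float(tilt_new.sum() + logc_site_new.sum()
                      - self.site_tilt.sum() - self.site_logc.sum())
        delta += np.log(phi_new / st.phi)          # log-walk Jacobian
        if self.spec.fixed_p is None:
            delta += (np.log((p_new - P_LO) * (P_HI - p_new))
                      - np.log((st.p - P_LO) * (P_HI - st.p)))
        if np.log(self.rng.random()) <= delta:
            st.phi, st.p = phi_new, p_new
            self.logc_f = logc_new
            self.site_tilt = tilt_new
            self.site_logc = logc_site_new
            self._count("tweedie", 1.0)
        else:
            self._count("tweedie", 0.0)

    def refresh_tweedie(self):
        """(phi, p) independence proposal from the prior (periodic move).

        Prior and proposal cancel, so the acceptance ratio is the bare
        likelihood ratio; under a weak likelihood this decorrelates the
        dispersion chain that the random walk alone mixes slowly.
        """
        st = self.state
        phi_new = float(self.rng.uniform(0.0, self.spec.priors.phi_max))
        p_new = st.p if self.spec.fixed_p is not None \
            else float(self.rng.uniform(P_LO, P_HI))
        if phi_new <= 0:
            self._count("tweedie_refresh", 0.0)
            return
        try:
            logc_new = tweedie.log_normalizer(self.y_f, phi_new, p_new) \
                if self.has_obs else self.logc_f
        except Exception:
            self._count("tweedie_refresh", 0.0)
            return
        if self.has_obs:
            mu_f = np.exp(self.logmu[self.rows, self.cols])
            tilt_new = self._site_sums(self._tilt(mu_f, phi_new, p_new))
            logc_site_new = self._site_sums(logc_new)
        else:
            tilt_new, logc_site_new = self.site_tilt, self.site_logc
        delta = float(tilt_new.sum() + logc_site_new.sum()
                      - self.site_tilt.sum() - self.site_logc.sum())
        if np.log(self.rng.random()) <= delta:
            st.phi, st.p = phi_new, p_new
            self.logc_f = logc_new
            self.site_tilt = tilt_new
            self.site_logc = logc_site_new
            self._count("tweedie_refresh", 1.0)
        else:
            self._count("tweedie_refresh", 0.0)

    def refresh_sigma_eps(self):
        """Joint (sigma2, eps) independence proposal from the prior."""
        st = self.state
        pr = self.spec.priors
        for _ in range(100):
            g = self.rng.gamma(pr.sigma2_shape)
            if g > 0:
                s2 = pr.sigma2_rate / g
                if SIGMA2_LO <= s2 <= SIGMA2_HI:
                    break
        else:  # pragma: no cover - astronomically unlikely
            self._count("refresh", 0.0)
            return
        m = st.alpha + self.prep.x_norm @ st.effective_beta()
        eps_new = m + np.sqrt(s2) * self.rng.standard_normal(len(st.eps))
        logu = np.log(self.rng.random())
        trial = st.copy()
        trial.sigma2 = float(s2)
        trial.eps = eps_new
        tilt_p, logmu_p, ok = self._site_tilt_for(trial)
        if ok and logu <= float(tilt_p.sum() - self.site_tilt.sum()):
            self.state = trial
            self.logmu = logmu_p
            self.site_tilt = tilt_p
            self._count("refresh", 1.0)
        else:
            self._count("refresh", 0.0)

    # -- reversible jump ---------------------------------------------------

    def _rj_odds(self, birth: bool) -> float:
        r = self.spec.inclusion_prior
        return np.log(r / (1 - r)) if birth else np.log((1 - r) / r)

    def _rj_lazy(self) -> bool:
        """Half the toggle attempts stay put: with a flat likelihood a
        toggle always accepts, and a lazy kernel breaks the resulting
        period-2 anti-correlation of the inclusion chain."""
        return self.rng.random() < 0.5

    def rj_toggle_beta(self, k: int):
        if self._rj_lazy():
            return
        st = self.state
        pr = self.spec.priors
        trial = st.copy()
        birth = not st.inc_beta[k]
        trial.inc_beta[k] = birth
        if birth:
            trial.beta[k] = self.rng.standard_normal() * np.sqrt(pr.coef_var)
        delta = (log_eps_density(trial, self.prep)
                 - log_eps_density(st, self.prep) + self._rj_odds(birth))
        if np.log(self.rng.random()) <= delta:
            if not birth:
                trial.beta[k] = 0.0
            self.state = trial
            self._count("rj_beta", 1.0)
        else:
            self._count("rj_beta", 0.0)

    def rj_toggle_gamma(self, k: int):
        if self._rj_lazy():
            return
        st = self.state
        pr = self.spec.priors
        trial = st.copy()
        birth = not st.inc_gamma[k]
        trial.inc_gamma[k] = birth
        if birth:
            trial.gamma[k] = self.rng.standard_normal() * np.sqrt(pr.coef_var)
        else:
            trial.gamma[k] = 0.0
        self._try_global("rj_gamma", trial, self._rj_odds(birth))

    def rj_toggle_dd(self):
        if self._rj_lazy():
            return
        st = self.state
        pr = self.spec.priors
        trial = st.copy()
        birth = not st.inc_dd
        trial.inc_dd = birth
        if birth:
            trial.gamma_dd = -abs(self.rng.standard_normal()) * np.sqrt(pr.dd_var)
        else:
            trial.gamma_dd = 0.0
        self._try_global("rj_dd", trial, self._rj_odds(birth))

    # -- sweep -------------------------------------------------------------

    def sweep(self):
        self.update_hypers()
        if self.spec.select_covariates:
            for k in range(3):
                self.rj_toggle_beta(k)
        self.update_eps()
        self.update_shear_eps_mu0()
        self.refresh_sigma_eps()
        self.update_mu0()
        self.update_gamma()
        self.update_shear_gamma()
        self.update_gamma_dd()
        self.update_shear_dd()
        if self.spec.select_covariates:
            for k in range(self.K):
                self.rj_toggle_gamma(k)
            if self.spec.include_density_dependence:
                self.rj_toggle_dd()
        self.update_tweedie()
        self._sweep_count = getattr(self, "_sweep_count", 0) + 1
        if self._sweep_count % 10 == 0:
            self.refresh_tweedie()

    def adapt_scales(self):
        """Nudge proposal scales toward the 0.2-0.4 acceptance window."""
        for block, key in (("eps", "eps"), ("mu0", "mu0"), ("gamma", "gamma"),
                           ("gamma_dd", "gamma_dd"), ("tweedie", "phi"),
                           ("tweedie", "p"), ("shear_eps", "shear_eps"),
                           ("shear_gamma", "shear_gamma"),
                           ("shear_dd", "shear_dd")):
            n = self.n_prop.get(block, 0)
            if n == 0:
                continue
            rate = self.acc[block] / n
            if rate < 0.2:
                self.scales[key] *= 0.7
            elif rate > 0.4:
                self.scales[key] *= 1.4
        # the mu0 walk needs no more than one fold across its box
        self.scales["mu0"] = min(self.scales["mu0"], self.spec.priors.mu0_max)
        self.acc.clear()
        self.n_prop.clear()


def run_chain(panel, spec: ModelSpec, config: ChainConfig) -> ChainResult:
    """Run one chain: full sweeps, burn-in discarded, every draw stored.

    Reproducible given (panel, spec, config): the only randomness is the
    generator seeded by ``config.seed``.
    """
    s = TweedieSampler(panel, spec, config)
    st = s.state
    S, K = len(st.eps), s.K
    M = (config.n_iter - config.n_burn) // config.thin
    out = ChainResult(
        spec=s.spec, config=config, selectable=s.selectable,
        alpha=np.empty(M), beta=np.empty((M, 3)), gamma=np.empty((M, K)),
        gamma_dd=np.empty(M), sigma2=np.empty(M), phi=np.empty(M),
        p=np.empty(M),
        eps=np.empty((M, S)) if config.store_site_params else None,
        mu0=np.empty((M, S)) if config.store_site_params else None,
        inclusion_trace=np.zeros((M, len(s.selectable)), dtype=np.int8),
        log_posterior_trace=np.empty(M), acceptance_rates={},
    )
    j = 0
    for it in range(config.n_iter):
        s.sweep()
        if config.adapt and it < config.n_burn and (it + 1) % 50 == 0:
            s.adapt_scales()
        if it == config.n_burn - 1:
            s.acc.clear()
            s.n_prop.clear()
        if it >= config.n_burn and (it - config.n_burn) % config.thin == 0 and j < M:
            st = s.state
            out.alpha[j] = st.alpha
            out.beta[j] = st.effective_beta()
            out.gamma[j] = st.effective_gamma()
            out.gamma_dd[j] = st.effective_gamma_dd()
            out.sigma2[j] = st.sigma2
            out.phi[j] = st.phi
            out.p[j] = st.p
            if config.store_site_params:
                out.eps[j] = st.eps
                out.mu0[j] = st.mu0
            if s.selectable:
                out.inclusion_trace[j] = np.concatenate([
                    st.inc_beta.astype(np.int8), st.inc_gamma.astype(np.int8),
                    [np.int8(st.inc_dd)] if s.spec.include_density_dependence else [],
                ])
            lp = s.log_posterior()
            if not np.isfinite(lp):
                raise DivergentStateError(
                    f"non-finite log posterior at iteration {it}; state: "
                    f"phi={st.phi:.3g} p={st.p:.3g} sigma2={st.sigma2:.3g}")
            out.log_posterior_trace[j] = lp
            j += 1
        if config.log_every and (it + 1) % config.log_every == 0:
            logger.info("iter %d/%d acceptance %s", it + 1, config.n_iter,
                        {k: round(v, 3) for k, v in s.acceptance_rates().items()})
    out.acceptance_rates = s.acceptance_rates()
    return out


def mh_update_block(state: ParameterState, block: str, panel, spec: ModelSpec,
                    rng_or_seed=0, proposal_scales=None) -> ParameterState:
    """Apply one named Metropolis block to ``state`` and return the result.

    ``block`` is one of ``gamma``, ``gamma_dd``, ``eps``, ``tw``, ``mu0``.
    Invalid proposals are auto-rejected, never raised.
    """
    seed = rng_or_seed if isinstance(rng_or_seed, int) else 0
    cfg = ChainConfig(n_iter=2, n_burn=0, seed=seed, adapt=False,
                      proposal_scales=proposal_scales or {}, log_every=0)
    s = TweedieSampler(panel, spec, cfg)
    if not isinstance(rng_or_seed, int):
        s.rng = rng_or_seed
    s.state = state.copy()
    s._refresh_all()
    dispatch = {"gamma": s.update_gamma, "gamma_dd": s.update_gamma_dd,
                "eps": s.update_eps, "tw": s.update_tweedie, "mu0": s.update_mu0}
    if block not in dispatch:
        raise ValueError(f"unknown block {block!r}")
    dispatch[block]()
    return s.state


def rj_toggle(state: ParameterState, covariate_index: int, panel, spec: ModelSpec,
              rng_or_seed=0) -> ParameterState:
    """One reversible-jump toggle of the indexed time covariate."""
    cfg = ChainConfig(n_iter=2, n_burn=0, adapt=False, log_every=0)
    s = TweedieSampler(panel, spec, cfg)
    if not isinstance(rng_or_seed, int):
        s.rng = rng_or_seed
    else:
        s.rng = np.random.default_rng(rng_or_seed)
    s.state = state.copy()
    s._refresh_all()
    s.rj_toggle_gamma(covariate_index)
    return s.state


def summarize(chain: ChainResult, spec: ModelSpec | None = None,
              scaling=None) -> dict:
    """Posterior summary: covariate decisions plus scalar parameter tables.

    Coefficient posterior means are model-averaged (excluded draws count
    as zero); Bayes factors compare posterior to prior inclusion odds and
    ``significant`` flags BF > 3.
    """
    spec = spec or chain.spec
    if chain.n_samples == 0:
        raise ValueError("empty chain")
    r = spec.inclusion_prior
    site_names = ("northing", "easting", "habitat")
    decisions = []
    for idx, name in enumerate(chain.selectable):
        if name.startswith("site:"):
            short = name.split(":", 1)[1]
            vals = chain.beta[:, site_names.index(short)]
        elif name == "density_dep":
            vals = chain.gamma_dd
        else:
            vals = chain.gamma[:, list(spec.covariate_names).index(name)]
        q = float(chain.inclusion_trace[:, idx].mean())
        bf = bayes_factor(q, r)
        per_unit = None
        if scaling is not None:
            key = name.split(":", 1)[-1]
            if spec.formulation == "change" and key in spec.covariate_names:
                key = f"logratio_{key}"
            sd = scaling.sd(key)
            per_unit = float(vals.mean()) / sd
        decisions.append(CovariateDecision(
            name=name.split(":", 1)[-1], posterior_mean=float(vals.mean()),
            inclusion_probability=q, bayes_factor=bf, significant=bf > 3.0,
            posterior_mean_per_unit=per_unit,
        ))
    scalars = {}
    for name, vals in (("alpha", chain.alpha), ("sigma2", chain.sigma2),
                       ("phi", chain.phi), ("p", chain.p)):
        scalars[name] = {
            "mean": float(vals.mean()),
            "ci_lower": float(np.quantile(vals, 0.025)),
            "ci_upper": float(np.quantile(vals, 0.975)),
        }
    return {"decisions": decisions, "scalars": scalars}
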