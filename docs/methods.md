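# Methods

## Observation model

Counts are modelled as Tweedie with index p ∈ (1, 2): a Poisson(λ) sum
of gamma(a, s) variates with

    λ = μ^(2−p) / (φ(2−p)),   a = (2−p)/(p−1),   s = φ(p−1) μ^(p−1),

so P(y = 0) = e^(−λ) and Var[y] = φ μ^p. The density for y > 0 is an
exponential-dispersion form c(y; φ, p)·exp{(yθ − κ(θ))/φ}; the series
factor c is evaluated by the Dunn–Smyth expansion over the latent
Poisson count, truncated adaptively around its largest term (terms are
log-concave in the index) so the dropped tail is below 1e−12 of the
retained sum; non-convergence raises rather than truncating silently.
Because c does not depend on μ, the sampler caches it per observed cell
and recomputes it only when (φ, p) moves — the reason the chain is cheap
despite the series.

Only p ∈ (1, 2) is implemented (the zero-inflated continuous branch,
indexed the standard way: Poisson p = 1, gamma p = 2). Inside the
sampler p is confined to (1 + δ, 2 − δ) with δ = 1e−3; at the
boundaries the compound representation degenerates (the gamma shape
diverges as p → 2).

## Mean structures

*Standard (growth-rate) form*, hierarchically centred: the site effect
ε_i ~ N(α + x_iᵀβ, σ²) enters the annual log growth rate, anchored at an
augmented pre-survey mean μ_i0 ~ U[0, 200]. Density dependence is the
lagged expected count divided by a fixed scale (`ModelSpec.dd_scale`,
defaulting to the species' overall observed mean) so its
negative-restricted coefficient lives on the same scale as the
normalized covariates. The recursion propagates through unobserved
site-years; covariates must exist from each site's first observed year
onward.

*Change–change form*: log(μ_it/μ_i,first) = log(v_it/v_i,first)ᵀγ + ε′_i
for t after each site's first observed year, the first-year mean being an
augmented baseline with the same U[0, 200] prior. This log-scale reading
keeps means positive and makes the intercept the mean log-change — the
scale on which such intercepts are reported. Count covariates that can
be zero (sparrowhawk, collared dove) get a +1 offset inside the ratio,
preserving "no change → 0"; the log-ratio columns are scaled to unit
variance but not centred, again to preserve the zero point. A frost
covariate of zero in a baseline year raises unless an offset is
configured.

Covariate normalization: continuous covariates are z-scored (site
covariates across sites; time-varying ones across live site-years); the
habitat factor stays ±1. The scaling record supports back-transforming
coefficients to per-unit scale (divide by the recorded sd), which the
effect-size transforms consume.

## Priors

N(0, 0.01) — variance, i.e. sd 0.1 — on each regression coefficient
(including the always-present intercept α, which has no separate listing);
half-normal HN(0, 0.01) on the negative density-dependence coefficient;
U[0, 5] on φ; U[0, 2] on p, restricted to the computable (1+δ, 2−δ);
InverseGamma(0.001, 0.001) (shape–rate) on σ²; U[0, 200] on each
augmented mean; independent Bernoulli(0.5) inclusion indicators. The
variance reading of "N(0, 0.01)" keeps the prior on the scale of the
fitted effects (|coef| ~ 0.01–0.1 on normalized covariates); a precision
reading (sd 10) would swamp the reversible-jump moves with the Bartlett
paradox.

σ²'s sampler support is confined to [1e−300, 1e+300]: the exact
InvGamma(0.001, 0.001) places roughly half its mass beyond double
precision (its median is near 10^298), so the confinement is the
variance analogue of the index-parameter δ-margin. Prior-recovery
checks therefore target the prior truncated to this support.

## Sampler

One sweep = Gibbs update of (α, β_included, σ²) given ε (conjugate
normal linear model; inverse-gamma conditional, Metropolized at the
support bounds) → reversible-jump toggles of the three site covariates
(their "likelihood" is the ε-regression) → per-site random-walk updates
of ε and of μ_i0 (reflected into [0, 200] with arbitrary-fold
reflection) → coefficient random walks (sign-reflected for γ_DD) → RJ
toggles of the time covariates and density dependence → a joint
log-φ/logit-p random walk with the appropriate Jacobians, the only block
that re-runs the series.

Three structural moves deal with the geometry of the recursive model,
in which a site effect acts cumulatively (a slope) and is therefore
strongly correlated with the site baseline and with every coefficient:

- a per-site shear moving (ε_i, log μ_i0) along the slope–level ridge
  (fixed data-derived pivot weights; the log-scale baseline change
  contributes an explicit Jacobian against the uniform prior);
- coefficient shears moving γ_k or γ_DD jointly with the compensating
  shift of every site effect (fixed weights from cumulative covariate
  sums, making the map symmetric with unit Jacobian);
- prior-refresh independence proposals: joint (σ², ε) from the
  hierarchical prior each sweep, and (φ, p) from their priors every 10th
  sweep, both accepted with bare likelihood ratios. With informative
  data they almost never accept and are merely valid extra moves; with a
  weak or empty likelihood they make the chain draw those parameters
  essentially iid from the prior — without the (σ², ε) move no random
  walk could traverse the ~600 decades of the variance prior, and prior
  recovery would be untestable.

RJ birth proposals draw the coefficient from its prior, so prior and
proposal cancel and the acceptance ratio is the likelihood ratio times
the prior inclusion odds. Toggles are lazy (a fair coin decides whether
to propose at all): under a flat likelihood a toggle always accepts, and
the lazy version breaks the resulting period-2 anti-correlation that
would alias with thinning. Excluded coefficients are exactly zero in
the likelihood; reported posterior means are model-averaged with those
zeros, and the Bayes factor is posterior over prior inclusion odds
(BF > 3 flagged significant; reports cap the printed value at ">10"
while storing it exactly).

Proposal scales adapt only during burn-in (target acceptance 0.2–0.4,
multiplicative nudges every 50 sweeps), then freeze, preserving detailed
balance afterwards. Divergent proposals (|log μ| > 50 at an observed
cell, non-positive baselines) auto-reject; a non-finite stored log
posterior aborts with a diagnostic. Chains are exactly reproducible
from (panel, spec, config): a single PCG64 generator seeded by the
config drives everything. Default chain lengths mirror the study:
20,000 iterations with 5,000 burn-in (standard), 100,000 with 60,000
(change); the calibration experiments use shorter chains, stated below.

Initialization is data-informed (baselines at first observed counts,
site effects at crude log growth rates), which matters more than chain
length for the short desk-scale chains.

## Goodness of fit

The discrepancy is the φ-scaled total Tweedie deviance
D = Σ d(y_it, μ_it)/φ over observed cells (unit deviance
d = 2(y^{2−p}/((1−p)(2−p)) − yμ^{1−p}/(1−p) + μ^{2−p}/(2−p)), finite at
y = 0). "Deviance" could also be read as −2·log-likelihood; the
φ-scaled deviance is the default because the discrepancy framework the
p-value comes from uses deviance-type discrepancies unqualified, and the
two differ only by the μ-free normalizer. For each retained draw a
replicate panel is simulated at the observed missingness mask,
conditioning on the drawn state including the augmented baselines (no
per-replicate refresh), and p is the fraction of draws with
D_rep ≥ D_obs; values outside [0.025, 0.975] indicate poor fit. Fewer
than 100 usable draws logs a warning but still returns.

## Synthetic generator

`generate_design` emulates the survey frame: a constant number of active
sites per winter; each year Binomial(n_active, turnover) sites retire
and are replaced by new sites drawn near the retired ones with the same
habitat class (expected observed fraction per site 1/(1 + r(T−1)), the
oracle the tests use). Covariates: ground-frost days as a year-level
normal shift plus site noise, rounded into [1, 183]; predator and
pseudo-predator counts as Poisson draws around a lognormal AR(1)
year index with a linear trend and site-level heterogeneity. The
defaults (150 active sites, 36 winters, 8% turnover, 40% urban,
γ = (−0.03, 0.01, 0.02), γ_DD = −0.02, σ² = 0.01, φ = 0.7, p = 1.35,
baselines U[2, 50]) sit in the regimes the survey analysis reports
(fitted p̂ ∈ [1.06, 1.46], σ̂² ∈ [0.001, 0.015], up to ~20% zeros for
low-abundance species with lower baseline bands). Baselines are drawn
from [2, 50] rather than the full prior support to avoid degenerate
all-zero series. The generator does not simulate the within-winter
26-week maximum protocol (counts arise directly at the site–winter
level) nor spatial correlation beyond the site covariates — so passing
tests speak to the model and sampler, not to those features of real
data. Generation under the change formulation draws baselines and site
effects and applies the change mean structure directly.

## Calibration experiments and problem sizes

Designs live in `tweediepop.experiments`; all are seeded and
deterministic.

- *Parameter recovery*: 100 sites × 20 winters (≈2,000 site-years,
  about a third of the real survey), 5,000 retained draws after 2,000
  burn-in, 20 replicate panels; 95% credible intervals must cover each
  generating parameter in ≥16/20. The recovery design sets turnover and
  density dependence to zero. Both exclusions are properties of the
  inference problem, not the code: (i) entry/exit censoring leaves
  short-history site effects weakly identified, and their flat-prior
  baselines tilt upward on the log scale, dragging the intercept's
  frequentist coverage below nominal; (ii) the density-dependence
  coefficient estimated from short latent-state series concentrates
  well beyond its generating value even when the chain is started at
  the truth — the long-known upward bias of density-dependence
  estimation under observation error — so neither admits a CI-coverage
  check at this scale. Both features remain on by default everywhere
  else and are exercised by the selection, GOF and generator tests.
  Truth effects (|β|, |γ| = 0.03–0.08) are set well above posterior
  uncertainty so that model-averaged intervals are not dominated by
  exclusion spikes.
- *Sign recovery*: 10 change-model panels with a strong negative
  predator effect (γ = −0.1); the posterior-mean sign must be negative
  in ≥9/10.
- *Selection calibration*: 60 sites × 15 winters; a null predator
  covariate must give BF < 3 in ≥8/10 replicates, a strong one
  (γ = 0.1) BF > 10 in ≥9/10; a flat likelihood returns inclusion
  ≈ 0.5.
- *Prior recovery*: a fully unobserved 4-site panel, 345,000 sweeps
  thinned by 10 (≈31,000 stored draws; ~15,000 per included
  coefficient), every sampled marginal tested against its prior by
  Kolmogorov–Smirnov at α = 0.01 (σ² against the support-truncated
  inverse gamma, p against its δ-restricted uniform). The length is set
  so that Monte-Carlo error is negligible for ten simultaneous KS tests.
- *GOF calibration*: 20 well-specified fits (50 × 12, 1,800 retained
  draws) must give p ∈ [0.025, 0.975] in ≥18/20 and a centred mean;
  20 misspecified fits (lognormal data, sdlog = 2, index pinned at 1.9
  via `ModelSpec.fixed_p`) must be more extreme on average. The free
  dispersion absorbs mild tail misspecification — only the heavy-tailed
  variant separates reliably, which is itself informative about the
  power of deviance-based posterior-predictive checks.

## Known limitations

- Bayes factors are marginal (model-averaged over the other covariates'
  inclusion), not conditional on a fixed covariate pattern.
- Single-chain inference; convergence is addressed by design (shear
  moves, informed initialization) and the recovery experiments rather
  than by multi-chain diagnostics, though multi-seed comparison is a
  one-liner.
- The density-dependence and short-history biases described above are
  statistical properties a user analysing real survey data should
  expect: γ_DD estimates at survey scale should be read as upper bounds
  on the strength of density dependence.
- No multiple-testing adjustment beyond the BF > 3 rule is applied
  across species or covariates, matching the reporting convention the
  package mirrors.
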