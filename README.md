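# tweediepop

Bayesian Tweedie hierarchical models for zero-inflated abundance panels —
the kind of data produced by long-running volunteer bird surveys, where
each site–winter observation is a mean of weekly maximum counts: a
non-negative, right-skewed value with a genuine point mass at exact zero.
The motivating question is whether a recovering predator (the
Sparrowhawk) depresses the winter garden counts of its songbird prey, or
whether apparent correlations are artefacts of habitat, weather and
density dependence.

## The model

Counts follow a Tweedie (compound Poisson–gamma) observation model with
index p ∈ (1, 2):

    y_it ~ Tw(μ_it, φ, p),    Var[y] = φ μ^p,

which is continuous on (0, ∞) with an atom at zero — a single family for
zero-inflated skewed abundances. Two mean structures are provided:

**Standard (growth-rate) model** — the log ratio of consecutive expected
counts is a linear function of time-varying covariates (sparrowhawk
count, collared-dove count as a pseudo-predator control, ground-frost
days), an optional negative density-dependence term in the lagged
expected count, and a site effect:

    log(μ_it / μ_i,t−1) = v_itᵀγ + γ_DD d_i,t−1 + ε_i,
    ε_i ~ N(α + x_iᵀβ, σ²)          (hierarchical centering)

anchored at an augmented pre-survey mean μ_i0 ~ U[0, 200]. Site
covariates x_i are northing, easting and a rural(−1)/urban(+1) factor.

**Change–change model** — log abundance change since each site's first
observed winter is regressed on covariate log-ratios:

    log(μ_it / μ_i,first) = log(v_it / v_i,first)ᵀγ + ε′_i,
    ε′_i ~ N(α + x_iᵀβ, σ²),

with the first-year mean an augmented baseline.

Inference is Metropolis-within-Gibbs MCMC. Covariate inclusion is
sampled by reversible-jump moves, giving posterior inclusion
probabilities and Bayes factors (BF > 3 read as positive evidence).
Goodness of fit uses the posterior-predictive Bayesian p-value with the
φ-scaled total Tweedie deviance as discrepancy; p outside
[0.025, 0.975] flags poor fit. A synthetic-panel generator reproduces
the survey's structure (≈8% annual site turnover, urban/rural mix,
autocorrelated covariates, zero-inflated skewed counts) so every stage
is testable with known truth.

## Worked example

`examples/03_fit_and_select_covariates.py` simulates 60 sites over 15
winters with a strong negative predator effect (γ = −0.1) and a null
pseudo-predator, then fits the standard model:

```
term             post.mean  incl.     BF  significant
northing            0.0042   0.28 0.3827  False
easting            -0.0018   0.16 0.1927  False
habitat            -0.0001   0.11 0.1261  False
sparrowhawk        -0.0868   1.00    >10  True
collared_dove       0.0024   0.17 0.2048  False
frost_days          0.0161   0.59  1.427  False
scalars: {'alpha': 0.011, 'sigma2': 0.008, 'phi': 0.649, 'p': 1.394}
```

The predator covariate is decisively included (Bayes factor above the
reporting cap, printed `>10` as in the study tables) with a posterior
mean near the generating −0.1, while the null collared dove is excluded
(BF ≈ 0.2). The effect-size transforms turn coefficients into the
quoted percentages: a per-sparrowhawk coefficient of −0.0369 is a
`100·(1 − exp(−0.0369)) = 3.6%` reduction in the annual rate of
population change, and a per-doubling coefficient of −0.0325 is a
`100·(1 − 2^−0.0325) = 2.2%` reduction
(`examples/05_effect_sizes_and_risk.py`).

Other examples: `01` the Tweedie distribution itself, `02` the synthetic
survey generator, `04` posterior-predictive goodness of fit.

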