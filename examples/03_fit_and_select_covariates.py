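"""Fit the standard model with reversible-jump covariate selection.

Simulates a panel with a strong negative sparrowhawk effect and a null
collared-dove (pseudo-predator) effect, fits the hierarchical Tweedie
model, and prints the covariate decision table: model-averaged posterior
means, inclusion probabilities and Bayes factors (BF > 3 = significant).
"""

from tweediepop import ChainConfig, SyntheticTruth, simulate_panel
from tweediepop.mcmc import format_bf, run_chain, summarize

truth = SyntheticTruth(
    n_site=60, T=15, seed=8,
    gamma=(-0.1, 0.0, 0.04),            # hawk, dove (null), frost
    include_density_dependence=False, gamma_dd=0.0,
)
panel, _ = simulate_panel(truth)
spec = truth.model_spec()
chain = run_chain(panel, spec, ChainConfig(n_iter=4000, n_burn=1500, seed=9))
summary = summarize(chain, spec)

print(f"{'term':<15} {'post.mean':>10} {'incl.':>6} {'BF':>6}  significant")
for d in summary["decisions"]:
    print(f"{d.name:<15} {d.posterior_mean:>10.4f} "
          f"{d.inclusion_probability:>6.2f} {format_bf(d.bayes_factor):>6}  "
          f"{d.significant}")
print("scalars:", {k: round(v['mean'], 3) for k, v in summary["scalars"].items()})
# Expect: sparrowhawk decisively included with a negative mean near -0.1,
# the null collared dove excluded (BF well under 3).
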