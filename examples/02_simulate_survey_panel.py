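"""Generate a survey-like panel: site turnover, covariates, known truth.

Writes the panel as CSV with a JSON truth sidecar, the same long format
the fitting pipeline reads.
"""

import numpy as np

from tweediepop import SyntheticTruth, simulate_panel
from tweediepop.synthetic import save_synthetic

truth = SyntheticTruth(n_site=150, T=36, turnover_rate=0.08, seed=42)
panel, state = simulate_panel(truth)

y = panel.observed_values()
print(f"{panel.n_site} distinct sites over {panel.n_year} winters, "
      f"{panel.n_obs} observed site-years "
      f"({panel.n_obs / (panel.n_site * panel.n_year):.0%} of the grid)")
print(f"counts: mean {y.mean():.1f}, max {y.max():.0f}, "
      f"{(y == 0).mean():.1%} exact zeros")
print(f"generating predator effect gamma_hawk = {truth.gamma[0]} "
      f"(per sd of normalized sparrowhawk count, per winter)")

save_synthetic(panel, truth, "scratch_panel")
print("wrote scratch_panel.csv + scratch_panel.truth.json")
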