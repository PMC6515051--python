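"""Fit a BIC-selected Gaussian mixture to a log-Ks age distribution.

Uses the generator's ground-truth Ks values (no sequence estimation) so the
example runs in seconds: a 2000-family paranome with a WGD burst at Ks 1.2.
"""

import numpy as np

from paleoks import SimulationConfig, simulate_population
from paleoks.mixture import select_k, summarize_components

config = SimulationConfig(n_families=2000, seed=3)
_, truth = simulate_population(config, sequences=False)
ks = truth.true_ks.to_numpy()
ks = ks[(ks >= 0.1) & (ks <= 5.0)]

best, fits = select_k(np.log(ks), k_range=range(1, 9), seed=3, n_init=3)
summaries = summarize_components(best, np.log(ks), B=100, seed=3)

print(f"n = {len(ks)} pairs in [0.1, 5];  BIC selects k = {best.k}")
for s in summaries:
    print(
        f"  component: mean Ks {s.mean_ks:5.3f}  "
        f"(95% CI {s.ci95[0]:.3f}-{s.ci95[1]:.3f})  "
        f"proportion {s.proportion:.3f}  -> {s.label}"
    )
print(
    "\nThe candidate-WGD component should sit near the generating burst "
    "(Ks 1.2); the remaining components tile the exponential background."
)
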