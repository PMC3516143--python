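"""Compare the three uncertainty propagators on a bistable response.

Propagates the Schlögl parameter distribution (log-normal, 10% CV on all
seven parameters) through the model under a mid-strength constant stimulus
that leaves the population straddling the two stable branches.  The Monte
Carlo reference shows a large response variance (bimodal population); the
sigma-point estimate tracks it, while linearization — a local method tied
to the nominal trajectory — reports a far smaller variance.
"""

import numpy as np

from roed import (propagate_linearized, propagate_monte_carlo,
                  propagate_sigma_points)
from roed.benchmarks.schlogl import build_schlogl_pair
from roed.stimulus import constant_stimulus

model_a, _, d = build_schlogl_pair()
dist, transform = d["dist"], d["transform"]
stim = constant_stimulus(30.0, 10.0)   # near the saddle-node threshold
grid = np.linspace(1.0, 10.0, 10)

lin = propagate_linearized(model_a, dist, stim, grid, transform)
# kappa=0 is the benchmark's packaged UT setting: it keeps all mean weights
# nonnegative, which matters when sigma points land on both stable branches
ut = propagate_sigma_points(model_a, dist, stim, grid, transform,
                            **d["ut_params"])
mc = propagate_monte_carlo(model_a, dist, stim, grid, transform,
                           n_samples=4000, seed=0)

print(f"{'t':>5} {'lin mean':>9} {'UT mean':>9} {'MC mean':>9}"
      f" {'lin var':>9} {'UT var':>9} {'MC var':>9}")
for k, t in enumerate(grid):
    print(f"{t:5.1f} {lin.means[k, 0]:9.2f} {ut.means[k, 0]:9.2f}"
          f" {mc.means[k, 0]:9.2f} {lin.covs[k, 0, 0]:9.2f}"
          f" {ut.covs[k, 0, 0]:9.2f} {mc.covs[k, 0, 0]:9.2f}")
print()
print("Monte Carlo is the reference: its variance is inflated by the")
print("bimodal split across the branches.  The sigma-point estimate follows")
print("it; the linearized variance misses the far branch entirely.")
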