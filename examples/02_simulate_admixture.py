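"""Calibrate and draw the 1D-geography admixture simulation.

Ten intermediate subpopulations sit on a line with differentiation growing
with position (a serial founder effect); individuals admix with
Normal-density weights.  The spread sigma is solved so the bias coefficient
s (mean coancestry over F_ST) is 1/2 -- the regime where the classical
F_ST estimators lose about half the signal -- and tau scales the
differentiations so F_ST = 0.1 exactly.
"""

import numpy as np

from structkin import (
    SimConfig, bias_coefficient, mean_relatedness, simulate_admix,
    uniform_weights,
)

config = SimConfig(n=200, m=5000)  # small version of the study conditions
bundle = simulate_admix(config, np.random.default_rng(0))
model = bundle.model

print(f"solved sigma = {model.sigma:.3f}, tau = {model.tau:.3f}")
w = uniform_weights(config.n)
mr = mean_relatedness(bundle.theta_true, w)
print(f"true F_ST = {mr.fst:.4f}, mean coancestry = {mr.theta_bar:.4f}, "
      f"bias coefficient s = {bias_coefficient(bundle.theta_true, w):.3f}")
print(f"genotypes: {bundle.X.shape[0]} individuals x {bundle.X.shape[1]} loci, "
      f"mean dosage {bundle.X.mean():.3f}")

# s = 0.5 means the average pair of individuals shares half as much
# coancestry as an average individual's inbreeding: no subpopulation is
# independent of any other, which is exactly what breaks the classical
# estimators.
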