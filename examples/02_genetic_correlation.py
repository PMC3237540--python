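"""Genetic correlation between two traits from a two-trait animal model.

Simulates two traits whose breeding values share a genetic correlation of
0.8 on a 30-sire half-sib design, fits the bivariate animal model with
unstructured 2x2 G and R matrices, and prints the posterior for r_g.
"""

import numpy as np
import pandas as pd

from stickleqg import ChainConfig, ModelSpec, fit_bivariate
from stickleqg.simulate import SimulationConfig, simulate_design, _breeding_values

rng = np.random.default_rng(3)
cfg = SimulationConfig(n_sires=30, offspring_range=(20, 20), n_tanks_per_family=1)
ped, design = simulate_design(cfg, rng)

true_rg = 0.8
G = np.array([[3.0, true_rg * 3.0], [true_rg * 3.0, 3.0]])  # additive covariance
bv = _breeding_values(ped, G, rng)
idx = np.array([ped.index[i] for i in design["id"]])
data = pd.DataFrame(
    {
        "id": design["id"],
        "size": bv[idx, 0] + rng.normal(0, 2.0, len(idx)),
        "timing": bv[idx, 1] + rng.normal(0, 2.0, len(idx)),
    }
)

bs = fit_bivariate(
    data, ("size", "timing"),
    ModelSpec(response="size", fixed=(), maternal=False),
    ped, chain=ChainConfig(6000, 1500, 4), seed=5,
)
lo, hi = bs.rg_hpd()
print(f"posterior mean r_g = {bs.rg_mean:.3f}  (95% HPD {lo:.3f} to {hi:.3f})")
print(
    "\nr_g is the correlation of additive genetic effects "
    "sigma_a12 / sqrt(sigma2_a1 sigma2_a2); the generating value is 0.8, "
    "so the interval should cover it. A positive r_g means the two traits "
    "are genetically coupled and respond jointly to selection."
)
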