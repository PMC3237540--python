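"""Compare quantitative (Q_ST) and neutral (F_ST) divergence.

Simulates two diverged half-sib populations with a between-population
variance equal to twice the within-population additive variance (true
Q_ST = 0.5), plus a 103-locus Balding-Nichols neutral panel at F = 0.458
for 24 + 24 fish.  Fits the Bayesian Q_ST model, estimates Weir-Cockerham
theta with jackknife SE and a 1000-permutation test, and classifies the
contrast.
"""

import numpy as np
import pandas as pd

from stickleqg import ChainConfig, fit_qst, fst_estimate, qst_fst_contrast
from stickleqg.simulate import GenotypeParams, simulate_genotypes, simulate_halfsib_trait

# --- quantitative trait in two populations --------------------------------
delta = 2 * np.sqrt(3.0)  # between-population gap -> sigma2_GB = 2 sigma2_GW
peds, frames = {}, []
for k, (pop, mu) in enumerate((("coastal", delta / 2), ("pond", -delta / 2))):
    ped, d = simulate_halfsib_trait(
        n_sires=20, n_offspring=12, v_a=3.0, v_m=0.5, v_e=4.0,
        mu=mu, seed=10 + k, population=pop,
    )
    d["population"] = pop
    peds[pop] = ped
    frames.append(d)
data = pd.concat(frames, ignore_index=True)

q = fit_qst(data, peds, response="y",
            chain=ChainConfig(iterations=10_000, burn_in=5_000, thin=2), seed=1)
print(f"Q_ST = {q.posterior_mean:.3f} +- {q.posterior_sd:.3f} "
      f"(posterior mean +- SD, rhat {q.rhat:.3f})")

# --- neutral markers -------------------------------------------------------
panel = simulate_genotypes(
    GenotypeParams(n_loci=103, alleles_per_locus=5, target_fst=0.458,
                   n_per_population=24),
    seed=2,
)
f = fst_estimate(panel, n_perm=1000, seed=3)
print(f"F_ST (theta) = {f.theta:.3f} +- {f.se:.3f} (jackknife SE), "
      f"permutation p = {f.p_value:.4f} over {f.n_permutations} permutations")

print(f"contrast: {qst_fst_contrast(q, f)}")
print(
    "\nQ_ST above F_ST indicates divergence beyond neutral drift "
    "(directional selection); below indicates stabilizing selection. Here "
    "the generating Q_ST (0.5) sits near the neutral baseline (0.458), so "
    "'indistinguishable' is the expected outcome."
)
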