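"""Independent reference implementations used as test oracles.

These are deliberately written in a different style from the package
(dictionaries and explicit loops, textbook formulas) so they share no code
path with the implementations they check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def wc_theta_oracle(panel) -> float:
    """Brute-force multi-allelic Weir-Cockerham theta, ratio of sums.

    Follows the per-allele variance-component formulas directly with
    explicit loops over loci, alleles and populations.
    """
    pops = panel.population_labels
    sum_a = sum_abc = 0.0
    for l, _locus in enumerate(panel.loci):
        # collect genotyped individuals per population
        by_pop: dict[str, list[tuple[int, int]]] = {p: [] for p in pops}
        for i in range(panel.n_individuals):
            g = panel.genotypes[i, l]
            if g[0] >= 0 and g[1] >= 0:
                by_pop[str(panel.populations[i])].append((int(g[0]), int(g[1])))
        sampled = [p for p in pops if by_pop[p]]
        r = len(sampled)
        if r < 2:
            continue
        alleles = sorted({a for p in sampled for g in by_pop[p] for a in g})
        if len(alleles) < 2:
            continue
        n = {p: len(by_pop[p]) for p in sampled}
        nbar = sum(n.values()) / r
        if nbar <= 1:
            continue
        nc = (r * nbar - sum(v * v for v in n.values()) / (r * nbar)) / (r - 1)
        if nc <= 0:
            continue
        for allele in alleles:
            p_freq = {}
            h_freq = {}
            for p in sampled:
                count = sum((g[0] == allele) + (g[1] == allele) for g in by_pop[p])
                hets = sum(
                    1 for g in by_pop[p] if g[0] != g[1] and allele in g
                )
                p_freq[p] = count / (2 * n[p])
                h_freq[p] = hets / n[p]
            pbar = sum(n[p] * p_freq[p] for p in sampled) / (r * nbar)
            s2 = sum(n[p] * (p_freq[p] - pbar) ** 2 for p in sampled) / ((r - 1) * nbar)
            hbar = sum(n[p] * h_freq[p] for p in sampled) / (r * nbar)
            a_val = (nbar / nc) * (
                s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
            )
            b_val = (nbar / (nbar - 1)) * (
                pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
            )
            c_val = hbar / 2
            sum_a += a_val
            sum_abc += a_val + b_val + c_val
    if sum_abc == 0:
        raise ValueError("theta undefined")
    return sum_a / sum_abc


def anova_halfsib_h2(data: pd.DataFrame, ped) -> float:
    """Balanced nested sire/dam ANOVA heritability: 4 sigma2_sire / total.

    Expects a balanced design (same number of dams per sire and offspring
    per dam) with columns ``id``, ``y``, ``dam``.
    """
    d = data.copy()
    d["sire"] = [ped.ids[ped.sire_idx[ped.index[i]]] for i in d["id"]]
    n_sires = d["sire"].nunique()
    dams_per_sire = d.groupby("sire")["dam"].nunique().iloc[0]
    per_dam = d.groupby("dam").size().iloc[0]
    grand = d["y"].mean()
    sire_means = d.groupby("sire")["y"].mean()
    dam_means = d.groupby("dam")["y"].mean()

    ms_sire = (
        dams_per_sire * per_dam * ((sire_means - grand) ** 2).sum() / (n_sires - 1)
    )
    dam_tab = d.groupby("dam").agg(y=("y", "mean"), sire=("sire", "first"))
    ms_dam = (
        per_dam
        * ((dam_tab["y"] - dam_tab["sire"].map(sire_means)) ** 2).sum()
        / (n_sires * (dams_per_sire - 1))
    )
    ms_within = ((d["y"] - d["dam"].map(dam_means)) ** 2).sum() / (
        len(d) - n_sires * dams_per_sire
    )
    sigma_sire = (ms_sire - ms_dam) / (dams_per_sire * per_dam)
    sigma_dam = (ms_dam - ms_within) / per_dam
    total = sigma_sire + sigma_dam + ms_within
    return float(4.0 * sigma_sire / total)


def random_pedigree(rng: np.random.Generator, n_founders: int = 10, n_offspring: int = 40):
    """A random multi-generation pedigree for property checks."""
    from stickleqg.pedigree import Pedigree

    records = [(f"f{i}", None, None, "p") for i in range(n_founders)]
    ids = [r[0] for r in records]
    for k in range(n_offspring):
        s, d = rng.choice(len(ids), size=2, replace=False)
        records.append((f"o{k}", ids[s], ids[d], "p"))
        ids.append(f"o{k}")
    return Pedigree(records)
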