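"""Bayesian Q_ST between two populations from a joint animal model.

Q_ST is the quantitative-trait analogue of F_ST:

    Q_ST = sigma2_GB / (sigma2_GB + 2 sigma2_GW)

with sigma2_GB the between-population additive variance (the variance of a
random population effect) and sigma2_GW the pooled within-population
additive variance from animal models run on each population's pedigree
(common-G assumption).  The whole hierarchy is sampled jointly by MCMC:
Q_ST is computed draw-wise, summarised as posterior mean +- SD, and
compared to the neutral expectation set by F_ST.

With only two populations sigma2_GB is weakly identified and the prior
matters: a half-Cauchy prior is placed on the population-effect standard
deviation, with a configurable scale and an optional sensitivity rerun at
several scales.  Convergence is monitored with the Gelman-Rubin statistic
across two chains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .animal_model import build_design
from .errors import InputError, ReferenceError_
from .fst import FstEstimate
from .mcmc import ChainConfig, RandomTerm, VariancePrior, hpd_interval, run_gibbs
from .pedigree import Pedigree, relationship_inverse

__all__ = ["QstEstimate", "fit_qst", "qst_fst_contrast", "qst_from_variances"]

RHAT_THRESHOLD = 1.2


def qst_from_variances(sigma2_gb, sigma2_gw):
    """Draw-wise (or scalar) Q_ST = s2_GB / (s2_GB + 2 s2_GW)."""
    sigma2_gb = np.asarray(sigma2_gb, dtype=float)
    sigma2_gw = np.asarray(sigma2_gw, dtype=float)
    return sigma2_gb / (sigma2_gb + 2.0 * sigma2_gw)


@dataclass
class QstEstimate:
    """Posterior of Q_ST for one trait at one age."""

    qst_draws: np.ndarray
    sigma2_gb_draws: np.ndarray
    sigma2_gw_draws: np.ndarray
    posterior_mean: float
    posterior_sd: float
    rhat: float
    prior_scale: float
    convergence_warning: str | None = None
    sensitivity: dict[float, tuple[float, float]] | None = None
    per_population_va: dict[str, float] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return len(self.qst_draws)

    def quantile(self, q) -> float:
        return float(np.quantile(self.qst_draws, q))

    def hpd(self, prob: float = 0.95) -> tuple[float, float]:
        return hpd_interval(self.qst_draws, prob)

    def to_json(self) -> dict:
        out = {
            "posterior_mean": self.posterior_mean,
            "posterior_sd": self.posterior_sd,
            "n_draws": self.n_draws,
            "rhat": self.rhat,
            "prior_scale": self.prior_scale,
        }
        if self.convergence_warning:
            out["convergence_warning"] = self.convergence_warning
        if self.sensitivity is not None:
            out["sensitivity"] = {str(k): v for k, v in self.sensitivity.items()}
        return out


def _default_chain() -> ChainConfig:
    # two chains of 10,000: 5000 burn-in, keep every 2nd -> 2 x 2500 draws
    return ChainConfig(iterations=10_000, burn_in=5_000, thin=2)


def fit_qst(
    data: pd.DataFrame,
    peds: dict[str, Pedigree],
    response: str = "length_mm",
    age: int | None = None,
    fixed: tuple[str, ...] = (),
    chain: ChainConfig | None = None,
    seed: int = 0,
    prior_scale: float = 1.0,
    include_maternal: bool = False,
    n_chains: int = 2,
    sensitivity_scales: tuple[float, ...] | None = None,
) -> QstEstimate:
    """Fit the hierarchical two-population Q_ST model by MCMC.

    Parameters
    ----------
    data : combined TraitTable for both populations (column ``population``).
    peds : mapping population label -> its Pedigree.
    age : optional filter on ``age_dah``.
    prior_scale : half-Cauchy scale on the population-effect SD, in units of
        the response SD.
    include_maternal : add dam-identity variance to the model (it is never
        part of the Q_ST denominator).
    sensitivity_scales : if given, rerun at these prior scales and report
        (posterior mean, SD) for each.

    The within-population additive variance and the residual carry flat
    priors on the SD scale, making Q_ST draws exactly invariant to shifting
    and rescaling the phenotypes (given the same seed).
    """
    chain = chain or _default_chain()
    sub = data if age is None else data[data["age_dah"] == age]
    pops = list(dict.fromkeys(sub["population"].astype(str)))
    if len(pops) < 2:
        raise InputError(f"Q_ST needs >= 2 populations, got {pops}")
    missing_ped = [p for p in pops if p not in peds]
    if missing_ped:
        raise ReferenceError_(f"no pedigree supplied for populations {missing_ped}")
    if response not in sub.columns:
        raise InputError(f"response column {response!r} not in data")
    sub = sub.dropna(subset=[response])

    # block-diagonal A^-1 across population pedigrees
    ped_list = [peds[p] for p in pops]
    all_ids: list[str] = []
    for ped in ped_list:
        all_ids.extend(ped.ids)
    if len(set(all_ids)) != len(all_ids):
        raise InputError("individual ids collide across population pedigrees")
    kinv = sp.block_diag([relationship_inverse(p) for p in ped_list], format="csr")
    id_index = {iid: k for k, iid in enumerate(all_ids)}

    ids = sub["id"].astype(str).to_numpy()
    unknown = [i for i in ids if i not in id_index]
    if unknown:
        raise ReferenceError_(f"individuals not in any pedigree: {unknown[:5]}")
    y = sub[response].to_numpy(dtype=float)
    sd_y = float(np.std(y))
    X, x_names = build_design(sub, fixed)

    obs_add = np.array([id_index[i] for i in ids], dtype=np.int64)
    pop_index = {p: k for k, p in enumerate(pops)}
    obs_pop = np.array([pop_index[str(p)] for p in sub["population"]], dtype=np.int64)

    def terms_for(scale: float) -> list[RandomTerm]:
        t = [
            RandomTerm("additive", all_ids, obs_add, kinv=kinv,
                       prior=VariancePrior(kind="flat_sd")),
            RandomTerm("population", pops, obs_pop, kinv=None,
                       prior=VariancePrior(kind="half_cauchy_sd", scale=scale * sd_y)),
        ]
        if include_maternal:
            dams = [peds[str(p)].dam_of(i) for i, p in zip(ids, sub["population"])]
            if any(d is None for d in dams):
                raise ReferenceError_("maternal term requested but some dams unknown")
            levels = sorted(set(dams))
            dmap = {d: k for k, d in enumerate(levels)}
            t.append(
                RandomTerm("maternal", levels,
                           np.array([dmap[d] for d in dams], dtype=np.int64),
                           kinv=None, prior=VariancePrior(kind="flat_sd"))
            )
        return t

    def run(scale: float, base_seed: int):
        gb_chains, gw_chains = [], []
        for c in range(n_chains):
            res = run_gibbs(
                y, X, terms_for(scale), chain, seed=base_seed + 1000 * c,
                residual_prior=VariancePrior(kind="flat_sd"), x_names=x_names,
            )
            gb_chains.append(res.variance_draws["population"])
            gw_chains.append(res.variance_draws["additive"])
        return np.array(gb_chains), np.array(gw_chains)

    gb, gw = run(prior_scale, seed)
    import arviz as az

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = float(az.rhat(az.convert_to_dataset(gb[None] if gb.ndim == 1 else gb))["x"].values) \
            if n_chains > 1 else float("nan")
    gb_flat, gw_flat = gb.ravel(), gw.ravel()
    qst_draws = qst_from_variances(gb_flat, gw_flat)
    warning = None
    if n_chains > 1 and np.isfinite(rhat) and rhat > RHAT_THRESHOLD:
        warning = (
            f"Gelman-Rubin rhat = {rhat:.3f} > {RHAT_THRESHOLD} on sigma2_GB; "
            "chains may not have converged"
        )
        warnings.warn(warning, UserWarning, stacklevel=2)

    sens = None
    if sensitivity_scales:
        sens = {}
        for s in sensitivity_scales:
            gb_s, gw_s = run(s, seed + 777)
            q_s = qst_from_variances(gb_s.ravel(), gw_s.ravel())
            sens[float(s)] = (float(q_s.mean()), float(q_s.std()))

    per_pop_va = {}
    for p in pops:
        mask = np.array([str(v) == p for v in sub["population"]])
        per_pop_va[p] = float(np.var(y[mask]))  # descriptive within-pop variance

    return QstEstimate(
        qst_draws=qst_draws,
        sigma2_gb_draws=gb_flat,
        sigma2_gw_draws=gw_flat,
        posterior_mean=float(qst_draws.mean()),
        posterior_sd=float(qst_draws.std()),
        rhat=rhat,
        prior_scale=prior_scale,
        convergence_warning=warning,
        sensitivity=sens,
        per_population_va=per_pop_va,
    )


def qst_fst_contrast(q: QstEstimate, f: "FstEstimate | float") -> str:
    """Classify divergence by where F_ST falls in the Q_ST posterior.

    Returns ``"directional"`` if the F_ST point estimate lies below the
    2.5% quantile of the Q_ST posterior (Q_ST > F_ST: divergence beyond
    drift), ``"stabilizing"`` if it lies above the 97.5% quantile
    (Q_ST < F_ST), otherwise ``"indistinguishable"``.
    """
    fst = f.theta if isinstance(f, FstEstimate) else float(f)
    lo, hi = q.quantile(0.025), q.quantile(0.975)
    if fst < lo:
        return "directional"
    if fst > hi:
        return "stabilizing"
    return "indistinguishable"
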