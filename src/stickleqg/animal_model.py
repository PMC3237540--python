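"""Bayesian animal models: variance components, heritability, r_g, DIC.

The central model is the pedigree mixed model

    y = X b + Z1 a + Z2 m + e

with a ~ N(0, A sigma2_a) the additive genetic values (A the numerator
relationship matrix), m ~ N(0, I sigma2_m) the maternal (dam-identity)
effects combining maternal genetic and environmental contributions, and
e ~ N(0, I sigma2_e).  Fixed effects are the overall mean plus any of
density, block and a three-level sex factor (male / female / immature,
because immature fish cannot be sexed).  Heritability and maternal-effect
draws follow from the variance draws:

    h2 = sigma2_a / (sigma2_a + sigma2_m + sigma2_e)
    m2 = sigma2_m / (sigma2_a + sigma2_m + sigma2_e)

Binary timing-of-maturation records (matured: 0, immature: 1) are analysed
on the Gaussian scale, i.e. as a numeric 0/1 response; no liability-link
fit is attempted.  Posterior modes are kernel-density argmaxima and
intervals are 95% highest-posterior-density intervals.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.stats import invwishart

from .errors import (
    ComparabilityError,
    DegenerateDataError,
    InputError,
    PrecisionError,
    ReferenceError_,
)
from .mcmc import (
    ChainConfig,
    GibbsResult,
    RandomTerm,
    VariancePrior,
    deviance_at,
    hpd_interval,
    kde_mode,
    run_gibbs,
)
from .pedigree import Pedigree, relationship_inverse

__all__ = [
    "ModelSpec",
    "McmcSamples",
    "VarianceSummary",
    "BivariateSamples",
    "fit_animal_model",
    "summarize_variances",
    "fit_bivariate",
    "dic",
    "dic_compare",
    "build_design",
]


# --------------------------------------------------------------------- #
@dataclass
class ModelSpec:
    """What to fit: response, fixed effects, random structure.

    ``fixed`` lists TraitTable column names; columns with object/category
    dtype (or listed in ``categorical``) enter as treatment-coded dummies,
    numeric columns as covariates.  The overall mean (intercept) is always
    included.  ``maternal=True`` adds the dam-identity random term, with
    each phenotyped individual's dam read from the pedigree.

    ``block_random`` names a column (typically the rearing tank) to add as
    an i.i.d. random term.  Because tanks are nested within dams in a
    split-family design, a flat-prior fixed block factor would absorb every
    dam contrast and leave the maternal variance unidentified; the random
    parameterisation keeps both estimable.  Tank variance is treated as a
    nuisance: it never enters V_P = sigma2_a + sigma2_m + sigma2_e.
    """

    response: str
    fixed: tuple[str, ...] = ()
    categorical: tuple[str, ...] = ("block", "sex", "population", "family")
    maternal: bool = True
    block_random: str | None = None
    additive_prior: VariancePrior = field(default_factory=VariancePrior)
    maternal_prior: VariancePrior = field(default_factory=VariancePrior)
    residual_prior: VariancePrior = field(default_factory=VariancePrior)
    block_prior: VariancePrior = field(default_factory=VariancePrior)


def build_design(data: pd.DataFrame, fixed: tuple[str, ...],
                 categorical: tuple[str, ...] = ()) -> tuple[np.ndarray, list[str]]:
    """Intercept + treatment-coded design matrix for the fixed effects."""
    cols = [np.ones(len(data))]
    names = ["(Intercept)"]
    for c in fixed:
        if c not in data.columns:
            raise InputError(f"fixed-effect column {c!r} not in data")
        col = data[c]
        if c in categorical or col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col.astype(str), prefix=c, drop_first=True)
            for name in dummies.columns:
                cols.append(dummies[name].to_numpy(dtype=float))
                names.append(name)
        else:
            x = col.to_numpy(dtype=float)
            if np.ptp(x) < 1e-12:
                continue  # constant covariate: absorbed by the intercept
            cols.append(x)
            names.append(c)
    X = np.column_stack(cols)
    return _drop_aliased(X, names)


def _drop_aliased(X: np.ndarray, names: list[str], tol: float = 1e-9):
    """Drop columns linearly dependent on earlier ones (sequential scan).

    Tank-level covariates (e.g. density) and a saturated block factor can be
    exactly collinear; like R's lm, later aliased columns are removed so the
    system matrix stays positive definite.
    """
    G = X.T @ X
    scale = np.sqrt(np.diag(G))
    scale[scale == 0] = 1.0
    Gn = G / np.outer(scale, scale)
    keep: list[int] = []
    L = np.zeros((0, 0))
    for j in range(X.shape[1]):
        g = Gn[np.ix_(keep, [j])].ravel()
        if keep:
            w = sla.solve_triangular(L, g, lower=True)
            resid = Gn[j, j] - w @ w
        else:
            w = np.zeros(0)
            resid = Gn[j, j]
        if resid < tol:
            continue
        newL = np.zeros((len(keep) + 1, len(keep) + 1))
        newL[:-1, :-1] = L
        newL[-1, :-1] = w
        newL[-1, -1] = np.sqrt(resid)
        L = newL
        keep.append(j)
    return X[:, keep], [names[j] for j in keep]


def _data_checksum(y: np.ndarray, ids: np.ndarray) -> str:
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(np.asarray(y, dtype=float)).tobytes())
    h.update("|".join(map(str, ids)).encode())
    return h.hexdigest()


# --------------------------------------------------------------------- #
@dataclass
class McmcSamples:
    """Post-burn-in, thinned draws from one univariate animal-model fit."""

    draws: dict[str, np.ndarray]  # keys V_A, V_M (optional), V_E
    fixed: pd.DataFrame
    deviance: np.ndarray
    dic_value: float
    dbar: float
    dhat: float
    meta: dict

    @property
    def n_draws(self) -> int:
        return len(self.deviance)

    @property
    def va_draws(self) -> np.ndarray:
        return self.draws["V_A"]

    @property
    def vm_draws(self) -> np.ndarray:
        return self.draws.get("V_M", np.zeros_like(self.draws["V_A"]))

    @property
    def ve_draws(self) -> np.ndarray:
        return self.draws["V_E"]

    @property
    def vp_draws(self) -> np.ndarray:
        return self.va_draws + self.vm_draws + self.ve_draws

    @property
    def h2_draws(self) -> np.ndarray:
        return self.va_draws / self.vp_draws

    @property
    def m2_draws(self) -> np.ndarray:
        return self.vm_draws / self.vp_draws

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(self.draws)
        out["h2"] = self.h2_draws
        out["m2"] = self.m2_draws
        out["deviance"] = self.deviance
        return pd.concat([out, self.fixed.add_prefix("b_")], axis=1)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _wrap_result(res: GibbsResult, term_map: dict[str, str], y: np.ndarray,
                 ids: np.ndarray, extra_meta: dict) -> McmcSamples:
    draws = {"V_E": res.variance_draws["residual"]}
    for term_name, out_name in term_map.items():
        draws[out_name] = res.variance_draws[term_name]
    dbar = float(np.mean(res.deviance_draws))
    dhat = deviance_at(res.system, y, res.theta_mean, res.sigma2_e_mean)
    dic_value = 2.0 * dbar - dhat
    burn, thin = res.chain.resolve()
    meta = {
        "n_obs": res.n_obs,
        "iterations": res.chain.iterations,
        "burn_in": burn,
        "thin": thin,
        "seed": res.seed,
        "data_checksum": _data_checksum(y, ids),
        "terms": sorted(term_map.values()),
        **extra_meta,
    }
    fixed = pd.DataFrame(res.fixed_draws, columns=res.fixed_names)
    return McmcSamples(
        draws=draws, fixed=fixed, deviance=res.deviance_draws,
        dic_value=dic_value, dbar=dbar, dhat=dhat, meta=meta,
    )


def fit_animal_model(
    data: pd.DataFrame,
    spec: ModelSpec,
    ped: Pedigree,
    chain: ChainConfig | None = None,
    seed: int = 0,
) -> McmcSamples:
    """Gibbs-sample the univariate animal model.

    ``data`` holds one row per phenotyped individual (``id`` column) for a
    single age; the pedigree must cover every phenotyped individual.  Fully
    reproducible given ``seed``.
    """
    chain = chain or ChainConfig()
    if spec.response not in data.columns:
        raise InputError(f"response column {spec.response!r} not in data")
    ids = data["id"].astype(str).to_numpy()
    missing = [i for i in ids if i not in ped]
    if missing:
        raise ReferenceError_(f"individuals not in pedigree: {missing[:5]}")
    y = data[spec.response].to_numpy(dtype=float)
    if np.ptp(y) < 1e-12:
        raise DegenerateDataError(f"response {spec.response!r} is constant")

    X, x_names = build_design(data, spec.fixed, spec.categorical)
    kinv = relationship_inverse(ped)
    obs_level = np.array([ped.index[i] for i in ids], dtype=np.int64)
    terms = [
        RandomTerm("additive", list(ped.ids), obs_level, kinv=kinv, prior=spec.additive_prior)
    ]
    term_map = {"additive": "V_A"}
    if spec.maternal:
        dams = [ped.dam_of(i) for i in ids]
        if any(d is None for d in dams):
            bad = [i for i, d in zip(ids, dams) if d is None][:5]
            raise ReferenceError_(
                f"maternal term requested but no dam recorded for {bad}"
            )
        dam_levels = sorted(set(dams))
        dam_index = {d: k for k, d in enumerate(dam_levels)}
        terms.append(
            RandomTerm(
                "maternal",
                dam_levels,
                np.array([dam_index[d] for d in dams], dtype=np.int64),
                kinv=None,
                prior=spec.maternal_prior,
            )
        )
        term_map["maternal"] = "V_M"
    if spec.block_random:
        if spec.block_random not in data.columns:
            raise InputError(f"block column {spec.block_random!r} not in data")
        blocks = data[spec.block_random].astype(str).to_numpy()
        blk_levels = sorted(set(blocks))
        blk_index = {b: k for k, b in enumerate(blk_levels)}
        terms.append(
            RandomTerm(
                "tank",
                blk_levels,
                np.array([blk_index[b] for b in blocks], dtype=np.int64),
                kinv=None,
                prior=spec.block_prior,
            )
        )
        term_map["tank"] = "V_block"

    res = run_gibbs(y, X, terms, chain, seed, residual_prior=spec.residual_prior,
                    x_names=x_names)
    return _wrap_result(res, term_map, y, ids, {"response": spec.response})


# --------------------------------------------------------------------- #
@dataclass
class QuantitySummary:
    mode: float
    hpd_low: float
    hpd_high: float


@dataclass
class VarianceSummary:
    """Posterior mode and 95% HPD for V_A, V_M, V_P, h2 and m2."""

    quantities: dict[str, QuantitySummary]

    def __getitem__(self, key: str) -> QuantitySummary:
        return self.quantities[key]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                name: {"mode": q.mode, "hpd_low": q.hpd_low, "hpd_high": q.hpd_high}
                for name, q in self.quantities.items()
            }
        ).T


def summarize_variances(samples: McmcSamples, prob: float = 0.95) -> VarianceSummary:
    """Draw-wise h2/m2 with KDE modes and shortest 95% HPD intervals."""
    if samples.n_draws < 100:
        raise PrecisionError(
            f"need at least 100 retained draws, got {samples.n_draws}"
        )
    series = {
        "V_A": samples.va_draws,
        "V_M": samples.vm_draws,
        "V_P": samples.vp_draws,
        "h2": samples.h2_draws,
        "m2": samples.m2_draws,
    }
    out = {}
    for name, draws in series.items():
        lo, hi = hpd_interval(draws, prob)
        out[name] = QuantitySummary(mode=kde_mode(draws), hpd_low=lo, hpd_high=hi)
    return VarianceSummary(out)


# --------------------------------------------------------------------- #
@dataclass
class BivariateSamples:
    """Retained draws from the two-trait animal model.

    ``g_draws``/``r_draws`` are (n_ret, 2, 2) additive-genetic and residual
    covariance matrices; ``rg_draws`` the derived genetic correlation
    sigma_a12 / sqrt(sigma2_a1 * sigma2_a2).
    """

    g_draws: np.ndarray
    r_draws: np.ndarray
    rg_draws: np.ndarray
    traits: tuple[str, str]
    meta: dict

    @property
    def rg_mean(self) -> float:
        return float(np.mean(self.rg_draws))

    def rg_hpd(self, prob: float = 0.95) -> tuple[float, float]:
        return hpd_interval(self.rg_draws, prob)


def fit_bivariate(
    data: pd.DataFrame,
    traits: tuple[str, str],
    spec: ModelSpec,
    ped: Pedigree,
    chain: ChainConfig | None = None,
    seed: int = 0,
) -> BivariateSamples:
    """Two-trait animal model with unstructured 2x2 G and R.

    Sampling alternates exact joint location draws for each trait given the
    other (conditional-normal offsets on both the genetic and residual
    side) with conjugate inverse-Wishart updates of G and R.  Only
    individuals with both traits observed are used.
    """
    chain = chain or ChainConfig()
    if len(traits) != 2 or traits[0] == traits[1]:
        raise InputError("exactly two distinct traits are required")
    for t in traits:
        if t not in data.columns:
            raise InputError(f"trait column {t!r} not in data")
    sub = data.dropna(subset=list(traits)).copy()
    if len(sub) < 10:
        raise InputError(
            f"only {len(sub)} individuals carry both traits; observation sets "
            "are (nearly) disjoint"
        )
    ids = sub["id"].astype(str).to_numpy()
    missing = [i for i in ids if i not in ped]
    if missing:
        raise ReferenceError_(f"individuals not in pedigree: {missing[:5]}")

    y = np.column_stack([sub[t].to_numpy(dtype=float) for t in traits])
    if np.any(np.ptp(y, axis=0) < 1e-12):
        raise DegenerateDataError("a trait is constant on the complete cases")
    X, x_names = build_design(sub, spec.fixed, spec.categorical)
    kinv = relationship_inverse(ped)
    obs_level = np.array([ped.index[i] for i in ids], dtype=np.int64)
    term = RandomTerm("additive", list(ped.ids), obs_level, kinv=kinv)

    from .mcmc import MixedModelSystem  # local import to keep module load light

    system = MixedModelSystem(y[:, 0], X, [term], x_names=x_names)
    WT = system.W.T.tocsr()
    n = len(sub)
    q = len(ped.ids)
    cols = system._term_cols["additive"]

    rng = np.random.default_rng(seed)
    vy = np.var(y, axis=0)
    G = np.diag(vy / 2.0)
    R = np.diag(vy / 2.0)
    # weakly-informative inverse-Wishart hyperparameters; df = dim + 1 makes
    # the implied marginal prior on each correlation uniform on (-1, 1)
    df_g, psi_g = 3.0, np.diag(1e-3 * vy)
    df_r, psi_r = 3.0, np.diag(1e-3 * vy)

    theta = [np.zeros(system.m), np.zeros(system.m)]
    burn, thin = chain.resolve()
    retained = np.arange(burn, chain.iterations, thin)
    keep = np.zeros(chain.iterations, dtype=bool)
    keep[retained] = True
    g_out = np.empty((retained.size, 2, 2))
    r_out = np.empty((retained.size, 2, 2))
    slot = 0

    for it in range(chain.iterations):
        for i in (0, 1):
            j = 1 - i
            e_j = y[:, j] - system.fitted(theta[j])
            a_j = system.term_values(theta[j], term)
            gam_r = R[i, j] / R[j, j]
            r_cond = R[i, i] - R[i, j] ** 2 / R[j, j]
            gam_g = G[i, j] / G[j, j]
            g_cond = G[i, i] - G[i, j] ** 2 / G[j, j]
            r_cond = max(r_cond, 1e-12 * vy[i])
            g_cond = max(g_cond, 1e-12 * vy[i])
            y_adj = y[:, i] - gam_r * e_j - gam_g * a_j[term.obs_level]
            rhs = WT @ y_adj
            th = system.draw_location(np.array([r_cond / g_cond]), r_cond, rng, rhs=rhs)
            th[cols] = th[cols] + gam_g * a_j
            theta[i] = th
        a1 = system.term_values(theta[0], term)
        a2 = system.term_values(theta[1], term)
        ka1, ka2 = kinv @ a1, kinv @ a2
        s_g = np.array([[a1 @ ka1, a1 @ ka2], [a1 @ ka2, a2 @ ka2]])
        G = invwishart.rvs(df=df_g + q, scale=psi_g + s_g, random_state=rng)
        e1 = y[:, 0] - system.fitted(theta[0])
        e2 = y[:, 1] - system.fitted(theta[1])
        s_r = np.array([[e1 @ e1, e1 @ e2], [e1 @ e2, e2 @ e2]])
        R = invwishart.rvs(df=df_r + n, scale=psi_r + s_r, random_state=rng)
        if keep[it]:
            g_out[slot] = G
            r_out[slot] = R
            slot += 1

    rg = g_out[:, 0, 1] / np.sqrt(g_out[:, 0, 0] * g_out[:, 1, 1])
    meta = {
        "n_obs": n,
        "iterations": chain.iterations,
        "burn_in": burn,
        "thin": thin,
        "seed": seed,
        "traits": traits,
    }
    return BivariateSamples(g_draws=g_out, r_draws=r_out, rg_draws=rg,
                            traits=tuple(traits), meta=meta)


# --------------------------------------------------------------------- #
def dic(samples: McmcSamples) -> float:
    """Deviance information criterion: Dbar + pD = 2 Dbar - Dhat."""
    return samples.dic_value


def dic_compare(full: McmcSamples, reduced: McmcSamples) -> tuple[float, float, float]:
    """DIC of the full and reduced model plus their difference (full - reduced).

    Lower DIC is preferred; the two fits must come from the same data.
    """
    if full.meta["data_checksum"] != reduced.meta["data_checksum"]:
        raise ComparabilityError("models were fit on different data subsets")
    t_full, t_red = set(full.meta["terms"]), set(reduced.meta["terms"])
    if not t_red <= t_full:
        raise ComparabilityError(
            f"reduced model terms {sorted(t_red)} are not nested in {sorted(t_full)}"
        )
    d_full, d_red = dic(full), dic(reduced)
    return d_full, d_red, d_full - d_red
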