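"""Phenotype-level comparisons: nested LMEs, maturation GLMs, sex ratio.

These are the non-pedigree analyses of a common-garden growth experiment:

* body length at each age compared between populations / sexes with linear
  mixed models (random intercepts for family and for block (replicate tank)
  nested in family), reduced stepwise by likelihood-ratio tests;
* the probability of having matured by a given age modelled from grouped
  family-level counts with binomial-logit GLMs, terms judged by deviance
  differences against chi-square;
* variance-component proportions (family %, block %, residual %);
* a Pearson chi-square test of the 1:1 sex ratio among matured fish.

LMEs are fitted by full maximum likelihood (not REML) so that LRTs on fixed
effects are valid; the two variance ratios are profiled out and optimised
directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as sla
from scipy.optimize import minimize
from scipy.stats import chi2

from .animal_model import build_design
from .errors import ComparabilityError, DegenerateDataError, InputError

__all__ = [
    "LmeFit",
    "GlmFit",
    "fit_lme",
    "lrt_compare",
    "fit_maturation_glm",
    "glm_drop_terms",
    "variance_proportions",
    "sex_ratio_chisq",
]


# --------------------------------------------------------------------- #
@dataclass
class LmeFit:
    """ML fit of y = X beta + family + block(family) + residual."""

    beta: pd.Series
    var_family: float
    var_block: float
    var_resid: float
    loglik: float
    n: int
    fixed: tuple[str, ...]
    response: str
    include_family: bool = True
    include_block: bool = True
    converged: bool = True

    @property
    def n_params(self) -> int:
        return len(self.beta) + 1 + int(self.include_family) + int(self.include_block)


def _family_blocks(data: pd.DataFrame, family_col: str, block_col: str | None):
    """Per-family observation indices and within-family block codes."""
    fam_codes, _ = pd.factorize(data[family_col])
    out = []
    for f in range(fam_codes.max() + 1):
        idx = np.where(fam_codes == f)[0]
        if block_col is None:
            blk = np.zeros(len(idx), dtype=np.int64)
        else:
            blk, _ = pd.factorize(data[block_col].iloc[idx])
        out.append((idx, blk))
    return out


def _neg2ll_profiled(gammas, y, X, blocks, include_family, include_block):
    """-2 log L with beta and sigma2_e profiled out (GLS + ML plug-in)."""
    g_fam = gammas[0] if include_family else 0.0
    g_blk = gammas[-1] if include_block else 0.0
    p = X.shape[1]
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    logdet = 0.0
    for idx, blk in blocks:
        ni = len(idx)
        V = np.eye(ni)
        if g_fam > 0:
            V += g_fam
        if g_blk > 0:
            same = blk[:, None] == blk[None, :]
            V += g_blk * same
        try:
            c, low = sla.cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            return np.inf
        logdet += 2.0 * np.log(np.diag(c)).sum()
        Xi, yi = X[idx], y[idx]
        Vx = sla.cho_solve((c, low), Xi)
        Vy = sla.cho_solve((c, low), yi)
        xtvx += Xi.T @ Vx
        xtvy += Xi.T @ Vy
        ytvy += yi @ Vy
    try:
        beta = np.linalg.solve(xtvx, xtvy)
    except np.linalg.LinAlgError:
        return np.inf
    rss = ytvy - beta @ xtvy
    n = len(y)
    if rss <= 0:
        return np.inf
    return n * np.log(2 * np.pi * rss / n) + logdet + n


def fit_lme(
    data: pd.DataFrame,
    response: str,
    fixed: tuple[str, ...] = (),
    family_col: str = "family",
    block_col: str = "block",
    categorical: tuple[str, ...] = ("population", "sex"),
    include_family: bool = True,
    include_block: bool = True,
) -> LmeFit:
    """ML fit of the nested random-intercept mixed model.

    Random structure: family intercepts and block-within-family intercepts
    (either can be switched off for reduced models).  Deterministic given
    the data: the profiled -2 log-likelihood over the two variance ratios
    is minimised from several starts.
    """
    if response not in data.columns:
        raise InputError(f"response column {response!r} not in data")
    data = data.reset_index(drop=True)
    y = data[response].to_numpy(dtype=float)
    if np.ptp(y) < 1e-12:
        raise DegenerateDataError(f"response {response!r} is constant")
    X, names = build_design(data, fixed, categorical)
    if data[family_col].nunique() < 2 and include_family:
        raise InputError("need at least 2 families for a family variance")
    blocks = _family_blocks(data, family_col, block_col if include_block else None)

    n_active = int(include_family) + int(include_block)
    if n_active == 0:
        obj = lambda g: _neg2ll_profiled((), y, X, blocks, False, False)  # noqa: E731
        best = (np.inf, np.zeros(0))
        val = obj(np.zeros(0))
        best = (val, np.zeros(0))
        converged = np.isfinite(val)
    else:
        starts = [np.full(n_active, s) for s in (0.05, 0.5, 2.0)]
        best = (np.inf, np.zeros(n_active))
        converged = False
        for s0 in starts:
            res = minimize(
                _neg2ll_profiled,
                s0,
                args=(y, X, blocks, include_family, include_block),
                method="L-BFGS-B",
                bounds=[(0.0, 1e5)] * n_active,
                options={"ftol": 1e-13, "gtol": 1e-9},
            )
            if res.fun < best[0]:
                best = (res.fun, res.x)
                converged = converged or res.success
        if not np.isfinite(best[0]):
            raise RuntimeError("LME optimisation failed from every start")

    g_fam = best[1][0] if include_family else 0.0
    g_blk = best[1][-1] if include_block else 0.0

    # recover beta and sigma2_e at the optimum
    p = X.shape[1]
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    for idx, blk in blocks:
        ni = len(idx)
        V = np.eye(ni) + g_fam
        if include_block and g_blk > 0:
            V += g_blk * (blk[:, None] == blk[None, :])
        c, low = sla.cho_factor(V, lower=True)
        Xi, yi = X[idx], y[idx]
        xtvx += Xi.T @ sla.cho_solve((c, low), Xi)
        xtvy += Xi.T @ sla.cho_solve((c, low), yi)
        ytvy += yi @ sla.cho_solve((c, low), yi)
    beta = np.linalg.solve(xtvx, xtvy)
    rss = ytvy - beta @ xtvy
    sigma2 = rss / len(y)
    loglik = -0.5 * best[0]

    return LmeFit(
        beta=pd.Series(beta, index=names),
        var_family=float(g_fam * sigma2),
        var_block=float(g_blk * sigma2),
        var_resid=float(sigma2),
        loglik=float(loglik),
        n=len(y),
        fixed=tuple(fixed),
        response=response,
        include_family=include_family,
        include_block=include_block,
        converged=bool(converged),
    )


def lrt_compare(full: LmeFit, reduced: LmeFit) -> tuple[float, float]:
    """Likelihood-ratio test of nested ML fits: (LRT statistic, p-value).

    LRT = 2 (l_full - l_reduced), referred to chi-square with df equal to
    the parameter-count difference (no boundary mixture correction).
    """
    if full.response != reduced.response or full.n != reduced.n:
        raise ComparabilityError("fits are not on the same data")
    nested_fixed = set(reduced.fixed) <= set(full.fixed)
    nested_random = (reduced.include_family <= full.include_family) and (
        reduced.include_block <= full.include_block
    )
    if not (nested_fixed and nested_random) or reduced.n_params >= full.n_params:
        raise ComparabilityError("reduced model is not nested in the full model")
    lrt = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    df = full.n_params - reduced.n_params
    return float(lrt), float(chi2.sf(lrt, df))


def variance_proportions(fit: LmeFit) -> tuple[float, float, float]:
    """(family %, block %, residual %) of the summed variance components."""
    comps = np.array([fit.var_family, fit.var_block, fit.var_resid])
    total = comps.sum()
    out = 100.0 * comps / total
    return float(out[0]), float(out[1]), float(out[2])


# --------------------------------------------------------------------- #
@dataclass
class GlmFit:
    """Grouped binomial-logit fit (counts of matured/immature per family)."""

    params: pd.Series
    deviance: float
    null_deviance: float
    df_resid: int
    n_groups: int
    converged: bool
    separation: bool

    @property
    def df_null(self) -> int:
        return self.n_groups - 1


def _binom_deviance(y, m, mu) -> float:
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = np.where(m - y > 0, (m - y) * np.log((m - y) / (m - mu)), 0.0)
    return float(2.0 * (t1 + t2).sum())


def _irls(X: np.ndarray, succ: np.ndarray, m: np.ndarray,
          tol: float = 1e-10, max_iter: int = 100):
    prop = (succ + 0.5) / (m + 1.0)
    eta = np.log(prop / (1 - prop))
    beta = np.zeros(X.shape[1])
    dev = np.inf
    converged = False
    for _ in range(max_iter):
        mu = 1.0 / (1.0 + np.exp(-eta))
        mu = np.clip(mu, 1e-10, 1 - 1e-10)
        w = m * mu * (1 - mu)
        z = eta + (succ / m - mu) / (mu * (1 - mu))
        WX = X * w[:, None]
        try:
            beta = np.linalg.solve(X.T @ WX, WX.T @ z)
        except np.linalg.LinAlgError as err:
            raise InputError(f"singular GLM design: {err}") from err
        eta = X @ beta
        new_dev = _binom_deviance(succ, m, m / (1.0 + np.exp(-eta)))
        if abs(dev - new_dev) < tol * (abs(new_dev) + 1.0):
            dev = new_dev
            converged = True
            break
        dev = new_dev
    separation = bool(np.any(np.abs(beta) > 15.0))
    return beta, dev, converged, separation


def fit_maturation_glm(
    table: pd.DataFrame,
    successes: str = "matured",
    failures: str = "immature",
    covariates: tuple[str, ...] = (),
    categorical: tuple[str, ...] = ("population",),
) -> GlmFit:
    """Binomial-logit IRLS fit on grouped (family-level) counts.

    ``table`` has one row per family with matured/immature counts and the
    family-level covariates (mean lengths, densities, population).  Deviance
    is reported against the saturated model; complete separation is flagged
    (coefficients diverging on the logit scale).
    """
    for c in (successes, failures):
        if c not in table.columns:
            raise InputError(f"count column {c!r} not in table")
    table = table.reset_index(drop=True)
    succ = table[successes].to_numpy(dtype=float)
    fail = table[failures].to_numpy(dtype=float)
    if np.any(succ < 0) or np.any(fail < 0):
        raise InputError("counts must be non-negative")
    m = succ + fail
    keep = m > 0
    table, succ, m = table[keep].reset_index(drop=True), succ[keep], m[keep]
    X, names = build_design(table, covariates, categorical)
    beta, dev, converged, separation = _irls(X, succ, m)
    null_beta, null_dev, _, _ = _irls(np.ones((len(table), 1)), succ, m)
    if separation:
        import warnings

        warnings.warn(
            "possible complete separation: a coefficient diverged on the logit scale",
            UserWarning,
            stacklevel=2,
        )
    return GlmFit(
        params=pd.Series(beta, index=names),
        deviance=dev,
        null_deviance=null_dev,
        df_resid=len(table) - X.shape[1],
        n_groups=len(table),
        converged=converged,
        separation=separation,
    )


def glm_drop_terms(
    table: pd.DataFrame,
    covariates: tuple[str, ...],
    successes: str = "matured",
    failures: str = "immature",
    categorical: tuple[str, ...] = ("population",),
) -> pd.DataFrame:
    """Single-term deletions: deviance difference D vs chi-square.

    Returns a tidy frame (term, deviance_diff, df, p) for dropping each
    covariate in turn from the full model.
    """
    full = fit_maturation_glm(table, successes, failures, covariates, categorical)
    rows = []
    for term in covariates:
        rest = tuple(c for c in covariates if c != term)
        red = fit_maturation_glm(table, successes, failures, rest, categorical)
        df = len(full.params) - len(red.params)
        d = max(0.0, red.deviance - full.deviance)
        rows.append(
            {"term": term, "deviance_diff": d, "df": df, "p": float(chi2.sf(d, df))}
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------- #
def sex_ratio_chisq(n_males: int, n_females: int) -> tuple[float, float]:
    """Pearson chi-square against a 1:1 sex ratio (df = 1, no continuity
    correction)."""
    if n_males < 0 or n_females < 0 or int(n_males) != n_males or int(n_females) != n_females:
        raise InputError("counts must be non-negative integers")
    total = n_males + n_females
    if total == 0:
        raise DegenerateDataError("both counts are zero; statistic undefined")
    expected = total / 2.0
    stat = (n_males - expected) ** 2 / expected + (n_females - expected) ** 2 / expected
    return float(stat), float(chi2.sf(stat, 1))
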