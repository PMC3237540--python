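import numpy as np
import pandas as pd
import pytest

from stickleqg.errors import ComparabilityError, DegenerateDataError, InputError
from stickleqg.phenotype_stats import (
    fit_lme,
    fit_maturation_glm,
    glm_drop_terms,
    lrt_compare,
    sex_ratio_chisq,
    variance_proportions,
)


def nested_data(n_fam=20, n_blk=2, n_obs=8, sd_fam=2.0, sd_blk=1.0, sd_res=1.0,
                beta_pop=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for f in range(n_fam):
        fe = rng.normal(0, sd_fam)
        pop = "A" if f < n_fam // 2 else "B"
        for b in range(n_blk):
            be = rng.normal(0, sd_blk)
            for _ in range(n_obs):
                rows.append(
                    {
                        "family": f"f{f}",
                        "block": f"f{f}_b{b}",
                        "population": pop,
                        "y": 10 + (beta_pop if pop == "B" else 0.0)
                        + fe + be + rng.normal(0, sd_res),
                    }
                )
    return pd.DataFrame(rows)


class TestLme:
    def test_zero_variance_components_hit_boundary(self):
        d = nested_data(sd_fam=0.0, sd_blk=0.0, sd_res=1.0, seed=1)
        fit = fit_lme(d, "y")
        assert fit.var_family < 0.05 * fit.var_resid
        assert fit.var_block < 0.05 * fit.var_resid

    def test_variance_recovery(self):
        d = nested_data(n_fam=30, n_obs=15, sd_fam=2.0, sd_blk=1.0, sd_res=1.0, seed=3)
        fit = fit_lme(d, "y")
        assert fit.var_family == pytest.approx(4.0, rel=0.5)
        assert fit.var_block == pytest.approx(1.0, rel=0.5)
        assert fit.var_resid == pytest.approx(1.0, rel=0.5)

    def test_matches_ols_when_no_random_structure(self):
        """With both variances switched off the ML fit is plain OLS."""
        import statsmodels.api as sm

        d = nested_data(sd_fam=0.0, sd_blk=0.0, seed=5)
        fit = fit_lme(d, "y", fixed=("population",),
                      include_family=False, include_block=False)
        X = pd.get_dummies(d["population"], drop_first=True).astype(float)
        ols = sm.OLS(d["y"], sm.add_constant(X)).fit()
        assert fit.loglik == pytest.approx(ols.llf, abs=1e-4)

    def test_matches_statsmodels_mixedlm(self):
        """ML log-likelihood agrees with the statsmodels nested VC fit."""
        import statsmodels.formula.api as smf

        d = nested_data(n_fam=12, n_obs=6, seed=7)
        fit = fit_lme(d, "y", fixed=("population",))
        sm_fit = smf.mixedlm(
            "y ~ population", d, groups="family", re_formula="1",
            vc_formula={"block": "0 + C(block)"},
        ).fit(reml=False)
        assert fit.loglik == pytest.approx(sm_fit.llf, abs=1e-3)

    def test_variance_invariant_to_mean_shift(self):
        d = nested_data(seed=9)
        f1 = fit_lme(d, "y")
        d2 = d.assign(y=d["y"] + 100.0)
        f2 = fit_lme(d2, "y")
        assert f1.var_family == pytest.approx(f2.var_family, rel=1e-4, abs=1e-8)
        assert f1.var_resid == pytest.approx(f2.var_resid, rel=1e-4)

    def test_constant_response_rejected(self):
        d = nested_data(seed=0).assign(y=1.0)
        with pytest.raises(DegenerateDataError):
            fit_lme(d, "y")


class TestLrt:
    def test_identical_models(self):
        d = nested_data(seed=2)
        fit = fit_lme(d, "y")
        fit2 = fit_lme(d, "y")
        # compare a model against itself via a dummy reduced copy
        from dataclasses import replace

        reduced = replace(fit2, fixed=(), beta=fit2.beta[:0])
        lrt, p = lrt_compare(fit, reduced) if reduced.n_params < fit.n_params else (0.0, 1.0)
        assert lrt == pytest.approx(0.0, abs=1e-6) or p <= 1.0

    def test_strong_population_effect_detected(self):
        d = nested_data(beta_pop=3.0, sd_fam=0.5, sd_blk=0.3, seed=4)
        full = fit_lme(d, "y", fixed=("population",))
        red = fit_lme(d, "y", fixed=())
        lrt, p = lrt_compare(full, red)
        assert lrt > 10
        assert p < 0.001

    def test_non_nested_rejected(self):
        d = nested_data(seed=2)
        full = fit_lme(d, "y", fixed=("population",))
        other = fit_lme(d.assign(y=d["y"] * 2), "y", fixed=("population",))
        other2 = fit_lme(d, "y", fixed=("population",))
        with pytest.raises(ComparabilityError):
            lrt_compare(full, other2)  # equal models: not strictly nested

    def test_different_data_rejected(self):
        d = nested_data(seed=2)
        full = fit_lme(d, "y", fixed=("population",))
        red = fit_lme(d.iloc[: len(d) // 2], "y", fixed=())
        with pytest.raises(ComparabilityError):
            lrt_compare(full, red)


class TestMaturationGlm:
    def test_two_group_closed_form_log_odds(self):
        """Fitted log-odds difference equals the 2x2 closed form."""
        tab = pd.DataFrame(
            {"matured": [30, 12], "immature": [10, 28], "x": [1.0, 0.0]}
        )
        fit = fit_maturation_glm(tab, covariates=("x",), categorical=())
        p1, p2 = 12 / 40, 30 / 40
        expect = np.log((p2 / (1 - p2)) / (p1 / (1 - p1)))
        assert fit.params["x"] == pytest.approx(expect, abs=1e-6)

    def test_matches_statsmodels_glm(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(0)
        tab = pd.DataFrame(
            {
                "matured": rng.integers(2, 20, 30),
                "immature": rng.integers(2, 20, 30),
                "length": rng.normal(20, 3, 30),
            }
        )
        fit = fit_maturation_glm(tab, covariates=("length",), categorical=())
        X = sm.add_constant(tab["length"])
        sm_fit = sm.GLM(
            tab[["matured", "immature"]].to_numpy(), X, family=sm.families.Binomial()
        ).fit()
        assert np.allclose(fit.params.to_numpy(), sm_fit.params.to_numpy(), atol=1e-6)
        assert fit.deviance == pytest.approx(sm_fit.deviance, abs=1e-6)

    def test_orthogonal_covariate_near_zero(self):
        tab = pd.DataFrame(
            {"matured": [10] * 6, "immature": [10] * 6, "x": [1, 2, 3, 4, 5, 6.0]}
        )
        fit = fit_maturation_glm(tab, covariates=("x",), categorical=())
        assert abs(fit.params["x"]) < 1e-8
        drops = glm_drop_terms(tab, ("x",), categorical=())
        assert drops.loc[0, "deviance_diff"] == pytest.approx(0.0, abs=1e-8)

    def test_score_equations_satisfied_at_convergence(self):
        rng = np.random.default_rng(3)
        tab = pd.DataFrame(
            {
                "matured": rng.integers(0, 15, 25),
                "immature": rng.integers(1, 15, 25),
                "x": rng.normal(size=25),
            }
        )
        fit = fit_maturation_glm(tab, covariates=("x",), categorical=())
        m = (tab["matured"] + tab["immature"]).to_numpy(dtype=float)
        X = np.column_stack([np.ones(len(tab)), tab["x"]])
        mu = m / (1 + np.exp(-(X @ fit.params.to_numpy())))
        score = X.T @ (tab["matured"].to_numpy() - mu)
        assert np.abs(score).max() < 1e-8

    def test_separation_flagged(self):
        tab = pd.DataFrame(
            {"matured": [20, 0], "immature": [0, 20], "x": [1.0, 0.0]}
        )
        with pytest.warns(UserWarning, match="separation"):
            fit = fit_maturation_glm(tab, covariates=("x",), categorical=())
        assert fit.separation

    def test_negative_counts_rejected(self):
        tab = pd.DataFrame({"matured": [-1], "immature": [3]})
        with pytest.raises(InputError):
            fit_maturation_glm(tab)


class TestVarianceProportions:
    def test_simple_arithmetic(self):
        from dataclasses import dataclass

        d = nested_data(seed=0)
        fit = fit_lme(d, "y")
        fit.var_family, fit.var_block, fit.var_resid = 2.0, 1.0, 7.0
        assert variance_proportions(fit) == pytest.approx((20.0, 10.0, 70.0))

    def test_zero_family_component(self):
        d = nested_data(seed=0)
        fit = fit_lme(d, "y")
        fit.var_family = 0.0
        fam, blk, res = variance_proportions(fit)
        assert fam == 0.0
        assert fam + blk + res == pytest.approx(100.0)


class TestSexRatio:
    def test_balanced_counts(self):
        assert sex_ratio_chisq(100, 100) == (0.0, 1.0)

    def test_study_counts_pearson_value(self):
        """234 males vs 204 females: Pearson chi-square is 450/219."""
        stat, p = sex_ratio_chisq(234, 204)
        assert stat == pytest.approx(450 / 219, abs=1e-12)
        assert 0 < p < 1

    def test_one_sided_counts(self):
        stat, _ = sex_ratio_chisq(0, 20)
        assert stat == pytest.approx(20.0)

    def test_empty_rejected(self):
        with pytest.raises(DegenerateDataError):
            sex_ratio_chisq(0, 0)
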