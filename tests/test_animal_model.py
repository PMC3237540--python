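import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from stickleqg.animal_model import (
    McmcSamples,
    ModelSpec,
    build_design,
    dic_compare,
    fit_animal_model,
    fit_bivariate,
    summarize_variances,
)
from stickleqg.errors import (
    ComparabilityError,
    DegenerateDataError,
    InputError,
    PrecisionError,
    ReferenceError_,
)
from stickleqg.mcmc import ChainConfig, hpd_interval, kde_mode
from stickleqg.pedigree import Pedigree
from stickleqg.simulate import simulate_halfsib_trait

SHORT = ChainConfig(iterations=3000, burn_in=1000, thin=2)


def make_samples(va, vm, ve, n=500):
    """McmcSamples with prescribed (possibly constant) variance draws."""
    draws = {
        "V_A": np.full(n, va, dtype=float),
        "V_M": np.full(n, vm, dtype=float),
        "V_E": np.full(n, ve, dtype=float),
    }
    return McmcSamples(
        draws=draws,
        fixed=pd.DataFrame({"(Intercept)": np.zeros(n)}),
        deviance=np.zeros(n),
        dic_value=0.0,
        dbar=0.0,
        dhat=0.0,
        meta={"data_checksum": "x", "terms": ["V_A", "V_M"], "n_obs": n},
    )


class TestFitAnimalModel:
    def test_null_variances_shrink_to_zero(self):
        """With sigma2_a = sigma2_m = 0 the h2 posterior piles up near 0."""
        ped, data = simulate_halfsib_trait(v_a=0.0, v_m=0.0, v_e=1.0, seed=3)
        samples = fit_animal_model(
            data, ModelSpec(response="y", fixed=()), ped, chain=SHORT, seed=4
        )
        summ = summarize_variances(samples)
        assert summ["h2"].hpd_low < 0.05
        assert summ["h2"].mode < 0.15

    def test_founders_only_tracks_sample_variance(self, rng):
        """With A = I and no structure, V_P matches the moment estimate."""
        ids = [f"f{i}" for i in range(400)]
        ped = Pedigree([(i, None, None, "p") for i in ids])
        y = rng.normal(10.0, 3.0, 400)
        data = pd.DataFrame({"id": ids, "y": y})
        samples = fit_animal_model(
            data, ModelSpec(response="y", fixed=(), maternal=False), ped,
            chain=SHORT, seed=1,
        )
        assert samples.vp_draws.mean() == pytest.approx(np.var(y, ddof=1), rel=0.10)

    def test_vp_identity_holds_drawwise(self):
        ped, data = simulate_halfsib_trait(n_sires=8, n_offspring=6, seed=0)
        s = fit_animal_model(data, ModelSpec(response="y", fixed=()), ped,
                             chain=ChainConfig(600, 200, 2), seed=0)
        assert np.allclose(s.h2_draws + s.m2_draws + s.ve_draws / s.vp_draws, 1.0)

    def test_seed_determinism(self):
        ped, data = simulate_halfsib_trait(n_sires=6, n_offspring=5, seed=2)
        kwargs = dict(chain=ChainConfig(500, 100, 2), seed=42)
        a = fit_animal_model(data, ModelSpec(response="y", fixed=()), ped, **kwargs)
        b = fit_animal_model(data, ModelSpec(response="y", fixed=()), ped, **kwargs)
        for key in a.draws:
            assert np.array_equal(a.draws[key], b.draws[key])
        assert np.array_equal(a.fixed.values, b.fixed.values)

    def test_constant_response_rejected(self):
        ped, data = simulate_halfsib_trait(n_sires=4, n_offspring=4, seed=0)
        data["y"] = 1.0
        with pytest.raises(DegenerateDataError):
            fit_animal_model(data, ModelSpec(response="y", fixed=()), ped, chain=SHORT)

    def test_unknown_individual_rejected(self):
        ped, data = simulate_halfsib_trait(n_sires=4, n_offspring=4, seed=0)
        data.loc[0, "id"] = "ghost"
        with pytest.raises(ReferenceError_):
            fit_animal_model(data, ModelSpec(response="y", fixed=()), ped, chain=SHORT)

    def test_maternal_without_dams_rejected(self):
        ids = [f"f{i}" for i in range(20)]
        ped = Pedigree([(i, None, None, "p") for i in ids])
        data = pd.DataFrame({"id": ids, "y": np.random.default_rng(0).normal(size=20)})
        with pytest.raises(ReferenceError_):
            fit_animal_model(data, ModelSpec(response="y", fixed=(), maternal=True),
                             ped, chain=SHORT)


class TestSummaries:
    def test_constant_draw_arithmetic(self):
        """sigma2 = (2, 1, 7) gives h2 = 0.20, m2 = 0.10, zero-width HPDs."""
        summ = summarize_variances(make_samples(2.0, 1.0, 7.0))
        assert summ["h2"].mode == pytest.approx(0.20)
        assert summ["m2"].mode == pytest.approx(0.10)
        assert summ["h2"].hpd_low == summ["h2"].hpd_high == pytest.approx(0.20)
        assert summ["V_P"].mode == pytest.approx(10.0)

    def test_too_few_draws_rejected(self):
        with pytest.raises(PrecisionError):
            summarize_variances(make_samples(2, 1, 7, n=50))

    def test_gaussian_hpd_matches_quantiles(self, rng):
        """95% HPD of a standard normal sample sits near +-1.96."""
        draws = rng.standard_normal(100_000)
        lo, hi = hpd_interval(draws, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.1)
        assert hi == pytest.approx(1.96, abs=0.1)

    @given(seed=st.integers(0, 100))
    def test_mode_inside_hpd(self, seed):
        r = np.random.default_rng(seed)
        draws = r.gamma(2.0, 1.5, size=400)
        lo, hi = hpd_interval(draws)
        mode = kde_mode(draws)
        assert lo - 1e-9 <= mode <= hi + 1e-9


class TestDesignMatrix:
    def test_categorical_and_numeric_columns(self):
        data = pd.DataFrame(
            {"sex": ["male", "female", "immature", "male"], "density": [1.0, 2, 3, 4]}
        )
        X, names = build_design(data, ("density", "sex"), categorical=("sex",))
        assert names[0] == "(Intercept)"
        assert "density" in names
        assert sum(n.startswith("sex_") for n in names) == 2
        assert X.shape == (4, 4)

    def test_aliased_column_dropped(self):
        data = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [2.0, 4, 6, 8]})
        X, names = build_design(data, ("a", "b"))
        assert names == ["(Intercept)", "a"]
        assert np.linalg.matrix_rank(X) == X.shape[1]

    def test_missing_column_rejected(self):
        with pytest.raises(InputError):
            build_design(pd.DataFrame({"a": [1.0]}), ("nope",))


class TestBivariate:
    def test_duplicated_trait_recovers_unit_correlation(self):
        ped, data = simulate_halfsib_trait(n_sires=10, n_offspring=8, seed=1)
        data["y2"] = data["y"]
        bs = fit_bivariate(
            data, ("y", "y2"), ModelSpec(response="y", fixed=(), maternal=False),
            ped, chain=ChainConfig(1500, 500, 2), seed=2,
        )
        assert bs.rg_mean > 0.9
        assert np.all(np.abs(bs.rg_draws) <= 1.0)

    def test_g_draws_positive_definite(self):
        ped, data = simulate_halfsib_trait(n_sires=8, n_offspring=6, seed=4)
        data["y2"] = np.random.default_rng(0).normal(size=len(data))
        bs = fit_bivariate(
            data, ("y", "y2"), ModelSpec(response="y", fixed=(), maternal=False),
            ped, chain=ChainConfig(800, 300, 2), seed=1,
        )
        dets = np.linalg.det(bs.g_draws)
        assert np.all(dets > 0)
        assert np.all(bs.g_draws[:, 0, 0] > 0)

    def test_identical_traits_rejected(self):
        ped, data = simulate_halfsib_trait(n_sires=4, n_offspring=4, seed=0)
        with pytest.raises(InputError):
            fit_bivariate(data, ("y", "y"), ModelSpec(response="y"), ped)

    def test_disjoint_observations_rejected(self):
        ped, data = simulate_halfsib_trait(n_sires=4, n_offspring=4, seed=0)
        data["y2"] = np.nan
        with pytest.raises(InputError):
            fit_bivariate(data, ("y", "y2"), ModelSpec(response="y"), ped)


class TestDic:
    def test_identical_models_zero_delta(self):
        ped, data = simulate_halfsib_trait(n_sires=6, n_offspring=5, seed=5)
        s = fit_animal_model(data, ModelSpec(response="y", fixed=()), ped,
                             chain=ChainConfig(800, 300, 2), seed=7)
        d_full, d_red, delta = dic_compare(s, s)
        assert delta == 0.0
        assert d_full == d_red

    def test_different_data_rejected(self):
        ped, data = simulate_halfsib_trait(n_sires=6, n_offspring=5, seed=5)
        s1 = fit_animal_model(data, ModelSpec(response="y", fixed=()), ped,
                              chain=ChainConfig(500, 200, 2), seed=1)
        data2 = data.copy()
        data2["y"] = data2["y"] + 1.0
        s2 = fit_animal_model(data2, ModelSpec(response="y", fixed=()), ped,
                              chain=ChainConfig(500, 200, 2), seed=1)
        with pytest.raises(ComparabilityError):
            dic_compare(s1, s2)

    def test_non_nested_terms_rejected(self):
        a = make_samples(1, 1, 1)
        b = make_samples(1, 1, 1)
        b.meta["terms"] = ["V_A", "V_X"]
        with pytest.raises(ComparabilityError):
            dic_compare(a, b)
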