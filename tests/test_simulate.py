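import numpy as np
import pandas as pd
import pytest

from stickleqg.errors import InputError
from stickleqg.fst import wc_theta
from stickleqg.simulate import (
    GenotypeParams,
    SimulationConfig,
    TraitParams,
    helsinki_config,
    pyorealampi_config,
    simulate_design,
    simulate_genotypes,
    simulate_halfsib_trait,
    simulate_maturation,
    simulate_phenotypes,
    simulate_study,
)


class TestDesign:
    def test_study_arithmetic(self):
        """36 sires x 2 dams x fixed 20 in duplicate: 72 families, 1440 fish."""
        cfg = SimulationConfig(n_sires=36, dams_per_sire=2,
                               offspring_range=(20, 20), n_tanks_per_family=2)
        ped, design = simulate_design(cfg, seed=0)
        assert design["family"].nunique() == 72
        assert len(design) == 1440
        assert design["block"].nunique() == 144
        assert ped.n_founders == 36 + 72

    def test_every_sire_has_two_mates(self):
        _, design = simulate_design(SimulationConfig(), seed=1)
        mates = design.groupby("sire")["dam"].nunique()
        assert (mates == 2).all()

    def test_offspring_counts_within_range(self):
        cfg = SimulationConfig(offspring_range=(10, 25))
        _, design = simulate_design(cfg, seed=2)
        counts = design.groupby("family").size()
        assert counts.min() >= 10 and counts.max() <= 25

    def test_single_tank_fraction(self):
        cfg = SimulationConfig(single_tank_fraction=1.0)
        _, design = simulate_design(cfg, seed=3)
        tanks_per_family = design.groupby("family")["block"].nunique()
        assert (tanks_per_family == 1).all()

    def test_seed_reproducibility(self):
        cfg = SimulationConfig()
        _, d1 = simulate_design(cfg, seed=7)
        _, d2 = simulate_design(cfg, seed=7)
        pd.testing.assert_frame_equal(d1, d2)


class TestPhenotypes:
    def test_null_structure_variance_matches_residual(self):
        cfg = SimulationConfig(
            n_sires=36, offspring_range=(20, 20),
            length=TraitParams(v_a=0.0, v_m=0.0, v_e=4.0, sex_effect=0.0,
                               density_slope=0.0, tank_sd=0.0),
            mortality_per_interval=0.0, ages=(50,),
        )
        ped, design = simulate_design(cfg, seed=0)
        traits = simulate_phenotypes(ped, design, cfg, seed=1)
        assert traits["length_mm"].var() == pytest.approx(4.0, rel=0.10)

    def test_breeding_value_variance(self):
        """Empirical Var(a) close to V_A = 4 on a 1440-offspring design."""
        from stickleqg.simulate import _breeding_values

        cfg = SimulationConfig(n_sires=36, offspring_range=(20, 20))
        ped, design = simulate_design(cfg, seed=2)
        G = np.array([[4.0]])
        bv = _breeding_values(ped, G, np.random.default_rng(3))[:, 0]
        off = [ped.index[i] for i in design["id"]]
        assert 3.2 <= np.var(bv[off]) <= 4.8

    def test_halfsib_covariance_matches_kinship(self):
        """Paternal half-sib phenotypic covariance tracks V_A / 4."""
        ped, data = simulate_halfsib_trait(
            n_sires=150, dams_per_sire=2, n_offspring=20,
            v_a=4.0, v_m=1.0, v_e=4.0, seed=5,
        )
        d = data.copy()
        d["sire"] = [ped.ids[ped.sire_idx[ped.index[i]]] for i in d["id"]]
        # covariance across dams within sire isolates the sire component V_A/4
        dm = d.groupby(["sire", "dam"])["y"].mean().reset_index()
        pairs = dm.groupby("sire")["y"].apply(lambda s: s.to_numpy()[:2])
        arr = np.vstack(pairs.to_numpy())
        cov = np.cov(arr[:, 0], arr[:, 1])[0, 1]
        assert cov == pytest.approx(1.0, abs=0.3)

    def test_fullsib_covariance_matches_kinship(self):
        """Full-sib phenotypic covariance tracks V_A/2 + V_M."""
        ped, data = simulate_halfsib_trait(
            n_sires=250, dams_per_sire=2, n_offspring=20,
            v_a=4.0, v_m=1.0, v_e=4.0, seed=8,
        )
        d = data.copy()
        g = d.groupby("dam")["y"]
        n = g.size()
        # between-family variance of family means minus within-family noise
        within = np.mean(g.var())
        between = g.mean().var()
        fullsib_cov = between - within / n.mean()
        assert fullsib_cov == pytest.approx(3.0, rel=0.2)

    def test_mortality_thins_later_ages(self):
        cfg = SimulationConfig(mortality_per_interval=0.2)
        ped, design = simulate_design(cfg, seed=0)
        traits = simulate_phenotypes(ped, design, cfg, seed=1)
        by_age = traits.groupby("age_dah").size()
        assert by_age.loc[140] < by_age.loc[20]

    def test_invalid_config_rejected(self):
        with pytest.raises(InputError):
            SimulationConfig(rg=1.5)
        with pytest.raises(InputError):
            SimulationConfig(length=TraitParams(v_a=-1.0))
        with pytest.raises(InputError):
            SimulationConfig(genotypes=GenotypeParams(target_fst=1.0))


class TestMaturation:
    @staticmethod
    def _traits(threshold, seed=0):
        cfg = SimulationConfig(
            n_sires=36, offspring_range=(20, 20), ages=(80,),
            mortality_per_interval=0.0,
            maturation_threshold_by_age={80: threshold},
        )
        ped, design = simulate_design(cfg, seed=seed)
        traits = simulate_phenotypes(ped, design, cfg, seed=seed + 1)
        return simulate_maturation(traits, cfg), traits

    def test_minus_infinity_threshold_all_mature(self):
        out, _ = self._traits(-np.inf)
        assert (out["mature"] == 0).all()
        assert set(out["sex"]) <= {"male", "female"}

    def test_plus_infinity_threshold_none_mature(self):
        """The giant-population regime: nobody matures, sex stays unknown."""
        out, _ = self._traits(np.inf)
        assert (out["mature"] == 1).all()
        assert (out["sex"] == "immature").all()

    def test_median_threshold_half_mature(self):
        out, traits = self._traits(0.0)
        med = float(np.median(traits["liability"]))
        out2, _ = self._traits(med)
        frac = (out2["mature"] == 0).mean()
        assert frac == pytest.approx(0.5, abs=0.05)

    def test_no_thresholds_means_no_maturation(self):
        cfg = pyorealampi_config()
        cfg.n_sires = 6
        ped, design = simulate_design(cfg, seed=0)
        traits = simulate_maturation(simulate_phenotypes(ped, design, cfg, seed=1), cfg)
        assert (traits["mature"] == 1).all()


class TestGenotypes:
    def test_panel_dimensions(self):
        """103 loci x (24 + 24) fish at the study's target divergence."""
        panel = simulate_genotypes(
            GenotypeParams(n_loci=103, alleles_per_locus=5,
                           target_fst=0.458, n_per_population=24),
            seed=0,
        )
        assert panel.n_loci == 103
        assert panel.n_individuals == 48
        assert panel.population_labels == ["Helsinki", "Pyorealampi"]

    def test_zero_divergence_theta_near_zero(self):
        panel = simulate_genotypes(
            GenotypeParams(n_loci=200, alleles_per_locus=4,
                           target_fst=0.0, n_per_population=100),
            seed=1,
        )
        assert abs(wc_theta(panel).theta) < 0.05

    def test_seed_reproducibility(self):
        gp = GenotypeParams(n_loci=10)
        a = simulate_genotypes(gp, seed=9)
        b = simulate_genotypes(gp, seed=9)
        assert np.array_equal(a.genotypes, b.genotypes)


class TestStudy:
    def test_two_population_bundle(self):
        cfg_a, cfg_b = helsinki_config(), pyorealampi_config()
        cfg_a.n_sires = cfg_b.n_sires = 5
        study = simulate_study(cfg_a, cfg_b, seed=0)
        assert set(study["peds"]) == {"Helsinki", "Pyorealampi"}
        assert set(study["traits"]["population"]) == {"Helsinki", "Pyorealampi"}
        # only the coastal population matures within the experiment
        mat = study["traits"].groupby("population")["mature"].min()
        assert mat["Pyorealampi"] == 1
        assert mat["Helsinki"] == 0
        assert study["panel"].n_loci == 103

    def test_study_seed_reproducibility(self):
        cfg_a, cfg_b = helsinki_config(), pyorealampi_config()
        cfg_a.n_sires = cfg_b.n_sires = 4
        t1 = simulate_study(cfg_a, cfg_b, seed=3, with_genotypes=False)["traits"]
        t2 = simulate_study(cfg_a, cfg_b, seed=3, with_genotypes=False)["traits"]
        pd.testing.assert_frame_equal(t1, t2)
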