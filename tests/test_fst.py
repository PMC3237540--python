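import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import wc_theta_oracle
from stickleqg.errors import (
    EstimationError,
    InputError,
    PrecisionError,
    ReferenceError_,
)
from stickleqg.fst import (
    GenotypePanel,
    fst_estimate,
    jackknife_se,
    permutation_test,
    read_genepop,
    wc_theta,
    write_genepop,
)
from stickleqg.simulate import GenotypeParams, simulate_genotypes


def make_panel(genotypes, n_per_pop=None, loci=None):
    n = genotypes.shape[0]
    n_per_pop = n_per_pop or n // 2
    pops = ["A"] * n_per_pop + ["B"] * (n - n_per_pop)
    loci = loci or [f"L{k}" for k in range(genotypes.shape[1])]
    return GenotypePanel([f"i{k}" for k in range(n)], pops, loci, genotypes)


def random_panel(seed, n_loci=10, n_per_pop=24, k=4, missing_rate=0.0):
    rng = np.random.default_rng(seed)
    g = rng.integers(0, k, size=(2 * n_per_pop, n_loci, 2)).astype(np.int32)
    if missing_rate:
        miss = rng.random((2 * n_per_pop, n_loci)) < missing_rate
        g[miss] = -1
    return make_panel(g)


class TestWcTheta:
    def test_fixed_differences_give_one(self):
        g = np.zeros((48, 10, 2), dtype=np.int32)
        g[24:] = 1
        assert wc_theta(make_panel(g)).theta == pytest.approx(1.0)

    def test_identical_populations_nonpositive(self):
        rng = np.random.default_rng(5)
        half = rng.integers(0, 4, size=(24, 10, 2)).astype(np.int32)
        est = wc_theta(make_panel(np.vstack([half, half])))
        assert est.theta <= 0.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_agrees_with_textbook_oracle(self, seed):
        panel = random_panel(seed)
        assert wc_theta(panel).theta == pytest.approx(
            wc_theta_oracle(panel), abs=1e-10
        )

    def test_oracle_agreement_with_missing_and_unbalanced(self):
        panel = random_panel(9, n_loci=8, missing_rate=0.15)
        panel.populations[:10] = "B"  # unbalanced sizes
        assert wc_theta(panel).theta == pytest.approx(
            wc_theta_oracle(panel), abs=1e-10
        )

    def test_monomorphic_loci_excluded(self):
        g = np.zeros((20, 3, 2), dtype=np.int32)
        g[10:, 0, :] = 1  # locus 0 informative; loci 1-2 monomorphic
        est = wc_theta(make_panel(g))
        assert est.loci_used == ["L0"]

    def test_no_polymorphic_locus_raises(self):
        g = np.zeros((20, 3, 2), dtype=np.int32)
        with pytest.raises(EstimationError):
            wc_theta(make_panel(g))

    def test_single_population_raises(self):
        g = np.random.default_rng(0).integers(0, 3, size=(10, 4, 2)).astype(np.int32)
        panel = GenotypePanel([f"i{k}" for k in range(10)], ["A"] * 10, ["L0", "L1", "L2", "L3"], g)
        with pytest.raises(InputError):
            wc_theta(panel)

    @given(seed=st.integers(0, 50))
    def test_invariant_to_allele_relabelling_and_locus_order(self, seed):
        panel = random_panel(seed, n_loci=5)
        theta = wc_theta(panel).theta
        # relabel alleles at every locus with a fixed permutation
        rng = np.random.default_rng(seed + 1)
        g2 = panel.genotypes.copy()
        for l in range(panel.n_loci):
            perm = rng.permutation(4)
            mask = g2[:, l, :] >= 0
            g2[:, l, :][mask] = perm[g2[:, l, :][mask]]
        order = rng.permutation(panel.n_loci)
        relabelled = make_panel(g2[:, order, :], loci=[panel.loci[o] for o in order])
        assert wc_theta(relabelled).theta == pytest.approx(theta, abs=1e-12)


class TestJackknife:
    def test_identical_loci_zero_se(self):
        g = np.zeros((48, 10, 2), dtype=np.int32)
        g[24:] = 1
        assert jackknife_se(make_panel(g)) == pytest.approx(0.0)

    def test_heterogeneous_loci_positive_se(self):
        g = np.zeros((48, 2, 2), dtype=np.int32)
        g[24:, 0, :] = 1  # locus 0: fixed difference
        rng = np.random.default_rng(2)
        g[:, 1, :] = rng.integers(0, 2, size=(48, 2))  # locus 1: shared noise
        assert jackknife_se(make_panel(g)) > 0.0

    def test_single_locus_raises(self):
        g = np.zeros((48, 1, 2), dtype=np.int32)
        g[24:] = 1
        with pytest.raises(PrecisionError):
            jackknife_se(make_panel(g))


class TestPermutation:
    def test_fixed_panel_minimum_p(self):
        g = np.zeros((48, 10, 2), dtype=np.int32)
        g[24:] = 1
        p = permutation_test(make_panel(g), n_perm=200, seed=0)
        assert p == pytest.approx(1 / 201)

    def test_seed_reproducibility(self):
        panel = random_panel(7)
        assert permutation_test(panel, 150, seed=3) == permutation_test(panel, 150, seed=3)

    def test_too_few_permutations_rejected(self):
        with pytest.raises(InputError):
            permutation_test(random_panel(0), n_perm=10)


class TestExcludeLoci:
    def test_named_exclusion_reduces_count(self):
        panel = random_panel(1, n_loci=104)
        reduced = panel.exclude_loci(["L7"])
        assert reduced.n_loci == 103
        assert "L7" not in reduced.loci

    def test_empty_exclusion_is_identity(self):
        panel = random_panel(1)
        same = panel.exclude_loci([])
        assert same.loci == panel.loci
        assert np.array_equal(same.genotypes, panel.genotypes)

    def test_unknown_locus_raises(self):
        with pytest.raises(ReferenceError_):
            random_panel(1).exclude_loci(["Ppgm35"])

    def test_excluding_all_flags_empty_panel(self):
        panel = random_panel(1, n_loci=3)
        with pytest.warns(UserWarning, match="all loci excluded"):
            empty = panel.exclude_loci(panel.loci)
        assert empty.n_loci == 0


class TestIO:
    def test_genepop_round_trip(self, tmp_path):
        panel = random_panel(4, n_loci=6, missing_rate=0.1)
        path = tmp_path / "panel.gen"
        write_genepop(panel, path)
        back = read_genepop(path)
        assert back.n_loci == panel.n_loci
        assert back.n_individuals == panel.n_individuals
        # theta must survive the round trip exactly (same data content)
        assert wc_theta(back).theta == pytest.approx(wc_theta(panel).theta, abs=1e-12)

    def test_csv_round_trip(self, tmp_path):
        panel = random_panel(6, n_loci=4)
        path = tmp_path / "panel.csv"
        panel.to_long_frame().to_csv(path, index=False)
        back = GenotypePanel.read_csv(path)
        assert wc_theta(back).theta == pytest.approx(wc_theta(panel).theta, abs=1e-12)


def test_fst_estimate_bundles_se_and_p():
    panel = simulate_genotypes(
        GenotypeParams(n_loci=30, alleles_per_locus=4, target_fst=0.3), seed=0
    )
    est = fst_estimate(panel, n_perm=150, seed=1)
    assert est.se is not None and est.se > 0
    assert est.p_value == pytest.approx(1 / 151)
    assert est.n_permutations == 150
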