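"""Synthetic data with the structure of a two-population half-sib study.

The generator emulates the breeding design behind the analyses: 36 sires
each mated to two dams per population, families of 10-25 offspring split
into duplicate rearing tanks at 20 days after hatching (DAH), body length
measured every 30 days to 140 DAH, maturation scored as a binary record
(matured: 0, immature: 1), sex unknown for immature fish (a three-level sex
factor), and a panel of ~103 multi-allelic neutral loci for 24 + 24
parental fish generated under a Balding-Nichols two-population model at a
target F_ST.

Phenotypes follow the generative direction of the animal model:

    y = population mean(age) + a + m + tank + sex + density slope * density + e

with founder breeding values a ~ N(0, V_A) (bivariate: MVN(0, G) implied by
V_A1, V_A2 and r_g), offspring values midparent + Mendelian sampling
N(0, V_A / 2), maternal effects per dam ~ N(0, V_M), and iid residuals
N(0, V_E) per age.  Maturation is a liability threshold trait: an
individual has matured by a given age iff its (heritable, Gaussian)
liability exceeds the population- and age-specific threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InputError
from .fst import GenotypePanel
from .pedigree import Pedigree

__all__ = [
    "TraitParams",
    "GenotypeParams",
    "SimulationConfig",
    "simulate_design",
    "simulate_phenotypes",
    "simulate_maturation",
    "simulate_genotypes",
    "simulate_halfsib_trait",
    "simulate_study",
    "helsinki_config",
    "pyorealampi_config",
]


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# --------------------------------------------------------------------- #
@dataclass
class TraitParams:
    """True variance components and fixed-effect values for one trait.

    Units follow the measured trait (mm for body length; the maturation
    liability is unit variance by convention).  ``mean_by_age`` carries the
    population growth trajectory (no parametric growth law is imposed).
    """

    v_a: float = 2.2
    v_m: float = 0.9
    v_e: float = 9.2
    mean_by_age: dict[int, float] = field(
        default_factory=lambda: {20: 8.0, 50: 17.0, 80: 25.0, 110: 30.0, 140: 33.0}
    )
    sex_effect: float = 1.0  # added for females (females grow larger)
    density_slope: float = -0.1  # mm per extra fish in the tank
    tank_sd: float = 0.7


@dataclass
class GenotypeParams:
    """Balding-Nichols settings for the neutral marker panel."""

    n_loci: int = 103
    alleles_per_locus: int = 5
    target_fst: float = 0.458
    n_per_population: int = 24


@dataclass
class SimulationConfig:
    """Study design and generative parameters for one population."""

    population: str = "Helsinki"
    n_sires: int = 36
    dams_per_sire: int = 2
    offspring_range: tuple[int, int] = (10, 25)
    n_tanks_per_family: int = 2
    single_tank_fraction: float = 0.0
    ages: tuple[int, ...] = (20, 50, 80, 110, 140)
    mortality_per_interval: float = 0.05
    length: TraitParams = field(default_factory=TraitParams)
    liability: TraitParams = field(
        default_factory=lambda: TraitParams(
            v_a=0.3, v_m=0.15, v_e=0.55,
            mean_by_age={20: 0.0, 50: 0.0, 80: 0.0, 110: 0.0, 140: 0.0},
            sex_effect=0.0, density_slope=0.0, tank_sd=0.0,
        )
    )
    rg: float = 0.0  # genetic correlation between length and liability
    # liability threshold per age; None = no maturation at that age (or at all)
    maturation_threshold_by_age: dict[int, float] | None = None
    genotypes: GenotypeParams = field(default_factory=GenotypeParams)

    def __post_init__(self):
        for tp in (self.length, self.liability):
            if min(tp.v_a, tp.v_m, tp.v_e) < 0:
                raise InputError("variance components must be non-negative")
        if abs(self.rg) > 1:
            raise InputError("|r_g| must be <= 1")
        if not (0 <= self.genotypes.target_fst < 1):
            raise InputError("target F_ST must be in [0, 1)")


def helsinki_config() -> SimulationConfig:
    """The small-sized coastal population: growth levels off, fish mature."""
    return SimulationConfig(
        population="Helsinki",
        single_tank_fraction=22 / 72,  # 22 of the families in one tank only
        length=TraitParams(
            v_a=2.2, v_m=0.9, v_e=9.2,
            mean_by_age={20: 9.0, 50: 18.0, 80: 26.0, 110: 29.0, 140: 31.0},
        ),
        # liability is a maturation *propensity*: genetically large fish mature
        # later, so length and propensity correlate negatively, making length
        # and the immature-coded (0/1) timing trait correlate positively
        rg=-0.6,
        maturation_threshold_by_age={80: 0.9, 110: 0.0, 140: -0.4},
    )


def pyorealampi_config() -> SimulationConfig:
    """The giant pond population: near-linear growth, no maturation by 140 DAH."""
    return SimulationConfig(
        population="Pyorealampi",
        length=TraitParams(
            v_a=1.6, v_m=1.1, v_e=12.0,
            mean_by_age={20: 7.0, 50: 15.0, 80: 25.0, 110: 33.0, 140: 40.0},
        ),
        maturation_threshold_by_age=None,
    )


# --------------------------------------------------------------------- #
def simulate_design(cfg: SimulationConfig, seed=0) -> tuple[Pedigree, pd.DataFrame]:
    """Half-sib pedigree plus the family/tank assignment table.

    Offspring counts per family are uniform over ``offspring_range``; each
    family is split across ``n_tanks_per_family`` tanks except a configured
    fraction reared in a single tank.
    """
    rng = _rng(seed)
    pop = cfg.population
    records = []
    rows = []
    fam_labels = []
    for s in range(cfg.n_sires):
        sire = f"{pop}_S{s + 1}"
        records.append((sire, None, None, pop))
        for d in range(cfg.dams_per_sire):
            dam = f"{pop}_D{s + 1}_{d + 1}"
            records.append((dam, None, None, pop))
            fam_labels.append((sire, dam))
    lo, hi = cfg.offspring_range
    n_fam = len(fam_labels)
    counts = rng.integers(lo, hi + 1, size=n_fam)
    single = rng.random(n_fam) < cfg.single_tank_fraction
    for f, (sire, dam) in enumerate(fam_labels):
        family = dam  # one cross per dam: the dam id identifies the family
        n_tanks = 1 if (single[f] or cfg.n_tanks_per_family == 1) else cfg.n_tanks_per_family
        for k in range(counts[f]):
            iid = f"{dam}_o{k + 1}"
            records.append((iid, sire, dam, pop))
            rows.append(
                {
                    "id": iid,
                    "sire": sire,
                    "dam": dam,
                    "family": family,
                    "block": f"{family}_t{(k % n_tanks) + 1}",
                    "population": pop,
                }
            )
    ped = Pedigree(records)
    return ped, pd.DataFrame(rows)


def _breeding_values(ped: Pedigree, G: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Breeding values for every pedigree member under covariance G (t x t).

    Founders ~ MVN(0, G); offspring = midparent + MVN(0, G/2) Mendelian
    sampling (non-inbred, unrelated parents).
    """
    t = G.shape[0]
    try:
        L_f = np.linalg.cholesky(G + 1e-12 * np.eye(t))
    except np.linalg.LinAlgError as err:
        raise InputError(f"implied G matrix is not positive semi-definite: {err}") from err
    L_m = L_f / np.sqrt(2.0)
    n = len(ped)
    bv = np.zeros((n, t))
    z = rng.standard_normal((n, t))
    for i in range(n):
        s, d = ped.sire_idx[i], ped.dam_idx[i]
        if s < 0 and d < 0:
            bv[i] = L_f @ z[i]
        else:
            mid = 0.5 * ((bv[s] if s >= 0 else 0.0) + (bv[d] if d >= 0 else 0.0))
            bv[i] = mid + L_m @ z[i]
    return bv


def simulate_phenotypes(
    ped: Pedigree,
    design: pd.DataFrame,
    cfg: SimulationConfig,
    seed=0,
) -> pd.DataFrame:
    """Long-format trait table over the configured ages.

    Returns one row per surviving individual per age with columns
    ``id, age_dah, length_mm, liability, true_sex, family, dam, block,
    density, population``.  The density covariate is the realized mean tank
    occupancy over the previous-to-focal interval (focal occupancy at the
    first age); mortality thins tanks between ages.
    """
    rng = _rng(seed)
    G = np.array(
        [
            [cfg.length.v_a, cfg.rg * np.sqrt(cfg.length.v_a * cfg.liability.v_a)],
            [cfg.rg * np.sqrt(cfg.length.v_a * cfg.liability.v_a), cfg.liability.v_a],
        ]
    )
    bv = _breeding_values(ped, G, rng)
    pos = {iid: ped.index[iid] for iid in design["id"]}
    off_idx = np.array([pos[i] for i in design["id"]], dtype=np.int64)
    bv_len = bv[off_idx, 0]
    bv_lia = bv[off_idx, 1]

    dams = design["dam"].to_numpy()
    dam_levels = list(dict.fromkeys(dams))
    m_len = dict(zip(dam_levels, rng.normal(0.0, np.sqrt(cfg.length.v_m), len(dam_levels))))
    m_lia = dict(zip(dam_levels, rng.normal(0.0, np.sqrt(cfg.liability.v_m), len(dam_levels))))

    tanks = design["block"].to_numpy()
    tank_levels = list(dict.fromkeys(tanks))
    tank_eff = dict(zip(tank_levels, rng.normal(0.0, cfg.length.tank_sd, len(tank_levels))))

    n = len(design)
    true_sex = np.where(rng.random(n) < 0.5, "male", "female")
    sex_term = np.where(true_sex == "female", cfg.length.sex_effect, 0.0)

    # liability is a single heritable Gaussian value per individual
    liability = (
        bv_lia
        + np.array([m_lia[d] for d in dams])
        + rng.normal(0.0, np.sqrt(cfg.liability.v_e), n)
    )

    alive = np.ones(n, dtype=bool)
    prev_occ = None
    frames = []
    for age in cfg.ages:
        if prev_occ is not None and cfg.mortality_per_interval > 0:
            alive = alive & (rng.random(n) >= cfg.mortality_per_interval)
        occ_by_tank = pd.Series(tanks[alive]).value_counts().to_dict()
        occ = np.array([occ_by_tank.get(t, 0) for t in tanks], dtype=float)
        density = occ if prev_occ is None else 0.5 * (occ + prev_occ)
        prev_occ = occ
        mu = cfg.length.mean_by_age[age]
        yl = (
            mu
            + bv_len
            + np.array([m_len[d] for d in dams])
            + np.array([tank_eff[t] for t in tanks])
            + sex_term
            + cfg.length.density_slope * (density - density[alive].mean() if alive.any() else density)
            + rng.normal(0.0, np.sqrt(cfg.length.v_e), n)
        )
        frames.append(
            pd.DataFrame(
                {
                    "id": design["id"],
                    "age_dah": age,
                    "length_mm": yl,
                    "liability": liability,
                    "true_sex": true_sex,
                    "family": design["family"],
                    "dam": dams,
                    "block": tanks,
                    "density": density,
                    "population": design["population"],
                }
            )[alive]
        )
    return pd.concat(frames, ignore_index=True)


def simulate_maturation(traits: pd.DataFrame, cfg: SimulationConfig, seed=0) -> pd.DataFrame:
    """Add the binary maturation record and the observed 3-level sex factor.

    ``mature`` follows the timing-of-maturation coding (matured: 0,
    immature: 1).  Sex is reported as "immature" while an individual has
    not matured, because immature fish cannot be sexed.
    """
    out = traits.copy()
    thresholds = cfg.maturation_threshold_by_age or {}
    thr = out["age_dah"].map(lambda a: thresholds.get(int(a), np.inf)).to_numpy(dtype=float)
    matured = out["liability"].to_numpy() > thr
    out["mature"] = np.where(matured, 0, 1)
    out["sex"] = np.where(matured, out["true_sex"], "immature")
    return out


def simulate_genotypes(cfg: SimulationConfig | GenotypeParams, seed=0,
                       populations: tuple[str, str] = ("Helsinki", "Pyorealampi")) -> GenotypePanel:
    """Balding-Nichols two-population genotype panel at a target F_ST.

    Ancestral allele frequencies are symmetric-Dirichlet; population
    frequencies are Dirichlet(p (1-F)/F) around the ancestral vector
    (equal to it when F = 0); diploid genotypes are drawn independently.
    """
    gp = cfg.genotypes if isinstance(cfg, SimulationConfig) else cfg
    rng = _rng(seed)
    L, k, F, n = gp.n_loci, gp.alleles_per_locus, gp.target_fst, gp.n_per_population
    if L < 1 or k < 2:
        raise InputError("need n_loci >= 1 and alleles_per_locus >= 2")
    ids = [f"{pop}_P{i + 1}" for pop in populations for i in range(n)]
    pops = [pop for pop in populations for _ in range(n)]
    geno = np.full((2 * n, L, 2), -1, dtype=np.int32)
    for l in range(L):
        p_anc = rng.dirichlet(np.ones(k))
        for j, _pop in enumerate(populations):
            if F == 0:
                p = p_anc
            else:
                alpha = np.maximum(p_anc * (1.0 - F) / F, 1e-6)
                p = rng.dirichlet(alpha)
            draws = rng.choice(k, size=(n, 2), p=p)
            geno[j * n : (j + 1) * n, l, :] = draws
    loci = [f"L{l + 1:03d}" for l in range(L)]
    labels = [[str(a + 1) for a in range(k)] for _ in range(L)]
    return GenotypePanel(ids, pops, loci, geno, labels)


# --------------------------------------------------------------------- #
def simulate_halfsib_trait(
    n_sires: int = 30,
    dams_per_sire: int = 2,
    n_offspring: int = 20,
    v_a: float = 3.0,
    v_m: float = 2.0,
    v_e: float = 5.0,
    mu: float = 0.0,
    seed=0,
    population: str = "pop1",
) -> tuple[Pedigree, pd.DataFrame]:
    """Minimal single-age half-sib dataset: y = mu + a + m + e.

    A stripped-down generator for parameter-recovery work: balanced design,
    no tanks, no sexes, no density.  Returns the pedigree and a table with
    columns ``id, y, dam, family``.
    """
    rng = _rng(seed)
    cfg = SimulationConfig(
        population=population,
        n_sires=n_sires,
        dams_per_sire=dams_per_sire,
        offspring_range=(n_offspring, n_offspring),
        n_tanks_per_family=1,
    )
    ped, design = simulate_design(cfg, rng)
    G = np.array([[max(v_a, 1e-12)]])
    bv = _breeding_values(ped, G, rng)[:, 0]
    if v_a == 0:
        bv = np.zeros_like(bv)
    off_idx = np.array([ped.index[i] for i in design["id"]], dtype=np.int64)
    dams = design["dam"].to_numpy()
    dam_levels = list(dict.fromkeys(dams))
    m_eff = dict(zip(dam_levels, rng.normal(0.0, np.sqrt(v_m), len(dam_levels))))
    y = (
        mu
        + bv[off_idx]
        + np.array([m_eff[d] for d in dams])
        + rng.normal(0.0, np.sqrt(v_e), len(design))
    )
    data = pd.DataFrame(
        {"id": design["id"], "y": y, "dam": dams, "family": design["family"]}
    )
    return ped, data


def simulate_study(
    cfg_a: SimulationConfig | None = None,
    cfg_b: SimulationConfig | None = None,
    seed: int = 0,
    with_genotypes: bool = True,
) -> dict:
    """Full two-population study: pedigrees, phenotypes, genotype panel.

    Returns a dict with ``peds`` (population -> Pedigree), ``traits``
    (combined long TraitTable) and ``panel`` (GenotypePanel or None).
    """
    cfg_a = cfg_a or helsinki_config()
    cfg_b = cfg_b or pyorealampi_config()
    ss = np.random.SeedSequence(seed)
    seeds = ss.spawn(5)
    peds = {}
    tables = []
    for cfg, s_design, s_pheno in ((cfg_a, seeds[0], seeds[1]), (cfg_b, seeds[2], seeds[3])):
        ped, design = simulate_design(cfg, np.random.default_rng(s_design))
        traits = simulate_phenotypes(ped, design, cfg, np.random.default_rng(s_pheno))
        traits = simulate_maturation(traits, cfg)
        peds[cfg.population] = ped
        tables.append(traits)
    panel = None
    if with_genotypes:
        panel = simulate_genotypes(
            cfg_a, np.random.default_rng(seeds[4]),
            populations=(cfg_a.population, cfg_b.population),
        )
    return {"peds": peds, "traits": pd.concat(tables, ignore_index=True), "panel": panel}
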