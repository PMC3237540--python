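"""End-to-end orchestration of the full analysis sequence.

One call (or ``stickleqg run``) reproduces the study's analysis chain on
simulated or user data: simulate -> phenotype statistics -> per-age,
per-population animal models -> bivariate genetic correlation -> per-age
Q_ST -> F_ST -> Q_ST/F_ST contrast, with a run manifest recording seeds,
config hash, per-stage outputs and wall-clock so a run can be replayed
exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .animal_model import ChainConfig, ModelSpec, fit_animal_model, fit_bivariate, summarize_variances
from .errors import StickleQGError
from .fst import fst_estimate, read_genepop, write_genepop
from .pedigree import Pedigree
from .phenotype_stats import fit_lme, lrt_compare, sex_ratio_chisq, variance_proportions
from .qst import fit_qst, qst_fst_contrast
from .simulate import SimulationConfig, helsinki_config, pyorealampi_config, simulate_study

__all__ = ["RunManifest", "run_full_pipeline", "default_config"]


def default_config() -> dict:
    """Baseline pipeline configuration (simulated two-population study)."""
    return {
        "simulate": True,
        "seedless_design": False,
        "ages": [20, 50, 80, 110, 140],
        "chain": {"iterations": 6000, "burn_in": 1500, "thin": 4},
        "qst_chain": {"iterations": 6000, "burn_in": 3000, "thin": 2},
        "bivariate": {"ages": [140], "traits": ["length_mm", "mature"]},
        "fst": {"n_permutations": 1000, "exclude": []},
        "design": {},  # overrides for SimulationConfig fields (both populations)
        "data": None,  # {"traits": ..., "pedigrees": {pop: path}, "genepop": ...}
    }


@dataclass
class RunManifest:
    """What a pipeline run did: inputs, outputs, timings, reproducibility."""

    config_hash: str
    seed: int
    version: str
    stages: list[dict] = field(default_factory=list)

    def add(self, name: str, outputs: list[str], seconds: float, note: str | None = None):
        entry = {"stage": name, "outputs": outputs, "seconds": round(seconds, 3)}
        if note:
            entry["note"] = note
        self.stages.append(entry)

    def to_json(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "stages": self.stages,
        }


class StageError(StickleQGError):
    """A pipeline stage failed; partial outputs are retained."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def _chain_from(cfg: dict | None, fallback: ChainConfig) -> ChainConfig:
    if not cfg:
        return fallback
    return ChainConfig(
        iterations=int(cfg.get("iterations", fallback.iterations)),
        burn_in=cfg.get("burn_in"),
        thin=cfg.get("thin"),
    )


def _apply_design_overrides(cfg: SimulationConfig, over: dict) -> SimulationConfig:
    for key, val in (over or {}).items():
        if not hasattr(cfg, key):
            raise StickleQGError(f"unknown design override {key!r}")
        if key == "offspring_range":
            val = tuple(val)
        setattr(cfg, key, val)
    return cfg


def run_full_pipeline(config: dict | str | Path, outdir: str | Path, seed: int = 0) -> RunManifest:
    """Execute the full analysis sequence; returns the run manifest.

    ``config`` is a dict or a YAML path; see :func:`default_config` for the
    schema.  One global seed deterministically spawns per-stage seeds so
    stages are independently reproducible.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    base = default_config()
    base.update(config or {})
    config = base
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cfg_hash = hashlib.sha256(
        yaml.safe_dump(config, sort_keys=True).encode()
    ).hexdigest()[:16]
    manifest = RunManifest(config_hash=cfg_hash, seed=seed, version=__version__)
    stage_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(8)]
    chain = _chain_from(config.get("chain"), ChainConfig(6000, 1500, 4))
    qst_chain = _chain_from(config.get("qst_chain"), ChainConfig(6000, 3000, 2))
    ages = list(config["ages"])

    # ------------------------------------------------------------ stage 1
    t0 = time.time()
    stage = "simulate"
    try:
        if config.get("simulate", True):
            cfg_a = _apply_design_overrides(helsinki_config(), config.get("design"))
            cfg_b = _apply_design_overrides(pyorealampi_config(), config.get("design"))
            cfg_a.ages = tuple(ages)
            cfg_b.ages = tuple(ages)
            study = simulate_study(cfg_a, cfg_b, seed=stage_seeds[0])
            traits, peds, panel = study["traits"], study["peds"], study["panel"]
            traits_path = outdir / "traits.csv"
            traits.to_csv(traits_path, index=False)
            outputs = [str(traits_path)]
            for pop, ped in peds.items():
                p = outdir / f"pedigree_{pop}.csv"
                ped.to_csv(p)
                outputs.append(str(p))
            if panel is not None:
                gp = outdir / "panel.gen"
                write_genepop(panel, gp)
                outputs.append(str(gp))
            manifest.add(stage, outputs, time.time() - t0)
        else:
            data_cfg = config.get("data") or {}
            if "traits" not in data_cfg:
                raise StickleQGError("config.data.traits is required when simulate is false")
            traits = pd.read_csv(data_cfg["traits"])
            peds = {pop: Pedigree.read_csv(path) for pop, path in (data_cfg.get("pedigrees") or {}).items()}
            panel = read_genepop(data_cfg["genepop"]) if data_cfg.get("genepop") else None
            manifest.add(stage, [], time.time() - t0, note="user data loaded")
    except StickleQGError:
        raise
    except Exception as err:  # noqa: BLE001
        raise StageError(stage, err) from err

    pops = list(peds)
    report_rows: list[dict] = []

    # ------------------------------------------------------------ stage 2
    t0 = time.time()
    stage = "phenotype_stats"
    try:
        stats_rows = []
        for age in ages:
            sub = traits[traits["age_dah"] == age]
            if sub["population"].nunique() < 2 or len(sub) < 20:
                continue
            full = fit_lme(sub, "length_mm", fixed=("population", "density"))
            red = fit_lme(sub, "length_mm", fixed=("density",))
            lrt, p = lrt_compare(full, red)
            fam_pct, blk_pct, res_pct = variance_proportions(full)
            stats_rows.append(
                {
                    "model": "length~population",
                    "age_dah": age,
                    "statistic": lrt,
                    "df": full.n_params - red.n_params,
                    "p": p,
                    "family_pct": fam_pct,
                    "block_pct": blk_pct,
                    "residual_pct": res_pct,
                }
            )
        matured = traits[(traits["age_dah"] == ages[-1]) & (traits["mature"] == 0)]
        if len(matured):
            n_m = int((matured["sex"] == "male").sum())
            n_f = int((matured["sex"] == "female").sum())
            if n_m + n_f:
                stat, p = sex_ratio_chisq(n_m, n_f)
                stats_rows.append(
                    {"model": "sex_ratio_1to1", "age_dah": ages[-1], "statistic": stat,
                     "df": 1, "p": p, "n_males": n_m, "n_females": n_f}
                )
        stats_path = outdir / "phenotype_stats.csv"
        pd.DataFrame(stats_rows).to_csv(stats_path, index=False)
        manifest.add(stage, [str(stats_path)], time.time() - t0)
    except Exception as err:  # noqa: BLE001
        raise StageError(stage, err) from err

    # ------------------------------------------------------------ stage 3
    t0 = time.time()
    stage = "animal_model"
    try:
        for k, (pop, age) in enumerate((p, a) for p in pops for a in ages):
            sub = traits[(traits["population"] == pop) & (traits["age_dah"] == age)]
            if len(sub) < 30:
                continue
            spec = ModelSpec(response="length_mm", fixed=("density", "sex"),
                             block_random="block")
            samples = fit_animal_model(sub, spec, peds[pop], chain=chain,
                                       seed=stage_seeds[1] + k)
            summ = summarize_variances(samples)
            for qty in ("V_A", "V_M", "V_P", "h2", "m2"):
                q = summ[qty]
                report_rows.append(
                    {
                        "section": "heritability",
                        "population": pop,
                        "age_dah": age,
                        "trait": "length_mm",
                        "quantity": qty,
                        "estimate": q.mode,
                        "hpd_low": q.hpd_low,
                        "hpd_high": q.hpd_high,
                    }
                )
        manifest.add(stage, [], time.time() - t0)
    except Exception as err:  # noqa: BLE001
        raise StageError(stage, err) from err

    # ------------------------------------------------------------ stage 4
    t0 = time.time()
    stage = "bivariate"
    try:
        biv = config.get("bivariate") or {}
        traits_pair = tuple(biv.get("traits", ("length_mm", "mature")))
        for age in biv.get("ages", []):
            for pop in pops:
                sub = traits[(traits["population"] == pop) & (traits["age_dah"] == age)]
                if len(sub) < 30 or sub[traits_pair[1]].nunique() < 2:
                    continue
                bs = fit_bivariate(sub, traits_pair, ModelSpec(response=traits_pair[0], fixed=("density",)),
                                   peds[pop], chain=chain, seed=stage_seeds[2])
                lo, hi = bs.rg_hpd()
                report_rows.append(
                    {
                        "section": "genetic_correlation",
                        "population": pop,
                        "age_dah": age,
                        "trait": "+".join(traits_pair),
                        "quantity": "r_g",
                        "estimate": bs.rg_mean,
                        "hpd_low": lo,
                        "hpd_high": hi,
                    }
                )
        manifest.add(stage, [], time.time() - t0)
    except Exception as err:  # noqa: BLE001
        raise StageError(stage, err) from err

    # ------------------------------------------------------------ stage 5
    t0 = time.time()
    stage = "qst"
    qst_by_age = {}
    try:
        for k, age in enumerate(ages):
            sub = traits[traits["age_dah"] == age]
            if sub["population"].nunique() < 2:
                continue
            q = fit_qst(sub, peds, response="length_mm", chain=qst_chain,
                        seed=stage_seeds[3] + k)
            qst_by_age[age] = q
            report_rows.append(
                {
                    "section": "qst",
                    "population": "both",
                    "age_dah": age,
                    "trait": "length_mm",
                    "quantity": "Q_ST",
                    "estimate": q.posterior_mean,
                    "sd": q.posterior_sd,
                    "rhat": q.rhat,
                }
            )
        manifest.add(stage, [], time.time() - t0)
    except Exception as err:  # noqa: BLE001
        raise StageError(stage, err) from err

    # ------------------------------------------------------------ stage 6
    t0 = time.time()
    stage = "fst"
    fst_est = None
    if panel is not None:
        try:
            fcfg = config.get("fst") or {}
            fst_est = fst_estimate(
                panel,
                exclude=fcfg.get("exclude", []),
                n_perm=int(fcfg.get("n_permutations", 1000)),
                seed=stage_seeds[4],
            )
            report_rows.append(
                {
                    "section": "fst",
                    "population": "both",
                    "quantity": "F_ST",
                    "estimate": fst_est.theta,
                    "se": fst_est.se,
                    "p": fst_est.p_value,
                }
            )
            for age, q in qst_by_age.items():
                report_rows.append(
                    {
                        "section": "qst_fst_contrast",
                        "population": "both",
                        "age_dah": age,
                        "quantity": "classification",
                        "classification": qst_fst_contrast(q, fst_est),
                    }
                )
            manifest.add(stage, [], time.time() - t0)
        except Exception as err:  # noqa: BLE001
            raise StageError(stage, err) from err
    else:
        manifest.add(stage, [], 0.0, note="skipped: no genotype panel configured")

    # ------------------------------------------------------------ report
    t0 = time.time()
    report_path = outdir / "report.csv"
    pd.DataFrame(report_rows).to_csv(report_path, index=False)
    outputs = [str(report_path)]
    if qst_by_age and fst_est is not None:
        fig_path = outdir / "qst_vs_fst.png"
        _qst_fst_figure(qst_by_age, fst_est, fig_path)
        outputs.append(str(fig_path))
    manifest_path = outdir / "manifest.json"
    manifest.add("report", outputs, time.time() - t0)
    with open(manifest_path, "w") as fh:
        json.dump(manifest.to_json(), fh, indent=2)
    return manifest


def _qst_fst_figure(qst_by_age: dict, fst_est, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ages = sorted(qst_by_age)
    means = [qst_by_age[a].posterior_mean for a in ages]
    sds = [qst_by_age[a].posterior_sd for a in ages]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.errorbar(ages, means, yerr=sds, fmt="o", color="k", capsize=3, label="Q_ST (mean ± SD)")
    ax.axhline(fst_est.theta, color="gray", label="F_ST")
    if fst_est.se:
        for off in (-fst_est.se, fst_est.se):
            ax.axhline(fst_est.theta + off, color="gray", linestyle=":")
    ax.set_xlabel("age (days after hatching)")
    ax.set_ylabel("divergence")
    ax.set_ylim(0, 1.05)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
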