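"""Weir-Cockerham F_ST (theta) for multi-allelic genotype panels.

Implements the 1984 variance-components estimator of the standardized
variance in allele frequencies among populations: per-allele components
a (among populations), b (among individuals within populations) and c
(within individuals) are summed within each locus, and the multilocus
estimate is the ratio of sums

    theta = sum_l a_l / sum_l (a_l + b_l + c_l)

over the included polymorphic loci — the global-estimator convention of
FSTAT.  Uncertainty comes from a delete-one jackknife over loci, and
significance from permuting individuals (both alleles together) across
population labels.

Genotype panels can be read from GENEPOP files (2- or 3-digit allele
coding) or from a long-format CSV ``id,population,locus,allele1,allele2``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EstimationError, InputError, PrecisionError, ReferenceError_

__all__ = [
    "GenotypePanel",
    "FstEstimate",
    "wc_theta",
    "jackknife_se",
    "permutation_test",
    "exclude_loci",
    "fst_estimate",
    "read_genepop",
    "write_genepop",
]


# --------------------------------------------------------------------- #
class GenotypePanel:
    """Individuals x loci multi-allelic diploid genotypes with populations.

    ``genotypes`` is an (n, L, 2) int array of per-locus allele codes
    (0..k_l-1); -1 marks a missing call (a genotype is treated as missing if
    either allele is).  ``allele_labels[l]`` maps codes back to the original
    allele names of locus l.
    """

    def __init__(self, ids, populations, loci, genotypes, allele_labels=None):
        self.ids = [str(i) for i in ids]
        self.populations = np.asarray(populations, dtype=object)
        self.loci = [str(l) for l in loci]
        self.genotypes = np.asarray(genotypes, dtype=np.int32)
        if self.genotypes.shape != (len(self.ids), len(self.loci), 2):
            raise InputError(
                f"genotype array shape {self.genotypes.shape} does not match "
                f"{len(self.ids)} individuals x {len(self.loci)} loci x 2"
            )
        if allele_labels is None:
            allele_labels = [
                [str(a + 1) for a in range(max(2, int(self.genotypes[:, l, :].max()) + 1))]
                for l in range(len(self.loci))
            ]
        self.allele_labels = allele_labels

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def population_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(str(p))
        return list(seen)

    def exclude_loci(self, names: list[str]) -> "GenotypePanel":
        """Panel without the named loci (e.g. a locus flagged as non-neutral)."""
        names = list(names)
        unknown = [n for n in names if n not in self.loci]
        if unknown:
            raise ReferenceError_(f"unknown loci: {unknown}")
        keep = [l for l, name in enumerate(self.loci) if name not in names]
        if not keep:
            warnings.warn("all loci excluded; panel is empty", UserWarning, stacklevel=2)
        return GenotypePanel(
            self.ids,
            self.populations,
            [self.loci[l] for l in keep],
            self.genotypes[:, keep, :],
            [self.allele_labels[l] for l in keep],
        )

    # ------------------------------------------------------------------ #
    @classmethod
    def from_long_frame(cls, frame: pd.DataFrame) -> "GenotypePanel":
        """Build from long-format records id,population,locus,allele1,allele2.

        Missing alleles may be empty strings, "0", or NA.
        """
        frame = frame.copy()
        ids = list(dict.fromkeys(frame["id"].astype(str)))
        loci = list(dict.fromkeys(frame["locus"].astype(str)))
        id_pos = {i: k for k, i in enumerate(ids)}
        loc_pos = {l: k for k, l in enumerate(loci)}
        pops = {}
        geno = np.full((len(ids), len(loci), 2), -1, dtype=np.int32)
        allele_maps: list[dict[str, int]] = [{} for _ in loci]
        for row in frame.itertuples(index=False):
            i, l = id_pos[str(row.id)], loc_pos[str(row.locus)]
            pops[str(row.id)] = str(row.population)
            for slot, raw in enumerate((row.allele1, row.allele2)):
                s = "" if raw is None or (isinstance(raw, float) and np.isnan(raw)) else str(raw).strip()
                if s in ("", "0", "NA"):
                    continue
                code = allele_maps[l].setdefault(s, len(allele_maps[l]))
                geno[i, l, slot] = code
        geno[np.any(geno < 0, axis=2)] = -1
        labels = [[a for a, _ in sorted(m.items(), key=lambda kv: kv[1])] for m in allele_maps]
        return cls(ids, [pops[i] for i in ids], loci, geno, labels)

    @classmethod
    def read_csv(cls, path) -> "GenotypePanel":
        return cls.from_long_frame(pd.read_csv(path, dtype=str, keep_default_na=False))

    def to_long_frame(self) -> pd.DataFrame:
        rows = []
        for i, iid in enumerate(self.ids):
            for l, locus in enumerate(self.loci):
                g = self.genotypes[i, l]
                rows.append(
                    {
                        "id": iid,
                        "population": self.populations[i],
                        "locus": locus,
                        "allele1": self.allele_labels[l][g[0]] if g[0] >= 0 else "0",
                        "allele2": self.allele_labels[l][g[1]] if g[1] >= 0 else "0",
                    }
                )
        return pd.DataFrame(rows)


# --------------------------------------------------------------------- #
# GENEPOP reader/writer (no installed library handles this format)
# --------------------------------------------------------------------- #
def read_genepop(path) -> GenotypePanel:
    """Read a GENEPOP file with 2- or 3-digit diploid allele coding.

    Populations are delimited by ``POP`` lines and labelled pop1, pop2, ...
    in order of appearance; 00/000 codes are missing alleles.
    """
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    if not lines:
        raise InputError("empty GENEPOP file")
    lines = lines[1:]  # title line
    loci: list[str] = []
    i = 0
    pop_re = re.compile(r"^\s*pop\s*$", re.IGNORECASE)
    while i < len(lines) and not pop_re.match(lines[i]):
        loci.extend(x.strip() for x in lines[i].split(",") if x.strip())
        i += 1
    if i == len(lines):
        raise InputError("no POP line found")

    ids, pops, rows = [], [], []
    pop_idx = 0
    digits = None
    for ln in lines[i:]:
        if pop_re.match(ln):
            pop_idx += 1
            continue
        if not ln.strip():
            continue
        if "," not in ln:
            raise InputError(f"malformed GENEPOP genotype line: {ln!r}")
        name, geno_part = ln.split(",", 1)
        tokens = geno_part.split()
        if len(tokens) != len(loci):
            raise InputError(
                f"{name.strip()!r}: {len(tokens)} genotypes for {len(loci)} loci"
            )
        if digits is None:
            digits = len(tokens[0]) // 2
            if len(tokens[0]) not in (4, 6):
                raise InputError("only 2- or 3-digit diploid coding is supported")
        row = []
        for tok in tokens:
            if len(tok) != 2 * digits:
                raise InputError(f"inconsistent allele coding in token {tok!r}")
            row.append((tok[:digits], tok[digits:]))
        ids.append(name.strip())
        pops.append(f"pop{pop_idx}")
        rows.append(row)

    n, L = len(ids), len(loci)
    geno = np.full((n, L, 2), -1, dtype=np.int32)
    allele_maps: list[dict[str, int]] = [{} for _ in range(L)]
    zero = "0" * (digits or 2)
    for i_ind, row in enumerate(rows):
        for l, (a1, a2) in enumerate(row):
            for slot, a in enumerate((a1, a2)):
                if a == zero:
                    continue
                geno[i_ind, l, slot] = allele_maps[l].setdefault(a, len(allele_maps[l]))
    geno[np.any(geno < 0, axis=2)] = -1
    labels = [[a for a, _ in sorted(m.items(), key=lambda kv: kv[1])] for m in allele_maps]
    return GenotypePanel(ids, pops, loci, geno, labels)


def write_genepop(panel: GenotypePanel, path, title: str = "stickleqg panel") -> None:
    """Write a panel in GENEPOP format with 3-digit allele coding."""
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in panel.loci:
            fh.write(locus + "\n")
        order = panel.population_labels
        for pop in order:
            fh.write("POP\n")
            for i, iid in enumerate(panel.ids):
                if str(panel.populations[i]) != pop:
                    continue
                toks = []
                for l in range(panel.n_loci):
                    g = panel.genotypes[i, l]
                    if g[0] < 0 or g[1] < 0:
                        toks.append("000000")
                    else:
                        toks.append(f"{g[0] + 1:03d}{g[1] + 1:03d}")
                fh.write(f"{iid} , " + " ".join(toks) + "\n")


# --------------------------------------------------------------------- #
# Weir-Cockerham variance components
# --------------------------------------------------------------------- #
def _locus_cache(panel: GenotypePanel, loci_idx: np.ndarray):
    """Per-locus packed arrays reused across permutations."""
    cache = []
    for l in loci_idx:
        g = panel.genotypes[:, l, :]
        ok = np.all(g >= 0, axis=1)
        ind = np.where(ok)[0]
        a1 = g[ind, 0].astype(np.int64)
        a2 = g[ind, 1].astype(np.int64)
        k = int(max(a1.max(initial=-1), a2.max(initial=-1))) + 1 if ind.size else 0
        het = a1 != a2
        cache.append((ind, a1, a2, het, k))
    return cache


def _locus_components(ind, a1, a2, het, k, pop_codes, n_pops):
    """Summed (a, b, c) over alleles at one locus; None if uninformative."""
    if ind.size == 0 or k < 2:
        return None
    pops = pop_codes[ind]
    n_i = np.bincount(pops, minlength=n_pops).astype(float)
    used = n_i > 0
    r = int(used.sum())
    if r < 2:
        return None
    # allele counts and per-allele heterozygote counts per population
    counts = (
        np.bincount(pops * k + a1, minlength=n_pops * k)
        + np.bincount(pops * k + a2, minlength=n_pops * k)
    ).reshape(n_pops, k)[used].astype(float)
    hets = (
        np.bincount(pops[het] * k + a1[het], minlength=n_pops * k)
        + np.bincount(pops[het] * k + a2[het], minlength=n_pops * k)
    ).reshape(n_pops, k)[used].astype(float)
    n_i = n_i[used]
    if (counts.sum(axis=0) > 0).sum() < 2:
        return None  # monomorphic in every sampled population
    nbar = n_i.mean()
    if nbar <= 1.0:
        return None
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    if nc <= 0:
        return None
    p = counts / (2.0 * n_i[:, None])  # (r, k)
    pbar = (n_i[:, None] * p).sum(axis=0) / (r * nbar)
    s2 = (n_i[:, None] * (p - pbar[None, :]) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = hets.sum(axis=0) / (r * nbar)
    inner = pbar * (1 - pbar) - (r - 1) / r * s2
    a_u = (nbar / nc) * (s2 - (inner - hbar / 4.0) / (nbar - 1.0))
    b_u = (nbar / (nbar - 1.0)) * (inner - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar)
    c_u = hbar / 2.0
    return float(a_u.sum()), float(b_u.sum()), float(c_u.sum())


def _components(panel: GenotypePanel, loci=None, pop_codes=None):
    loci_idx = _resolve_loci(panel, loci)
    if pop_codes is None:
        pop_codes = _pop_codes(panel)
    codes, n_pops = pop_codes
    cache = _locus_cache(panel, loci_idx)
    a, b, c, used = [], [], [], []
    for l, packed in zip(loci_idx, cache):
        comp = _locus_components(*packed, codes, n_pops)
        if comp is None:
            continue
        a.append(comp[0])
        b.append(comp[1])
        c.append(comp[2])
        used.append(panel.loci[l])
    return np.array(a), np.array(b), np.array(c), used


def _resolve_loci(panel: GenotypePanel, loci) -> np.ndarray:
    if loci is None:
        return np.arange(panel.n_loci)
    unknown = [l for l in loci if l not in panel.loci]
    if unknown:
        raise ReferenceError_(f"unknown loci: {unknown}")
    pos = {name: k for k, name in enumerate(panel.loci)}
    return np.array([pos[l] for l in loci], dtype=np.int64)


def _pop_codes(panel: GenotypePanel):
    labels = panel.population_labels
    if len(labels) < 2:
        raise InputError("theta needs at least two populations")
    pos = {p: k for k, p in enumerate(labels)}
    return np.array([pos[str(p)] for p in panel.populations], dtype=np.int64), len(labels)


@dataclass
class FstEstimate:
    """Multilocus theta with its per-locus components and uncertainty."""

    theta: float
    loci_used: list[str]
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    se: float | None = None
    p_value: float | None = None
    n_permutations: int | None = None
    excluded: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "theta": self.theta,
            "se": self.se,
            "p_value": self.p_value,
            "n_loci_used": len(self.loci_used),
            "n_permutations": self.n_permutations,
            "excluded": list(self.excluded),
        }


def wc_theta(panel: GenotypePanel, loci: list[str] | None = None) -> FstEstimate:
    """Multilocus Weir-Cockerham theta (ratio of summed components).

    Loci monomorphic across all sampled populations are excluded; negative
    per-locus components are retained so the ratio-of-sums stays unbiased.
    """
    a, b, c, used = _components(panel, loci)
    if len(used) == 0:
        raise EstimationError("no polymorphic locus shared between populations")
    denom = float((a + b + c).sum())
    if denom <= 0:
        raise EstimationError("zero total variance across loci; theta undefined")
    return FstEstimate(theta=float(a.sum()) / denom, loci_used=used, a=a, b=b, c=c)


def jackknife_se(panel: GenotypePanel, loci: list[str] | None = None) -> float:
    """Delete-one-locus jackknife standard error of multilocus theta."""
    a, b, c, used = _components(panel, loci)
    L = len(used)
    if L < 2:
        raise PrecisionError(f"jackknife needs at least 2 informative loci, got {L}")
    tot_a = a.sum()
    tot_all = (a + b + c).sum()
    denom = tot_all - (a + b + c)
    if np.any(denom <= 0):
        raise PrecisionError("a delete-one denominator is non-positive")
    pseudo = (tot_a - a) / denom
    return float(np.sqrt((L - 1) / L * ((pseudo - pseudo.mean()) ** 2).sum()))


def permutation_test(
    panel: GenotypePanel,
    n_perm: int = 1000,
    seed: int = 0,
    loci: list[str] | None = None,
) -> float:
    """Permutation p-value for theta > 0.

    Individuals (both alleles together) are shuffled across population
    labels; p = (1 + #{theta_perm >= theta_obs}) / (n_perm + 1).
    """
    if n_perm < 100:
        raise InputError(f"n_perm must be >= 100, got {n_perm}")
    loci_idx = _resolve_loci(panel, loci)
    codes, n_pops = _pop_codes(panel)
    cache = _locus_cache(panel, loci_idx)

    def theta_for(perm_codes: np.ndarray) -> float | None:
        sa = sb = sc = 0.0
        any_used = False
        for packed in cache:
            comp = _locus_components(*packed, perm_codes, n_pops)
            if comp is None:
                continue
            any_used = True
            sa += comp[0]
            sb += comp[1]
            sc += comp[2]
        if not any_used or (sa + sb + sc) <= 0:
            return None
        return sa / (sa + sb + sc)

    obs = theta_for(codes)
    if obs is None:
        raise EstimationError("theta undefined on observed panel")
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        t = theta_for(perm)
        if t is not None and t >= obs:
            exceed += 1
    return (1 + exceed) / (n_perm + 1)


def exclude_loci(panel: GenotypePanel, names: list[str]) -> GenotypePanel:
    """Functional alias for :meth:`GenotypePanel.exclude_loci`."""
    return panel.exclude_loci(names)


def fst_estimate(
    panel: GenotypePanel,
    exclude: list[str] = (),
    n_perm: int = 1000,
    seed: int = 0,
) -> FstEstimate:
    """Point estimate + jackknife SE + permutation p in one call."""
    work = panel.exclude_loci(list(exclude)) if exclude else panel
    est = wc_theta(work)
    est.excluded = list(exclude)
    if len(est.loci_used) >= 2:
        est.se = jackknife_se(work)
    est.p_value = permutation_test(work, n_perm=n_perm, seed=seed)
    est.n_permutations = n_perm
    return est
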