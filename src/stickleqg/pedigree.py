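"""Pedigrees and the additive (numerator) relationship matrix.

The animal model treats each individual's additive genetic value as a random
effect whose covariance is proportional to the numerator relationship matrix
``A`` implied by the pedigree.  This module builds validated pedigrees
(typically one-generation paternal half-sib designs: each sire mated to two
dams), computes ``A`` by the tabular method, and computes ``A``:sup:`-1`
directly from the pedigree by Henderson's rules so the MCMC sampler never has
to invert a dense matrix.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp


class PedigreeError(ValueError):
    """Base class for pedigree validation failures."""


class PedigreeStructureError(PedigreeError):
    """Cycles, self-parenthood, or duplicated individual ids."""


class UnknownParentError(PedigreeError):
    """A sire or dam id that is not itself a pedigree record."""


class PopulationMismatchError(PedigreeError):
    """Parent and offspring assigned to different populations."""


UNKNOWN = frozenset(("", "0", "NA", "na", "None"))


def _clean_parent(value) -> str | None:
    if value is None:
        return None
    if isinstance(value, float) and np.isnan(value):
        return None
    s = str(value).strip()
    return None if s in UNKNOWN else s


@dataclass(frozen=True)
class PedigreeRecord:
    id: str
    sire: str | None
    dam: str | None
    population: str


class Pedigree:
    """A validated, topologically sorted pedigree.

    Parents always precede their offspring in the internal ordering (stable
    with respect to insertion order among unrelated individuals), which is
    the ordering used for the relationship matrix and by the sampler.

    Attributes
    ----------
    ids : list of str
        Individual identifiers in topological order.
    sire_idx, dam_idx : ndarray of int
        Position of each individual's sire/dam in ``ids`` (-1 = unknown,
        i.e. a base-population parent).
    population : ndarray of str
        Population label per individual.
    """

    def __init__(self, records: Iterable[PedigreeRecord | tuple]):
        recs = []
        for r in records:
            if not isinstance(r, PedigreeRecord):
                iid, sire, dam, pop = r
                r = PedigreeRecord(str(iid), _clean_parent(sire), _clean_parent(dam), str(pop))
            recs.append(r)

        seen: dict[str, PedigreeRecord] = {}
        for r in recs:
            if r.id in seen:
                raise PedigreeStructureError(f"duplicate individual id {r.id!r}")
            seen[r.id] = r

        for r in recs:
            for role, par in (("sire", r.sire), ("dam", r.dam)):
                if par is None:
                    continue
                if par == r.id:
                    raise PedigreeStructureError(f"{r.id!r} listed as its own {role}")
                if par not in seen:
                    raise UnknownParentError(f"{role} {par!r} of {r.id!r} has no pedigree record")
                if seen[par].population != r.population:
                    raise PopulationMismatchError(
                        f"{role} {par!r} (population {seen[par].population!r}) does not match "
                        f"offspring {r.id!r} (population {r.population!r})"
                    )

        order = self._toposort(recs)
        self.ids: list[str] = [r.id for r in order]
        self.index: dict[str, int] = {iid: i for i, iid in enumerate(self.ids)}
        self.sire_idx = np.array(
            [self.index[r.sire] if r.sire is not None else -1 for r in order], dtype=np.int64
        )
        self.dam_idx = np.array(
            [self.index[r.dam] if r.dam is not None else -1 for r in order], dtype=np.int64
        )
        self.population = np.array([r.population for r in order], dtype=object)

    @staticmethod
    def _toposort(recs: list[PedigreeRecord]) -> list[PedigreeRecord]:
        # Kahn's algorithm, FIFO over insertion order for stability.
        by_id = {r.id: r for r in recs}
        children: dict[str, list[str]] = {r.id: [] for r in recs}
        indeg = {r.id: 0 for r in recs}
        for r in recs:
            for par in (r.sire, r.dam):
                if par is not None:
                    children[par].append(r.id)
                    indeg[r.id] += 1
        queue = [r.id for r in recs if indeg[r.id] == 0]
        out: list[PedigreeRecord] = []
        head = 0
        while head < len(queue):
            iid = queue[head]
            head += 1
            out.append(by_id[iid])
            for ch in children[iid]:
                indeg[ch] -= 1
                if indeg[ch] == 0:
                    queue.append(ch)
        if len(out) != len(recs):
            cyclic = sorted(set(by_id) - {r.id for r in out})
            raise PedigreeStructureError(f"pedigree contains a cycle involving {cyclic[:5]}")
        return out

    # ------------------------------------------------------------------ #
    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, iid: str) -> bool:
        return iid in self.index

    @property
    def n_founders(self) -> int:
        return int(np.sum((self.sire_idx < 0) & (self.dam_idx < 0)))

    @property
    def founders(self) -> list[str]:
        mask = (self.sire_idx < 0) & (self.dam_idx < 0)
        return [iid for iid, m in zip(self.ids, mask) if m]

    def records(self) -> list[PedigreeRecord]:
        return [
            PedigreeRecord(
                iid,
                self.ids[s] if s >= 0 else None,
                self.ids[d] if d >= 0 else None,
                pop,
            )
            for iid, s, d, pop in zip(self.ids, self.sire_idx, self.dam_idx, self.population)
        ]

    def dam_of(self, iid: str) -> str | None:
        d = self.dam_idx[self.index[iid]]
        return self.ids[d] if d >= 0 else None

    # ------------------------------------------------------------------ #
    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "Pedigree":
        """Build from a dataframe with columns id, sire, dam, population."""
        return cls(
            (row.id, row.sire, row.dam, row.population)
            for row in frame.itertuples(index=False)
        )

    @classmethod
    def read_csv(cls, path) -> "Pedigree":
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
        return cls.from_frame(frame)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": ["" if s < 0 else self.ids[s] for s in self.sire_idx],
                "dam": ["" if d < 0 else self.ids[d] for d in self.dam_idx],
                "population": self.population,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def build_pedigree(crosses: pd.DataFrame) -> Pedigree:
    """Build a one-generation pedigree from a cross table.

    Parameters
    ----------
    crosses : DataFrame
        One row per sire x dam cross with columns ``sire``, ``dam``,
        ``n_offspring`` and optionally ``population`` (default "pop1").
        Offspring ids are generated as ``"<sire>_<dam>_o<k>"``.

    The paternal half-sib design mated each sire to two dams, but any valid
    cross table is accepted.
    """
    records: list[tuple] = []
    seen_parents: set[str] = set()
    for row in crosses.itertuples(index=False):
        pop = str(getattr(row, "population", "pop1"))
        sire, dam = str(row.sire), str(row.dam)
        for par in (sire, dam):
            if par not in seen_parents:
                records.append((par, None, None, pop))
                seen_parents.add(par)
        for k in range(int(row.n_offspring)):
            records.append((f"{sire}_{dam}_o{k + 1}", sire, dam, pop))
    return Pedigree(records)


def additive_relationship(ped: Pedigree) -> np.ndarray:
    """Numerator relationship matrix A by the tabular method.

    Founders are taken as non-inbred and mutually unrelated.  Row order
    matches ``ped.ids``.  A_ii = 1 + A_{sd}/2 and
    A_ij = (A_{js} + A_{jd}) / 2 for j preceding i.
    """
    n = len(ped)
    A = np.zeros((n, n))
    s, d = ped.sire_idx, ped.dam_idx
    for i in range(n):
        si, di = s[i], d[i]
        if si >= 0 and di >= 0:
            A[i, i] = 1.0 + 0.5 * A[si, di]
        else:
            A[i, i] = 1.0
        row = np.zeros(i)
        if si >= 0:
            row += 0.5 * A[si, :i]
        if di >= 0:
            row += 0.5 * A[di, :i]
        A[i, :i] = row
        A[:i, i] = row
    return A


def _mendelian_variances(ped: Pedigree) -> np.ndarray:
    """Variance of the Mendelian-sampling deviation for each individual.

    d_i = A_ii - (A_ss + A_dd + 2 A_sd)/4 over known parents; with founders
    non-inbred this is 1, 3/4 or 1/2 for 0, 1 or 2 known parents in a
    one-generation design, and the general inbreeding-aware value otherwise
    (parental diagonal entries come from the tabular A).
    """
    n = len(ped)
    s, d = ped.sire_idx, ped.dam_idx
    # Parental inbreeding is needed only when some parent is itself a
    # non-founder; founders are non-inbred and unrelated by assumption.
    parents_are_founders = np.all(
        (s < 0) | ((ped.sire_idx[np.maximum(s, 0)] < 0) & (ped.dam_idx[np.maximum(s, 0)] < 0))
    ) and np.all(
        (d < 0) | ((ped.sire_idx[np.maximum(d, 0)] < 0) & (ped.dam_idx[np.maximum(d, 0)] < 0))
    )
    if parents_are_founders:
        diag = np.ones(n)
    else:
        diag = np.diag(additive_relationship(ped)).copy()
    # var(a_i - (a_s + a_d)/2): the mate-covariance term of A_ii cancels,
    # leaving d_i = 1 - (A_ss + A_dd)/4 over the known parents.
    dvec = np.ones(n)
    both = (s >= 0) & (d >= 0)
    one_s = (s >= 0) & (d < 0)
    one_d = (s < 0) & (d >= 0)
    dvec[both] = 1.0 - 0.25 * (diag[s[both]] + diag[d[both]])
    dvec[one_s] = 1.0 - 0.25 * diag[s[one_s]]
    dvec[one_d] = 1.0 - 0.25 * diag[d[one_d]]
    return dvec


def relationship_inverse(ped_or_A: "Pedigree | np.ndarray", dense: bool = False):
    """Inverse of the numerator relationship matrix.

    Given a :class:`Pedigree`, A^-1 is assembled directly by Henderson's
    rules (sparse, no dense inversion): for each individual i with
    Mendelian-sampling variance d_i, add (1/d_i) * w w^T where w has 1 at i
    and -1/2 at each known parent.  Given a dense matrix, it is inverted
    numerically.

    Returns a CSR sparse matrix unless ``dense=True``.
    """
    if isinstance(ped_or_A, np.ndarray):
        A = ped_or_A
        try:
            Ainv = np.linalg.inv(A)
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(f"relationship matrix is singular: {err}") from err
        return Ainv if dense else sp.csr_matrix(Ainv)

    ped = ped_or_A
    n = len(ped)
    dvec = _mendelian_variances(ped)
    if np.any(dvec <= 1e-12):
        bad = [ped.ids[i] for i in np.where(dvec <= 1e-12)[0][:5]]
        raise np.linalg.LinAlgError(
            f"singular relationship matrix: zero Mendelian-sampling variance for {bad}"
        )
    rows, cols, vals = [], [], []
    s, d = ped.sire_idx, ped.dam_idx
    for i in range(n):
        w_idx = [i]
        w_val = [1.0]
        if s[i] >= 0:
            w_idx.append(s[i])
            w_val.append(-0.5)
        if d[i] >= 0:
            w_idx.append(d[i])
            w_val.append(-0.5)
        inv_d = 1.0 / dvec[i]
        for a, va in zip(w_idx, w_val):
            for b, vb in zip(w_idx, w_val):
                rows.append(a)
                cols.append(b)
                vals.append(inv_d * va * vb)
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    Ainv.sum_duplicates()
    return Ainv.toarray() if dense else Ainv
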