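"""Numerator relationship machinery for the animal-model genetic prior.

A pedigree is an ordered list of (animal, sire, dam) triples with parents
preceding offspring.  From it we compute inbreeding coefficients ``F`` by a
Meuwissen-Luo style decomposition (A = L D L', accumulating the diagonal of
A one animal at a time) and the sparse inverse of the numerator relationship
matrix A by Henderson's rules with the inbreeding-adjusted Mendelian-sampling
variance.  Unknown parents are treated as unrelated, non-inbred founders from
a single base population.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import scipy.sparse as sp
from numba import njit

UNKNOWN = {None, 0, "0", "", "NA", "."}


class PedigreeError(ValueError):
    pass


def _norm_id(x):
    """Normalise an id token: all-digit strings become ints, unknown -> None."""
    if x in UNKNOWN:
        return None
    if isinstance(x, str):
        x = x.strip()
        if x in UNKNOWN:
            return None
        if x.isdigit():
            xi = int(x)
            return None if xi == 0 else xi
        return x
    if isinstance(x, (int, np.integer)):
        xi = int(x)
        return None if xi == 0 else xi
    return x


@dataclass
class Pedigree:
    """Topologically ordered pedigree with integer-indexed parent pointers."""

    ids: list
    sire_idx: np.ndarray  # int64, -1 = unknown
    dam_idx: np.ndarray
    id_index: dict = field(repr=False)

    @classmethod
    def from_records(cls, triples: Iterable[tuple]) -> "Pedigree":
        ids: list = []
        id_index: dict = {}
        sires: list[int] = []
        dams: list[int] = []
        for animal, sire, dam in triples:
            animal = _norm_id(animal)
            if animal is None:
                raise PedigreeError("animal id may not be the unknown code")
            if animal in id_index:
                raise PedigreeError(f"duplicate animal id {animal!r}")
            pidx = []
            for parent in (sire, dam):
                parent = _norm_id(parent)
                if parent is None:
                    pidx.append(-1)
                    continue
                if parent == animal:
                    raise PedigreeError(f"animal {animal!r} is its own parent")
                j = id_index.get(parent)
                if j is None:
                    raise PedigreeError(
                        f"parent {parent!r} of {animal!r} does not precede it: "
                        "pedigree must be topologically ordered with all parents listed"
                    )
                pidx.append(j)
            id_index[animal] = len(ids)
            ids.append(animal)
            sires.append(pidx[0])
            dams.append(pidx[1])
        return cls(
            ids=ids,
            sire_idx=np.asarray(sires, dtype=np.int64),
            dam_idx=np.asarray(dams, dtype=np.int64),
            id_index=id_index,
        )

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def is_founder(self) -> np.ndarray:
        return (self.sire_idx < 0) & (self.dam_idx < 0)

    def triples(self):
        for i, a in enumerate(self.ids):
            s = self.ids[self.sire_idx[i]] if self.sire_idx[i] >= 0 else None
            d = self.ids[self.dam_idx[i]] if self.dam_idx[i] >= 0 else None
            yield a, s, d


def read_pedigree(path) -> Pedigree:
    """Read a 3-column (animal, sire, dam) TSV/CSV; 0 codes an unknown parent."""
    rows = []
    text = Path(path).read_text()
    for ln, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        sep = "\t" if "\t" in line else ","
        parts = [p.strip() for p in line.split(sep)]
        if ln == 1 and not parts[0].isdigit() and parts[0].lower() in ("animal", "id"):
            continue  # optional header
        if len(parts) < 3:
            raise PedigreeError(f"line {ln}: expected 3 columns, got {len(parts)}")
        rows.append((parts[0], parts[1], parts[2]))
    return Pedigree.from_records(rows)


def write_pedigree(pedigree: Pedigree, path) -> None:
    with open(path, "w") as fh:
        fh.write("animal\tsire\tdam\n")
        for a, s, d in pedigree.triples():
            fh.write(f"{a}\t{s if s is not None else 0}\t{d if d is not None else 0}\n")


@njit(cache=False)
def _inbreeding_scan(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """F by accumulating the diagonal of A = L D L' one animal at a time.

    For animal i the row of L restricted to its ancestors is generated by a
    top-down sweep (each visited ancestor passes half its weight to each known
    parent); a_ii = sum_j w_j^2 * D_j and F_i = a_ii - 1.
    """
    n = sire.shape[0]
    F = np.zeros(n)
    D = np.empty(n)
    w = np.zeros(n)
    for i in range(n):
        s, d = sire[i], dam[i]
        if s >= 0 and d >= 0:
            D[i] = 0.5 - 0.25 * (F[s] + F[d])
        elif s >= 0:
            D[i] = 0.75 - 0.25 * F[s]
        elif d >= 0:
            D[i] = 0.75 - 0.25 * F[d]
        else:
            D[i] = 1.0
        if s < 0 or d < 0:
            continue  # an animal with an unknown parent cannot be inbred
        w[: i + 1] = 0.0
        w[i] = 1.0
        aii = 0.0
        for j in range(i, -1, -1):
            wj = w[j]
            if wj == 0.0:
                continue
            aii += wj * wj * D[j]
            sj, dj = sire[j], dam[j]
            if sj >= 0:
                w[sj] += 0.5 * wj
            if dj >= 0:
                w[dj] += 0.5 * wj
        F[i] = aii - 1.0
    return F


def inbreeding_array(pedigree: Pedigree) -> np.ndarray:
    """Inbreeding coefficients in pedigree order."""
    return _inbreeding_scan(pedigree.sire_idx, pedigree.dam_idx)


def compute_inbreeding(pedigree: Pedigree) -> dict:
    """Map animal id -> inbreeding coefficient F (0 for founders)."""
    F = inbreeding_array(pedigree)
    return {a: float(F[i]) for i, a in enumerate(pedigree.ids)}


def mendelian_variance(pedigree: Pedigree, F: np.ndarray | None = None) -> np.ndarray:
    """Per-animal Mendelian-sampling variance share d_i.

    d = 1 with no known parent, 0.75 - F_known/4 with one, and
    0.5 - (F_s + F_d)/4 with both, scaling the within-family deviation from
    the parental average.
    """
    if F is None:
        F = inbreeding_array(pedigree)
    s, d = pedigree.sire_idx, pedigree.dam_idx
    out = np.ones(pedigree.n)
    both = (s >= 0) & (d >= 0)
    out[both] = 0.5 - 0.25 * (F[s[both]] + F[d[both]])
    only_s = (s >= 0) & (d < 0)
    out[only_s] = 0.75 - 0.25 * F[s[only_s]]
    only_d = (s < 0) & (d >= 0)
    out[only_d] = 0.75 - 0.25 * F[d[only_d]]
    return out


def build_a_inverse(
    pedigree: Pedigree,
    inbreeding: Mapping | np.ndarray | None = None,
) -> sp.csr_matrix:
    """Sparse inverse of the numerator relationship matrix (Henderson's rules).

    Each animal contributes alpha = 1/d_i to its own diagonal, -alpha/2 to the
    animal-parent cells and alpha/4 to the parent-parent cells, with d_i the
    inbreeding-adjusted Mendelian-sampling variance share.
    """
    if inbreeding is None:
        F = inbreeding_array(pedigree)
    elif isinstance(inbreeding, np.ndarray):
        F = inbreeding
    else:
        try:
            F = np.array([inbreeding[a] for a in pedigree.ids], dtype=float)
        except KeyError as exc:
            raise PedigreeError(f"inbreeding map is missing animal {exc.args[0]!r}")
    d = mendelian_variance(pedigree, F)
    n = pedigree.n
    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    alpha = 1.0 / d
    idx = np.arange(n, dtype=np.int64)

    def add(r, c, v):
        rows.append(r)
        cols.append(c)
        vals.append(v)

    add(idx, idx, alpha)
    for parent in (pedigree.sire_idx, pedigree.dam_idx):
        m = parent >= 0
        add(idx[m], parent[m], -0.5 * alpha[m])
        add(parent[m], idx[m], -0.5 * alpha[m])
        add(parent[m], parent[m], 0.25 * alpha[m])
    both = (pedigree.sire_idx >= 0) & (pedigree.dam_idx >= 0)
    s, dd = pedigree.sire_idx[both], pedigree.dam_idx[both]
    add(s, dd, 0.25 * alpha[both])
    add(dd, s, 0.25 * alpha[both])
    ai = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    ).tocsr()
    ai.sum_duplicates()
    return ai


def write_a_inverse_coo(ai: sp.spmatrix, path) -> None:
    """Dump A-inverse in (i, j, value) coordinate text format for inspection."""
    coo = ai.tocoo()
    with open(path, "w") as fh:
        fh.write("i\tj\tvalue\n")
        for i, j, v in zip(coo.row, coo.col, coo.data):
            fh.write(f"{i}\t{j}\t{v:.12g}\n")
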