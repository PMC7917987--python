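"""Pedigree relationship algebra.

The numerator relationship matrix **A** encodes expected additive
genetic covariances between animals implied by the pedigree:
``a(i,j) = 0.5*(a(s_i,j) + a(d_i,j))`` for an animal ``i`` with parents
``s_i, d_i`` and an earlier animal ``j``, and
``a(i,i) = 1 + 0.5*a(s_i,d_i)`` (the excess over 1 being the inbreeding
coefficient F). This module provides the dense tabular construction of
A, a Meuwissen–Luo style inbreeding recursion that never forms A, the
sparse inverse of A via Henderson's rules with inbreeding-corrected
Mendelian-sampling variances, and the genotyped-block extraction A22
used by single-step evaluations.

Unknown parents are treated as unrelated, non-inbred founders.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

#: sentinel used in pedigree files for an unknown parent
UNKNOWN_PARENT = "0"


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (duplicates, cycles, ...)."""


@dataclass
class PedigreeTable:
    """Animal/sire/dam/birth-year records.

    Ids are arbitrary strings externally; after :func:`sort_pedigree`
    every parent row precedes its offspring row and dense 0..n-1 codes
    (``sire_idx``/``dam_idx``, -1 for unknown) index into the table.
    """

    animal: np.ndarray
    sire: np.ndarray
    dam: np.ndarray
    birth_year: np.ndarray
    _index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.animal = np.asarray(self.animal, dtype=object)
        self.sire = np.asarray(self.sire, dtype=object)
        self.dam = np.asarray(self.dam, dtype=object)
        self.birth_year = np.asarray(self.birth_year, dtype=np.int64)
        ids, counts = np.unique(self.animal, return_counts=True)
        dup = ids[counts > 1]
        if dup.size:
            raise PedigreeError(f"duplicate animal id(s): {', '.join(map(str, dup[:10]))}")
        for lab, par in (("sire", self.sire), ("dam", self.dam)):
            own = self.animal == par
            if own.any():
                bad = self.animal[own][0]
                raise PedigreeError(f"animal {bad!r} is its own {lab} (cycle: [{bad!r}])")
        self._index = {a: i for i, a in enumerate(self.animal)}

    @property
    def n(self) -> int:
        return len(self.animal)

    def position(self, animal_id: str) -> int:
        try:
            return self._index[animal_id]
        except KeyError:
            raise KeyError(f"animal {animal_id!r} not in pedigree") from None

    def parent_codes(self) -> tuple[np.ndarray, np.ndarray]:
        """Dense integer codes of sire and dam (-1 = unknown founder parent)."""
        def code(par):
            out = np.empty(self.n, dtype=np.int64)
            for i, pid in enumerate(par):
                if pid == UNKNOWN_PARENT:
                    out[i] = -1
                else:
                    j = self._index.get(pid, -2)
                    if j == -2:
                        raise PedigreeError(
                            f"parent id {pid!r} does not appear as an animal; "
                            "add it as a founder row"
                        )
                    out[i] = j
            return out

        return code(self.sire), code(self.dam)

    def is_sorted(self) -> bool:
        s, d = self.parent_codes()
        i = np.arange(self.n)
        return bool(np.all(s < i) and np.all(d < i))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal": self.animal,
                "sire": self.sire,
                "dam": self.dam,
                "birth_year": self.birth_year,
            }
        )

    def id_map(self) -> pd.DataFrame:
        """External id -> 1-based dense code, in current row order."""
        return pd.DataFrame({"animal": self.animal, "code": np.arange(1, self.n + 1)})


def _find_cycle(children: dict, in_deg: dict, remaining: set) -> list:
    # walk parent links inside the unresolved set until a node repeats
    node = next(iter(remaining))
    seen = {}
    path = []
    while node not in seen:
        seen[node] = len(path)
        path.append(node)
        nxt = [p for p in children.get(node, ()) if p in remaining]
        if not nxt:  # pragma: no cover - defensive
            break
        node = nxt[0]
    return path[seen.get(node, 0):]


def sort_pedigree(ped: PedigreeTable) -> PedigreeTable:
    """Topologically sort so parents precede offspring.

    Stable: animals of equal pedigree depth keep their input order.
    Raises :class:`PedigreeError` listing the cycle if ancestry loops.
    """
    n = ped.n
    idx = ped._index
    parents = []
    for i in range(n):
        pp = []
        for pid in (ped.sire[i], ped.dam[i]):
            if pid != UNKNOWN_PARENT and pid in idx:
                pp.append(idx[pid])
        parents.append(pp)
    depth = np.full(n, -1, dtype=np.int64)
    # Kahn-style resolution of pedigree depth
    children = [[] for _ in range(n)]
    indeg = np.zeros(n, dtype=np.int64)
    for i, pp in enumerate(parents):
        indeg[i] = len(pp)
        for p in pp:
            children[p].append(i)
    queue = [i for i in range(n) if indeg[i] == 0]
    for i in queue:
        depth[i] = 0
    resolved = 0
    while queue:
        nxt = []
        for i in queue:
            resolved += 1
            for c in children[i]:
                indeg[c] -= 1
                depth[c] = max(depth[c], depth[i] + 1)
                if indeg[c] == 0:
                    nxt.append(c)
        queue = nxt
    if resolved < n:
        remaining = {i for i in range(n) if indeg[i] > 0}
        par_map = {i: parents[i] for i in remaining}
        cyc = _find_cycle(par_map, indeg, remaining)
        names = [repr(ped.animal[i]) for i in cyc]
        raise PedigreeError(f"cyclic ancestry: [{', '.join(names)}]")
    order = np.lexsort((np.arange(n), depth))
    return PedigreeTable(
        ped.animal[order], ped.sire[order], ped.dam[order], ped.birth_year[order]
    )


def _require_sorted(ped: PedigreeTable) -> tuple[np.ndarray, np.ndarray]:
    s, d = ped.parent_codes()
    i = np.arange(ped.n)
    if np.any(s >= i) or np.any(d >= i):
        raise PedigreeError("pedigree is not sorted (a parent row follows its offspring); call sort_pedigree first")
    return s, d


def build_A(ped: PedigreeTable) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular method."""
    s, d = _require_sorted(ped)
    n = ped.n
    A = np.zeros((n, n))
    for i in range(n):
        si, di = s[i], d[i]
        if si >= 0 and di >= 0:
            if i:
                A[i, :i] = 0.5 * (A[si, :i] + A[di, :i])
            A[i, i] = 1.0 + 0.5 * A[si, di]
        elif si >= 0 or di >= 0:
            p = si if si >= 0 else di
            if i:
                A[i, :i] = 0.5 * A[p, :i]
            A[i, i] = 1.0
        else:
            A[i, i] = 1.0
        A[:i, i] = A[i, :i]
    return A


def _mendelian_variances(s: np.ndarray, d: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Variance of the Mendelian sampling deviation per animal."""
    n = len(s)
    D = np.empty(n)
    for i in range(n):
        si, di = s[i], d[i]
        if si >= 0 and di >= 0:
            D[i] = 0.5 - 0.25 * (F[si] + F[di])
        elif si >= 0 or di >= 0:
            p = si if si >= 0 else di
            D[i] = 0.75 - 0.25 * F[p]
        else:
            D[i] = 1.0
    return D


def inbreeding(ped: PedigreeTable) -> np.ndarray:
    """Inbreeding coefficients F without forming dense A (Meuwissen–Luo).

    For each animal the diagonal a(i,i) = sum_j L_ij^2 D_j is accumulated
    over its ancestor closure, processing ancestors in decreasing code
    order so gene contributions L aggregate before use; F_i = a(i,i) - 1.
    """
    s, d = _require_sorted(ped)
    n = ped.n
    F = np.zeros(n)
    D = np.empty(n)
    for i in range(n):
        si, di = s[i], d[i]
        if si >= 0 and di >= 0:
            D[i] = 0.5 - 0.25 * (F[si] + F[di])
        elif si >= 0 or di >= 0:
            p = si if si >= 0 else di
            D[i] = 0.75 - 0.25 * F[p]
        else:
            D[i] = 1.0
        if si < 0 or di < 0:
            F[i] = 0.0
            continue
        # accumulate a(i,i) over the ancestor closure of i
        L = {i: 1.0}
        heap = [-i]
        inheap = {i}
        aii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            inheap.discard(j)
            lj = L.pop(j)
            aii += lj * lj * D[j]
            for p in (s[j], d[j]):
                if p >= 0:
                    L[p] = L.get(p, 0.0) + 0.5 * lj
                    if p not in inheap:
                        heapq.heappush(heap, -p)
                        inheap.add(p)
        F[i] = aii - 1.0
    return F


def build_A_inverse(ped: PedigreeTable, F: np.ndarray | None = None) -> sparse.csr_matrix:
    """Sparse A^-1 by Henderson's rules with inbreeding.

    Each animal contributes b = 1/D_i to the (i,i) cell, -b/2 to the
    animal-parent cells and b/4 among known parents, where D_i is the
    Mendelian-sampling variance from :func:`inbreeding`.
    """
    s, d = _require_sorted(ped)
    if F is None:
        F = inbreeding(ped)
    D = _mendelian_variances(s, d, F)
    rows, cols, vals = [], [], []

    def add(i, j, v):
        rows.append(i)
        cols.append(j)
        vals.append(v)

    for i in range(ped.n):
        b = 1.0 / D[i]
        add(i, i, b)
        pp = [p for p in (s[i], d[i]) if p >= 0]
        for p in pp:
            add(i, p, -0.5 * b)
            add(p, i, -0.5 * b)
        for p in pp:
            for q in pp:
                add(p, q, 0.25 * b)
    Ainv = sparse.coo_matrix((vals, (rows, cols)), shape=(ped.n, ped.n))
    return Ainv.tocsr()


def extract_A22(ped: PedigreeTable, genotyped_ids) -> np.ndarray:
    """Genotyped-by-genotyped block of A, in the order of ``genotyped_ids``."""
    pos = np.array([ped.position(g) for g in genotyped_ids], dtype=np.int64)
    A = build_A(ped)
    return A[np.ix_(pos, pos)]


def write_sparse_triplets(path, mat: sparse.spmatrix) -> None:
    """Lower-triangle (i, j, value) export, 1-based codes."""
    coo = sparse.triu(mat.T).T.tocoo()  # lower triangle incl. diagonal
    df = pd.DataFrame({"i": coo.row + 1, "j": coo.col + 1, "value": coo.data})
    df = df.sort_values(["i", "j"], kind="stable")
    df.to_csv(path, index=False, float_format="%.12g")
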