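"""Inbreeding, kinship (coancestry), A-inverse, and generation interval.

The numerator relationship matrix A holds additive relationships
A_ij = 2·C_ij, where the kinship C_ij is the probability that one allele
drawn from i and one from j are identical by descent; A_ii = 1 + F_i with
F_i the inbreeding coefficient (the kinship of i's parents).

Inbreeding coefficients use the Meuwissen & Luo ancestor-traversal
algorithm.  A⁻¹ is assembled directly by the Henderson/Quaas rules with
inbreeding accounted for in the Mendelian-sampling variances; kinship
submatrices are then recovered by sparse-LU solves against A⁻¹, which keeps
memory at O(n·|subset|) even when the subset's ancestry spans the whole
pedigree.  Unknown parents are treated as unrelated, non-inbred founders
throughout (no unknown-parent groups).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import splu

from .pedigree_core import UNKNOWN, Pedigree, require_valid


def _mendelian_variance(F: np.ndarray, sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Within-family (Mendelian-sampling) variance d_i given parental F."""
    f_s = np.where(sire != UNKNOWN, F[np.maximum(sire, 0)], 0.0)
    f_d = np.where(dam != UNKNOWN, F[np.maximum(dam, 0)], 0.0)
    known = (sire != UNKNOWN).astype(float) + (dam != UNKNOWN).astype(float)
    # 1 with no parent known, 0.75 - F_p/4 with one, 0.5 - (F_s+F_d)/4 with two
    return 1.0 - 0.25 * known - 0.25 * (f_s + f_d)


def inbreeding(ped: Pedigree) -> np.ndarray:
    """Inbreeding coefficients by the Meuwissen & Luo algorithm.

    For each animal the traversal accumulates A_ii = Σ_j L_ij²·d_j over its
    ancestors j, visiting ancestors in decreasing topological position so
    every path contribution is folded into a single coefficient per
    ancestor; F_i = A_ii − 1.
    """
    require_valid(ped)
    n = len(ped)
    sire, dam = ped.sire, ped.dam
    F = np.zeros(n)
    d = np.zeros(n)
    for i in range(n):
        d[i] = _mendelian_variance(F, sire[i : i + 1], dam[i : i + 1])[0]
        if sire[i] == UNKNOWN or dam[i] == UNKNOWN:
            F[i] = 0.0
            continue
        # Traverse i and its ancestors from i down to the founders.
        coeff: dict[int, float] = {i: 1.0}
        heap: list[int] = [-i]
        a_ii = 0.0
        while heap:
            j = -heapq.heappop(heap)
            L = coeff.pop(j)
            a_ii += L * L * d[j]
            for p in (sire[j], dam[j]):
                if p != UNKNOWN:
                    if p not in coeff:
                        heapq.heappush(heap, -p)
                    coeff[p] = coeff.get(p, 0.0) + 0.5 * L
        F[i] = a_ii - 1.0
    return F


def inbreeding_table(ped: Pedigree) -> pd.DataFrame:
    return pd.DataFrame({"id": ped.ids, "F": inbreeding(ped)})


def a_inverse(ped: Pedigree) -> sparse.csc_matrix:
    """Sparse inverse of the numerator relationship matrix (Quaas rules).

    Each animal contributes α_i = 1/d_i times the outer product of
    (1, −1/2, −1/2) on (itself, sire, dam), restricted to known parents;
    d_i accounts for parental inbreeding, so A·A⁻¹ = I exactly (to
    floating-point) also on inbred pedigrees.
    """
    require_valid(ped)
    n = len(ped)
    F = inbreeding(ped)
    d = _mendelian_variance(F, ped.sire, ped.dam)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    for i in range(n):
        alpha = 1.0 / d[i]
        parents = [p for p in (ped.sire[i], ped.dam[i]) if p != UNKNOWN]
        rows.append(i); cols.append(i); vals.append(alpha)
        for p in parents:
            rows.extend((i, p)); cols.extend((p, i)); vals.extend((-alpha / 2,) * 2)
            for q in parents:
                rows.append(p); cols.append(q); vals.append(alpha / 4)
    return sparse.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()


@dataclass(frozen=True)
class KinshipMatrix:
    """Symmetric matrix of pairwise kinships for a subset of animals."""

    ids: tuple[str, ...]
    values: np.ndarray  # C_ij; C_ii = 0.5 * (1 + F_i)

    @property
    def relationship(self) -> np.ndarray:
        """Numerator relationship submatrix A = 2C."""
        return 2.0 * self.values

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))


def kinship(ped: Pedigree, subset: list[str] | None = None) -> KinshipMatrix:
    """Pairwise kinship C for ``subset`` (default: all animals).

    Columns of A are obtained by solving A⁻¹ x = e_j with a single sparse LU
    factorisation, then halved; exact (to solver precision) and equal to the
    tabular recursion A_ij = (A_i,sire(j) + A_i,dam(j))/2.
    """
    if subset is None:
        subset = list(ped.ids)
    if not subset:
        raise ValueError("subset must be non-empty")
    idx = np.array([ped.index_of(a) for a in subset], dtype=np.int64)
    n = len(ped)
    lu = splu(a_inverse(ped))
    rhs = np.zeros((n, len(idx)))
    rhs[idx, np.arange(len(idx))] = 1.0
    cols = lu.solve(rhs)  # full A columns for the subset
    A_sub = cols[idx, :]
    A_sub = 0.5 * (A_sub + A_sub.T)  # symmetrise solver noise
    return KinshipMatrix(ids=tuple(subset), values=0.5 * A_sub)


@dataclass(frozen=True)
class GenerationInterval:
    """Mid-parent age distribution and the generation-interval estimate."""

    mid_parent_ages: np.ndarray
    gi: float
    method: str = "midparent"


def generation_interval(ped: Pedigree, method: str = "midparent") -> GenerationInterval:
    """Generation interval from parent ages at offspring birth.

    ``midparent`` (default) averages, per offspring, the sire age and dam
    age at birth, then averages over offspring with both parental years
    known.  ``pathway`` averages parent age within each of the four
    parent-sex × offspring-sex pathways and then averages the pathway means.
    """
    year = ped.birth_year
    has = (
        (year != UNKNOWN)
        & (ped.sire != UNKNOWN) & (ped.dam != UNKNOWN)
        & (year[np.maximum(ped.sire, 0)] != UNKNOWN)
        & (year[np.maximum(ped.dam, 0)] != UNKNOWN)
    )
    if not has.any():
        raise ValueError("no offspring with both parental birth years known")
    off = np.flatnonzero(has)
    sire_age = (year[off] - year[ped.sire[off]]).astype(float)
    dam_age = (year[off] - year[ped.dam[off]]).astype(float)
    mid = 0.5 * (sire_age + dam_age)
    if method == "midparent":
        gi = float(mid.mean())
    elif method == "pathway":
        sex = ped.sex[off]
        means = []
        for ages in (sire_age, dam_age):
            for s in ("M", "F"):
                mask = sex == s
                if mask.any():
                    means.append(float(ages[mask].mean()))
        gi = float(np.mean(means))
    else:
        raise ValueError(f"unknown method {method!r}")
    return GenerationInterval(mid_parent_ages=mid, gi=gi, method=method)
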