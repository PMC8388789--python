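"""Genetic connectedness between management units from an animal model.

Connectedness measures how safely estimated breeding values (EBVs) can be
compared across management units (flocks): units that share no genetic links
confound unit effects with genetic merit, biasing across-unit rankings.

The model is the standard animal model y = Xb + Zu + e with one fixed level
per unit, u ~ (0, A·σu²), e ~ (0, I·σe²), λ = σe²/σu² = (1−h²)/h².
Henderson's mixed-model equations give the coefficient matrix

    M = [X'X   X'Z        ]
        [Z'X   Z'Z + λA⁻¹ ]

whose inverse's animal block C²², scaled by σe², holds the prediction error
variances (PEV, diagonal) and covariances (PEC, off-diagonal) of the EBVs.
Four unit-pair statistics are aggregated over the recorded animals of each
unit:

* PEVD_ind   — mean pairwise PEV of an EBV difference across units
               (smaller = better connected);
* PEVD_group — prediction error variance of the difference of unit-mean
               EBVs (includes within-unit PEC terms);
* CD         — PEVD rescaled by the corresponding relationship variance
               (larger = better connected, ≤ 1);
* r          — prediction-error correlation between units; benchmarks of
               0.05 ("good") and 0.10 ("superior") apply.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import splu

from .pedigree_core import Pedigree, require_valid
from .relatedness import a_inverse, kinship

#: r̄ benchmarks: below GOOD is insufficient for unbiased across-unit ranking.
R_BENCHMARK_GOOD = 0.05
R_BENCHMARK_SUPERIOR = 0.10

_STATISTICS = ("PEVD_ind", "PEVD_group", "CD", "r")


@dataclass(frozen=True)
class RecordsDesign:
    """Phenotype records: one (animal, unit) pair per record.

    Repeated records per animal are allowed; unit membership aggregates over
    distinct recorded animals.
    """

    animals: tuple[str, ...]
    units: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.animals) != len(self.units):
            raise ValueError("animals and units must have equal length")
        if not self.animals:
            raise ValueError("design has no records")

    @property
    def unit_labels(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.units)))

    def unit_members(self) -> dict[str, list[str]]:
        """Distinct recorded animals per unit (insertion order)."""
        members: dict[str, dict[str, None]] = {u: {} for u in self.unit_labels}
        for a, u in zip(self.animals, self.units):
            members[u][a] = None
        return {u: list(d) for u, d in members.items()}

    @classmethod
    def from_frame(cls, df: pd.DataFrame, animal_col: str = "animal_id", unit_col: str = "unit") -> "RecordsDesign":
        return cls(
            animals=tuple(str(a) for a in df[animal_col]),
            units=tuple(str(u) for u in df[unit_col]),
        )


def read_records(path, animal_col: str = "animal_id", unit_col: str = "unit") -> RecordsDesign:
    """Read a records CSV with columns ``animal_id, unit``."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in (animal_col, unit_col):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")
    return RecordsDesign.from_frame(df, animal_col, unit_col)


@dataclass(frozen=True)
class MMESystem:
    """Assembled mixed-model equations for one animal-model design."""

    ped: Pedigree = field(repr=False)
    design: RecordsDesign = field(repr=False)
    unit_labels: tuple[str, ...]
    X: sparse.csr_matrix = field(repr=False)
    Z: sparse.csr_matrix = field(repr=False)
    coefficient_matrix: sparse.csc_matrix = field(repr=False)
    lam: float
    sigma_e2: float

    @property
    def sigma_u2(self) -> float:
        return self.sigma_e2 / self.lam

    @property
    def n_units(self) -> int:
        return len(self.unit_labels)


def build_mme(ped: Pedigree, design: RecordsDesign, h2: float = 0.3, sigma_e2: float = 1.0) -> MMESystem:
    """Assemble Henderson's MME coefficient matrix.

    One fixed-effect level per unit and no separate intercept, so the fixed
    block is full rank and M is positive definite; all pedigree animals
    occupy the random block regardless of whether they carry records.
    """
    if not 0.0 < h2 < 1.0:
        raise ValueError("h2 must lie strictly in (0, 1)")
    if sigma_e2 <= 0:
        raise ValueError("sigma_e2 must be positive")
    require_valid(ped)
    missing = [a for a in set(design.animals) if a not in ped]
    if missing:
        raise ValueError(f"recorded animals not in pedigree: {sorted(missing)[:5]}")
    lam = (1.0 - h2) / h2
    units = design.unit_labels
    unit_pos = {u: k for k, u in enumerate(units)}
    m = len(design.animals)
    n = len(ped)
    p = len(units)
    rows = np.arange(m)
    X = sparse.csr_matrix(
        (np.ones(m), (rows, [unit_pos[u] for u in design.units])), shape=(m, p)
    )
    Z = sparse.csr_matrix(
        (np.ones(m), (rows, [ped.index_of(a) for a in design.animals])), shape=(m, n)
    )
    M = sparse.bmat(
        [[X.T @ X, X.T @ Z], [Z.T @ X, Z.T @ Z + lam * a_inverse(ped)]],
        format="csc",
    )
    return MMESystem(
        ped=ped, design=design, unit_labels=units, X=X, Z=Z,
        coefficient_matrix=M, lam=lam, sigma_e2=sigma_e2,
    )


@dataclass(frozen=True)
class PevPecMatrix:
    """PEV (diagonal) / PEC (off-diagonal) matrix for a set of animals."""

    ids: tuple[str, ...]
    values: np.ndarray  # symmetric, σe² units
    sigma_e2: float

    @property
    def pev(self) -> np.ndarray:
        return np.diag(self.values)

    @property
    def c22(self) -> np.ndarray:
        """Animal block of the inverted coefficient matrix (unscaled)."""
        return self.values / self.sigma_e2


def pev_pec(mme: MMESystem, animals: list[str] | None = None) -> PevPecMatrix:
    """Prediction error (co)variances PEV/PEC = C²²·σe² for ``animals``.

    Computed by sparse-LU column solves against the coefficient matrix
    (default animal set: all distinct recorded animals).  Falls back to a
    dense pseudoinverse if the system is singular beyond round-off.
    """
    if animals is None:
        animals = list(dict.fromkeys(mme.design.animals))
    if not animals:
        raise ValueError("no animals requested")
    p = mme.n_units
    idx = np.array([mme.ped.index_of(a) for a in animals], dtype=np.int64)
    M = mme.coefficient_matrix
    rhs = np.zeros((M.shape[0], len(idx)))
    rhs[p + idx, np.arange(len(idx))] = 1.0
    try:
        cols = splu(M).solve(rhs)
    except RuntimeError:  # singular factorisation
        cols = np.linalg.pinv(M.toarray(), hermitian=True) @ rhs
    C22 = cols[p + idx, :]
    C22 = 0.5 * (C22 + C22.T)
    return PevPecMatrix(ids=tuple(animals), values=C22 * mme.sigma_e2, sigma_e2=mme.sigma_e2)


def _unit_blocks(pp: PevPecMatrix, design: RecordsDesign) -> tuple[list[str], list[np.ndarray]]:
    pos = {a: i for i, a in enumerate(pp.ids)}
    members = design.unit_members()
    units = list(design.unit_labels)
    idx = []
    for u in units:
        try:
            idx.append(np.array([pos[a] for a in members[u]], dtype=np.int64))
        except KeyError as e:
            raise ValueError(f"animal {e} of unit {u!r} missing from PEV/PEC matrix") from None
    return units, idx


def pevd_ind(pp: PevPecMatrix, design: RecordsDesign) -> pd.DataFrame:
    """Mean individual-level PEVD over cross-unit animal pairs.

    Entry (i', j') averages PEV_k + PEV_l − 2·PEC_kl over the n_i'·n_j'
    animal pairs; the diagonal holds the within-unit mean (reported, but
    excluded from summaries).
    """
    units, idx = _unit_blocks(pp, design)
    P = pp.values
    pev = np.diag(P)
    mean_pev = np.array([pev[s].mean() for s in idx])
    q = len(units)
    out = np.empty((q, q))
    for i in range(q):
        for j in range(i, q):
            block = P[np.ix_(idx[i], idx[j])]
            out[i, j] = out[j, i] = mean_pev[i] + mean_pev[j] - 2.0 * block.mean()
    return pd.DataFrame(out, index=units, columns=units)


def pevd_group(pp: PevPecMatrix, design: RecordsDesign) -> pd.DataFrame:
    """Prediction error variance of the difference of unit-mean EBVs.

    var(mean û_i' − mean û_j') = 1'P_ii1/n_i'² + 1'P_jj1/n_j'² −
    2·1'P_ij1/(n_i'·n_j'); exactly zero for a unit against itself.
    """
    units, idx = _unit_blocks(pp, design)
    P = pp.values
    q = len(units)
    block_mean = np.empty((q, q))
    for i in range(q):
        for j in range(i, q):
            block_mean[i, j] = block_mean[j, i] = P[np.ix_(idx[i], idx[j])].mean()
    diag = np.diag(block_mean)
    out = diag[:, None] + diag[None, :] - 2.0 * block_mean
    return pd.DataFrame(out, index=units, columns=units)


def cd_ind(pp: PevPecMatrix, K: np.ndarray, design: RecordsDesign, lam: float) -> pd.DataFrame:
    """Unit-level coefficient of determination of EBV differences.

    CD_i'j' = 1 − λ·Σ(C²²_kk + C²²_ll − 2C²²_kl) / Σ(K_kk + K_ll − 2K_kl),
    the sums running over cross-unit animal pairs, with K the numerator
    relationship matrix over the same animals (same order as ``pp.ids``).
    Same-animal pairs contribute zero to both sums, so the diagonal is
    well-defined for units of ≥ 2 non-identical animals and NaN otherwise.
    """
    if K.shape != pp.values.shape:
        raise ValueError("K must match the PEV/PEC matrix shape and order")
    units, idx = _unit_blocks(pp, design)
    C22 = pp.c22
    q = len(units)
    out = np.empty((q, q))
    for i in range(q):
        for j in range(i, q):
            si, sj = idx[i], idx[j]
            num = (
                len(sj) * C22[si, si].sum()
                + len(si) * C22[sj, sj].sum()
                - 2.0 * C22[np.ix_(si, sj)].sum()
            )
            den = (
                len(sj) * K[si, si].sum()
                + len(si) * K[sj, sj].sum()
                - 2.0 * K[np.ix_(si, sj)].sum()
            )
            if den <= 0:
                if i != j:
                    raise ValueError(
                        f"degenerate relationship structure between units "
                        f"{units[i]!r} and {units[j]!r} (zero K denominator)"
                    )
                out[i, j] = np.nan
            else:
                out[i, j] = 1.0 - lam * num / den
            out[j, i] = out[i, j]
    return pd.DataFrame(out, index=units, columns=units)


def r_individual(pp: PevPecMatrix) -> np.ndarray:
    """Animal-level prediction error correlation r_kl = PEC/√(PEV·PEV)."""
    pev = np.diag(pp.values)
    if np.any(pev <= 0):
        raise ValueError("non-positive PEV encountered")
    d = np.sqrt(pev)
    return pp.values / np.outer(d, d)


def r_stat(pp: PevPecMatrix, design: RecordsDesign) -> pd.DataFrame:
    """Unit-level prediction error correlation.

    r_i'j' = ΣPEC_i'j' / √(ΣPEV_i'i'·ΣPEV_j'j'), the sums running over full
    within/between blocks of the PEV/PEC matrix (so the diagonal is 1 and
    every entry lies in [−1, 1]): the correlation of unit-mean prediction
    errors.
    """
    units, idx = _unit_blocks(pp, design)
    P = pp.values
    q = len(units)
    block_sum = np.empty((q, q))
    for i in range(q):
        for j in range(i, q):
            block_sum[i, j] = block_sum[j, i] = P[np.ix_(idx[i], idx[j])].sum()
    diag = np.diag(block_sum)
    if np.any(diag <= 0):
        bad = [u for u, s in zip(units, diag) if s <= 0]
        raise ValueError(f"non-positive PEV sum for unit(s) {bad}")
    out = block_sum / np.sqrt(np.outer(diag, diag))
    return pd.DataFrame(out, index=units, columns=units)


@dataclass(frozen=True)
class ConnectednessResult:
    """The four unit×unit statistics with per-unit and overall summaries."""

    unit_labels: tuple[str, ...]
    matrices: dict[str, pd.DataFrame] = field(repr=False)
    unit_means: pd.DataFrame = field(repr=False)
    overall_means: pd.Series = field(repr=False)
    n_per_unit: pd.Series = field(repr=False)

    def cross_statistic_correlation(self) -> pd.DataFrame:
        """Pearson correlations between the vectorised off-diagonals."""
        q = len(self.unit_labels)
        iu, ju = np.triu_indices(q, k=1)
        vecs = {s: self.matrices[s].to_numpy()[iu, ju] for s in _STATISTICS}
        return pd.DataFrame(vecs).corr()


def classify_connectedness(r_bar: float) -> str:
    """Benchmark classification of an overall r̄: 0.05 good, 0.10 superior."""
    if r_bar >= R_BENCHMARK_SUPERIOR:
        return "superior"
    if r_bar >= R_BENCHMARK_GOOD:
        return "good"
    return "insufficient"


def summarize_connectedness(matrices: dict[str, pd.DataFrame], design: RecordsDesign) -> ConnectednessResult:
    """Per-unit means over other units, overall means over unit pairs.

    Diagonal (self-pair) entries are excluded: the summaries describe
    between-unit connectedness.
    """
    units = design.unit_labels
    if len(units) < 2:
        raise ValueError("need >= 2 units to summarise connectedness")
    q = len(units)
    off = ~np.eye(q, dtype=bool)
    unit_means = {}
    overall = {}
    for s in _STATISTICS:
        m = matrices[s].to_numpy()
        unit_means[s] = np.array([m[k, off[k]].mean() for k in range(q)])
        iu, ju = np.triu_indices(q, k=1)
        overall[s] = float(m[iu, ju].mean())
    members = design.unit_members()
    return ConnectednessResult(
        unit_labels=units,
        matrices=matrices,
        unit_means=pd.DataFrame(unit_means, index=list(units)),
        overall_means=pd.Series(overall),
        n_per_unit=pd.Series({u: len(members[u]) for u in units}),
    )


def connectedness(
    ped: Pedigree,
    design: RecordsDesign,
    h2: float = 0.3,
    sigma_e2: float = 1.0,
) -> ConnectednessResult:
    """End-to-end connectedness analysis: MME → PEV/PEC → four statistics."""
    mme = build_mme(ped, design, h2=h2, sigma_e2=sigma_e2)
    pp = pev_pec(mme)
    K = kinship(ped, list(pp.ids)).relationship
    matrices = {
        "PEVD_ind": pevd_ind(pp, design),
        "PEVD_group": pevd_group(pp, design),
        "CD": cd_ind(pp, K, design, mme.lam),
        "r": r_stat(pp, design),
    }
    return summarize_connectedness(matrices, design)
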