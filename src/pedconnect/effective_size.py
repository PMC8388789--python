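"""Effective population size from the mean rate of increase in coancestry.

For a pair of animals (i, j) with kinship C_ij and equivalent complete
generations g_i, g_j, the per-generation rate of coancestry increase is

    ΔC_ij = 1 − (1 − C_ij)^(1 / ((g_i + g_j)/2))

and the realised effective population size of a reference population is
Ne = 1 / (2·mean ΔC) over all unordered distinct member pairs.  A reference
population is a birth-year window optionally gated on pedigree quality
(minimum PCI / NEG / NFG), because pairs with shallow recorded ancestry
understate their true coancestry and inflate Ne.

Sliding birth-year windows (one generation interval wide) yield a series of
Ne and mean-F values whose ordinary-least-squares slope on the window index
estimates the per-generation trend (ΔNe, ΔF).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree_core import UNKNOWN, Pedigree
from .completeness_metrics import DEFAULT_PCI_DEPTH, neg_all, nfg_all, pci_all
from .relatedness import inbreeding, kinship


@dataclass(frozen=True)
class ReferencePopulation:
    """Birth-year window plus pedigree-quality constraints, resolved to ids."""

    start: int
    end: int  # inclusive
    members: tuple[str, ...]
    min_pci: float | None = None
    min_neg: float | None = None
    min_nfg: int | None = None
    label: str = ""

    @property
    def nt(self) -> int:
        return len(self.members)


def reference_population(
    ped: Pedigree,
    start: int,
    end: int,
    min_pci: float | None = None,
    min_neg: float | None = None,
    min_nfg: int | None = None,
    pci_depth: int = DEFAULT_PCI_DEPTH,
    label: str = "",
) -> ReferencePopulation:
    """Select animals born in [start, end] meeting all active constraints.

    Animals with unknown birth year are excluded.
    """
    if end < start:
        raise ValueError("window end before start")
    mask = (ped.birth_year != UNKNOWN) & (ped.birth_year >= start) & (ped.birth_year <= end)
    if min_pci is not None:
        mask &= pci_all(ped, pci_depth) >= min_pci
    if min_neg is not None:
        mask &= neg_all(ped) >= min_neg
    if min_nfg is not None:
        mask &= nfg_all(ped) >= min_nfg
    members = tuple(np.array(ped.ids, dtype=object)[mask])
    return ReferencePopulation(
        start=start, end=end, members=members,
        min_pci=min_pci, min_neg=min_neg, min_nfg=min_nfg,
        label=label or f"{start}-{end}",
    )


def pairwise_delta_c(c_ij: float, g_i: float, g_j: float) -> float:
    """Per-generation coancestry increase for one pair."""
    if g_i + g_j <= 0:
        raise ValueError("undefined rate: g_i + g_j must be positive")
    if not 0.0 <= c_ij < 1.0:
        raise ValueError("kinship must lie in [0, 1)")
    return 1.0 - (1.0 - c_ij) ** (2.0 / (g_i + g_j))


@dataclass(frozen=True)
class NeEstimate:
    """Realised Ne for one reference population / window."""

    label: str
    ne: float  # inf when mean ΔC = 0
    mean_delta_c: float
    nt: int
    mean_f: float

    @property
    def ne_nt_ratio(self) -> float:
        return self.ne / self.nt if self.nt else float("nan")


def ne(ped: Pedigree, refpop: ReferencePopulation) -> NeEstimate:
    """Ne = 1/(2·mean ΔC) over unordered distinct pairs of the reference set.

    Members with NEG = 0 carry no rate information (the exponent is
    undefined) and are excluded from the pair set; at least two members with
    NEG > 0 are required.  Mean F averages over all members.
    """
    if refpop.nt < 2:
        raise ValueError("reference population needs at least 2 members")
    neg = neg_all(ped)
    f = inbreeding(ped)
    idx = np.array([ped.index_of(a) for a in refpop.members], dtype=np.int64)
    mean_f = float(f[idx].mean())
    informative = [a for a, i in zip(refpop.members, idx) if neg[i] > 0]
    if len(informative) < 2:
        raise ValueError("need >= 2 members with NEG > 0")
    km = kinship(ped, informative)
    g = neg[[ped.index_of(a) for a in informative]]
    C = km.values
    iu, ju = np.triu_indices(len(informative), k=1)
    with np.errstate(invalid="ignore"):
        dc = 1.0 - (1.0 - C[iu, ju]) ** (2.0 / (g[iu] + g[ju]))
    mean_dc = float(dc.mean())
    ne_val = float("inf") if mean_dc == 0 else 1.0 / (2.0 * mean_dc)
    return NeEstimate(
        label=refpop.label, ne=ne_val, mean_delta_c=mean_dc,
        nt=refpop.nt, mean_f=mean_f,
    )


@dataclass(frozen=True)
class WindowTemplate:
    """One sliding window: a year span plus its 1-based generation index."""

    generation: int
    start: int
    end: int

    @property
    def label(self) -> str:
        return f"GI {self.generation} ({self.start}-{self.end})"


def sliding_windows(start_year: int, end_year: int, window_len: int, step: int = 1) -> list[WindowTemplate]:
    """Fixed-length windows sliding over [start_year, end_year] inclusive.

    A window of length L covers L calendar years (start..start+L−1); windows
    are emitted while they fit inside the range, labelled with a 1-based
    generation index used as the trend regressor.
    """
    if window_len < 1:
        raise ValueError("window_len must be >= 1")
    if step < 1:
        raise ValueError("step must be >= 1")
    if end_year < start_year:
        raise ValueError("empty year range")
    windows = []
    g = 1
    s = start_year
    while s + window_len - 1 <= end_year:
        windows.append(WindowTemplate(generation=g, start=s, end=s + window_len - 1))
        s += step
        g += 1
    if not windows:
        raise ValueError("year range shorter than one window")
    return windows


@dataclass(frozen=True)
class TrendEstimate:
    """OLS slope of a windowed series on the window index 1..n."""

    slope: float
    se: float
    p_value: float
    n: int


def trend(values) -> TrendEstimate:
    """Regress window values on 1..n; two-sided t test with n−2 df."""
    y = np.asarray(values, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need >= 3 windows for a trend (SE undefined below)")
    x = np.arange(1, n + 1, dtype=float)
    sxx = float(((x - x.mean()) ** 2).sum())
    slope = float(((x - x.mean()) * (y - y.mean())).sum() / sxx)
    resid = y - (y.mean() + slope * (x - x.mean()))
    se = float(np.sqrt((resid**2).sum() / (n - 2) / sxx))
    if se == 0.0:  # exact line: p degenerates to 0 unless the line is flat
        p = 1.0 if slope == 0.0 else 0.0
    else:
        p = float(2.0 * stats.t.sf(abs(slope) / se, n - 2))
    return TrendEstimate(slope=slope, se=se, p_value=p, n=int(n))


@dataclass(frozen=True)
class NeTrendResult:
    """Windowed Ne table plus ΔNe and ΔF trend estimates."""

    table: pd.DataFrame = field(repr=False)
    delta_ne: TrendEstimate | None
    delta_f: TrendEstimate | None


def ne_trend(
    ped: Pedigree,
    start_year: int,
    end_year: int,
    window_len: int,
    step: int = 1,
    min_pci: float | None = None,
    min_neg: float | None = None,
    min_nfg: int | None = None,
    pci_depth: int = DEFAULT_PCI_DEPTH,
) -> NeTrendResult:
    """Sliding-window Ne with the per-generation ΔNe / ΔF regressions.

    Windows whose reference population is too small (or uninformative) are
    reported with NaN and excluded from the regressions.
    """
    rows = []
    for w in sliding_windows(start_year, end_year, window_len, step):
        refpop = reference_population(
            ped, w.start, w.end, min_pci=min_pci, min_neg=min_neg,
            min_nfg=min_nfg, pci_depth=pci_depth, label=w.label,
        )
        try:
            est = ne(ped, refpop)
            rows.append((w.generation, w.label, est.ne, est.nt, est.ne_nt_ratio, est.mean_f))
        except ValueError:
            rows.append((w.generation, w.label, np.nan, refpop.nt, np.nan, np.nan))
    table = pd.DataFrame(
        rows, columns=["generation", "window", "Ne", "Nt", "Ne_Nt", "mean_F"]
    )
    usable = table.dropna(subset=["Ne"])
    usable = usable[np.isfinite(usable["Ne"])]
    delta_ne = trend(usable["Ne"]) if len(usable) >= 3 else None
    delta_f = trend(usable["mean_F"]) if len(usable) >= 3 else None
    return NeTrendResult(table=table, delta_ne=delta_ne, delta_f=delta_f)
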