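"""Pedigree-quality metrics: completeness, PCI, NEG, NFG, NMG, and tables.

The metrics quantify how much ancestry is actually recorded for each animal,
and are used to gate which animals enter inbreeding / effective-size
estimation:

* completeness a_g — proportion of the 2^g ancestor slots at generation g
  that are occupied by a known animal (an ancestor appearing in several
  slots counts once per slot);
* PCI — pedigree completeness index, the harmonic mean of sire-side and
  dam-side mean completeness over ``depth`` generations; zero whenever a
  parent is unknown, so shallow pedigrees are penalised hard;
* NEG — equivalent complete generations, Σ (1/2)^g over all known ancestor
  slots at any depth (1/2 per known parent, 1/4 per known grandparent, ...);
* NFG — number of fully traced generations (every slot known up to g);
* NMG — maximum generations traced (longest known ancestral path).

All per-animal metrics are computed in one vectorised pass over the
topologically ordered pedigree, so whole-pedigree tables are cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pedigree_core import UNKNOWN, Pedigree

#: Default number of generations over which PCI averages completeness.
DEFAULT_PCI_DEPTH = 5


@dataclass(frozen=True)
class CompletenessProfile:
    """Per-generation proportion of known ancestors for one animal."""

    animal: str
    proportions: np.ndarray  # a_1..a_d, each in [0, 1]

    @property
    def depth(self) -> int:
        return len(self.proportions)


@dataclass(frozen=True)
class QualityScores:
    """The four per-animal pedigree-quality metrics."""

    pci: float
    neg: float
    nfg: int
    nmg: int


def known_ancestor_slots(ped: Pedigree, depth: int) -> np.ndarray:
    """Count known ancestor slots per animal and generation.

    Returns an (n, depth) integer matrix K with K[i, g-1] = number of the
    2^g ancestor slots of animal i at generation g occupied by a known
    animal.  Computed by the slot recursion K_g(i) = K_{g-1}(sire_i) +
    K_{g-1}(dam_i) over the topological ordering.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    n = len(ped)
    has_sire = ped.sire != UNKNOWN
    has_dam = ped.dam != UNKNOWN
    K = np.zeros((n, depth), dtype=np.int64)
    K[:, 0] = has_sire.astype(np.int64) + has_dam.astype(np.int64)
    sire = np.where(has_sire, ped.sire, 0)
    dam = np.where(has_dam, ped.dam, 0)
    for g in range(1, depth):
        K[:, g] = np.where(has_sire, K[sire, g - 1], 0) + np.where(
            has_dam, K[dam, g - 1], 0
        )
    return K


def completeness_by_generation(
    ped: Pedigree, animal: str, depth: int
) -> CompletenessProfile:
    """Proportion of known ancestors of ``animal`` in generations 1..depth."""
    i = ped.index_of(animal)
    K = known_ancestor_slots(ped, depth)
    a = K[i] / (2.0 ** np.arange(1, depth + 1))
    return CompletenessProfile(animal=animal, proportions=a)


def cohort_completeness(
    ped: Pedigree, depth: int, members: np.ndarray | None = None
) -> np.ndarray:
    """Mean completeness profile a_1..a_depth over a group of animals."""
    K = known_ancestor_slots(ped, depth)
    if members is not None:
        K = K[members]
    if K.shape[0] == 0:
        raise ValueError("empty cohort")
    return K.mean(axis=0) / (2.0 ** np.arange(1, depth + 1))


def _side_completeness(ped: Pedigree, depth: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean completeness of the sire side (C_f) and dam side (C_m).

    The parent occupies generation 1 of its side; the parent's own ancestors
    shift one generation deeper.  A missing parent gives side completeness 0,
    which is what makes PCI vanish when either parent is unknown.
    """
    a = known_ancestor_slots(ped, depth) / (2.0 ** np.arange(1, depth + 1))
    # Cumulative mean of the parent's own profile over the first depth-1
    # generations, prefixed by the parent itself (a=1 at generation 1).
    parent_part = (1.0 + a[:, : depth - 1].sum(axis=1)) / depth
    has_sire = ped.sire != UNKNOWN
    has_dam = ped.dam != UNKNOWN
    sire = np.where(has_sire, ped.sire, 0)
    dam = np.where(has_dam, ped.dam, 0)
    c_f = np.where(has_sire, parent_part[sire], 0.0)
    c_m = np.where(has_dam, parent_part[dam], 0.0)
    return c_f, c_m


def pci_all(ped: Pedigree, depth: int = DEFAULT_PCI_DEPTH) -> np.ndarray:
    """Pedigree completeness index for every animal (harmonic mean of sides)."""
    c_f, c_m = _side_completeness(ped, depth)
    s = c_f + c_m
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(s > 0, 2.0 * c_f * c_m / np.where(s > 0, s, 1.0), 0.0)
    return out


def pci(ped: Pedigree, animal: str, depth: int = DEFAULT_PCI_DEPTH) -> float:
    if depth < 1:
        raise ValueError("depth must be >= 1")
    return float(pci_all(ped, depth)[ped.index_of(animal)])


def neg_all(ped: Pedigree) -> np.ndarray:
    """Equivalent complete generations for every animal.

    Single topological pass of NEG_i = Σ_{known parents p} (1 + NEG_p) / 2,
    equivalent to summing (1/2)^g over every known ancestor slot with no
    depth cap.
    """
    n = len(ped)
    neg = np.zeros(n)
    for i in range(n):
        total = 0.0
        for p in (ped.sire[i], ped.dam[i]):
            if p != UNKNOWN:
                total += 0.5 * (1.0 + neg[p])
        neg[i] = total
    return neg


def neg(ped: Pedigree, animal: str) -> float:
    return float(neg_all(ped)[ped.index_of(animal)])


def nfg_all(ped: Pedigree) -> np.ndarray:
    """Fully traced generations: largest g with all 2^g slots known up to g."""
    n = len(ped)
    out = np.zeros(n, dtype=np.int64)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        out[i] = 0 if s == UNKNOWN or d == UNKNOWN else 1 + min(out[s], out[d])
    return out


def nmg_all(ped: Pedigree) -> np.ndarray:
    """Maximum generations traced: length of the longest known ancestral path."""
    n = len(ped)
    out = np.zeros(n, dtype=np.int64)
    for i in range(n):
        best = 0
        for p in (ped.sire[i], ped.dam[i]):
            if p != UNKNOWN:
                best = max(best, 1 + out[p])
        out[i] = best
    return out


def nfg(ped: Pedigree, animal: str) -> int:
    return int(nfg_all(ped)[ped.index_of(animal)])


def nmg(ped: Pedigree, animal: str) -> int:
    return int(nmg_all(ped)[ped.index_of(animal)])


def quality_scores(ped: Pedigree, animal: str, pci_depth: int = DEFAULT_PCI_DEPTH) -> QualityScores:
    i = ped.index_of(animal)
    return QualityScores(
        pci=float(pci_all(ped, pci_depth)[i]),
        neg=float(neg_all(ped)[i]),
        nfg=int(nfg_all(ped)[i]),
        nmg=int(nmg_all(ped)[i]),
    )


def quality_table(ped: Pedigree, pci_depth: int = DEFAULT_PCI_DEPTH) -> pd.DataFrame:
    """Per-animal table of id, PCI, NEG, NFG, NMG (topological order)."""
    return pd.DataFrame(
        {
            "id": ped.ids,
            "PCI": pci_all(ped, pci_depth),
            "NEG": neg_all(ped),
            "NFG": nfg_all(ped),
            "NMG": nmg_all(ped),
        }
    )


def distribution_table(values, bin_edges) -> pd.DataFrame:
    """Frequency table in the style of a printed distribution table.

    Bins are left-closed with the final bin closed on both sides.  Percent
    is rounded to two decimals per row and the cumulative column accumulates
    the rounded values, so its final entry is 100 up to rounding.
    """
    values = np.asarray(values, dtype=float)
    edges = np.asarray(bin_edges, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if edges.ndim != 1 or edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be increasing with >= 2 edges")
    if values.min() < edges[0] or values.max() > edges[-1]:
        raise ValueError("bin_edges must cover the data range")
    freq, _ = np.histogram(values, bins=edges)
    pct = np.round(freq / values.size * 100.0, 2)
    labels = [
        f"[{lo:g}, {hi:g}" + ("]" if k == len(freq) - 1 else ")")
        for k, (lo, hi) in enumerate(zip(edges[:-1], edges[1:]))
    ]
    return pd.DataFrame(
        {
            "bin": labels,
            "frequency": freq,
            "percent": pct,
            "cumulative_percent": np.round(np.cumsum(pct), 2),
        }
    )


def summarize(ped: Pedigree, pci_depth: int = DEFAULT_PCI_DEPTH) -> pd.DataFrame:
    """min/max/median/mean of NEG, NFG, NMG and PCI over the whole pedigree."""
    q = quality_table(ped, pci_depth)
    stats = {}
    for col in ("NEG", "NFG", "NMG", "PCI"):
        v = q[col].to_numpy(dtype=float)
        stats[col] = {
            "min": float(v.min()),
            "max": float(v.max()),
            "median": float(np.median(v)),
            "mean": float(v.mean()),
        }
    return pd.DataFrame(stats).T[["min", "max", "median", "mean"]]
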