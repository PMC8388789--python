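"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from pedconnect import FEMALE, MALE, Pedigree, PedigreeRecord


# ---------------------------------------------------------------------------
# Hand-built pedigrees
# ---------------------------------------------------------------------------

@pytest.fixture
def trio() -> Pedigree:
    """Unrelated sire and dam with one offspring."""
    return Pedigree(
        [
            PedigreeRecord("S", sex=MALE, birth_year=2000),
            PedigreeRecord("D", sex=FEMALE, birth_year=2000),
            PedigreeRecord("C", sire="S", dam="D", birth_year=2003),
        ]
    )


@pytest.fixture
def full_sib_mating() -> Pedigree:
    """Offspring of two full sibs from unrelated non-inbred parents."""
    return Pedigree(
        [
            PedigreeRecord("S", sex=MALE),
            PedigreeRecord("D", sex=FEMALE),
            PedigreeRecord("B1", sire="S", dam="D", sex=MALE),
            PedigreeRecord("B2", sire="S", dam="D", sex=FEMALE),
            PedigreeRecord("X", sire="B1", dam="B2"),
        ]
    )


def complete_pedigree(generations: int) -> tuple[Pedigree, str]:
    """Fully known pedigree of ``generations`` complete ancestral
    generations behind one focal animal; returns (pedigree, focal id)."""
    records: list[PedigreeRecord] = []

    def build(name: str, depth: int, sex: str) -> str:
        if depth == 0:
            records.append(PedigreeRecord(name, sex=sex))
        else:
            s = build(name + "s", depth - 1, MALE)
            d = build(name + "d", depth - 1, FEMALE)
            records.append(PedigreeRecord(name, sire=s, dam=d, sex=sex))
        return name

    focal = build("X", generations, MALE)
    return Pedigree(records), focal


def random_pedigree(rng: np.random.Generator, n: int, p_known: float = 0.8,
                    n_flocks: int = 3) -> Pedigree:
    """Random valid pedigree of ``n`` animals with overlapping cohorts.

    Each animal may draw a sire/dam independently from earlier animals of
    the right sex (probability ``p_known`` per side), giving a mix of
    founders, half-links, inbreeding loops, and flock labels.
    """
    records: list[PedigreeRecord] = []
    males: list[str] = []
    females: list[str] = []
    for i in range(n):
        sex = MALE if rng.random() < 0.5 else FEMALE
        sire = males[int(rng.integers(len(males)))] if males and rng.random() < p_known else None
        dam = females[int(rng.integers(len(females)))] if females and rng.random() < p_known else None
        name = f"R{i}"
        records.append(
            PedigreeRecord(
                name, sire=sire, dam=dam, sex=sex,
                birth_year=2000 + i // max(1, n // 10),
                flock=f"U{int(rng.integers(n_flocks)) + 1}",
            )
        )
        (males if sex == MALE else females).append(name)
    return Pedigree(records)


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def coancestry_oracle(ped: Pedigree) -> np.ndarray:
    """Brute-force recursive coancestry over all ancestor paths.

    Independent of the production route (A-inverse + sparse LU): the
    classic double recursion f(a,b) = mean of f(a, parents of b), with
    f(a,a) = (1 + f(sire_a, dam_a))/2, memoised on ordered pairs.
    """
    n = len(ped)
    sire, dam = ped.sire, ped.dam
    memo: dict[tuple[int, int], float] = {}

    def f(a: int, b: int) -> float:
        if a < 0 or b < 0:
            return 0.0
        if a > b:
            a, b = b, a
        key = (a, b)
        if key in memo:
            return memo[key]
        if a == b:
            val = 0.5 * (1.0 + f(sire[a], dam[a]))
        else:  # b is topologically later, so a is never a descendant of b
            val = 0.5 * (f(a, sire[b]) + f(a, dam[b]))
        memo[key] = val
        return val

    out = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            out[i, j] = out[j, i] = f(i, j)
    return out


def is_ancestor_bruteforce(ped: Pedigree, anc: int, desc: int) -> bool:
    """Exhaustive ancestor search (used to cross-check topological order)."""
    stack = [desc]
    seen = set()
    while stack:
        a = stack.pop()
        for p in (ped.sire[a], ped.dam[a]):
            if p >= 0 and p not in seen:
                if p == anc:
                    return True
                seen.add(p)
                stack.append(p)
    return False
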