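"""Pedigree simulators with known truth for testing every analysis stage.

Two generators:

* :func:`simulate_flock_population` — a multi-flock sheep population with
  overlapping generations, breeding-ram exchange between flocks at a
  tunable migration rate, parent links deleted in older cohorts to mimic
  historic recording gaps, and phenotype records confined to a subset of
  performance-recorded flocks.  This reproduces the statistical structure
  the analysis assumes (generation interval near 3.8 years, completeness
  decaying with ancestral generation, connectedness driven by ram flow).

* :func:`simulate_idealized` — discrete generations of constant census N,
  random mating with uniformly drawn parents (Poisson-equivalent family
  sizes), the textbook population whose realised effective size is N up to
  terms of order 1/N.  Used as ground truth for the coancestry-rate Ne
  estimator and for the closed-form mean-F trajectory 1 − (1 − 1/2N)^t.

All randomness flows through one seeded ``numpy.random.Generator``; the
same seed yields a byte-identical pedigree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .pedigree_core import FEMALE, MALE, Pedigree, PedigreeRecord
from .connectedness import RecordsDesign


def default_missing_parent_schedule(years_before_end: int) -> float:
    """Probability of deleting each parent link, by cohort age.

    Older cohorts lose ancestry fast (systematic recording only started
    recently), recent cohorts are nearly complete — the source of the
    roughly 20%-per-generation completeness decay the quality metrics are
    designed to expose.
    """
    return float(np.clip(0.08 * (years_before_end - 4), 0.0, 0.9))


@dataclass(frozen=True)
class SimConfig:
    """Multi-flock scenario parameters (defaults are the stated world).

    14 performance-recorded flocks of 30 ewes + 2 rams over 12 years:
    thousands of animals in seconds.  ``mean_parent_age`` sets the breeder
    replacement hazard (breeders enter at age 2, mean age 1 + 1/rate), so
    the realised generation interval lands near the 3.8-year target.
    """

    n_flocks: int = 14
    n_recorded_flocks: int = 14
    ewes_per_flock: int = 30
    rams_per_flock: int = 2
    n_years: int = 12
    migration_rate: float = 0.1
    mean_parent_age: float = 3.8
    replacement_rate: float | None = None
    lambing_rate: float = 0.9
    missing_parent_rate: Callable[[int], float] = field(
        default=default_missing_parent_schedule
    )
    record_years: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_flocks, self.ewes_per_flock, self.rams_per_flock, self.n_years) < 1:
            raise ValueError("counts must be >= 1")
        if not 0 <= self.n_recorded_flocks <= self.n_flocks:
            raise ValueError("n_recorded_flocks must lie in [0, n_flocks]")
        for p in (self.migration_rate, self.lambing_rate):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.mean_parent_age <= 2.0:
            raise ValueError("mean_parent_age must exceed the entry age of 2")

    @property
    def effective_replacement_rate(self) -> float:
        if self.replacement_rate is not None:
            return self.replacement_rate
        return 1.0 / (self.mean_parent_age - 1.0)


@dataclass
class _Animal:
    id: str
    sire: str | None
    dam: str | None
    sex: str
    birth_year: int
    flock: int


def simulate_flock_population(cfg: SimConfig) -> tuple[Pedigree, RecordsDesign]:
    """Simulate an overlapping-generation multi-flock pedigree plus records.

    Each year every flock's ewes lamb with probability ``lambing_rate``; the
    lamb's sire is drawn from the flock's breeding rams, except that with
    probability ``migration_rate`` it comes from a uniformly chosen other
    flock.  Breeders are culled with the replacement hazard and refilled
    from the flock's own yearlings.  Parent links of each cohort are then
    deleted independently at ``missing_parent_rate(years_before_end)``.
    Records go to ewes of the first ``n_recorded_flocks`` flocks born in the
    final ``record_years`` years.
    """
    rng = np.random.default_rng(cfg.seed)
    repl = cfg.effective_replacement_rate
    first_year = 2000
    last_year = first_year + cfg.n_years - 1
    counter = 0

    def new_animal(sire, dam, sex, year, flock) -> _Animal:
        nonlocal counter
        counter += 1
        a = _Animal(f"A{counter:06d}", sire, dam, sex, year, flock)
        animals.append(a)
        return a

    animals: list[_Animal] = []
    # Founders: breeding ewes and rams per flock, aged 2-5 at first year.
    ewes: list[list[_Animal]] = []
    rams: list[list[_Animal]] = []
    for fl in range(cfg.n_flocks):
        ewes.append(
            [
                new_animal(None, None, FEMALE, first_year - int(rng.integers(2, 6)), fl)
                for _ in range(cfg.ewes_per_flock)
            ]
        )
        rams.append(
            [
                new_animal(None, None, MALE, first_year - int(rng.integers(2, 6)), fl)
                for _ in range(cfg.rams_per_flock)
            ]
        )

    yearlings: list[list[_Animal]] = [[] for _ in range(cfg.n_flocks)]
    for year in range(first_year, last_year + 1):
        # Lambing: sire flock possibly differs from the dam's flock.
        newborn: list[list[_Animal]] = [[] for _ in range(cfg.n_flocks)]
        for fl in range(cfg.n_flocks):
            for ewe in ewes[fl]:
                if rng.random() >= cfg.lambing_rate:
                    continue
                sire_flock = fl
                if cfg.n_flocks > 1 and rng.random() < cfg.migration_rate:
                    other = int(rng.integers(cfg.n_flocks - 1))
                    sire_flock = other if other < fl else other + 1
                sire = rams[sire_flock][int(rng.integers(len(rams[sire_flock])))]
                sex = MALE if rng.random() < 0.5 else FEMALE
                newborn[fl].append(new_animal(sire.id, ewe.id, sex, year, fl))

        # Replacement: cull breeders, recruit from last year's lambs.
        for fl in range(cfg.n_flocks):
            for pool, target, sex in (
                (ewes, cfg.ewes_per_flock, FEMALE),
                (rams, cfg.rams_per_flock, MALE),
            ):
                keep = [b for b in pool[fl] if rng.random() >= repl]
                recruits = [a for a in yearlings[fl] if a.sex == sex]
                rng.shuffle(recruits)
                keep.extend(recruits[: target - len(keep)])
                if not keep:  # never leave a flock without breeders
                    keep = pool[fl][:1]
                pool[fl] = keep
        yearlings = newborn

    # Historic recording gaps: delete parent links of older cohorts.
    for a in animals:
        p_miss = cfg.missing_parent_rate(last_year - a.birth_year)
        if a.sire is not None and rng.random() < p_miss:
            a.sire = None
        if a.dam is not None and rng.random() < p_miss:
            a.dam = None

    records = [
        PedigreeRecord(
            id=a.id, sire=a.sire, dam=a.dam, sex=a.sex,
            birth_year=a.birth_year, flock=f"F{a.flock + 1:02d}",
        )
        for a in animals
    ]
    ped = Pedigree(records)

    recorded = [
        a
        for a in animals
        if a.sex == FEMALE
        and a.flock < cfg.n_recorded_flocks
        and a.birth_year > last_year - cfg.record_years
    ]
    if not recorded:
        raise ValueError("infeasible config: no recordable ewes produced")
    design = RecordsDesign(
        animals=tuple(a.id for a in recorded),
        units=tuple(f"F{a.flock + 1:02d}" for a in recorded),
    )
    return ped, design


@dataclass(frozen=True)
class IdealizedConfig:
    """Constant-census Wright–Fisher-like scenario parameters."""

    N: int = 50
    n_generations: int = 10
    male_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N < 4:
            raise ValueError("N must be >= 4")
        if self.n_generations < 1:
            raise ValueError("need >= 1 generation")
        n_males = int(round(self.N * self.male_fraction))
        if not 0 < n_males < self.N:
            raise ValueError("both sexes need at least one individual")


def simulate_idealized(cfg: IdealizedConfig) -> Pedigree:
    """Discrete generations, constant N, uniformly drawn parents.

    Each offspring of generation t+1 draws its sire uniformly from the
    generation-t males and its dam uniformly from the generation-t females;
    birth_year holds the generation index (founders are generation 0).
    """
    rng = np.random.default_rng(cfg.seed)
    n_males = int(round(cfg.N * cfg.male_fraction))
    records: list[PedigreeRecord] = []

    def cohort_ids(t: int) -> list[str]:
        return [f"G{t}_{k}" for k in range(cfg.N)]

    sexes = [MALE] * n_males + [FEMALE] * (cfg.N - n_males)
    for k, a in enumerate(cohort_ids(0)):
        records.append(PedigreeRecord(id=a, sex=sexes[k], birth_year=0, flock="I"))
    for t in range(1, cfg.n_generations + 1):
        prev = cohort_ids(t - 1)
        males = prev[:n_males]
        females = prev[n_males:]
        for k, a in enumerate(cohort_ids(t)):
            records.append(
                PedigreeRecord(
                    id=a,
                    sire=males[int(rng.integers(len(males)))],
                    dam=females[int(rng.integers(len(females)))],
                    sex=sexes[k],
                    birth_year=t,
                    flock="I",
                )
            )
    return Pedigree(records)
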