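"""Pedigree data model: reading, validation, recoding, topological ordering.

A pedigree is a table of animals with sire/dam links, sex, birth year and a
flock (management-unit) label.  All downstream computations — completeness
metrics, inbreeding and kinship, effective population size, connectedness —
consume the :class:`Pedigree` defined here, in which every parent precedes
its offspring (topological order) and parents are integer positions into the
same table (``-1`` meaning unknown).

Parents that are referenced but have no row of their own are materialised as
founder placeholder records with both parents unknown; sex is inferred from
the role (an id used as a sire becomes male).  Unknown parents can be coded
``"0"``, the empty string, or any configurable token in the input file; all
are normalised to the single internal UNKNOWN (-1).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

# Sex codes used throughout the package.
MALE = "M"
FEMALE = "F"
UNKNOWN_SEX = "U"

#: Sentinel for an unknown parent position / unknown birth year.
UNKNOWN = -1

_SEX_ALIASES = {
    "m": MALE, "male": MALE, "1": MALE, "ram": MALE, "sire": MALE,
    "f": FEMALE, "female": FEMALE, "2": FEMALE, "ewe": FEMALE, "dam": FEMALE,
}


def _normalise_sex(token: object) -> str:
    if token is None:
        return UNKNOWN_SEX
    s = str(token).strip().lower()
    return _SEX_ALIASES.get(s, UNKNOWN_SEX)


@dataclass(frozen=True)
class PedigreeDialect:
    """Column names and missing-value coding of a delimited pedigree file."""

    id_col: str = "id"
    sire_col: str = "sire"
    dam_col: str = "dam"
    sex_col: str = "sex"
    year_col: str = "birth_year"
    flock_col: str = "flock"
    missing_codes: tuple[str, ...] = ("0", "", "NA", ".")
    sep: str = ","

    def is_missing(self, token: object) -> bool:
        if token is None:
            return True
        s = str(token).strip()
        # "0" and the empty string always denote a missing value.
        return s in ("", "0") or s in self.missing_codes or s.lower() == "nan"


@dataclass(frozen=True)
class PedigreeRecord:
    """One animal: identity, parent labels, sex, birth year, flock."""

    id: str
    sire: str | None = None
    dam: str | None = None
    sex: str = UNKNOWN_SEX
    birth_year: int | None = None
    flock: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("animal id must be non-empty")
        if self.sire == self.id or self.dam == self.id:
            raise ValueError(f"animal {self.id!r} cannot be its own parent")


class Pedigree:
    """Topologically ordered pedigree with integer parent links.

    Attributes
    ----------
    ids : list of str
        Animal labels in topological order (parents before offspring).
    sire, dam : ndarray of int
        Position of each animal's sire/dam in ``ids``; ``UNKNOWN`` (-1) when
        the parent is missing.
    sex : ndarray of str
        ``"M"``, ``"F"`` or ``"U"`` per animal.
    birth_year : ndarray of int
        Calendar year, ``UNKNOWN`` (-1) when not recorded.
    flock : ndarray of str
        Flock label; empty string when not recorded.
    cyclic_ids : frozenset of str
        Animals involved in parentage cycles.  Non-empty pedigrees with
        cycles are rejected by :func:`validate`-gated operations.
    """

    def __init__(self, records: list[PedigreeRecord]):
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate animal id(s): {dupes}")
        by_id = {r.id: r for r in records}

        # Materialise founder placeholders for referenced-but-absent parents.
        placeholders: dict[str, PedigreeRecord] = {}
        for r in records:
            for parent, sex in ((r.sire, MALE), (r.dam, FEMALE)):
                if parent is not None and parent not in by_id:
                    prev = placeholders.get(parent)
                    inferred = sex if prev is None or prev.sex == sex else UNKNOWN_SEX
                    placeholders[parent] = PedigreeRecord(id=parent, sex=inferred)
        all_records = list(placeholders.values()) + records
        order, cyclic = _topological_order(all_records)

        n = len(order)
        self.ids: list[str] = [r.id for r in order]
        self._index: dict[str, int] = {a: i for i, a in enumerate(self.ids)}
        self.sire = np.full(n, UNKNOWN, dtype=np.int64)
        self.dam = np.full(n, UNKNOWN, dtype=np.int64)
        self.sex = np.array([r.sex for r in order], dtype=object)
        self.birth_year = np.array(
            [UNKNOWN if r.birth_year is None else int(r.birth_year) for r in order],
            dtype=np.int64,
        )
        self.flock = np.array([r.flock or "" for r in order], dtype=object)
        for i, r in enumerate(order):
            if r.sire is not None:
                self.sire[i] = self._index[r.sire]
            if r.dam is not None:
                self.dam[i] = self._index[r.dam]
        self.cyclic_ids: frozenset[str] = frozenset(cyclic)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, animal: str) -> bool:
        return animal in self._index

    def index_of(self, animal: str) -> int:
        try:
            return self._index[animal]
        except KeyError:
            raise KeyError(f"animal {animal!r} not in pedigree") from None

    def record(self, animal: str) -> PedigreeRecord:
        i = self.index_of(animal)
        return PedigreeRecord(
            id=self.ids[i],
            sire=self.ids[self.sire[i]] if self.sire[i] != UNKNOWN else None,
            dam=self.ids[self.dam[i]] if self.dam[i] != UNKNOWN else None,
            sex=self.sex[i],
            birth_year=None if self.birth_year[i] == UNKNOWN else int(self.birth_year[i]),
            flock=self.flock[i] or None,
        )

    @property
    def records(self) -> list[PedigreeRecord]:
        return [self.record(a) for a in self.ids]

    @property
    def n_founders(self) -> int:
        return int(np.sum((self.sire == UNKNOWN) & (self.dam == UNKNOWN)))

    def to_frame(self) -> pd.DataFrame:
        """Normalised tabular view (id, sire, dam, sex, birth_year, flock)."""
        sire = ["0" if s == UNKNOWN else self.ids[s] for s in self.sire]
        dam = ["0" if d == UNKNOWN else self.ids[d] for d in self.dam]
        year = ["0" if y == UNKNOWN else str(int(y)) for y in self.birth_year]
        return pd.DataFrame(
            {
                "id": self.ids,
                "sire": sire,
                "dam": dam,
                "sex": list(self.sex),
                "birth_year": year,
                "flock": ["0" if not f else f for f in self.flock],
            }
        )


def _topological_order(
    records: list[PedigreeRecord],
) -> tuple[list[PedigreeRecord], list[str]]:
    """Kahn's algorithm over parent→offspring edges.

    Ready animals are emitted in lexicographic id order, so the resulting
    ordering is canonical: independent of the input row order.  Animals
    caught in cycles are appended at the end and reported separately so that
    validation can name them instead of the constructor failing outright.
    """
    by_id = {r.id: r for r in records}
    children: dict[str, list[str]] = {r.id: [] for r in records}
    indeg = {r.id: 0 for r in records}
    for r in records:
        for p in (r.sire, r.dam):
            if p is not None and p in by_id:
                children[p].append(r.id)
                indeg[r.id] += 1
    heap = sorted(r.id for r in records if indeg[r.id] == 0)
    heapq.heapify(heap)
    ordered: list[str] = []
    while heap:
        a = heapq.heappop(heap)
        ordered.append(a)
        for c in children[a]:
            indeg[c] -= 1
            if indeg[c] == 0:
                heapq.heappush(heap, c)
    placed = set(ordered)
    cyclic = [r.id for r in records if r.id not in placed]
    return [by_id[a] for a in ordered + cyclic], cyclic


@dataclass
class ValidationReport:
    """Outcome of structural pedigree checks.

    ``errors`` makes a pedigree unusable downstream; ``warnings`` (e.g. an
    offspring not born after its parent) merely flag suspect records.
    """

    errors: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str]] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate(ped: Pedigree) -> ValidationReport:
    """Check a pedigree for cycles, dual-role parents, sex conflicts, selfing.

    Birth-year inversions (offspring born no later than a parent) are
    warnings, not errors: historic pedigrees plainly contain year gaps and
    birth-year-windowed analyses simply exclude animals with unknown years.
    """
    report = ValidationReport()
    for a in sorted(ped.cyclic_ids):
        report.errors.append((a, "cycle: animal is its own ancestor"))

    used_as_sire = set(ped.sire[ped.sire != UNKNOWN])
    used_as_dam = set(ped.dam[ped.dam != UNKNOWN])
    for i in sorted(used_as_sire & used_as_dam):
        report.errors.append((ped.ids[i], "used as both sire and dam"))
    for i in sorted(used_as_sire):
        if ped.sex[i] == FEMALE:
            report.errors.append((ped.ids[i], "sex-inconsistency: female used as sire"))
    for i in sorted(used_as_dam):
        if ped.sex[i] == MALE:
            report.errors.append((ped.ids[i], "sex-inconsistency: male used as dam"))
    for i in range(len(ped)):
        if ped.sire[i] != UNKNOWN and ped.sire[i] == ped.dam[i]:
            report.errors.append((ped.ids[i], "selfing: sire equals dam"))
        if ped.birth_year[i] != UNKNOWN:
            for p in (ped.sire[i], ped.dam[i]):
                if p != UNKNOWN and ped.birth_year[p] != UNKNOWN:
                    if ped.birth_year[i] <= ped.birth_year[p]:
                        report.warnings.append(
                            (ped.ids[i], f"born {ped.birth_year[i]} but parent "
                                         f"{ped.ids[p]} born {ped.birth_year[p]}")
                        )

    report.counts = {
        "animals": len(ped),
        "founders": ped.n_founders,
        "sires": len(used_as_sire),
        "dams": len(used_as_dam),
        "flocks": len({f for f in ped.flock if f}),
    }
    return report


def require_valid(ped: Pedigree) -> None:
    """Raise if ``ped`` fails validation; used as the downstream gate."""
    report = validate(ped)
    if not report.ok:
        msgs = "; ".join(f"{a}: {rule}" for a, rule in report.errors[:5])
        raise ValueError(f"pedigree has {len(report.errors)} error(s): {msgs}")


def read_pedigree(path, dialect: PedigreeDialect | None = None) -> Pedigree:
    """Read a delimited pedigree file into a topologically ordered Pedigree.

    The file must have a header row naming at least the id, sire and dam
    columns of ``dialect``; sex, year and flock columns are optional.
    """
    dialect = dialect or PedigreeDialect()
    df = pd.read_csv(path, sep=dialect.sep, dtype=str, keep_default_na=False)
    for col in (dialect.id_col, dialect.sire_col, dialect.dam_col):
        if col not in df.columns:
            raise ValueError(f"missing required column {col!r} in {path}")

    records = []
    for line, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        animal = str(row[dialect.id_col]).strip()
        if dialect.is_missing(animal):
            raise ValueError(f"{path}:{line}: missing animal id")
        def parent(col: str) -> str | None:
            tok = str(row.get(col, "")).strip()
            return None if dialect.is_missing(tok) else tok
        year_tok = str(row.get(dialect.year_col, "")).strip()
        if dialect.is_missing(year_tok):
            year = None
        else:
            try:
                year = int(float(year_tok))
            except ValueError:
                raise ValueError(
                    f"{path}:{line}: unparseable birth year {year_tok!r}"
                ) from None
        flock_tok = str(row.get(dialect.flock_col, "")).strip()
        records.append(
            PedigreeRecord(
                id=animal,
                sire=parent(dialect.sire_col),
                dam=parent(dialect.dam_col),
                sex=_normalise_sex(row.get(dialect.sex_col)),
                birth_year=year,
                flock=None if dialect.is_missing(flock_tok) else flock_tok,
            )
        )
    return Pedigree(records)


def write_pedigree(ped: Pedigree, path) -> None:
    """Write the normalised pedigree CSV (UNKNOWN coded as "0")."""
    ped.to_frame().to_csv(path, index=False)


def recode(ped: Pedigree) -> tuple[Pedigree, dict[str, int]]:
    """Renumber animals 1..n in topological order.

    Returns a pedigree whose labels are the stringified codes, plus the
    id→code bijection.  The inverse mapping recovers the input pedigree.
    """
    require_valid(ped)
    mapping = {a: i + 1 for i, a in enumerate(ped.ids)}
    records = []
    for i, a in enumerate(ped.ids):
        r = ped.record(a)
        records.append(
            replace(
                r,
                id=str(mapping[a]),
                sire=None if r.sire is None else str(mapping[r.sire]),
                dam=None if r.dam is None else str(mapping[r.dam]),
            )
        )
    return Pedigree(records), mapping
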