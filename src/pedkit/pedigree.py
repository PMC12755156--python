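"""Pedigree container, I/O, validation, and population slicing.

A pedigree is a directed acyclic graph of animals linked by sire/dam
records.  Everything downstream (completeness, inbreeding, coancestry,
gene-origin accounting) derives from the topologically ordered arrays
held by :class:`Pedigree`: for animal at position ``i``, both parents
(when known) sit at positions ``< i``.

Missing parents are the norm in livestock registries; the reader maps
the usual sentinels (empty field, ``0``, ``NA``) to MISSING and
synthesises founder records for parents that are referenced but never
appear as a row of their own.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("pedkit")

# Sex codes used in the packed arrays.
SEX_UNKNOWN = 0
SEX_MALE = 1
SEX_FEMALE = 2

_SEX_LABEL = {SEX_UNKNOWN: "unknown", SEX_MALE: "male", SEX_FEMALE: "female"}
_SEX_CODE = {"unknown": SEX_UNKNOWN, "male": SEX_MALE, "female": SEX_FEMALE}

#: sentinel for an unset birth year in the packed arrays
YEAR_UNSET = -1

_MALE_TOKENS = {"m", "male", "1", "s", "sire", "bull", "toro"}
_FEMALE_TOKENS = {"f", "female", "2", "d", "dam", "cow", "h", "vaca"}


class PedigreeError(ValueError):
    """Structural problem in a pedigree (duplicate id, self-parentage...)."""


class PedigreeCycleError(PedigreeError):
    """An animal is its own ancestor; carries one offending cycle."""

    def __init__(self, cycle: Sequence[str]):
        self.cycle = list(cycle)
        super().__init__("pedigree cycle detected: " + " -> ".join(self.cycle))


@dataclass(frozen=True)
class PedigreeRecord:
    """One registry row: an animal with its (possibly unknown) parents."""

    animal_id: str
    sire_id: str | None = None
    dam_id: str | None = None
    sex: str = "unknown"
    birth_year: int | None = None

    def __post_init__(self):
        if not self.animal_id:
            raise PedigreeError("animal_id must be non-empty")
        if self.sire_id == self.animal_id or self.dam_id == self.animal_id:
            raise PedigreeError(f"self-parentage for animal {self.animal_id!r}")
        if self.sex not in _SEX_CODE:
            raise PedigreeError(f"unknown sex {self.sex!r} for {self.animal_id!r}")


@dataclass(frozen=True)
class PedigreeDialect:
    """Column mapping and token conventions of a delimited pedigree file.

    ``dayfirst`` controls day/month/year versus ISO-ish parsing for full
    birth dates; only the year is retained either way.
    """

    animal_col: str = "animal"
    sire_col: str = "sire"
    dam_col: str = "dam"
    sex_col: str | None = "sex"
    birth_col: str | None = "birth_date"
    sep: str | None = None  # None = sniff comma vs tab
    missing_tokens: frozenset[str] = frozenset({"", "0", "NA", "na", "."})
    dayfirst: bool = False


DEFAULT_DIALECT = PedigreeDialect()


class Pedigree:
    """Topologically ordered, validated animal graph.

    Construct with :meth:`from_records` (or :func:`read_pedigree`); the
    positional arrays are ordered so that every known parent precedes
    its offspring.
    """

    def __init__(self, ids, sire, dam, sex, birth_year):
        self.ids: list[str] = list(ids)
        self.index: dict[str, int] = {a: i for i, a in enumerate(self.ids)}
        if len(self.index) != len(self.ids):
            raise PedigreeError("duplicate animal ids in pedigree")
        self.sire = np.asarray(sire, dtype=np.int64)
        self.dam = np.asarray(dam, dtype=np.int64)
        self.sex = np.asarray(sex, dtype=np.int8)
        self.birth_year = np.asarray(birth_year, dtype=np.int64)
        n = len(self.ids)
        if not (len(self.sire) == len(self.dam) == len(self.sex) == len(self.birth_year) == n):
            raise PedigreeError("array length mismatch")
        # parents must precede offspring
        pos = np.arange(n)
        for par in (self.sire, self.dam):
            known = par >= 0
            if np.any(par[known] >= pos[known]):
                raise PedigreeError("pedigree is not topologically ordered")
        self._children: list[list[int]] | None = None

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------
    @classmethod
    def from_records(cls, records: Iterable[PedigreeRecord]) -> "Pedigree":
        """Validate, synthesise missing founders, and topologically order."""
        records = list(records)
        by_id: dict[str, PedigreeRecord] = {}
        for rec in records:
            if rec.animal_id in by_id:
                raise PedigreeError(f"duplicate animal_id {rec.animal_id!r}")
            by_id[rec.animal_id] = rec

        # synthesise founder rows for parents never defined as a row;
        # sex inferred from the parental slot, birth year left unset
        order_of_appearance = list(by_id)
        for rec in list(by_id.values()):
            for pid, slot_sex in ((rec.sire_id, "male"), (rec.dam_id, "female")):
                if pid is not None and pid not in by_id:
                    by_id[pid] = PedigreeRecord(pid, None, None, slot_sex, None)
                    order_of_appearance.append(pid)
                    logger.warning(
                        "parent %r of %r has no row; synthesised %s founder",
                        pid, rec.animal_id, slot_sex,
                    )

        # sex consistency across slots
        used_as_sire: set[str] = set()
        used_as_dam: set[str] = set()
        for rec in by_id.values():
            if rec.sire_id is not None:
                used_as_sire.add(rec.sire_id)
            if rec.dam_id is not None:
                used_as_dam.add(rec.dam_id)
        for aid in used_as_sire:
            if by_id[aid].sex == "female":
                raise PedigreeError(f"animal {aid!r} recorded female but used as sire")
        for aid in used_as_dam:
            if by_id[aid].sex == "male":
                raise PedigreeError(f"animal {aid!r} recorded male but used as dam")

        order = _topological_order(by_id)
        index = {a: i for i, a in enumerate(order)}
        n = len(order)
        sire = np.full(n, -1, dtype=np.int64)
        dam = np.full(n, -1, dtype=np.int64)
        sex = np.zeros(n, dtype=np.int8)
        year = np.full(n, YEAR_UNSET, dtype=np.int64)
        for aid, i in index.items():
            rec = by_id[aid]
            if rec.sire_id is not None:
                sire[i] = index[rec.sire_id]
            if rec.dam_id is not None:
                dam[i] = index[rec.dam_id]
            sex[i] = _SEX_CODE[rec.sex]
            if rec.birth_year is not None:
                year[i] = rec.birth_year

        ped = cls(order, sire, dam, sex, year)
        ped._warn_parent_ages()
        return ped

    def _warn_parent_ages(self) -> None:
        # registry noise: parent recorded as born at/after its offspring
        for par in (self.sire, self.dam):
            off = np.nonzero(par >= 0)[0]
            py = self.birth_year[par[off]]
            oy = self.birth_year[off]
            bad = off[(py != YEAR_UNSET) & (oy != YEAR_UNSET) & (py >= oy)]
            for i in bad[:20]:
                logger.warning(
                    "parent %r born %d, offspring %r born %d",
                    self.ids[par[i]], self.birth_year[par[i]],
                    self.ids[i], self.birth_year[i],
                )

    # ------------------------------------------------------------------
    # basic queries
    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, animal_id: str) -> bool:
        return animal_id in self.index

    def __iter__(self) -> Iterator[PedigreeRecord]:
        for i in range(len(self)):
            yield self.record(self.ids[i])

    def record(self, animal_id: str) -> PedigreeRecord:
        i = self.index[animal_id]
        return PedigreeRecord(
            animal_id=self.ids[i],
            sire_id=self.ids[self.sire[i]] if self.sire[i] >= 0 else None,
            dam_id=self.ids[self.dam[i]] if self.dam[i] >= 0 else None,
            sex=_SEX_LABEL[int(self.sex[i])],
            birth_year=int(self.birth_year[i]) if self.birth_year[i] != YEAR_UNSET else None,
        )

    @property
    def founder_mask(self) -> np.ndarray:
        """Animals with both parents unknown."""
        return (self.sire < 0) & (self.dam < 0)

    @property
    def year_known_mask(self) -> np.ndarray:
        return self.birth_year != YEAR_UNSET

    def children_of(self) -> list[list[int]]:
        """Offspring index lists, one per animal (built lazily)."""
        if self._children is None:
            kids: list[list[int]] = [[] for _ in range(len(self))]
            for i in range(len(self)):
                if self.sire[i] >= 0:
                    kids[self.sire[i]].append(i)
                if self.dam[i] >= 0:
                    kids[self.dam[i]].append(i)
            self._children = kids
        return self._children

    def indices(self, animal_ids: Iterable[str]) -> np.ndarray:
        return np.fromiter((self.index[a] for a in animal_ids), dtype=np.int64)

    # ------------------------------------------------------------------
    # I/O
    # ------------------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Canonical table: topological order, MISSING as empty string."""
        sire_ids = ["" if s < 0 else self.ids[s] for s in self.sire]
        dam_ids = ["" if d < 0 else self.ids[d] for d in self.dam]
        sexes = [_SEX_LABEL[int(s)] for s in self.sex]
        years = ["" if y == YEAR_UNSET else str(int(y)) for y in self.birth_year]
        return pd.DataFrame(
            {"animal": self.ids, "sire": sire_ids, "dam": dam_ids,
             "sex": sexes, "birth_date": years}
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _topological_order(by_id: Mapping[str, PedigreeRecord]) -> list[str]:
    """Kahn's algorithm with a deterministic (birth_year, id) tie-break.

    Raises :class:`PedigreeCycleError` with one explicit cycle if the
    graph is not acyclic.
    """
    n_unmet = {a: 0 for a in by_id}
    children: dict[str, list[str]] = {a: [] for a in by_id}
    for rec in by_id.values():
        for pid in (rec.sire_id, rec.dam_id):
            if pid is not None:
                n_unmet[rec.animal_id] += 1
                children[pid].append(rec.animal_id)

    def key(aid: str):
        y = by_id[aid].birth_year
        return (y if y is not None else -(10 ** 9), aid)

    ready = [key(a) for a, k in n_unmet.items() if k == 0]
    heapq.heapify(ready)
    order: list[str] = []
    while ready:
        _, aid = heapq.heappop(ready)
        order.append(aid)
        for child in children[aid]:
            n_unmet[child] -= 1
            if n_unmet[child] == 0:
                heapq.heappush(ready, key(child))
    if len(order) != len(by_id):
        raise PedigreeCycleError(_find_cycle(by_id, {a for a in by_id if n_unmet[a] > 0}))
    return order


def _find_cycle(by_id, remaining: set[str]) -> list[str]:
    start = min(remaining)
    seen: dict[str, int] = {}
    path: list[str] = []
    cur = start
    while cur not in seen:
        seen[cur] = len(path)
        path.append(cur)
        rec = by_id[cur]
        nxt = [p for p in (rec.sire_id, rec.dam_id) if p in remaining]
        cur = nxt[0]
    cycle = path[seen[cur]:] + [cur]
    return cycle


# ----------------------------------------------------------------------
# reading delimited files
# ----------------------------------------------------------------------
def _parse_birth_year(token: str | None, dayfirst: bool) -> int | None:
    if token is None:
        return None
    token = str(token).strip()
    if not token or token.lower() in {"na", "nan", "."}:
        return None
    if token.isdigit() and len(token) == 4:
        return int(token)
    ts = pd.to_datetime(token, dayfirst=dayfirst, errors="coerce")
    if ts is pd.NaT:
        logger.warning("unparseable birth date %r; birth year left unset", token)
        return None
    return int(ts.year)


def _parse_sex(token: str | None) -> str:
    if token is None:
        return "unknown"
    t = str(token).strip().lower()
    if t in _MALE_TOKENS:
        return "male"
    if t in _FEMALE_TOKENS:
        return "female"
    return "unknown"


def read_pedigree(path, dialect: PedigreeDialect = DEFAULT_DIALECT) -> Pedigree:
    """Read a delimited pedigree file into a validated :class:`Pedigree`.

    The file may or may not carry a header; when the configured columns
    are absent the first five columns are taken positionally as
    (animal, sire, dam, sex, birth_date).
    """
    sep = dialect.sep
    if sep is None:
        with open(path, "r", encoding="utf-8") as fh:
            first = fh.readline()
        sep = "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    cols = list(df.columns)
    if dialect.animal_col not in cols:
        # headerless file: re-read positionally
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, header=None)
        names = [dialect.animal_col, dialect.sire_col, dialect.dam_col]
        if dialect.sex_col:
            names.append(dialect.sex_col)
        if dialect.birth_col:
            names.append(dialect.birth_col)
        df.columns = names[: df.shape[1]] + [f"x{i}" for i in range(df.shape[1] - len(names))]

    missing = {t.lower() for t in dialect.missing_tokens} | {""}

    def parent(token: str) -> str | None:
        token = str(token).strip()
        return None if token.lower() in missing else token

    records = []
    for row in df.itertuples(index=False):
        d = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        records.append(
            PedigreeRecord(
                animal_id=str(d[dialect.animal_col]).strip(),
                sire_id=parent(d.get(dialect.sire_col, "")),
                dam_id=parent(d.get(dialect.dam_col, "")),
                sex=_parse_sex(d.get(dialect.sex_col)) if dialect.sex_col else "unknown",
                birth_year=_parse_birth_year(d.get(dialect.birth_col), dialect.dayfirst)
                if dialect.birth_col else None,
            )
        )
    return Pedigree.from_records(records)


# ----------------------------------------------------------------------
# population slices
# ----------------------------------------------------------------------
@dataclass(frozen=True)
class PopulationSlice:
    """A study population: member ids plus the full pedigree for recursion.

    Statistics over a slice always recurse through the complete
    pedigree, so ancestors born outside the window still count as known.
    """

    label: str
    member_ids: frozenset[str]
    pedigree: Pedigree

    def __post_init__(self):
        missing = [a for a in self.member_ids if a not in self.pedigree]
        if missing:
            raise PedigreeError(f"slice members not in pedigree: {sorted(missing)[:5]}")

    def __len__(self) -> int:
        return len(self.member_ids)

    @property
    def member_indices(self) -> np.ndarray:
        return np.sort(self.pedigree.indices(self.member_ids))


def historical_slice(ped: Pedigree, label: str = "historical") -> PopulationSlice:
    return PopulationSlice(label, frozenset(ped.ids), ped)


def slice_by_birth_years(ped: Pedigree, start: int, end: int,
                         label: str | None = None) -> PopulationSlice:
    """Animals born in [start, end]; unset birth years are excluded."""
    if start > end:
        raise ValueError(f"start {start} > end {end}")
    mask = (ped.birth_year != YEAR_UNSET) & (ped.birth_year >= start) & (ped.birth_year <= end)
    members = frozenset(ped.ids[i] for i in np.nonzero(mask)[0])
    if not members:
        logger.warning("slice %s-%s is empty", start, end)
    return PopulationSlice(label or f"{start}–{end}", members, ped)


def reference_slice(sl: PopulationSlice) -> PopulationSlice:
    """Members restricted to animals with both parents known."""
    ped = sl.pedigree
    members = frozenset(
        a for a in sl.member_ids
        if ped.sire[ped.index[a]] >= 0 and ped.dam[ped.index[a]] >= 0
    )
    return PopulationSlice(f"{sl.label} (reference)", members, ped)


def census_summary(sl: PopulationSlice) -> dict[str, int]:
    """Registry head-counts for a slice.

    Parents are attributed by the offspring's birth year: an animal is a
    sire/dam of the slice if it has at least one offspring among the
    members, regardless of its own birth year.  Progeny counts, in
    contrast, look at the whole pedigree ("kept for reproduction").
    """
    ped = sl.pedigree
    idx = sl.member_indices
    sire = ped.sire[idx]
    dam = ped.dam[idx]
    both = (sire >= 0) & (dam >= 0)
    sire_only = (sire >= 0) & (dam < 0)
    dam_only = (sire < 0) & (dam >= 0)
    none_known = (sire < 0) & (dam < 0)

    kids = ped.children_of()
    with_prog = sum(1 for i in idx if kids[i])
    return {
        "total": int(len(idx)),
        "reference": int(both.sum()),
        "dams_total": int(len(np.unique(dam[dam >= 0]))),
        "sires_total": int(len(np.unique(sire[sire >= 0]))),
        "with_progeny": int(with_prog),
        "without_progeny": int(len(idx) - with_prog),
        "both_known": int(both.sum()),
        "sire_only": int(sire_only.sum()),
        "dam_only": int(dam_only.sum()),
        "no_known_parent": int(none_known.sum()),
    }
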