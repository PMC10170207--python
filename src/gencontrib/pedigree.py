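"""Reading, validating and traversing genealogical pedigrees.

A pedigree is a set of individual records (id, sire, dam, sex, birth/death
years, birth/marriage places, marriage year) linked into a directed acyclic
graph by the parent columns.  All downstream computations — local-population
presence, expected genetic contributions, fitness proxies — operate on the
:class:`PedigreeTable` built here.

Input is schema-mapped delimited text (CSV/TSV); a minimal 3-column file
(id, sire, dam) is also accepted.  Parents referenced but absent from the id
column are materialised as *stub* founders so that traversal never dangles.
"""

from __future__ import annotations

import csv
import logging
import math
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

logger = logging.getLogger("gencontrib")

FEMALE = "F"
MALE = "M"
UNKNOWN = "U"

#: default mapping from canonical field name to input column name
DEFAULT_DIALECT: dict[str, str] = {
    "id": "id",
    "sire": "sire",
    "dam": "dam",
    "sex": "sex",
    "birth_year": "birth_year",
    "death_year": "death_year",
    "birth_place": "birth_place",
    "marriage_place": "marriage_place",
    "marriage_year": "marriage_year",
}

_SEX_CODES = {
    "f": FEMALE, "female": FEMALE, "2": FEMALE,
    "m": MALE, "male": MALE, "1": MALE,
    "u": UNKNOWN, "unknown": UNKNOWN, "0": UNKNOWN, "": UNKNOWN,
}


class PedigreeError(ValueError):
    """Raised for structural problems: cycles, duplicate ids, self-parenting."""


@dataclass(frozen=True)
class IndividualRecord:
    """One genealogy row.  Years are integer calendar years; missing is None."""

    id: str
    sire_id: str | None = None
    dam_id: str | None = None
    sex: str = UNKNOWN
    birth_year: int | None = None
    death_year: int | None = None
    birth_place: str | None = None
    marriage_place: str | None = None
    marriage_year: int | None = None
    is_stub: bool = False

    def __post_init__(self) -> None:
        if self.sire_id == self.id or self.dam_id == self.id:
            raise PedigreeError(f"individual {self.id!r} lists itself as a parent")
        if (
            self.birth_year is not None
            and self.death_year is not None
            and self.death_year < self.birth_year
        ):
            raise PedigreeError(
                f"individual {self.id!r}: death year {self.death_year} precedes "
                f"birth year {self.birth_year}"
            )

    @property
    def is_founder(self) -> bool:
        return self.sire_id is None and self.dam_id is None

    @property
    def lifespan(self) -> int | None:
        if self.birth_year is None or self.death_year is None:
            return None
        return self.death_year - self.birth_year


class PedigreeTable:
    """Validated pedigree with a parent->offspring index.

    Parameters
    ----------
    records
        Individual records; ids must be unique and parent links acyclic.
        Parents referenced but not present are added as stub founders.
    """

    def __init__(self, records: Iterable[IndividualRecord]):
        self._records: dict[str, IndividualRecord] = {}
        for rec in records:
            if rec.id in self._records:
                raise PedigreeError(f"duplicate id {rec.id!r}")
            self._records[rec.id] = rec
        self._add_stubs()
        self.child_index: dict[str, set[str]] = {}
        for rec in self._records.values():
            for parent in (rec.sire_id, rec.dam_id):
                if parent is not None:
                    self.child_index.setdefault(parent, set()).add(rec.id)
        self._check_acyclic()
        self._topo_cache: list[str] | None = None

    # -- construction helpers -------------------------------------------------

    def _add_stubs(self) -> None:
        stubs = []
        for rec in self._records.values():
            for parent, sex in ((rec.sire_id, MALE), (rec.dam_id, FEMALE)):
                if parent is not None and parent not in self._records:
                    stubs.append(IndividualRecord(id=parent, sex=sex, is_stub=True))
        if stubs:
            logger.warning(
                "%d parent id(s) absent from the id column; added as stub founders",
                len(stubs),
            )
            for s in stubs:
                self._records.setdefault(s.id, s)

    def _check_acyclic(self) -> None:
        # Kahn's algorithm on parent->child edges; leftover nodes form cycles.
        indeg = {i: 0 for i in self._records}
        for rec in self._records.values():
            n = (rec.sire_id is not None) + (rec.dam_id is not None)
            indeg[rec.id] = n
        queue = deque(i for i, d in indeg.items() if d == 0)
        seen = 0
        while queue:
            node = queue.popleft()
            seen += 1
            for child in self.child_index.get(node, ()):
                indeg[child] -= 1
                if indeg[child] == 0:
                    queue.append(child)
        if seen != len(self._records):
            cycle = sorted(i for i, d in indeg.items() if d > 0)
            raise PedigreeError(f"cycle in parent links involving: {cycle}")

    # -- mapping-ish API ------------------------------------------------------

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, ind_id: str) -> bool:
        return ind_id in self._records

    def __getitem__(self, ind_id: str) -> IndividualRecord:
        try:
            return self._records[ind_id]
        except KeyError:
            raise KeyError(f"unknown individual id {ind_id!r}") from None

    def __iter__(self):
        return iter(self._records.values())

    @property
    def ids(self) -> list[str]:
        return list(self._records)

    def children(self, ind_id: str) -> set[str]:
        return set(self.child_index.get(ind_id, ()))

    def topological_order(self) -> list[str]:
        """Ids ordered so every parent precedes all of its offspring."""
        if self._topo_cache is None:
            indeg = {
                r.id: (r.sire_id is not None) + (r.dam_id is not None)
                for r in self._records.values()
            }
            queue = deque(sorted(i for i, d in indeg.items() if d == 0))
            order: list[str] = []
            while queue:
                node = queue.popleft()
                order.append(node)
                for child in sorted(self.child_index.get(node, ())):
                    indeg[child] -= 1
                    if indeg[child] == 0:
                        queue.append(child)
            self._topo_cache = order
        return self._topo_cache

    def to_frame(self) -> pd.DataFrame:
        """Normalised genealogy table, one row per individual (stubs included)."""
        rows = [
            {
                "id": r.id,
                "sire": r.sire_id,
                "dam": r.dam_id,
                "sex": r.sex,
                "birth_year": r.birth_year,
                "death_year": r.death_year,
                "birth_place": r.birth_place,
                "marriage_place": r.marriage_place,
                "marriage_year": r.marriage_year,
            }
            for r in self._records.values()
        ]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class PedigreeSummary:
    n_individuals: int
    n_maternities: int
    n_paternities: int
    n_fullsib_pairs: int
    n_founders: int
    mean_depth: float
    max_depth: int
    mean_maternal_sibship: float
    mean_paternal_sibship: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


# -- loading ------------------------------------------------------------------


def _parse_year(value) -> int | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if not s or s.lower() in {"na", "nan", "none"}:
        return None
    return int(float(s))


def _parse_str(value) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    s = str(value).strip()
    if not s or s.lower() in {"na", "nan", "none"}:
        return None
    return s


def load_genealogy(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> PedigreeTable:
    """Read a delimited genealogy file into a validated :class:`PedigreeTable`.

    Parameters
    ----------
    path
        CSV or TSV file, UTF-8.  The delimiter is sniffed unless ``sep`` is
        given.
    dialect
        Mapping from canonical field names (``id``, ``sire``, ``dam``, ...)
        to the file's column names; unmapped optional fields are left missing.
        ``id``, ``sire`` and ``dam`` must be mappable.

    Raises
    ------
    PedigreeError
        On missing mandatory columns, duplicate ids, self-parenting or parent
        cycles; the offending rows/ids are named in the message.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mapping = dict(DEFAULT_DIALECT)
    if dialect:
        mapping.update(dialect)
    if sep is None:
        with open(path, newline="", encoding="utf-8") as fh:
            sample = fh.read(4096)
        try:
            sep = csv.Sniffer().sniff(sample, delimiters=",\t;").delimiter
        except csv.Error:
            sep = ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for field_name in ("id", "sire", "dam"):
        if mapping[field_name] not in df.columns:
            raise PedigreeError(
                f"mandatory column {mapping[field_name]!r} (for {field_name}) "
                f"not found in {path.name}; available: {list(df.columns)}"
            )

    def col(row, name):
        c = mapping.get(name)
        return row.get(c) if c in df.columns else None

    records = []
    for i, row in enumerate(df.to_dict("records"), start=2):  # header is line 1
        try:
            records.append(
                IndividualRecord(
                    id=_parse_str(col(row, "id")),
                    sire_id=_parse_str(col(row, "sire")),
                    dam_id=_parse_str(col(row, "dam")),
                    sex=_SEX_CODES.get(
                        (_parse_str(col(row, "sex")) or "").lower(), UNKNOWN
                    ),
                    birth_year=_parse_year(col(row, "birth_year")),
                    death_year=_parse_year(col(row, "death_year")),
                    birth_place=_parse_str(col(row, "birth_place")),
                    marriage_place=_parse_str(col(row, "marriage_place")),
                    marriage_year=_parse_year(col(row, "marriage_year")),
                )
            )
        except PedigreeError as exc:
            raise PedigreeError(f"{path.name} line {i}: {exc}") from None
    return PedigreeTable(records)


def write_genealogy(ped: PedigreeTable, path: str | Path) -> None:
    """Write the normalised genealogy CSV (lossless round-trip partner of
    :func:`load_genealogy`; stub founders are written like any other row)."""
    df = ped.to_frame()
    for c in ("birth_year", "death_year", "marriage_year"):
        df[c] = df[c].astype("Int64")
    df.to_csv(path, index=False)


def pedigree_table_from_frame(df: pd.DataFrame) -> PedigreeTable:
    """Build a PedigreeTable from an in-memory normalised frame
    (columns as in :meth:`PedigreeTable.to_frame`)."""
    records = []
    for row in df.to_dict("records"):
        records.append(
            IndividualRecord(
                id=_parse_str(row.get("id")),
                sire_id=_parse_str(row.get("sire")),
                dam_id=_parse_str(row.get("dam")),
                sex=_SEX_CODES.get(str(row.get("sex", "")).lower(), UNKNOWN),
                birth_year=_parse_year(row.get("birth_year")),
                death_year=_parse_year(row.get("death_year")),
                birth_place=_parse_str(row.get("birth_place")),
                marriage_place=_parse_str(row.get("marriage_place")),
                marriage_year=_parse_year(row.get("marriage_year")),
            )
        )
    return PedigreeTable(records)


# -- summaries and traversal ---------------------------------------------------


def pedigree_depths(ped: PedigreeTable) -> dict[str, int]:
    """Depth of each individual = length of its longest known-ancestor path
    (founders, including stubs, have depth 0)."""
    depths: dict[str, int] = {}
    for ind in ped.topological_order():
        rec = ped[ind]
        parent_depths = [
            depths[p] for p in (rec.sire_id, rec.dam_id) if p is not None
        ]
        depths[ind] = 1 + max(parent_depths) if parent_depths else 0
    return depths


def pedigree_summary(ped: PedigreeTable, one_based_depth: bool = True) -> PedigreeSummary:
    """Headline pedigree statistics.

    Full-sib pairs are unordered offspring pairs sharing both a known sire
    and a known dam.  Depth counts generations of known ancestors above an
    individual; with ``one_based_depth`` (default) founders are generation 1.
    """
    if len(ped) == 0:
        return PedigreeSummary(0, 0, 0, 0, 0, 0.0, 0, 0.0, 0.0)
    maternities = 0
    paternities = 0
    fullsib_groups: dict[tuple[str, str], int] = {}
    for rec in ped:
        if rec.dam_id is not None:
            maternities += 1
        if rec.sire_id is not None:
            paternities += 1
        if rec.sire_id is not None and rec.dam_id is not None:
            key = (rec.sire_id, rec.dam_id)
            fullsib_groups[key] = fullsib_groups.get(key, 0) + 1
    n_fullsib = sum(k * (k - 1) // 2 for k in fullsib_groups.values())
    founders = sum(1 for rec in ped if rec.is_founder)
    depths = pedigree_depths(ped)
    offset = 1 if one_based_depth else 0
    vals = [d + offset for d in depths.values()]
    mothers = {r.dam_id for r in ped if r.dam_id is not None}
    fathers = {r.sire_id for r in ped if r.sire_id is not None}
    return PedigreeSummary(
        n_individuals=len(ped),
        n_maternities=maternities,
        n_paternities=paternities,
        n_fullsib_pairs=n_fullsib,
        n_founders=founders,
        mean_depth=float(sum(vals) / len(vals)),
        max_depth=max(vals),
        mean_maternal_sibship=maternities / len(mothers) if mothers else 0.0,
        mean_paternal_sibship=paternities / len(fathers) if fathers else 0.0,
    )


def descendants(ped: PedigreeTable, focal: str) -> set[str]:
    """All individuals reachable from ``focal`` through offspring links,
    excluding the focal itself."""
    if focal not in ped:
        raise KeyError(f"unknown individual id {focal!r}")
    out: set[str] = set()
    stack = [focal]
    while stack:
        node = stack.pop()
        for child in ped.child_index.get(node, ()):
            if child not in out:
                out.add(child)
                stack.append(child)
    return out


def ancestors(ped: PedigreeTable, focal: str) -> set[str]:
    """All known ancestors of ``focal`` (transitive closure of parent links)."""
    if focal not in ped:
        raise KeyError(f"unknown individual id {focal!r}")
    out: set[str] = set()
    stack = [focal]
    while stack:
        rec = ped[stack.pop()]
        for parent in (rec.sire_id, rec.dam_id):
            if parent is not None and parent not in out:
                out.add(parent)
                stack.append(parent)
    return out
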