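"""Local-population presence and migration classification.

The gene pool of a parish in year *y* is the set of individuals alive and
located there at year end.  Location is inferred from birth and marriage
places: an individual born and married in a study parish is a *resident*,
born outside but married in is an *immigrant* (arriving at marriage), born
in but married outside is an *emigrant* (leaving at marriage), and born in
one study parish but married in the other is an *inter-parish mover* whose
residency switches to the destination parish in the marriage year.
Unmarried locally-born individuals count as residents; individuals with no
usable place information are unclassifiable and never enter a gene pool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .pedigree import PedigreeTable

logger = logging.getLogger("gencontrib")

RESIDENT = "resident"
IMMIGRANT = "immigrant"
EMIGRANT = "emigrant"
INTER_PARISH_MOVER = "inter_parish_mover"
UNCLASSIFIABLE = "unclassifiable"


@dataclass(frozen=True)
class MigrationStatus:
    status: str
    home_parish: str | None = None       # parish whose gene pool the individual belongs to
    origin_parish: str | None = None     # birth parish for movers/emigrants
    arrival_year: int | None = None
    departure_year: int | None = None

    def __post_init__(self) -> None:
        if self.status == IMMIGRANT and self.arrival_year is None:
            raise ValueError("immigrant status requires an arrival year")
        if self.status == EMIGRANT and self.departure_year is None:
            raise ValueError("emigrant status requires a departure year")


def classify_migration(
    ped: PedigreeTable, parishes: Iterable[str]
) -> dict[str, MigrationStatus]:
    """Classify every individual against the set of study parishes.

    Rules (place labels compared exactly):

    * born in parish, married in the same parish -> resident
    * born outside, married in a parish -> immigrant (arrival = marriage year)
    * born in parish, married outside -> emigrant (departure = marriage year)
    * born in one study parish, married in the other -> inter-parish mover
    * born in parish, never married -> resident
    * no usable place data (and not married in a parish) -> unclassifiable
    """
    parish_set = set(parishes)
    out: dict[str, MigrationStatus] = {}
    for rec in ped:
        born_in = rec.birth_place if rec.birth_place in parish_set else None
        married_in = rec.marriage_place if rec.marriage_place in parish_set else None
        married_at_all = rec.marriage_place is not None
        if born_in and married_in:
            if born_in == married_in:
                out[rec.id] = MigrationStatus(RESIDENT, home_parish=born_in)
            else:
                out[rec.id] = MigrationStatus(
                    INTER_PARISH_MOVER,
                    home_parish=married_in,
                    origin_parish=born_in,
                    arrival_year=rec.marriage_year,
                    departure_year=rec.marriage_year,
                )
        elif born_in and married_at_all:
            out[rec.id] = MigrationStatus(
                EMIGRANT,
                home_parish=born_in,
                origin_parish=born_in,
                departure_year=rec.marriage_year
                if rec.marriage_year is not None
                else (rec.death_year if rec.death_year is not None else rec.birth_year),
            )
        elif born_in:
            out[rec.id] = MigrationStatus(RESIDENT, home_parish=born_in)
        elif married_in:
            out[rec.id] = MigrationStatus(
                IMMIGRANT,
                home_parish=married_in,
                arrival_year=rec.marriage_year
                if rec.marriage_year is not None
                else rec.birth_year,
            )
        else:
            out[rec.id] = MigrationStatus(UNCLASSIFIABLE)
    return out


def _last_event_year(ped: PedigreeTable, ind_id: str) -> int | None:
    """Latest year the individual verifiably existed: own marriage or last
    offspring birth; falls back to birth year."""
    rec = ped[ind_id]
    years = [rec.birth_year, rec.marriage_year]
    for child in ped.child_index.get(ind_id, ()):
        years.append(ped[child].birth_year)
    years = [y for y in years if y is not None]
    return max(years) if years else None


def presence_interval(
    ped: PedigreeTable,
    statuses: Mapping[str, MigrationStatus],
    ind_id: str,
    parish: str,
    censor_horizon: int = 0,
) -> tuple[int, int] | None:
    """Closed [start, end] year interval during which ``ind_id`` belongs to
    ``parish``'s gene pool, or None if never present there.

    An individual with a missing death year is kept until its last recorded
    event (own marriage, last offspring birth) plus ``censor_horizon`` years.
    """
    st = statuses.get(ind_id)
    if st is None or st.status == UNCLASSIFIABLE:
        return None
    rec = ped[ind_id]
    end_of_life = rec.death_year
    if end_of_life is None:
        last = _last_event_year(ped, ind_id)
        if last is None:
            return None
        end_of_life = last + censor_horizon

    if st.status == RESIDENT and st.home_parish == parish:
        start, end = rec.birth_year, end_of_life
    elif st.status == IMMIGRANT and st.home_parish == parish:
        start, end = st.arrival_year, end_of_life
    elif st.status == EMIGRANT and st.home_parish == parish:
        start, end = rec.birth_year, st.departure_year
    elif st.status == INTER_PARISH_MOVER and st.origin_parish == parish:
        # present in the birth parish up to the year before the move
        move = st.departure_year
        if move is None or rec.birth_year is None:
            return None
        start, end = rec.birth_year, move - 1
    elif st.status == INTER_PARISH_MOVER and st.home_parish == parish:
        # transition year assigned to the destination parish
        start, end = st.arrival_year, end_of_life
    else:
        return None
    if start is None or end is None or end < start:
        return None
    return int(start), int(end)


class PresenceTable:
    """Per-parish, per-year gene pool membership."""

    def __init__(self, parish: str, by_year: dict[int, set[str]]):
        self.parish = parish
        self.by_year = by_year

    @property
    def pop_size(self) -> dict[int, int]:
        return {y: len(s) for y, s in self.by_year.items()}

    @property
    def years(self) -> list[int]:
        return sorted(self.by_year)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"parish": self.parish, "year": y, "individual_id": i}
            for y in sorted(self.by_year)
            for i in sorted(self.by_year[y])
        ]
        return pd.DataFrame(rows, columns=["parish", "year", "individual_id"])

    def pop_size_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"parish": self.parish, "year": y, "n": len(self.by_year[y])}
             for y in sorted(self.by_year)]
        )


def presence_intervals(
    ped: PedigreeTable,
    statuses: Mapping[str, MigrationStatus],
    parish: str,
    year_range: tuple[int, int],
    censor_horizon: int = 0,
) -> dict[str, tuple[int, int]]:
    """Clipped closed presence interval per individual present in ``parish``
    at some point inside ``year_range``.  Presence is one contiguous
    interval per individual per parish by construction."""
    start_y, end_y = year_range
    out: dict[str, tuple[int, int]] = {}
    for ind_id in statuses:
        iv = presence_interval(ped, statuses, ind_id, parish, censor_horizon)
        if iv is None:
            continue
        lo, hi = max(iv[0], start_y), min(iv[1], end_y)
        if lo <= hi:
            out[ind_id] = (lo, hi)
    return out


def build_presence(
    ped: PedigreeTable,
    statuses: Mapping[str, MigrationStatus],
    parish: str,
    year_range: tuple[int, int],
    censor_horizon: int = 0,
) -> PresenceTable:
    """Assemble the year-by-year gene pool of ``parish`` over ``year_range``
    (closed interval) from per-individual presence intervals."""
    start_y, end_y = year_range
    by_year: dict[int, set[str]] = {y: set() for y in range(start_y, end_y + 1)}
    for ind_id, (lo, hi) in presence_intervals(
        ped, statuses, parish, year_range, censor_horizon
    ).items():
        for y in range(lo, hi + 1):
            by_year[y].add(ind_id)
    empties = [y for y, s in by_year.items() if not s]
    if empties:
        logger.info(
            "parish %s: %d year(s) with an empty gene pool (e.g. %s)",
            parish, len(empties), empties[0],
        )
    return PresenceTable(parish, by_year)


def migration_rates(
    statuses: Mapping[str, MigrationStatus]
) -> dict[str, dict[str, float]]:
    """Per-parish proportions of each migration class among classifiable
    individuals.  Each individual counts toward its home parish; inter-parish
    movers count toward their parish of origin."""
    counts: dict[str, dict[str, int]] = {}
    for st in statuses.values():
        if st.status == UNCLASSIFIABLE:
            continue
        parish = st.origin_parish if st.status == INTER_PARISH_MOVER else st.home_parish
        bucket = counts.setdefault(parish, {})
        bucket[st.status] = bucket.get(st.status, 0) + 1
    rates: dict[str, dict[str, float]] = {}
    for parish, bucket in counts.items():
        total = sum(bucket.values())
        rates[parish] = {k: v / total for k, v in bucket.items()}
    return rates
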