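"""Expected individual genetic contributions (IGC) and their stabilization.

Under Mendelian expectation each parent transmits half of an offspring's
alleles, so the expected contribution of a focal individual to a descendant
is the additive-relationship coefficient between them, computed with the
focal's own parents severed so that only direct descent (never shared kin
ancestry) counts.  Summing the coefficients of everyone present in a parish
gene pool in a year and dividing by the number present yields the focal's
IGC for that year, a proportion in [0, 1].

Contributions are computed by propagating coefficients down the focal's
descendant subgraph in topological order — c(focal) = 1 and
c(d) = 0.5 c(sire(d)) + 0.5 c(dam(d)), non-descendant parents contributing
zero — which equals the focal's row of the numerator relationship matrix
built by the classical tabular method with the focal treated as a founder.
The dense tabular construction is also provided (``relationship_matrix``)
as the cross-check route for small pedigrees.

Stabilization: individuals are grouped into parish-specific 10-year birth
cohorts and, for each year, the Pearson correlation across cohort members
between that year's IGC and the final-year (default 1990) IGC is computed.
A cohort's IGC are considered stabilized when the correlation stays at or
above 0.95 for the final two generations (generation = mean parental age at
offspring birth).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .migration import MigrationStatus, PresenceTable
from .pedigree import PedigreeTable, descendants

logger = logging.getLogger("gencontrib")

FINAL_YEAR_DEFAULT = 1990


# -- expected contributions ----------------------------------------------------


@dataclass(frozen=True)
class ContributionVector:
    """Expected contribution of ``focal`` to itself (1) and each descendant."""

    focal: str
    coeff: Mapping[str, float]

    def __getitem__(self, ind_id: str) -> float:
        return self.coeff.get(ind_id, 0.0)


def expected_contribution_vector(ped: PedigreeTable, focal: str) -> ContributionVector:
    """Expected genetic contributions of ``focal`` to all of its descendants.

    The focal's parents are (implicitly) severed: propagation only descends,
    so kin contributions through shared ancestors are excluded by
    construction.
    """
    if focal not in ped:
        raise KeyError(f"unknown individual id {focal!r}")
    desc = descendants(ped, focal)
    coeff: dict[str, float] = {focal: 1.0}
    members = desc | {focal}
    # topological order restricted to the descendant subgraph
    for ind in ped.topological_order():
        if ind not in desc:
            continue
        rec = ped[ind]
        c = 0.0
        for parent in (rec.sire_id, rec.dam_id):
            if parent in coeff:
                c += 0.5 * coeff[parent]
        coeff[ind] = c
    assert all(i in members for i in coeff)
    return ContributionVector(focal=focal, coeff=coeff)


def relationship_matrix(
    ped: PedigreeTable, sever_parents_of: str | None = None
) -> tuple[np.ndarray, dict[str, int]]:
    """Numerator (additive) relationship matrix by the tabular method.

    Dense O(n^2); intended for pedigrees up to a few thousand individuals,
    where it serves as the independent route against which the per-focal
    propagation is checked.  With ``sever_parents_of`` set, that individual
    is treated as a founder, so its row holds its direct-descent expected
    contributions.
    """
    order = ped.topological_order()
    idx = {ind: k for k, ind in enumerate(order)}
    n = len(order)
    A = np.zeros((n, n))
    for ind in order:
        i = idx[ind]
        rec = ped[ind]
        if ind == sever_parents_of:
            sire = dam = None
        else:
            sire, dam = rec.sire_id, rec.dam_id
        si = idx[sire] if sire is not None else None
        di = idx[dam] if dam is not None else None
        a_self = 1.0
        if si is not None and di is not None:
            a_self += 0.5 * A[si, di]
        A[i, i] = a_self
        row = np.zeros(n)
        if si is not None:
            row += 0.5 * A[si]
        if di is not None:
            row += 0.5 * A[di]
        A[i, :i] = row[:i]
        A[:i, i] = row[:i]
    return A, idx


# -- IGC series ----------------------------------------------------------------


@dataclass
class IGCSeries:
    """Year-indexed proportional expected genetic contribution of one focal."""

    focal: str
    parish: str
    by_year: dict[int, float]

    @property
    def final_year_value(self) -> float:
        return self.by_year[max(self.by_year)] if self.by_year else float("nan")

    def value(self, year: int) -> float | None:
        return self.by_year.get(year)


def igc_series(
    vec: ContributionVector,
    presence: PresenceTable,
    start_year: int,
    end_year: int = FINAL_YEAR_DEFAULT,
) -> IGCSeries:
    """Convert a contribution vector into a per-year IGC series.

    by_year[y] = (sum of coefficients over individuals present in year y,
    including the focal itself while present) / pop size in year y.  Years
    with an empty gene pool are recorded as missing.
    """
    by_year: dict[int, float] = {}
    coeff = vec.coeff
    for y in range(start_year, end_year + 1):
        pool = presence.by_year.get(y)
        if not pool:
            continue  # undefined; logged once at presence-building time
        total = 0.0
        # iterate the smaller collection
        if len(coeff) <= len(pool):
            for ind, c in coeff.items():
                if ind in pool:
                    total += c
        else:
            for ind in pool:
                c = coeff.get(ind)
                if c:
                    total += c
        by_year[y] = total / len(pool)
    return IGCSeries(focal=vec.focal, parish=presence.parish, by_year=by_year)


def igc_series_from_intervals(
    vec: ContributionVector,
    intervals: Mapping[str, tuple[int, int]],
    pop_size: Mapping[int, int],
    parish: str,
    start_year: int,
    end_year: int = FINAL_YEAR_DEFAULT,
) -> IGCSeries:
    """Fast route for :func:`igc_series` when each individual's presence is
    one contiguous year interval: coefficients are scattered into a
    difference array at interval bounds and cumulatively summed over years.
    Exactly equals the set-based route."""
    n_years = end_year - start_year + 1
    diff = np.zeros(n_years + 1)
    for ind, c in vec.coeff.items():
        iv = intervals.get(ind)
        if iv is None:
            continue
        lo, hi = max(iv[0], start_year), min(iv[1], end_year)
        if lo > hi:
            continue
        diff[lo - start_year] += c
        diff[hi - start_year + 1] -= c
    totals = np.cumsum(diff[:-1])
    by_year = {}
    for k in range(n_years):
        y = start_year + k
        size = pop_size.get(y, 0)
        if size > 0:
            by_year[y] = totals[k] / size
    return IGCSeries(focal=vec.focal, parish=parish, by_year=by_year)


def igc_for_focals(
    ped: PedigreeTable,
    presence: PresenceTable,
    focals: Iterable[str],
    statuses: Mapping[str, MigrationStatus] | None = None,
    end_year: int = FINAL_YEAR_DEFAULT,
) -> dict[str, IGCSeries]:
    """IGC series for many focal individuals against one parish's gene pool.

    A focal's series starts at its birth year, or at its arrival year for
    immigrants.
    """
    out: dict[str, IGCSeries] = {}
    for focal in focals:
        rec = ped[focal]
        start = rec.birth_year
        if statuses is not None:
            st = statuses.get(focal)
            if st is not None and st.arrival_year is not None:
                start = st.arrival_year
        if start is None:
            logger.info("focal %s has no start year; skipped", focal)
            continue
        vec = expected_contribution_vector(ped, focal)
        out[focal] = igc_series(vec, presence, start, end_year)
    return out


def igc_wide_frame(series: Mapping[str, IGCSeries]) -> pd.DataFrame:
    """Wide CSV layout: rows = focal ids, columns = years."""
    return pd.DataFrame(
        {f: pd.Series(s.by_year) for f, s in series.items()}
    ).T.sort_index(axis=1)


# -- generation time -----------------------------------------------------------


def generation_time(
    ped: PedigreeTable,
    parish: str | None = None,
    statuses: Mapping[str, MigrationStatus] | None = None,
) -> tuple[float, float]:
    """Mean and standard error of parental age at offspring birth, pooled over
    sexes.  With ``parish`` given, restricted to parents whose home parish
    matches (per migration classification)."""
    gaps: list[int] = []
    for rec in ped:
        if rec.birth_year is None:
            continue
        for parent in (rec.sire_id, rec.dam_id):
            if parent is None:
                continue
            if parish is not None and statuses is not None:
                st = statuses.get(parent)
                if st is None or st.home_parish != parish:
                    continue
            pb = ped[parent].birth_year
            if pb is not None:
                gaps.append(rec.birth_year - pb)
    if not gaps:
        raise ValueError("no parent-offspring pairs with known birth years")
    arr = np.asarray(gaps, dtype=float)
    se = arr.std(ddof=1) / math.sqrt(len(arr)) if len(arr) > 1 else 0.0
    return float(arr.mean()), float(se)


# -- stabilization -------------------------------------------------------------


@dataclass
class StabilizationResult:
    parish: str
    cohort_start: int                      # first birth year of the decade
    n_members: int
    correlations: dict[int, float | None]  # year -> Pearson r (None = undefined)
    stabilized: bool
    window_years: int = 0


@dataclass
class StabilizationReport:
    parish: str
    final_year: int
    threshold: float
    window_years: int
    generation_time: float
    cohorts: list[StabilizationResult] = field(default_factory=list)

    @property
    def cutoff_birth_year(self) -> int | None:
        """Exclusive upper bound on birth decades with stabilized IGC: the
        first year after the latest decade such that it and every earlier
        (analysable) decade stabilized.  None if no leading decade
        stabilized."""
        cutoff = None
        for res in sorted(self.cohorts, key=lambda r: r.cohort_start):
            if res.stabilized:
                cutoff = res.cohort_start + 10
            else:
                break
        return cutoff

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for res in self.cohorts:
            for year, r in sorted(res.correlations.items()):
                rows.append(
                    {
                        "parish": self.parish,
                        "cohort": res.cohort_start,
                        "year": year,
                        "r": r,
                        "n": res.n_members,
                    }
                )
        return pd.DataFrame(rows, columns=["parish", "cohort", "year", "r", "n"])


def _pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    if len(x) < 2 or x.std() == 0 or y.std() == 0:
        return None
    return float(np.corrcoef(x, y)[0, 1])


def cohort_stabilization(
    series: Mapping[str, IGCSeries],
    ped: PedigreeTable,
    parish: str,
    gen_time: float,
    cohort_width: int = 10,
    final_year: int = FINAL_YEAR_DEFAULT,
    threshold: float = 0.95,
    window_generations: float = 2.0,
) -> StabilizationReport:
    """Detect per-cohort stabilization of IGC.

    For each parish-specific ``cohort_width``-year birth cohort with at least
    two members, correlate members' IGC in each year with their final-year
    IGC.  The cohort is stabilized when r >= ``threshold`` for every year in
    the closed window [final_year - ceil(window_generations * gen_time),
    final_year]; years where the correlation is undefined (zero variance,
    or members not yet all present) fail the check.
    """
    window_years = math.ceil(window_generations * gen_time)
    report = StabilizationReport(
        parish=parish,
        final_year=final_year,
        threshold=threshold,
        window_years=window_years,
        generation_time=gen_time,
    )
    cohorts: dict[int, list[IGCSeries]] = {}
    for s in series.values():
        by = ped[s.focal].birth_year
        if by is None:
            continue
        cohorts.setdefault((by // cohort_width) * cohort_width, []).append(s)
    for start in sorted(cohorts):
        members = cohorts[start]
        if len(members) < 2:
            logger.info(
                "parish %s cohort %d: only %d member(s); excluded",
                parish, start, len(members),
            )
            continue
        finals = np.array([m.by_year.get(final_year, np.nan) for m in members])
        if np.isnan(finals).any():
            logger.info("parish %s cohort %d: missing final-year IGC; excluded",
                        parish, start)
            continue
        first_common = max(min(m.by_year) for m in members if m.by_year)
        corrs: dict[int, float | None] = {}
        for y in range(first_common, final_year + 1):
            vals = np.array([m.by_year.get(y, np.nan) for m in members])
            corrs[y] = None if np.isnan(vals).any() else _pearson(vals, finals)
        window = range(final_year - window_years, final_year + 1)
        all_extinct = bool(np.all(finals == 0.0))

        def year_ok(y: int) -> bool:
            r = corrs.get(y)
            if r is not None and r >= threshold:
                return True
            if all_extinct:
                # extinct lineages can never recover: identically-zero IGC
                # across the window is perfectly stable even though the
                # correlation is undefined
                vals = np.array([m.by_year.get(y, np.nan) for m in members])
                return bool(np.all(vals == 0.0))
            return False

        stabilized = all(year_ok(y) for y in window)
        report.cohorts.append(
            StabilizationResult(
                parish=parish,
                cohort_start=start,
                n_members=len(members),
                correlations=corrs,
                stabilized=stabilized,
                window_years=window_years,
            )
        )
    return report
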