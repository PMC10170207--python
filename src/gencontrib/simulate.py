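"""Synthetic genealogies, regression data with known truth, and gene dropping.

``simulate_population`` runs an individual-based yearly simulation of a
two-parish historical human population: high infant mortality (about a
quarter dead by age five, median lifespan near 50), marriage from the late
teens onward (mean around 25), births only within marriage while the wife
is aged between the adulthood threshold and 49, remarriage after widowhood,
emigration at marriage, immigrant spouses entering as pedigree founders,
and rare inter-parish moves.  Fertility is damped as a parish approaches
its carrying capacity so population size stays roughly stationary.  The
output uses the genealogy schema consumed by :mod:`gencontrib.pedigree`.

``simulate_regression_data`` draws covariates and a response from the exact
zero-inflated beta likelihood of :mod:`gencontrib.zib`, returning the
ground-truth parameters for recovery tests.

``gene_drop`` is the Monte-Carlo oracle for expected contributions: the
focal's two distinguishable alleles are dropped down the pedigree by
independent Mendelian sampling, and the realized proportion of focal allele
copies in a year's gene pool is averaged over replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .migration import PresenceTable
from .pedigree import FEMALE, MALE, PedigreeTable, descendants, pedigree_table_from_frame
from .zib import ModelSpec, simulate_response

logger = logging.getLogger("gencontrib")

OUTSIDE = "outside"  # place label for the world beyond the study parishes


# -- demographic simulation ----------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Demographic parameters of the synthetic two-parish population.

    Defaults emulate a pre-industrial Alpine parish pair: ~26% dead by age
    five, reproduction from the late teens, a median of about four offspring
    among reproducers, a generation time near 32 years, roughly 16%
    immigrants and 21% emigrants among classifiable individuals, and parish
    sizes of a few hundred each.
    """

    parishes: tuple[str, ...] = ("ParishA", "ParishB")
    founding_size: tuple[int, ...] = (380, 240)
    years: tuple[int, int] = (1600, 1990)
    # age-specific annual mortality hazard (piecewise)
    q_infant: float = 0.13          # age 0
    q_child: float = 0.04           # ages 1-4
    q_juvenile: float = 0.006       # ages 5-14
    q_adult: float = 0.009          # ages 15-49
    q_senescent_base: float = 0.012  # age 50, then Gompertz growth
    q_senescent_rate: float = 0.085
    marriage_age_mean: float = 24.0
    marriage_age_sd: float = 4.0
    marriage_age_min: float = 19.0
    fertility: float = 0.32         # per-year birth probability while married
    fecundity_decline_age: float = 33.0  # female age at half fecundity
    female_fertile_max: int = 49
    crowding_exponent: float = 3.0  # strength of density damping near capacity
    p_emigrate: float = 0.40        # marry outside and leave, per marrying local
    p_immigrant_spouse: float = 0.30  # local marriage recruits an outside spouse
    p_move_parish: float = 0.002    # marry into the other study parish
    sex_ratio: float = 0.5

    def __post_init__(self) -> None:
        for name in ("q_infant", "q_child", "q_juvenile", "q_adult",
                     "p_emigrate", "p_immigrant_spouse", "p_move_parish",
                     "sex_ratio", "fertility"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if len(self.parishes) != len(self.founding_size):
            raise ValueError("one founding size per parish required")


class ExtinctionError(RuntimeError):
    """The simulated population died out; rerun with gentler mortality or
    higher fertility."""


@dataclass
class _Person:
    id: int
    sex: str
    birth_year: int
    parish: str            # current location ('' once emigrated)
    birth_place: str
    sire: int | None = None
    dam: int | None = None
    death_year: int | None = None
    marriage_year: int | None = None
    marriage_place: str | None = None
    spouse: int | None = None
    marriage_age: float = field(default=25.0)


def _annual_mortality(cfg: SimConfig, age: int) -> float:
    """Hazard for the yearly mortality sweep; the age-0 (infant) hazard is
    applied at birth instead, so age 0 here never occurs for in-simulation
    births."""
    if age == 0:
        return cfg.q_infant
    if age < 5:
        return cfg.q_child
    if age < 15:
        return cfg.q_juvenile
    if age < 50:
        return cfg.q_adult
    return min(1.0, cfg.q_senescent_base * np.exp(cfg.q_senescent_rate * (age - 50)))


def simulate_population(config: SimConfig | None = None, seed: int = 0
                        ) -> pd.DataFrame:
    """Simulate the genealogy; returns one row per ever-born individual in
    the genealogy schema (id, sire, dam, sex, birth_year, death_year,
    birth_place, marriage_place, marriage_year).  Deterministic given
    ``seed``."""
    cfg = config or SimConfig()
    rng = np.random.default_rng(seed)
    start, end = cfg.years
    people: dict[int, _Person] = {}
    next_id = 0

    def new_person(sex, birth_year, parish, birth_place, sire=None, dam=None):
        nonlocal next_id
        next_id += 1
        p = _Person(
            id=next_id, sex=sex, birth_year=birth_year, parish=parish,
            birth_place=birth_place, sire=sire, dam=dam,
            marriage_age=float(np.clip(
                rng.normal(cfg.marriage_age_mean, cfg.marriage_age_sd),
                cfg.marriage_age_min, 48.0)),
        )
        people[p.id] = p
        return p

    # founders: a standing population with a plausible age pyramid
    for parish, size in zip(cfg.parishes, cfg.founding_size):
        for _ in range(size):
            sex = FEMALE if rng.random() < cfg.sex_ratio else MALE
            age = int(rng.integers(0, 55))
            new_person(sex, start - age, parish, parish)

    capacity = dict(zip(cfg.parishes, cfg.founding_size))

    for year in range(start, end + 1):
        alive_by_parish: dict[str, list[_Person]] = {p: [] for p in cfg.parishes}
        for p in people.values():
            if p.death_year is None and p.parish in alive_by_parish:
                alive_by_parish[p.parish].append(p)

        for parish, members in alive_by_parish.items():
            if not members:
                raise ExtinctionError(
                    f"parish {parish} empty in {year}; increase fertility or "
                    "founding size, or soften mortality"
                )
        # mortality applies to everyone still alive, emigrants included
        for p in people.values():
            if p.death_year is None:
                if rng.random() < _annual_mortality(cfg, year - p.birth_year):
                    p.death_year = year

        # crowding factor: damps fertility and immigrant recruitment so the
        # parish hovers near its carrying capacity
        damp_by_parish = {}
        for parish in cfg.parishes:
            n_alive = sum(1 for p in alive_by_parish[parish]
                          if p.death_year is None)
            damp_by_parish[parish] = min(
                1.25,
                (capacity[parish] / max(n_alive, 1)) ** cfg.crowding_exponent,
            )

        # marriage market, per parish
        for parish in cfg.parishes:
            singles = [
                p for p in alive_by_parish[parish]
                if p.death_year is None
                and p.marriage_year is None
                and (year - p.birth_year) >= p.marriage_age
            ]
            widowed = [
                p for p in alive_by_parish[parish]
                if p.death_year is None and p.spouse is not None
                and people[p.spouse].death_year is not None
            ]
            for p in widowed:
                p.spouse = None  # back on the market; first marriage stays on record
            candidates = singles + widowed
            rng.shuffle(candidates)
            pool_f = [p for p in candidates if p.sex == FEMALE]
            pool_m = [p for p in candidates if p.sex == MALE]
            for p in candidates:
                if p.spouse is not None or p.death_year is not None:
                    continue
                first = p.marriage_year is None
                u = rng.random()
                if first and u < cfg.p_emigrate:
                    # marries outside the study populations and leaves
                    p.marriage_year = year
                    p.marriage_place = OUTSIDE
                    p.parish = ""
                    continue
                if first and u < cfg.p_emigrate + cfg.p_move_parish and len(cfg.parishes) > 1:
                    other = [q for q in cfg.parishes if q != parish][0]
                    p.marriage_year = year
                    p.marriage_place = other
                    p.parish = other
                    # spouse in the destination parish is drawn next year there
                    continue
                if rng.random() < cfg.p_immigrant_spouse * min(
                        1.0, damp_by_parish[parish]):
                    sp_sex = MALE if p.sex == FEMALE else FEMALE
                    sp_age = float(np.clip(
                        rng.normal(cfg.marriage_age_mean + 2, cfg.marriage_age_sd),
                        cfg.marriage_age_min, 50.0))
                    sp = new_person(sp_sex, year - int(sp_age), parish, OUTSIDE)
                    sp.marriage_year = year
                    sp.marriage_place = parish
                    sp.spouse = p.id
                    if p.marriage_year is None:
                        p.marriage_year = year
                        p.marriage_place = parish
                    p.spouse = sp.id
                else:
                    pool = pool_f if p.sex == MALE else pool_m
                    mate = next(
                        (q for q in pool if q.spouse is None
                         and q.death_year is None and q.id != p.id), None)
                    if mate is None:
                        continue  # waits for next year
                    for a, b in ((p, mate), (mate, p)):
                        if a.marriage_year is None:
                            a.marriage_year = year
                            a.marriage_place = parish
                        a.spouse = b.id

        # reproduction (married couples with a local, fertile wife)
        for parish in cfg.parishes:
            damp = damp_by_parish[parish]
            for p in alive_by_parish[parish]:
                if p.sex != FEMALE or p.spouse is None or p.death_year is not None:
                    continue
                mate = people[p.spouse]
                if mate.death_year is not None or p.parish != parish:
                    continue
                age = year - p.birth_year
                if not (cfg.marriage_age_min <= age <= cfg.female_fertile_max):
                    continue
                fecundity = 1.0 / (1.0 + np.exp((age - cfg.fecundity_decline_age) / 4.0))
                if rng.random() < cfg.fertility * damp * fecundity:
                    sex = FEMALE if rng.random() < cfg.sex_ratio else MALE
                    baby = new_person(sex, year, parish, parish,
                                      sire=mate.id, dam=p.id)
                    # infant hazard applies in the birth year itself
                    if rng.random() < cfg.q_infant:
                        baby.death_year = year

    # run out remaining lifetimes (mortality only, no births) so every death
    # year is recorded; the final-year gene pool then reflects true survival
    year = end
    while any(p.death_year is None for p in people.values()):
        year += 1
        for p in people.values():
            if p.death_year is None:
                if rng.random() < _annual_mortality(cfg, year - p.birth_year):
                    p.death_year = year

    rows = []
    for p in people.values():
        rows.append({
            "id": str(p.id),
            "sire": str(p.sire) if p.sire is not None else None,
            "dam": str(p.dam) if p.dam is not None else None,
            "sex": p.sex,
            "birth_year": p.birth_year,
            "death_year": p.death_year,
            "birth_place": p.birth_place,
            "marriage_place": p.marriage_place,
            "marriage_year": p.marriage_year,
        })
    df = pd.DataFrame(rows).sort_values("id", key=lambda s: s.astype(int))
    return df.reset_index(drop=True)


def simulate_pedigree(config: SimConfig | None = None, seed: int = 0
                      ) -> PedigreeTable:
    """Convenience wrapper: simulate and build the validated pedigree."""
    return pedigree_table_from_frame(simulate_population(config, seed))


# -- regression data with known ground truth -----------------------------------


def simulate_regression_data(
    coefficients: Mapping[str, object],
    n: int,
    seed: int = 0,
    n_cohorts: int = 4,
    zero_inflated: bool = True,
    proxy_dist: str = "poisson",
) -> tuple[pd.DataFrame, dict]:
    """Covariates plus a response drawn from the exact model likelihood.

    ``coefficients`` holds ``beta`` (and ``zero`` when zero-inflated) fixed
    effects ordered (intercept, proxy, parish[B], sex[M]), ``phi``, and the
    random-effect scales ``sigma_int_beta``/``sigma_slope_beta`` (zero-part
    analogues likewise).  The proxy is drawn Poisson(4) by default
    (count-like, as for offspring numbers) or standard log-normal with
    ``proxy_dist='lognormal'``.  Parish-specific 10-year birth cohorts are
    assigned uniformly.  Returns (data, ground truth).
    """
    if n < 100:
        raise ValueError("need n >= 100")
    rng = np.random.default_rng(seed)
    parish = np.where(rng.random(n) < 0.5, "A", "B")
    sex = np.where(rng.random(n) < 0.5, "F", "M")
    decade = 1600 + 10 * rng.integers(0, n_cohorts, n)
    cohort = np.char.add(np.char.add(parish.astype(str), ":"),
                         decade.astype(str))
    if proxy_dist == "poisson":
        proxy = rng.poisson(4.0, n).astype(float)
    elif proxy_dist == "lognormal":
        proxy = rng.lognormal(0.0, 1.0, n)
    else:
        raise ValueError(f"unknown proxy_dist {proxy_dist!r}")
    data = pd.DataFrame({
        "proxy": proxy, "parish": parish, "sex": sex, "birth_cohort": cohort,
    })
    spec = ModelSpec(response="igc", proxy="proxy", zero_inflated=zero_inflated)
    out, truth = simulate_response(data, spec, dict(coefficients),
                                   seed=int(rng.integers(0, 2**31 - 1)))
    truth["spec"] = spec
    return out, truth


# -- gene dropping -------------------------------------------------------------


@dataclass
class GeneDropResult:
    focal: str
    year: int
    reps: int
    realized: np.ndarray   # per-replicate proportion of focal allele copies
    expected_pool: int     # gene-pool size in the year

    @property
    def mean(self) -> float:
        return float(self.realized.mean())

    @property
    def mc_se(self) -> float:
        return float(self.realized.std(ddof=1) / np.sqrt(self.reps))


def gene_drop(
    ped: PedigreeTable,
    focal: str,
    presence: PresenceTable,
    year: int,
    reps: int = 10_000,
    seed: int = 0,
) -> GeneDropResult:
    """Monte-Carlo realized genetic contribution of ``focal`` to the gene
    pool of ``year``.

    The focal carries two distinguishable alleles; all other founders (and
    every non-descendant) carry null alleles.  Each replicate drops alleles
    down the focal's descendant subgraph by independent Mendelian sampling;
    the realized contribution is the number of focal allele copies among
    individuals present in the year divided by twice the pool size.
    """
    if reps < 2:
        raise ValueError("need at least 2 replicates for a Monte-Carlo s.e.")
    pool = presence.by_year.get(year)
    if pool is None:
        raise KeyError(f"year {year} outside the presence table")
    rng = np.random.default_rng(seed)
    desc = descendants(ped, focal)
    members = [i for i in ped.topological_order() if i in desc]
    # allele codes: 0 = null, 1/2 = the focal's two copies
    alleles: dict[str, np.ndarray] = {
        focal: np.tile(np.array([[1], [2]], dtype=np.int8), (1, reps))
    }
    for ind in members:
        rec = ped[ind]
        own = np.zeros((2, reps), dtype=np.int8)
        for slot, parent in enumerate((rec.sire_id, rec.dam_id)):
            if parent in alleles:
                pick = rng.integers(0, 2, reps)
                own[slot] = alleles[parent][pick, np.arange(reps)]
        alleles[ind] = own
    copies = np.zeros(reps, dtype=np.int64)
    for ind in pool:
        a = alleles.get(ind)
        if a is not None:
            copies += (a > 0).sum(axis=0)
    realized = copies / (2.0 * len(pool))
    return GeneDropResult(focal=focal, year=year, reps=reps,
                          realized=realized, expected_pool=len(pool))
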