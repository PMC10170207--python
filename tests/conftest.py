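import numpy as np
import pytest

from gencontrib.migration import build_presence, classify_migration, presence_intervals
from gencontrib.pedigree import IndividualRecord as R
from gencontrib.pedigree import PedigreeTable
from gencontrib.simulate import SimConfig, simulate_pedigree


def random_pedigree(n: int, rng: np.random.Generator,
                    p_parents: float = 0.8) -> PedigreeTable:
    """Random acyclic pedigree: individual i may take two distinct parents
    among earlier individuals, so topological order is the index order."""
    recs = []
    for i in range(n):
        sire = dam = None
        if i >= 4 and rng.random() < p_parents:
            sire, dam = rng.choice(i, size=2, replace=False)
            sire, dam = str(sire), str(dam)
        recs.append(R(str(i), sire_id=sire, dam_id=dam,
                      birth_year=1600 + i))
    return PedigreeTable(recs)


@pytest.fixture
def family_ped() -> PedigreeTable:
    """Two founders, two children who mate (inbred grandchild), one outbred
    grandchild via an unrelated immigrant."""
    return PedigreeTable([
        R("f", sex="M", birth_year=1700, death_year=1760, birth_place="Elm",
          marriage_place="Elm", marriage_year=1725),
        R("m", sex="F", birth_year=1702, death_year=1770, birth_place="Elm",
          marriage_place="Elm", marriage_year=1725),
        R("c1", sire_id="f", dam_id="m", sex="M", birth_year=1726,
          death_year=1790, birth_place="Elm", marriage_place="Elm",
          marriage_year=1750),
        R("c2", sire_id="f", dam_id="m", sex="F", birth_year=1728,
          death_year=1800, birth_place="Elm", marriage_place="Elm",
          marriage_year=1750),
        R("g", sire_id="c1", dam_id="c2", sex="F", birth_year=1755,
          death_year=1820, birth_place="Elm"),
        R("x", sex="F", birth_year=1730, death_year=1795,
          marriage_place="Elm", marriage_year=1752),
        R("g2", sire_id="c1", dam_id="x", sex="M", birth_year=1756,
          death_year=1830, birth_place="Elm"),
    ])


@pytest.fixture(scope="session")
def sim_setup():
    """Small simulated two-parish population shared across tests, with
    migration statuses, presence tables and intervals for parish A."""
    cfg = SimConfig(years=(1600, 1780), founding_size=(90, 60))
    ped = simulate_pedigree(cfg, seed=7)
    statuses = classify_migration(ped, cfg.parishes)
    births = [r.birth_year for r in ped if r.birth_year is not None]
    year_range = (min(births), 1780)
    presence = {
        p: build_presence(ped, statuses, p, year_range) for p in cfg.parishes
    }
    intervals = {
        p: presence_intervals(ped, statuses, p, year_range)
        for p in cfg.parishes
    }
    return {
        "cfg": cfg, "ped": ped, "statuses": statuses,
        "presence": presence, "intervals": intervals,
        "year_range": year_range, "final_year": 1780,
    }
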