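"""Fitness proxies, adulthood thresholds, lineage fates."""

import numpy as np
import pandas as pd
import pytest

from gencontrib.igc import IGCSeries
from gencontrib.migration import classify_migration
from gencontrib.pedigree import IndividualRecord as R
from gencontrib.pedigree import PedigreeTable
from gencontrib.proxies import (
    AdulthoodThreshold,
    adulthood_threshold,
    compute_proxies,
    extinction_stages,
    lineage_fates,
    offspring_mean_igc,
)

THRESH = AdulthoodThreshold(female=19.0, male=21.0, pooled=20.0)


def _series(focal, final, parish="Elm"):
    return IGCSeries(focal=focal, parish=parish, by_year={1990: final})


def _reproducers(n_per_sex, age_fn):
    """Pedigree with n reproducing individuals per sex whose age at first
    reproduction is age_fn(index)."""
    recs = []
    for sex in ("F", "M"):
        for i in range(n_per_sex):
            pid = f"{sex}{i}"
            recs.append(R(pid, sex=sex, birth_year=1700))
            kw = {"dam_id" if sex == "F" else "sire_id": pid}
            recs.append(R(f"k_{pid}", birth_year=1700 + age_fn(i), **kw))
    return PedigreeTable(recs)


class TestAdulthoodThreshold:
    def test_constant_ages(self):
        ped = _reproducers(25, lambda i: 20)
        thr = adulthood_threshold(ped)
        assert thr.female == thr.male == thr.pooled == 20.0

    def test_linear_interpolation_matches_bruteforce(self):
        # ages 19..118 per sex; brute-force type-7: idx = 0.05*(n-1) = 4.95
        ped = _reproducers(100, lambda i: 19 + i)
        thr = adulthood_threshold(ped)
        ages = np.arange(19, 119, dtype=float)
        k = 0.05 * (len(ages) - 1)
        lo = int(np.floor(k))
        expected = ages[lo] + (k - lo) * (ages[lo + 1] - ages[lo])
        assert thr.female == pytest.approx(expected)  # 23.95
        assert expected == pytest.approx(23.95)

    def test_too_few_reproducers(self):
        ped = _reproducers(5, lambda i: 20)
        with pytest.raises(ValueError, match="reproducing"):
            adulthood_threshold(ped)


class TestComputeProxies:
    def test_childless_individual(self):
        ped = PedigreeTable([R("a", sex="F", birth_year=1700, death_year=1750,
                               birth_place="Elm")])
        df = compute_proxies(ped, THRESH, {"a": _series("a", 0.0)})
        row = df.iloc[0]
        assert (row.lifespan, row.lrs, row.lrs_sa, row.grandoffspring) == \
            (50, 0, 0, 0)
        assert row.eligible_core and row.eligible_grand

    def test_hand_traced_family(self):
        """4 offspring, 2 surviving past the threshold, with 3 and 0
        grandoffspring."""
        recs = [
            R("p", sex="F", birth_year=1700, death_year=1760,
              birth_place="Elm"),
            # survivors (lifespan 40) and early deaths (lifespan 2)
            R("o1", dam_id="p", sex="F", birth_year=1725, death_year=1765),
            R("o2", dam_id="p", sex="M", birth_year=1727, death_year=1767),
            R("o3", dam_id="p", sex="F", birth_year=1730, death_year=1732),
            R("o4", dam_id="p", sex="M", birth_year=1733, death_year=1735),
        ]
        recs += [R(f"g{i}", dam_id="o1", birth_year=1750 + i)
                 for i in range(3)]
        ped = PedigreeTable(recs)
        df = compute_proxies(ped, THRESH, {"p": _series("p", 0.001)})
        row = df.iloc[0]
        assert (row.lrs, row.lrs_sa, row.grandoffspring) == (4, 2, 3)

    def test_incomplete_offspring_blocks_grandoffspring(self):
        ped = PedigreeTable([
            R("p", sex="F", birth_year=1700, death_year=1760),
            R("o", dam_id="p", birth_year=1725),        # death unknown
        ])
        df = compute_proxies(ped, THRESH, {"p": _series("p", 0.0)})
        row = df.iloc[0]
        assert np.isnan(row.grandoffspring)
        assert not row.eligible_grand and not row.eligible_model

    def test_lrs_sa_never_exceeds_lrs_and_order_invariance(self, sim_setup):
        ped = sim_setup["ped"]
        igc = {
            i: _series(i, 0.0, parish="ParishA")
            for i in list(ped.ids)[:200]
        }
        thr = adulthood_threshold(ped)
        df = compute_proxies(ped, thr, igc)
        assert (df.lrs_sa <= df.lrs).all()
        assert ((df.loc[df.lrs == 0, "grandoffspring"]).fillna(0) == 0).all()
        # record order must not matter
        shuffled = dict(reversed(list(igc.items())))
        df2 = compute_proxies(ped, thr, shuffled)
        pd.testing.assert_frame_equal(df, df2)


class TestLineageFates:
    def test_all_reproduced(self, family_ped):
        st = classify_migration(family_ped, {"Elm"})
        igc = {"f": _series("f", 0.01)}
        # restrict to descendants that reproduced: c1 and c2 did, g/g2 did not
        fates = lineage_fates(family_ped, st, igc, ["f"], 1990)
        f = fates[0]
        assert f.n_descendants == 4
        assert f.pct_descendants_reproduced == pytest.approx(50.0)
        assert not f.extinct

    def test_percentage_arithmetic(self):
        # 10 descendants: 2 reproduced, 3 alive-unreproduced, 5 failed of
        # which 2 emigrated -> 20/30/50, emigration share 40%
        recs = [R("root", sex="F", birth_year=1600, death_year=1670,
                  birth_place="Elm")]
        kids = []
        for i in range(10):
            kids.append(f"d{i}")
            recs.append(R(f"d{i}", dam_id="root", sex="F",
                          birth_year=1630,
                          death_year=None if 2 <= i < 5 else 1700,
                          birth_place="Elm",
                          marriage_place="Chur" if i in (5, 6) else None,
                          marriage_year=1655 if i in (5, 6) else None))
        for i in (0, 1):  # reproducers; their children die without issue
            recs.append(R(f"gk{i}", dam_id=f"d{i}", birth_year=1660,
                          death_year=1700, birth_place="Elm"))
        ped = PedigreeTable(recs)
        st = classify_migration(ped, {"Elm"})
        fates = lineage_fates(ped, st, {"root": _series("root", 0.0)},
                              ["root"], 1990)
        f = fates[0]
        assert f.n_descendants == 12  # 10 children + 2 grandchildren
        # 2 reproduced, 3 alive-unreproduced, 7 failed (5 dead incl. the two
        # grandchildren, 2 emigrated)
        assert f.pct_descendants_reproduced == pytest.approx(100 * 2 / 12)
        assert f.pct_descendants_alive_unreproduced == pytest.approx(100 * 3 / 12)
        assert f.pct_failed == pytest.approx(100 * 7 / 12)
        assert f.pct_failed_by_emigration == pytest.approx(100 * 2 / 7)

    def test_childless_focal_extinct_with_nan_percentages(self):
        ped = PedigreeTable([R("a", birth_year=1700, death_year=1750)])
        st = classify_migration(ped, {"Elm"})
        f = lineage_fates(ped, st, {"a": _series("a", 0.0)}, ["a"], 1990)[0]
        assert f.extinct and f.n_descendants == 0
        assert np.isnan(f.pct_descendants_reproduced)

    def test_extinction_flag_tracks_final_igc(self, sim_setup):
        ped = sim_setup["ped"]
        igc = {}
        ids = list(ped.ids)[:50]
        rng = np.random.default_rng(0)
        for i in ids:
            igc[i] = _series(i, float(rng.random() < 0.5) * 0.01)
        fates = lineage_fates(ped, sim_setup["statuses"], igc, ids, 1780)
        for f in fates:
            assert f.extinct == (igc[f.focal].final_year_value == 0.0)


class TestExtinctionStages:
    def test_stage_partition(self):
        df = pd.DataFrame({
            "igc": [0.0, 0.0, 0.0, 0.0, 0.01],
            "lifespan": [3, 50, 50, 50, 60],
            "lrs": [0, 0, 2, 3, 4],
            "lrs_sa": [0, 0, 0, 2, 2],
            "grandoffspring": [0, 0, 0, 0, 5],
        })
        out = extinction_stages(df, THRESH)
        c = out["counts"]
        assert c["died_before_adulthood"] == 1
        assert c["no_offspring"] == 1
        assert c["no_adult_surviving_offspring"] == 1
        assert c["no_grandoffspring"] == 1
        assert sum(out["pct_of_extinct"].values()) == pytest.approx(100.0)


class TestOffspringMeanIGC:
    def test_simple_mean(self, family_ped):
        igc = {"c1": _series("c1", 0.002), "c2": _series("c2", 0.000)}
        out = offspring_mean_igc(family_ped, igc, ["f", "g"])
        assert out["f"] == pytest.approx(0.001)
        assert "g" not in out  # non-reproducer excluded

    def test_all_offspring_extinct(self, family_ped):
        igc = {"c1": _series("c1", 0.0), "c2": _series("c2", 0.0)}
        assert offspring_mean_igc(family_ped, igc, ["f"])["f"] == 0.0
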