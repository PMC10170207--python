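"""Expected genetic contributions, IGC series, generation time and
stabilization detection."""

import math

import numpy as np
import pytest

from gencontrib.igc import (
    IGCSeries,
    cohort_stabilization,
    expected_contribution_vector,
    generation_time,
    igc_series,
    igc_series_from_intervals,
    relationship_matrix,
)
from gencontrib.migration import PresenceTable
from gencontrib.pedigree import IndividualRecord as R
from gencontrib.pedigree import PedigreeTable

from conftest import random_pedigree


class TestContributionVector:
    def test_offspring_half_self_one(self, family_ped):
        v = expected_contribution_vector(family_ped, "f")
        assert v["f"] == 1.0
        assert v["c1"] == 0.5

    def test_grandchild_via_one_child_quarter(self, family_ped):
        assert expected_contribution_vector(family_ped, "f")["g2"] == 0.25

    def test_grandchild_via_two_children_half(self, family_ped):
        # both of g's parents are offspring of f
        assert expected_contribution_vector(family_ped, "f")["g"] == 0.5

    def test_nondescendants_zero(self, family_ped):
        v = expected_contribution_vector(family_ped, "c1")
        assert v["m"] == 0.0 and v["c2"] == 0.0

    def test_unknown_focal(self, family_ped):
        with pytest.raises(KeyError):
            expected_contribution_vector(family_ped, "zz")

    def test_equals_severed_relationship_matrix(self):
        """Propagation must reproduce the tabular-method matrix row with the
        focal treated as a founder, to numerical identity."""
        rng = np.random.default_rng(11)
        for _ in range(10):
            ped = random_pedigree(int(rng.integers(30, 150)), rng)
            focal = str(rng.integers(0, len(ped)))
            A, idx = relationship_matrix(ped, sever_parents_of=focal)
            v = expected_contribution_vector(ped, focal)
            for j in ped.ids:
                expected = A[idx[focal], idx[j]] if j != focal else 1.0
                assert v[j] == pytest.approx(expected, abs=1e-12)

    def test_founder_completeness(self):
        """Contributions from all founders to a fully-pedigreed individual
        sum to one."""
        rng = np.random.default_rng(5)
        ped = random_pedigree(120, rng, p_parents=1.0)
        founders = [r.id for r in ped if r.is_founder]
        target = ped.ids[-1]
        total = sum(
            expected_contribution_vector(ped, f)[target] for f in founders
        )
        assert total == pytest.approx(1.0, abs=1e-12)


def _presence(parish, pools):
    return PresenceTable(parish, {y: set(s) for y, s in pools.items()})


class TestIGCSeries:
    def test_focal_with_child_among_unrelated(self, family_ped):
        pres = _presence("Elm", {1730: {"f", "c1", "x", "m"}})
        # m is f's mate, not descendant: (1 + 0.5 + 0 + 0) / 4
        v = expected_contribution_vector(family_ped, "f")
        s = igc_series(v, pres, 1730, 1730)
        assert s.by_year[1730] == pytest.approx(0.375)

    def test_dead_focal_no_descendants_zero(self, family_ped):
        pres = _presence("Elm", {1900: {"x"}})
        v = expected_contribution_vector(family_ped, "f")
        assert igc_series(v, pres, 1900, 1900).by_year[1900] == 0.0

    def test_alone_in_pool_is_one(self, family_ped):
        pres = _presence("Elm", {1710: {"f"}})
        v = expected_contribution_vector(family_ped, "f")
        assert igc_series(v, pres, 1710, 1710).by_year[1710] == 1.0

    def test_empty_pool_year_missing(self, family_ped):
        pres = _presence("Elm", {1710: set(), 1711: {"f"}})
        v = expected_contribution_vector(family_ped, "f")
        s = igc_series(v, pres, 1710, 1711)
        assert 1710 not in s.by_year and 1711 in s.by_year

    def test_monotone_dilution(self, family_ped):
        v = expected_contribution_vector(family_ped, "f")
        small = igc_series(v, _presence("Elm", {1730: {"f", "c1"}}), 1730, 1730)
        big = igc_series(
            v, _presence("Elm", {1730: {"f", "c1", "x", "m"}}), 1730, 1730)
        assert big.by_year[1730] < small.by_year[1730]

    def test_interval_route_equals_set_route(self, sim_setup):
        ped = sim_setup["ped"]
        parish = sim_setup["cfg"].parishes[0]
        pres = sim_setup["presence"][parish]
        ivs = sim_setup["intervals"][parish]
        rng = np.random.default_rng(2)
        focals = [i for i in ped.ids if ped[i].birth_year is not None
                  and i in ivs][:40]
        for focal in rng.choice(focals, size=8, replace=False):
            v = expected_contribution_vector(ped, focal)
            s1 = igc_series(v, pres, ped[focal].birth_year,
                            sim_setup["final_year"])
            s2 = igc_series_from_intervals(
                v, ivs, pres.pop_size, parish, ped[focal].birth_year,
                sim_setup["final_year"])
            assert s1.by_year.keys() == s2.by_year.keys()
            for y in s1.by_year:
                assert s1.by_year[y] == pytest.approx(s2.by_year[y], abs=1e-12)


class TestGenerationTime:
    def test_single_pair(self):
        ped = PedigreeTable([
            R("p", birth_year=1700), R("k", sire_id="p", birth_year=1732),
        ])
        mean, se = generation_time(ped)
        assert (mean, se) == (32.0, 0.0)

    def test_two_pairs_mean_and_se(self):
        ped = PedigreeTable([
            R("p", birth_year=1700),
            R("k1", sire_id="p", birth_year=1730),
            R("k2", sire_id="p", birth_year=1734),
        ])
        mean, se = generation_time(ped)
        assert mean == pytest.approx(32.0)
        assert se == pytest.approx(2.0)

    def test_no_pairs_errors(self):
        with pytest.raises(ValueError):
            generation_time(PedigreeTable([R("a", birth_year=1700)]))


def _series(focal, values, parish="P"):
    return IGCSeries(focal=focal, parish=parish, by_year=dict(values))


class TestStabilization:
    years = range(1900, 1991)

    def _ped(self, members):
        return PedigreeTable(
            [R(m, birth_year=1900) for m in members]
        )

    def test_constant_series_stabilize(self):
        members = ["a", "b", "c"]
        series = {
            m: _series(m, {y: v for y in self.years})
            for m, v in zip(members, (0.1, 0.2, 0.3))
        }
        rep = cohort_stabilization(series, self._ped(members), "P",
                                   gen_time=10.0, final_year=1990)
        assert len(rep.cohorts) == 1
        res = rep.cohorts[0]
        assert res.stabilized
        assert res.correlations[1990] == pytest.approx(1.0)

    def test_single_member_cohort_excluded(self):
        series = {"a": _series("a", {y: 0.1 for y in self.years})}
        rep = cohort_stabilization(series, self._ped(["a"]), "P",
                                   gen_time=10.0, final_year=1990)
        assert rep.cohorts == []

    def test_dip_below_threshold_fails(self):
        # values deviate inside the two-generation window
        series = {}
        finals = {"a": 0.1, "b": 0.2, "c": 0.3}
        for m, v in finals.items():
            vals = {y: v for y in self.years}
            series[m] = _series(m, vals)
        # inject an uncorrelated year inside the window (r far below 0.95)
        series["a"].by_year[1985] = 0.3
        series["b"].by_year[1985] = 0.1
        rep = cohort_stabilization(series, self._ped(finals), "P",
                                   gen_time=10.0, final_year=1990)
        assert not rep.cohorts[0].stabilized

    def test_all_extinct_cohort_counts_as_stabilized(self):
        members = ["a", "b"]
        series = {m: _series(m, {y: 0.0 for y in self.years})
                  for m in members}
        rep = cohort_stabilization(series, self._ped(members), "P",
                                   gen_time=10.0, final_year=1990)
        assert rep.cohorts[0].stabilized

    def test_cutoff_is_latest_leading_stabilized_decade(self):
        ped = PedigreeTable([
            R("a", birth_year=1900), R("b", birth_year=1900),
            R("c", birth_year=1910), R("d", birth_year=1910),
            R("e", birth_year=1920), R("f", birth_year=1920),
        ])
        def flat(focal, v):
            return _series(focal, {y: v for y in self.years})
        series = {
            "a": flat("a", 0.1), "b": flat("b", 0.2),
            "c": flat("c", 0.1), "d": flat("d", 0.3),
            "e": flat("e", 0.1), "f": flat("f", 0.2),
        }
        # break the 1920 cohort inside the window
        series["e"].by_year[1988] = 0.2
        series["f"].by_year[1988] = 0.1
        rep = cohort_stabilization(series, ped, "P", gen_time=10.0,
                                   final_year=1990)
        assert [c.stabilized for c in rep.cohorts] == [True, True, False]
        assert rep.cutoff_birth_year == 1920

    def test_window_uses_ceiled_generations(self):
        series = {m: _series(m, {y: v for y in self.years})
                  for m, v in (("a", 0.1), ("b", 0.2))}
        rep = cohort_stabilization(series, self._ped(["a", "b"]), "P",
                                   gen_time=31.7, final_year=1990)
        assert rep.window_years == math.ceil(2 * 31.7)
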