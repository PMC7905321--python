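"""Scheme policies: ranking, retention/transfer, service pools, culling."""

import numpy as np
import pytest

from polledsim import POLICIES, ScenarioConfig, Sector, Sex
from polledsim.breeding import mate
from polledsim.pedigree import UNKNOWN
from polledsim.population import Fate, Herdbook
from polledsim.selection import (
    build_service_pool,
    cull,
    rank_yearling_bulls,
    retain_and_transfer,
    steer_commercial_bull_calves,
)


def add_bulls(hb, genotypes, tbvs, sector=Sector.SEEDSTOCK, birth_year=-3, origin=None):
    n = len(genotypes)
    return hb.add(
        sex=np.full(n, Sex.MALE, np.int8),
        birth_year=birth_year,
        sector=sector,
        herd=-1,
        sire=UNKNOWN,
        dam=UNKNOWN,
        genotype=np.asarray(genotypes, np.int8),
        tbv=np.asarray(tbvs, float),
        origin_sector=origin,
    )


class TestRanking:
    def test_scheme_a_ranks_on_tbv_alone(self):
        ids = np.array([0, 1])
        order = rank_yearling_bulls(ids, np.array([0, 2]), np.array([80.0, 50.0]), POLICIES["A"])
        assert order.tolist() == [0, 1]  # horned $80 ahead of PP $50

    def test_polled_schemes_rank_genotype_first(self):
        ids = np.array([0, 1, 2])
        order = rank_yearling_bulls(
            ids, np.array([0, 2, 1]), np.array([80.0, 50.0, 60.0]), POLICIES["B"]
        )
        assert order.tolist() == [1, 2, 0]  # PP, then Pp, then horned

    def test_ties_break_by_lower_id(self):
        ids = np.array([5, 3])
        order = rank_yearling_bulls(ids, np.array([1, 1]), np.array([60.0, 60.0]), POLICIES["B"])
        assert order.tolist() == [3, 5]


class TestRetainAndTransfer:
    def test_top_five_percent_retained_rest_transferred(self, rng):
        hb = Herdbook()
        ids = add_bulls(hb, np.ones(1000, np.int8), rng.normal(50, 10, 1000), birth_year=0)
        cfg = ScenarioConfig()
        ranked = rank_yearling_bulls(ids, hb.genotype[ids], hb.tbv[ids], POLICIES["A"])
        retained, transferred = retain_and_transfer(hb, ranked, cfg)
        assert retained.size == 50 and transferred.size == 950
        assert np.array_equal(retained, ranked[:50])  # ranking prefix
        assert (hb.sector[transferred] == Sector.COMMERCIAL).all()
        assert (hb.sector[retained] == Sector.SEEDSTOCK).all()
        assert (hb.origin_sector[transferred] == Sector.SEEDSTOCK).all()


class TestServicePools:
    def test_scheme_d_pools_only_homozygous_polled(self, rng):
        hb = Herdbook()
        add_bulls(hb, [2, 1, 0, 2], [10, 99, 99, 20], sector=Sector.COMMERCIAL)
        cfg = ScenarioConfig()
        pool = build_service_pool(hb, int(Sector.COMMERCIAL), 0, cfg, POLICIES["D"], rng)
        assert set(pool) == {0, 3}  # the PP bulls only, regardless of TBV

    def test_scheme_d_seedstock_supplemented_by_commercial_born_pp(self, rng):
        hb = Herdbook()
        nucleus = add_bulls(hb, [2], [40], sector=Sector.SEEDSTOCK)
        comm_born = add_bulls(hb, [2, 2], [90, 80], sector=Sector.COMMERCIAL)
        transfers = add_bulls(
            hb, [2], [99], sector=Sector.COMMERCIAL, origin=int(Sector.SEEDSTOCK)
        )
        cfg = ScenarioConfig()
        pool = build_service_pool(hb, int(Sector.SEEDSTOCK), 0, cfg, POLICIES["D"], rng)
        assert pool[0] == nucleus[0]  # retained nucleus bull first
        assert set(pool[1:]) == set(comm_born)  # transfers never pulled back

    def test_scheme_b_tiers_polled_over_horned(self, rng):
        hb = Herdbook()
        add_bulls(hb, [0, 1, 2, 0], [99, 10, 20, 98])
        cfg = ScenarioConfig()
        pool = build_service_pool(hb, int(Sector.SEEDSTOCK), 0, cfg, POLICIES["B"], rng)
        assert pool.tolist() == [2, 1, 0, 3]  # polled tier by TBV, then horned

    def test_scheme_c_overflow_tier_is_tbv_only(self, rng):
        hb = Herdbook()
        add_bulls(hb, [2, 1, 0], [10, 50, 80])
        cfg = ScenarioConfig()
        pool = build_service_pool(hb, int(Sector.SEEDSTOCK), 0, cfg, POLICIES["C"], rng)
        assert pool.tolist() == [0, 2, 1]  # PP first; then horned $80 over Pp $50

    def test_scheme_d_capacity_arithmetic(self, rng):
        hb = Herdbook()
        bulls = add_bulls(hb, [2] * 5, [50] * 5, sector=Sector.COMMERCIAL)
        cfg = ScenarioConfig()
        pool = build_service_pool(hb, int(Sector.COMMERCIAL), 0, cfg, POLICIES["D"], rng)
        cows = {0: np.arange(100, 400, dtype=np.int64)}
        plan = mate(1, cows, {0: pool}, cfg.matings_per_bull, rng)
        assert plan.cow_ids.size == 175 and plan.n_open == 125


class TestSteering:
    def test_commercial_bull_calves_become_steers_except_d_pp(self, rng):
        cfg = ScenarioConfig()
        for scheme, expect_kept in (("A", 0), ("D", 1)):
            hb = Herdbook()
            calves = hb.add(
                sex=np.full(3, Sex.MALE, np.int8), birth_year=0,
                sector=Sector.COMMERCIAL, herd=10, sire=UNKNOWN, dam=UNKNOWN,
                genotype=np.array([2, 1, 0], np.int8), tbv=0.0,
            )
            steer_commercial_bull_calves(hb, calves, POLICIES[scheme], cfg, rng, 0, 10**6)
            kept = int((hb.status[calves] == Fate.ALIVE).sum())
            assert kept == expect_kept  # PP kept entire only under D


class TestCulling:
    def test_age_limits_enforced(self, rng):
        hb = Herdbook()
        hb.add(
            sex=np.array([0, 0, 1, 1], np.int8), birth_year=np.array([-10, -9, -5, -4]),
            sector=Sector.SEEDSTOCK, herd=0, sire=UNKNOWN, dam=UNKNOWN, genotype=1, tbv=0.0,
        )
        cull(hb, ScenarioConfig(), POLICIES["A"], 0, rng)
        assert hb.status[0] == Fate.CULLED_AGE  # cow aged exactly 10
        assert hb.status[1] == Fate.ALIVE
        assert hb.status[2] == Fate.CULLED_AGE  # bull aged 5
        assert hb.status[3] == Fate.ALIVE

    def test_seedstock_bull_cap_culls_horned_lowest_first_under_b(self, rng):
        hb = Herdbook()
        genos = np.array([0] * 30 + [1] * 20 + [2] * 20, np.int8)
        tbvs = np.arange(70, dtype=float)
        add_bulls(hb, genos, tbvs)
        counts = cull(hb, ScenarioConfig(), POLICIES["B"], 0, rng)
        assert counts[int(Sector.SEEDSTOCK)]["merit_cull_male"] == 10
        culled = np.flatnonzero(hb.status == Fate.CULLED_MERIT)
        assert (hb.genotype[culled] == 0).all()
        assert set(culled) == set(range(10))  # the lowest-TBV horned bulls

    def test_no_involuntary_culls_below_caps(self, rng):
        hb = Herdbook()
        add_bulls(hb, [1] * 10, [0.0] * 10)
        counts = cull(hb, ScenarioConfig(), POLICIES["A"], 0, rng)
        for c in counts.values():
            assert c["capacity_cull_female"] == 0 and c["merit_cull_male"] == 0
        assert (hb.status == Fate.ALIVE).all()

    def test_female_cap_enforced(self, rng):
        hb = Herdbook()
        hb.add(
            sex=np.zeros(3100, np.int8), birth_year=-2, sector=Sector.SEEDSTOCK,
            herd=0, sire=UNKNOWN, dam=UNKNOWN, genotype=1, tbv=0.0,
        )
        counts = cull(hb, ScenarioConfig(), POLICIES["A"], 0, rng)
        assert counts[int(Sector.SEEDSTOCK)]["capacity_cull_female"] == 100
        assert int(hb.alive().sum()) == 3000
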