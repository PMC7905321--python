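"""Portfolio assignment, mating caps, calf creation and mortality."""

import dataclasses

import numpy as np
import pytest

from polledsim import ScenarioConfig, Sector, Sex
from polledsim.breeding import apply_mortality, assign_portfolios, create_calves, mate
from polledsim.pedigree import UNKNOWN, PedigreeRegistry
from polledsim.population import Herdbook


def make_parents(n_bulls, n_cows, bull_geno=1, cow_geno=1, sector=Sector.COMMERCIAL):
    hb = Herdbook()
    reg = PedigreeRegistry()
    hb.add(
        sex=np.full(n_bulls, Sex.MALE, np.int8), birth_year=-3, sector=sector,
        herd=-1, sire=UNKNOWN, dam=UNKNOWN, genotype=bull_geno, tbv=50.0,
    )
    hb.add(
        sex=np.full(n_cows, Sex.FEMALE, np.int8), birth_year=-4, sector=sector,
        herd=0, sire=UNKNOWN, dam=UNKNOWN, genotype=cow_geno, tbv=10.0,
    )
    reg.register_batch(np.full(hb.n, UNKNOWN), np.full(hb.n, UNKNOWN))
    bulls = np.arange(n_bulls, dtype=np.int64)
    cows = np.arange(n_bulls, n_bulls + n_cows, dtype=np.int64)
    return hb, reg, bulls, cows


class TestPortfolios:
    def test_even_split_across_herds(self, rng):
        counts = {h: 700 for h in range(10)}
        out = assign_portfolios(counts, np.arange(200), 35, rng)
        assert sorted(len(v) for v in out.values()) == [20] * 10
        allocated = np.concatenate(list(out.values()))
        assert np.unique(allocated).size == 200  # no bull serves two herds

    def test_small_herd_portfolio(self, rng):
        out = assign_portfolios({0: 100}, np.array([7, 8]), 35, rng)
        assert set(out[0]) == {7, 8}

    def test_deficit_is_legal(self, rng):
        out = assign_portfolios({0: 700, 1: 700}, np.arange(5), 35, rng)
        assert sum(len(v) for v in out.values()) == 5  # 40 needed, 5 available


class TestMating:
    def test_full_capacity_leaves_no_open_cows(self, rng):
        cows = {0: np.arange(100, 170, dtype=np.int64)}
        plan = mate(1, cows, {0: np.arange(2, dtype=np.int64)}, 35, rng)
        assert plan.n_open == 0
        assert set(plan.bull_usage.values()) == {35}

    def test_single_bull_cap(self, rng):
        cows = {0: np.arange(100, 200, dtype=np.int64)}
        plan = mate(1, cows, {0: np.array([0], dtype=np.int64)}, 35, rng)
        assert plan.cow_ids.size == 35 and plan.n_open == 65
        assert max(plan.bull_usage.values()) == 35

    def test_each_cow_mated_at_most_once_and_usage_capped(self, rng):
        cows = {h: np.arange(1000 + 80 * h, 1000 + 80 * (h + 1), dtype=np.int64) for h in range(5)}
        portfolios = assign_portfolios({h: 80 for h in range(5)}, np.arange(14), 35, rng)
        plan = mate(1, cows, portfolios, 35, rng)
        assert np.unique(plan.cow_ids).size == plan.cow_ids.size
        assert max(plan.bull_usage.values()) <= 35


class TestCalfCreation:
    def test_zero_ms_variance_gives_exact_parent_average(self, rng):
        hb, reg, bulls, cows = make_parents(2, 20)
        cfg = dataclasses.replace(ScenarioConfig(), tbv_sd=0.0)
        calves = create_calves(hb, reg, np.repeat(bulls, 10), cows, 1, cfg, rng)
        assert np.allclose(hb.tbv[calves], 30.0)  # (50 + 10) / 2

    def test_pp_sire_horned_dam_gives_all_carriers(self, rng):
        hb, reg, bulls, cows = make_parents(1, 200, bull_geno=2, cow_geno=0)
        cfg = ScenarioConfig()
        calves = create_calves(hb, reg, np.repeat(bulls, 200), cows, 1, cfg, rng)
        assert (hb.genotype[calves] == 1).all()

    def test_sex_ratio_is_even(self, rng):
        hb, reg, bulls, cows = make_parents(1, 20000)
        calves = create_calves(
            hb, reg, np.repeat(bulls, 20000), cows, 1, ScenarioConfig(), rng
        )
        males = int(hb.sex[calves].sum())
        assert abs(males - 10000) < 3 * np.sqrt(20000 * 0.25)

    def test_calves_inherit_dam_herd_and_get_registered(self, rng):
        hb, reg, bulls, cows = make_parents(1, 5)
        calves = create_calves(hb, reg, np.repeat(bulls, 5), cows, 3, ScenarioConfig(), rng)
        assert (hb.herd[calves] == 0).all()
        assert (hb.birth_year[calves] == 3).all()
        assert len(reg) == len(hb)
        assert (reg.sire_ids[calves] == 0).all()

    def test_unregistered_parents_rejected(self, rng):
        hb, reg, bulls, cows = make_parents(1, 5)
        with pytest.raises(ValueError):
            create_calves(hb, reg, np.array([999]), cows[:1], 1, ScenarioConfig(), rng)


class TestMortality:
    def test_commercial_horned_survival_rate(self, rng):
        hb, reg, bulls, cows = make_parents(1, 30000, bull_geno=0, cow_geno=0)
        cfg = ScenarioConfig(mutation_rate=0.0)
        calves = create_calves(hb, reg, np.repeat(bulls, 30000), cows, 1, cfg, rng)
        apply_mortality(hb, calves, cfg, rng)
        surv = (hb.status[calves] == 0).mean()
        p = 0.87 * 0.98  # pre-weaning then dehorning, independent risks
        assert abs(surv - p) < 3 * np.sqrt(p * (1 - p) / 30000)

    def test_polled_calves_have_no_dehorning_deaths(self, rng):
        hb, reg, bulls, cows = make_parents(1, 20000, bull_geno=2, cow_geno=2)
        cfg = ScenarioConfig()
        calves = create_calves(hb, reg, np.repeat(bulls, 20000), cows, 1, cfg, rng)
        deaths = apply_mortality(hb, calves, cfg, rng)
        assert deaths["dehorning"] == 0

    def test_seedstock_preweaning_rate(self, rng):
        hb, reg, bulls, cows = make_parents(
            1, 30000, bull_geno=2, cow_geno=2, sector=Sector.SEEDSTOCK
        )
        cfg = ScenarioConfig()
        calves = create_calves(hb, reg, np.repeat(bulls, 30000), cows, 1, cfg, rng)
        deaths = apply_mortality(hb, calves, cfg, rng)
        assert deaths["preweaning"] / 30000 == pytest.approx(0.08, abs=0.005)
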