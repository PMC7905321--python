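"""Annual simulation cycle and replicated scenario runs.

One simulated year, per sector: build the scheme's service pool, assign
sire portfolios to herds, mate cows at random within herds under the
mating cap, create calves (parent-average TBV plus Mendelian sampling,
Mendelian genotype with the one-way mutation), gene-edit the selected
seedstock bull fetuses (so edited calves are born polled, ahead of the
mortality draws), apply calf mortality, steer commercial bull calves,
rank/retain/transfer seedstock yearling bulls, and cull to the age limits
and population caps.  Yearly statistics are captured after culling.

Scenario runs are replicated with per-replicate generators seeded as
``default_rng([master_seed, replicate])`` so every replicate is exactly
reproducible on its own.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .breeding import apply_mortality, assign_portfolios, create_calves, mate
from .config import ScenarioConfig, scenario_name
from .editing import perform_edits, select_edit_candidates
from .genetics import horned_frequency_from_codes
from .pedigree import PedigreeRegistry
from .population import Fate, Herdbook, Sector, Sex, build_base_population
from .selection import (
    POLICIES,
    MatingSchemePolicy,
    build_service_pool,
    cull,
    rank_yearling_bulls,
    retain_and_transfer,
    steer_commercial_bull_calves,
)

log = logging.getLogger("polledsim")

_SECTOR_NAMES = {int(Sector.SEEDSTOCK): "seedstock", int(Sector.COMMERCIAL): "commercial"}


def _cows_by_herd(hb: Herdbook, sector: int, year: int, cfg: ScenarioConfig) -> dict[int, np.ndarray]:
    """Eligible breeding cows of a sector, grouped by herd."""
    mask = (
        hb.alive()
        & (hb.sex == Sex.FEMALE)
        & (hb.sector == sector)
        & (hb.age(year) >= cfg.cow_mating_age)
    )
    ids = np.flatnonzero(mask).astype(np.int64)
    herds = hb.herd[ids]
    order = np.argsort(herds, kind="stable")
    ids, herds = ids[order], herds[order]
    uniq, starts = np.unique(herds, return_index=True)
    bounds = np.append(starts, ids.size)
    return {int(h): ids[bounds[i] : bounds[i + 1]] for i, h in enumerate(uniq)}


def annual_cycle(
    hb: Herdbook,
    reg: PedigreeRegistry,
    cfg: ScenarioConfig,
    year: int,
    policy: MatingSchemePolicy | None,
    rng: np.random.Generator,
    burn_in: bool = False,
) -> list[dict]:
    """Run one simulated year in place; returns one stats row per sector.

    ``burn_in=True`` replaces every preference with randomness: random
    service order, random capacity culls, no editing, no steering, and no
    yearling retention/transfer (the tiers stay closed, which is why the
    commercial tier enters year 1 of a scheme with only its own bulls).
    """
    # The seedstock herds are served first; under scheme D commercial-born
    # homozygous polled bulls may fill the seedstock deficit, so bulls
    # committed to seedstock portfolios are excluded from the commercial
    # pool (no bull ever serves two herds in a year).  Under A/B/C the
    # sector pools are disjoint by construction.
    plans = {}
    all_calves = []
    committed = np.empty(0, dtype=np.int64)
    for sector in (int(Sector.SEEDSTOCK), int(Sector.COMMERCIAL)):
        cows = _cows_by_herd(hb, sector, year, cfg)
        pool = build_service_pool(
            hb, sector, year, cfg, None if burn_in else policy, rng, exclude=committed
        )
        portfolios = assign_portfolios(
            {h: ids.size for h, ids in cows.items()}, pool, cfg.matings_per_bull, rng
        )
        plan = mate(year, cows, portfolios, cfg.matings_per_bull, rng)
        plans[sector] = plan
        if plan.cow_ids.size:
            calves = create_calves(hb, reg, plan.bull_ids, plan.cow_ids, year, cfg, rng)
            all_calves.append(calves)
        if sector == int(Sector.SEEDSTOCK) and portfolios:
            parts = [p for p in portfolios.values() if p.size]
            if parts:
                committed = np.concatenate(parts)
    calves = np.concatenate(all_calves) if all_calves else np.empty(0, dtype=np.int64)

    edits = []
    if not burn_in and cfg.edit_fraction > 0:
        candidates = select_edit_candidates(hb, calves, cfg.edit_fraction)
        edits = perform_edits(hb, candidates, cfg.edit_success, cfg.et_success, year, rng)

    apply_mortality(hb, calves, cfg, rng)

    n_steers = 0
    if burn_in:
        n_steers = _steer_burn_in_surplus_males(hb, calves, cfg, rng)
    else:
        n_steers = steer_commercial_bull_calves(
            hb, calves, policy, cfg, rng, year,
            open_cows=plans[int(Sector.COMMERCIAL)].n_open,
        )
        yearlings = np.flatnonzero(
            hb.alive()
            & (hb.sex == Sex.MALE)
            & (hb.sector == Sector.SEEDSTOCK)
            & (hb.age(year) == 1)
        ).astype(np.int64)
        if yearlings.size:
            ranked = rank_yearling_bulls(
                yearlings, hb.genotype[yearlings], hb.tbv[yearlings], policy
            )
            retain_and_transfer(hb, ranked, cfg)

    cull_counts = cull(hb, cfg, None if burn_in else policy, year, rng)

    return _collect_stats(hb, cfg, year, plans, calves, edits, n_steers, cull_counts)


def _steer_burn_in_surplus_males(hb, calves, cfg, rng) -> int:
    """Keep the burn-in bull inventory at replacement level.

    During the random-mating burn-in each sector retains only enough male
    weanlings per year to sustain its mating-age bull population at the cap
    over a bull's service life; the surplus is steered at random.  This
    hands the schemes a steady-state year-0 bull pool instead of a backlog
    of entire young males that no scheme year would have produced.
    """
    service_years = max(1, cfg.bull_cull_age - cfg.bull_service_age)
    total = 0
    for sector, cap in (
        (int(Sector.SEEDSTOCK), cfg.seedstock_bull_cap),
        (int(Sector.COMMERCIAL), cfg.commercial_bull_cap),
    ):
        males = calves[
            (hb.status[calves] == Fate.ALIVE)
            & (hb.sex[calves] == Sex.MALE)
            & (hb.sector[calves] == sector)
        ]
        quota = -(-cap // service_years)
        excess = males.size - quota
        if excess > 0:
            steers = rng.choice(males, size=excess, replace=False)
            hb.status[steers] = Fate.SOLD_STEER
            total += excess
    return total


def _collect_stats(hb, cfg, year, plans, calves, edits, n_steers, cull_counts) -> list[dict]:
    rows = []
    calf_sector = hb.sector[calves] if calves.size else np.empty(0, np.int8)
    for sector in (int(Sector.SEEDSTOCK), int(Sector.COMMERCIAL)):
        alive = hb.alive() & (hb.sector == sector)
        idx = np.flatnonzero(alive)
        plan = plans.get(sector)

        sector_calves = calves[calf_sector == sector]
        live_calves = sector_calves[hb.status[sector_calves] == Fate.ALIVE]
        died_pre = int((hb.status[sector_calves] == Fate.DIED_PREWEANING).sum())
        died_dehorn = int((hb.status[sector_calves] == Fate.DIED_DEHORNING).sum())

        sires = np.unique(plan.bull_ids) if plan is not None else np.empty(0, np.int64)
        sire_geno = hb.genotype[sires]
        cc = cull_counts[sector]
        n_sold = (
            (n_steers if sector == int(Sector.COMMERCIAL) else 0)
            + cc["age_cull_female"]
            + cc["age_cull_male"]
            + cc["capacity_cull_female"]
        )
        rows.append(
            {
                "year": year,
                "sector": _SECTOR_NAMES[sector],
                "horned_allele_freq": horned_frequency_from_codes(hb.genotype[idx])
                if idx.size
                else np.nan,
                "n_alive": int(idx.size),
                "n_births": int(sector_calves.size),
                "cohort_mean_tbv": float(hb.tbv[live_calves].mean()) if live_calves.size else np.nan,
                "cohort_mean_f": float(hb.f[live_calves].mean()) if live_calves.size else np.nan,
                "n_matings": int(plan.cow_ids.size) if plan is not None else 0,
                "n_open_cows": plan.n_open if plan is not None else 0,
                "n_sires_used": int(sires.size),
                "n_sires_hom_polled": int((sire_geno == 2).sum()),
                "n_sires_het_polled": int((sire_geno == 1).sum()),
                "n_sires_horned": int((sire_geno == 0).sum()),
                "n_sires_commercial_origin": int(
                    (hb.origin_sector[sires] == Sector.COMMERCIAL).sum()
                ),
                "n_sires_edited": int(hb.edited[sires].sum()),
                "sire_mean_tbv": float(hb.tbv[sires].mean()) if sires.size else np.nan,
                "n_edited_calves": sum(
                    1 for e in edits if hb.sector[e.calf_id] == sector
                ),
                "deaths_preweaning": died_pre,
                "deaths_dehorning": died_dehorn,
                "n_steers_sold": n_steers if sector == int(Sector.COMMERCIAL) else 0,
                "age_cull_female": cc["age_cull_female"],
                "age_cull_male": cc["age_cull_male"],
                "capacity_cull_female": cc["capacity_cull_female"],
                "merit_cull_male": cc["merit_cull_male"],
                "n_sold_beef": int(n_sold),
            }
        )
    return rows


def run_replicate(
    cfg: ScenarioConfig,
    replicate: int = 0,
    *,
    return_state: bool = False,
):
    """One full replicate: base population, burn-in, then the scheme years.

    Returns a DataFrame of yearly per-sector statistics for report years
    0..``cfg.years`` (year 0 is the state at the end of the burn-in), with
    a ``replicate`` column.  With ``return_state=True`` also returns the
    final :class:`Herdbook` and :class:`PedigreeRegistry`.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, replicate])
    hb, reg = build_base_population(cfg, rng)
    policy = POLICIES[cfg.scheme]

    rows: list[dict] = []
    for y in range(1, cfg.burn_in_years + cfg.years + 1):
        in_burn_in = y <= cfg.burn_in_years
        year_rows = annual_cycle(hb, reg, cfg, y, policy, rng, burn_in=in_burn_in)
        report_year = y - cfg.burn_in_years
        if report_year >= 0:
            for r in year_rows:
                r["year"] = report_year
                rows.append(r)
        log.debug("replicate %d year %d done (%d animals)", replicate, y, hb.n)

    df = pd.DataFrame(rows)
    df.insert(0, "replicate", replicate)
    if return_state:
        return df, hb, reg
    return df


def run_scenario(cfg: ScenarioConfig) -> pd.DataFrame:
    """Run all replicates of one scenario; returns tidy per-year statistics.

    Each replicate uses its own generator seeded from the master seed, so
    the whole scenario is reproducible bit for bit under a fixed seed and
    any single replicate can be recreated in isolation.
    """
    frames = []
    name = scenario_name(cfg.scheme, cfg.edit_fraction)
    for rep in range(cfg.replicates):
        log.info("scenario %s: replicate %d/%d", name, rep + 1, cfg.replicates)
        frames.append(run_replicate(cfg, rep))
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "scenario", name)
    return out
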