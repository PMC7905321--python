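"""Mating-scheme policies: bull ranking, retention, service pools, culling.

Four schemes are modelled.  A is the baseline: bulls are ranked, used and
culled on the $JapOx index (TBV) alone.  B prefers all polled bulls (PP and
Pp) over horned, C prefers homozygous polled bulls over everything else,
and D is obligatory polled: only PP bulls may ever serve, with PP bulls
from the commercial tier supplementing the seedstock supply and any cows
beyond PP capacity left open.  B/C/D rank seedstock yearlings genotype
first (PP > Pp > pp) and cull bulls in the reverse order (horned first).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import ScenarioConfig
from .population import Fate, Herdbook, Sector, Sex


@dataclass(frozen=True)
class MatingSchemePolicy:
    scheme_id: str
    #: yearling ranking / retention and bull culling use genotype class first
    rank_by_genotype: bool
    #: genotype codes allowed to serve at all (None = any)
    service_genotypes: tuple[int, ...] | None
    #: genotype codes served preferentially before the rest (None = no tiers)
    preferred_genotypes: tuple[int, ...] | None
    #: PP bulls from the commercial tier may fill a seedstock-supply deficit
    commercial_supplement: bool
    #: commercial-born PP bull calves are kept entire instead of steered
    keep_commercial_pp_entire: bool


POLICIES: dict[str, MatingSchemePolicy] = {
    "A": MatingSchemePolicy("A", False, None, None, False, False),
    "B": MatingSchemePolicy("B", True, None, (1, 2), False, False),
    "C": MatingSchemePolicy("C", True, None, (2,), False, False),
    "D": MatingSchemePolicy("D", True, (2,), (2,), True, True),
}


def rank_yearling_bulls(
    ids: np.ndarray, genotypes: np.ndarray, tbvs: np.ndarray, policy: MatingSchemePolicy
) -> np.ndarray:
    """Order yearling bulls for retention.

    Scheme A: descending TBV.  B/C/D: genotype class (PP > Pp > pp) first,
    then descending TBV within class.  Ties broken by ascending id so the
    ordering is deterministic.
    """
    ids = np.asarray(ids)
    if policy.rank_by_genotype:
        order = np.lexsort((ids, -np.asarray(tbvs), -np.asarray(genotypes)))
    else:
        order = np.lexsort((ids, -np.asarray(tbvs)))
    return ids[order]


def retain_and_transfer(
    hb: Herdbook, ranked_yearling_ids: np.ndarray, cfg: ScenarioConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Keep the top fraction of ranked seedstock yearlings; move the rest.

    The retained prefix stays in the seedstock tier as breeding candidates;
    the remainder change sector to commercial (herd reassigned round-robin
    across commercial herds) where they become the commercial service-bull
    supply.  Returns ``(retained_ids, transferred_ids)``.
    """
    ranked = np.asarray(ranked_yearling_ids, dtype=np.int64)
    n_keep = math.ceil(cfg.seedstock_retention_fraction * ranked.size)
    retained, transferred = ranked[:n_keep], ranked[n_keep:]
    if transferred.size:
        hb.sector[transferred] = Sector.COMMERCIAL
        herds = cfg.n_seedstock_herds + (np.arange(transferred.size) % cfg.n_commercial_herds)
        hb.herd[transferred] = herds
    return retained, transferred


def _ranking_tbv(hb: Herdbook, ids: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """TBV as usable for ranking bulls.

    Only the nucleus performance-records its animals, so seedstock-born
    bulls rank on their true TBV while commercial-born bulls carry no
    usable merit information: their TBVs are shuffled among themselves,
    which keeps the group's merit distribution but makes every individual
    ordering decision among them effectively random.
    """
    tbv = hb.tbv[ids].copy()
    comm = hb.origin_sector[ids] == Sector.COMMERCIAL
    if comm.any():
        tbv[comm] = rng.permutation(tbv[comm])
    return tbv


def build_service_pool(
    hb: Herdbook,
    sector: int,
    year: int,
    cfg: ScenarioConfig,
    policy: MatingSchemePolicy | None,
    rng: np.random.Generator,
    exclude: np.ndarray | None = None,
) -> np.ndarray:
    """Priority-ordered ids of bulls eligible to serve a sector this year.

    Under schemes A/B/C a sector is served only by bulls standing in it;
    B (C) puts polled (homozygous polled) bulls in the first tier, used to
    their full mating capacity before any other bull, with the overflow
    tier ordered by TBV alone.  Under scheme D only homozygous polled
    bulls serve anywhere: seedstock herds use the retained seedstock PP
    bulls first and commercial-born PP bulls to fill the deficit, while
    commercial herds draw on every PP bull standing in the commercial tier
    (transferred or commercial-born) without origin preference —
    transferred bulls are never pulled back into the nucleus herds.
    Within every ranked tier bulls are ordered by descending usable TBV
    (ties by id; commercial-born bulls carry no merit record and rank in
    random order).  ``exclude`` drops bulls
    already committed to the other sector this year; ``policy=None``
    (burn-in) returns the sector's eligible bulls in random order.
    """
    serviceable = hb.alive() & (hb.sex == Sex.MALE) & (hb.age(year) >= cfg.bull_service_age)

    if policy is not None and policy.scheme_id == "D":
        serviceable &= hb.genotype == 2
        in_sector = hb.sector == sector
        commercial_born = (hb.sector == Sector.COMMERCIAL) & (
            hb.origin_sector == Sector.COMMERCIAL
        )
        if sector == int(Sector.SEEDSTOCK):
            eligible = serviceable & (in_sector | commercial_born)
            ids = np.flatnonzero(eligible).astype(np.int64)
            tier = np.where(in_sector[ids], 0, 1)  # retained nucleus bulls first
        else:
            eligible = serviceable & in_sector
            ids = np.flatnonzero(eligible).astype(np.int64)
            tier = np.zeros(ids.size, dtype=np.int64)
        # scheme D selects on genotype alone: within a tier, PP bulls are
        # used interchangeably, with no merit ordering in either sector
        if exclude is not None and exclude.size:
            keep = ~np.isin(ids, exclude)
            ids, tier = ids[keep], tier[keep]
        order = np.lexsort((ids, rng.random(ids.size), tier))
        return ids[order]
    else:
        eligible = serviceable & (hb.sector == sector)
        ids = np.flatnonzero(eligible).astype(np.int64)
        if policy is None:
            if exclude is not None and exclude.size:
                ids = ids[~np.isin(ids, exclude)]
            return rng.permutation(ids)
        geno = hb.genotype[ids]
        if policy.service_genotypes is not None:
            keep = np.isin(geno, policy.service_genotypes)
            ids, geno = ids[keep], geno[keep]
        if policy.preferred_genotypes is not None:
            tier = np.where(np.isin(geno, policy.preferred_genotypes), 0, 1)
        else:
            tier = np.zeros(ids.size, dtype=np.int64)

    if exclude is not None and exclude.size:
        keep = ~np.isin(ids, exclude)
        ids, tier = ids[keep], tier[keep]
    order = np.lexsort((ids, -_ranking_tbv(hb, ids, rng), tier))
    return ids[order]


def steer_commercial_bull_calves(
    hb: Herdbook,
    calf_ids: np.ndarray,
    policy: MatingSchemePolicy,
    cfg: ScenarioConfig,
    rng: np.random.Generator,
    year: int,
    open_cows: int = 0,
) -> int:
    """Castrate/sell the year's commercial bull calves at weaning.

    Under scheme D confirmed homozygous polled commercial bull calves
    (hornless calves separated at the first muster and genotype-confirmed)
    are kept entire as future breeding candidates, but only while the
    scheme is short of serviceable bulls: while the tier's standing
    mating-age PP inventory is below the bull cap, or cows went unserved
    this year — the keeps exist to fill the sire deficit, not to replace
    the seedstock supply.  Which PP calves are kept is random because the
    multiplier tier records no merit.  Everywhere else every commercial
    bull calf becomes a steer.  Returns the number steered.
    """
    calf_ids = np.asarray(calf_ids, dtype=np.int64)
    mask = (
        (hb.status[calf_ids] == Fate.ALIVE)
        & (hb.sex[calf_ids] == Sex.MALE)
        & (hb.sector[calf_ids] == Sector.COMMERCIAL)
    )
    steers = calf_ids[mask]
    if policy.keep_commercial_pp_entire:
        pp = steers[hb.genotype[steers] == 2]
        mating_age_pp = int(
            (
                hb.alive()
                & (hb.sex == Sex.MALE)
                & (hb.sector == Sector.COMMERCIAL)
                & (hb.genotype == 2)
                & (hb.age(year) >= cfg.bull_service_age)
            ).sum()
        )
        deficit_bulls = -(-int(open_cows) // cfg.matings_per_bull)
        quota = max(0, cfg.commercial_bull_cap - mating_age_pp, deficit_bulls)
        kept = rng.choice(pp, size=min(quota, pp.size), replace=False) if pp.size else pp
        steers = steers[~np.isin(steers, kept)]
    hb.status[steers] = Fate.SOLD_STEER
    return int(steers.size)


def cull(
    hb: Herdbook,
    cfg: ScenarioConfig,
    policy: MatingSchemePolicy | None,
    year: int,
    rng: np.random.Generator,
) -> dict[int, dict[str, int]]:
    """End-of-year culling: by age, then down to the sector caps.

    Cows are culled at the age limit and then at random (involuntary culls)
    until the sector female cap holds.  Bulls are culled at their age limit
    and then, among mating-age bulls over the cap, in the scheme's culling
    order — scheme A by lowest TBV only, B/C/D horned first, then
    heterozygous, then homozygous polled, lowest TBV within class.  During
    burn-in (``policy=None``) capacity culls are random for both sexes.
    """
    counts: dict[int, dict[str, int]] = {}
    age = hb.age(year)

    for sector, female_cap, bull_cap in (
        (Sector.SEEDSTOCK, cfg.seedstock_female_cap, cfg.seedstock_bull_cap),
        (Sector.COMMERCIAL, cfg.commercial_female_cap, cfg.commercial_bull_cap),
    ):
        c = counts[int(sector)] = {
            "age_cull_female": 0, "age_cull_male": 0,
            "capacity_cull_female": 0, "merit_cull_male": 0,
        }
        alive = hb.alive() & (hb.sector == sector)

        old_cows = np.flatnonzero(alive & (hb.sex == Sex.FEMALE) & (age >= cfg.cow_cull_age))
        hb.status[old_cows] = Fate.CULLED_AGE
        c["age_cull_female"] = int(old_cows.size)
        old_bulls = np.flatnonzero(alive & (hb.sex == Sex.MALE) & (age >= cfg.bull_cull_age))
        hb.status[old_bulls] = Fate.CULLED_AGE
        c["age_cull_male"] = int(old_bulls.size)

        alive = hb.alive() & (hb.sector == sector)
        females = np.flatnonzero(alive & (hb.sex == Sex.FEMALE))
        excess = females.size - female_cap
        if excess > 0:
            victims = rng.choice(females, size=excess, replace=False)
            hb.status[victims] = Fate.CULLED_CAPACITY
            c["capacity_cull_female"] = excess

        bulls = np.flatnonzero(alive & (hb.sex == Sex.MALE) & (age >= cfg.bull_service_age))
        excess = bulls.size - bull_cap
        if excess > 0:
            if policy is None:
                victims = rng.choice(bulls, size=excess, replace=False)
                fate = Fate.CULLED_CAPACITY
            else:
                # the nucleus culls on merit within genotype class; the
                # multiplier tier's capacity culls are involuntary (random
                # within class) because it keeps no merit records
                if sector == Sector.COMMERCIAL:
                    key = rng.random(bulls.size)
                else:
                    key = _ranking_tbv(hb, bulls, rng)
                if policy.rank_by_genotype:
                    order = np.lexsort((bulls, key, hb.genotype[bulls]))
                else:
                    order = np.lexsort((bulls, key))
                victims = bulls[order[:excess]]
                fate = Fate.CULLED_MERIT
            hb.status[victims] = fate
            c["merit_cull_male"] = excess
    return counts
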