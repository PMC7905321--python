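"""Annual mating, calf creation and calf mortality.

Natural-service mating: each herd receives a unique portfolio of bulls for
the year (no bull serves two herds), cows are matched uniformly at random
to portfolio bulls, and no bull ever exceeds the per-year mating cap.
Portfolio capacity is matched to the herd's cow count by ceiling division,
with the highest-priority bulls dealt out first in a round-robin so every
herd gets a share of the best bulls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ScenarioConfig
from .genetics import sample_offspring_genotypes
from .pedigree import PedigreeRegistry, mendelian_sampling_variance
from .population import Fate, Herdbook, Sector, Sex


@dataclass
class MatingPlan:
    """The realised matings of one sector in one year."""

    year: int
    cow_ids: np.ndarray  # matched 1:1 with bull_ids
    bull_ids: np.ndarray
    herd_ids: np.ndarray
    open_cow_ids: np.ndarray  # eligible cows left uncovered
    portfolios: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def bull_usage(self) -> dict[int, int]:
        ids, counts = np.unique(self.bull_ids, return_counts=True)
        return dict(zip(ids.tolist(), counts.tolist()))

    @property
    def n_open(self) -> int:
        return int(self.open_cow_ids.size)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"year": self.year, "herd": self.herd_ids, "cow": self.cow_ids, "bull": self.bull_ids}
        )


def assign_portfolios(
    herd_cow_counts: dict[int, int],
    bulls_by_priority: np.ndarray,
    matings_per_bull: int,
    rng: np.random.Generator,
) -> dict[int, np.ndarray]:
    """Partition bulls across herds, highest-priority bulls dealt first.

    Each herd needs ``ceil(cows / matings_per_bull)`` bulls.  Bulls are dealt
    one at a time to herds still short, cycling herds in random order, so a
    shortage is spread evenly and top-priority bulls do not pool in one herd.
    Deficits (herds receiving fewer bulls than needed) are legal.
    """
    herds = list(herd_cow_counts)
    order = rng.permutation(len(herds))
    need = {
        h: -(-herd_cow_counts[h] // matings_per_bull) if herd_cow_counts[h] > 0 else 0
        for h in herds
    }
    portfolios: dict[int, list[int]] = {h: [] for h in herds}
    cursor = 0
    for bull in bulls_by_priority:
        placed = False
        for _ in range(len(herds)):
            h = herds[order[cursor % len(herds)]]
            cursor += 1
            if len(portfolios[h]) < need[h]:
                portfolios[h].append(int(bull))
                placed = True
                break
        if not placed:
            break  # every herd is at capacity
    return {h: np.array(p, dtype=np.int64) for h, p in portfolios.items()}


def mate(
    year: int,
    cow_ids_by_herd: dict[int, np.ndarray],
    portfolios: dict[int, np.ndarray],
    matings_per_bull: int,
    rng: np.random.Generator,
) -> MatingPlan:
    """Randomly match eligible cows to portfolio bulls under the mating cap.

    Within a herd each bull contributes ``matings_per_bull`` slots; slots are
    shuffled and dealt to cows, so mating counts per bull are exchangeable
    and never exceed the cap.  Cows beyond total capacity are left open.
    """
    cows_out, bulls_out, herds_out, open_out = [], [], [], []
    for herd, cows in cow_ids_by_herd.items():
        bulls = portfolios.get(herd, np.empty(0, dtype=np.int64))
        if bulls.size == 0 or cows.size == 0:
            open_out.append(cows)
            continue
        capacity = bulls.size * matings_per_bull
        cows = rng.permutation(cows)
        covered, left_open = cows[:capacity], cows[capacity:]
        slots = np.repeat(bulls, matings_per_bull)
        rng.shuffle(slots)
        cows_out.append(covered)
        bulls_out.append(slots[: covered.size])
        herds_out.append(np.full(covered.size, herd, dtype=np.int64))
        open_out.append(left_open)

    cat = lambda parts: (
        np.concatenate(parts) if parts else np.empty(0, dtype=np.int64)
    )
    plan = MatingPlan(
        year=year,
        cow_ids=cat(cows_out),
        bull_ids=cat(bulls_out),
        herd_ids=cat(herds_out),
        open_cow_ids=cat(open_out),
        portfolios=portfolios,
    )
    if plan.bull_ids.size:
        assert max(plan.bull_usage.values()) <= matings_per_bull
    return plan


def create_calves(
    hb: Herdbook,
    reg: PedigreeRegistry,
    sire_ids: np.ndarray,
    dam_ids: np.ndarray,
    year: int,
    cfg: ScenarioConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Create one calf per mating (vectorised); returns the new calf ids.

    TBV_calf = 0.5 (TBV_sire + TBV_dam) + MS, with the Mendelian sampling
    term drawn from N(0, 0.5 [1 - 0.5 (f_S + f_D)] sigma_a^2).  The genotype
    is built by sampling one allele from each parent (with the one-way
    pp -> Pp mutation), sex is Bernoulli(1/2), and the calf is born in its
    dam's herd and sector.  Calves are registered in the pedigree and their
    inbreeding coefficients computed immediately.
    """
    sire_ids = np.asarray(sire_ids, dtype=np.int64)
    dam_ids = np.asarray(dam_ids, dtype=np.int64)
    if sire_ids.shape != dam_ids.shape:
        raise ValueError("sire and dam arrays must be matched 1:1")
    if sire_ids.size and (sire_ids.max() >= hb.n or dam_ids.max() >= hb.n):
        raise ValueError("parents must exist in the herdbook")
    k = sire_ids.size

    ms_var = mendelian_sampling_variance(
        reg.inbreeding_of(sire_ids), reg.inbreeding_of(dam_ids), cfg.sigma_a2
    )
    tbv = 0.5 * (hb.tbv[sire_ids] + hb.tbv[dam_ids]) + rng.normal(0.0, 1.0, k) * np.sqrt(ms_var)
    genotype = sample_offspring_genotypes(
        hb.genotype[sire_ids], hb.genotype[dam_ids], cfg.mutation_rate, rng
    )
    sex = (rng.random(k) < 0.5).astype(np.int8)  # Bernoulli 50:50

    ped_ids = reg.register_batch(sire_ids, dam_ids)
    calf_ids = hb.add(
        sex=sex,
        birth_year=year,
        sector=hb.sector[dam_ids],
        herd=hb.herd[dam_ids],
        sire=sire_ids,
        dam=dam_ids,
        genotype=genotype,
        tbv=tbv,
        f=reg.inbreeding_of(ped_ids),
    )
    assert np.array_equal(ped_ids, calf_ids)
    return calf_ids


def apply_mortality(
    hb: Herdbook, calf_ids: np.ndarray, cfg: ScenarioConfig, rng: np.random.Generator
) -> dict[str, int]:
    """Pre-weaning loss, then dehorning mortality on horned survivors.

    Each calf dies pre-weaning with its sector's rate; horned (pp) survivors
    additionally die with the dehorning mortality rate — the management
    penalty on horned calves in this extensive tropical system.  Returns
    death counts by cause; statuses are updated in place.
    """
    calf_ids = np.asarray(calf_ids, dtype=np.int64)
    rate = np.where(
        hb.sector[calf_ids] == Sector.SEEDSTOCK,
        cfg.preweaning_loss_seedstock,
        cfg.preweaning_loss_commercial,
    )
    dies_pre = rng.random(calf_ids.size) < rate
    hb.status[calf_ids[dies_pre]] = Fate.DIED_PREWEANING

    survivors = calf_ids[~dies_pre]
    horned = survivors[hb.genotype[survivors] == 0]
    dies_dehorn = horned[rng.random(horned.size) < cfg.dehorning_mortality]
    hb.status[dies_dehorn] = Fate.DIED_DEHORNING

    return {
        "preweaning": int(dies_pre.sum()),
        "dehorning": int(dies_dehorn.size),
    }
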