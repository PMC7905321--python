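"""Animal inventory and base-population synthesis.

The :class:`Herdbook` is a columnar (structure-of-arrays) store of every
animal ever created in a replicate, in birth order, so that whole cohorts
can be created and queried with vectorised NumPy operations.  Individual
animals can be materialised as :class:`Animal` records for inspection.

:func:`build_base_population` synthesises the founder herds from the
configured parameters: ages uniform on the configured ranges, true breeding
values (TBV, $JapOx) normal with sector/sex-specific means, cow genotypes
drawn as two Bernoulli alleles at the HORNED frequency, and bull genotypes
assigned by stratified proportions so that small populations still match
the configured polled mix.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ScenarioConfig
from .genetics import genotype_label
from .pedigree import UNKNOWN, PedigreeRegistry


class Sex(enum.IntEnum):
    FEMALE = 0
    MALE = 1


class Sector(enum.IntEnum):
    SEEDSTOCK = 0
    COMMERCIAL = 1


class Fate(enum.IntEnum):
    """Life status; anything other than ALIVE is terminal."""

    ALIVE = 0
    SOLD_STEER = 1
    DIED_PREWEANING = 2
    DIED_DEHORNING = 3
    CULLED_AGE = 4
    CULLED_CAPACITY = 5
    CULLED_MERIT = 6


@dataclass(frozen=True)
class Animal:
    """A single animal's record (a read-only view into the herdbook)."""

    animal_id: int
    sex: Sex
    birth_year: int
    sector: Sector
    origin_sector: Sector
    herd_id: int
    sire_id: int
    dam_id: int
    genotype: str
    tbv: float
    f: float
    edited: bool
    status: Fate


_COLUMNS = (
    ("sex", np.int8),
    ("birth_year", np.int32),
    ("sector", np.int8),
    ("origin_sector", np.int8),
    ("herd", np.int32),
    ("sire", np.int64),
    ("dam", np.int64),
    ("genotype", np.int8),
    ("tbv", np.float64),
    ("f", np.float64),
    ("edited", np.bool_),
    ("status", np.int8),
)


class Herdbook:
    """Columnar inventory of all animals in one simulation replicate."""

    def __init__(self, capacity: int = 1024):
        self.n = 0
        self._cap = max(capacity, 16)
        for name, dtype in _COLUMNS:
            setattr(self, "_" + name, np.zeros(self._cap, dtype))

    def __len__(self) -> int:
        return self.n

    def _grow(self, need: int) -> None:
        if self.n + need <= self._cap:
            return
        new_cap = max(self._cap * 2, self.n + need)
        for name, _ in _COLUMNS:
            old = getattr(self, "_" + name)
            arr = np.zeros(new_cap, old.dtype)
            arr[: self.n] = old[: self.n]
            setattr(self, "_" + name, arr)
        self._cap = new_cap

    def add(
        self,
        *,
        sex,
        birth_year,
        sector,
        herd,
        sire,
        dam,
        genotype,
        tbv,
        f=0.0,
        edited=False,
        origin_sector=None,
    ) -> np.ndarray:
        """Append a cohort of animals; returns their new ids (birth-ordered)."""
        sex = np.asarray(sex, dtype=np.int8)
        k = sex.shape[0]
        self._grow(k)
        ids = np.arange(self.n, self.n + k)
        self._sex[ids] = sex
        self._birth_year[ids] = birth_year
        self._sector[ids] = sector
        self._origin_sector[ids] = sector if origin_sector is None else origin_sector
        self._herd[ids] = herd
        self._sire[ids] = sire
        self._dam[ids] = dam
        self._genotype[ids] = genotype
        self._tbv[ids] = tbv
        self._f[ids] = f
        self._edited[ids] = edited
        self._status[ids] = Fate.ALIVE
        self.n += k
        return ids

    # column views (writable, sliced to the live length)
    @property
    def sex(self):
        return self._sex[: self.n]

    @property
    def birth_year(self):
        return self._birth_year[: self.n]

    @property
    def sector(self):
        return self._sector[: self.n]

    @property
    def origin_sector(self):
        return self._origin_sector[: self.n]

    @property
    def herd(self):
        return self._herd[: self.n]

    @property
    def sire(self):
        return self._sire[: self.n]

    @property
    def dam(self):
        return self._dam[: self.n]

    @property
    def genotype(self):
        return self._genotype[: self.n]

    @property
    def tbv(self):
        return self._tbv[: self.n]

    @property
    def f(self):
        return self._f[: self.n]

    @property
    def edited(self):
        return self._edited[: self.n]

    @property
    def status(self):
        return self._status[: self.n]

    def alive(self) -> np.ndarray:
        return self.status == Fate.ALIVE

    def age(self, year: int) -> np.ndarray:
        return year - self.birth_year

    def animal(self, animal_id: int) -> Animal:
        i = int(animal_id)
        if not 0 <= i < self.n:
            raise KeyError(f"animal id {animal_id} does not exist")
        return Animal(
            animal_id=i,
            sex=Sex(int(self._sex[i])),
            birth_year=int(self._birth_year[i]),
            sector=Sector(int(self._sector[i])),
            origin_sector=Sector(int(self._origin_sector[i])),
            herd_id=int(self._herd[i]),
            sire_id=int(self._sire[i]),
            dam_id=int(self._dam[i]),
            genotype=genotype_label(int(self._genotype[i])),
            tbv=float(self._tbv[i]),
            f=float(self._f[i]),
            edited=bool(self._edited[i]),
            status=Fate(int(self._status[i])),
        )

    def snapshot(self) -> pd.DataFrame:
        """One row per animal: the inventory snapshot CSV layout."""
        return pd.DataFrame(
            {
                "animal_id": np.arange(self.n),
                "sex": np.where(self.sex == Sex.MALE, "M", "F"),
                "birth_year": self.birth_year.copy(),
                "sector": np.where(self.sector == Sector.SEEDSTOCK, "seedstock", "commercial"),
                "herd": self.herd.copy(),
                "sire": self.sire.copy(),
                "dam": self.dam.copy(),
                "genotype": np.array([genotype_label(g) for g in self.genotype]),
                "tbv": self.tbv.copy(),
                "f": self.f.copy(),
                "edited": self.edited.copy(),
                "status": np.array([Fate(s).name.lower() for s in self.status]),
            }
        )


# ---------------------------------------------------------------------------
# base population
# ---------------------------------------------------------------------------


def _sample_cow_genotypes(n: int, q_horned: float, rng: np.random.Generator) -> np.ndarray:
    """Two independent Bernoulli alleles at POLLED frequency 1 - q."""
    p = 1.0 - q_horned
    return (rng.random(n) < p).astype(np.int8) + (rng.random(n) < p)


def _stratified_bull_genotypes(n: int, cfg: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Bull genotypes hitting the configured polled proportions exactly."""
    n_pp_hom = round(cfg.base_bull_hom_polled * n)
    n_het = round(cfg.base_bull_het_polled * n)
    g = np.zeros(n, dtype=np.int8)
    g[:n_pp_hom] = 2
    g[n_pp_hom : n_pp_hom + n_het] = 1
    rng.shuffle(g)
    return g


def _ensure_carrier(genotypes: np.ndarray, rng: np.random.Generator) -> None:
    """Force at least one POLLED carrier in place (guards against drift loss)."""
    if genotypes.size and not (genotypes > 0).any():
        genotypes[rng.integers(genotypes.size)] = 1


def build_base_population(
    cfg: ScenarioConfig, rng: np.random.Generator
) -> tuple[Herdbook, PedigreeRegistry]:
    """Synthesise the founder herds and register them in a fresh pedigree.

    All base animals are founders (unknown parents, f = 0).  Cows are split
    evenly across their sector's herds and never move; bulls are not tied to
    a herd (their herd is -1) because sire portfolios are re-drawn annually.
    Homozygous polled base bulls draw their TBV from a distribution whose
    mean is shifted down by the configured penalty.
    """
    cfg.validate()
    hb = Herdbook(capacity=4 * (cfg.seedstock_base_cows + cfg.commercial_base_cows))
    reg = PedigreeRegistry(capacity=hb._cap)

    cow_lo, cow_hi = cfg.cow_birth_year_range
    bull_lo, bull_hi = cfg.bull_birth_year_range

    for sector, n_cows, n_bulls, cow_mean, n_herds in (
        (Sector.SEEDSTOCK, cfg.seedstock_base_cows, cfg.seedstock_base_bulls,
         cfg.tbv_mean_seedstock_cows, cfg.n_seedstock_herds),
        (Sector.COMMERCIAL, cfg.commercial_base_cows, cfg.commercial_base_bulls,
         cfg.tbv_mean_commercial_cows, cfg.n_commercial_herds),
    ):
        # cows: even split across the sector's herds
        herd_base = 0 if sector == Sector.SEEDSTOCK else cfg.n_seedstock_herds
        cow_herds = herd_base + (np.arange(n_cows) % n_herds)
        cow_geno = _sample_cow_genotypes(n_cows, cfg.horned_allele_freq, rng)
        _ensure_carrier(cow_geno, rng)
        hb.add(
            sex=np.full(n_cows, Sex.FEMALE, np.int8),
            birth_year=rng.integers(cow_lo, cow_hi + 1, n_cows),
            sector=sector,
            herd=cow_herds,
            sire=UNKNOWN,
            dam=UNKNOWN,
            genotype=cow_geno,
            tbv=rng.normal(cow_mean, cfg.tbv_sd, n_cows),
        )

        bull_geno = _stratified_bull_genotypes(n_bulls, cfg, rng)
        _ensure_carrier(bull_geno, rng)
        bull_mean = cow_mean + cfg.bull_mean_offset_sd * cfg.tbv_sd
        bull_tbv = rng.normal(bull_mean, cfg.tbv_sd, n_bulls)
        bull_tbv[bull_geno == 2] -= cfg.hom_polled_bull_tbv_penalty
        hb.add(
            sex=np.full(n_bulls, Sex.MALE, np.int8),
            birth_year=rng.integers(bull_lo, bull_hi + 1, n_bulls),
            sector=sector,
            herd=-1,
            sire=UNKNOWN,
            dam=UNKNOWN,
            genotype=bull_geno,
            tbv=bull_tbv,
        )

    reg.register_batch(np.full(hb.n, UNKNOWN), np.full(hb.n, UNKNOWN))
    return hb, reg


def run_burn_in(
    hb: Herdbook, reg: PedigreeRegistry, cfg: ScenarioConfig, rng: np.random.Generator
) -> int:
    """Advance the base population through the random-mating burn-in.

    Ten (``cfg.burn_in_years``) annual cycles of within-sector random mating
    with the standard calf-creation, mortality, aging and capacity rules but
    no genotype or merit preference anywhere (capacity culls are random),
    producing the year-0 state from which the mating schemes start.
    Returns the absolute year index of the burn-in end.
    """
    from .simulate import annual_cycle  # local import to avoid a cycle

    for year in range(1, cfg.burn_in_years + 1):
        annual_cycle(hb, reg, cfg, year, policy=None, rng=rng, burn_in=True)
    return cfg.burn_in_years
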