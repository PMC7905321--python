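"""Scenario configuration.

Every numeric parameter of the simulation lives in :class:`ScenarioConfig`.
The defaults describe the modelled northern-Australian Brahman population: a
nucleus (seedstock) tier of 10 herds supplying natural-service bulls to a
multiplier (commercial) tier of 200 herds, a starting HORNED allele
frequency of 80%, a $JapOx index SD of $34, and the mortality, cap and
selection parameters of that production system.  A bare default run is one
of the study scenarios (scheme A, no editing).

``scaled()`` shrinks every population size, cap and herd count by a common
factor while leaving rates, ages and variances untouched, preserving
selection intensities and cows-per-herd so that desk-scale runs keep the
full-scale dynamics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

SCHEMES = ("A", "B", "C", "D")


@dataclass(frozen=True)
class ScenarioConfig:
    # scenario identity
    scheme: str = "A"
    edit_fraction: float = 0.0  # fraction of seedstock bull calves edited per year
    years: int = 20
    burn_in_years: int = 10
    replicates: int = 10
    seed: int = 42
    scale: float = 1.0  # bookkeeping: factor already applied by scaled()

    # base population
    seedstock_base_cows: int = 15000
    seedstock_base_bulls: int = 600
    commercial_base_cows: int = 35000
    commercial_base_bulls: int = 1500
    n_seedstock_herds: int = 10
    n_commercial_herds: int = 200
    cow_birth_year_range: tuple[int, int] = (-10, 0)
    bull_birth_year_range: tuple[int, int] = (-5, 0)
    tbv_sd: float = 34.0  # $JapOx additive genetic SD (AUD)
    tbv_mean_seedstock_cows: float = 34.0
    tbv_mean_commercial_cows: float = 0.0
    bull_mean_offset_sd: float = 1.0  # base bulls average 1 SD above their cows
    horned_allele_freq: float = 0.80
    base_bull_het_polled: float = 0.30
    base_bull_hom_polled: float = 0.026
    hom_polled_bull_tbv_penalty: float = 5.44  # AUD (0.16 SD)

    # reproduction and mortality
    matings_per_bull: int = 35
    cow_first_calf_age: int = 3  # mated from age cow_first_calf_age - 1
    bull_service_age: int = 2
    cow_cull_age: int = 10
    bull_cull_age: int = 5
    preweaning_loss_seedstock: float = 0.08
    preweaning_loss_commercial: float = 0.13
    dehorning_mortality: float = 0.02
    mutation_rate: float = 1e-5

    # caps and selection
    seedstock_female_cap: int = 3000
    commercial_female_cap: int = 100000
    seedstock_bull_cap: int = 60
    commercial_bull_cap: int = 2000
    seedstock_retention_fraction: float = 0.05

    # gene editing
    edit_success: float = 0.61
    et_success: float = 0.21

    @property
    def sigma_a2(self) -> float:
        """Additive genetic variance of the $JapOx index."""
        return self.tbv_sd**2

    @property
    def cow_mating_age(self) -> int:
        """Youngest age at which a cow is mated.

        The annual cycle books a mating and its calf in the same simulated
        year (the one-year cycle absorbs gestation), so a cow entering the
        mating pool at this age has her first calf at this age — which is
        why it equals ``cow_first_calf_age``, keeping dam calving ages at
        3..``cow_cull_age`` exactly as in the modelled system.
        """
        return self.cow_first_calf_age

    def validate(self) -> "ScenarioConfig":
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")
        probs = {
            "edit_fraction": self.edit_fraction,
            "horned_allele_freq": self.horned_allele_freq,
            "base_bull_het_polled": self.base_bull_het_polled,
            "base_bull_hom_polled": self.base_bull_hom_polled,
            "preweaning_loss_seedstock": self.preweaning_loss_seedstock,
            "preweaning_loss_commercial": self.preweaning_loss_commercial,
            "dehorning_mortality": self.dehorning_mortality,
            "mutation_rate": self.mutation_rate,
            "seedstock_retention_fraction": self.seedstock_retention_fraction,
            "edit_success": self.edit_success,
            "et_success": self.et_success,
        }
        for name, v in probs.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.base_bull_het_polled + self.base_bull_hom_polled > 1.0:
            raise ValueError("base bull genotype proportions exceed 1")
        positive = {
            "years": self.years,
            "replicates": self.replicates,
            "seedstock_base_cows": self.seedstock_base_cows,
            "seedstock_base_bulls": self.seedstock_base_bulls,
            "commercial_base_cows": self.commercial_base_cows,
            "commercial_base_bulls": self.commercial_base_bulls,
            "n_seedstock_herds": self.n_seedstock_herds,
            "n_commercial_herds": self.n_commercial_herds,
            "matings_per_bull": self.matings_per_bull,
            "seedstock_female_cap": self.seedstock_female_cap,
            "commercial_female_cap": self.commercial_female_cap,
            "seedstock_bull_cap": self.seedstock_bull_cap,
            "commercial_bull_cap": self.commercial_bull_cap,
            "tbv_sd": self.tbv_sd,
        }
        for name, v in positive.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.burn_in_years < 0:
            raise ValueError("burn_in_years must be >= 0")
        if not 0 < self.edit_success * self.et_success or self.edit_fraction == 0:
            pass  # joint success only matters when editing is on
        if self.edit_fraction > 0 and self.edit_success * self.et_success == 0:
            raise ValueError("editing enabled but joint success probability is 0")
        if self.cow_first_calf_age < 1 or self.bull_service_age < 1:
            raise ValueError("first-calf and service ages must be >= 1")
        return self

    def scaled(self, factor: float) -> "ScenarioConfig":
        """Uniformly shrink population sizes, caps and herd counts by ``factor``."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        if factor == 1.0:
            return self

        def sz(x: int) -> int:
            return max(1, round(x * factor))

        return dataclasses.replace(
            self,
            scale=self.scale * factor,
            seedstock_base_cows=sz(self.seedstock_base_cows),
            seedstock_base_bulls=sz(self.seedstock_base_bulls),
            commercial_base_cows=sz(self.commercial_base_cows),
            commercial_base_bulls=sz(self.commercial_base_bulls),
            n_seedstock_herds=sz(self.n_seedstock_herds),
            n_commercial_herds=sz(self.n_commercial_herds),
            seedstock_female_cap=sz(self.seedstock_female_cap),
            commercial_female_cap=sz(self.commercial_female_cap),
            seedstock_bull_cap=sz(self.seedstock_bull_cap),
            commercial_bull_cap=sz(self.commercial_bull_cap),
        )

    # -- (de)serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cow_birth_year_range"] = list(self.cow_birth_year_range)
        d["bull_birth_year_range"] = list(self.bull_birth_year_range)
        return d

    @classmethod
    def from_mapping(cls, mapping: dict) -> "ScenarioConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        kwargs = dict(mapping)
        for key in ("cow_birth_year_range", "bull_birth_year_range"):
            if key in kwargs:
                lo, hi = kwargs[key]
                kwargs[key] = (int(lo), int(hi))
        return cls(**kwargs).validate()

    @classmethod
    def from_file(cls, path) -> "ScenarioConfig":
        """Load overrides from a TOML file of flat ``key = value`` pairs."""
        import tomllib

        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        return cls.from_mapping(data)


def scenario_name(scheme: str, edit_fraction: float) -> str:
    """Canonical scenario label, e.g. ``B_10%`` for scheme B editing 10%."""
    if edit_fraction == 0:
        return scheme
    return f"{scheme}_{edit_fraction:.0%}"


#: The ten study scenarios: baseline A, and schemes B/C/D each without
#: editing and with editing of the top 1% or 10% of seedstock bull calves.
STUDY_SCENARIOS: tuple[tuple[str, float], ...] = (
    ("A", 0.0),
    ("B", 0.0),
    ("B", 0.01),
    ("B", 0.10),
    ("C", 0.0),
    ("C", 0.01),
    ("C", 0.10),
    ("D", 0.0),
    ("D", 0.01),
    ("D", 0.10),
)
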