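"""Livestock biomass and the population correction unit (PCU).

The PCU standardizes antimicrobial consumption across regions with
different herd structures: it is the estimated total live biomass (kg)
of the food-producing animal population at typical treatment age,
computed per species and summed.

Species formulas follow European veterinary-surveillance conventions:

* slaughtered stock: number slaughtered x average live weight;
* cattle herd: census population x age-class-weighted mean live weight
  (calves, young 1-3 y, adults);
* live sheep/goats: slaughtered biomass plus a breeding-stock term,
  ``(census - n_slaughtered / cycles) x 75 kg`` with 1.5 breeding
  cycles per year and 75 kg as the standard breeding small-ruminant
  weight;
* poultry: one kg per mature bird, excluding chicks under two weeks,
  which are neither treated nor slaughtered.

All formulas are linear in animal counts and in weights.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from .errors import ConfigError

__all__ = [
    "Species",
    "SpeciesBiomassInput",
    "BiomassResult",
    "slaughtered_biomass",
    "bovine_census_biomass",
    "smallstock_live_biomass",
    "poultry_biomass",
    "total_pcu",
    "census_count_shares",
    "read_census_yaml",
    "read_census_config",
    "write_census_yaml",
    "DEFAULT_BREEDING_CYCLES",
    "DEFAULT_BREEDING_WEIGHT_KG",
    "DEFAULT_SMALLSTOCK_SLAUGHTER_WEIGHT_KG",
    "DEFAULT_POULTRY_WEIGHT_KG",
    "DEFAULT_SHEEP_AGE_WEIGHTS_KG",
    "DEFAULT_GOAT_AGE_WEIGHTS_KG",
]

DEFAULT_BREEDING_CYCLES: float = 1.5
DEFAULT_BREEDING_WEIGHT_KG: float = 75.0
DEFAULT_SMALLSTOCK_SLAUGHTER_WEIGHT_KG: float = 20.0
DEFAULT_POULTRY_WEIGHT_KG: float = 1.0
#: Mean live weight (kg) by age class (<1 y, 1-2 y, >2 y).
DEFAULT_SHEEP_AGE_WEIGHTS_KG: tuple[float, ...] = (18.0, 27.0, 30.0)
DEFAULT_GOAT_AGE_WEIGHTS_KG: tuple[float, ...] = (15.0, 25.0, 30.0)


class Species(str, enum.Enum):
    CATTLE = "cattle"
    SHEEP = "sheep"
    GOAT = "goat"
    POULTRY = "poultry"
    OTHER = "other"


def slaughtered_biomass(n_slaughtered: float, avg_live_weight: float) -> float:
    """Biomass (kg) of slaughtered animals: count x average live weight."""
    if n_slaughtered < 0 or avg_live_weight < 0:
        raise ConfigError("n_slaughtered and avg_live_weight must be >= 0")
    return n_slaughtered * avg_live_weight


def bovine_census_biomass(
    census: float,
    age_class_weights: Sequence[float],
    age_class_proportions: Sequence[float],
) -> float:
    """Cattle herd biomass: census x age-class-weighted mean live weight.

    ``age_class_weights`` and ``age_class_proportions`` are aligned lists
    (typically calves, young 1-3 y, adults); proportions must sum to 1.
    """
    if census < 0:
        raise ConfigError("census must be >= 0")
    if len(age_class_weights) != len(age_class_proportions):
        raise ConfigError(
            f"{len(age_class_weights)} weights vs "
            f"{len(age_class_proportions)} proportions"
        )
    if any(p < 0 for p in age_class_proportions):
        raise ConfigError("proportions must be >= 0")
    if any(w <= 0 for w in age_class_weights):
        raise ConfigError("weights must be > 0")
    if not math.isclose(sum(age_class_proportions), 1.0, abs_tol=1e-9):
        raise ConfigError(
            f"proportions must sum to 1, got {sum(age_class_proportions)}"
        )
    mean_weight = sum(
        w * p for w, p in zip(age_class_weights, age_class_proportions)
    )
    return census * mean_weight


def smallstock_live_biomass(
    slaughter_live_weight: float,
    n_slaughtered: float,
    census: float,
    breeding_cycles: float = DEFAULT_BREEDING_CYCLES,
    breeding_weight: float = DEFAULT_BREEDING_WEIGHT_KG,
) -> float:
    """Sheep/goat biomass: slaughtered stock plus retained breeding stock.

    ``slaughter_live_weight x n_slaughtered`` is the year's slaughter
    throughput; ``(census - n_slaughtered / breeding_cycles) x
    breeding_weight`` is the stock retained for breeding, with the
    slaughter count discounted by the number of breeding cycles per
    year.  The division applies to ``n_slaughtered`` only.
    """
    if n_slaughtered < 0 or census < 0:
        raise ConfigError("census and n_slaughtered must be >= 0")
    if breeding_cycles <= 0:
        raise ConfigError("breeding_cycles must be > 0")
    retained = census - n_slaughtered / breeding_cycles
    if retained < 0:
        raise ConfigError(
            f"retained breeding population is negative ({retained:.1f}); "
            "slaughter count inconsistent with census"
        )
    return slaughter_live_weight * n_slaughtered + retained * breeding_weight


def poultry_biomass(
    total_chickens: float,
    chicks_under_2_weeks: float = 0,
    unit_weight: float = DEFAULT_POULTRY_WEIGHT_KG,
) -> float:
    """Poultry biomass: (total birds - young chicks) x unit weight (1 kg)."""
    if not 0 <= chicks_under_2_weeks <= total_chickens:
        raise ConfigError("need 0 <= chicks_under_2_weeks <= total_chickens")
    return (total_chickens - chicks_under_2_weeks) * unit_weight


@dataclass(frozen=True)
class SpeciesBiomassInput:
    """Census, slaughter and weight inputs for one species' biomass.

    Which fields are required depends on the species formula: cattle use
    census + age-class weights/proportions (plus optional slaughter
    throughput), sheep/goats use slaughter + census + breeding
    parameters, poultry use total birds minus young chicks.  ``other``
    species use census x mean of ``age_class_weights`` weighted by
    ``age_class_proportions``.
    """

    species: Species
    census_population: float = 0.0
    n_slaughtered: float = 0.0
    age_class_weights: tuple[float, ...] = ()
    age_class_proportions: tuple[float, ...] = ()
    breeding_cycles_per_year: float = DEFAULT_BREEDING_CYCLES
    breeding_standard_weight: float = DEFAULT_BREEDING_WEIGHT_KG
    slaughter_weight: float = DEFAULT_SMALLSTOCK_SLAUGHTER_WEIGHT_KG
    chicks_excluded: float = 0.0
    poultry_unit_weight: float = DEFAULT_POULTRY_WEIGHT_KG
    food_producing: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", Species(self.species))
        object.__setattr__(
            self, "age_class_weights", tuple(self.age_class_weights)
        )
        object.__setattr__(
            self, "age_class_proportions", tuple(self.age_class_proportions)
        )
        if self.census_population < 0 or self.n_slaughtered < 0:
            raise ConfigError("census and slaughter counts must be >= 0")

    def biomass_kg(self) -> float:
        """Dispatch to the species-appropriate formula."""
        sp = self.species
        if sp is Species.CATTLE:
            herd = bovine_census_biomass(
                self.census_population,
                self.age_class_weights,
                self.age_class_proportions,
            )
            if self.n_slaughtered:
                herd += slaughtered_biomass(
                    self.n_slaughtered, self.slaughter_weight
                )
            return herd
        if sp in (Species.SHEEP, Species.GOAT):
            return smallstock_live_biomass(
                self.slaughter_weight,
                self.n_slaughtered,
                self.census_population,
                self.breeding_cycles_per_year,
                self.breeding_standard_weight,
            )
        if sp is Species.POULTRY:
            return poultry_biomass(
                self.census_population,
                self.chicks_excluded,
                self.poultry_unit_weight,
            )
        # OTHER: census x weighted mean weight
        return bovine_census_biomass(
            self.census_population,
            self.age_class_weights,
            self.age_class_proportions,
        )


@dataclass(frozen=True)
class BiomassResult:
    """Per-species biomass (kg), the total PCU and percentage shares."""

    per_species_kg: dict[Species, float]
    total_pcu_kg: float
    shares_pct: dict[Species, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_species_kg": {s.value: v for s, v in self.per_species_kg.items()},
            "total_pcu_kg": self.total_pcu_kg,
            "shares_pct": {s.value: v for s, v in self.shares_pct.items()},
        }


def total_pcu(inputs: Sequence[SpeciesBiomassInput]) -> BiomassResult:
    """Total PCU: sum of species biomasses, with percentage shares.

    Requires at least one species and no duplicates.  Species flagged
    ``food_producing=False`` (e.g. draft animals) are excluded.
    """
    if not inputs:
        raise ConfigError("total_pcu requires at least one species input")
    food = [i for i in inputs if i.food_producing]
    seen = [i.species for i in food]
    if len(set(seen)) != len(seen):
        raise ConfigError(f"duplicate species in inputs: {seen}")
    per = {i.species: i.biomass_kg() for i in food}
    if not per:
        raise ConfigError("no food-producing species among inputs")
    total = sum(per.values())
    shares = {
        s: (100.0 * v / total if total else 0.0) for s, v in per.items()
    }
    return BiomassResult(per_species_kg=per, total_pcu_kg=total, shares_pct=shares)


def census_count_shares(
    inputs: Sequence[SpeciesBiomassInput], food_only: bool = True
) -> dict[Species, float]:
    """Percentage of animal *heads* per species in the census.

    With ``food_only`` the denominator covers food-producing species
    only; otherwise all species including draft animals and swine.
    """
    pool = [i for i in inputs if i.food_producing or not food_only]
    total = sum(i.census_population for i in pool)
    if total <= 0:
        raise ConfigError("census populations sum to zero")
    return {i.species: 100.0 * i.census_population / total for i in pool}


def write_census_yaml(
    inputs: Sequence[SpeciesBiomassInput],
    path: str | Path,
    total_pcu_override_kg: float | None = None,
) -> None:
    raw = {
        "species": [
            {
                "species": i.species.value,
                "census_population": i.census_population,
                "n_slaughtered": i.n_slaughtered,
                "age_class_weights": list(i.age_class_weights),
                "age_class_proportions": list(i.age_class_proportions),
                "breeding_cycles_per_year": i.breeding_cycles_per_year,
                "breeding_standard_weight": i.breeding_standard_weight,
                "slaughter_weight": i.slaughter_weight,
                "chicks_excluded": i.chicks_excluded,
                "poultry_unit_weight": i.poultry_unit_weight,
                "food_producing": i.food_producing,
            }
            for i in inputs
        ]
    }
    if total_pcu_override_kg is not None:
        raw["total_pcu_override_kg"] = float(total_pcu_override_kg)
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(raw, fh, sort_keys=False)


def read_census_yaml(path: str | Path) -> list[SpeciesBiomassInput]:
    return read_census_config(path)[0]


def read_census_config(
    path: str | Path,
) -> tuple[list[SpeciesBiomassInput], float | None]:
    """Read ``census.yaml``: species inputs plus an optional externally
    supplied total-PCU denominator (``total_pcu_override_kg``), used when
    the surveillance denominator comes from a wider extrapolation than
    the local census can reproduce."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    entries = raw.get("species")
    if not entries:
        raise ConfigError(f"{path}: no species entries")
    out = []
    for e in entries:
        kwargs = dict(e)
        kwargs["species"] = Species(kwargs["species"])
        kwargs["age_class_weights"] = tuple(kwargs.get("age_class_weights", ()))
        kwargs["age_class_proportions"] = tuple(
            kwargs.get("age_class_proportions", ())
        )
        out.append(SpeciesBiomassInput(**kwargs))
    override = raw.get("total_pcu_override_kg")
    return out, (float(override) if override is not None else None)
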