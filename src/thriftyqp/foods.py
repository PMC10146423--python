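"""Item-level and intake-level domain types.

Quantities follow the conventions of the USDA food databases they emulate:
nutrients are stored per 100 g of edible food as consumed (FNDDS style),
food-pattern components as cup/oz equivalents per 100 g (FPED style), and
prices in USD per 100 g edible.  Category profiles downstream are per gram.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: nutrients carried through the pipeline (vitamin D deliberately absent: the
#: recommended intake is not achievable from foods alone, so it is excluded
#: from the constraint system).
NUTRIENTS = (
    "energy", "protein", "carbohydrate", "fiber", "added_sugars",
    "total_fat", "saturated_fat", "linoleic_acid", "linolenic_acid",
    "calcium", "copper", "iron", "magnesium", "phosphorus", "potassium",
    "sodium", "zinc", "vitamin_a", "thiamin", "riboflavin", "niacin",
    "vitamin_b6", "folate", "folic_acid", "vitamin_b12", "vitamin_e",
    "vitamin_k", "choline",
)

#: nutrients bounded from above only (public-health limits); all others get
#: two-sided adequacy bounds.
LIMIT_NUTRIENTS = frozenset({"sodium", "saturated_fat", "added_sugars"})

#: food-pattern components used in the dietary-guidance constraints.
PATTERN_COMPONENTS = (
    "total_vegetables", "total_fruits", "whole_fruits",
    "total_grains", "whole_grains", "total_dairy",
    "protein_foods", "meat_poultry_eggs", "seafood", "nuts_seeds_soy",
    "eggs", "oils",
)

#: components bounded by observed-intake percentiles rather than by a
#: recommendation (aggregated food groups without a direct pattern target).
AGGREGATED_COMPONENTS = frozenset({"meat_poultry_eggs", "nuts_seeds_soy", "eggs"})


@dataclass
class FoodItem:
    """One food or beverage, identified by an 8-digit WWEIA-style food code."""

    code: str
    description: str
    initial_category: str
    nutrients_per_100g: dict[str, float]
    fped_per_100g: dict[str, float]
    price_per_100g: float | None      # USD per 100 g edible; None = missing
    consumption_weight: float
    breakfast_energy_fraction: float

    def __post_init__(self):
        if self.consumption_weight < 0:
            raise ValueError(f"item {self.code}: negative consumption weight")
        if not 0.0 <= self.breakfast_energy_fraction <= 1.0:
            raise ValueError(f"item {self.code}: breakfast fraction outside [0, 1]")
        if self.price_per_100g is not None:
            if math.isnan(self.price_per_100g):
                self.price_per_100g = None
            elif self.price_per_100g <= 0:
                raise ValueError(f"item {self.code}: price must be missing or > 0")
        for name, val in self.nutrients_per_100g.items():
            if val < 0:
                raise ValueError(f"item {self.code}: negative nutrient {name}")
        for name, val in self.fped_per_100g.items():
            if val < 0:
                raise ValueError(f"item {self.code}: negative component {name}")

    @property
    def has_price(self) -> bool:
        return self.price_per_100g is not None


@dataclass
class IntakeRecord:
    """One person-day of reported intake, expressed per combined category."""

    person_id: str
    group_id: str
    amounts: dict[str, float] = field(default_factory=dict)  # combined -> g/day
    quality_score: float = 0.0  # HEI-2015-like, 0-100

    def __post_init__(self):
        for name, val in self.amounts.items():
            if val < 0:
                raise ValueError(f"record {self.person_id}: negative amount for {name}")
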