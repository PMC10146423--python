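"""Category scheme for a TFP-style food system.

The Thrifty Food Plan taxonomy is three-layered:

* *initial categories* — WWEIA-style food groups, some split into a
  higher/lower nutrient-density (hnd/lnd) pair;
* *combined categories* — the unit of the deviation objective, obtained by
  re-aggregating the nutrient-density pairs (46 of them when fresh pork and
  beef are separated);
* *modeling categories* — the optimization variables, obtained by further
  splitting a designated subset of initial categories at the 35th price
  percentile into lower/higher-cost tiers (99 of them at full scale).

This module is the declarative blueprint: which combined categories exist,
which are nutrient-density pairs, which initial categories receive the price
split, the market-basket mapping, and per-category generative parameters used
by :mod:`thriftyqp.synthetic`.  Initial-category *membership* of individual
items is treated as an input everywhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

BASKETS = ("vegetables", "fruits", "grains", "dairy", "protein foods", "miscellaneous")
PROTEIN_SUBS = ("beef", "pork", "cured meat", "poultry", "eggs", "seafood", "nuts-seeds-soy")

#: combined categories that have no cap row despite not matching a Healthy
#: U.S.-Style Dietary Pattern component (they carry dedicated constraints).
CAP_EXEMPT = frozenset({"coffee and tea"})

#: whole-grain fraction of the grain pattern contribution, by nutrient-density tier
WHOLE_GRAIN_FRACTION = {"higher": 0.85, "lower": 0.20, "n/a": 0.50}

#: fruit categories whose fruit equivalents do not count as whole fruit
NON_WHOLE_FRUIT = frozenset({"fruit juice"})

GROUPS = (
    "F4-13", "F14-19", "F20-50", "F51-70",
    "M4-13", "M14-19", "M20-50", "M51-70",
)

#: relative energy scale per age-gender group (adult female 20-50 = 1.0)
GROUP_SCALE = {
    "F4-13": 0.72, "M4-13": 0.80,
    "F14-19": 0.90, "M14-19": 1.18,
    "F20-50": 1.00, "M20-50": 1.25,
    "F51-70": 0.90, "M51-70": 1.08,
}


def is_adult(group_id: str) -> bool:
    """Age band entirely 20 y or older."""
    band = group_id[1:]
    return band in ("20-50", "51-70")


@dataclass(frozen=True)
class CombinedSpec:
    """Blueprint for one combined category."""

    name: str
    nd_pair: bool            # split into hnd/lnd initial categories
    pattern_flag: bool       # matches a Healthy U.S.-Style pattern component
    cost_split: bool         # its initial categories get the 35th-pctile price split
    basket: str
    protein_sub: str | None
    price: float             # median national price, USD per 100 g edible
    energy: float            # kcal per 100 g
    protein: float           # g per 100 g
    carb: float
    fat: float
    satfat: float
    fiber: float
    added_sugar: float
    sodium: float            # mg per 100 g
    comp: float              # food-pattern equivalents per 100 g (semantics from basket)
    intake: float            # adult mean intake, g/day
    breakfast: float         # mean breakfast-energy fraction
    dense: bool              # drives the synthetic diet-quality score


def _c(*args) -> CombinedSpec:
    return CombinedSpec(*args)


# name, pair, pattern, cost_split, basket, sub, price, kcal, prot, carb, fat,
# satfat, fiber, addsug, sodium, comp, intake, breakfast, dense
_ROWS = [
    # -- protein foods -------------------------------------------------------
    _c("pork", True, True, True, "protein foods", "pork",
       0.90, 210, 26, 0, 11, 4.0, 0, 0, 70, 3.3, 30, 0.05, False),
    _c("beef", True, True, True, "protein foods", "beef",
       1.60, 230, 25, 0, 14, 5.5, 0, 0, 75, 3.3, 45, 0.03, False),
    _c("poultry", True, True, True, "protein foods", "poultry",
       0.80, 190, 27, 0, 8, 2.2, 0, 0, 80, 3.3, 80, 0.03, False),
    _c("seafood", True, True, True, "protein foods", "seafood",
       2.20, 150, 22, 2, 5, 1.2, 0, 0, 300, 3.0, 20, 0.02, True),
    _c("eggs", False, True, True, "protein foods", "eggs",
       0.45, 150, 12, 1, 10, 3.2, 0, 0, 140, 2.2, 40, 0.55, False),
    _c("cured meat", False, True, True, "protein foods", "cured meat",
       1.30, 300, 20, 2, 24, 8.5, 0, 0, 1100, 3.0, 25, 0.30, False),
    _c("nuts and seeds", True, True, False, "protein foods", "nuts-seeds-soy",
       1.50, 580, 20, 20, 50, 6.0, 8, 2, 150, 5.0, 15, 0.15, True),
    _c("soy products", True, True, False, "protein foods", "nuts-seeds-soy",
       1.00, 130, 13, 5, 7, 1.0, 2, 0, 250, 2.5, 10, 0.05, True),
    # -- dairy ---------------------------------------------------------------
    _c("milk and yogurt", True, True, True, "dairy", None,
       0.15, 60, 3.4, 6, 2.5, 1.5, 0, 3, 45, 0.42, 180, 0.45, True),
    _c("cheese", True, True, True, "dairy", None,
       1.00, 380, 23, 3, 31, 18.0, 0, 0, 650, 1.50, 30, 0.10, False),
    # -- grains --------------------------------------------------------------
    _c("breakfast cereals", True, True, True, "grains", None,
       0.90, 380, 8, 82, 3, 0.8, 8, 15, 400, 2.5, 30, 0.80, True),
    _c("breads", True, True, True, "grains", None,
       0.50, 270, 9, 50, 4, 0.9, 4, 4, 480, 3.0, 90, 0.30, True),
    _c("rice and pasta", True, True, True, "grains", None,
       0.25, 140, 4, 29, 1, 0.3, 1.5, 0, 5, 1.8, 100, 0.02, False),
    _c("other grains", True, True, False, "grains", None,
       0.50, 200, 6, 40, 2, 0.5, 3, 1, 300, 2.0, 40, 0.20, True),
    # -- fruits --------------------------------------------------------------
    _c("citrus fruits", True, True, True, "fruits", None,
       0.50, 47, 0.9, 12, 0.2, 0.02, 2.4, 0, 1, 0.40, 40, 0.35, True),
    _c("other fruits", True, True, True, "fruits", None,
       0.55, 60, 0.7, 15, 0.3, 0.05, 2.6, 0, 2, 0.45, 110, 0.25, True),
    _c("fruit juice", True, True, False, "fruits", None,
       0.35, 45, 0.5, 11, 0.1, 0.02, 0.2, 0, 4, 0.42, 80, 0.50, False),
    _c("dried fruit", False, True, False, "fruits", None,
       1.60, 300, 2.5, 75, 0.5, 0.06, 7, 0, 10, 1.20, 5, 0.20, True),
    # -- vegetables ----------------------------------------------------------
    _c("dark green vegetables", False, True, True, "vegetables", None,
       0.90, 30, 2.5, 5, 0.4, 0.05, 2.8, 0, 40, 0.45, 30, 0.02, True),
    _c("red and orange vegetables", False, True, True, "vegetables", None,
       0.60, 35, 1.0, 8, 0.2, 0.04, 2.2, 0, 50, 0.45, 60, 0.02, True),
    _c("starchy vegetables", False, True, True, "vegetables", None,
       0.45, 85, 2.2, 19, 0.2, 0.05, 2.5, 0, 10, 0.40, 60, 0.02, True),
    _c("other vegetables", False, True, True, "vegetables", None,
       0.70, 28, 1.3, 6, 0.2, 0.04, 1.9, 0, 25, 0.40, 90, 0.02, True),
    _c("legumes", False, True, True, "vegetables", None,
       0.35, 120, 8, 21, 0.5, 0.1, 7, 0, 240, 0.35, 40, 0.02, True),
    _c("potatoes", False, False, True, "vegetables", None,
       0.35, 130, 2.5, 22, 4, 1.0, 2, 0, 250, 0.0, 70, 0.15, False),
    # -- miscellaneous -------------------------------------------------------
    _c("coffee and tea", False, False, False, "miscellaneous", None,
       0.08, 2, 0.1, 0.3, 0, 0, 0, 0, 3, 0.0, 400, 0.50, False),
    _c("oils", False, True, True, "miscellaneous", None,
       0.90, 880, 0, 0, 100, 14.0, 0, 0, 0, 95.0, 15, 0.10, False),
    _c("butter and animal fats", False, False, False, "miscellaneous", None,
       1.20, 720, 0.9, 0.1, 81, 51.0, 0, 0, 640, 0.0, 5, 0.30, False),
    _c("margarine and cream substitutes", False, False, False, "miscellaneous", None,
       0.90, 600, 0.5, 2, 65, 18.0, 0, 1, 600, 0.0, 10, 0.30, False),
    _c("condiments and sauces", False, False, True, "miscellaneous", None,
       0.70, 150, 2, 20, 7, 1.2, 1, 10, 900, 0.0, 40, 0.05, False),
    _c("mixed dishes", False, False, False, "miscellaneous", None,
       0.90, 180, 9, 18, 8, 3.0, 1.5, 1, 420, 0.0, 150, 0.05, False),
    _c("soups", False, False, False, "miscellaneous", None,
       0.35, 55, 3, 7, 1.5, 0.6, 1, 0, 330, 0.0, 60, 0.02, False),
    _c("soda", True, False, False, "miscellaneous", None,
       0.15, 40, 0, 10, 0, 0, 0, 10, 10, 0.0, 250, 0.02, False),
    _c("fruit drinks", True, False, False, "miscellaneous", None,
       0.20, 45, 0, 11, 0, 0, 0, 10, 15, 0.0, 60, 0.15, False),
    _c("milk substitutes and nutritional beverages", True, False, False,
       "miscellaneous", None,
       0.40, 55, 2, 8, 1.8, 0.3, 0.5, 5, 60, 0.0, 20, 0.35, False),
    _c("smoothies", False, False, False, "miscellaneous", None,
       0.60, 70, 1.5, 15, 0.5, 0.1, 1, 5, 20, 0.0, 15, 0.40, False),
    _c("sweet bakery products", True, False, False, "miscellaneous", None,
       0.80, 400, 5, 55, 18, 6.0, 1.5, 25, 330, 0.0, 50, 0.25, False),
    _c("biscuits, muffins, and quick breads", False, False, False,
       "miscellaneous", None,
       0.70, 360, 7, 48, 15, 5.0, 1.5, 12, 560, 0.0, 25, 0.55, False),
    _c("snack bars", True, False, False, "miscellaneous", None,
       1.40, 420, 8, 62, 14, 4.0, 4, 22, 230, 0.0, 8, 0.45, False),
    _c("candy", False, False, False, "miscellaneous", None,
       1.30, 500, 4, 65, 25, 10.0, 1.5, 55, 70, 0.0, 15, 0.01, False),
    _c("tortilla, corn, and other chips", False, False, False,
       "miscellaneous", None,
       1.10, 520, 7, 55, 29, 3.5, 4, 1, 450, 0.0, 15, 0.02, False),
    _c("crackers", False, False, False, "miscellaneous", None,
       0.90, 450, 8, 65, 16, 3.0, 2.5, 4, 700, 0.0, 10, 0.05, False),
    _c("pretzels and snack mixes", False, False, False, "miscellaneous", None,
       1.00, 400, 9, 75, 5, 1.0, 3, 2, 1100, 0.0, 8, 0.02, False),
    _c("popcorn", True, False, False, "miscellaneous", None,
       1.00, 450, 9, 55, 22, 3.8, 10, 1, 500, 0.0, 5, 0.02, False),
    _c("other desserts", False, False, False, "miscellaneous", None,
       0.90, 320, 4, 45, 14, 7.0, 1, 28, 220, 0.0, 30, 0.03, False),
    _c("ice cream and frozen desserts", False, False, False,
       "miscellaneous", None,
       0.70, 210, 3.5, 24, 11, 7.0, 0.7, 20, 80, 0.0, 30, 0.01, False),
    _c("sugars and sweeteners", False, False, False, "miscellaneous", None,
       0.50, 380, 0, 98, 0, 0, 0, 95, 10, 0.0, 15, 0.25, False),
]


@dataclass(frozen=True)
class InitialCategory:
    """One initial category: a combined category or one of its nd tiers."""

    id: str
    combined: str
    nd_tier: str  # "higher", "lower", or "n/a"


@dataclass
class CategoryScheme:
    """Resolved scheme: combined rows plus the derived initial categories."""

    combined: dict[str, CombinedSpec]
    initial: list[InitialCategory] = field(default_factory=list)

    def __post_init__(self):
        if not self.initial:
            for spec in self.combined.values():
                if spec.nd_pair:
                    self.initial.append(
                        InitialCategory(f"{spec.name} (hnd)", spec.name, "higher"))
                    self.initial.append(
                        InitialCategory(f"{spec.name} (lnd)", spec.name, "lower"))
                else:
                    self.initial.append(InitialCategory(spec.name, spec.name, "n/a"))

    @property
    def initial_ids(self) -> list[str]:
        return [ic.id for ic in self.initial]

    @property
    def cost_split_ids(self) -> list[str]:
        """Initial categories designated for the lower/higher-cost split."""
        return [ic.id for ic in self.initial if self.combined[ic.combined].cost_split]

    def spec_of_initial(self, initial_id: str) -> CombinedSpec:
        for ic in self.initial:
            if ic.id == initial_id:
                return self.combined[ic.combined]
        raise KeyError(initial_id)

    def tier_of_initial(self, initial_id: str) -> str:
        for ic in self.initial:
            if ic.id == initial_id:
                return ic.nd_tier
        raise KeyError(initial_id)


def default_scheme(split_pork_beef: bool = True) -> CategoryScheme:
    """Full-scale scheme: 67 initial / 46 combined categories with the
    pork/beef separation, 65 / 45 without it (pooled "meats" category)."""
    rows = {}
    pooled_done = False
    for spec in _ROWS:
        if not split_pork_beef and spec.name in ("pork", "beef"):
            if pooled_done:
                continue
            pork = next(r for r in _ROWS if r.name == "pork")
            beef = next(r for r in _ROWS if r.name == "beef")
            w = pork.intake + beef.intake
            mix = lambda a, b: (a * pork.intake + b * beef.intake) / w
            pooled = CombinedSpec(
                "meats", True, True, True, "protein foods", "beef",
                mix(pork.price, beef.price), mix(pork.energy, beef.energy),
                mix(pork.protein, beef.protein), 0.0, mix(pork.fat, beef.fat),
                mix(pork.satfat, beef.satfat), 0.0, 0.0,
                mix(pork.sodium, beef.sodium), 3.3, w, 0.04, False)
            rows["meats"] = pooled
            pooled_done = True
        else:
            rows[spec.name] = spec
    return CategoryScheme(combined=rows)
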