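"""Synthetic food system with the statistical structure the pipeline assumes.

The generator emulates the shape of the real inputs (FNDDS-style item tables
with right-skewed national prices, NHANES-style one-day intake records, and
DRI/dietary-guidance bound sets) without claiming their values: ~3,000 items
over 67 initial categories, log-normal prices with outlier contamination and
missing values, per-group gamma-distributed intakes, and a diet-quality score
correlated with nutrient-dense categories so the median filter has bite.

Bound sets are *anchored*: they are built around the waste-adjusted mean diet
of each group, which guarantees a non-empty feasible region at the observed
cost for every seed.

:func:`toy_fixture` returns a deterministic six-category system (with a
pork-like and a beef-like category of identical nutritional profile but
different price) whose lowest-cost plans are derivable by hand and by
exhaustive grid search.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .categories import (CombinedCategory, ModelingCategory, Taxonomy,
                         build_taxonomy)
from .constraints import bounds_rules
from .foods import (FoodItem, IntakeRecord, LIMIT_NUTRIENTS, NUTRIENTS,
                    PATTERN_COMPONENTS)
from .intake import GroupProfile, expand_to_modeling
from .scheme import (CategoryScheme, GROUPS, GROUP_SCALE, NON_WHOLE_FRUIT,
                     WHOLE_GRAIN_FRACTION, default_scheme, is_adult)

# plausible per-100g ranges for the micronutrients not carried in the scheme
# table; category base values are drawn once per category, items jitter around
# them.  Units follow the DRI convention for each nutrient.
_MICRO_RANGES = {
    "linoleic_acid": (0.05, 3.0), "linolenic_acid": (0.01, 0.5),
    "calcium": (5, 150), "copper": (0.02, 0.3), "iron": (0.2, 3.5),
    "magnesium": (5, 80), "phosphorus": (20, 250), "potassium": (40, 450),
    "zinc": (0.1, 3.0), "vitamin_a": (2, 150), "thiamin": (0.01, 0.4),
    "riboflavin": (0.02, 0.4), "niacin": (0.2, 6.0), "vitamin_b6": (0.02, 0.5),
    "folate": (2, 80), "folic_acid": (0, 60), "vitamin_b12": (0, 1.5),
    "vitamin_e": (0.05, 3.0), "vitamin_k": (0.5, 60), "choline": (2, 60),
}

DEFAULT_INTAKE_CV = 0.35


@dataclass
class PriceSpec:
    """Log-normal price model with contamination."""

    sigma: float = 0.35            # log-scale spread within a category
    outlier_fraction: float = 0.03  # share of items multiplied by 5-20x
    outlier_scale: tuple[float, float] = (5.0, 20.0)
    missing_fraction: float = 0.05

    def __post_init__(self):
        if self.sigma < 0 or not 0 <= self.outlier_fraction < 1 \
                or not 0 <= self.missing_fraction < 1:
            raise ValueError("invalid price distribution parameters")
        if min(self.outlier_scale) <= 1:
            raise ValueError("outlier scale factors must exceed 1")


def generate_food_items(n_items: int = 3000,
                        scheme: CategoryScheme | None = None,
                        seed: int = 0,
                        price_spec: PriceSpec | None = None) -> list[FoodItem]:
    """Generate an item table over the scheme's initial categories.

    Every initial category is non-empty and retains at least two priced items
    (so the designated price-tier splits are always defined).  Deterministic
    for a fixed seed.
    """
    scheme = scheme or default_scheme()
    price_spec = price_spec or PriceSpec()
    n_cats = len(scheme.initial)
    if n_items < n_cats or n_cats < 1:
        raise ValueError(f"need n_items >= {n_cats} (one per initial category)")
    rng = np.random.default_rng(seed)

    # allocation: one item per category, remainder by popularity
    pops = np.array([np.sqrt(scheme.spec_of_initial(ic.id).intake) + 1.0
                     for ic in scheme.initial])
    counts = np.ones(n_cats, dtype=int)
    extra = rng.multinomial(n_items - n_cats, pops / pops.sum())
    counts += extra

    micro_base = {}
    items: list[FoodItem] = []
    code = 10000000
    for ic, count in zip(scheme.initial, counts):
        spec = scheme.spec_of_initial(ic.id)
        micro_base[ic.id] = {m: rng.uniform(*_MICRO_RANGES[m]) for m in _MICRO_RANGES}
        prices = _category_prices(rng, spec.price, count, price_spec)
        for k in range(count):
            noise = lambda s=0.25: float(rng.lognormal(0.0, s))
            if ic.nd_tier == "higher":
                satfat = float(rng.uniform(0.0, 4.4))
            elif ic.nd_tier == "lower":
                satfat = float(rng.uniform(4.6, 4.6 + 2.0 * max(spec.satfat, 1.0)))
            else:
                satfat = spec.satfat * noise(0.3)
            nutrients = {
                "energy": spec.energy * noise(),
                "protein": spec.protein * noise(),
                "carbohydrate": spec.carb * noise(),
                "total_fat": spec.fat * noise(),
                "saturated_fat": satfat,
                "fiber": spec.fiber * noise(),
                "added_sugars": spec.added_sugar * noise(),
                "sodium": spec.sodium * noise(),
            }
            for m, base in micro_base[ic.id].items():
                nutrients[m] = base * noise(0.2)
            fped = _fped_for(spec, ic.nd_tier, noise(0.15))
            price = prices[k]
            missing = rng.random() < price_spec.missing_fraction and k >= 2
            b = max(spec.breakfast, 1e-3)
            bf = float(np.clip(rng.beta(8 * b + 0.2, 8 * (1 - b) + 0.2), 0.0, 1.0))
            items.append(FoodItem(
                code=str(code), description=f"{ic.id} item {k}",
                initial_category=ic.id, nutrients_per_100g=nutrients,
                fped_per_100g=fped,
                price_per_100g=None if missing else price,
                consumption_weight=spec.intake * float(rng.lognormal(0.0, 0.8)),
                breakfast_energy_fraction=bf))
            code += 1

    _enforce_density_weight_guards(items, scheme)
    return items


def _category_prices(rng, median: float, count: int,
                     price_spec: PriceSpec) -> np.ndarray:
    """Right-skewed category prices: a log-normal body clamped at its own
    1.5-IQR-above-Q1 fence (so the uncontaminated table is outlier-free by
    the flagging rule), plus deliberate 5-20x outliers on top."""
    base = median * rng.lognormal(0.0, price_spec.sigma, size=count)
    if count >= 4:
        q1, q3 = np.percentile(base, [25, 75])
        base = np.minimum(base, q1 + 1.5 * (q3 - q1))
    hit = rng.random(count) < price_spec.outlier_fraction
    base[hit] *= rng.uniform(*price_spec.outlier_scale, size=hit.sum())
    return base


def _fped_for(spec, tier: str, jitter: float) -> dict[str, float]:
    comp = spec.comp * jitter
    basket, sub, name = spec.basket, spec.protein_sub, spec.name
    f: dict[str, float] = {}
    if comp == 0:
        return f
    if basket == "vegetables":
        f["total_vegetables"] = comp
    elif basket == "fruits":
        f["total_fruits"] = comp
        if name not in NON_WHOLE_FRUIT:
            f["whole_fruits"] = comp
    elif basket == "grains":
        f["total_grains"] = comp
        f["whole_grains"] = comp * WHOLE_GRAIN_FRACTION[tier]
    elif basket == "dairy":
        f["total_dairy"] = comp
    elif basket == "protein foods":
        f["protein_foods"] = comp
        if sub == "seafood":
            f["seafood"] = comp
        elif sub == "nuts-seeds-soy":
            f["nuts_seeds_soy"] = comp
        else:
            f["meat_poultry_eggs"] = comp
            if sub == "eggs":
                f["eggs"] = comp
    elif name == "oils":
        f["oils"] = comp
    return f


def _enforce_density_weight_guards(items: list[FoodItem],
                                   scheme: CategoryScheme,
                                   ratio: float = 1.5) -> None:
    """Anchored-construction guard on nutrient-density weight splits.

    The observed diet is spread over a pair's hnd/lnd tiers in proportion to
    item weights, so the milk/yogurt density rule and the 50%-whole-grain
    rule hold at the anchor only if the higher-density tier dominates by
    weight.  Draws where the random weights fall short are rescaled so the
    hnd tier is at least ``ratio`` times the lnd tier, both in total weight
    and in priced weight (the anchor splits by the latter)."""
    for name, spec in scheme.combined.items():
        if not spec.nd_pair:
            continue
        if name != "milk and yogurt" and spec.basket != "grains":
            continue
        hnd = [it for it in items if it.initial_category == f"{name} (hnd)"]
        lnd = [it for it in items if it.initial_category == f"{name} (lnd)"]
        if not hnd or not lnd:
            continue
        factor = 1.0
        for priced_only in (False, True):
            wh = sum(it.consumption_weight for it in hnd
                     if it.has_price or not priced_only)
            wl = sum(it.consumption_weight for it in lnd
                     if it.has_price or not priced_only)
            if wh > 0 and wh < ratio * wl:
                factor = max(factor, ratio * wl / wh)
        if factor > 1.0:
            for it in hnd:
                it.consumption_weight *= factor


# ---------------------------------------------------------------------------
# intake records
# ---------------------------------------------------------------------------

def default_intake_spec(scheme: CategoryScheme | None = None,
                        cv: float = DEFAULT_INTAKE_CV) -> dict[str, tuple[float, float]]:
    """Adult baseline mean (g/day) and coefficient of variation per combined
    category; group scaling is applied at draw time."""
    scheme = scheme or default_scheme()
    return {name: (spec.intake, cv) for name, spec in scheme.combined.items()}


def generate_intake_records(groups: list[str] = GROUPS,
                            n_per_group: int = 300,
                            seed: int = 0,
                            intake_spec: dict | None = None,
                            scheme: CategoryScheme | None = None,
                            quality_noise: float = 6.0) -> list[IntakeRecord]:
    """Gamma-distributed intakes per combined category and group.

    The diet-quality score is a noisy linear function of intake of the
    nutrient-dense categories rescaled to 0-100, so filtering on the group
    median shifts the retained-set composition.  Coffee/tea intake is zero
    for the youth groups.  Deterministic for a fixed seed.
    """
    if not groups:
        raise ValueError("empty group list")
    scheme = scheme or default_scheme()
    spec = intake_spec or default_intake_spec(scheme)
    if any(mean < 0 for mean, _ in spec.values()):
        raise ValueError("intake means must be non-negative")
    dense = [name for name, s in scheme.combined.items() if s.dense]
    rng = np.random.default_rng(seed)
    records: list[IntakeRecord] = []
    for gid in groups:
        scale = GROUP_SCALE.get(gid, 1.0)
        adult = is_adult(gid)
        draws = {}
        for cat, (mean, cv) in spec.items():
            mu = mean * scale
            if cat == "coffee and tea" and not adult:
                mu = 0.0
            if mu == 0 or cv == 0:
                draws[cat] = np.full(n_per_group, mu)
            else:
                shape = 1.0 / cv ** 2
                draws[cat] = rng.gamma(shape, mu / shape, size=n_per_group)
        raw = np.zeros(n_per_group)
        for cat in dense:
            mu = spec[cat][0] * scale
            if mu > 0:
                raw += draws[cat] / mu
        sdev = raw.std()
        z = (raw - raw.mean()) / sdev if sdev > 0 else np.zeros(n_per_group)
        score = np.clip(50 + 18 * z + rng.normal(0, quality_noise, n_per_group), 0, 100)
        for k in range(n_per_group):
            records.append(IntakeRecord(
                person_id=f"{gid}-{k:05d}", group_id=gid,
                amounts={cat: float(draws[cat][k]) for cat in spec},
                quality_score=float(score[k])))
    return records


# ---------------------------------------------------------------------------
# recommendation bounds (anchored)
# ---------------------------------------------------------------------------

ENERGY_SLACK = (0.90, 1.10)
NUTRIENT_SLACK = (0.75, 1.40)
LIMIT_SLACK = 1.60
REC_FRACTION = 0.95   # pattern recommendation relative to the anchored intake


def generate_recommendations(group: GroupProfile, taxonomy: Taxonomy,
                             records: list[IntakeRecord],
                             nutrients=NUTRIENTS) -> GroupProfile:
    """Attach anchored nutrient and pattern bounds to a group profile.

    The anchor is the group's waste-adjusted observed diet expanded to
    modeling categories.  Nutrient bounds bracket the anchor's totals
    (energy +-10%, adequacy nutrients -25%/+40%, public-health limits upper
    bound only).  Pattern bounds follow the recommendation/percentile rules
    of :func:`thriftyqp.constraints.bounds_rules`, with the recommendation
    set slightly below the anchor and, where a percentile bound would exclude
    the anchor, widened just enough to contain it — the anchored-feasibility
    guarantee of the generator.  Vitamin D is refused.
    """
    if any(n.lower().replace(" ", "_") == "vitamin_d" for n in nutrients):
        raise ValueError("vitamin D is not part of the constraint system "
                         "(recommended intake unachievable from food alone)")
    x = expand_to_modeling(group.observed_c, taxonomy)
    if (x < 0).any():
        raise ValueError("feasibility anchor has negative amounts")

    D_LB, D_UB = {}, {}
    for n in nutrients:
        total = float(taxonomy.profile_matrix([n], "d")[0] @ x)
        if n == "energy":
            D_LB[n], D_UB[n] = total * ENERGY_SLACK[0], total * ENERGY_SLACK[1]
        elif n in LIMIT_NUTRIENTS:
            D_LB[n], D_UB[n] = 0.0, total * LIMIT_SLACK
        else:
            D_LB[n], D_UB[n] = total * NUTRIENT_SLACK[0], total * NUTRIENT_SLACK[1]

    # per-record pattern totals for the percentile rules, on the same
    # waste-adjusted scale as the anchor
    gid_records = [r for r in records if r.group_id == group.group_id]
    comp_profiles = _combined_pattern_profiles(taxonomy)
    pct: dict[str, dict[int, float]] = {}
    recommended: dict[str, float] = {}
    anchor_totals = {}
    for comp in PATTERN_COMPONENTS:
        anchor_totals[comp] = float(taxonomy.profile_matrix([comp], "f")[0] @ x)
        if gid_records:
            totals = np.array([
                1.05 * sum(amt * comp_profiles[cid].get(comp, 0.0)
                           for cid, amt in r.amounts.items() if cid in comp_profiles)
                for r in gid_records])
            pct[comp] = {q: float(np.percentile(totals, q)) for q in (25, 75, 95)}
        else:
            pct[comp] = {25: 0.0, 75: anchor_totals[comp], 95: anchor_totals[comp]}
        recommended[comp] = REC_FRACTION * anchor_totals[comp]

    F_LB, F_UB = bounds_rules(recommended, pct)
    for comp, total in anchor_totals.items():  # anchored-feasibility guarantee
        F_LB[comp] = min(F_LB[comp], 0.98 * total)
        F_UB[comp] = max(F_UB[comp], 1.02 * total)

    return GroupProfile(group.group_id, dict(group.observed_c),
                        dict(group.observed_sd), D_LB, D_UB, F_LB, F_UB,
                        group.C_obs)


def _combined_pattern_profiles(taxonomy: Taxonomy) -> dict[str, dict[str, float]]:
    """Weight-averaged per-gram pattern profile of each combined category."""
    out = {}
    for cid, cc in taxonomy.combined.items():
        members = [taxonomy.modeling[m] for m in cc.members]
        w = np.array([max(m.weight, 0.0) for m in members])
        if w.sum() <= 0:
            w = np.ones(len(members))
        keys = {k for m in members for k in m.f}
        out[cid] = {k: float(np.average([m.f.get(k, 0.0) for m in members],
                                        weights=w)) for k in keys}
    return out


# ---------------------------------------------------------------------------
# full synthetic system
# ---------------------------------------------------------------------------

@dataclass
class FoodSystem:
    """A complete generated study system ready for optimization."""

    items: list[FoodItem]
    taxonomy: Taxonomy
    records: list[IntakeRecord]
    groups: dict[str, GroupProfile]
    seed: int
    manifest: dict = field(default_factory=dict)


def generate_system(seed: int = 0, n_items: int = 3000, n_per_group: int = 300,
                    groups=GROUPS, scheme: CategoryScheme | None = None,
                    price_spec: PriceSpec | None = None) -> FoodSystem:
    """Item table -> taxonomy -> intake records -> anchored group profiles."""
    from .intake import build_group_profile
    scheme = scheme or default_scheme()
    items = generate_food_items(n_items, scheme, seed=seed, price_spec=price_spec)
    taxonomy = build_taxonomy(items, scheme)
    records = generate_intake_records(groups, n_per_group, seed=seed + 1,
                                      scheme=scheme)
    profiles = {}
    for gid in groups:
        gp = build_group_profile(gid, [r for r in records if r.group_id == gid],
                                 taxonomy)
        profiles[gid] = generate_recommendations(gp, taxonomy, records)
    manifest = {"seed": seed, "n_items": n_items, "n_per_group": n_per_group,
                "groups": list(groups)}
    return FoodSystem(items, taxonomy, records, profiles, seed, manifest)


# ---------------------------------------------------------------------------
# toy fixture
# ---------------------------------------------------------------------------

@dataclass
class ToyFixture:
    """Deterministic six-category system with hand-derived optima."""

    taxonomy: Taxonomy
    groups: dict[str, GroupProfile]
    known: dict

    def grid_ranges(self, group_id: str) -> dict[str, tuple[float, float]]:
        """Variable boxes for the exhaustive grid oracle (pinned categories
        are fixed to their unique feasible amount)."""
        s = self.known["scale"][group_id]
        return {
            "grain": (200 * s, 300 * s),
            "vegetables": (300 * s, 300 * s),
            "fruit": (200 * s, 200 * s),
            "dairy": (250 * s, 250 * s),
            "pork": (0.0, 160 * s),
            "beef": (0.0, 160 * s),
        }


def toy_fixture() -> ToyFixture:
    """Six modeling categories, two adult groups, no randomness.

    The pork-like and beef-like categories share one nutritional profile but
    pork is half the price.  Vegetables, fruit, and dairy are pinned by
    equality pattern bounds, leaving grain/pork/beef free, so every optimum is
    reachable by a 1-g grid search.  The separated lowest-cost plan sits on
    integer grams by construction; minimum costs and cent budgets are recorded
    in ``known`` (hand-derived).
    """
    profiles = {
        "grain": ({"energy": 3.5, "protein": 0.10},
                  {"total_grains": 0.035, "whole_grains": 0.020}, 0.002),
        "vegetables": ({"energy": 0.5, "protein": 0.02},
                       {"total_vegetables": 0.010}, 0.003),
        "fruit": ({"energy": 0.6, "protein": 0.01},
                  {"total_fruits": 0.010, "whole_fruits": 0.010}, 0.003),
        "dairy": ({"energy": 0.8, "protein": 0.035},
                  {"total_dairy": 0.004}, 0.00252),
        "pork": ({"energy": 2.0, "protein": 0.25},
                 {"protein_foods": 0.035, "meat_poultry_eggs": 0.035}, 0.004),
        "beef": ({"energy": 2.0, "protein": 0.25},
                 {"protein_foods": 0.035, "meat_poultry_eggs": 0.035}, 0.008),
    }
    baskets = {"grain": "grains", "vegetables": "vegetables", "fruit": "fruits",
               "dairy": "dairy", "pork": "protein foods", "beef": "protein foods"}
    subs = {"pork": "pork", "beef": "beef"}
    observed = {"grain": 250.0, "vegetables": 300.0, "fruit": 200.0,
                "dairy": 250.0, "pork": 115.0, "beef": 5.0}

    modeling, combined = {}, {}
    for name, (d, f, p) in profiles.items():
        modeling[name] = ModelingCategory(
            id=name, combined_id=name, market_basket_id=baskets[name],
            protein_sub=subs.get(name), nd_tier="n/a", cost_tier="n/a",
            d=d, f=f, p=p, breakfast_fraction=0.0,
            weight=observed[name], weight_priced=observed[name])
        combined[name] = CombinedCategory(
            id=name, members=[name], p=p, pattern_flag=True,
            basket=baskets[name], protein_sub=subs.get(name))
    taxonomy = Taxonomy(modeling=modeling, combined=combined, n_initial=6)

    base_D = {"energy": (1500.0, 1700.0), "protein": (60.0, 100.0)}
    base_F = {"total_vegetables": (3.0, 3.0), "total_fruits": (2.0, 2.0),
              "whole_fruits": (2.0, 2.0), "total_dairy": (1.0, 1.0),
              "total_grains": (7.0, 10.5), "whole_grains": (4.0, 6.0),
              "protein_foods": (3.5, 5.6), "meat_poultry_eggs": (3.5, 5.6)}
    scales = {"F20-50": 1.0, "M20-50": 1.2}
    groups = {}
    for gid, s in scales.items():
        c = {k: v * s for k, v in observed.items()}
        sd = {k: 0.1 * v for k, v in c.items()}
        prices = {k: profiles[k][2] for k in profiles}
        groups[gid] = GroupProfile(
            gid, c, sd,
            D_LB={k: lo * s for k, (lo, hi) in base_D.items()},
            D_UB={k: hi * s for k, (lo, hi) in base_D.items()},
            F_LB={k: lo * s for k, (lo, hi) in base_F.items()},
            F_UB={k: hi * s for k, (lo, hi) in base_F.items()},
            C_obs=sum(c[k] * prices[k] for k in c))

    # hand-derived: fixed veg+fruit+dairy cost 2.13; the energy floor forces
    # grain >= 830/3.5 g once meat sits at its 100 g pattern floor
    min_cost_sep = 2.13 + 0.40 + (830.0 / 3.5) * 0.002        # pork-only meat
    min_cost_pooled = 2.13 + 100 * (0.46 + 0.04) / 120 + (830.0 / 3.5) * 0.002
    min_cost_beef = 2.13 + 0.80 + (830.0 / 3.5) * 0.002       # beef-only meat
    known = {
        "scale": scales,
        "observed_cost": {"F20-50": 3.13, "M20-50": 3.756},
        "min_cost_separated": {g: min_cost_sep * s for g, s in scales.items()},
        "min_cost_pooled": {g: min_cost_pooled * s for g, s in scales.items()},
        "min_cost_beef_only": {g: min_cost_beef * s for g, s in scales.items()},
        # lowest cent-grid budgets reachable from C_obs in 0.01 steps
        "lowest_budget_separated": {"F20-50": 3.01, "M20-50": 3.606},
        "lowest_budget_pooled": {"F20-50": 3.03, "M20-50": 3.626},
        "lowest_budget_beef_only": {"F20-50": 3.41, "M20-50": 4.086},
        # optimum of the separated model at its lowest budget (integer grams)
        "optimum_separated": {
            "F20-50": {"grain": 240.0, "vegetables": 300.0, "fruit": 200.0,
                       "dairy": 250.0, "pork": 100.0, "beef": 0.0},
            "M20-50": {"grain": 285.0, "vegetables": 360.0, "fruit": 240.0,
                       "dairy": 300.0, "pork": 120.0, "beef": 0.0},
        },
    }
    return ToyFixture(taxonomy=taxonomy, groups=groups, known=known)


# ---------------------------------------------------------------------------
# CSV / JSON writers and readers
# ---------------------------------------------------------------------------

def write_items(items: list[FoodItem], path, manifest: dict | None = None) -> None:
    rows = []
    for it in items:
        row = {"code": it.code, "description": it.description,
               "initial_category": it.initial_category,
               "price_per_100g": it.price_per_100g,
               "consumption_weight": it.consumption_weight,
               "breakfast_energy_fraction": it.breakfast_energy_fraction}
        row.update({f"n:{k}": v for k, v in it.nutrients_per_100g.items()})
        row.update({f"f:{k}": v for k, v in it.fped_per_100g.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
    if manifest is not None:
        with open(str(path) + ".manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)


def read_items(path) -> list[FoodItem]:
    df = pd.read_csv(path, dtype={"code": str})
    items = []
    for _, row in df.iterrows():
        price = row["price_per_100g"]
        items.append(FoodItem(
            code=row["code"], description=row["description"],
            initial_category=row["initial_category"],
            nutrients_per_100g={k[2:]: row[k] for k in df.columns
                                if k.startswith("n:") and pd.notna(row[k])},
            fped_per_100g={k[2:]: row[k] for k in df.columns
                           if k.startswith("f:") and pd.notna(row[k])},
            price_per_100g=None if pd.isna(price) else float(price),
            consumption_weight=float(row["consumption_weight"]),
            breakfast_energy_fraction=float(row["breakfast_energy_fraction"])))
    return items


def write_records(records: list[IntakeRecord], path) -> None:
    rows = []
    for r in records:
        row = {"person_id": r.person_id, "group_id": r.group_id,
               "quality_score": r.quality_score}
        row.update({f"g:{k}": v for k, v in r.amounts.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_records(path) -> list[IntakeRecord]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        out.append(IntakeRecord(
            person_id=row["person_id"], group_id=row["group_id"],
            amounts={k[2:]: float(row[k]) for k in df.columns if k.startswith("g:")},
            quality_score=float(row["quality_score"])))
    return out
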