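"""Construction of modeling and combined categories from item tables.

Implements the TFP-style category pipeline: the saturated-fat nutrient-density
split, price-outlier flagging (items priced more than 1.5 interquartile ranges
above the first quartile of their category), consumption-weighted category
prices with missing/outlier prices carrying zero weight, the 35th-percentile
lower/higher-cost split for the designated categories, and weighted per-gram
nutrient and food-pattern profiles.  At full scale the result is 67 initial,
99 modeling, and 46 combined categories.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .foods import FoodItem
from .scheme import CategoryScheme

__all__ = [
    "ModelingCategory", "CombinedCategory", "Taxonomy",
    "split_by_nutrient_density", "flag_price_outliers", "weighted_mean_price",
    "split_by_price_tier", "weighted_profile", "build_taxonomy",
]

DENSITY_THRESHOLD = 4.5   # g saturated fat per 100 g
PRICE_PERCENTILE = 35.0
OUTLIER_MIN_SUPPORT = 4   # quartiles are ill-defined below this


@dataclass
class ModelingCategory:
    """One optimization variable with per-gram profiles and price."""

    id: str
    combined_id: str
    market_basket_id: str
    protein_sub: str | None
    nd_tier: str            # "higher" / "lower" / "n/a"
    cost_tier: str          # "higher" / "lower" / "n/a"
    d: dict[str, float]     # nutrient amounts per gram
    f: dict[str, float]     # pattern equivalents per gram
    p: float                # USD per gram
    breakfast_fraction: float
    weight: float = 0.0         # total consumption weight of member items
    weight_priced: float = 0.0  # weight of items contributing to the price

    def __post_init__(self):
        if self.p <= 0:
            raise ValueError(f"modeling category {self.id}: price must be > 0")

    @property
    def energy(self) -> float:
        return self.d.get("energy", 0.0)


@dataclass
class CombinedCategory:
    """Aggregation unit of the deviation objective."""

    id: str
    members: list[str]
    p: float                 # USD per gram, weighted over member items
    pattern_flag: bool
    basket: str
    protein_sub: str | None = None
    c: float | None = None   # g/day observed mean (group-specific)
    sd: float | None = None
    beta: float | None = None


@dataclass
class Taxonomy:
    """The resolved category system used by the optimizer and reporting."""

    modeling: dict[str, ModelingCategory]
    combined: dict[str, CombinedCategory]
    n_initial: int

    def __post_init__(self):
        members = [m for cc in self.combined.values() for m in cc.members]
        if sorted(members) != sorted(self.modeling):
            raise ValueError("combined categories do not partition the modeling categories")

    @property
    def modeling_ids(self) -> list[str]:
        return list(self.modeling)

    @property
    def combined_ids(self) -> list[str]:
        return list(self.combined)

    def aggregation_matrix(self) -> np.ndarray:
        """0/1 matrix A with A[j, i] = 1 iff modeling category i belongs to
        combined category j (orders follow ``combined_ids``/``modeling_ids``)."""
        idx = {mid: i for i, mid in enumerate(self.modeling_ids)}
        A = np.zeros((len(self.combined), len(self.modeling)))
        for j, cid in enumerate(self.combined_ids):
            for mid in self.combined[cid].members:
                A[j, idx[mid]] = 1.0
        return A

    def profile_matrix(self, keys, which: str = "d") -> np.ndarray:
        """len(keys) x n_modeling matrix of per-gram profile values."""
        mats = []
        for key in keys:
            row = [getattr(self.modeling[mid], which).get(key, 0.0)
                   for mid in self.modeling_ids]
            mats.append(row)
        return np.asarray(mats)

    def prices(self) -> np.ndarray:
        return np.array([self.modeling[mid].p for mid in self.modeling_ids])

    def pool_combined(self, ids: list[str], new_id: str) -> "Taxonomy":
        """Merge combined categories into one, fusing all their modeling
        categories into a single variable with weight-averaged profiles and a
        weight-averaged price (used for the pooled-meat scenario)."""
        old = [self.combined[i] for i in ids]
        members = [self.modeling[m] for cc in old for m in cc.members]
        w = np.array([m.weight for m in members])
        if w.sum() <= 0:
            w = np.ones(len(members))
        wp = np.array([m.weight_priced for m in members])
        if wp.sum() <= 0:
            wp = w
        nutr = {k: float(np.average([m.d.get(k, 0.0) for m in members], weights=w))
                for k in {k for m in members for k in m.d}}
        fped = {k: float(np.average([m.f.get(k, 0.0) for m in members], weights=w))
                for k in {k for m in members for k in m.f}}
        subs = {m.protein_sub for m in members if m.protein_sub}
        # pooled red meat is conventionally reported on the beef row
        sub = "beef" if "beef" in subs else (sorted(subs)[0] if subs else None)
        pooled = ModelingCategory(
            id=new_id, combined_id=new_id,
            market_basket_id=members[0].market_basket_id,
            protein_sub=sub, nd_tier="n/a", cost_tier="n/a",
            d=nutr, f=fped,
            p=float(np.average([m.p for m in members], weights=wp)),
            breakfast_fraction=float(np.average(
                [m.breakfast_fraction for m in members], weights=w)),
            weight=float(w.sum()), weight_priced=float(wp.sum()))
        modeling = {mid: mc for mid, mc in self.modeling.items()
                    if mc.combined_id not in ids}
        modeling[new_id] = pooled
        combined = {cid: cc for cid, cc in self.combined.items() if cid not in ids}
        combined[new_id] = CombinedCategory(
            id=new_id, members=[new_id], p=pooled.p,
            pattern_flag=all(cc.pattern_flag for cc in old),
            basket=old[0].basket, protein_sub=old[0].protein_sub)
        return Taxonomy(modeling=modeling, combined=combined, n_initial=self.n_initial)

    # -- serialization -------------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "n_initial": self.n_initial,
            "modeling": {k: asdict(v) for k, v in self.modeling.items()},
            "combined": {k: asdict(v) for k, v in self.combined.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Taxonomy":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            modeling={k: ModelingCategory(**v) for k, v in payload["modeling"].items()},
            combined={k: CombinedCategory(**v) for k, v in payload["combined"].items()},
            n_initial=payload["n_initial"])


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------

def split_by_nutrient_density(items: list[FoodItem],
                              threshold: float = DENSITY_THRESHOLD,
                              boundary: str = "higher") -> dict[str, str]:
    """Assign items to a higher/lower nutrient-density tier by saturated fat.

    Items strictly below `threshold` g/100 g are "higher" density, strictly
    above are "lower"; an item exactly at the threshold follows `boundary`
    (default "higher").  Items without a saturated-fat value are excluded
    with a warning and absent from the returned mapping.
    """
    out: dict[str, str] = {}
    skipped = []
    for item in items:
        sf = item.nutrients_per_100g.get("saturated_fat")
        if sf is None or np.isnan(sf):
            skipped.append(item.code)
            continue
        if sf < threshold:
            out[item.code] = "higher"
        elif sf > threshold:
            out[item.code] = "lower"
        else:
            out[item.code] = boundary
    if skipped:
        warnings.warn(
            f"{len(skipped)} item(s) lack a saturated-fat value and were "
            f"excluded from the nutrient-density split: {skipped[:5]}...")
    return out


def flag_price_outliers(prices, k: float = 1.5, fence: str = "q1",
                        min_support: int = OUTLIER_MIN_SUPPORT) -> np.ndarray:
    """Flag prices more than ``k`` interquartile ranges above the fence.

    ``fence="q1"`` uses Q1 + k*IQR (the rule as printed in the TFP 2021
    description); ``fence="q3"`` gives the conventional Tukey fence.
    Quartiles are linear-interpolation ("type 7") over non-missing prices.
    Missing prices are never flagged; with fewer than ``min_support``
    non-missing prices no flags are raised.
    """
    arr = np.array([np.nan if p is None else p for p in prices], dtype=float)
    flags = np.zeros(arr.shape, dtype=bool)
    finite = np.isfinite(arr)
    if finite.sum() < min_support:
        return flags
    q1, q3 = np.percentile(arr[finite], [25, 75])
    base = q1 if fence == "q1" else q3
    cutoff = base + k * (q3 - q1)
    flags[finite] = arr[finite] > cutoff
    return flags


def weighted_mean_price(items: list[FoodItem],
                        outlier_flags=None,
                        label: str = "category") -> float:
    """Consumption-weighted mean price in USD per gram.

    Items with a missing price or a flagged outlier price contribute zero
    weight, following the TFP convention.  Raises if no usable item remains.
    """
    if outlier_flags is None:
        outlier_flags = np.zeros(len(items), dtype=bool)
    num = den = 0.0
    for item, bad in zip(items, outlier_flags):
        if item.has_price and not bad and item.consumption_weight > 0:
            num += item.consumption_weight * item.price_per_100g
            den += item.consumption_weight
    if den == 0:
        raise ValueError(
            f"{label}: no item with a usable (non-missing, non-outlier, "
            "positively weighted) price")
    return (num / den) / 100.0


def split_by_price_tier(prices, percentile: float = PRICE_PERCENTILE):
    """Label prices "lower"/"higher" cost at the given percentile cut.

    The cut-point is the linear-interpolation percentile of *non-missing*
    prices; prices at or below it are "lower" cost.  Missing prices get the
    label "lower" by convention (their price never enters any calculation).
    Returns (labels, cut_point); if fewer than two prices are non-missing the
    split is skipped and (None, None) is returned.
    """
    arr = np.array([np.nan if p is None else p for p in prices], dtype=float)
    finite = np.isfinite(arr)
    if finite.sum() < 2:
        return None, None
    cut = float(np.percentile(arr[finite], percentile))
    labels = np.where(finite & (arr > cut), "higher", "lower")
    return list(labels), cut


def weighted_profile(items: list[FoodItem]) -> tuple[dict, dict]:
    """Consumption-weighted per-gram nutrient and pattern profiles.

    All items contribute by consumption weight regardless of price status
    (price outlier exclusion is price-specific).  Values are converted from
    per-100 g to per-gram.  Raises on zero total weight.
    """
    w = np.array([it.consumption_weight for it in items], dtype=float)
    if w.sum() <= 0:
        raise ValueError("weighted profile requires positive total weight")
    nutr_keys = {k for it in items for k in it.nutrients_per_100g}
    fped_keys = {k for it in items for k in it.fped_per_100g}
    d = {k: float(np.average([it.nutrients_per_100g.get(k, 0.0) for it in items],
                             weights=w)) / 100.0
         for k in sorted(nutr_keys)}
    f = {k: float(np.average([it.fped_per_100g.get(k, 0.0) for it in items],
                             weights=w)) / 100.0
         for k in sorted(fped_keys)}
    return d, f


# ---------------------------------------------------------------------------
# taxonomy assembly
# ---------------------------------------------------------------------------

def build_taxonomy(items: list[FoodItem], scheme: CategoryScheme,
                   percentile: float = PRICE_PERCENTILE,
                   outlier_k: float = 1.5, outlier_fence: str = "q1") -> Taxonomy:
    """Build the modeling/combined category system from an item table.

    Initial-category membership is taken from the items; the designated
    cost-split list, nutrient-density tiers, and basket mapping come from the
    scheme.  Every initial category must be non-empty and must yield a usable
    weighted price.
    """
    by_initial: dict[str, list[FoodItem]] = {ic: [] for ic in scheme.initial_ids}
    for item in items:
        if item.initial_category not in by_initial:
            raise ValueError(f"item {item.code}: unknown initial category "
                             f"{item.initial_category!r}")
        by_initial[item.initial_category].append(item)
    empty = [ic for ic, members in by_initial.items() if not members]
    if empty:
        raise ValueError(f"initial categories with no items: {empty}")

    split_set = set(scheme.cost_split_ids)
    modeling: dict[str, ModelingCategory] = {}
    members_of: dict[str, list[str]] = {}
    price_num: dict[str, float] = {}
    price_den: dict[str, float] = {}

    for initial_id, group in by_initial.items():
        spec = scheme.spec_of_initial(initial_id)
        tier = scheme.tier_of_initial(initial_id)
        flags = flag_price_outliers([it.price_per_100g for it in group],
                                    k=outlier_k, fence=outlier_fence)
        labels = None
        if initial_id in split_set:
            labels, _ = split_by_price_tier(
                [it.price_per_100g for it in group], percentile)
            if labels is not None and "higher" not in labels:
                labels = None  # degenerate prices: category remains unsplit
        buckets: dict[str, tuple[list[FoodItem], list[bool]]] = {}
        if labels is None:
            buckets["n/a"] = (group, list(flags))
        else:
            for lab in ("lower", "higher"):
                sub = [(it, fl) for it, fl, la in zip(group, flags, labels) if la == lab]
                buckets[lab] = ([x[0] for x in sub], [x[1] for x in sub])

        for cost_tier, (sub_items, sub_flags) in buckets.items():
            mid = initial_id if cost_tier == "n/a" else f"{initial_id} [{cost_tier} cost]"
            d, f = weighted_profile(sub_items)
            p = weighted_mean_price(sub_items, sub_flags, label=mid)
            w = sum(it.consumption_weight for it in sub_items)
            wp = sum(it.consumption_weight for it, fl in zip(sub_items, sub_flags)
                     if it.has_price and not fl and it.consumption_weight > 0)
            energies = np.array([it.nutrients_per_100g.get("energy", 0.0)
                                 for it in sub_items])
            weights = np.array([it.consumption_weight for it in sub_items])
            ew = energies * weights
            if ew.sum() > 0:
                bf = float(np.average(
                    [it.breakfast_energy_fraction for it in sub_items], weights=ew))
            else:
                bf = float(np.average(
                    [it.breakfast_energy_fraction for it in sub_items], weights=weights))
            modeling[mid] = ModelingCategory(
                id=mid, combined_id=spec.name,
                market_basket_id=spec.basket, protein_sub=spec.protein_sub,
                nd_tier=tier, cost_tier=cost_tier,
                d=d, f=f, p=p, breakfast_fraction=bf,
                weight=w, weight_priced=wp)
            members_of.setdefault(spec.name, []).append(mid)
            price_num[spec.name] = price_num.get(spec.name, 0.0) + wp * p
            price_den[spec.name] = price_den.get(spec.name, 0.0) + wp

    combined = {}
    for name, spec in scheme.combined.items():
        if name not in members_of:
            raise ValueError(f"combined category {name!r} has no modeling members")
        combined[name] = CombinedCategory(
            id=name, members=members_of[name],
            p=price_num[name] / price_den[name],
            pattern_flag=spec.pattern_flag, basket=spec.basket,
            protein_sub=spec.protein_sub)
    return Taxonomy(modeling=modeling, combined=combined,
                    n_initial=len(scheme.initial))
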