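"""Category engine: density split, outlier fences, weighted prices/profiles,
price-tier split, and taxonomy assembly."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from thriftyqp import (FoodItem, build_taxonomy, default_scheme,
                       flag_price_outliers, generate_food_items,
                       split_by_nutrient_density, split_by_price_tier,
                       weighted_mean_price, weighted_profile)


def _item(code="10000001", category="x", satfat=1.0, price=1.0, weight=1.0,
          nutrients=None):
    n = {"energy": 100.0, "saturated_fat": satfat}
    if nutrients:
        n.update(nutrients)
    return FoodItem(code=code, description="test", initial_category=category,
                    nutrients_per_100g=n, fped_per_100g={},
                    price_per_100g=price, consumption_weight=weight,
                    breakfast_energy_fraction=0.0)


@pytest.mark.parametrize("satfat,expected", [
    (0.0, "higher"),      # fat-free food is higher density
    (10.0, "lower"),      # far above the cut
    (4.5, "higher"),      # boundary convention: the threshold itself is higher
    (4.4999, "higher"),
    (4.5001, "lower"),
])
def test_nutrient_density_split(satfat, expected):
    items = [_item(satfat=satfat)]
    assert split_by_nutrient_density(items)["10000001"] == expected


def test_density_split_missing_satfat_warns_and_excludes():
    good = _item(code="1", satfat=1.0)
    bad = FoodItem(code="2", description="?", initial_category="x",
                   nutrients_per_100g={"energy": 10.0}, fped_per_100g={},
                   price_per_100g=1.0, consumption_weight=1.0,
                   breakfast_energy_fraction=0.0)
    with pytest.warns(UserWarning):
        out = split_by_nutrient_density([good, bad])
    assert "2" not in out and out["1"] == "higher"


@pytest.mark.parametrize("prices,expected", [
    ([1, 2, 3, 4, 100], [False, False, False, False, True]),  # Q1=2, Q3=4, fence 5
    ([5, 5, 5, 5, 5], [False] * 5),                           # IQR=0: nothing above Q1
    ([1, 2, 3], [False] * 3),                                 # below minimum support
    ([1, 2, None, 3, 4, 100], [False, False, False, False, False, True]),
])
def test_price_outlier_flags(prices, expected):
    assert flag_price_outliers(prices).tolist() == expected


def test_outlier_fence_variant_is_looser():
    prices = [1, 2, 3, 4, 8]
    q1 = flag_price_outliers(prices, fence="q1")
    q3 = flag_price_outliers(prices, fence="q3")
    assert q1.sum() >= q3.sum()  # Q3 + 1.5 IQR can only sit higher


def test_weighted_mean_price_cases():
    assert weighted_mean_price([_item(price=2.0)]) == pytest.approx(0.02)
    two = [_item(code="1", price=1.0), _item(code="2", price=3.0)]
    assert weighted_mean_price(two) * 100 == pytest.approx(2.0)
    # missing price carries zero weight: (1*1 + 2*2) / 3 = 5/3 per 100 g
    three = [_item(code="1", price=1.0, weight=1.0),
             _item(code="2", price=2.0, weight=2.0),
             _item(code="3", price=None, weight=5.0)]
    assert weighted_mean_price(three) * 100 == pytest.approx(5.0 / 3.0)


def test_weighted_mean_price_requires_usable_item():
    with pytest.raises(ValueError, match="usable"):
        weighted_mean_price([_item(price=None)])


@given(st.lists(st.tuples(st.floats(0.1, 50), st.floats(0.1, 10)),
                min_size=1, max_size=20),
       st.floats(0.5, 20))
def test_weighted_mean_invariant_to_weight_rescaling(pw, scale):
    items = [_item(code=str(i), price=p, weight=w) for i, (p, w) in enumerate(pw)]
    scaled = [_item(code=str(i), price=p, weight=w * scale)
              for i, (p, w) in enumerate(pw)]
    assert weighted_mean_price(items) == pytest.approx(
        weighted_mean_price(scaled), rel=1e-9)


@given(st.lists(st.tuples(st.floats(0.1, 50), st.floats(0.1, 10)),
                min_size=4, max_size=30))
def test_outlier_exclusion_never_increases_mean_price(pw):
    items = [_item(code=str(i), price=p, weight=w) for i, (p, w) in enumerate(pw)]
    flags = flag_price_outliers([p for p, _ in pw])
    with_excl = weighted_mean_price(items, flags)
    without = weighted_mean_price(items)
    assert with_excl <= without + 1e-12


def test_price_tier_split():
    labels, cut = split_by_price_tier(list(range(1, 11)))
    assert cut == pytest.approx(4.15)  # linear-interpolation percentile
    assert labels[:4] == ["lower"] * 4 and labels[4:] == ["higher"] * 6

    labels, _ = split_by_price_tier([2.0, 2.0, 2.0])
    assert labels == ["lower"] * 3  # single price value: all at the cut

    labels, cut = split_by_price_tier([None, 5.0])
    assert labels is None and cut is None  # below minimum support


def test_tier_split_preserves_items():
    prices = [1, 5, None, 2, 9, 3]
    labels, _ = split_by_price_tier(prices)
    n_priced = sum(p is not None for p in prices)
    # missing-price items land in "lower" by convention
    assert len(labels) == len(prices)
    assert sum(l == "higher" for l in labels) + \
        sum(l == "lower" and p is not None for l, p in zip(labels, prices)) == n_priced


def test_weighted_profile():
    same = [_item(code="1", nutrients={"iron": 10.0}),
            _item(code="2", nutrients={"iron": 10.0})]
    d, _ = weighted_profile(same)
    assert d["iron"] == pytest.approx(0.10)
    mix = [_item(code="1", weight=1.0, nutrients={"iron": 10.0}),
           _item(code="2", weight=3.0, nutrients={"iron": 20.0})]
    d, _ = weighted_profile(mix)
    assert d["iron"] == pytest.approx(0.175)  # 17.5 per 100 g
    zero = [_item(code="1", nutrients={"zinc": 0.0})]
    d, _ = weighted_profile(zero)
    assert d["zinc"] == 0.0


def test_taxonomy_counts_and_partition():
    scheme = default_scheme()
    items = generate_food_items(2000, scheme, seed=5)
    tax = build_taxonomy(items, scheme)
    assert tax.n_initial == 67
    assert len(tax.modeling) == 99
    assert len(tax.combined) == 46
    # partition invariants
    members = [m for cc in tax.combined.values() for m in cc.members]
    assert sorted(members) == sorted(tax.modeling)
    assert all(tax.modeling[m].combined_id == cid
               for cid, cc in tax.combined.items() for m in cc.members)
    baskets = {cc.basket for cc in tax.combined.values()}
    assert baskets <= {"vegetables", "fruits", "grains", "dairy",
                       "protein foods", "miscellaneous"}
    # pork and beef live in distinct modeling and combined categories
    assert {"pork", "beef"} <= set(tax.combined)
    assert not set(tax.combined["pork"].members) & set(tax.combined["beef"].members)


def test_taxonomy_without_pork_beef_separation():
    scheme = default_scheme(split_pork_beef=False)
    items = generate_food_items(2000, scheme, seed=5)
    tax = build_taxonomy(items, scheme)
    assert tax.n_initial == 65
    assert len(tax.combined) == 45
    assert "meats" in tax.combined and "pork" not in tax.combined


def test_build_taxonomy_rejects_empty_category():
    scheme = default_scheme()
    items = generate_food_items(500, scheme, seed=1)
    victim = items[0].initial_category
    pruned = [it for it in items if it.initial_category != victim]
    with pytest.raises(ValueError, match="no items"):
        build_taxonomy(pruned, scheme)


def test_taxonomy_json_roundtrip(tmp_path, small_system):
    path = tmp_path / "tax.json"
    small_system.taxonomy.to_json(path)
    from thriftyqp import Taxonomy
    back = Taxonomy.from_json(path)
    assert back.modeling_ids == small_system.taxonomy.modeling_ids
    mid = back.modeling_ids[0]
    assert back.modeling[mid].p == small_system.taxonomy.modeling[mid].p
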