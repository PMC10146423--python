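"""Synthetic generator: determinism, distributional targets, anchored
feasibility, and the hand-derived toy fixture."""

import numpy as np
import pytest

from thriftyqp import (GROUPS, PriceSpec, default_scheme, expand_to_modeling,
                       generate_food_items, generate_intake_records,
                       generate_recommendations, generate_system, toy_fixture)
from thriftyqp.categories import flag_price_outliers
from thriftyqp.constraints import compile_constraints
from thriftyqp.intake import build_group_profile
from thriftyqp.synthetic import (default_intake_spec, read_items,
                                 read_records, write_items, write_records)


def test_item_generation_is_deterministic():
    a = generate_food_items(200, seed=1)
    b = generate_food_items(200, seed=1)
    assert [(i.code, i.price_per_100g, i.consumption_weight,
             i.nutrients_per_100g) for i in a] == \
           [(i.code, i.price_per_100g, i.consumption_weight,
             i.nutrients_per_100g) for i in b]
    c = generate_food_items(200, seed=2)
    assert any(x.price_per_100g != y.price_per_100g for x, y in zip(a, c))


def test_every_initial_category_nonempty():
    scheme = default_scheme()
    items = generate_food_items(3000, scheme, seed=4)
    cats = {it.initial_category for it in items}
    assert cats == set(scheme.initial_ids)
    assert len(cats) == 67


def test_no_outliers_when_contamination_zero():
    """With zero contamination and the moderate log-normal spread, no
    category contains a price beyond its own 1.5-IQR-above-Q1 fence
    (brute-force quartile check)."""
    scheme = default_scheme()
    items = generate_food_items(2500, scheme, seed=9,
                                price_spec=PriceSpec(sigma=0.15,
                                                     outlier_fraction=0.0,
                                                     missing_fraction=0.0))
    for cat in scheme.initial_ids:
        prices = sorted(it.price_per_100g for it in items
                        if it.initial_category == cat)
        if len(prices) < 4:
            continue
        q1, q3 = np.percentile(prices, [25, 75])
        assert max(prices) <= q1 + 1.5 * (q3 - q1) + 1e-12, cat


def test_contaminated_prices_do_get_flagged():
    scheme = default_scheme()
    items = generate_food_items(3000, scheme, seed=9,
                                price_spec=PriceSpec(outlier_fraction=0.08))
    flagged = 0
    for cat in scheme.initial_ids:
        prices = [it.price_per_100g for it in items if it.initial_category == cat]
        flagged += flag_price_outliers(prices).sum()
    assert flagged > 50  # the 5-20x contamination is visible to the fence


def test_invalid_generator_parameters_rejected():
    with pytest.raises(ValueError):
        generate_food_items(10, default_scheme(), seed=0)  # fewer than categories
    with pytest.raises(ValueError):
        PriceSpec(outlier_fraction=-0.1)
    with pytest.raises(ValueError):
        PriceSpec(missing_fraction=1.5)


def test_intake_means_converge():
    spec = default_intake_spec()
    records = generate_intake_records(["F20-50"], 2000, seed=7)
    for cat, (mean, _) in spec.items():
        if mean < 20:  # tiny categories: 5% of a few grams is sub-sampling noise
            continue
        sample = np.mean([r.amounts[cat] for r in records])
        assert sample == pytest.approx(mean, rel=0.05), cat


def test_zero_dispersion_reproduces_means_exactly():
    spec = {k: (v, 0.0) for k, (v, _) in default_intake_spec().items()}
    records = generate_intake_records(["F20-50"], 5, seed=1, intake_spec=spec)
    for r in records:
        for cat, (mean, _) in spec.items():
            assert r.amounts[cat] == mean


def test_eight_groups_present_and_youth_coffee_zero():
    records = generate_intake_records(GROUPS, 20, seed=2)
    assert {r.group_id for r in records} == set(GROUPS)
    for r in records:
        if r.group_id in ("F4-13", "M4-13", "F14-19", "M14-19"):
            assert r.amounts["coffee and tea"] == 0.0


def test_empty_group_list_rejected():
    with pytest.raises(ValueError, match="empty"):
        generate_intake_records([], 10, seed=0)


def test_quality_score_correlates_with_dense_intake():
    records = generate_intake_records(["M20-50"], 800, seed=5)
    dense = [name for name, s in default_scheme().combined.items() if s.dense]
    intake = np.array([sum(r.amounts[c] for c in dense) for r in records])
    score = np.array([r.quality_score for r in records])
    assert np.corrcoef(intake, score)[0, 1] > 0.5
    med = np.median(score)
    kept = intake[score > med]
    assert kept.mean() > intake.mean()  # the median filter shifts the mean


def test_recommendations_anchor_is_feasible(small_system):
    for gid, g in small_system.groups.items():
        cset = compile_constraints(g, small_system.taxonomy, g.C_obs)
        x = expand_to_modeling(g.observed_c, small_system.taxonomy)
        assert cset.check(x) == [], gid


def test_recommendations_widened_bounds_stay_feasible(small_system):
    g = small_system.groups["F20-50"]
    g2 = type(g)(g.group_id, g.observed_c, g.observed_sd,
                 {k: v / 2 for k, v in g.D_LB.items()},
                 {k: v * 2 for k, v in g.D_UB.items()},
                 {k: v / 2 for k, v in g.F_LB.items()},
                 {k: v * 2 for k, v in g.F_UB.items()}, g.C_obs)
    cset = compile_constraints(g2, small_system.taxonomy, g.C_obs)
    x = expand_to_modeling(g.observed_c, small_system.taxonomy)
    assert cset.check(x) == []


def test_vitamin_d_refused(small_system):
    g = small_system.groups["F20-50"]
    with pytest.raises(ValueError, match="[Vv]itamin D"):
        generate_recommendations(g, small_system.taxonomy,
                                 small_system.records,
                                 nutrients=("energy", "vitamin_d"))


def test_fixture_observed_diet_feasible_and_above_minimum(fixture_system):
    fx = fixture_system
    for gid, g in fx.groups.items():
        cset = compile_constraints(g, fx.taxonomy, g.C_obs)
        x = expand_to_modeling(g.observed_c, fx.taxonomy)
        assert cset.check(x) == []
        assert g.C_obs == pytest.approx(fx.known["observed_cost"][gid])
        assert fx.known["min_cost_separated"][gid] < g.C_obs


def test_fixture_optimum_rederived_by_grid_search(fixture_system):
    from thriftyqp import grid_minimize
    fx = fixture_system
    for gid, g in fx.groups.items():
        budget = fx.known["lowest_budget_separated"][gid]
        cset = compile_constraints(g, fx.taxonomy, budget)
        res = grid_minimize(fx.taxonomy, g, cset, fx.grid_ranges(gid))
        assert res.x == fx.known["optimum_separated"][gid]
        assert res.min_cost >= fx.known["min_cost_separated"][gid] - 1e-9


def test_item_and_record_io_roundtrip(tmp_path):
    items = generate_food_items(120, seed=3)
    write_items(items, tmp_path / "items.csv", manifest={"seed": 3})
    back = read_items(tmp_path / "items.csv")
    assert len(back) == len(items)
    assert back[5].code == items[5].code
    assert back[5].price_per_100g == pytest.approx(items[5].price_per_100g)
    assert back[5].nutrients_per_100g["energy"] == \
        pytest.approx(items[5].nutrients_per_100g["energy"])

    records = generate_intake_records(["F20-50"], 10, seed=3)
    write_records(records, tmp_path / "rec.csv")
    back = read_records(tmp_path / "rec.csv")
    assert back[3].amounts == pytest.approx(records[3].amounts)
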