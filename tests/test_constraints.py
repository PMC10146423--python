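"""Constraint compilation: bound rules, ratio/cap/beverage/breakfast rows,
cost modes, labels, and the independent checker."""

import numpy as np
import pytest

from thriftyqp import bounds_rules, compile_constraints, expand_to_modeling
from thriftyqp.constraints import (beverage_rows, breakfast_row, cost_row,
                                   non_pattern_caps, nutrient_rows,
                                   pattern_rows, ratio_rows)
from thriftyqp.intake import GroupProfile


def test_bounds_rules_standard_component():
    lb, ub = bounds_rules({"total_fruits": 2.5},
                          {"total_fruits": {25: 1.0, 75: 3.0, 95: 4.0}})
    assert (lb["total_fruits"], ub["total_fruits"]) == (2.5, 4.0)


def test_bounds_rules_ten_percent_headroom():
    lb, ub = bounds_rules({"total_fruits": 2.5},
                          {"total_fruits": {25: 1.0, 75: 1.8, 95: 2.0}})
    assert (lb["total_fruits"], ub["total_fruits"]) == (2.5, pytest.approx(2.75))


def test_bounds_rules_aggregated_and_eggs():
    lb, ub = bounds_rules({"meat_poultry_eggs": 3.0, "eggs": 1.0},
                          {"meat_poultry_eggs": {25: 2.0, 75: 4.0, 95: 5.0},
                           "eggs": {25: 0.2, 75: 0.6, 95: 0.9}})
    assert (lb["meat_poultry_eggs"], ub["meat_poultry_eggs"]) == (2.0, 5.0)
    assert (lb["eggs"], ub["eggs"]) == (0.2, 0.6)  # eggs cap at the 75th pct


def test_bounds_rules_missing_percentiles_rejected():
    with pytest.raises(ValueError, match="percentile"):
        bounds_rules({"total_fruits": 2.0}, {"total_fruits": {25: 1.0}})


def test_nutrient_rows_detect_violations(fixture_system):
    fx = fixture_system
    g = fx.groups["F20-50"]
    rows = nutrient_rows(g, fx.taxonomy)
    labels = {r.label for r in rows}
    assert "eq2:energy" in labels and "eq2:protein" in labels
    from thriftyqp.constraints import LinearConstraintSet
    cset = LinearConstraintSet(var_ids=list(fx.taxonomy.modeling_ids))
    cset.extend(rows)
    x0 = np.zeros(len(fx.taxonomy.modeling_ids))   # empty diet breaks the LB
    assert "eq2:energy" in cset.check(x0)
    anchor = expand_to_modeling(g.observed_c, fx.taxonomy)
    assert cset.check(anchor) == []


def test_nutrient_rows_unknown_nutrient_rejected(fixture_system):
    g = fixture_system.groups["F20-50"]
    bad = GroupProfile(g.group_id, g.observed_c, g.observed_sd,
                       {"selenium": 10.0}, {"selenium": 50.0}, {}, {}, g.C_obs)
    with pytest.raises(ValueError, match="selenium"):
        nutrient_rows(bad, fixture_system.taxonomy)


def test_ratio_rows(fixture_system):
    fx = fixture_system
    rows = ratio_rows(fx.taxonomy)
    labels = [r.label for r in rows]
    assert labels == ["eq4a", "eq4b"]  # no milk density pair in the fixture
    ids = fx.taxonomy.modeling_ids
    # all-whole-fruit diet satisfies 4a with slack
    x = np.array([200.0 if m == "fruit" else 0.0 for m in ids])
    assert rows[0].a @ x > 0
    # the fixture grain is 4/7 whole, so 4b holds for any grain amount
    x = np.array([100.0 if m == "grain" else 0.0 for m in ids])
    assert rows[1].a @ x >= 0


def test_milk_density_ratio_row(small_system):
    rows = ratio_rows(small_system.taxonomy)
    assert [r.label for r in rows] == ["eq4a", "eq4b", "eq4c"]
    row = rows[2]
    tax = small_system.taxonomy
    hnd = [i for i, m in enumerate(tax.modeling_ids)
           if tax.modeling[m].combined_id == "milk and yogurt"
           and tax.modeling[m].nd_tier == "higher"]
    lnd = [i for i, m in enumerate(tax.modeling_ids)
           if tax.modeling[m].combined_id == "milk and yogurt"
           and tax.modeling[m].nd_tier == "lower"]
    x = np.zeros(len(tax.modeling_ids))
    x[hnd[0]] = x[lnd[0]] = 100.0      # equal amounts sit on the boundary
    assert row.a @ x == pytest.approx(0.0)
    x[lnd[0]] = 150.0
    assert row.a @ x < 0


def test_refined_grain_only_diet_violates_whole_grain_rule(small_system):
    tax = small_system.taxonomy
    rows = ratio_rows(tax)
    eq4b = next(r for r in rows if r.label == "eq4b")
    lnd_grain = [i for i, m in enumerate(tax.modeling_ids)
                 if tax.modeling[m].combined_id == "rice and pasta"
                 and tax.modeling[m].nd_tier == "lower"]
    x = np.zeros(len(tax.modeling_ids))
    x[lnd_grain] = 100.0
    assert eq4b.a @ x < 0  # mostly refined grains fail the 50% whole rule


def test_non_pattern_caps(small_system):
    tax = small_system.taxonomy
    g = small_system.groups["F20-50"]
    g2 = GroupProfile(g.group_id, dict(g.observed_c), dict(g.observed_sd),
                      C_obs=g.C_obs)
    g2.observed_c["soda"], g2.observed_sd["soda"] = 100.0, 20.0
    rows = non_pattern_caps(g2, tax)
    by_label = {r.label: r for r in rows}
    assert by_label["eq5:soda"].ub == pytest.approx(140.0)  # c + 2 sd
    g2.observed_sd["soda"] = 0.0
    rows = non_pattern_caps(g2, tax)
    assert {r.label: r for r in rows}["eq5:soda"].ub == pytest.approx(100.0)
    # pattern-flagged categories never get a cap row
    assert not any(r.label == "eq5:breads" for r in rows)
    # coffee/tea is exempt (it has its own dedicated constraint)
    assert not any(r.label == "eq5:coffee and tea" for r in rows)


def test_beverage_rows(small_system):
    tax = small_system.taxonomy
    adult = small_system.groups["F20-50"]
    youth = small_system.groups["M4-13"]
    (row_a,) = beverage_rows(adult, tax)
    (row_y,) = beverage_rows(youth, tax)
    coffee = [i for i, m in enumerate(tax.modeling_ids)
              if tax.modeling[m].combined_id == "coffee and tea"]
    x = np.zeros(len(tax.modeling_ids))
    assert row_a.a @ x < row_a.lb            # adult plan without coffee fails
    x[coffee[0]] = 240.0
    assert row_a.a @ x == pytest.approx(240.0)  # exactly at the floor
    assert row_y.ub == 0.0 and row_y.a @ x > row_y.ub  # youth must have none


def test_breakfast_row_single_category_logic(fixture_system):
    fx = fixture_system
    row = breakfast_row(fx.taxonomy)
    x = np.full(len(fx.taxonomy.modeling_ids), 123.0)
    assert row.a @ x <= 0.0   # all fractions 0: the cap can never bind

    # single category at fraction 0.5: any positive amount violates
    tax = fx.taxonomy
    tax.modeling["grain"].breakfast_fraction = 0.5
    try:
        row = breakfast_row(tax)
        x = np.array([100.0 if m == "grain" else 0.0 for m in tax.modeling_ids])
        assert row.a @ x > 0
        tax.modeling["grain"].breakfast_fraction = 0.23
        row = breakfast_row(tax)
        assert row.a @ x == pytest.approx(0.0)  # boundary-satisfied
    finally:
        tax.modeling["grain"].breakfast_fraction = 0.0


def test_cost_row_modes(fixture_system):
    tax = fixture_system.taxonomy
    r = cost_row(tax, 3.13, "upper_bound")
    assert r.ub == 3.13 and r.lb == -np.inf
    r = cost_row(tax, 2.0, "equality")
    assert r.lb == r.ub == 2.0
    with pytest.raises(ValueError):
        cost_row(tax, -1.0)
    with pytest.raises(ValueError):
        cost_row(tax, 0.0, "equality")


def test_compiled_labels_cover_all_equations(small_system):
    g = small_system.groups["F20-50"]
    cset = compile_constraints(g, small_system.taxonomy, g.C_obs)
    prefixes = {lab.split(":")[0] for lab in cset.labels}
    assert {"eq2", "eq3", "eq4a", "eq4b", "eq4c", "eq5", "eq6",
            "eq7", "eq8"} <= prefixes


def test_checker_agrees_with_lp_feasibility(fixture_system):
    """A diet the independent checker accepts is feasible for the solver and
    vice versa."""
    from thriftyqp.optimize import _phase1
    fx = fixture_system
    g = fx.groups["F20-50"]
    for budget, expect in ((g.C_obs, True), (2.99, False)):
        cset = compile_constraints(g, fx.taxonomy, budget)
        n = len(fx.taxonomy.modeling_ids)
        x = _phase1(cset, np.full(n, np.inf), fx.taxonomy.prices())
        if expect:
            assert x is not None and cset.check(x) == []
        else:
            assert x is None  # below the hand-derived minimum cost
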