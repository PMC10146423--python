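# thriftyqp

Lowest-cost healthy diet plans by quadratic programming, in the style of the
USDA Thrifty Food Plan (TFP) 2021 — the optimization that underlies SNAP
benefit levels — with fresh pork and beef separated so their substitution can
be studied.

The package is aimed at nutrition economists and public-health modelers who
want a tested, reusable version of this pipeline:

1. **Category construction** — item tables (FNDDS/FPED-style nutrients,
   pattern equivalents, national prices per 100 g edible) are organized into
   initial categories, split by nutrient density (saturated fat below/above
   4.5 g/100 g) and, for a designated subset, by price at the 35th
   percentile into lower/higher-cost tiers.  Weighted category prices
   exclude missing prices and outliers (more than 1.5 interquartile ranges
   above the first quartile).  At full scale: 67 initial, 99 modeling, and
   46 combined categories.
2. **Observed consumption** — per-group intake records are filtered to
   respondents with diet-quality scores strictly above the group median,
   averaged, and adjusted +5% for food waste; the observed diet cost is
   C_obs = Σⱼ cⱼ pⱼ.
3. **Constraints** — nutrient adequacy and limits (Dᴸᴮₙ ≤ Σᵢ xᵢ dᵢ,ₙ ≤ Dᵁᴮₙ),
   food-pattern ranges (Fᴸᴮₚ ≤ Σᵢ xᵢ fᵢ,ₚ ≤ Fᵁᴮₚ), whole-fruit/whole-grain
   and milk-density ratios, caps of c + 2·sd on categories outside the
   healthy pattern, a coffee/tea floor for adults (240 g/day, zero for
   youth), a 23% breakfast-energy cap, and the budget row Σᵢ xᵢ pᵢ ≤ C.
4. **Optimization** — minimize Σⱼ βⱼ (xⱼ − cⱼ)² with βⱼ = pⱼcⱼ / Σⱼ pⱼcⱼ,
   the expenditure-weighted deviation from observed intake; the budget is
   tightened in USD 0.01 steps from C_obs until no solution remains.
5. **Scenarios** — M1 pools pork and beef (TFP replica); M2 separates them
   at M1's cost and meat amount; M3 separates and searches for the lowest
   cost; M4 is pork-only (beef and poultry zero); M5 is beef-only.
6. **Reporting** — weekly market baskets in lbs and USD, protein
   sub-baskets, cost shares, and family-of-four totals (the post-hoc sum of
   one male and one female each of 20–50 y and 4–13 y).

Because the real inputs (NHANES 2013–2016, FNDDS/FPED 2015-16, TFP 2021
price files) are not redistributable, a first-class synthetic generator
produces item tables, intake records, and bound sets with the same
structure, anchored so the observed diet is always feasible at its own cost.
A deterministic six-category toy fixture with hand-derivable optima supports
exhaustive grid-search validation of the solver.

## Worked example

```python
import thriftyqp as tq

fx = tq.toy_fixture()                      # 6 categories, 2 adult groups
res = tq.run_all_models(fx.taxonomy, fx.groups)
g = "F20-50"
print(round(fx.groups[g].C_obs, 2))        # 3.13  observed diet cost, USD/day
print(res["M3"][g].budget)                 # 3.01  lowest feasible cent budget
print(round(res["M3"][g].plan.x["pork"]))  # 100   g/day pork in the plan
print(round(res["M3"][g].plan.x["beef"]))  # 0     beef priced out entirely
print(res["M5"][g].budget)                 # 3.41  beef-only costs strictly more
```

The fixture's pork-like and beef-like categories share one nutritional
profile, but pork is half the price: the separated lowest-cost plan (M3)
keeps the pattern floor of 100 g/day of meat entirely as pork and lands on a
3.01 USD/day budget — the same optimum an exhaustive 1-g grid search finds —
while forcing beef-only (M5) raises the budget by 0.40 USD/day.

The same pipeline at full synthetic scale:

```python
system = tq.generate_system(seed=1, n_items=3000, n_per_group=300)
results = tq.run_all_models(system.taxonomy, system.groups)
```

A `thriftyqp` CLI wraps the library (`generate`, `build`, `optimize`,
`report`).

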