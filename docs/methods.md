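# Methods

## Model

The package estimates lowest-cost healthy diet plans per age–gender group.
Amounts are continuous grams per day of 99 modeling categories x_i, each a
food group split by nutrient density (higher/lower, at 4.5 g saturated fat
per 100 g) and, for 32 designated initial categories, by price tier (at the
35th percentile of item prices).  Modeling categories aggregate into 46
combined categories x_j, the unit of the objective

    min Σ_j β_j (x_j − c_j)²,    β_j = p_j c_j / Σ_j p_j c_j,

where c_j is the group's observed (quality-filtered, waste-adjusted) mean
intake and p_j the weighted category price in USD/g.  β weights deviations
by expenditure share, so the plan disturbs budget-relevant habits least;
categories with no observed intake carry zero weight.  Constraints are all
linear: nutrient adequacy/limit rows over 28 nutrients (vitamin D excluded —
its recommendation is unattainable from food alone), food-pattern ranges,
whole-fruit ≥ ½ fruit, whole-grain ≥ ½ grains, higher-density milk/yogurt ≥
lower-density, caps of c_j + 2·sd_j on combined categories outside the
healthy dietary pattern, a coffee/tea floor of 240 g/day for adult groups
(zero for 4–13 and 14–19), a 23% cap on breakfast-occasion energy, and a
budget row.  The lowest cost is found by moving the budget in USD 0.01 steps
from the observed cost C_obs = Σ_j c_j p_j until infeasibility; because
feasibility is monotone in the budget, a bisection over the cent grid
(default) returns the identical cent to the literal scan, which remains
available (`strategy="scan"`).

Two printed-source inconsistencies are resolved in favor of their
surrounding prose: the non-pattern cap is implemented as c + 2·sd (the
printed "c − 2·sd" would usually be negative and contradicts "two standard
deviations **above** the average"; it remains available as
`printed_variant=True`), and the coffee/tea age condition is zero for bands
entirely ≤ 19 y and a floor for 20+ (the printed "= 0 for ages ≥ 19 y"
contradicts its own sentence).  The outlier fence is likewise kept exactly
as printed — Q1 + 1.5·IQR — with the conventional Tukey Q3 fence behind
`fence="q3"`.

## Scenarios

M1 pools fresh pork and beef into one meat category (weight-averaged price
and profiles) and searches for the lowest cost.  M2 separates them, fixes
total pork+beef grams to M1's meat amount and total cost to M1's budget
(equality), and lets the solver choose the split.  M3 separates and
searches.  M4 fixes beef and poultry to zero (pork-only); M5 fixes pork and
poultry to zero (beef-only).  Eggs, seafood, and nuts/seeds/soy are always
free.  Each group is optimized independently; the family of four is the
post-hoc sum of four group plans, never a joint optimization.

## Numerical choices

The QP is convex with linear constraints and is solved with scipy's
`trust-constr` using the analytic gradient and Hessian.  A presolve folds
single-variable rows into the variable box, substitutes out box-fixed
variables, and drops duplicate/empty rows iteratively — without this the
active-set Jacobian is rank-deficient whenever two rows coincide (e.g.
protein foods and meat/poultry/eggs in the toy fixture) and the interior
point stalls.  The audited rows are always the original, unpresolved set.
Feasibility certificates come from a HiGHS phase-1 linear program (with the
minimum-cost objective, so warm starts are deterministic); solver failure is
therefore distinguishable from model infeasibility.  Solutions are audited
row-by-row at 1e-6 relative tolerance with a 1e-9 absolute floor.  A
tie-break regularization ε·Σ x_i² (ε = 1e-9) makes the split of x_j across
member tiers unique when the budget is slack; the reported objective
excludes this term.  The budget search stops with an error above 5 × C_obs.
Amounts reaching a zero bound are zero to interior-point precision
(≲ 1e-4 g); tests treat ≤ 1 mg/day as zero.

## Synthetic data

The generator emulates the *structure* of the real inputs, not their
values: ~3,000 items across 67 initial categories; log-normal within-
category prices (σ = 0.35) whose uncontaminated body is clamped at its own
Q1 + 1.5·IQR fence, with a configurable fraction (3%) multiplied by 5–20×
as deliberate outliers and 5% missing; gamma-distributed intakes
(CV = 0.35) scaled per group; a diet-quality score that is a noisy linear
function of nutrient-dense category intake rescaled to 0–100, so the
above-median filter genuinely shifts the retained-set composition; and
Beta-distributed breakfast-energy fractions biased high for cereals, eggs,
and coffee/tea.  Category-level macronutrients come from a fixed per-
category table chosen once to be grossly realistic (meat ≈ 26 g protein/
100 g, oils ≈ 880 kcal/100 g, beef priced above pork, ...); micronutrient
bases are drawn per category from plausible ranges.

Bound sets are *anchored*: nutrient and pattern bounds are built around the
group's waste-adjusted mean diet (energy ±10%, adequacy nutrients −25%/+40%,
upper-limit nutrients 1.6×, pattern recommendations at 95% of the anchor
with percentile-based upper bounds widened minimally when they would exclude
the anchor).  Two construction guards keep the anchor feasible for every
seed: the higher-density tier of the milk/yogurt and grain pairs is kept at
least 1.5× the lower tier by item weight (otherwise the random weight split
can break the milk-density and whole-grain ratio rows at the anchor), and
the first two items of every category always carry a price so the tier
split and weighted price are defined.  Consequently every generated system
is feasible at the observed diet and cost, which is what the recovery and
feasibility-audit tests exercise.

What the generator does **not** emulate: FNDDS nutrient covariance, NHANES
survey design (strata/PSUs; only a single per-item weight), usual-intake
modeling, seasonal or regional price variation, and the real division of
household income groups in the price data.  Passing tests therefore show
that the pipeline's logic is correct under the stated statistical structure,
not that its outputs match any real population's numbers; the published
family-of-four tables are bundled only as fixed inputs for aggregation
checks of the reporting layer.

## Toy fixture

Six categories (grain, vegetables, fruit, dairy, pork-like, beef-like; the
two meats share one profile but pork costs 0.004 vs 0.008 USD/g), two adult
groups (the second a 1.2× scale of the first).  Equality pattern bounds pin
vegetables, fruit, and dairy, leaving three free variables, so a 1-g grid
search is exhaustive.  The constraint geometry was chosen so the separated
lowest-cost optimum lies on integer grams (grain 240 g, pork 100 g, beef
0 g at a 3.01 USD/day budget for the base group): the grid oracle and the
QP then agree in objective to solver precision rather than to grid
resolution.  Hand-derived minimum costs, cent budgets, and optima for the
pooled, separated, and beef-only variants are recorded in the fixture's
`known` manifest and re-verified by tests.

## Problem sizes

Default study sizes are 3,000 items and 300 records per group (full scale);
the scenario audit runs at 800 items and 250 records per group, and the
recovery/monotonicity property checks at 300 items and 120 records per
group over one group per seed — sizes at which the law-of-large-numbers
tolerances in the tests (5% on means at n = 2,000) and the anchored-
feasibility guarantee comfortably hold while keeping a full five-model,
eight-group run around a minute.

## Known limitations

- The 35th-percentile price split is unweighted over item prices; whether
  the original procedure weights it by consumption is unstated.  Missing-
  price items in a split category default to the lower-cost tier.
- Whether sd_j is computed before or after the quality filter and waste
  adjustment is unstated; it is computed after both.
- M2's meat peg is imposed on total pork+beef grams, not per tier.
- The breakfast-energy cap uses a fixed per-category occasion fraction, not
  a modeled occasion assignment.
- Amounts are "as consumed"; no as-purchased yield conversion, no inflation
  adjustment, and no 15-group age stratification.
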