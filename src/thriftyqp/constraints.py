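"""Solver-agnostic linear constraints for the diet optimization.

Each constraint family maps to one labeled row group:

* nutrient adequacy/limit rows over per-gram nutrient profiles,
* food-pattern rows over FPED-style component profiles,
* structural ratios (whole fruit >= half of fruit, whole grains >= half of
  grains, higher-density milk and yogurt >= lower-density),
* caps on combined categories without a dietary-pattern counterpart
  (observed mean + 2 sd),
* coffee/tea floor for adults and exclusion for youth,
* a cap on the share of energy eaten at breakfast (23%),
* the budget row (inequality for cost search, equality for the pegged model).

An independent row-by-row checker verifies any proposed plan against the
same rows at 1e-6 relative tolerance (1e-9 absolute floor).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .categories import Taxonomy
from .foods import AGGREGATED_COMPONENTS, LIMIT_NUTRIENTS
from .intake import GroupProfile
from .scheme import CAP_EXEMPT

BREAKFAST_ENERGY_SHARE = 0.23
COFFEE_TEA_MIN_G = 240.0
COFFEE_CATEGORY = "coffee and tea"
MILK_CATEGORY = "milk and yogurt"

RTOL = 1e-6
ATOL = 1e-9


@dataclass
class Row:
    label: str                # equation of origin, e.g. "eq2:energy"
    a: np.ndarray             # coefficients over modeling categories
    lb: float
    ub: float

    def __post_init__(self):
        if self.lb > self.ub:
            raise ValueError(f"row {self.label}: lb {self.lb} > ub {self.ub}")


@dataclass
class LinearConstraintSet:
    var_ids: list[str]
    rows: list[Row] = field(default_factory=list)

    def add(self, label: str, a, lb: float, ub: float) -> None:
        a = np.asarray(a, dtype=float)
        if a.shape != (len(self.var_ids),):
            raise ValueError(f"row {label}: coefficient length mismatch")
        self.rows.append(Row(label, a, lb, ub))

    def extend(self, rows: list[Row]) -> None:
        for r in rows:
            self.add(r.label, r.a, r.lb, r.ub)

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.rows]

    def matrix(self) -> np.ndarray:
        return np.vstack([r.a for r in self.rows])

    def lbs(self) -> np.ndarray:
        return np.array([r.lb for r in self.rows])

    def ubs(self) -> np.ndarray:
        return np.array([r.ub for r in self.rows])

    def check(self, x, rtol: float = RTOL, atol: float = ATOL) -> list[str]:
        """Independent feasibility audit; returns violated row labels."""
        x = np.asarray(x, dtype=float)
        bad = []
        if (x < -max(atol, rtol)).any():
            bad.append("nonneg")
        for r in self.rows:
            v = float(r.a @ x)
            tol = max(atol, rtol * max(abs(v), abs(r.lb), abs(r.ub), 1.0))
            if v < r.lb - tol or v > r.ub + tol:
                bad.append(r.label)
        return bad

    def to_json(self, path) -> None:
        payload = {"var_ids": self.var_ids,
                   "rows": [{"label": r.label, "a": r.a.tolist(),
                             "lb": r.lb, "ub": r.ub} for r in self.rows]}
        with open(path, "w") as fh:
            json.dump(payload, fh)


# ---------------------------------------------------------------------------
# row builders
# ---------------------------------------------------------------------------

def _profile_row(taxonomy: Taxonomy, key: str, which: str) -> np.ndarray:
    return taxonomy.profile_matrix([key], which=which)[0]


def nutrient_rows(group: GroupProfile, taxonomy: Taxonomy) -> list[Row]:
    """Two-sided adequacy rows D_LB <= sum x_i d_i,n <= D_UB per nutrient."""
    rows = []
    present = {k for mc in taxonomy.modeling.values() for k in mc.d}
    for nutrient in group.D_LB:
        if nutrient not in present:
            raise ValueError(f"nutrient {nutrient!r} bounded but absent from "
                             "all modeling-category profiles")
        rows.append(Row(f"eq2:{nutrient}", _profile_row(taxonomy, nutrient, "d"),
                        group.D_LB[nutrient],
                        group.D_UB.get(nutrient, np.inf)))
    return rows


def pattern_rows(group: GroupProfile, taxonomy: Taxonomy) -> list[Row]:
    """Food-pattern rows F_LB <= sum x_i f_i,p <= F_UB per component."""
    rows = []
    present = {k for mc in taxonomy.modeling.values() for k in mc.f}
    for comp in group.F_LB:
        if comp not in present:
            raise ValueError(f"pattern component {comp!r} bounded but absent "
                             "from all modeling-category profiles")
        rows.append(Row(f"eq3:{comp}", _profile_row(taxonomy, comp, "f"),
                        group.F_LB[comp], group.F_UB.get(comp, np.inf)))
    return rows


def bounds_rules(recommended: dict[str, float],
                 percentiles: dict[str, dict[int, float]],
                 headroom: float = 1.10) -> tuple[dict, dict]:
    """Compose pattern bounds from recommendations and intake percentiles.

    Standard components: lower bound = recommended amount; upper bound = the
    95th percentile of reported intake, or the recommendation increased by
    10% when that percentile falls below the recommendation.  Aggregated
    groups (meat/poultry/eggs and nuts/seeds/soy) take the 25th and 95th
    percentiles; eggs take the 25th and 75th.
    """
    F_LB, F_UB = {}, {}
    for comp, rec in recommended.items():
        pct = percentiles.get(comp)
        if pct is None:
            raise ValueError(f"missing intake percentiles for component {comp!r}")
        if comp in AGGREGATED_COMPONENTS:
            hi = 75 if comp == "eggs" else 95
            if 25 not in pct or hi not in pct:
                raise ValueError(f"missing percentile for {comp!r}")
            F_LB[comp], F_UB[comp] = pct[25], pct[hi]
        else:
            if 95 not in pct:
                raise ValueError(f"missing 95th percentile for {comp!r}")
            F_LB[comp] = rec
            F_UB[comp] = pct[95] if pct[95] >= rec else rec * headroom
    return F_LB, F_UB


def ratio_rows(taxonomy: Taxonomy) -> list[Row]:
    """Whole-fruit, whole-grain, and milk/yogurt density ratio rows."""
    rows = []
    present = {k for mc in taxonomy.modeling.values() for k in mc.f}
    for label, num, den in (("eq4a", "whole_fruits", "total_fruits"),
                            ("eq4b", "whole_grains", "total_grains")):
        if num not in present or den not in present:
            raise ValueError(f"{label}: component {num!r}/{den!r} missing from profiles")
        a = _profile_row(taxonomy, num, "f") - 0.5 * _profile_row(taxonomy, den, "f")
        rows.append(Row(label, a, 0.0, np.inf))
    hnd = [i for i, mid in enumerate(taxonomy.modeling_ids)
           if taxonomy.modeling[mid].combined_id == MILK_CATEGORY
           and taxonomy.modeling[mid].nd_tier == "higher"]
    lnd = [i for i, mid in enumerate(taxonomy.modeling_ids)
           if taxonomy.modeling[mid].combined_id == MILK_CATEGORY
           and taxonomy.modeling[mid].nd_tier == "lower"]
    if hnd and lnd:  # only when the milk/yogurt density pair exists
        a = np.zeros(len(taxonomy.modeling_ids))
        a[hnd] = 1.0
        a[lnd] = -1.0
        rows.append(Row("eq4c", a, 0.0, np.inf))
    return rows


def non_pattern_caps(group: GroupProfile, taxonomy: Taxonomy,
                     printed_variant: bool = False) -> list[Row]:
    """0 <= x_j <= c_j + 2 sd_j for combined categories without a pattern
    counterpart.  ``printed_variant=True`` reproduces the c_j - 2 sd_j form
    as printed in the source formula (usually empty or infeasible; kept for
    sensitivity checks only)."""
    rows = []
    ids = taxonomy.modeling_ids
    for cid, cc in taxonomy.combined.items():
        if cc.pattern_flag or cid in CAP_EXEMPT:
            continue
        c = group.observed_c.get(cid, 0.0)
        sd = group.observed_sd.get(cid, 0.0)
        cap = c - 2.0 * sd if printed_variant else c + 2.0 * sd
        a = np.array([1.0 if taxonomy.modeling[m].combined_id == cid else 0.0
                      for m in ids])
        rows.append(Row(f"eq5:{cid}", a, 0.0, max(cap, 0.0) if printed_variant else cap))
    return rows


def beverage_rows(group: GroupProfile, taxonomy: Taxonomy) -> list[Row]:
    """Coffee/tea floor (240 g/day) for adult groups; exclusion for youth."""
    if COFFEE_CATEGORY not in taxonomy.combined:
        return []
    a = np.array([1.0 if taxonomy.modeling[m].combined_id == COFFEE_CATEGORY else 0.0
                  for m in taxonomy.modeling_ids])
    if group.is_adult:
        return [Row("eq6", a, COFFEE_TEA_MIN_G, np.inf)]
    return [Row("eq6", a, 0.0, 0.0)]


def breakfast_row(taxonomy: Taxonomy,
                  share: float = BREAKFAST_ENERGY_SHARE) -> Row:
    """sum x_i * breakfast_fraction_i * energy_i <= share * sum x_i * energy_i."""
    e = _profile_row(taxonomy, "energy", "d")
    b = np.array([taxonomy.modeling[m].breakfast_fraction
                  for m in taxonomy.modeling_ids])
    return Row("eq7", b * e - share * e, -np.inf, 0.0)


def cost_row(taxonomy: Taxonomy, budget: float, mode: str = "upper_bound") -> Row:
    """Budget row: sum x_i p_i <= budget, or == budget for the pegged model."""
    if budget < 0:
        raise ValueError("negative budget")
    p = taxonomy.prices()
    if mode == "upper_bound":
        return Row("eq8", p, -np.inf, budget)
    if mode == "equality":
        if budget <= 0:
            raise ValueError("equality budget must be positive")
        return Row("eq8", p, budget, budget)
    raise ValueError(f"unknown cost mode {mode!r}")


def compile_constraints(group: GroupProfile, taxonomy: Taxonomy,
                        budget: float, cost_mode: str = "upper_bound",
                        printed_cap_variant: bool = False) -> LinearConstraintSet:
    """Assemble the full labeled constraint set for one group and budget."""
    cset = LinearConstraintSet(var_ids=list(taxonomy.modeling_ids))
    cset.extend(nutrient_rows(group, taxonomy))
    cset.extend(pattern_rows(group, taxonomy))
    cset.extend(ratio_rows(taxonomy))
    cset.extend(non_pattern_caps(group, taxonomy, printed_variant=printed_cap_variant))
    cset.extend(beverage_rows(group, taxonomy))
    cset.add("eq7", *(lambda r: (r.a, r.lb, r.ub))(breakfast_row(taxonomy)))
    r = cost_row(taxonomy, budget, cost_mode)
    cset.add(r.label, r.a, r.lb, r.ub)
    return cset
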