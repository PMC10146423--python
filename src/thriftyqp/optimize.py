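"""Quadratic-programming core and the five meat-scenario models.

The objective is the expenditure-weighted squared deviation from the observed
diet,

    min sum_j beta_j (x_j - c_j)^2,   beta_j = p_j c_j / sum_j p_j c_j,

where x_j sums the modeling-category amounts of combined category j.  The
cost constraint is tightened in USD 0.01 steps from the observed diet cost
(or relaxed upward when the observed cost itself is infeasible) until no
solution remains; the plan at the last feasible budget is the lowest-cost
healthy plan.  A monotone bisection over the cent grid gives the identical
budget to the literal scan and is the default.

Scenario models: M1 pools fresh pork and beef into a single meat category and
searches for the lowest cost; M2 separates them, pegs total meat and total
cost to the M1 solution; M3 separates and searches; M4 forces beef and
poultry to zero (pork-only); M5 forces pork and poultry to zero (beef-only).

Solved with scipy's trust-region interior-point method with analytic
gradient/Hessian; feasibility certificates come from a HiGHS phase-1 linear
program, and every optimal plan is audited by the independent row checker.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, linprog, minimize

from .categories import Taxonomy
from .constraints import LinearConstraintSet, compile_constraints
from .intake import GroupProfile, expand_to_modeling

DECREMENT = 0.01
TIE_BREAK_REG = 1e-9     # epsilon * ||x||^2 for a unique modeling-level split
SEARCH_CEILING = 5.0     # give up above this multiple of the observed cost

MEAT_IDS = ("pork", "beef")
POOLED_ID = "meats"
POULTRY_ID = "poultry"


class SolverError(RuntimeError):
    """Numerical failure, as opposed to model infeasibility."""


@dataclass
class ScenarioSpec:
    """One of the five models, resolved against a taxonomy."""

    model_id: str
    meat_handling: str                  # "pooled" | "separated"
    zero_fixed: tuple[str, ...] = ()    # combined categories forced to zero
    cost_mode: str = "search"           # "search" | "fixed"
    fixed_budget: float | None = None
    linked_total: tuple[tuple[str, ...], float] | None = None
    decrement: float = DECREMENT

    def __post_init__(self):
        if self.decrement <= 0:
            raise ValueError("decrement must be positive")
        if self.model_id == "M1" and self.meat_handling != "pooled":
            raise ValueError("M1 pools pork and beef")
        if self.model_id in ("M2", "M3", "M4", "M5") and self.meat_handling != "separated":
            raise ValueError(f"{self.model_id} separates pork and beef")


@dataclass
class FoodPlan:
    """An optimization solution (amounts in g/day, cost in USD/day)."""

    x: dict[str, float]
    x_combined: dict[str, float]
    cost: float
    objective: float
    status: str                       # "optimal" | "infeasible"
    budget: float | None = None
    group_id: str | None = None

    def __post_init__(self):
        if self.status == "optimal" and any(v < -1e-6 for v in self.x.values()):
            raise ValueError("negative amounts in an optimal plan")


@dataclass
class ScenarioResult:
    plan: FoodPlan
    budget: float
    extras: dict = field(default_factory=dict)


def objective_weights(p: np.ndarray, c: np.ndarray) -> np.ndarray:
    """beta_j proportional to p_j c_j, normalized to sum to one."""
    pc = np.asarray(p, float) * np.asarray(c, float)
    if (pc < 0).any():
        raise ValueError("negative expenditure share")
    total = pc.sum()
    if total <= 0:
        raise ValueError("all expenditure shares are zero")
    return pc / total


def _objective_data(taxonomy: Taxonomy, group: GroupProfile):
    cids = taxonomy.combined_ids
    c = np.array([group.observed_c.get(j, 0.0) for j in cids])
    p = np.array([taxonomy.combined[j].p for j in cids])
    beta = objective_weights(p, c)
    A = taxonomy.aggregation_matrix()
    return A, beta, c


def _var_upper_bounds(taxonomy: Taxonomy, zero_fixed) -> np.ndarray:
    ub = np.full(len(taxonomy.modeling_ids), np.inf)
    zero_members = {m for cid in zero_fixed if cid in taxonomy.combined
                    for m in taxonomy.combined[cid].members}
    for i, mid in enumerate(taxonomy.modeling_ids):
        if mid in zero_members:
            ub[i] = 0.0
    return ub


def _with_linked_row(cset: LinearConstraintSet, taxonomy: Taxonomy,
                     linked) -> LinearConstraintSet:
    if linked is None:
        return cset
    ids, amount = linked
    out = LinearConstraintSet(var_ids=list(cset.var_ids))
    out.extend(cset.rows)
    a = np.array([1.0 if taxonomy.modeling[m].combined_id in ids else 0.0
                  for m in cset.var_ids])
    out.add("linked", a, amount, amount)
    return out


def _phase1(cset: LinearConstraintSet, ub: np.ndarray, prices: np.ndarray):
    """HiGHS feasibility solve (minimum-cost LP); returns x or None."""
    A_ub, b_ub, A_eq, b_eq = [], [], [], []
    for r in cset.rows:
        if r.lb == r.ub:
            A_eq.append(r.a)
            b_eq.append(r.lb)
            continue
        if np.isfinite(r.ub):
            A_ub.append(r.a)
            b_ub.append(r.ub)
        if np.isfinite(r.lb):
            A_ub.append(-r.a)
            b_ub.append(-r.lb)
    res = linprog(prices,
                  A_ub=np.array(A_ub) if A_ub else None,
                  b_ub=np.array(b_ub) if b_ub else None,
                  A_eq=np.array(A_eq) if A_eq else None,
                  b_eq=np.array(b_eq) if b_eq else None,
                  bounds=list(zip(np.zeros_like(ub), [None if not np.isfinite(u)
                                                      else u for u in ub])),
                  method="highs")
    if res.status == 2:
        return None
    if res.status != 0:
        raise SolverError(f"phase-1 LP failed with status {res.status}: {res.message}")
    return res.x


def _presolve(cset: LinearConstraintSet, lb: np.ndarray, ub: np.ndarray):
    """Iteratively fold single-variable rows into the box, substitute out
    box-fixed variables, and drop duplicate/empty rows.

    Returns (M, row_lb, row_ub, lb, ub, fixed_value) where M spans only the
    still-free variables.  Purely a conditioning step (the original rows
    remain the audit reference); feasibility was already certified, so
    consistent eliminations are safe.
    """
    lb, ub = lb.copy(), ub.copy()
    n = lb.size
    M = np.array([r.a for r in cset.rows], dtype=float)
    rlb = np.array([r.lb for r in cset.rows], dtype=float)
    rub = np.array([r.ub for r in cset.rows], dtype=float)
    xfix = np.full(n, np.nan)

    for _ in range(20):
        changed = False
        keep = []
        for k in range(M.shape[0]):
            nz = np.flatnonzero(M[k])
            if nz.size == 0:
                changed = True
                continue
            if nz.size == 1:
                i, a = nz[0], M[k, nz[0]]
                lo, hi = (rlb[k] / a, rub[k] / a) if a > 0 else (rub[k] / a, rlb[k] / a)
                lb[i] = max(lb[i], lo)
                ub[i] = min(ub[i], hi)
                changed = True
                continue
            keep.append(k)
        M, rlb, rub = M[keep], rlb[keep], rub[keep]
        newly = np.isnan(xfix) & (ub - lb <= 1e-12)
        if newly.any():
            xfix[newly] = lb[newly]
            if M.shape[0]:
                shift = M[:, newly] @ lb[newly]
                rlb, rub = rlb - shift, rub - shift
                M[:, newly] = 0.0
            changed = True
        if not changed:
            break

    seen, keep = set(), []
    for k in range(M.shape[0]):
        key = (M[k].tobytes(), round(rlb[k], 12), round(rub[k], 12))
        if key not in seen:
            seen.add(key)
            keep.append(k)
    return M[keep], rlb[keep], rub[keep], lb, ub, xfix


def solve_plan(taxonomy: Taxonomy, group: GroupProfile,
               cset: LinearConstraintSet,
               zero_fixed=(), linked=None,
               x0: np.ndarray | None = None,
               reg: float = TIE_BREAK_REG,
               budget: float | None = None) -> FoodPlan:
    """Minimize the weighted squared deviation subject to the compiled rows.

    Returns an infeasible plan when the constraint set admits no diet; raises
    :class:`SolverError` on numerical failure.  Every optimal plan passes the
    independent row checker.
    """
    cset = _with_linked_row(cset, taxonomy, linked)
    ub = _var_upper_bounds(taxonomy, zero_fixed)
    prices = taxonomy.prices()
    feas = _phase1(cset, ub, prices)
    if feas is None:
        return FoodPlan({}, {}, 0.0, np.inf, "infeasible", budget, group.group_id)

    A, beta, c = _objective_data(taxonomy, group)
    n = A.shape[1]
    H = 2.0 * (A.T @ (beta[:, None] * A) + reg * np.eye(n))
    lin = -2.0 * (A.T @ (beta * c))
    M, rlb, rub, blo, bhi, xfix = _presolve(cset, np.zeros(n), ub)
    bhi = np.maximum(bhi, blo)  # absorb 1e-12 fold noise; phase-1 certified
    fixed = ~np.isnan(xfix)
    free = ~fixed
    xf = np.where(fixed, xfix, 0.0)

    if free.any():
        Mf = M[:, free] if M.size else M
        Hff = H[np.ix_(free, free)]
        linf = lin[free] + H[np.ix_(free, fixed)] @ xf[fixed]

        def fun(z):
            return float(0.5 * z @ (Hff @ z) + linf @ z)

        def jac(z):
            return Hff @ z + linf

        z0 = (x0 if x0 is not None else feas)[free]
        z0 = np.clip(z0, blo[free], bhi[free])
        constraints = [LinearConstraint(Mf, rlb, rub)] if M.size else []
        res = minimize(fun, z0, jac=jac, hess=lambda z: Hff,
                       method="trust-constr", constraints=constraints,
                       bounds=Bounds(blo[free], bhi[free]),
                       options={"gtol": 1e-10, "xtol": 1e-14, "maxiter": 5000})
        if res.status not in (1, 2):
            raise SolverError(f"QP did not converge: {res.message}")
        x = xf.copy()
        x[free] = res.x
    else:
        x = xf.copy()  # the presolve pinned the entire diet
    x = np.clip(x, 0.0, None)
    violations = cset.check(x)
    if violations:
        raise SolverError(f"solution violates rows {violations}")
    xc = A @ x
    r = xc - c
    plan = FoodPlan(
        x=dict(zip(taxonomy.modeling_ids, map(float, x))),
        x_combined=dict(zip(taxonomy.combined_ids, map(float, xc))),
        cost=float(prices @ x),
        objective=float(r @ (beta * r)),   # reported without the tie-break term
        status="optimal", budget=budget, group_id=group.group_id)
    return plan


def _feasible_at(taxonomy: Taxonomy, group: GroupProfile, budget: float,
                 cost_mode: str, zero_fixed, linked) -> bool:
    cset = compile_constraints(group, taxonomy, budget, cost_mode)
    cset = _with_linked_row(cset, taxonomy, linked)
    return _phase1(cset, _var_upper_bounds(taxonomy, zero_fixed),
                   taxonomy.prices()) is not None


def minimize_cost(taxonomy: Taxonomy, group: GroupProfile,
                  scenario: ScenarioSpec,
                  strategy: str = "bisection") -> tuple[FoodPlan, float]:
    """Cent-grid lowest-budget search from the observed diet cost.

    Decrements the budget by one cent while feasible; if the observed cost is
    itself infeasible, increments instead.  ``strategy="scan"`` walks the
    grid literally; ``"bisection"`` exploits that feasibility is monotone in
    the budget and returns the identical cent.  The plan at the final budget
    is solved as a full QP.
    """
    if scenario.cost_mode != "search":
        raise ValueError("minimize_cost requires a cost-searching scenario")
    d = scenario.decrement
    base = group.C_obs
    zf, ln = scenario.zero_fixed, scenario.linked_total

    def ok(k: int, direction: int) -> bool:
        return _feasible_at(taxonomy, group, base + direction * k * d,
                            "upper_bound", zf, ln)

    if ok(0, -1):
        kmax = int(np.floor(base / d))
        if strategy == "scan":
            k = 0
            while k + 1 <= kmax and ok(k + 1, -1):
                k += 1
        else:
            lo, hi = 0, kmax  # ok(lo), maybe-ok(hi)
            if ok(kmax, -1):
                lo = kmax
            while hi - lo > 1:
                mid = (lo + hi) // 2
                if ok(mid, -1):
                    lo = mid
                else:
                    hi = mid
            k = lo
        budget = base - k * d
    else:
        kmax = int(np.ceil((SEARCH_CEILING - 1.0) * base / d))
        if strategy == "scan":
            k = 1
            while k <= kmax and not ok(k, +1):
                k += 1
            if k > kmax:
                raise SolverError(f"no feasible budget up to {SEARCH_CEILING} "
                                  "times the observed cost")
        else:
            if not ok(kmax, +1):
                raise SolverError(f"no feasible budget up to {SEARCH_CEILING} "
                                  "times the observed cost")
            lo, hi = 0, kmax  # infeasible(lo), feasible(hi)
            while hi - lo > 1:
                mid = (lo + hi) // 2
                if ok(mid, +1):
                    hi = mid
                else:
                    lo = mid
            k = hi
        budget = base + k * d

    cset = compile_constraints(group, taxonomy, budget, "upper_bound")
    plan = solve_plan(taxonomy, group, cset, zero_fixed=zf, linked=ln,
                      x0=expand_to_modeling(group.observed_c, taxonomy),
                      budget=budget)
    if plan.status != "optimal":
        raise SolverError("budget declared feasible but QP found no solution")
    return plan, budget


# ---------------------------------------------------------------------------
# scenario orchestration
# ---------------------------------------------------------------------------

def make_scenario(model_id: str) -> ScenarioSpec:
    table = {
        "M1": ScenarioSpec("M1", "pooled"),
        "M2": ScenarioSpec("M2", "separated", cost_mode="fixed"),
        "M3": ScenarioSpec("M3", "separated"),
        "M4": ScenarioSpec("M4", "separated", zero_fixed=("beef", POULTRY_ID)),
        "M5": ScenarioSpec("M5", "separated", zero_fixed=("pork", POULTRY_ID)),
    }
    if model_id not in table:
        raise ValueError(f"unknown model {model_id!r}")
    return table[model_id]


def run_scenario(model_id: str, taxonomy: Taxonomy,
                 groups: dict[str, GroupProfile],
                 prior: dict[str, ScenarioResult] | None = None,
                 strategy: str = "bisection") -> dict[str, ScenarioResult]:
    """Run one model for every group.

    M1 needs both meat categories present to pool; M2 needs the completed M1
    results (its pegged cost and meat amount).  Eggs, seafood, and
    nuts/seeds/soy are always left to the optimizer.
    """
    spec = make_scenario(model_id)
    if spec.meat_handling == "pooled" and all(m in taxonomy.combined for m in MEAT_IDS):
        tax = taxonomy.pool_combined(list(MEAT_IDS), POOLED_ID)
        transform = lambda g: g.pool(list(MEAT_IDS), POOLED_ID)
    else:
        tax = taxonomy
        transform = lambda g: g
    zero = tuple(z for z in spec.zero_fixed if z in tax.combined)
    spec = ScenarioSpec(spec.model_id, spec.meat_handling, zero,
                        spec.cost_mode, spec.fixed_budget, spec.linked_total,
                        spec.decrement)

    results: dict[str, ScenarioResult] = {}
    for gid, group in groups.items():
        g = transform(group)
        if model_id == "M2":
            if prior is None or gid not in prior:
                raise ValueError("M2 requires the completed M1 results")
            meat_amount = prior[gid].plan.x_combined.get(
                POOLED_ID, sum(prior[gid].plan.x_combined.get(m, 0.0)
                               for m in MEAT_IDS))
            budget = prior[gid].budget
            linked = (tuple(m for m in MEAT_IDS if m in tax.combined), meat_amount)
            cset = compile_constraints(g, tax, budget, "equality")
            plan = solve_plan(tax, g, cset, zero_fixed=zero, linked=linked,
                              budget=budget)
            if plan.status != "optimal":
                raise SolverError(f"M2 infeasible for group {gid} at the "
                                  f"pegged cost {budget:.2f}")
            results[gid] = ScenarioResult(plan, budget,
                                          {"meat_amount": meat_amount})
        else:
            plan, budget = minimize_cost(tax, g, spec, strategy=strategy)
            results[gid] = ScenarioResult(plan, budget)
    return results


def run_all_models(taxonomy: Taxonomy, groups: dict[str, GroupProfile],
                   models=("M1", "M2", "M3", "M4", "M5"),
                   strategy: str = "bisection") -> dict[str, dict[str, ScenarioResult]]:
    """Run the requested models in order, feeding M1's results into M2."""
    out: dict[str, dict[str, ScenarioResult]] = {}
    if "M2" in models and "M1" not in models:
        raise ValueError("M2 requires M1 in the model list")
    for mid in models:
        prior = out.get("M1") if mid == "M2" else None
        out[mid] = run_scenario(mid, taxonomy, groups, prior=prior,
                                strategy=strategy)
    return out
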