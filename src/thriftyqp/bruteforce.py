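"""Exhaustive grid-search validation of the quadratic program.

Independent of the QP path by construction: candidate diets are enumerated on
a regular grid (1 g resolution by default), each candidate is tested against
every constraint row directly, and the weighted squared deviation is
evaluated from its definition.  Practical only for systems with few free
variables (the toy fixture); used as the oracle in tests and in the
acceptance checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .categories import Taxonomy
from .constraints import LinearConstraintSet
from .intake import GroupProfile


@dataclass
class GridResult:
    x: dict[str, float]          # best feasible grid point
    objective: float
    min_cost: float              # cheapest feasible grid diet
    n_feasible: int


def grid_minimize(taxonomy: Taxonomy, group: GroupProfile,
                  cset: LinearConstraintSet,
                  ranges: dict[str, tuple[float, float]],
                  step: float = 1.0) -> GridResult:
    """Enumerate diets on a grid and return the best feasible one.

    ``ranges`` gives an inclusive box per modeling category; a degenerate box
    pins the variable.  Rows are checked with a tolerance of 1e-9 so exact
    boundary points count as feasible.
    """
    var_ids = taxonomy.modeling_ids
    axes = []
    for mid in var_ids:
        lo, hi = ranges[mid]
        axes.append(np.arange(lo, hi + step / 2, step) if hi > lo
                    else np.array([lo]))
    grids = np.meshgrid(*axes, indexing="ij", sparse=True)

    feasible = np.ones(np.broadcast_shapes(*(g.shape for g in grids)), dtype=bool)
    for row in cset.rows:
        v = sum(a * g for a, g in zip(row.a, grids) if a != 0.0)
        if np.isscalar(v) or np.ndim(v) == 0:
            v = np.full(feasible.shape, float(v))
        feasible &= (v >= row.lb - 1e-9) & (v <= row.ub + 1e-9)
    n_feasible = int(feasible.sum())
    if n_feasible == 0:
        return GridResult({}, np.inf, np.inf, 0)

    # weighted squared deviation, from its definition
    cids = taxonomy.combined_ids
    c = np.array([group.observed_c.get(j, 0.0) for j in cids])
    p = np.array([taxonomy.combined[j].p for j in cids])
    beta = p * c / float(p @ c)
    obj = np.zeros(feasible.shape)
    for j, cid in enumerate(cids):
        xj = sum(g for mid, g in zip(var_ids, grids)
                 if taxonomy.modeling[mid].combined_id == cid)
        obj = obj + beta[j] * (xj - c[j]) ** 2

    cost = sum(taxonomy.modeling[mid].p * g for mid, g in zip(var_ids, grids))
    cost = np.broadcast_to(cost, feasible.shape)

    obj_masked = np.where(feasible, obj, np.inf)
    best = np.unravel_index(int(np.argmin(obj_masked)), obj_masked.shape)
    best_x = {mid: float(ax[idx]) for mid, ax, idx in zip(var_ids, axes, best)}
    return GridResult(
        x=best_x,
        objective=float(obj_masked[best]),
        min_cost=float(cost[feasible].min()),
        n_feasible=n_feasible)


def grid_lowest_budget(taxonomy: Taxonomy, group: GroupProfile,
                       cset_without_cost, ranges, base_cost: float,
                       decrement: float = 0.01, step: float = 1.0) -> float:
    """Cent-grid budget reachable from ``base_cost`` according to the grid.

    Mirrors the decrement/increment search: the smallest budget of the form
    base_cost - k*decrement (k may be negative) that still admits a feasible
    grid diet, judged by the exhaustive minimum cost.
    """
    res = grid_minimize(taxonomy, group, cset_without_cost, ranges, step=step)
    if not np.isfinite(res.min_cost):
        raise ValueError("no feasible grid diet at any budget")
    if res.min_cost <= base_cost:
        k = int(np.floor((base_cost - res.min_cost) / decrement + 1e-9))
        return base_cost - k * decrement
    k = int(np.ceil((res.min_cost - base_cost) / decrement - 1e-9))
    return base_cost + k * decrement
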