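"""Per-group observed consumption patterns.

Pipeline: keep only respondents whose diet-quality score lies strictly above
the group's unweighted median, average intakes per combined category, apply
the +5% food-waste adjustment, and price the observed diet (C_obs = sum of
c_j * p_j).  The result per group is a :class:`GroupProfile` carrying the
observed pattern and the nutrient/pattern bounds used by the optimizer.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .categories import Taxonomy
from .foods import IntakeRecord
from .scheme import is_adult as _is_adult

WASTE_FACTOR = 1.05


@dataclass
class GroupProfile:
    """One age-gender group's observed diet and constraint bounds."""

    group_id: str
    observed_c: dict[str, float]        # combined category -> g/day (waste-adjusted)
    observed_sd: dict[str, float]
    D_LB: dict[str, float] = field(default_factory=dict)
    D_UB: dict[str, float] = field(default_factory=dict)
    F_LB: dict[str, float] = field(default_factory=dict)
    F_UB: dict[str, float] = field(default_factory=dict)
    C_obs: float = 0.0

    def __post_init__(self):
        for n in self.D_LB:
            if n in self.D_UB and self.D_LB[n] > self.D_UB[n]:
                raise ValueError(f"{self.group_id}: D_LB > D_UB for {n}")
        for p in self.F_LB:
            if p in self.F_UB and self.F_LB[p] > self.F_UB[p]:
                raise ValueError(f"{self.group_id}: F_LB > F_UB for {p}")
        if any(v < 0 for v in self.observed_c.values()):
            raise ValueError(f"{self.group_id}: negative observed intake")
        if any(v < 0 for v in self.observed_sd.values()):
            raise ValueError(f"{self.group_id}: negative observed sd")

    @property
    def is_adult(self) -> bool:
        return _is_adult(self.group_id)

    def pool(self, ids: list[str], new_id: str) -> "GroupProfile":
        """Merge observed categories (for the pooled-meat scenario); the sd of
        the pooled category treats the members as independent."""
        c = {k: v for k, v in self.observed_c.items() if k not in ids}
        sd = {k: v for k, v in self.observed_sd.items() if k not in ids}
        c[new_id] = sum(self.observed_c.get(i, 0.0) for i in ids)
        sd[new_id] = float(np.sqrt(sum(self.observed_sd.get(i, 0.0) ** 2 for i in ids)))
        return GroupProfile(self.group_id, c, sd, dict(self.D_LB), dict(self.D_UB),
                            dict(self.F_LB), dict(self.F_UB), self.C_obs)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroupProfile":
        with open(path) as fh:
            return cls(**json.load(fh))


def median_quality_filter(records: list[IntakeRecord]) -> list[IntakeRecord]:
    """Retain records strictly above the unweighted median quality score."""
    if len(records) < 2:
        raise ValueError("quality filter needs at least two records per group")
    med = float(np.median([r.quality_score for r in records]))
    kept = [r for r in records if r.quality_score > med]
    if not kept:
        warnings.warn("no record strictly above the median quality score; "
                      "all retained sets are empty for this group")
    return kept


def mean_intake(records: list[IntakeRecord],
                categories: list[str]) -> tuple[dict[str, float], dict[str, float]]:
    """Unweighted mean and sample sd (n-1) of intake per combined category.

    Categories never consumed get mean 0 and sd 0; a single record yields its
    own amounts with sd 0.
    """
    if not records:
        raise ValueError("mean intake of an empty record set")
    c, sd = {}, {}
    for cat in categories:
        vals = np.array([r.amounts.get(cat, 0.0) for r in records])
        c[cat] = float(vals.mean())
        sd[cat] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return c, sd


def apply_waste_adjustment(values: dict[str, float] | float,
                           factor: float = WASTE_FACTOR):
    """Scale amounts (or bounds) by the food-waste factor (+5% by default)."""
    if factor <= 0:
        raise ValueError("waste factor must be positive")
    if isinstance(values, dict):
        return {k: v * factor for k, v in values.items()}
    return values * factor


def observed_cost(c: dict[str, float], prices: dict[str, float]) -> float:
    """C_obs = sum over combined categories of c_j * p_j (USD/day)."""
    total = 0.0
    for cat, amount in c.items():
        if amount == 0:
            continue
        if cat not in prices:
            raise ValueError(f"no price for combined category {cat!r} with "
                             "positive observed intake")
        total += amount * prices[cat]
    return total


def expand_to_modeling(c: dict[str, float], taxonomy: Taxonomy) -> np.ndarray:
    """Spread combined-category amounts over member modeling categories.

    The split is proportional to the weight of the items that contributed to
    each member's price, which makes the expanded diet cost exactly
    sum(c_j * p_j).  Used as the feasibility anchor and as a warm start.
    """
    x = np.zeros(len(taxonomy.modeling_ids))
    idx = {mid: i for i, mid in enumerate(taxonomy.modeling_ids)}
    for cid, cc in taxonomy.combined.items():
        amount = c.get(cid, 0.0)
        if amount == 0:
            continue
        w = np.array([max(taxonomy.modeling[m].weight_priced, 0.0) for m in cc.members])
        if w.sum() <= 0:
            w = np.ones(len(cc.members))
        for m, share in zip(cc.members, w / w.sum()):
            x[idx[m]] = amount * share
    return x


def build_group_profile(group_id: str, records: list[IntakeRecord],
                        taxonomy: Taxonomy,
                        waste_factor: float = WASTE_FACTOR) -> GroupProfile:
    """Quality filter -> mean/sd -> waste adjustment -> observed cost.

    Nutrient and pattern bounds are attached separately (see
    :func:`thriftyqp.synthetic.generate_recommendations`).
    """
    kept = median_quality_filter(records)
    if not kept:
        raise ValueError(f"group {group_id}: no records retained by the quality filter")
    c, sd = mean_intake(kept, taxonomy.combined_ids)
    c = apply_waste_adjustment(c, waste_factor)
    sd = apply_waste_adjustment(sd, waste_factor)
    prices = {cid: cc.p for cid, cc in taxonomy.combined.items()}
    return GroupProfile(group_id, c, sd, C_obs=observed_cost(c, prices))
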