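"""Market-basket reporting of optimized plans.

Daily plans are converted to weekly amounts (x7), grams to pounds, and
aggregated into the six as-consumed market-basket categories; protein foods
are further broken out by source, with cured meat kept separate from fresh
beef and pork.  The reference family of four is the post-hoc sum of the
independently optimized plans for one male and one female 20-50 y and one
male and one female 4-13 y.  Display rounding is two decimals for USD and
lbs and one decimal for cost shares, half away from zero; all internal
arithmetic is unrounded.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

from .categories import Taxonomy
from .optimize import FoodPlan
from .scheme import BASKETS, PROTEIN_SUBS

GRAMS_PER_LB = 453.59237
FAMILY_GROUPS = ("M20-50", "F20-50", "M4-13", "F4-13")


def round_display(value: float, decimals: int = 2) -> float:
    """Round half away from zero, as in the printed tables."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def to_weekly(plan: FoodPlan) -> dict:
    """Daily plan to weekly amounts (g/week) and cost (USD/week)."""
    return {"amounts": {k: 7.0 * v for k, v in plan.x.items()},
            "cost": 7.0 * plan.cost}


def grams_to_lbs(mass_g: float) -> float:
    if mass_g < 0:
        raise ValueError("negative mass")
    return mass_g / GRAMS_PER_LB


@dataclass
class MarketBasket:
    """Weekly quantities (lbs) and costs (USD) by market-basket category."""

    group_id: str
    rows: dict[str, list[float]] = field(default_factory=dict)     # [lbs, usd]
    protein: dict[str, list[float]] = field(default_factory=dict)  # [lbs, usd]

    def __post_init__(self):
        for d in (self.rows, self.protein):
            for k, (lbs, usd) in d.items():
                if lbs < -1e-9:
                    raise ValueError(f"negative quantity in basket row {k!r}")

    @property
    def total_lbs(self) -> float:
        return sum(v[0] for v in self.rows.values())

    @property
    def total_cost(self) -> float:
        return sum(v[1] for v in self.rows.values())

    @property
    def protein_total(self) -> tuple[float, float]:
        return (sum(v[0] for v in self.protein.values()),
                sum(v[1] for v in self.protein.values()))


def aggregate_market_basket(plan: FoodPlan, taxonomy: Taxonomy,
                            group_id: str | None = None) -> MarketBasket:
    """Sum a plan's weekly mass and cost into market-basket categories."""
    basket = MarketBasket(group_id=group_id or plan.group_id or "?",
                          rows={b: [0.0, 0.0] for b in BASKETS},
                          protein={s: [0.0, 0.0] for s in PROTEIN_SUBS})
    for mid, grams in plan.x.items():
        mc = taxonomy.modeling.get(mid)
        if mc is None or mc.market_basket_id not in basket.rows:
            raise ValueError(f"modeling category {mid!r} has no market-basket "
                             "assignment")
        lbs = grams_to_lbs(7.0 * grams)
        usd = 7.0 * grams * mc.p
        basket.rows[mc.market_basket_id][0] += lbs
        basket.rows[mc.market_basket_id][1] += usd
        if mc.market_basket_id == "protein foods":
            sub = mc.protein_sub
            if sub is None:
                raise ValueError(f"protein category {mid!r} lacks a sub-basket")
            if sub not in basket.protein:  # pooled-meat scenario: report as beef+pork row
                basket.protein[sub] = [0.0, 0.0]
            basket.protein[sub][0] += lbs
            basket.protein[sub][1] += usd
    return basket


def family_of_four(baskets: dict[str, MarketBasket]) -> MarketBasket:
    """Element-wise sum over exactly the four reference-family groups."""
    if set(baskets) != set(FAMILY_GROUPS):
        raise ValueError(f"family of four needs exactly the groups "
                         f"{FAMILY_GROUPS}, got {sorted(baskets)}")
    out = MarketBasket(group_id="family of four")
    for b in baskets.values():
        for src, dst in ((b.rows, out.rows), (b.protein, out.protein)):
            for k, (lbs, usd) in src.items():
                dst.setdefault(k, [0.0, 0.0])
                dst[k][0] += lbs
                dst[k][1] += usd
    return out


def cost_share(basket: MarketBasket, decimals: int = 1) -> dict[str, float]:
    """Percentage of total cost per category, display-rounded."""
    total = basket.total_cost
    if total <= 0:
        raise ValueError("cost share of a zero-cost basket")
    return {k: round_display(100.0 * v[1] / total, decimals)
            for k, v in basket.rows.items()}


# ---------------------------------------------------------------------------
# table rendering
# ---------------------------------------------------------------------------

def _basket_frame(baskets_by_model: dict[str, MarketBasket],
                  kind: str) -> pd.DataFrame:
    if kind == "baskets":
        cats = list(BASKETS)
        get = lambda b, cat: b.rows.get(cat, [0.0, 0.0])
        tot = lambda b: (b.total_lbs, b.total_cost)
    else:
        cats = list(PROTEIN_SUBS)
        get = lambda b, cat: b.protein.get(cat, [0.0, 0.0])
        tot = lambda b: b.protein_total
    data = {}
    for model, basket in baskets_by_model.items():
        if basket is None:  # explicit gap in a partial render
            data[f"{model} lbs"] = [float("nan")] * (len(cats) + 1)
            data[f"{model} USD"] = [float("nan")] * (len(cats) + 1)
            continue
        lbs, usd = [], []
        for cat in cats:
            q, c = get(basket, cat)
            lbs.append(round_display(q))
            usd.append(round_display(c))
        tq, tc = tot(basket)
        lbs.append(round_display(tq))
        usd.append(round_display(tc))
        data[f"{model} lbs"] = lbs
        data[f"{model} USD"] = usd
    return pd.DataFrame(data, index=cats + ["Total"])


def render_tables(baskets_by_model: dict[str, MarketBasket],
                  kind: str = "baskets") -> tuple[str, str]:
    """Deterministic CSV and aligned-text renderings of a basket table.

    ``kind`` selects the six market-basket rows or the protein sub-basket
    rows; missing models render as explicit blank columns.  An empty model
    dict yields header-only output.
    """
    df = _basket_frame(baskets_by_model, kind)
    buf = io.StringIO()
    df.to_csv(buf, float_format="%.2f")
    csv_text = buf.getvalue()

    width = max([len(str(i)) for i in df.index] + [8]) + 2
    cols = list(df.columns)
    lines = ["".ljust(width) + "".join(f"{c:>12}" for c in cols)]
    for idx, row in df.iterrows():
        cells = "".join("            " if pd.isna(v) else f"{v:>12.2f}" for v in row)
        lines.append(str(idx).ljust(width) + cells)
    return csv_text, "\n".join(lines) + "\n"
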