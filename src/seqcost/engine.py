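"""Core costing arithmetic.

For one weekly batch of ``n`` samples, each line item contributes a
per-sample cost through one of three behavior routes:

* VARIABLE      — consumption proportional to n; per-sample cost is
                  independent of batch size.
* STEP_FIXED    — consumption per block of ``block_capacity`` samples;
                  a batch needs ceil(n / capacity) blocks, so per-sample
                  cost follows a sawtooth that declines at capacity
                  multiples.
* FIXED         — an annual cost (amortized instrument, floor space,
                  license fee) divided by the yearly number of samples
                  N = n x runs_per_year.

Instruments are annuitized with the standard capital-recovery
(equivalent annual cost) formula at the configured interest rate, plus
undiscounted annual maintenance.  Long-term data storage is costed per
sample over its full retention horizon.  A flat overhead markup is
applied uniformly to all direct costs.  All arithmetic is unrounded;
rounding belongs to the report layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inventory import (BehaviorKind, CostBehavior, CostCategory, Inventory,
                        ModelParams, ResourceLineItem, STEP_INDICES,
                        STEP_LABELS, ValuationKind, loaded_hourly_rate)

CATEGORIES = tuple(CostCategory)


def units_required(behavior: CostBehavior, quantity: float, n: int) -> float:
    """Units consumed by one batch of ``n`` samples.

    VARIABLE quantities are per sample, STEP_FIXED quantities per block.
    FIXED items have no per-batch consumption (they follow the annual
    route) and are rejected here.
    """
    if n < 1:
        raise ValueError(f"batch size must be >= 1, got {n}")
    if behavior.kind is BehaviorKind.VARIABLE:
        return quantity * n
    if behavior.kind is BehaviorKind.STEP_FIXED:
        return quantity * math.ceil(n / behavior.block_capacity)
    raise ValueError("FIXED items have no per-batch unit consumption; "
                     "use annual_fixed_cost")


def equivalent_annual_cost(purchase_price: float, interest_rate: float,
                           lifetime_years: float, annual_maintenance: float = 0.0) -> float:
    """Annuitized capital cost of equipment plus annual maintenance.

    Capital recovery: P x r / (1 - (1+r)^-L) + M.  At r = 0 the
    straight-line limit P / L + M applies.
    """
    if lifetime_years < 1:
        raise ValueError(f"equipment lifetime must be >= 1 year, got {lifetime_years}")
    if purchase_price < 0 or annual_maintenance < 0 or interest_rate < 0:
        raise ValueError("price, maintenance and interest rate must be nonnegative")
    if interest_rate == 0.0:
        return purchase_price / lifetime_years + annual_maintenance
    crf = interest_rate / (1.0 - (1.0 + interest_rate) ** -lifetime_years)
    return purchase_price * crf + annual_maintenance


def annual_fixed_cost(item: ResourceLineItem, params: ModelParams) -> float:
    """Annual cost of a FIXED item in the report currency.

    Amortized equipment uses the equivalent annual cost; space uses
    area x internal rate; a FIXED unit-price item is an annual fee
    (quantity x price per year).  The allocation weight scales shared
    resources to the fraction attributable to this workflow.
    """
    if item.behavior.kind is not BehaviorKind.FIXED:
        raise ValueError(f"item {item.id!r} is not FIXED")
    w = item.allocation_weight
    if item.valuation is ValuationKind.EQUIPMENT:
        am = item.amortization
        eac = equivalent_annual_cost(am.purchase_price, params.interest_rate,
                                     am.lifetime_years.pick(params.estimate),
                                     am.annual_maintenance)
        native = eac * w
    elif item.valuation is ValuationKind.SPACE:
        native = item.space.area_m2 * item.space.rate_per_m2_year * w
    elif item.valuation is ValuationKind.UNIT_PRICE:
        native = item.quantity.pick(params.estimate) * item.unit_price * w
    else:
        raise ValueError(f"item {item.id!r}: valuation {item.valuation.value!r} "
                         "has no annual fixed route")
    return params.convert(native, item.currency)


def storage_cost_per_sample(item: ResourceLineItem, params: ModelParams) -> float:
    """Per-sample cost of retaining the sample's data for the full horizon:
    GB per sample x price per GB-year x horizon years."""
    if item.storage is None:
        raise ValueError(f"item {item.id!r} has no storage fields")
    st = item.storage
    native = (st.gb_per_sample.pick(params.estimate) * st.price_per_gb_year
              * st.horizon_years * item.allocation_weight)
    return params.convert(native, item.currency)


def _unit_value(item: ResourceLineItem, params: ModelParams) -> float:
    """Value of one consumed unit (one item, or one task occurrence), in the
    report currency."""
    if item.valuation is ValuationKind.UNIT_PRICE:
        return params.convert(item.unit_price, item.currency)
    if item.valuation is ValuationKind.PERSONNEL:
        hourly = loaded_hourly_rate(item.personnel)
        native = item.time_hours.pick(params.estimate) * hourly
        return params.convert(native, item.personnel.currency)
    raise ValueError(f"item {item.id!r}: valuation {item.valuation.value!r} "
                     "is not a per-unit route")


def item_cost_per_sample(item: ResourceLineItem, params: ModelParams) -> float:
    """Per-sample cost of one line item at the configured batch size."""
    n = params.batch_size
    kind = item.behavior.kind
    if item.valuation is ValuationKind.STORAGE:
        return storage_cost_per_sample(item, params)
    if kind is BehaviorKind.FIXED:
        return annual_fixed_cost(item, params) / params.yearly_samples
    units = units_required(item.behavior, item.quantity.pick(params.estimate), n)
    return units * _unit_value(item, params) * item.allocation_weight / n


@dataclass(frozen=True)
class CostMatrix:
    """Per-sample step x category cost table with derived overhead and totals.

    ``per_sample`` is a 9 x 4 DataFrame (steps x categories) of direct
    per-sample costs; everything else is derived from it and the overhead
    rate, unrounded.
    """

    per_sample: pd.DataFrame
    overhead_rate: float
    currency: str
    batch_size: int

    @property
    def overhead(self) -> pd.Series:
        return self.per_sample.sum(axis=1) * self.overhead_rate

    @property
    def step_total(self) -> pd.Series:
        return self.per_sample.sum(axis=1) * (1.0 + self.overhead_rate)

    @property
    def category_total(self) -> pd.Series:
        return self.per_sample.sum(axis=0)

    @property
    def overhead_total(self) -> float:
        return float(self.per_sample.values.sum()) * self.overhead_rate

    @property
    def grand_total(self) -> float:
        return float(self.per_sample.values.sum()) * (1.0 + self.overhead_rate)

    def step_share(self) -> pd.Series:
        """Percent of the grand total attributable to each step (sums to 100)."""
        g = self.grand_total
        if g == 0:
            return pd.Series(0.0, index=self.per_sample.index)
        return self.step_total / g * 100.0

    def category_share(self) -> pd.Series:
        """Percent of the grand total by direct category (overhead excluded;
        the overhead share is ``overhead_total / grand_total``)."""
        g = self.grand_total
        if g == 0:
            return pd.Series(0.0, index=self.per_sample.columns)
        return self.category_total / g * 100.0

    def scaled_steps(self, weights: dict[int, float]) -> "CostMatrix":
        """Multiply the direct costs of selected steps by given weights
        (overhead follows proportionally)."""
        ps = self.per_sample.copy()
        for step, w in weights.items():
            if step not in ps.index:
                raise ValueError(f"unknown step index {step}")
            if w < 0:
                raise ValueError(f"step weight must be >= 0, got {w}")
            ps.loc[step] = ps.loc[step] * w
        return CostMatrix(per_sample=ps, overhead_rate=self.overhead_rate,
                          currency=self.currency, batch_size=self.batch_size)

    def to_frame(self) -> pd.DataFrame:
        """Unrounded export with fixed column order."""
        df = self.per_sample.copy()
        df.columns = [c.value for c in df.columns]
        df["overhead"] = self.overhead
        df["total"] = self.step_total
        df["pct_of_total"] = self.step_share()
        df.insert(0, "step", [f"{i}: {STEP_LABELS[i]}" for i in df.index])
        return df


def empty_matrix(params: ModelParams) -> CostMatrix:
    ps = pd.DataFrame(0.0, index=list(STEP_INDICES), columns=list(CATEGORIES))
    return CostMatrix(per_sample=ps, overhead_rate=params.overhead_rate,
                      currency=params.report_currency, batch_size=params.batch_size)


def compute_matrix(inv: Inventory, params: ModelParams) -> CostMatrix:
    """Aggregate every line item into the per-sample step x category matrix.

    Deterministic: identical inputs give identical output.  An empty
    inventory yields a valid all-zero matrix.
    """
    ps = pd.DataFrame(0.0, index=list(STEP_INDICES), columns=list(CATEGORIES))
    for it in inv.items:
        ps.loc[it.step, it.category] += item_cost_per_sample(it, params)
    return CostMatrix(per_sample=ps, overhead_rate=params.overhead_rate,
                      currency=params.report_currency, batch_size=params.batch_size)
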