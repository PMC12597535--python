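"""Declarative scenario analysis.

A scenario is a named bundle of modifications applied to an
(inventory, parameters) pair without mutating the originals:

1. substitution of a variant inventory (e.g. an automated workflow),
2. percentage discounts / surcharges on unit valuations, per category
   or per item id,
3. batch-size and estimate (low/base/high) overrides,
4. exclusion of whole workflow steps,
5. one-off investments amortized over a number of samples and carried
   as software/storage fixed costs,
6. percentage weights on whole steps (e.g. 110% to absorb control
   samples and re-runs), applied to the direct step costs so that
   overhead follows proportionally.

Scenario files are YAML; see ``fixtures_data/scenarios`` for examples.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .engine import CostMatrix, compute_matrix
from .inventory import (Amortization, BehaviorKind, Bounded, CostBehavior,
                        CostCategory, Estimate, Inventory, ModelParams,
                        PersonnelRate, ResourceLineItem, Space, Storage,
                        ValuationKind)


class Investment(BaseModel):
    model_config = ConfigDict(frozen=True)

    label: str
    total_cost: float = Field(ge=0)
    currency: str = "USD"
    #: Number of samples the investment is spread over; defaults to one
    #: year of samples at the effective batch size.
    amortization_samples: Optional[int] = Field(default=None, gt=0)


class ScenarioSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    name: str = "scenario"
    #: (category name or item id) -> percent change, e.g. -50 halves prices.
    price_adjustments: dict[str, float] = {}
    #: step index -> multiplier on the step's direct costs, e.g. 1.10.
    step_weights: dict[int, float] = {}
    excluded_steps: frozenset[int] = frozenset()
    batch_size_override: Optional[int] = Field(default=None, ge=1)
    estimate_override: Optional[Estimate] = None
    variant_inventory: Optional[Inventory] = None
    investments: tuple[Investment, ...] = ()

    def _validate_against(self, inv: Inventory) -> None:
        ids = {it.id for it in inv.items}
        cats = {c.value for c in CostCategory} | {c.name for c in CostCategory}
        for key, pct in self.price_adjustments.items():
            if key not in cats and key not in ids:
                raise ValueError(f"scenario {self.name!r}: unknown price-adjustment "
                                 f"target {key!r}")
            if pct <= -100:
                raise ValueError(f"scenario {self.name!r}: percent change must be > -100")
        for step, w in self.step_weights.items():
            if step not in range(1, 10):
                raise ValueError(f"scenario {self.name!r}: unknown step {step}")
            if w < 0:
                raise ValueError(f"scenario {self.name!r}: step weight must be >= 0")
        bad = set(self.excluded_steps) - set(range(1, 10))
        if bad:
            raise ValueError(f"scenario {self.name!r}: unknown excluded steps {sorted(bad)}")


def _scale_valuation(item: ResourceLineItem, factor: float) -> ResourceLineItem:
    """Scale every unit valuation of an item (price, wage, purchase price,
    maintenance, space rate, storage price) by ``factor``."""
    patch: dict = {}
    if item.unit_price is not None:
        patch["unit_price"] = item.unit_price * factor
    if item.personnel is not None:
        patch["personnel"] = item.personnel.model_copy(
            update={"annual_salary": item.personnel.annual_salary * factor})
    if item.amortization is not None:
        patch["amortization"] = item.amortization.model_copy(
            update={"purchase_price": item.amortization.purchase_price * factor,
                    "annual_maintenance": item.amortization.annual_maintenance * factor})
    if item.space is not None:
        patch["space"] = item.space.model_copy(
            update={"rate_per_m2_year": item.space.rate_per_m2_year * factor})
    if item.storage is not None:
        patch["storage"] = item.storage.model_copy(
            update={"price_per_gb_year": item.storage.price_per_gb_year * factor})
    return item.model_copy(update=patch)


def _adjustment_factor(spec: ScenarioSpec, item: ResourceLineItem) -> float:
    """Sequential multiplicative composition of all adjustments matching the
    item (category-level first, then item-level)."""
    factor = 1.0
    for key, pct in spec.price_adjustments.items():
        if key in (item.category.value, item.category.name):
            factor *= 1.0 + pct / 100.0
    for key, pct in spec.price_adjustments.items():
        if key == item.id:
            factor *= 1.0 + pct / 100.0
    return factor


def apply_scenario(spec: ScenarioSpec, inv: Inventory,
                   params: ModelParams) -> tuple[Inventory, ModelParams]:
    """Return modified copies of the inventory and parameters.

    Application order: variant substitution, price adjustments,
    batch/estimate overrides, step exclusion, investments.  Step weights
    are not materialized here — they post-multiply the cost matrix in
    :func:`run_scenario`.
    """
    if spec.variant_inventory is not None:
        inv = spec.variant_inventory
    spec._validate_against(inv)

    items = list(inv.items)
    if spec.price_adjustments:
        items = [
            it if (f := _adjustment_factor(spec, it)) == 1.0 else _scale_valuation(it, f)
            for it in items
        ]

    updates: dict = {}
    if spec.batch_size_override is not None:
        updates["batch_size"] = spec.batch_size_override
    if spec.estimate_override is not None:
        updates["estimate"] = spec.estimate_override
    if updates:
        params = params.model_copy(update=updates)

    if spec.excluded_steps:
        items = [it for it in items if it.step not in spec.excluded_steps]

    for k, investment in enumerate(spec.investments):
        amort = investment.amortization_samples or params.yearly_samples
        # FIXED annual fee chosen so per-sample cost at the effective batch
        # equals total / amortization_samples; at larger batches the
        # investment, like any fixed cost, dilutes further.
        fee = investment.total_cost * params.yearly_samples / amort
        items.append(ResourceLineItem(
            id=f"investment_{k}_{investment.label}".replace(" ", "_"),
            step=6, category=CostCategory.SOFTWARE_STORAGE,
            behavior=CostBehavior(kind=BehaviorKind.FIXED),
            valuation=ValuationKind.UNIT_PRICE,
            unit_price=fee, currency=investment.currency,
            note=f"investment: {investment.label}"))

    return inv.with_items(items), params


@dataclass(frozen=True)
class ScenarioResult:
    name: str
    matrix: CostMatrix
    base_matrix: CostMatrix

    @property
    def pct_change_total(self) -> float:
        return 100.0 * (self.matrix.grand_total / self.base_matrix.grand_total - 1.0)

    @property
    def pct_change_by_category(self) -> dict[CostCategory, float]:
        out = {}
        for cat in self.base_matrix.per_sample.columns:
            base = self.base_matrix.category_total[cat]
            new = self.matrix.category_total[cat]
            out[cat] = float("nan") if base == 0 else 100.0 * (new / base - 1.0)
        return out


def run_scenario(spec: ScenarioSpec, inv: Inventory, params: ModelParams,
                 base_matrix: CostMatrix | None = None) -> ScenarioResult:
    """Compute base and scenario matrices and their percent changes."""
    if base_matrix is None:
        base_matrix = compute_matrix(inv, params)
    mod_inv, mod_params = apply_scenario(spec, inv, params)
    matrix = compute_matrix(mod_inv, mod_params)
    if spec.step_weights:
        matrix = matrix.scaled_steps(spec.step_weights)
    return ScenarioResult(name=spec.name, matrix=matrix, base_matrix=base_matrix)


def compare(a: CostMatrix, b: CostMatrix) -> dict[str, float]:
    """Percent change of ``a`` relative to base ``b``, by total and category.

    compare(x, x) is zero everywhere; swapping the arguments inverts the
    underlying ratio.
    """
    if a.currency != b.currency:
        raise ValueError("matrices must share a report currency")
    if b.grand_total == 0:
        raise ZeroDivisionError("percent change undefined for a zero base total")
    out = {"total": 100.0 * (a.grand_total / b.grand_total - 1.0)}
    for cat in b.per_sample.columns:
        base = b.category_total[cat]
        out[cat.value] = (float("nan") if base == 0
                          else 100.0 * (a.category_total[cat] / base - 1.0))
    return out


def read_scenario(path: str | Path) -> ScenarioSpec:
    """Load a scenario YAML file.

    Recognized keys: ``name``, ``price_adjustments``, ``step_weights``,
    ``excluded_steps``, ``batch_size_override``, ``estimate_override``,
    ``investments`` (list of ``label`` / ``total_cost`` / ``currency`` /
    ``amortization_samples``), ``variant_inventory`` (path to an inventory
    CSV, resolved relative to the scenario file).
    """
    from .io import read_inventory

    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    variant = data.pop("variant_inventory", None)
    if variant is not None:
        variant = read_inventory((path.parent / variant).resolve())
    if "excluded_steps" in data:
        data["excluded_steps"] = frozenset(data["excluded_steps"])
    if "investments" in data:
        data["investments"] = tuple(Investment(**inv) for inv in data["investments"])
    if "step_weights" in data:
        data["step_weights"] = {int(k): float(v) for k, v in data["step_weights"].items()}
    return ScenarioSpec(variant_inventory=variant, **data)
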