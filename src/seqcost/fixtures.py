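"""Bundled inventories, a synthetic-inventory generator and a costing oracle.

``calibrated_inventory`` loads the bundled workflow whose engine output at
batch size 12 reproduces the published base-case cost table cell by cell
(after rounding).  Its line-item granularity — how a cell splits into kits,
tasks and instruments — is illustrative; only the cell-level sums are
calibrated.  ``automated_inventory`` is an illustrative variant with a
library-preparation robot; it is not calibrated.

``synthetic_inventory`` draws random but valid inventories for property
tests, and ``oracle_total`` recomputes a grand total naively and
independently of the engine.
"""

from __future__ import annotations

import math
from importlib import resources
from typing import Mapping

import numpy as np

from .inventory import (Amortization, BehaviorKind, Bounded, CostBehavior,
                        CostCategory, Inventory, ModelParams, PersonnelRate,
                        ResourceLineItem, Space, Storage, ValuationKind)
from .io import read_inventory, read_params

_DATA = resources.files("seqcost") / "fixtures_data"


def _read_bundled(name: str) -> Inventory:
    with resources.as_file(_DATA / name) as path:
        return read_inventory(path)


def calibrated_inventory() -> Inventory:
    """The bundled inventory calibrated to the published base-case table."""
    return _read_bundled("calibrated_inventory.csv")


def automated_inventory() -> Inventory:
    """Illustrative variant with robotic library preparation (not calibrated)."""
    return _read_bundled("automated_inventory.csv")


def default_params() -> ModelParams:
    """Bundled base-case model parameters (batch 12, 20% overhead, 4% interest)."""
    with resources.as_file(_DATA / "model_params.yaml") as path:
        return read_params(path)


def scenario_path(name: str):
    """Filesystem path of a bundled scenario YAML (context-manager free:
    returns a Traversable usable with ``read_scenario`` via as_file)."""
    return _DATA / "scenarios" / name


# ---------------------------------------------------------------------------
# synthetic inventories

DEFAULT_BEHAVIOR_MIX: Mapping[str, float] = {
    "variable": 0.55, "fixed": 0.25, "step_fixed": 0.20,
}

_CURRENCIES = ("NOK", "USD", "EUR")
_CAPACITIES = (4, 8, 12, 16, 24, 64)


def synthetic_inventory(seed: int, n_items: int = 20,
                        mix: Mapping[str, float] = DEFAULT_BEHAVIOR_MIX) -> Inventory:
    """A reproducible random inventory satisfying every domain invariant.

    ``mix`` gives the proportions of variable / fixed / step-fixed items
    and must sum to one.
    """
    if n_items < 1:
        raise ValueError("n_items must be >= 1")
    total = sum(mix.get(k, 0.0) for k in ("variable", "fixed", "step_fixed"))
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"behavior proportions must sum to 1, got {total}")
    rng = np.random.default_rng(seed)
    kinds = rng.choice(["variable", "fixed", "step_fixed"], size=n_items,
                       p=[mix.get("variable", 0.0), mix.get("fixed", 0.0),
                          mix.get("step_fixed", 0.0)])
    items = []
    for i, kind_name in enumerate(kinds):
        kind = BehaviorKind(kind_name)
        step = int(rng.integers(1, 10))
        currency = str(rng.choice(_CURRENCIES))
        weight = float(np.round(rng.uniform(0.2, 1.0), 3))
        cap = int(rng.choice(_CAPACITIES)) if kind is BehaviorKind.STEP_FIXED else None
        behavior = CostBehavior(kind=kind, block_capacity=cap)
        base_qty = float(rng.integers(1, 5))
        qty = Bounded(low=base_qty * 0.8, base=base_qty, high=base_qty * 1.3)

        if kind is BehaviorKind.FIXED:
            category = (CostCategory.EQUIPMENT if rng.random() < 2 / 3
                        else CostCategory.SOFTWARE_STORAGE)
            if category is CostCategory.EQUIPMENT and rng.random() < 0.6:
                life = int(rng.integers(5, 13))
                items.append(ResourceLineItem(
                    id=f"syn_{i}_equipment", step=step, category=category,
                    behavior=behavior, valuation=ValuationKind.EQUIPMENT,
                    currency=currency,
                    amortization=Amortization(
                        purchase_price=float(np.round(rng.uniform(5e3, 1e6), 2)),
                        lifetime_years=Bounded(low=max(1, life - 2), base=life,
                                               high=life + 2),
                        annual_maintenance=float(np.round(rng.uniform(0, 5e4), 2))),
                    allocation_weight=weight))
            elif category is CostCategory.EQUIPMENT:
                items.append(ResourceLineItem(
                    id=f"syn_{i}_space", step=step, category=category,
                    behavior=behavior, valuation=ValuationKind.SPACE,
                    currency=currency,
                    space=Space(area_m2=float(np.round(rng.uniform(2, 60), 1)),
                                rate_per_m2_year=float(np.round(rng.uniform(100, 6000), 2))),
                    allocation_weight=weight))
            else:
                items.append(ResourceLineItem(
                    id=f"syn_{i}_license", step=step, category=category,
                    behavior=behavior, valuation=ValuationKind.UNIT_PRICE,
                    currency=currency, quantity=Bounded.of(1.0),
                    unit_price=float(np.round(rng.uniform(500, 5e4), 2)),
                    allocation_weight=weight))
            continue

        # variable / step-fixed routes
        category = list(CostCategory)[int(rng.integers(0, 4))]
        if category is CostCategory.PERSONNEL:
            t = float(np.round(rng.uniform(0.1, 8.0), 3))
            items.append(ResourceLineItem(
                id=f"syn_{i}_task", step=step, category=category,
                behavior=behavior, valuation=ValuationKind.PERSONNEL,
                currency="NOK", quantity=qty,
                personnel=PersonnelRate(
                    role=f"role_{int(rng.integers(0, 5))}",
                    annual_salary=float(rng.integers(400, 1200) * 1000),
                    currency="NOK", annual_hours=1695.0),
                time_hours=Bounded(low=t * 0.8, base=t, high=t * 1.5),
                allocation_weight=weight))
        elif category is CostCategory.SOFTWARE_STORAGE and kind is BehaviorKind.VARIABLE \
                and rng.random() < 0.5:
            g = float(np.round(rng.uniform(1, 100), 1))
            items.append(ResourceLineItem(
                id=f"syn_{i}_storage", step=step, category=category,
                behavior=behavior, valuation=ValuationKind.STORAGE,
                currency=currency,
                storage=Storage(gb_per_sample=Bounded(low=g * 0.5, base=g, high=g * 1.5),
                                price_per_gb_year=float(np.round(rng.uniform(0.01, 1.0), 4)),
                                horizon_years=10.0),
                allocation_weight=weight))
        else:
            items.append(ResourceLineItem(
                id=f"syn_{i}_unit", step=step, category=category,
                behavior=behavior, valuation=ValuationKind.UNIT_PRICE,
                currency=currency, quantity=qty,
                unit_price=float(np.round(rng.uniform(0.5, 1500), 2)),
                allocation_weight=weight))
    return Inventory(name=f"synthetic_{seed}", items=tuple(items))


# ---------------------------------------------------------------------------
# independent costing oracle

_ORACLE_NOK_PER = {"NOK": 1.0}


def oracle_total(inv: Inventory, params: ModelParams) -> float:
    """Naive line-by-line grand total (direct costs times 1 + overhead).

    Deliberately shares no code with the engine: the annuity is obtained
    by inverting an explicit discounted payment sum, block counts use
    integer arithmetic, and conversion goes literally through NOK.
    """
    nok_per = {"NOK": 1.0, "USD": params.nok_per_usd, "EUR": params.nok_per_eur}

    def to_report(amount: float, cur: str) -> float:
        return amount * nok_per[cur] / nok_per[params.report_currency]

    def pick(b, est):
        return {"low": b.low, "base": b.base, "high": b.high}[est.value]

    n = params.batch_size
    yearly = n * params.runs_per_year
    direct = 0.0
    for it in inv.items:
        est = params.estimate
        w = it.allocation_weight
        if it.valuation is ValuationKind.STORAGE:
            st = it.storage
            per_sample = (pick(st.gb_per_sample, est) * st.price_per_gb_year
                          * st.horizon_years * w)
            direct += to_report(per_sample, it.currency)
            continue
        if it.behavior.kind is BehaviorKind.FIXED:
            if it.valuation is ValuationKind.EQUIPMENT:
                am = it.amortization
                life = int(round(pick(am.lifetime_years, est)))
                r = params.interest_rate
                if r == 0.0:
                    capital = am.purchase_price / life
                else:
                    discounted = sum((1.0 + r) ** -t for t in range(1, life + 1))
                    capital = am.purchase_price / discounted
                annual = (capital + am.annual_maintenance) * w
            elif it.valuation is ValuationKind.SPACE:
                annual = it.space.area_m2 * it.space.rate_per_m2_year * w
            else:
                annual = pick(it.quantity, est) * it.unit_price * w
            direct += to_report(annual, it.currency) / yearly
            continue
        qty = pick(it.quantity, est)
        if it.behavior.kind is BehaviorKind.VARIABLE:
            units = qty * n
        else:
            blocks = -(-n // it.behavior.block_capacity)
            units = qty * blocks
        if it.valuation is ValuationKind.PERSONNEL:
            p = it.personnel
            hourly = (p.annual_salary * (1.0 + p.employer_contribution_rate)
                      * (1.0 + p.social_security_rate) / p.annual_hours)
            value = pick(it.time_hours, est) * hourly
            cur = p.currency
        else:
            value = it.unit_price
            cur = it.currency
        direct += to_report(units * value * w, cur) / n
    return direct * (1.0 + params.overhead_rate)
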