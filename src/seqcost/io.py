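"""CSV / YAML readers and writers for inventories and model parameters.

The inventory schema is one flat table, one row per line item, with a
``valuation_kind`` discriminator column.  Money columns are valued in the
row's ``currency``.  Bounded parameters use three columns (``*_low``,
``*_base``, ``*_high``); a missing low/high defaults to the base value.
The full column dictionary ships in ``docs/columns.md``.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from .inventory import (Amortization, BehaviorKind, Bounded, CostBehavior,
                        CostCategory, Inventory, ModelParams, PersonnelRate,
                        ResourceLineItem, Space, Storage, ValuationKind)

REQUIRED_COLUMNS = ["id", "step", "category", "behavior", "valuation_kind", "currency"]

OPTIONAL_COLUMNS = [
    "block_capacity",
    "qty_low", "qty_base", "qty_high",
    "unit_price",
    "role", "annual_salary", "employer_contribution_rate",
    "social_security_rate", "annual_hours",
    "time_low_h", "time_base_h", "time_high_h",
    "purchase_price", "lifetime_low_y", "lifetime_base_y", "lifetime_high_y",
    "annual_maintenance",
    "area_m2", "rate_per_m2_year",
    "storage_gb_low", "storage_gb_base", "storage_gb_high",
    "price_per_gb_year", "storage_years",
    "allocation_weight", "note",
]

ALL_COLUMNS = REQUIRED_COLUMNS + OPTIONAL_COLUMNS


class SchemaError(ValueError):
    """Raised when an inventory file violates the documented schema."""


def _is_na(v: Any) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v)) or v == ""


def _num(row: pd.Series, col: str, rownum: int, required: bool = False) -> float | None:
    v = row.get(col)
    if _is_na(v):
        if required:
            raise SchemaError(f"row {rownum}: missing required field {col!r}")
        return None
    try:
        return float(v)
    except (TypeError, ValueError):
        raise SchemaError(f"row {rownum}: field {col!r} is not numeric: {v!r}") from None


def _bounded3(row: pd.Series, low_c: str, base_c: str, high_c: str, rownum: int,
              required: bool = False) -> Bounded | None:
    base = _num(row, base_c, rownum, required=required)
    if base is None:
        return None
    low = _num(row, low_c, rownum)
    high = _num(row, high_c, rownum)
    try:
        return Bounded.of(base, low, high)
    except ValueError as exc:
        raise SchemaError(f"row {rownum}: {base_c}: {exc}") from None


def _row_to_item(row: pd.Series, rownum: int) -> ResourceLineItem:
    try:
        step = int(row["step"])
    except (TypeError, ValueError):
        raise SchemaError(f"row {rownum}: step {row['step']!r} is not an integer") from None
    if not 1 <= step <= 9:
        raise SchemaError(f"row {rownum}: unknown step index {step}")
    try:
        category = CostCategory(str(row["category"]).strip().lower())
    except ValueError:
        raise SchemaError(f"row {rownum}: unknown category {row['category']!r}") from None
    try:
        kind = BehaviorKind(str(row["behavior"]).strip().lower())
    except ValueError:
        raise SchemaError(f"row {rownum}: unknown behavior {row['behavior']!r}") from None
    cap = _num(row, "block_capacity", rownum)
    if kind is BehaviorKind.STEP_FIXED and cap is None:
        raise SchemaError(f"row {rownum}: STEP_FIXED item without block_capacity")
    try:
        behavior = CostBehavior(kind=kind,
                                block_capacity=None if cap is None else int(cap))
    except ValueError as exc:
        raise SchemaError(f"row {rownum}: {exc}") from None
    try:
        valuation = ValuationKind(str(row["valuation_kind"]).strip().lower())
    except ValueError:
        raise SchemaError(f"row {rownum}: unknown valuation_kind "
                          f"{row['valuation_kind']!r}") from None

    qty = _bounded3(row, "qty_low", "qty_base", "qty_high", rownum) \
        or Bounded.of(1.0)
    if min(qty.low, qty.base, qty.high) < 0:
        raise SchemaError(f"row {rownum}: negative quantity")
    unit_price = _num(row, "unit_price", rownum)
    if unit_price is not None and unit_price < 0:
        raise SchemaError(f"row {rownum}: negative unit_price")

    personnel = None
    time_hours = None
    if valuation is ValuationKind.PERSONNEL:
        role = row.get("role")
        if _is_na(role):
            raise SchemaError(f"row {rownum}: personnel item without role")
        personnel = PersonnelRate(
            role=str(role),
            annual_salary=_num(row, "annual_salary", rownum, required=True),
            currency=str(row["currency"]),
            employer_contribution_rate=_num(row, "employer_contribution_rate", rownum) or 0.13,
            social_security_rate=_num(row, "social_security_rate", rownum) or 0.25,
            annual_hours=_num(row, "annual_hours", rownum, required=True),
        )
        time_hours = _bounded3(row, "time_low_h", "time_base_h", "time_high_h",
                               rownum, required=True)

    amortization = None
    if valuation is ValuationKind.EQUIPMENT:
        amortization = Amortization(
            purchase_price=_num(row, "purchase_price", rownum, required=True),
            lifetime_years=_bounded3(row, "lifetime_low_y", "lifetime_base_y",
                                     "lifetime_high_y", rownum, required=True),
            annual_maintenance=_num(row, "annual_maintenance", rownum) or 0.0,
        )

    space = None
    if valuation is ValuationKind.SPACE:
        space = Space(area_m2=_num(row, "area_m2", rownum, required=True),
                      rate_per_m2_year=_num(row, "rate_per_m2_year", rownum, required=True))

    storage = None
    if valuation is ValuationKind.STORAGE:
        storage = Storage(
            gb_per_sample=_bounded3(row, "storage_gb_low", "storage_gb_base",
                                    "storage_gb_high", rownum, required=True),
            price_per_gb_year=_num(row, "price_per_gb_year", rownum, required=True),
            horizon_years=_num(row, "storage_years", rownum) or 10.0,
        )

    try:
        return ResourceLineItem(
            id=str(row["id"]),
            step=step,
            category=category,
            behavior=behavior,
            valuation=valuation,
            quantity=qty,
            currency=str(row["currency"]),
            unit_price=unit_price,
            personnel=personnel,
            time_hours=time_hours,
            amortization=amortization,
            space=space,
            storage=storage,
            allocation_weight=_num(row, "allocation_weight", rownum) or 1.0,
            note="" if _is_na(row.get("note")) else str(row.get("note")),
        )
    except ValueError as exc:
        raise SchemaError(f"row {rownum}: {exc}") from None


def read_inventory(path: str | Path, name: str | None = None) -> Inventory:
    """Read a flat-table inventory CSV into a validated :class:`Inventory`.

    Raises :class:`SchemaError` naming the offending row and field on any
    schema violation.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required columns {missing}")
    unknown = [c for c in df.columns if c not in ALL_COLUMNS]
    if unknown:
        raise SchemaError(f"{path.name}: unknown columns {unknown}")
    items = [_row_to_item(row, rownum) for rownum, (_, row) in enumerate(df.iterrows(), start=2)]
    return Inventory(name=name or path.stem, items=tuple(items))


def inventory_to_frame(inv: Inventory) -> pd.DataFrame:
    """Flatten an inventory back into the tabular schema."""
    rows = []
    for it in inv.items:
        r: dict[str, Any] = {c: None for c in ALL_COLUMNS}
        r.update(id=it.id, step=it.step, category=it.category.value,
                 behavior=it.behavior.kind.value,
                 block_capacity=it.behavior.block_capacity,
                 valuation_kind=it.valuation.value, currency=it.currency,
                 qty_low=it.quantity.low, qty_base=it.quantity.base,
                 qty_high=it.quantity.high, unit_price=it.unit_price,
                 allocation_weight=it.allocation_weight, note=it.note or None)
        if it.personnel is not None:
            r.update(role=it.personnel.role,
                     annual_salary=it.personnel.annual_salary,
                     employer_contribution_rate=it.personnel.employer_contribution_rate,
                     social_security_rate=it.personnel.social_security_rate,
                     annual_hours=it.personnel.annual_hours,
                     time_low_h=it.time_hours.low, time_base_h=it.time_hours.base,
                     time_high_h=it.time_hours.high)
        if it.amortization is not None:
            r.update(purchase_price=it.amortization.purchase_price,
                     lifetime_low_y=it.amortization.lifetime_years.low,
                     lifetime_base_y=it.amortization.lifetime_years.base,
                     lifetime_high_y=it.amortization.lifetime_years.high,
                     annual_maintenance=it.amortization.annual_maintenance)
        if it.space is not None:
            r.update(area_m2=it.space.area_m2,
                     rate_per_m2_year=it.space.rate_per_m2_year)
        if it.storage is not None:
            r.update(storage_gb_low=it.storage.gb_per_sample.low,
                     storage_gb_base=it.storage.gb_per_sample.base,
                     storage_gb_high=it.storage.gb_per_sample.high,
                     price_per_gb_year=it.storage.price_per_gb_year,
                     storage_years=it.storage.horizon_years)
        rows.append(r)
    return pd.DataFrame(rows, columns=ALL_COLUMNS)


def write_inventory(inv: Inventory, path: str | Path) -> None:
    """Write an inventory as CSV; ``read_inventory`` round-trips it."""
    inventory_to_frame(inv).to_csv(path, index=False, float_format="%.10g")


def read_params(path: str | Path) -> ModelParams:
    """Read model parameters from a YAML mapping."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise SchemaError(f"{path}: parameter file must be a YAML mapping")
    return ModelParams(**data)


def write_params(params: ModelParams, path: str | Path) -> None:
    data = params.model_dump()
    data["estimate"] = params.estimate.value
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
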