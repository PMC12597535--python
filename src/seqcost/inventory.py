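"""Domain model for resource inventories of a sequencing-based diagnostic workflow.

A workflow is a fixed sequence of nine steps (from analysis request through
data storage).  Each step holds resource line items — reagent kits, staff
tasks, amortized instruments, laboratory space, software licenses, data
storage — that the costing engine turns into a per-sample cost.

Every money amount carries an explicit currency tag (NOK, USD or EUR);
conversion uses fixed 2024 reference rates and happens only at valuation /
reporting time.
"""

from __future__ import annotations

import enum
import math
from typing import Iterable, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

# ---------------------------------------------------------------------------
# currencies

#: NOK per unit of foreign currency (2024 annual reference rates).
NOK_PER_USD = 10.7433
NOK_PER_EUR = 11.6276

_NOK_PER = {"NOK": 1.0, "USD": NOK_PER_USD, "EUR": NOK_PER_EUR}


def convert_currency(amount: float, from_currency: str, to_currency: str,
                     nok_per_usd: float = NOK_PER_USD,
                     nok_per_eur: float = NOK_PER_EUR) -> float:
    """Convert ``amount`` between NOK, USD and EUR at the fixed rates.

    The conversion is a linear bijection through NOK, so round trips
    preserve amounts to floating-point accuracy.
    """
    rates = {"NOK": 1.0, "USD": nok_per_usd, "EUR": nok_per_eur}
    try:
        in_nok = amount * rates[from_currency]
        return in_nok / rates[to_currency]
    except KeyError as exc:
        raise ValueError(f"unknown currency tag: {exc.args[0]!r}") from None


# ---------------------------------------------------------------------------
# workflow steps

#: The nine ordered steps of the diagnostic workflow, index -> label.
STEP_LABELS: dict[int, str] = {
    1: "Analysis request and sampling",
    2: "Sample registration and processing",
    3: "DNA/RNA extraction",
    4: "Library preparation",
    5: "Sequencing",
    6: "Data analysis",
    7: "Data interpretation",
    8: "Molecular tumor board and reporting",
    9: "Storage",
}

STEP_INDICES: tuple[int, ...] = tuple(STEP_LABELS)


class CostCategory(str, enum.Enum):
    """Direct cost categories.

    EQUIPMENT subsumes laboratory-space costs; SOFTWARE_STORAGE subsumes
    licenses and data storage.  Overhead is never stored — it is derived as
    a flat markup on direct costs.
    """

    CONSUMABLES = "consumables"
    PERSONNEL = "personnel"
    EQUIPMENT = "equipment"
    SOFTWARE_STORAGE = "software_storage"


class BehaviorKind(str, enum.Enum):
    VARIABLE = "variable"        # consumption proportional to batch size
    FIXED = "fixed"              # annual consumption independent of batch size
    STEP_FIXED = "step_fixed"    # consumption per ceil(n / block_capacity) blocks


class ValuationKind(str, enum.Enum):
    UNIT_PRICE = "unit_price"    # price per unit (or per year when FIXED, e.g. a license fee)
    PERSONNEL = "personnel"      # loaded hourly wage x working time
    EQUIPMENT = "equipment"      # amortized purchase price + maintenance
    SPACE = "space"              # floor area x internal rate per m2 per year
    STORAGE = "storage"          # GB per sample x price per GB-year x horizon


class CostBehavior(BaseModel):
    model_config = ConfigDict(frozen=True)

    kind: BehaviorKind
    block_capacity: Optional[int] = Field(default=None, gt=0)

    @model_validator(mode="after")
    def _check_capacity(self) -> "CostBehavior":
        if self.kind is BehaviorKind.STEP_FIXED and self.block_capacity is None:
            raise ValueError("STEP_FIXED behavior requires block_capacity")
        if self.kind is not BehaviorKind.STEP_FIXED and self.block_capacity is not None:
            raise ValueError("block_capacity only applies to STEP_FIXED behavior")
        return self


class Bounded(BaseModel):
    """A deterministic sensitivity range: low <= base <= high, same units."""

    model_config = ConfigDict(frozen=True)

    low: float
    base: float
    high: float

    @classmethod
    def of(cls, base: float, low: float | None = None, high: float | None = None) -> "Bounded":
        return cls(low=base if low is None else low, base=base,
                   high=base if high is None else high)

    def pick(self, estimate: "Estimate") -> float:
        return {Estimate.LOW: self.low, Estimate.BASE: self.base,
                Estimate.HIGH: self.high}[estimate]

    def is_ordered(self) -> bool:
        return self.low <= self.base <= self.high


class Estimate(str, enum.Enum):
    LOW = "low"
    BASE = "base"
    HIGH = "high"


class PersonnelRate(BaseModel):
    """Annual salary plus statutory wage loading, per profession.

    The loaded hourly cost compounds the employer contribution (default 13%)
    and social security costs (default 25%) multiplicatively on the salary.
    """

    model_config = ConfigDict(frozen=True)

    role: str
    annual_salary: float = Field(gt=0)
    currency: str = "NOK"
    employer_contribution_rate: float = Field(default=0.13, ge=0)
    social_security_rate: float = Field(default=0.25, ge=0)
    annual_hours: float = Field(gt=0)


def loaded_hourly_rate(rate: PersonnelRate) -> float:
    """Loaded hourly wage, in the rate's own currency.

    annual_salary x (1 + employer contribution) x (1 + social security)
    / annual hours.
    """
    if rate.annual_salary <= 0 or rate.annual_hours <= 0:
        raise ValueError("salary and annual hours must be positive")
    return (rate.annual_salary
            * (1.0 + rate.employer_contribution_rate)
            * (1.0 + rate.social_security_rate)
            / rate.annual_hours)


class Amortization(BaseModel):
    model_config = ConfigDict(frozen=True)

    purchase_price: float = Field(ge=0)
    lifetime_years: Bounded
    annual_maintenance: float = Field(default=0.0, ge=0)


class Space(BaseModel):
    model_config = ConfigDict(frozen=True)

    area_m2: float = Field(gt=0)
    rate_per_m2_year: float = Field(ge=0)


class Storage(BaseModel):
    model_config = ConfigDict(frozen=True)

    gb_per_sample: Bounded
    price_per_gb_year: float = Field(ge=0)
    horizon_years: float = Field(default=10.0, gt=0)


class ResourceLineItem(BaseModel):
    """One costed resource attached to a workflow step.

    Exactly one valuation route applies, selected by ``valuation``:
    a unit price, a personnel task (role + working time), an amortized
    instrument, a floor-space share, or long-term data storage.
    ``allocation_weight`` scales shared resources down to the fraction
    attributable to this workflow.
    """

    model_config = ConfigDict(frozen=True)

    id: str
    step: int
    category: CostCategory
    behavior: CostBehavior
    valuation: ValuationKind
    quantity: Bounded = Bounded(low=1.0, base=1.0, high=1.0)
    currency: str = "USD"
    unit_price: Optional[float] = None
    personnel: Optional[PersonnelRate] = None
    time_hours: Optional[Bounded] = None
    amortization: Optional[Amortization] = None
    space: Optional[Space] = None
    storage: Optional[Storage] = None
    allocation_weight: float = Field(default=1.0)
    note: str = ""

    @model_validator(mode="after")
    def _check_route(self) -> "ResourceLineItem":
        if self.step not in STEP_LABELS:
            raise ValueError(f"unknown step index {self.step}")
        k = self.valuation
        if k is ValuationKind.UNIT_PRICE and self.unit_price is None:
            raise ValueError(f"item {self.id!r}: unit_price valuation requires unit_price")
        if k is ValuationKind.PERSONNEL and (self.personnel is None or self.time_hours is None):
            raise ValueError(f"item {self.id!r}: personnel valuation requires role and time_hours")
        if k is ValuationKind.EQUIPMENT and self.amortization is None:
            raise ValueError(f"item {self.id!r}: equipment valuation requires amortization fields")
        if k is ValuationKind.SPACE and self.space is None:
            raise ValueError(f"item {self.id!r}: space valuation requires area and rate")
        if k is ValuationKind.STORAGE and self.storage is None:
            raise ValueError(f"item {self.id!r}: storage valuation requires storage fields")
        return self


class ModelParams(BaseModel):
    """Global economic parameters of a costing run."""

    model_config = ConfigDict(frozen=True)

    batch_size: int = Field(default=12, ge=1)
    runs_per_year: int = Field(default=52, ge=1)
    overhead_rate: float = Field(default=0.20, ge=0)
    interest_rate: float = Field(default=0.04, ge=0)
    nok_per_usd: float = NOK_PER_USD
    nok_per_eur: float = NOK_PER_EUR
    report_currency: str = "USD"
    estimate: Estimate = Estimate.BASE

    @property
    def yearly_samples(self) -> int:
        return self.batch_size * self.runs_per_year

    def convert(self, amount: float, from_currency: str) -> float:
        return convert_currency(amount, from_currency, self.report_currency,
                                self.nok_per_usd, self.nok_per_eur)


class Inventory(BaseModel):
    """A complete workflow definition: nine ordered steps with line items."""

    model_config = ConfigDict(frozen=True)

    name: str = "inventory"
    items: tuple[ResourceLineItem, ...] = ()

    def items_in_step(self, step: int) -> list[ResourceLineItem]:
        return [it for it in self.items if it.step == step]

    def with_items(self, items: Iterable[ResourceLineItem]) -> "Inventory":
        return Inventory(name=self.name, items=tuple(items))

    def __len__(self) -> int:
        return len(self.items)


# ---------------------------------------------------------------------------
# validation

class Finding(BaseModel):
    model_config = ConfigDict(frozen=True)

    item_id: str
    invariant: str
    severity: str = "error"
    message: str = ""


def _bounded_findings(item_id: str, name: str, b: Bounded | None,
                      nonneg: bool = True) -> list[Finding]:
    out: list[Finding] = []
    if b is None:
        return out
    if not b.is_ordered():
        out.append(Finding(item_id=item_id, invariant=f"{name}.ordering",
                           message=f"{name}: low <= base <= high violated "
                                   f"({b.low}, {b.base}, {b.high})"))
    if nonneg and min(b.low, b.base, b.high) < 0:
        out.append(Finding(item_id=item_id, invariant=f"{name}.nonnegative",
                           message=f"{name} has negative values"))
    return out


def validate_inventory(inv: Inventory) -> list[Finding]:
    """Check every domain invariant; returns findings instead of raising.

    An empty list means the inventory satisfies all invariants.
    """
    findings: list[Finding] = []
    seen: set[str] = set()
    for it in inv.items:
        if it.id in seen:
            findings.append(Finding(item_id=it.id, invariant="id.unique",
                                    message="duplicate line-item id"))
        seen.add(it.id)
        if not (0.0 < it.allocation_weight <= 1.0):
            findings.append(Finding(item_id=it.id, invariant="allocation_weight.range",
                                    message=f"allocation weight {it.allocation_weight} "
                                            "outside (0, 1]"))
        if it.currency not in _NOK_PER:
            findings.append(Finding(item_id=it.id, invariant="currency.known",
                                    message=f"unknown currency {it.currency!r}"))
        findings += _bounded_findings(it.id, "quantity", it.quantity)
        findings += _bounded_findings(it.id, "time_hours", it.time_hours)
        if it.unit_price is not None and it.unit_price < 0:
            findings.append(Finding(item_id=it.id, invariant="unit_price.nonnegative",
                                    message=f"negative unit price {it.unit_price}"))
        if it.amortization is not None:
            findings += _bounded_findings(it.id, "lifetime_years",
                                          it.amortization.lifetime_years)
            if it.amortization.lifetime_years.low < 1:
                findings.append(Finding(item_id=it.id, invariant="lifetime.min",
                                        message="equipment lifetime below one year"))
            if it.category is not CostCategory.EQUIPMENT:
                findings.append(Finding(item_id=it.id, invariant="amortization.category",
                                        message="amortized items must be EQUIPMENT"))
            if it.behavior.kind is not BehaviorKind.FIXED:
                findings.append(Finding(item_id=it.id, invariant="amortization.behavior",
                                        message="amortized items must be FIXED"))
        if it.space is not None and it.category is not CostCategory.EQUIPMENT:
            findings.append(Finding(item_id=it.id, invariant="space.category",
                                    message="space items must be EQUIPMENT"))
        if it.storage is not None:
            findings += _bounded_findings(it.id, "gb_per_sample", it.storage.gb_per_sample)
            if it.category is not CostCategory.SOFTWARE_STORAGE:
                findings.append(Finding(item_id=it.id, invariant="storage.category",
                                        message="storage items must be SOFTWARE_STORAGE"))
        if it.valuation is ValuationKind.PERSONNEL and it.category is not CostCategory.PERSONNEL:
            findings.append(Finding(item_id=it.id, invariant="personnel.category",
                                    severity="warning",
                                    message="personnel-valued item outside PERSONNEL category"))
    return findings
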