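"""Costing arithmetic: unit consumption, annuitization, matrix invariants."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from seqcost import (BehaviorKind, Bounded, CostBehavior, CostCategory,
                     Inventory, ModelParams, ResourceLineItem, Storage,
                     ValuationKind, compute_matrix, equivalent_annual_cost,
                     annual_fixed_cost, item_cost_per_sample,
                     storage_cost_per_sample, synthetic_inventory,
                     units_required)

VAR = CostBehavior(kind=BehaviorKind.VARIABLE)
FIX = CostBehavior(kind=BehaviorKind.FIXED)


def blocks_brute_force(n: int, capacity: int) -> int:
    """Fill samples into blocks one at a time."""
    blocks, used = 0, 0
    for _ in range(n):
        if used == 0:
            blocks += 1
            used = capacity
        used -= 1
    return blocks


class TestUnitsRequired:
    def test_variable_is_proportional(self):
        assert units_required(VAR, 2.0, 12) == 24

    @pytest.mark.parametrize("n,expected", [(12, 2), (16, 2), (17, 3), (1, 1)])
    def test_step_fixed_blocks(self, n, expected):
        sf = CostBehavior(kind=BehaviorKind.STEP_FIXED, block_capacity=8)
        assert units_required(sf, 1.0, n) == expected
        assert expected == blocks_brute_force(n, 8)

    @given(n=st.integers(1, 500), cap=st.integers(1, 70))
    @settings(max_examples=100, deadline=None)
    def test_step_fixed_matches_block_enumeration(self, n, cap):
        sf = CostBehavior(kind=BehaviorKind.STEP_FIXED, block_capacity=cap)
        assert units_required(sf, 1.0, n) == blocks_brute_force(n, cap)

    def test_fixed_has_no_batch_route(self):
        with pytest.raises(ValueError, match="annual"):
            units_required(FIX, 1.0, 12)

    def test_batch_below_one_rejected(self):
        with pytest.raises(ValueError):
            units_required(VAR, 1.0, 0)


def eac_oracle(price: float, r: float, life: int, maintenance: float) -> float:
    """Solve for the annuity A with sum_{t=1..L} A/(1+r)^t = price."""
    factor = sum((1 + r) ** -t for t in range(1, life + 1))
    return price / factor + maintenance


class TestEquivalentAnnualCost:
    def test_straight_line_limit_at_zero_interest(self):
        assert equivalent_annual_cost(1000, 0.0, 5) == pytest.approx(200.0)

    def test_pure_maintenance(self):
        assert equivalent_annual_cost(0, 0.04, 10, 2000) == pytest.approx(2000.0)

    def test_matches_discounted_sum_oracle(self):
        got = equivalent_annual_cost(100_000, 0.04, 5, 2000)
        assert got == pytest.approx(eac_oracle(100_000, 0.04, 5, 2000), rel=1e-12)
        assert got == pytest.approx(24462.71, abs=0.01)

    @given(price=st.floats(0, 1e7), r=st.floats(0.001, 0.2),
           life=st.integers(1, 30), m=st.floats(0, 1e5))
    @settings(max_examples=100, deadline=None)
    def test_closed_form_equals_sum_inversion(self, price, r, life, m):
        assert equivalent_annual_cost(price, r, life, m) == pytest.approx(
            eac_oracle(price, r, life, m), rel=1e-9, abs=1e-9)

    def test_annuity_limit_r_to_zero(self):
        # capital recovery converges to straight-line depreciation
        assert equivalent_annual_cost(1000, 1e-8, 8) == pytest.approx(
            1000 / 8, rel=1e-6)

    def test_lifetime_below_one_year_rejected(self):
        with pytest.raises(ValueError):
            equivalent_annual_cost(1000, 0.04, 0.5)


def _unit_item(price=10.0, step=4, behavior=VAR, category=CostCategory.CONSUMABLES,
               **kw):
    return ResourceLineItem(id="x", step=step, category=category,
                            behavior=behavior, valuation=ValuationKind.UNIT_PRICE,
                            currency="USD", unit_price=price, **kw)


class TestItemCost:
    def test_variable_cost_is_batch_invariant(self):
        item = _unit_item(10.0)
        costs = {n: item_cost_per_sample(item, ModelParams(batch_size=n))
                 for n in (1, 12, 64)}
        assert all(c == pytest.approx(10.0) for c in costs.values())

    def test_fixed_annual_cost_divided_by_yearly_samples(self):
        item = _unit_item(62_400.0, behavior=FIX)
        p = ModelParams(batch_size=12, runs_per_year=52)
        assert item_cost_per_sample(item, p) == pytest.approx(100.0)

    def test_step_fixed_block_price(self):
        sf = CostBehavior(kind=BehaviorKind.STEP_FIXED, block_capacity=8)
        item = _unit_item(80.0, behavior=sf)
        got = item_cost_per_sample(item, ModelParams(batch_size=12))
        assert got == pytest.approx(2 * 80 / 12)

    def test_space_and_license_routes(self):
        from seqcost import Space
        space = ResourceLineItem(
            id="s", step=2, category=CostCategory.EQUIPMENT, behavior=FIX,
            valuation=ValuationKind.SPACE, currency="USD",
            space=Space(area_m2=10, rate_per_m2_year=100),
            allocation_weight=0.5)
        assert annual_fixed_cost(space, ModelParams()) == pytest.approx(500.0)
        license_ = _unit_item(12_000.0, behavior=FIX,
                              category=CostCategory.SOFTWARE_STORAGE)
        assert annual_fixed_cost(license_, ModelParams()) == pytest.approx(12_000.0)

    def test_equipment_allocation_weight_halves_eac(self):
        from seqcost import Amortization
        item = ResourceLineItem(
            id="e", step=5, category=CostCategory.EQUIPMENT, behavior=FIX,
            valuation=ValuationKind.EQUIPMENT, currency="USD",
            amortization=Amortization(purchase_price=100_000,
                                      lifetime_years=Bounded.of(5),
                                      annual_maintenance=2000),
            allocation_weight=0.5)
        assert annual_fixed_cost(item, ModelParams()) == pytest.approx(
            24462.71 / 2, abs=0.01)

    @pytest.mark.parametrize("gb,price,years,expected", [
        (0.0, 1.0, 10, 0.0),
        (10.0, 0.5, 10, 50.0),
        (1.0, 1.0, 1, 1.0),
    ])
    def test_storage_cost_over_retention_horizon(self, gb, price, years, expected):
        item = ResourceLineItem(
            id="st", step=9, category=CostCategory.SOFTWARE_STORAGE, behavior=VAR,
            valuation=ValuationKind.STORAGE, currency="USD",
            storage=Storage(gb_per_sample=Bounded.of(gb), price_per_gb_year=price,
                            horizon_years=years))
        assert storage_cost_per_sample(item, ModelParams()) == pytest.approx(expected)
        # storage is per sample, independent of batch size
        assert item_cost_per_sample(item, ModelParams(batch_size=37)) == \
            pytest.approx(expected)


class TestCostMatrix:
    def test_empty_inventory_gives_zero_matrix(self):
        m = compute_matrix(Inventory(items=()), ModelParams())
        assert m.grand_total == 0.0
        assert (m.per_sample.values == 0).all()
        assert (m.step_share() == 0).all()

    @pytest.mark.parametrize("seed", range(12))
    def test_additivity_and_normalization(self, seed):
        inv = synthetic_inventory(seed, n_items=25)
        m = compute_matrix(inv, ModelParams())
        assert (m.per_sample.values >= 0).all()
        assert m.grand_total == pytest.approx(m.step_total.sum(), rel=1e-9)
        assert m.grand_total == pytest.approx(
            1.2 * m.category_total.sum(), rel=1e-9)
        assert m.overhead_total == pytest.approx(
            0.2 * m.category_total.sum(), rel=1e-9)
        assert m.step_share().sum() == pytest.approx(100.0)
        assert m.category_share().sum() + m.overhead_total / m.grand_total * 100 \
            == pytest.approx(100.0)

    def test_deterministic(self):
        inv = synthetic_inventory(7, n_items=15)
        a = compute_matrix(inv, ModelParams())
        b = compute_matrix(inv, ModelParams())
        assert a.per_sample.equals(b.per_sample)

    @pytest.mark.parametrize("k", [0.5, 2.0, 13.7])
    def test_homogeneity_under_price_scaling(self, k):
        from seqcost.scenario import _scale_valuation
        inv = synthetic_inventory(11, n_items=30)
        scaled = inv.with_items(_scale_valuation(it, k) for it in inv.items)
        m0 = compute_matrix(inv, ModelParams())
        m1 = compute_matrix(scaled, ModelParams())
        assert m1.grand_total == pytest.approx(k * m0.grand_total, rel=1e-9)
        assert (m1.per_sample.values ==
                pytest.approx(k * m0.per_sample.values, rel=1e-9))

    def test_variable_only_inventory_is_batch_invariant(self):
        inv = synthetic_inventory(3, n_items=20,
                                  mix={"variable": 1.0, "fixed": 0, "step_fixed": 0})
        totals = [compute_matrix(inv, ModelParams(batch_size=n)).grand_total
                  for n in (1, 12, 64)]
        assert totals[0] == pytest.approx(totals[1], rel=1e-12)
        assert totals[0] == pytest.approx(totals[2], rel=1e-12)

    def test_fixed_only_per_sample_cost_halves_when_batch_doubles(self):
        inv = synthetic_inventory(5, n_items=20,
                                  mix={"variable": 0, "fixed": 1.0, "step_fixed": 0})
        # storage items are per-sample regardless of behavior; exclude
        inv = inv.with_items(it for it in inv.items
                             if it.valuation is not ValuationKind.STORAGE)
        t12 = compute_matrix(inv, ModelParams(batch_size=12)).grand_total
        t24 = compute_matrix(inv, ModelParams(batch_size=24)).grand_total
        assert t24 == pytest.approx(t12 / 2, rel=1e-12)

    def test_step_fixed_sawtooth_nonincreasing_on_common_multiples(self):
        inv = synthetic_inventory(9, n_items=25,
                                  mix={"variable": 0.3, "fixed": 0.2, "step_fixed": 0.5})
        caps = [it.behavior.block_capacity for it in inv.items
                if it.behavior.kind is BehaviorKind.STEP_FIXED]
        lcm = math.lcm(*caps)
        totals = [compute_matrix(inv, ModelParams(batch_size=k * lcm)).grand_total
                  for k in (1, 2, 3, 4)]
        assert all(a >= b - 1e-9 for a, b in zip(totals, totals[1:]))
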