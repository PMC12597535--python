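"""Scenario layer: adjustments, exclusions, weights, investments."""

import pytest

from seqcost import (CostCategory, Investment, ModelParams, ScenarioSpec,
                     apply_scenario, compare, compute_matrix, read_scenario,
                     run_scenario, synthetic_inventory)
from seqcost.fixtures import scenario_path
from importlib.resources import as_file


def test_identity_scenario_is_a_noop(calibrated, params):
    result = run_scenario(ScenarioSpec(name="identity"), calibrated, params)
    assert result.matrix.per_sample.equals(result.base_matrix.per_sample)
    assert result.pct_change_total == 0.0


def test_category_price_adjustment_touches_only_that_category(calibrated, params):
    spec = ScenarioSpec(name="half consumables",
                        price_adjustments={"consumables": -50})
    r = run_scenario(spec, calibrated, params)
    base, new = r.base_matrix, r.matrix
    assert new.category_total[CostCategory.CONSUMABLES] == pytest.approx(
        base.category_total[CostCategory.CONSUMABLES] / 2, rel=1e-12)
    for cat in (CostCategory.PERSONNEL, CostCategory.EQUIPMENT,
                CostCategory.SOFTWARE_STORAGE):
        assert new.category_total[cat] == pytest.approx(
            base.category_total[cat], rel=1e-12)


def test_item_level_adjustment(calibrated, params):
    spec = ScenarioSpec(price_adjustments={"flow_cell": 25})
    inv2, _ = apply_scenario(spec, calibrated, params)
    fc0 = next(i for i in calibrated.items if i.id == "flow_cell")
    fc1 = next(i for i in inv2.items if i.id == "flow_cell")
    assert fc1.unit_price == pytest.approx(fc0.unit_price * 1.25)
    # originals untouched
    assert fc0.unit_price == 986.40


def test_minus_then_plus_composes_multiplicatively(calibrated, params):
    p = 30.0
    spec = ScenarioSpec(price_adjustments={"personnel": -p})
    inv1, _ = apply_scenario(spec, calibrated, params)
    inv2, _ = apply_scenario(ScenarioSpec(price_adjustments={"personnel": p}),
                             inv1, params)
    m0 = compute_matrix(calibrated, params)
    m2 = compute_matrix(inv2, params)
    factor = (1 - p / 100) * (1 + p / 100)
    assert m2.category_total[CostCategory.PERSONNEL] == pytest.approx(
        factor * m0.category_total[CostCategory.PERSONNEL], rel=1e-9)


def test_step_exclusion_subtracts_exactly_that_step(calibrated, params):
    base = compute_matrix(calibrated, params)
    r = run_scenario(ScenarioSpec(excluded_steps=frozenset({8})), calibrated, params)
    assert not any(i.step == 8 for (i) in
                   apply_scenario(ScenarioSpec(excluded_steps=frozenset({8})),
                                  calibrated, params)[0].items)
    assert r.matrix.grand_total == pytest.approx(
        base.grand_total - base.step_total[8], rel=1e-12)


def test_step_weights_scale_direct_costs_and_overhead_follows(calibrated, params):
    r = run_scenario(ScenarioSpec(step_weights={4: 1.10}), calibrated, params)
    base = r.base_matrix
    assert r.matrix.step_total[4] == pytest.approx(1.10 * base.step_total[4])
    assert r.matrix.step_total[3] == pytest.approx(base.step_total[3])
    assert r.matrix.overhead[4] == pytest.approx(1.10 * base.overhead[4])


def test_investment_adds_total_over_amortization_samples_with_overhead(
        calibrated, params):
    spec = ScenarioSpec(investments=(
        Investment(label="dev", total_cost=62_400.0, currency="USD",
                   amortization_samples=624),))
    r = run_scenario(spec, calibrated, params)
    added = r.matrix.grand_total - r.base_matrix.grand_total
    assert added == pytest.approx(62_400.0 / 624 * 1.2, rel=1e-12)
    # investments land in software/storage
    delta = (r.matrix.category_total[CostCategory.SOFTWARE_STORAGE]
             - r.base_matrix.category_total[CostCategory.SOFTWARE_STORAGE])
    assert delta == pytest.approx(100.0, rel=1e-12)


def test_batch_and_estimate_overrides(calibrated, params):
    spec = ScenarioSpec(batch_size_override=24)
    _, p2 = apply_scenario(spec, calibrated, params)
    assert p2.batch_size == 24 and params.batch_size == 12


def test_unknown_targets_are_rejected(calibrated, params):
    with pytest.raises(ValueError, match="unknown price-adjustment"):
        run_scenario(ScenarioSpec(price_adjustments={"nonexistent": -10}),
                     calibrated, params)
    with pytest.raises(Exception):
        ScenarioSpec(excluded_steps=frozenset({12}))._validate_against(calibrated)


class TestCompare:
    def test_identity_is_zero(self, base_matrix):
        assert compare(base_matrix, base_matrix)["total"] == 0.0

    def test_printed_ratio(self, base_matrix):
        scaled = base_matrix.scaled_steps({s: 2622.0 / 2944.8 for s in range(1, 10)})
        got = compare(scaled, base_matrix)["total"]
        assert got == pytest.approx(100 * (2622.0 / 2944.8 - 1), rel=1e-9)
        assert round(got) == -11

    def test_doubling_prices_is_plus_100(self, calibrated, params):
        from seqcost.scenario import _scale_valuation
        doubled = calibrated.with_items(_scale_valuation(i, 2.0)
                                        for i in calibrated.items)
        m0 = compute_matrix(calibrated, params)
        m1 = compute_matrix(doubled, params)
        assert compare(m1, m0)["total"] == pytest.approx(100.0, rel=1e-9)

    def test_zero_base_is_undefined(self, base_matrix, params):
        from seqcost import Inventory, empty_matrix
        with pytest.raises(ZeroDivisionError):
            compare(base_matrix, empty_matrix(params))


def test_bundled_scenario_files_parse_and_run(calibrated, params):
    base = compute_matrix(calibrated, params)
    for name in ("consumables_minus50.yaml", "double_batch.yaml",
                 "exclude_step8.yaml", "controls_steps_3_5.yaml",
                 "bioinformatic_development.yaml", "automated_library_prep.yaml"):
        with as_file(scenario_path(name)) as path:
            spec = read_scenario(path)
        r = run_scenario(spec, calibrated, params, base_matrix=base)
        assert r.matrix.grand_total > 0


def test_automated_variant_runs_at_higher_batch(calibrated, params):
    with as_file(scenario_path("automated_library_prep.yaml")) as path:
        spec = read_scenario(path)
    r = run_scenario(spec, calibrated, params)
    assert r.matrix.batch_size == 16
    # robot appears as amortized equipment in the variant
    inv, _ = apply_scenario(spec, calibrated, params)
    assert any(i.id == "libprep_robot" for i in inv.items)
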