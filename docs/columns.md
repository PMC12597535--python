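# Inventory file schema

One CSV row per resource line item (UTF-8, comma-separated, header row,
dot decimal separator). Money columns are valued in the row's
`currency`. Bounded parameters use three columns; a missing `*_low` /
`*_high` defaults to the base value.

## Required columns

| column | type | meaning |
|---|---|---|
| `id` | text | unique line-item identifier |
| `step` | int 1–9 | workflow step (1 analysis request and sampling … 9 storage) |
| `category` | text | `consumables`, `personnel`, `equipment`, `software_storage` |
| `behavior` | text | `variable`, `fixed`, `step_fixed` |
| `valuation_kind` | text | `unit_price`, `personnel`, `equipment`, `space`, `storage` |
| `currency` | text | `NOK`, `USD` or `EUR` |

## Optional columns

| column | applies to | meaning |
|---|---|---|
| `block_capacity` | step_fixed | samples per block (required for step_fixed) |
| `qty_low/base/high` | unit_price | units per sample (variable), per block (step_fixed) or per year (fixed); default 1 |
| `unit_price` | unit_price | price per unit (annual fee when fixed) |
| `role` | personnel | profession label (aggregation key for capacity flags) |
| `annual_salary` | personnel | annual salary before loading |
| `employer_contribution_rate` | personnel | default 0.13 |
| `social_security_rate` | personnel | default 0.25 |
| `annual_hours` | personnel | contracted hours per year |
| `time_low_h/base_h/high_h` | personnel | working time per occurrence, hours |
| `purchase_price` | equipment | instrument purchase price |
| `lifetime_low_y/base_y/high_y` | equipment | expected lifetime, years (≥ 1) |
| `annual_maintenance` | equipment | maintenance per year |
| `area_m2` | space | floor area |
| `rate_per_m2_year` | space | internal annual rate per m² |
| `storage_gb_low/base/high` | storage | data volume per sample, GB |
| `price_per_gb_year` | storage | storage price per GB per year |
| `storage_years` | storage | retention horizon, default 10 |
| `allocation_weight` | all | fraction in (0, 1] attributed to this workflow; default 1 |
| `note` | all | free text |

## Model-parameter YAML

Keys of `ModelParams`: `batch_size` (default 12), `runs_per_year` (52),
`overhead_rate` (0.20), `interest_rate` (0.04), `nok_per_usd` (10.7433),
`nok_per_eur` (11.6276), `report_currency` (`USD`), `estimate`
(`low` / `base` / `high`).

## Scenario YAML

Keys of `ScenarioSpec`: `name`; `price_adjustments` (category name or
item id → percent change, e.g. `consumables: -50`); `step_weights`
(step index → multiplier, e.g. `4: 1.10`); `excluded_steps` (list);
`batch_size_override`; `estimate_override`; `investments` (list of
`label`, `total_cost`, `currency`, `amortization_samples`);
`variant_inventory` (path to an inventory CSV, relative to the scenario
file). Examples in `src/seqcost/fixtures_data/scenarios/`.
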