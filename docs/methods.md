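# Methods

## Scope and perspective

`seqcost` implements deterministic, bottom-up (micro)costing of a
diagnostic genomic-profiling workflow from a health-care perspective:
every resource is identified as a line item, measured in natural units
(kits, hours, m², GB, years) and valued with a unit cost. The output is
the expected cost per patient sample, decomposed over nine workflow
steps and four direct cost categories, at a configurable weekly batch
size. There is no stochastic modeling: uncertainty is handled by
deterministic low/base/high parameter bounds and by scenario analysis.

## Cost behaviors

Every item is variable, fixed, or step-fixed.

* Variable items scale with the batch size `n`; their per-sample cost is
  independent of `n`.
* Step-fixed items are consumed in blocks of `block_capacity` samples
  (tube strips with eight wells, per-run reagent kits and flow cells,
  per-batch protocol work). A batch needs `ceil(n / capacity)` blocks,
  so the per-sample cost is a declining sawtooth; it is monotone only
  along batch sizes that are common multiples of all capacities, which
  is how the monotonicity tests are phrased.
* Fixed items are annual amounts divided by the yearly sample count
  `N = n × runs_per_year`. The workflow runs weekly, so `runs_per_year`
  defaults to 52 and `N = 624` in the base case; it is configurable for
  other cadences.

Personnel time is costed per task occurrence; whether a task is
per-sample or per-batch is encoded entirely by its behavior (a variable
task with hours per sample versus a step-fixed task with hours per
block), not by a special personnel rule.

## Valuation routes

* **Unit price** — quantity × price; with FIXED behavior this is an
  annual fee (software licenses).
* **Personnel** — loaded hourly wage × working time. The loading
  compounds multiplicatively: salary × (1 + employer contribution,
  default 13%) × (1 + social security, default 25%) / annual hours.
  Additive loading (1 + 0.13 + 0.25) was the alternative; the
  multiplicative form matches Norwegian unit-cost practice and both
  rates are per-role inputs, so either convention can be expressed.
  Annual working hours is an explicit input per role (1695 h in the
  bundled fixture); no national default is hard-coded.
* **Equipment** — the standard capital-recovery annuity
  `EAC = P·r/(1 − (1+r)^−L) + M` at interest rate `r` (default 4%/year)
  over lifetime `L`, plus *undiscounted* annual maintenance `M`; at
  `r = 0` the straight-line limit `P/L + M` applies, and the
  implementation is continuous in `r` (verified down to `r = 1e-8`).
  Discounting maintenance as well would lower equipment costs slightly;
  it was not adopted because maintenance is a recurring annual charge,
  not a capital outlay.
* **Space** — floor area × internal per-m² annual rate, a fixed annual
  cost grouped under equipment.
* **Storage** — GB per sample × price per GB-year × retention horizon
  (default 10 years). The price is interpreted *per gigabyte-year*; a
  one-off per-gigabyte interpretation would simply set the horizon to 1.
  Storage is charged in full against the sample at analysis time, so it
  is per-sample (batch-invariant) even though it accrues over a decade.

An allocation weight `α ∈ (0, 1]` prorates resources shared with other
assays or departments (e.g. the sequencer at 0.8). Overhead is a flat
markup (default 20%) applied uniformly to every direct cost including
storage; it is always derived, never stored.

## Estimates and currencies

Working times, equipment lifetimes, storage volume and quantities carry
`low ≤ base ≤ high` bounds on the *parameter value*; the global
`estimate` switch selects one bound for every parameter at once. Note
the LOW estimate selects the shorter equipment lifetime, which raises
the annuity — the switch is a parameter-bound selector, not a guaranteed
cost ordering (for the bundled fixture, where personnel times dominate
the bounds, totals are nonetheless ordered LOW < BASE < HIGH).
Consumables quantities in the fixture have degenerate bounds, so the
estimate switch leaves consumables unchanged.

Monies are tagged NOK, USD or EUR, stored as entered, and converted only
at valuation/reporting through fixed 2024 reference rates
(10.7433 NOK/USD, 11.6276 NOK/EUR); conversion is a linear bijection, so
results are currency-consistent.

## Scenarios

Scenarios are declarative, never mutate their inputs, and compose in a
fixed order: variant-inventory substitution, percentage price
adjustments (category- or item-targeted, sequentially multiplicative),
batch/estimate overrides, step exclusion, investments, then per-step
percentage weights. Step weights multiply the *direct* step costs, so
overhead follows proportionally — numerically identical to weighting
overhead-inclusive step totals under a flat markup, and simpler to
audit. Investments (e.g. one-off bioinformatic development work) are
appended as fixed annual software/storage fees chosen so the per-sample
charge at the scenario's batch size equals `total / amortization_samples`
(default: one year of samples); like any fixed cost they dilute at
higher batch sizes. The automation variant is a full alternate
inventory (robot as amortized equipment, reduced per-run engineer time,
larger block capacity), not ad-hoc switches.

## Rounding

All internal arithmetic is unrounded. Rendering rounds once, half away
from zero, to whole dollars and whole percents; rendered totals are
recomputed from unrounded values before rounding, so a printed row may
differ by ±1 from the sum of its printed cells. This mirrors how such
tables are typically published and is why the bundled fixture's printed
rows are internally inconsistent by ±1.

## The calibrated fixture

The bundled inventory reproduces a published base-case cost table for
TruSight Oncology 500 profiling at 12 samples/week (grand total $2944,
library preparation $1014, overhead $491, consumables/personnel shares
34%/35%), and its scenario analysis (−21% under a 50% consumables
discount, $2695 without the tumor-board step, ≈$3136 with a 10%
surcharge on the wet-lab steps, equipment $187 and −11% at batch 24).
The printed cells alone do not pin down the unrounded values — summing
the printed cells and applying 20% overhead gives 2944.8, which rounds
to 2945, not the published 2944 — so `scripts/build_fixture.py` places
each cell inside its rounding band such that all cell, row, column,
total and scenario constraints hold simultaneously, then synthesizes
line items around round-valued anchors (list prices, salaries,
instrument prices) with one solved free parameter per cell, and
re-verifies every constraint through the engine before writing the CSV.
The committed CSV is static data; tests verify it but never re-fit it.

What the fixture does *not* claim: the split of a cell into individual
kits, tasks and instruments is illustrative (real vendor prices and
wages are confidential), as is the automated-library-prep variant, which
is deliberately not calibrated to any published figure because the
robot's cost inputs are not public. Low/high fixture bounds are
plausible elicitation-style ranges (times −25%/+50%, lifetimes 8/10/12
years, storage 30/43/60 GB), not calibrated to published low/high totals.

## Synthetic inventories and the oracle

`synthetic_inventory(seed, n_items, mix)` draws reproducible random
inventories (behavior mix, categories, valuation routes, currencies,
weights, integer lifetimes) that satisfy every domain invariant. It
emulates the *structure* of real inventories, not their magnitudes or
correlations (e.g. real consumables cluster in library prep, real wages
are role-consistent across steps), so property tests establish the
arithmetic of the engine — additivity, homogeneity, batch invariances,
oracle equivalence — not the realism of any particular cost level.

`oracle_total` recomputes the grand total naively and independently of
the engine: the annuity is obtained by inverting an explicit discounted
payment sum `Σ A/(1+r)^t = P` (hence integer lifetimes in generated
data), block counts use integer ceiling arithmetic, and currency
conversion goes literally through NOK. Engine and oracle agree to 1e-9
relative over 500 seeded inventories across batch sizes and estimates.

## Problem sizes and numerics

All computations are closed-form arithmetic on at most a few dozen line
items; the full test suite and the reproduction script run in seconds.
Property suites use 500 seeded random inventories (8 items each) for
oracle equivalence and 20–40 items elsewhere — sizes chosen to exercise
every route combination many times over, since the arithmetic has no
scale-dependent behavior. Comparisons use 1e-9 relative tolerance for
equalities and 1e-12 where exactness is structural (e.g. fixed-cost
halving). Degenerate inputs: an empty inventory yields a valid all-zero
matrix with shares defined as 0; percent change against a zero base
total is an error; batch sizes below 1 and lifetimes below one year are
rejected.

## Known limitations

* Overhead as a flat markup does not model non-laboratory space or
  administration in detail.
* Personnel capacity flags are threshold checks on weekly hours, not a
  queueing or scheduling model; capacities are user inputs.
* Extrapolating to very large batch sizes ignores reorganization,
  training and coordination costs that real upscaling would incur.
* No probabilistic sensitivity analysis; bounds are deterministic
  switches applied globally.
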