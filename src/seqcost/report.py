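"""Rendering of cost matrices and scenario tables.

All internal arithmetic is unrounded; this module applies the single
rounding pass — half away from zero, to whole currency units and whole
percents.  Rendered step totals and the grand total are recomputed from
unrounded values before rounding, so a rendered row may differ by +-1
from the sum of its rendered cells.  Rendering is pure: the same matrix
always produces byte-identical output.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .engine import CostMatrix
from .inventory import STEP_LABELS, CostCategory
from .scenario import ScenarioResult

CATEGORY_HEADERS = {
    CostCategory.CONSUMABLES: "consumables",
    CostCategory.PERSONNEL: "personnel",
    CostCategory.EQUIPMENT: "equipment",
    CostCategory.SOFTWARE_STORAGE: "software_storage",
}


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (so 0.5 -> 1, -0.5 -> -1)."""
    scale = 10.0 ** ndigits
    scaled = x * scale
    return math.copysign(math.floor(abs(scaled) + 0.5), scaled) / scale


@dataclass(frozen=True)
class RoundingPolicy:
    money_digits: int = 0
    percent_digits: int = 0

    def money(self, x: float) -> int | float:
        r = round_half_away(x, self.money_digits)
        return int(r) if self.money_digits == 0 else r

    def percent(self, x: float) -> int | float:
        r = round_half_away(x, self.percent_digits)
        return int(r) if self.percent_digits == 0 else r


DEFAULT_POLICY = RoundingPolicy()


def render_base_table(m: CostMatrix, policy: RoundingPolicy = DEFAULT_POLICY) -> pd.DataFrame:
    """Base-case table: nine step rows plus a totals row and a share row.

    Columns: the four direct categories, overhead, total per sample and
    percent of total.  Every cell is independently rounded from the
    unrounded matrix.
    """
    rows = []
    cats = list(m.per_sample.columns)
    for step in m.per_sample.index:
        row: dict = {"step": f"{step}: {STEP_LABELS[step]}"}
        for cat in cats:
            row[CATEGORY_HEADERS[cat]] = policy.money(m.per_sample.loc[step, cat])
        row["overhead"] = policy.money(m.overhead[step])
        row["total"] = policy.money(m.step_total[step])
        row["pct_of_total"] = policy.percent(m.step_share()[step])
        rows.append(row)

    totals: dict = {"step": "Total costs"}
    for cat in cats:
        totals[CATEGORY_HEADERS[cat]] = policy.money(m.category_total[cat])
    totals["overhead"] = policy.money(m.overhead_total)
    totals["total"] = policy.money(m.grand_total)
    totals["pct_of_total"] = policy.percent(100.0) if m.grand_total else 0
    rows.append(totals)

    shares: dict = {"step": "% of total costs"}
    cat_share = m.category_share()
    for cat in cats:
        shares[CATEGORY_HEADERS[cat]] = policy.percent(cat_share[cat])
    oh_share = 0.0 if m.grand_total == 0 else m.overhead_total / m.grand_total * 100.0
    shares["overhead"] = policy.percent(oh_share)
    shares["total"] = policy.percent(100.0) if m.grand_total else 0
    shares["pct_of_total"] = ""
    rows.append(shares)
    return pd.DataFrame(rows)


def render_scenario_table(results: Sequence[ScenarioResult],
                          policy: RoundingPolicy = DEFAULT_POLICY) -> pd.DataFrame:
    """Scenario table: the shared base case first, then one row per
    scenario with category cells, total, and percent change vs base."""
    if not results:
        raise ValueError("no scenario results to render")
    base = results[0].base_matrix
    for r in results:
        if r.base_matrix is not base and not r.base_matrix.per_sample.equals(base.per_sample):
            raise ValueError("scenario results do not share one base matrix")

    def row_for(name: str, m: CostMatrix, change) -> dict:
        row: dict = {"scenario": name}
        for cat in m.per_sample.columns:
            row[CATEGORY_HEADERS[cat]] = policy.money(m.category_total[cat])
        row["overhead"] = policy.money(m.overhead_total)
        row["total"] = policy.money(m.grand_total)
        row["pct_change"] = change
        return row

    rows = [row_for("Base case", base, "reference")]
    for r in results:
        rows.append(row_for(r.name, r.matrix, policy.percent(r.pct_change_total)))
    return pd.DataFrame(rows)


def to_text(table: pd.DataFrame) -> str:
    """Aligned plain-text rendering."""
    return table.to_string(index=False) + "\n"


def to_csv(table: pd.DataFrame, path: str | Path | None = None) -> str | None:
    if path is None:
        buf = io.StringIO()
        table.to_csv(buf, index=False)
        return buf.getvalue()
    table.to_csv(path, index=False)
    return None


def to_json(table: pd.DataFrame, path: str | Path | None = None) -> str | None:
    payload = json.dumps(table.to_dict(orient="records"), indent=2, default=str)
    if path is None:
        return payload
    Path(path).write_text(payload + "\n", encoding="utf-8")
    return None


def matrix_to_json(m: CostMatrix, policy: RoundingPolicy | None = None) -> dict:
    """Machine-readable matrix export (unrounded unless a policy is given)."""
    money = (lambda x: x) if policy is None else policy.money
    return {
        "currency": m.currency,
        "batch_size": m.batch_size,
        "overhead_rate": m.overhead_rate,
        "per_sample": {
            str(step): {CATEGORY_HEADERS[cat]: money(m.per_sample.loc[step, cat])
                        for cat in m.per_sample.columns}
            for step in m.per_sample.index
        },
        "step_total": {str(s): money(m.step_total[s]) for s in m.per_sample.index},
        "category_total": {CATEGORY_HEADERS[c]: money(m.category_total[c])
                           for c in m.per_sample.columns},
        "overhead_total": money(m.overhead_total),
        "grand_total": money(m.grand_total),
    }
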