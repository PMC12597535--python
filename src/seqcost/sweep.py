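"""Batch-size sweeps and personnel capacity flags.

Sweeping the weekly batch size shows how fixed and step-fixed costs
dilute with throughput while variable costs stay flat, and where
personnel workload outgrows weekly capacity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .engine import CostMatrix, compute_matrix, units_required
from .inventory import (BehaviorKind, Inventory, ModelParams, ValuationKind)

#: Default grid of simulated weekly batch sizes.
DEFAULT_SIZES: tuple[int, ...] = (1, 4, 8, 12, 16, 24, 32, 64)


@dataclass(frozen=True)
class CapacityFlag:
    batch_size: int
    role: str
    load_hours: float
    capacity_hours: float

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (f"n={self.batch_size}: role {self.role!r} needs "
                f"{self.load_hours:.1f} h/week but has {self.capacity_hours:.1f}")


@dataclass(frozen=True)
class SweepResult:
    batch_sizes: tuple[int, ...]
    matrices: dict[int, CostMatrix]
    personnel_hours: dict[int, dict[str, float]]
    flags: tuple[CapacityFlag, ...]

    def long_frame(self) -> pd.DataFrame:
        """Long-format (batch_size, step, category, cost_per_sample) table
        suitable for stacked-area plotting."""
        rows = []
        for n in self.batch_sizes:
            ps = self.matrices[n].per_sample
            for step in ps.index:
                for cat in ps.columns:
                    rows.append({"batch_size": n, "step": step,
                                 "category": cat.value,
                                 "cost_per_sample": ps.loc[step, cat]})
        return pd.DataFrame(rows)

    def totals_frame(self) -> pd.DataFrame:
        """Per-batch-size category totals, overhead and grand total."""
        rows = []
        for n in self.batch_sizes:
            m = self.matrices[n]
            row: dict = {"batch_size": n}
            row.update({cat.value: m.category_total[cat] for cat in m.per_sample.columns})
            row["overhead"] = m.overhead_total
            row["total"] = m.grand_total
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.long_frame().to_csv(path, index=False)


def personnel_load(inv: Inventory, n: int) -> dict[str, float]:
    """Weekly personnel hours per role for a batch of ``n`` samples.

    Sums working time x units required over all personnel tasks; the
    base working-time estimate is used.
    """
    load: dict[str, float] = {}
    for it in inv.items:
        if it.valuation is not ValuationKind.PERSONNEL:
            continue
        if it.behavior.kind is BehaviorKind.FIXED:
            continue
        units = units_required(it.behavior, it.quantity.base, n)
        hours = units * it.time_hours.base
        load[it.personnel.role] = load.get(it.personnel.role, 0.0) + hours
    return load


def sweep(inv: Inventory, params: ModelParams,
          sizes: Sequence[int] = DEFAULT_SIZES,
          role_capacity_hours: Optional[Mapping[str, float]] = None) -> SweepResult:
    """Recompute the cost matrix independently at every batch size.

    ``role_capacity_hours`` optionally maps roles to available weekly
    hours; a role whose load exceeds its capacity is flagged at that and
    (because load is non-decreasing in n) every larger batch size.
    """
    if not sizes:
        raise ValueError("sizes must be nonempty")
    if any(n < 1 for n in sizes):
        raise ValueError("batch sizes must be >= 1")
    sizes = tuple(sizes)
    matrices: dict[int, CostMatrix] = {}
    hours: dict[int, dict[str, float]] = {}
    flags: list[CapacityFlag] = []
    for n in sizes:
        p = params.model_copy(update={"batch_size": n})
        matrices[n] = compute_matrix(inv, p)
        hours[n] = personnel_load(inv, n)
        if role_capacity_hours:
            for role, cap in role_capacity_hours.items():
                if hours[n].get(role, 0.0) > cap:
                    flags.append(CapacityFlag(batch_size=n, role=role,
                                              load_hours=hours[n][role],
                                              capacity_hours=cap))
    return SweepResult(batch_sizes=sizes, matrices=matrices,
                       personnel_hours=hours, flags=tuple(flags))


def plot_sweep(result: SweepResult, path: str | Path) -> None:  # pragma: no cover
    """Render the cost decomposition as a stacked-area chart (SVG/PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = result.totals_frame().set_index("batch_size")
    fig, ax = plt.subplots(figsize=(7, 4.5))
    cats = [c for c in df.columns if c != "total"]
    ax.stackplot(df.index, [df[c] for c in cats], labels=cats)
    ax.set_xlabel("weekly batch size")
    ax.set_ylabel("cost per sample")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
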