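"""Comparative cost-effectiveness metrics: NMB, ICER, dominance, frontier."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "StrategyResult",
    "Comparison",
    "nmb",
    "compare",
    "frontier",
    "results_table",
]


@dataclass(frozen=True)
class StrategyResult:
    """Total expected discounted cost (USD) and effectiveness (QALYs) of one strategy."""

    name: str
    cost: float
    qalys: float

    def __post_init__(self) -> None:
        if self.cost < 0:
            raise ValueError(f"cost must be nonnegative, got {self.cost}")
        if self.qalys < 0:
            raise ValueError(f"QALYs must be nonnegative, got {self.qalys}")


@dataclass(frozen=True)
class Comparison:
    """Incremental quantities of a new strategy against a reference.

    ``category`` is ``dominant`` (cheaper and at least as effective),
    ``dominated`` (the mirror), ``equal`` (identical), or ``icer`` with the
    ratio filled in.  Negative ICERs are never reported as ratios — the
    dominance category carries that information.
    """

    new: str
    reference: str
    delta_cost: float
    delta_qalys: float
    category: str
    icer: float | None
    inmb: float
    wtp: float


def nmb(result: StrategyResult, wtp: float) -> float:
    """Net monetary benefit: the strategy's value at a willingness to pay."""
    if wtp < 0:
        raise ValueError(f"wtp must be nonnegative, got {wtp}")
    return wtp * result.qalys - result.cost


def compare(new: StrategyResult, reference: StrategyResult, wtp: float) -> Comparison:
    """Incremental comparison of ``new`` against ``reference``.

    INMB = wtp x dQALYs - dCost; a positive INMB favors the new strategy.
    """
    if new.name == reference.name:
        raise ValueError("compared strategies must have distinct names")
    d_cost = new.cost - reference.cost
    d_qalys = new.qalys - reference.qalys
    inmb = wtp * d_qalys - d_cost

    icer: float | None = None
    if d_cost == 0.0 and d_qalys == 0.0:
        category = "equal"
    elif (d_cost < 0 and d_qalys >= 0) or (d_cost <= 0 and d_qalys > 0):
        category = "dominant"
    elif (d_cost > 0 and d_qalys <= 0) or (d_cost >= 0 and d_qalys < 0):
        category = "dominated"
    else:  # both increments share a sign
        category = "icer"
        icer = d_cost / d_qalys
    return Comparison(
        new=new.name,
        reference=reference.name,
        delta_cost=d_cost,
        delta_qalys=d_qalys,
        category=category,
        icer=icer,
        inmb=inmb,
        wtp=wtp,
    )


def frontier(results: Iterable[StrategyResult]) -> list[StrategyResult]:
    """Efficiency frontier with strong and extended dominance removed.

    Strategies are ordered by increasing effectiveness (ties broken by
    lower cost, then name for determinism).  A strategy is strongly
    dominated if another is at least as effective for lower cost (or more
    effective at equal cost); extended dominance is eliminated by the
    standard sweep that removes any strategy whose incremental ratio
    exceeds that of the next, more effective one.
    """
    pool = sorted(results, key=lambda r: (r.qalys, r.cost, r.name))
    if not pool:
        raise ValueError("frontier requires at least one strategy")

    def strongly_dominated(r: StrategyResult) -> bool:
        for s in pool:
            if s is r:
                continue
            if s.cost <= r.cost and s.qalys >= r.qalys:
                if s.cost < r.cost or s.qalys > r.qalys:
                    return True
                if s.name < r.name:  # exact tie: keep one, deterministically
                    return True
        return False

    kept = [r for r in pool if not strongly_dominated(r)]

    # extended dominance: sequential ICERs must be increasing
    changed = True
    while changed and len(kept) > 2:
        changed = False
        for i in range(1, len(kept) - 1):
            lo, mid, hi = kept[i - 1], kept[i], kept[i + 1]
            icer_lo = (mid.cost - lo.cost) / (mid.qalys - lo.qalys)
            icer_hi = (hi.cost - mid.cost) / (hi.qalys - mid.qalys)
            if icer_lo >= icer_hi:
                del kept[i]
                changed = True
                break
    return kept


def results_table(
    results: Sequence[StrategyResult], wtp: float, reference: str = "CTA"
) -> pd.DataFrame:
    """Full-precision results table: one row per strategy vs the reference."""
    by_name = {r.name: r for r in results}
    if reference not in by_name:
        raise ValueError(f"reference strategy {reference!r} not among results")
    ref = by_name[reference]
    rows = []
    for r in results:
        row: dict[str, object] = {
            "strategy": r.name,
            "cost": r.cost,
            "qalys": r.qalys,
            "nmb": nmb(r, wtp),
            "comparator": "" if r.name == reference else reference,
            "delta_cost": float("nan"),
            "delta_qalys": float("nan"),
            "icer_or_category": "",
            "inmb": float("nan"),
        }
        if r.name != reference:
            c = compare(r, ref, wtp)
            row.update(
                delta_cost=c.delta_cost,
                delta_qalys=c.delta_qalys,
                icer_or_category=c.category if c.icer is None else f"{c.icer:.2f}",
                inmb=c.inmb,
            )
        rows.append(row)
    return pd.DataFrame(rows)
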