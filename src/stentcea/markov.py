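"""Three-state annual-cycle Markov cohort engine with discounting.

States: alive without symptomatic stenosis requiring therapy, alive with
symptomatic stenosis requiring therapy, dead (absorbing).  Each cycle is
one year — all published transition probabilities are annual.  The cohort's
occupancy vector is propagated through the transition matrix, accruing
per-cycle discounted costs (state yearly costs plus an angioplasty event
charge on each new in-model stenosis) and QALYs (state utilities).

Modelling choices that the published analysis leaves open are collected in
:class:`ModelOptions` as named conventions; the patient-level
microsimulation (`stentcea.microsim`) shares :func:`cycle_rewards` so that
both engines account rewards identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import mortality
from .parameters import ParameterSet

__all__ = [
    "STATE_NAMES",
    "ModelOptions",
    "MarkovTrace",
    "discount_factor",
    "transition_matrix",
    "cycle_rewards",
    "run_cohort",
]

STATE_NAMES = ("NoStenosis", "Stenosis", "Dead")
NO_STENOSIS, STENOSIS, DEAD = 0, 1, 2

_RISK_RULES = ("multiplicative", "additive")
_RESOLUTIONS = ("tunnel", "persistent")
_MORTALITY_MODES = ("constant", "age-specific")
_ACCRUALS = ("end", "start", "half")


@dataclass(frozen=True)
class ModelOptions:
    """Named conventions for everything the source model leaves unstated.

    entry_convention
        branch-to-state mapping at model entry (see
        ``decision_tree.initial_state_distribution``).  Default
        ``positives-decrement``: every test-positive patient carries a
        first-year decrement — the only mapping under which the perfusion
        strategy gains QALYs over angiography, as the published results
        report.
    risk_rule
        how a state's disease and other-cause death risks combine.
        ``multiplicative`` (default) composes survival,
        1-(1-p_disease)(1-p_other), guaranteeing a valid row; ``additive``
        sums the risks (spreadsheet-style replication) and errors if the
        row overflows.
    stenosis_resolution
        ``tunnel`` (default): one symptomatic year with the higher cost and
        lower utility plus an angioplasty event charge, then back to the
        well state — consistent with the new-stenosis rate being a yearly
        revascularization rate.  ``persistent``: the symptomatic state is
        permanent.
    mortality
        ``constant`` (default) uses the fixed other-cause probability;
        ``age-specific`` uses the synthetic age schedule, recomputing the
        matrix each cycle.
    accrual
        reward timing.  Rewards are earned by the state occupied during
        the cycle (occupancy at cycle start, so the entry distribution is
        lived through in cycle one).  ``end`` (default) discounts the
        cycle-t reward at exponent t; ``start`` at t-1; ``half`` applies
        the half-cycle correction — mean of start and end occupancy,
        discounted at mid-cycle.
    charge_event_ptca
        charge the angioplasty cost on each well-to-stenosis transition
        (default on).  Entry-time stenosis occupancy is never charged — the
        acute treatment cost is already applied by the decision tree.
    """

    entry_convention: str = "positives-decrement"
    risk_rule: str = "multiplicative"
    stenosis_resolution: str = "tunnel"
    mortality: str = "constant"
    accrual: str = "end"
    charge_event_ptca: bool = True

    def __post_init__(self) -> None:
        from .decision_tree import ENTRY_CONVENTIONS

        for value, allowed, label in (
            (self.entry_convention, ENTRY_CONVENTIONS, "entry_convention"),
            (self.risk_rule, _RISK_RULES, "risk_rule"),
            (self.stenosis_resolution, _RESOLUTIONS, "stenosis_resolution"),
            (self.mortality, _MORTALITY_MODES, "mortality"),
            (self.accrual, _ACCRUALS, "accrual"),
        ):
            if value not in allowed:
                raise ValueError(f"unknown {label} {value!r}; expected one of {allowed}")


def discount_factor(t: float, rate: float) -> float:
    """Present-value factor (1+rate)^-t for a cash flow or QALY at year t."""
    if t < 0:
        raise ValueError(f"time must be nonnegative, got {t}")
    if rate < 0:
        raise ValueError(f"rate must be nonnegative, got {rate}")
    return (1.0 + rate) ** (-t)


def _combined_death(p_disease: float, p_other: float, rule: str) -> float:
    if rule == "multiplicative":
        return 1.0 - (1.0 - p_disease) * (1.0 - p_other)
    return p_disease + p_other


def transition_matrix(
    age: float, params: ParameterSet, options: ModelOptions = ModelOptions()
) -> np.ndarray:
    """Annual transition matrix at a given age, rows summing to one."""
    if not params.start_age <= age <= 110.0:
        raise ValueError(f"age {age} outside [{params.start_age}, 110]")
    if options.mortality == "age-specific":
        p_other = mortality.other_cause_death_probability(age)
    else:
        p_other = params.p_death_other

    d_well = _combined_death(params.p_death_no_stenosis, p_other, options.risk_rule)
    d_sick = _combined_death(params.p_death_stenosis, p_other, options.risk_rule)
    if options.risk_rule == "additive":
        if d_well + params.p_new_stenosis > 1.0 or d_sick > 1.0:
            raise ValueError(
                "additive risks exceed 1 in a row; use risk_rule='multiplicative'"
            )
        to_stenosis = params.p_new_stenosis
    else:
        # new stenosis arises among that cycle's survivors
        to_stenosis = (1.0 - d_well) * params.p_new_stenosis

    m = np.zeros((3, 3))
    m[NO_STENOSIS] = (1.0 - d_well - to_stenosis, to_stenosis, d_well)
    if options.stenosis_resolution == "tunnel":
        m[STENOSIS] = (1.0 - d_sick, 0.0, d_sick)
    else:
        m[STENOSIS] = (0.0, 1.0 - d_sick, d_sick)
    m[DEAD] = (0.0, 0.0, 1.0)
    return m


def cycle_rewards(
    occ_start: np.ndarray,
    occ_end: np.ndarray,
    new_stenosis_flow: np.ndarray | float,
    cycle: int,
    params: ParameterSet,
    options: ModelOptions,
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Discounted (cost, QALY) increment for one cycle.

    Shared verbatim by the cohort engine and the microsimulation: occupancy
    arguments broadcast over a leading patient axis, where the
    microsimulation passes one-hot state indicators and realized transition
    flags instead of expected masses.
    """
    if options.accrual == "end":
        occ_used, exponent = occ_start, float(cycle)
    elif options.accrual == "start":
        occ_used, exponent = occ_start, float(cycle - 1)
    else:  # half-cycle correction
        occ_used, exponent = 0.5 * (occ_start + occ_end), cycle - 0.5

    state_costs = np.array(
        [params.yearly_cost_no_stenosis, params.yearly_cost_stenosis, 0.0]
    )
    utilities = np.array(
        [params.utility_no_stenosis, params.utility_stenosis, params.utility_dead]
    )
    cost = occ_used @ state_costs
    if options.charge_event_ptca:
        cost = cost + np.asarray(new_stenosis_flow) * params.cost_ptca
    df = discount_factor(exponent, params.discount_rate)
    return cost * df, (occ_used @ utilities) * df


@dataclass
class MarkovTrace:
    """Per-cycle occupancy and discounted reward accrual of one cohort run."""

    occupancy: np.ndarray  # (horizon+1, 3), row 0 = entry
    cost_increments: np.ndarray  # (horizon,), discounted USD per cycle
    qaly_increments: np.ndarray  # (horizon,), discounted QALYs per cycle
    start_age: float
    cumulative_cost: np.ndarray = field(init=False)
    cumulative_qalys: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.cumulative_cost = np.cumsum(self.cost_increments)
        self.cumulative_qalys = np.cumsum(self.qaly_increments)

    @property
    def total_cost(self) -> float:
        return float(self.cost_increments.sum())

    @property
    def total_qalys(self) -> float:
        return float(self.qaly_increments.sum())

    @property
    def cycles(self) -> int:
        return len(self.cost_increments)

    def to_frame(self) -> pd.DataFrame:
        """Tabular trace: one row per cycle (cycle 0 = entry, no accrual)."""
        n = self.cycles
        cycle = np.arange(n + 1)
        return pd.DataFrame(
            {
                "cycle": cycle,
                "age": self.start_age + cycle,
                "occ_no_stenosis": self.occupancy[:, NO_STENOSIS],
                "occ_stenosis": self.occupancy[:, STENOSIS],
                "occ_dead": self.occupancy[:, DEAD],
                "disc_cost_increment": np.concatenate(([0.0], self.cost_increments)),
                "disc_qaly_increment": np.concatenate(([0.0], self.qaly_increments)),
                "cumulative_cost": np.concatenate(([0.0], self.cumulative_cost)),
                "cumulative_qalys": np.concatenate(([0.0], self.cumulative_qalys)),
            }
        )


def run_cohort(
    initial: Sequence[float] | np.ndarray,
    params: ParameterSet,
    options: ModelOptions = ModelOptions(),
) -> MarkovTrace:
    """Propagate a cohort from an initial state distribution over the horizon.

    Returns the full trace; totals are the discounted per-patient long-term
    cost and QALYs (acute decision-tree costs are not included here).
    """
    occ = np.asarray(initial, dtype=float)
    if occ.shape != (3,):
        raise ValueError(f"initial distribution must have 3 entries, got {occ.shape}")
    if np.any(occ < 0) or abs(occ.sum() - 1.0) > 1e-9:
        raise ValueError(f"initial distribution must be nonnegative and sum to 1: {occ}")

    n = params.horizon_cycles
    occupancy = np.empty((n + 1, 3))
    occupancy[0] = occ
    costs = np.empty(n)
    qalys = np.empty(n)

    age_varying = options.mortality == "age-specific"
    m = transition_matrix(params.start_age, params, options)
    for t in range(1, n + 1):
        if age_varying:
            m = transition_matrix(params.start_age + t - 1, params, options)
        occ_start = occupancy[t - 1]
        flow = occ_start[NO_STENOSIS] * m[NO_STENOSIS, STENOSIS]
        occ_end = occ_start @ m
        occupancy[t] = occ_end
        costs[t - 1], qalys[t - 1] = cycle_rewards(
            occ_start, occ_end, flow, t, params, options
        )
    return MarkovTrace(occupancy, costs, qalys, params.start_age)
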