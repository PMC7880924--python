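"""Patient-level microsimulation oracle and synthetic accuracy-study generator.

The cohort engine propagates expected state masses; this module realizes
the same process patient by patient — draw the true disease status from
the pre-test probability, the test result from the strategy's accuracy,
charge the branch's acute cost, then walk the yearly state chain under the
identical transition probabilities.  Reward accounting goes through the
cohort engine's own ``cycle_rewards`` (with one-hot occupancy indicators),
so any disagreement between the two engines isolates the transition logic.
By the law of large numbers the microsimulation means must match the
cohort totals; the equivalence check is the module's reason to exist.

Randomness: patient ``i`` consumes row ``i`` of a fixed-shape uniform
matrix drawn under the master seed, with fixed column slots (disease
status, test result, one per cycle).  Results are therefore reproducible
and independent of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decision_tree import StrategySpec
from .markov import DEAD, NO_STENOSIS, STENOSIS, ModelOptions, cycle_rewards, transition_matrix
from .parameters import ParameterSet

__all__ = ["StudyTable", "MicrosimResult", "simulate_patients", "generate_study"]


@dataclass(frozen=True)
class StudyTable:
    """2x2 diagnostic-outcome counts of one test in a finite cohort."""

    test: str
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def prevalence_hat(self) -> float:
        return (self.tp + self.fn) / self.n

    @property
    def sensitivity_hat(self) -> float:
        diseased = self.tp + self.fn
        return self.tp / diseased if diseased else float("nan")

    @property
    def specificity_hat(self) -> float:
        healthy = self.fp + self.tn
        return self.tn / healthy if healthy else float("nan")


def generate_study(
    n: int,
    prevalence: float,
    sensitivity: float,
    specificity: float,
    seed: int,
    test: str = "synthetic",
) -> StudyTable:
    """Simulate one diagnostic-accuracy study of ``n`` patients.

    The diseased count is binomial at the prevalence; true positives and
    true negatives are binomial at the test's sensitivity and specificity
    within their margins.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    for name, v in (
        ("prevalence", prevalence),
        ("sensitivity", sensitivity),
        ("specificity", specificity),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    rng = np.random.default_rng(seed)
    diseased = int(rng.binomial(n, prevalence))
    tp = int(rng.binomial(diseased, sensitivity)) if diseased else 0
    tn = int(rng.binomial(n - diseased, specificity)) if n - diseased else 0
    return StudyTable(test=test, tp=tp, fn=diseased - tp, fp=n - diseased - tn, tn=tn)


@dataclass
class MicrosimResult:
    """Per-patient trajectories and their Monte Carlo summaries."""

    strategy: str
    truth: np.ndarray  # bool, diseased at entry
    test_positive: np.ndarray  # bool
    acute_cost: np.ndarray  # USD, charged undiscounted at entry
    states: np.ndarray  # (n, horizon+1) int8, column 0 = entry state
    disc_cost: np.ndarray  # discounted long-term USD per patient
    disc_qalys: np.ndarray  # discounted QALYs per patient

    @property
    def n(self) -> int:
        return len(self.truth)

    @property
    def total_cost(self) -> np.ndarray:
        return self.acute_cost + self.disc_cost

    @property
    def mean_cost(self) -> float:
        return float(self.total_cost.mean())

    @property
    def mean_qalys(self) -> float:
        return float(self.disc_qalys.mean())

    @property
    def se_cost(self) -> float:
        return float(self.total_cost.std(ddof=1) / np.sqrt(self.n))

    @property
    def se_qalys(self) -> float:
        return float(self.disc_qalys.std(ddof=1) / np.sqrt(self.n))

    def to_frame(self) -> pd.DataFrame:
        years_alive = (self.states[:, 1:] != DEAD).sum(axis=1)
        return pd.DataFrame(
            {
                "patient": np.arange(self.n),
                "truth": self.truth.astype(int),
                "test_result": self.test_positive.astype(int),
                "acute_cost": self.acute_cost,
                "years_alive": years_alive,
                "disc_cost": self.disc_cost,
                "disc_qalys": self.disc_qalys,
            }
        )


def _entry_states(
    truth: np.ndarray, positive: np.ndarray, convention: str
) -> np.ndarray:
    if convention == "all-treated":
        sick = np.zeros_like(truth, dtype=bool)
    elif convention == "fn-diseased":
        sick = truth & ~positive
    elif convention == "positives-decrement":
        sick = positive
    else:  # mirror of decision_tree.initial_state_distribution
        raise ValueError(f"unknown entry convention {convention!r}")
    return np.where(sick, STENOSIS, NO_STENOSIS).astype(np.int8)


def simulate_patients(
    n: int,
    strategy: StrategySpec,
    params: ParameterSet,
    options: ModelOptions = ModelOptions(),
    seed: int = 0,
) -> MicrosimResult:
    """Simulate ``n`` independent patient trajectories under one strategy."""
    if n < 1:
        raise ValueError(f"need at least 1 patient, got {n}")
    horizon = params.horizon_cycles
    u = np.random.default_rng(seed).random((n, 2 + horizon))

    truth = u[:, 0] < params.pretest_probability
    p_positive = np.where(truth, strategy.sensitivity, 1.0 - strategy.specificity)
    positive = u[:, 1] < p_positive

    acute = np.full(n, strategy.imaging_cost)
    acute[truth & positive] += params.cost_ptca
    acute[truth & ~positive] += params.cost_ptca_delayed
    acute[~truth & positive] += params.cost_ica

    states = np.empty((n, horizon + 1), dtype=np.int8)
    states[:, 0] = _entry_states(truth, positive, options.entry_convention)
    disc_cost = np.zeros(n)
    disc_qalys = np.zeros(n)

    eye = np.eye(3)
    age_varying = options.mortality == "age-specific"
    m = transition_matrix(params.start_age, params, options)
    for t in range(1, horizon + 1):
        if age_varying:
            m = transition_matrix(params.start_age + t - 1, params, options)
        current = states[:, t - 1]
        cum = np.cumsum(m[current], axis=1)  # (n, 3)
        uu = u[:, 1 + t]
        nxt = (uu >= cum[:, 0]).astype(np.int8) + (uu >= cum[:, 1]).astype(np.int8)
        states[:, t] = nxt
        flow = ((current == NO_STENOSIS) & (nxt == STENOSIS)).astype(float)
        cost_inc, qaly_inc = cycle_rewards(
            eye[current], eye[nxt], flow, t, params, options
        )
        disc_cost += cost_inc
        disc_qalys += qaly_inc

    return MicrosimResult(
        strategy=strategy.name,
        truth=truth,
        test_positive=positive,
        acute_cost=acute,
        states=states,
        disc_cost=disc_cost,
        disc_qalys=disc_qalys,
    )
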