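"""Diagnostic decision tree: from test accuracy to branch probabilities,
acute costs and the cohort's initial health-state distribution.

Patients enter with a pre-test probability of a stenosis requiring
angioplasty, undergo one imaging strategy and land on one of four branches.
A true positive receives a timely angioplasty, a false negative a delayed
(more expensive) one, a false positive an unnecessary invasive angiography,
and a true negative no acute intervention.  The branch masses then seed the
Markov cohort according to a named entry convention (the published model
does not state the branch-to-state mapping, so all plausible readings are
first-class options; see ``docs/methods.md``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import ParameterSet

__all__ = [
    "BranchProbabilities",
    "StrategySpec",
    "ENTRY_CONVENTIONS",
    "classify",
    "acute_cost",
    "combine_tests_or_rule",
    "initial_state_distribution",
    "strategies_from_params",
]

STRATEGY_NAMES = ("CTA", "CTP", "CTA_CTP")

#: recognized branch-to-state entry conventions
ENTRY_CONVENTIONS = ("all-treated", "fn-diseased", "positives-decrement")


@dataclass(frozen=True)
class BranchProbabilities:
    """Joint probabilities of the four diagnostic outcomes for one strategy."""

    tp: float
    fn: float
    fp: float
    tn: float

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        total = self.tp + self.fn + self.fp + self.tn
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"branch probabilities must sum to 1, got {total!r}")

    @property
    def prevalence(self) -> float:
        return self.tp + self.fn

    @property
    def positive_rate(self) -> float:
        return self.tp + self.fp


@dataclass(frozen=True)
class StrategySpec:
    """Name, test accuracy and acute imaging cost of one diagnostic strategy."""

    name: str
    sensitivity: float
    specificity: float
    imaging_cost: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.sensitivity <= 1.0:
            raise ValueError(f"sensitivity must be in [0, 1], got {self.sensitivity}")
        if not 0.0 <= self.specificity <= 1.0:
            raise ValueError(f"specificity must be in [0, 1], got {self.specificity}")
        if self.imaging_cost < 0:
            raise ValueError(f"imaging cost must be nonnegative, got {self.imaging_cost}")


def classify(
    prevalence: float, sensitivity: float, specificity: float
) -> BranchProbabilities:
    """Joint TP/FN/FP/TN probabilities of one test at a given prevalence."""
    for name, v in (
        ("prevalence", prevalence),
        ("sensitivity", sensitivity),
        ("specificity", specificity),
    ):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return BranchProbabilities(
        tp=prevalence * sensitivity,
        fn=prevalence * (1.0 - sensitivity),
        fp=(1.0 - prevalence) * (1.0 - specificity),
        tn=(1.0 - prevalence) * specificity,
    )


def acute_cost(
    branches: BranchProbabilities, strategy: StrategySpec, params: ParameterSet
) -> float:
    """Expected time-0 cost: imaging plus the branch-contingent procedures.

    TP -> timely angioplasty; FN -> delayed angioplasty (1.3x, extended
    stay); FP -> invasive angiography without revascularization; TN -> no
    acute cost.  Charged undiscounted at model entry.
    """
    return (
        strategy.imaging_cost
        + branches.tp * params.cost_ptca
        + branches.fn * params.cost_ptca_delayed
        + branches.fp * params.cost_ica
    )


def combine_tests_or_rule(
    sens_a: float, spec_a: float, sens_b: float, spec_b: float
) -> tuple[float, float]:
    """Accuracy of two tests combined under a discordant-positive rule.

    Any positive on either test counts as positive, so sensitivity composes
    as 1-(1-sA)(1-sB) and specificity as sA*sB (assuming conditional
    independence).  Diagnostic cross-check only: the combined strategy in
    the pipeline uses the source study's empirical values by default, which
    differ from this independence rule (0.429 vs 0.305 specificity at the
    base inputs) because the two scans' errors are correlated in practice.
    """
    for v in (sens_a, spec_a, sens_b, spec_b):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"accuracies must be in [0, 1], got {v}")
    sensitivity = 1.0 - (1.0 - sens_a) * (1.0 - sens_b)
    specificity = spec_a * spec_b
    return sensitivity, specificity


def initial_state_distribution(
    branches: BranchProbabilities, convention: str
) -> np.ndarray:
    """Initial occupancy over (NoStenosis, Stenosis, Dead) for a branch mix.

    Conventions:

    ``all-treated``
        every branch enters the well state — treatment at entry (or absence
        of disease) restores everyone.
    ``fn-diseased``
        only untreated diseased patients (false negatives) spend their
        first cycle symptomatic.
    ``positives-decrement``
        every test-positive patient (treated or worked up invasively)
        carries a first-year quality-of-life and cost decrement.

    Nobody enters dead.
    """
    if convention == "all-treated":
        stenosis = 0.0
    elif convention == "fn-diseased":
        stenosis = branches.fn
    elif convention == "positives-decrement":
        stenosis = branches.positive_rate
    else:
        raise ValueError(
            f"unknown entry convention {convention!r}; expected one of {ENTRY_CONVENTIONS}"
        )
    return np.array([1.0 - stenosis, stenosis, 0.0])


def strategies_from_params(params: ParameterSet) -> dict[str, StrategySpec]:
    """The three compared strategies with accuracies and imaging costs."""
    return {
        "CTA": StrategySpec("CTA", params.sens_cta, params.spec_cta, params.cost_cta),
        "CTP": StrategySpec("CTP", params.sens_ctp, params.spec_ctp, params.cost_ctp),
        "CTA_CTP": StrategySpec(
            "CTA_CTP", params.sens_combo, params.spec_combo, params.combo_imaging_cost
        ),
    }
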