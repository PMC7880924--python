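"""End-to-end strategy evaluation: decision tree -> Markov cohort -> totals.

One call site ties the stages together so the base case, the deterministic
sensitivity analysis and every probabilistic draw all run the identical
code path.
"""

from __future__ import annotations

from .cea import Comparison, StrategyResult, compare
from .decision_tree import (
    StrategySpec,
    acute_cost,
    classify,
    initial_state_distribution,
    strategies_from_params,
)
from .markov import ModelOptions, run_cohort
from .parameters import ParameterSet

__all__ = ["evaluate_strategy", "evaluate_strategies", "inmb_ctp_vs_cta"]


def evaluate_strategy(
    strategy: StrategySpec,
    params: ParameterSet,
    options: ModelOptions = ModelOptions(),
) -> StrategyResult:
    """Total expected discounted cost and QALYs of one diagnostic strategy.

    Acute decision-tree costs are charged undiscounted at entry; long-term
    costs and QALYs accrue through the Markov cohort.
    """
    branches = classify(
        params.pretest_probability, strategy.sensitivity, strategy.specificity
    )
    entry_cost = acute_cost(branches, strategy, params)
    initial = initial_state_distribution(branches, options.entry_convention)
    trace = run_cohort(initial, params, options)
    return StrategyResult(
        name=strategy.name,
        cost=entry_cost + trace.total_cost,
        qalys=trace.total_qalys,
    )


def evaluate_strategies(
    params: ParameterSet, options: ModelOptions = ModelOptions()
) -> dict[str, StrategyResult]:
    """Evaluate the three compared strategies on one shared parameter set."""
    return {
        name: evaluate_strategy(spec, params, options)
        for name, spec in strategies_from_params(params).items()
    }


def inmb_ctp_vs_cta(
    params: ParameterSet,
    options: ModelOptions = ModelOptions(),
    wtp: float | None = None,
) -> Comparison:
    """Incremental comparison of the perfusion strategy against angiography."""
    results = evaluate_strategies(params, options)
    return compare(results["CTP"], results["CTA"], params.wtp if wtp is None else wtp)
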