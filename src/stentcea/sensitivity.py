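"""Deterministic (one-way / tornado) and probabilistic sensitivity analysis.

The one-way analysis re-runs the whole pipeline along a grid for a single
parameter (1.3x-linked partners follow their source while the cost link is
on) and reports the incremental net monetary benefit of perfusion imaging
versus angiography at each point.  The probabilistic analysis draws every
distributed parameter independently per iteration — one RNG substream per
iteration under a master seed, so the sample sequence is reproducible and
independent of evaluation order — and summarizes the share of iterations
in which perfusion imaging is cost-effective, plus the acceptability curve
over a willingness-to-pay grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .markov import ModelOptions
from .parameters import DistributionSpec, ParameterSet
from .pipeline import evaluate_strategies

__all__ = [
    "DsaRange",
    "DsaResult",
    "PsaResult",
    "one_way_dsa",
    "tornado",
    "psa",
    "default_dsa_ranges",
]


@dataclass(frozen=True)
class DsaRange:
    """Evaluation range for one parameter in the one-way analysis."""

    parameter: str
    low: float
    high: float
    n_points: int = 11
    must_bracket: bool = True

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError(f"low {self.low} exceeds high {self.high}")
        if self.n_points < 2:
            raise ValueError(f"need at least 2 evaluation points, got {self.n_points}")

    def grid(self) -> np.ndarray:
        return np.linspace(self.low, self.high, self.n_points)


@dataclass(frozen=True)
class DsaResult:
    """INMB of CTP vs CTA along one parameter's grid."""

    parameter: str
    values: np.ndarray
    inmb: np.ndarray

    @property
    def inmb_low(self) -> float:
        return float(self.inmb[0])

    @property
    def inmb_high(self) -> float:
        return float(self.inmb[-1])

    @property
    def span(self) -> float:
        return abs(self.inmb_high - self.inmb_low)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"value": self.values, "inmb": self.inmb})


def one_way_dsa(
    dsa_range: DsaRange,
    params: ParameterSet,
    options: ModelOptions = ModelOptions(),
    wtp: float | None = None,
) -> DsaResult:
    """Re-run the pipeline along one parameter's grid; INMB CTP vs CTA per point."""
    name = dsa_range.parameter
    if name not in type(params).model_fields:
        raise KeyError(f"unknown parameter for one-way analysis: {name!r}")
    base = getattr(params, name)
    if dsa_range.must_bracket and not dsa_range.low <= base <= dsa_range.high:
        raise ValueError(
            f"range [{dsa_range.low}, {dsa_range.high}] does not bracket the "
            f"base value {base} of {name!r}"
        )
    wtp_used = params.wtp if wtp is None else wtp
    inmb = np.empty(dsa_range.n_points)
    values = dsa_range.grid()
    for i, v in enumerate(values):
        results = evaluate_strategies(params.with_values(**{name: float(v)}), options)
        c = results["CTP"], results["CTA"]
        inmb[i] = wtp_used * (c[0].qalys - c[1].qalys) - (c[0].cost - c[1].cost)
    return DsaResult(name, values, inmb)


def tornado(
    ranges: Sequence[DsaRange],
    params: ParameterSet,
    options: ModelOptions = ModelOptions(),
    wtp: float | None = None,
) -> pd.DataFrame:
    """One row per parameter, sorted by descending INMB span (name tie-break)."""
    if not ranges:
        raise ValueError("tornado requires at least one range")
    rows = []
    for r in ranges:
        res = one_way_dsa(r, params, options, wtp)
        rows.append(
            {
                "parameter": res.parameter,
                "inmb_low": res.inmb_low,
                "inmb_high": res.inmb_high,
                "span": res.span,
            }
        )
    frame = pd.DataFrame(rows)
    return frame.sort_values(
        ["span", "parameter"], ascending=[False, True], ignore_index=True
    )


def default_dsa_ranges(params: ParameterSet) -> list[DsaRange]:
    """The published one-way ranges: perfusion-scan cost $370-570, invasive
    angiography +/-$500, angioplasty +/-$1000, pre-test probability 40-80%,
    and each test accuracy +/-5 percentage points clipped to [0, 1]."""

    def pm(name: str, delta: float) -> DsaRange:
        base = getattr(params, name)
        return DsaRange(name, max(base - delta, 0.0), min(base + delta, 1.0))

    return [
        DsaRange("cost_ctp", 370.0, 570.0),
        DsaRange("cost_ica", params.cost_ica - 500.0, params.cost_ica + 500.0),
        DsaRange("cost_ptca", params.cost_ptca - 1000.0, params.cost_ptca + 1000.0),
        DsaRange("pretest_probability", 0.40, 0.80),
        pm("sens_cta", 0.05),
        pm("spec_cta", 0.05),
        pm("sens_ctp", 0.05),
        pm("spec_ctp", 0.05),
    ]


@dataclass
class PsaResult:
    """Monte Carlo samples and summaries of the probabilistic analysis."""

    samples: pd.DataFrame  # one row per iteration
    wtp: float
    ceac: pd.DataFrame = field(repr=False)  # wtp grid -> P(cost-effective)

    @property
    def fraction_cost_effective(self) -> float:
        """Share of iterations with INMB(CTP vs CTA) > 0 at the analysis WTP."""
        return float((self.samples["inmb"] > 0).mean())


def psa(
    n_iterations: int,
    seed: int,
    params: ParameterSet,
    dists: Mapping[str, DistributionSpec],
    options: ModelOptions = ModelOptions(),
    wtp: float | None = None,
    wtp_grid: Sequence[float] | None = None,
) -> PsaResult:
    """Probabilistic sensitivity analysis over the given parameter distributions.

    Each iteration draws one value per distributed parameter (independent
    draws, fixed alphabetical order within the iteration's own substream),
    evaluates all three strategies on the identical draw, and records the
    incremental quantities of CTP versus CTA.
    """
    if n_iterations < 1:
        raise ValueError(f"need at least 1 iteration, got {n_iterations}")
    for name, spec in dists.items():
        if name not in type(params).model_fields:
            raise KeyError(f"distribution given for unknown parameter {name!r}")
        if not isinstance(spec, DistributionSpec):
            raise TypeError(f"invalid distribution spec for {name!r}: {spec!r}")
    names = sorted(dists)
    wtp_used = params.wtp if wtp is None else wtp
    children = np.random.SeedSequence(seed).spawn(n_iterations)

    columns = {
        key: np.empty(n_iterations)
        for key in (
            "cost_cta",
            "qalys_cta",
            "cost_ctp",
            "qalys_ctp",
            "cost_cta_ctp",
            "qalys_cta_ctp",
        )
    }
    for i in range(n_iterations):
        rng = np.random.Generator(np.random.PCG64(children[i]))
        draws = {name: float(dists[name].sample(rng)) for name in names}
        results = evaluate_strategies(params.with_values(**draws), options)
        columns["cost_cta"][i] = results["CTA"].cost
        columns["qalys_cta"][i] = results["CTA"].qalys
        columns["cost_ctp"][i] = results["CTP"].cost
        columns["qalys_ctp"][i] = results["CTP"].qalys
        columns["cost_cta_ctp"][i] = results["CTA_CTP"].cost
        columns["qalys_cta_ctp"][i] = results["CTA_CTP"].qalys

    delta_cost = columns["cost_ctp"] - columns["cost_cta"]
    delta_qalys = columns["qalys_ctp"] - columns["qalys_cta"]
    samples = pd.DataFrame(
        {
            "iteration": np.arange(n_iterations),
            **columns,
            "delta_cost": delta_cost,
            "delta_qalys": delta_qalys,
            "inmb": wtp_used * delta_qalys - delta_cost,
        }
    )

    grid = (
        np.linspace(0.0, 200_000.0, 41) if wtp_grid is None else np.asarray(wtp_grid)
    )
    prob = [
        float((g * delta_qalys - delta_cost > 0).mean()) for g in grid
    ]
    ceac = pd.DataFrame({"wtp": grid, "probability_cost_effective": prob})
    return PsaResult(samples=samples, wtp=wtp_used, ceac=ceac)
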