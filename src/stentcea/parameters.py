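"""Model inputs: the validated parameter set and PSA sampling distributions.

Every quantity the model consumes lives in :class:`ParameterSet` — the
pre-test probability of a stenosis requiring angioplasty, per-strategy test
accuracies, acute and yearly costs (2019 USD), health-state utilities,
annual transition probabilities and the analysis settings (willingness to
pay, discount rate, horizon, start age).  Defaults are the published base
case for a cohort of stented patients worked up for suspected obstructive
CAD or in-stent restenosis.

Two derived costs are tied to their partners by a 1.3x assumption (a delayed
angioplasty costs 1.3x a timely one; a year lived with a relevant stenosis
costs 1.3x a year without).  While ``linked_cost_assumption`` is on
(default) those fields are recomputed from their partners at validation
time, so they track any override of the partner — in one-way sensitivity
analysis as well as in probabilistic draws.

For probabilistic sensitivity analysis each input carries a distribution:
beta for probabilities and utilities, gamma for costs.  The source
literature states the families but no dispersion, so hyperparameters are
method-of-moments fits from configurable effective sample sizes
(accuracy-type parameters: the n=150 diagnostic-accuracy cohort) and a
configurable coefficient of variation for costs.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "ParameterSet",
    "DistributionSpec",
    "load_parameters",
    "save_parameters",
    "fit_beta_moments",
    "fit_gamma_moments",
    "default_distributions",
]

#: factor linking the delayed-intervention and with-stenosis costs to their partners
LINK_FACTOR = 1.3


class ParameterSet(BaseModel):
    """All model inputs with their base-case values.

    Probabilities and utilities are constrained to [0, 1], costs to be
    nonnegative.  Unknown keys are rejected.  The model is immutable; use
    :meth:`with_values` to derive a modified copy (re-validated, so linked
    fields stay consistent).
    """

    model_config = ConfigDict(frozen=True, extra="forbid", validate_assignment=True)

    # cohort & analysis settings
    pretest_probability: float = Field(default=0.6267, ge=0.0, le=1.0)
    start_age: float = Field(default=65.0, ge=0.0, le=110.0)
    wtp: float = Field(default=100_000.0, ge=0.0)
    discount_rate: float = Field(default=0.03, ge=0.0)
    horizon_cycles: int = Field(default=10, ge=0)

    # diagnostic performances
    sens_cta: float = Field(default=1.000, ge=0.0, le=1.0)
    spec_cta: float = Field(default=0.386, ge=0.0, le=1.0)
    sens_ctp: float = Field(default=0.914, ge=0.0, le=1.0)
    spec_ctp: float = Field(default=0.789, ge=0.0, le=1.0)
    sens_combo: float = Field(default=1.000, ge=0.0, le=1.0)
    spec_combo: float = Field(default=0.429, ge=0.0, le=1.0)

    # acute costs (USD)
    cost_cta: float = Field(default=397.87, ge=0.0)
    cost_ctp: float = Field(default=470.31, ge=0.0)
    cost_combo: float | None = Field(default=None, ge=0.0)  # None -> cost_cta + cost_ctp
    cost_ica: float = Field(default=2810.00, ge=0.0)
    cost_ptca: float = Field(default=4678.00, ge=0.0)
    cost_ptca_delayed: float = Field(default=6081.40, ge=0.0)

    # long-term costs (USD per year)
    yearly_cost_no_stenosis: float = Field(default=5837.27, ge=0.0)
    yearly_cost_stenosis: float = Field(default=7588.45, ge=0.0)

    # utilities (QALY weight per year in state)
    utility_no_stenosis: float = Field(default=0.75, ge=0.0, le=1.0)
    utility_stenosis: float = Field(default=0.70, ge=0.0, le=1.0)
    utility_dead: float = Field(default=0.0, ge=0.0, le=0.0)

    # annual transition probabilities
    p_new_stenosis: float = Field(default=0.0264, ge=0.0, le=1.0)
    p_death_stenosis: float = Field(default=0.0230, ge=0.0, le=1.0)
    p_death_no_stenosis: float = Field(default=0.0232, ge=0.0, le=1.0)
    p_death_other: float = Field(default=0.0126, ge=0.0, le=1.0)

    # keep the 1.3x-linked fields tied to their partners
    linked_cost_assumption: bool = True

    @model_validator(mode="before")
    @classmethod
    def _apply_cost_links(cls, data: Any) -> Any:
        if not isinstance(data, dict):
            return data
        if data.get("linked_cost_assumption", True):
            ptca = data.get("cost_ptca", cls.model_fields["cost_ptca"].default)
            yearly = data.get(
                "yearly_cost_no_stenosis",
                cls.model_fields["yearly_cost_no_stenosis"].default,
            )
            data = dict(data)
            data["cost_ptca_delayed"] = LINK_FACTOR * float(ptca)
            data["yearly_cost_stenosis"] = LINK_FACTOR * float(yearly)
        return data

    @property
    def combo_imaging_cost(self) -> float:
        """Acute imaging cost of the combined strategy (both scans performed)."""
        if self.cost_combo is not None:
            return self.cost_combo
        return self.cost_cta + self.cost_ctp

    def with_values(self, **updates: Any) -> "ParameterSet":
        """Copy with the given fields replaced, re-validated.

        Linked 1.3x fields are recomputed from their partners when the link
        flag is on, so e.g. ``with_values(cost_ptca=5000)`` also moves
        ``cost_ptca_delayed`` to 6500.
        """
        unknown = set(updates) - set(type(self).model_fields)
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        data = self.model_dump()
        data.update(updates)
        return ParameterSet.model_validate(data)


def load_parameters(source: str | Path | Mapping[str, Any]) -> ParameterSet:
    """Build a validated :class:`ParameterSet` from a JSON file or mapping.

    Omitted keys take the base-case defaults; unknown keys raise; values out
    of range raise a validation error naming the field and bound.
    """
    if isinstance(source, Mapping):
        data: Mapping[str, Any] = source
    else:
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(f"configuration file not found: {path}")
        with open(path) as fh:
            data = json.load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"configuration root must be a JSON object: {path}")
    return ParameterSet.model_validate(dict(data))


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    """Write the parameter set as JSON (round-trips exactly through load)."""
    Path(path).write_text(json.dumps(params.model_dump(), indent=2) + "\n")


@dataclass(frozen=True)
class DistributionSpec:
    """One sampling distribution for the probabilistic sensitivity analysis.

    ``family`` is ``beta`` (probabilities, utilities), ``gamma`` (costs) or
    ``fixed`` (degenerate: the parameter is not sampled).
    """

    family: str
    hyperparameters: dict[str, float] = field(default_factory=dict)
    provenance: str = "fitted"

    def __post_init__(self) -> None:
        if self.family not in ("beta", "gamma", "fixed"):
            raise ValueError(f"unknown distribution family: {self.family!r}")
        if self.family == "beta":
            a, b = self.hyperparameters["alpha"], self.hyperparameters["beta"]
            if a <= 0 or b <= 0:
                raise ValueError("beta hyperparameters must be positive")
        elif self.family == "gamma":
            k, th = self.hyperparameters["shape"], self.hyperparameters["scale"]
            if k <= 0 or th <= 0:
                raise ValueError("gamma hyperparameters must be positive")
        else:
            if set(self.hyperparameters) != {"value"}:
                raise ValueError("a fixed spec has exactly one hyperparameter: value")

    def mean(self) -> float:
        h = self.hyperparameters
        if self.family == "beta":
            return h["alpha"] / (h["alpha"] + h["beta"])
        if self.family == "gamma":
            return h["shape"] * h["scale"]
        return h["value"]

    def sd(self) -> float:
        h = self.hyperparameters
        if self.family == "beta":
            a, b = h["alpha"], h["beta"]
            return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))
        if self.family == "gamma":
            return math.sqrt(h["shape"]) * h["scale"]
        return 0.0

    def sample(self, rng: np.random.Generator, size: int | None = None):
        h = self.hyperparameters
        if self.family == "beta":
            return rng.beta(h["alpha"], h["beta"], size=size)
        if self.family == "gamma":
            return rng.gamma(h["shape"], h["scale"], size=size)
        value = h["value"]
        return value if size is None else np.full(size, value)


def fit_beta_moments(mean: float, n_eff: float) -> DistributionSpec:
    """Beta spec by moment matching: alpha = mean*n_eff, beta = (1-mean)*n_eff.

    A degenerate mean (0 or 1) cannot carry a beta distribution; a fixed
    spec is returned with a warning.
    """
    if not 0.0 <= mean <= 1.0:
        raise ValueError(f"mean must be in [0, 1], got {mean}")
    if n_eff <= 0:
        raise ValueError(f"n_eff must be positive, got {n_eff}")
    if mean in (0.0, 1.0):
        warnings.warn(
            f"degenerate mean {mean}: returning a fixed spec instead of beta",
            stacklevel=2,
        )
        return DistributionSpec("fixed", {"value": mean}, provenance="fitted")
    return DistributionSpec(
        "beta", {"alpha": mean * n_eff, "beta": (1.0 - mean) * n_eff}
    )


def fit_gamma_moments(mean: float, se: float) -> DistributionSpec:
    """Gamma spec by moment matching: shape = (mean/se)^2, scale = se^2/mean."""
    if mean <= 0:
        raise ValueError(f"mean must be positive, got {mean}")
    if se <= 0:
        raise ValueError(f"se must be positive, got {se}")
    return DistributionSpec("gamma", {"shape": (mean / se) ** 2, "scale": se**2 / mean})


#: parameters sampled with the diagnostic-accuracy-study effective sample size
_ACCURACY_PARAMS: tuple[str, ...] = (
    "pretest_probability",
    "sens_cta",
    "spec_cta",
    "sens_ctp",
    "spec_ctp",
    "sens_combo",
    "spec_combo",
)

#: utilities and transition probabilities (smaller assumed evidence base)
_RATE_PARAMS: tuple[str, ...] = (
    "utility_no_stenosis",
    "utility_stenosis",
    "p_new_stenosis",
    "p_death_stenosis",
    "p_death_no_stenosis",
    "p_death_other",
)

#: independently sampled costs (the 1.3x-linked partners follow their source
#: draw while the link flag is on)
_COST_PARAMS: tuple[str, ...] = (
    "cost_cta",
    "cost_ctp",
    "cost_ica",
    "cost_ptca",
    "yearly_cost_no_stenosis",
)

_LINKED_COST_PARAMS: tuple[str, ...] = ("cost_ptca_delayed", "yearly_cost_stenosis")


def default_distributions(
    params: ParameterSet,
    *,
    n_eff_accuracy: float = 150.0,
    n_eff_rates: float = 100.0,
    cost_cv: float = 0.20,
) -> dict[str, DistributionSpec]:
    """Default PSA distributions for every input carrying a beta/gamma family.

    Probabilities and utilities get method-of-moments beta fits
    (diagnostic-accuracy parameters and prevalence at ``n_eff_accuracy``,
    the source cohort size; utilities and transition probabilities at
    ``n_eff_rates``); costs get gamma fits with standard error
    ``cost_cv`` x mean.  WTP, discount rate, horizon and start age are never
    sampled, nor is the zero utility of death.  While the cost link is on,
    the delayed-intervention and with-stenosis costs follow their sampled
    partners instead of being drawn independently.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate accuracies (1.0) -> fixed specs
        dists: dict[str, DistributionSpec] = {}
        for name in _ACCURACY_PARAMS:
            dists[name] = fit_beta_moments(getattr(params, name), n_eff_accuracy)
        for name in _RATE_PARAMS:
            dists[name] = fit_beta_moments(getattr(params, name), n_eff_rates)
        for name in _COST_PARAMS:
            mean = getattr(params, name)
            dists[name] = fit_gamma_moments(mean, cost_cv * mean)
        if not params.linked_cost_assumption:
            for name in _LINKED_COST_PARAMS:
                mean = getattr(params, name)
                dists[name] = fit_gamma_moments(mean, cost_cv * mean)
    return dists


def fixed_distributions(params: ParameterSet) -> dict[str, DistributionSpec]:
    """Zero-variance specs for every default-sampled parameter (degenerate PSA)."""
    names: Iterable[str] = (*_ACCURACY_PARAMS, *_RATE_PARAMS, *_COST_PARAMS)
    return {
        name: DistributionSpec("fixed", {"value": getattr(params, name)})
        for name in names
    }
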