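"""Synthetic age-specific other-cause mortality schedule.

The base case uses a constant annual other-cause death probability of
0.0126 (the life-table value at the cohort's start age of 65).  As an
option the Markov engine can instead use an age-specific schedule.  No
official life table ships with the package; the schedule below is a
SYNTHETIC Gompertz approximation anchored so that q(65) = 0.0126 with a
mortality-rate doubling time of 8.5 years — the canonical adult pattern —
capped at 0.7/year in extreme old age.  It reproduces the qualitative
shape of a recent US all-cause table, not any published row.
"""

from __future__ import annotations

import math

__all__ = ["other_cause_death_probability"]

_ANCHOR_AGE = 65.0
_ANCHOR_Q = 0.0126
_DOUBLING_TIME = 8.5  # years
_CAP = 0.7


def other_cause_death_probability(age: float) -> float:
    """Annual probability of death from causes other than coronary disease."""
    if age < 0:
        raise ValueError(f"age must be nonnegative, got {age}")
    q = _ANCHOR_Q * 2.0 ** ((age - _ANCHOR_AGE) / _DOUBLING_TIME)
    return min(q, _CAP)
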