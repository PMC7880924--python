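"""Bit-stable tabular output and run manifests.

Number formatting is fixed (costs to 2 decimals, QALYs to 4, probabilities
to 6) so re-running a command with the same configuration and seed yields
byte-identical CSV bodies; volatile metadata (timestamp) lives only in the
JSON manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .markov import ModelOptions
from .parameters import ParameterSet

__all__ = ["RunManifest", "config_digest", "write_csv", "COLUMN_FORMATS"]

#: fixed per-column formatting by name pattern
COLUMN_FORMATS: dict[str, str] = {
    "cost": "%.2f",
    "nmb": "%.2f",
    "inmb": "%.2f",
    "span": "%.2f",
    "qalys": "%.4f",
    "qaly": "%.4f",
    "probability": "%.6f",
    "occ": "%.6f",
    "value": "%.6f",
    "wtp": "%.2f",
}


def _format_for(column: str) -> str | None:
    for key, fmt in COLUMN_FORMATS.items():
        if key in column:
            return fmt
    return None


def write_csv(frame: pd.DataFrame, path: str | Path) -> Path:
    """Write a DataFrame with the fixed numeric formatting, one format per column."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = frame.copy()
    for column in out.columns:
        fmt = _format_for(str(column))
        if fmt is not None and pd.api.types.is_float_dtype(out[column]):
            out[column] = out[column].map(
                lambda v: "" if pd.isna(v) else fmt % v
            )
    out.to_csv(path, index=False)
    return path


def config_digest(params: ParameterSet, options: ModelOptions) -> str:
    """Stable hash of every resolved configuration value and convention flag."""
    payload = {
        "parameters": params.model_dump(),
        "options": dataclasses.asdict(options),
    }
    blob = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record written next to every command's outputs."""

    command: str
    config_digest: str
    seed: int | None
    options: dict
    outputs: list[str] = field(default_factory=list)
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")
        return path
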