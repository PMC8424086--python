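"""Pipeline configuration: validated settings with the recording-protocol defaults.

The defaults reproduce the standard acquisition and analysis settings:
150 Hz sampling for 10 minutes, a 0.05 Hz high-pass for gravity removal, a
±2 s lag window for jerk synchrony, range-division normalization of the
composite index, and 1,000 bootstrap resamples for the cutoff confidence
interval.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, Field, ValidationError, field_validator

from .errors import ConfigError


class FilterConfig(BaseModel):
    """High-pass filter settings (see :class:`kcindex.preprocess.FilterSpec`)."""

    cutoff_hz: float = Field(default=0.05, gt=0)
    order: int = Field(default=4, ge=1)
    zero_phase: bool = True


class PipelineConfig(BaseModel):
    """All tunable settings of the scoring and evaluation pipeline."""

    filter: FilterConfig = FilterConfig()
    max_lag_s: float = Field(default=2.0, gt=0)
    normalization: Literal["range_divide", "min_max"] = "range_divide"
    # recorded for provenance; only one convention is implemented
    kurtosis_convention: Literal["pearson_biased"] = "pearson_biased"
    target_rate_hz: float = Field(default=150.0, gt=0)
    min_duration_s: float = Field(default=600.0, gt=0)
    duration_tol: float = Field(default=0.05, ge=0, lt=1)
    settle_s: float = Field(default=0.0, ge=0)
    n_boot: int = Field(default=1000, ge=1)
    seed: int = Field(default=0, ge=0)
    positive_labels: tuple[str, ...] = ("PR", "CS")

    @field_validator("positive_labels")
    @classmethod
    def _known_labels(cls, v):
        for label in v:
            if label not in ("N", "PR", "CS"):
                raise ValueError(f"unknown gm_label {label!r}")
        if not v:
            raise ValueError("positive_labels must not be empty")
        return tuple(v)

    def config_hash(self) -> str:
        """Short stable hash of the full configuration, for provenance."""
        payload = json.dumps(self.model_dump(mode="json"), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        try:
            return cls.model_validate_json(Path(path).read_text())
        except ValidationError as exc:
            raise ConfigError(str(exc)) from exc
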