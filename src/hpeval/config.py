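"""Analysis configuration shared across the pipeline.

All thresholds and windows that define the evaluation live here so that the
event detector, the non-event extractor and the ROC stage agree on them.
Defaults follow the standard intraoperative-hypotension conventions: MAP
threshold 65 mmHg, minimum event duration 1 min on 20-s averaged samples,
30-min normotensive sections kept 20 min clear of any event, prediction
horizons of 5/10/15 min, bradycardia below 60 beats/min, and an index alarm
threshold of 85.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import yaml


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and windows for the hypotension evaluation.

    Units are part of the field names; horizons are minutes of lead time at
    which a predictor's score is read before event onset.
    """

    map_threshold: float = 65.0          # mmHg; events are MAP strictly below
    min_event_duration_s: float = 60.0   # sustained time below threshold
    section_length_min: float = 30.0     # normotensive section span
    section_gap_min: float = 20.0        # clearance between section and events
    horizons_min: tuple[float, ...] = (5.0, 10.0, 15.0)
    hr_threshold: float = 60.0           # beats/min; bradycardia strictly below
    alarm_threshold: float = 85.0        # index units
    sample_interval_s: float = 20.0      # nominal grid spacing
    grid_tol_s: float = 2.0              # jitter tolerated before a gap is declared
    lookback_tol_s: float = 10.0         # nearest-sample tolerance for look-backs
    delta_map_window_min: float = 15.0   # window of the MAP-change comparator

    def __post_init__(self) -> None:
        positive = (
            "map_threshold", "min_event_duration_s", "section_length_min",
            "section_gap_min", "hr_threshold", "alarm_threshold",
            "sample_interval_s", "lookback_tol_s", "delta_map_window_min",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.grid_tol_s < 0:
            raise ValueError("grid_tol_s must be nonnegative")
        horizons = tuple(float(h) for h in self.horizons_min)
        if len(set(horizons)) != len(horizons):
            raise ValueError("horizons_min must be distinct")
        if any(h <= 0 for h in horizons):
            raise ValueError("horizons_min must be strictly positive")
        object.__setattr__(self, "horizons_min", horizons)

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "AnalysisConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown analysis config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data.get("analysis", data))

    def to_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def load_yaml(path: str | Path) -> dict[str, Any]:
    """Load a YAML run/cohort config into a plain dict (empty file -> {})."""
    with open(path, "r", encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}
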