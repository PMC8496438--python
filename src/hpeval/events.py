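"""Hypotensive-event detection, non-event extraction and burden metrics.

A hypotensive event is a maximal run of consecutive 20-s samples with
MAP strictly below the threshold (65 mmHg by default) sustained for at least
the minimum duration (1 min, i.e. three consecutive samples). A sample at
exactly the threshold belongs to neither events nor normotensive sections,
and a masked/missing sample breaks a run.

Non-events (negative data points for the ROC stage) are centres of 30-min
continuous normotensive sections lying at least 20 min clear of every event;
sections are tiled greedily left-to-right without overlap.

Burden metrics follow the depth-duration convention: each event's area under
the threshold (AUT, mmHg*min) is the rectangular sum of (threshold - MAP)
over its samples times the 20-s exposure, and the time-weighted average
(TWA, mmHg) is total AUT divided by usable monitoring minutes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .config import AnalysisConfig
from .timeseries import PatientRecord


@dataclass(frozen=True)
class HypotensiveEvent:
    """A detected sub-threshold episode.

    ``start_t`` is the first sub-threshold sample's timestamp; ``end_t`` is
    ``start_t`` plus the covered exposure (exclusive), so adjacent-in-time
    quantities can measure distance to either boundary.
    """

    patient_id: str
    start_t: float      # seconds
    end_t: float        # seconds (exclusive end of exposure)
    n_samples: int
    duration: float     # minutes
    aut: float          # mmHg * min, area under the threshold
    min_map: float      # mmHg


@dataclass(frozen=True)
class NonEventPoint:
    """Centre of a normotensive section usable as a ROC negative."""

    patient_id: str
    center_t: float
    section_start_t: float
    section_end_t: float


@dataclass(frozen=True)
class BurdenSummary:
    patient_id: str
    n_events: int
    cumulative_hypotension: float   # minutes
    total_aut: float                # mmHg * min
    twa: float                      # mmHg
    n_bradycardia_episodes: int


def _require_masked(record: PatientRecord, op: str) -> None:
    if not record.is_masked:
        raise ValueError(
            f"{op}: record {record.patient_id!r} still contains poor-quality "
            "samples; apply mask_poor_quality first"
        )


def _contiguous_runs(
    mask: np.ndarray, t: np.ndarray, max_dt: float
) -> list[tuple[int, int]]:
    """Maximal index runs [i, j] where mask holds and samples are contiguous."""
    runs: list[tuple[int, int]] = []
    n = mask.size
    i = 0
    while i < n:
        if not mask[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and mask[j + 1] and (t[j + 1] - t[j]) <= max_dt:
            j += 1
        runs.append((i, j))
        i = j + 1
    return runs


def detect_hypotensive_events(
    record: PatientRecord, cfg: AnalysisConfig = AnalysisConfig()
) -> list[HypotensiveEvent]:
    """Detect maximal sustained sub-threshold runs in a masked record.

    Runs shorter than ``cfg.min_event_duration_s`` of covered exposure (run
    length x 20 s) are discarded; each event reports its duration, its area
    under the threshold and its nadir. Raises if the record is unmasked.
    """
    _require_masked(record, "detect_hypotensive_events")
    interval = cfg.sample_interval_s
    max_dt = interval + cfg.grid_tol_s
    below = record.map < cfg.map_threshold
    events = []
    for i, j in _contiguous_runs(below, record.t, max_dt):
        n = j - i + 1
        if n * interval < cfg.min_event_duration_s:
            continue
        seg = record.map[i : j + 1]
        events.append(
            HypotensiveEvent(
                patient_id=record.patient_id,
                start_t=float(record.t[i]),
                end_t=float(record.t[i]) + n * interval,
                n_samples=n,
                duration=n * interval / 60.0,
                aut=float(np.sum(cfg.map_threshold - seg)) * interval / 60.0,
                min_map=float(seg.min()),
            )
        )
    return events


def extract_non_event_points(
    record: PatientRecord,
    events: Sequence[HypotensiveEvent],
    cfg: AnalysisConfig = AnalysisConfig(),
) -> list[NonEventPoint]:
    """Tile normotensive sections greedily and return their centre points.

    A section is a continuous (no gaps) span of ``section_length_min`` whose
    samples all have MAP strictly above the threshold, and whose endpoints
    lie at least ``section_gap_min`` from every event boundary. Sections do
    not overlap; each yields one negative point at its central sample.
    """
    _require_masked(record, "extract_non_event_points")
    length_s = cfg.section_length_min * 60.0
    gap_s = cfg.section_gap_min * 60.0
    max_dt = cfg.sample_interval_s + cfg.grid_tol_s
    t = record.t
    n = record.n_samples
    points = []
    i = 0
    while i < n:
        ws = t[i]
        we = ws + length_s
        # last sample inside [ws, we)
        j = int(np.searchsorted(t, we, side="left")) - 1
        if j < i:
            break
        ok = (
            we - t[j] <= max_dt  # section filled to its end
            and bool(np.all(record.map[i : j + 1] > cfg.map_threshold))
            and (j == i or bool(np.all(np.diff(t[i : j + 1]) <= max_dt)))
        )
        if ok:
            for ev in events:
                if ev.end_t <= ws:
                    if ws - ev.end_t < gap_s:
                        ok = False
                elif ev.start_t >= we:
                    if ev.start_t - we < gap_s:
                        ok = False
                else:  # temporal overlap (possible only across masked spans)
                    ok = False
                if not ok:
                    break
        if ok:
            center = ws + length_s / 2.0
            k = i + int(np.argmin(np.abs(t[i : j + 1] - center)))
            points.append(
                NonEventPoint(
                    patient_id=record.patient_id,
                    center_t=float(t[k]),
                    section_start_t=float(ws),
                    section_end_t=float(we),
                )
            )
            i = int(np.searchsorted(t, we, side="left"))
        else:
            i += 1
    return points


def area_under_threshold(
    record: PatientRecord, events: Sequence[HypotensiveEvent]
) -> float:
    """Total AUT in mmHg*min: the sum of per-event areas.

    Sub-minimum dips (below threshold but never qualifying as an event)
    contribute nothing, matching the convention that burden is integrated
    over counted events only.
    """
    return float(sum(ev.aut for ev in events))


def twa_map(record: PatientRecord, events: Sequence[HypotensiveEvent]) -> float:
    """Time-weighted average burden: total AUT / usable monitoring minutes."""
    duration = record.monitoring_duration
    if duration <= 0:
        raise ValueError(
            f"twa_map: record {record.patient_id!r} has zero usable monitoring time"
        )
    return area_under_threshold(record, events) / duration


def detect_bradycardia(
    record: PatientRecord,
    cfg: AnalysisConfig = AnalysisConfig(),
    *,
    min_samples: int = 1,
) -> int:
    """Count maximal runs of samples with HR strictly below the threshold.

    No minimum duration is imposed by default (``min_samples=1``); pass a
    larger value to require sustained episodes.
    """
    below = record.hr < cfg.hr_threshold
    max_dt = cfg.sample_interval_s + cfg.grid_tol_s
    runs = _contiguous_runs(below, record.t, max_dt)
    return sum(1 for i, j in runs if j - i + 1 >= min_samples)


def burden_summary(
    record: PatientRecord,
    events: Sequence[HypotensiveEvent],
    cfg: AnalysisConfig = AnalysisConfig(),
) -> BurdenSummary:
    total_aut = area_under_threshold(record, events)
    duration = record.monitoring_duration
    return BurdenSummary(
        patient_id=record.patient_id,
        n_events=len(events),
        cumulative_hypotension=float(sum(ev.duration for ev in events)),
        total_aut=total_aut,
        twa=total_aut / duration if duration > 0 else 0.0,
        n_bradycardia_episodes=detect_bradycardia(record, cfg),
    )
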