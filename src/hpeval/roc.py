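"""Horizon-aligned ROC analysis for hypotension early-warning scores.

Positives are hypotensive events scored by the predictor's value at a single
look-back sample ``horizon`` minutes before event onset (nearest sample
within +/-10 s); negatives are non-event centre points. Classification is
weak inequality for positives (score >= threshold) and strict for negatives
(score < threshold). The operating cutpoint is the threshold minimizing
|sensitivity - specificity|.

Two score sources are supported: ``"index"`` reads the prediction index
stored on the record; ``"delta_map"`` is the naive comparator, the MAP
change over the preceding 15 min, oriented so that a pressure fall gives a
positive (higher-risk) score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .config import AnalysisConfig
from .events import HypotensiveEvent, NonEventPoint
from .timeseries import PatientRecord

SOURCES = ("index", "delta_map")


class NoEvaluableDataError(ValueError):
    """Raised when a labeled set has an empty class."""


@dataclass(frozen=True)
class LabeledPoint:
    """A (score, label) pair entering the ROC analysis at one horizon."""

    patient_id: str
    t: float                # seconds: look-back sample (positives) or centre (negatives)
    label: int              # 1 positive (pre-event), 0 negative (non-event)
    score: float
    horizon_min: float
    source: str


@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray  # descending; first entry is +inf (sentinel)
    sens: np.ndarray
    spec: np.ndarray
    auc: float
    n_pos: int
    n_neg: int


@dataclass(frozen=True)
class CutpointResult:
    threshold: float
    sens: float
    spec: float


@dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    sens: float
    spec: float
    ppv: float | None   # None when TP+FP == 0
    npv: float | None   # None when TN+FN == 0


@dataclass(frozen=True)
class RocSummary:
    """One row of the per-horizon performance table."""

    source: str
    horizon_min: float
    n_pos: int
    n_neg: int
    auc: float
    cutpoint: float
    sens: float
    spec: float
    ppv: float | None
    npv: float | None
    ci: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    se: Mapping[str, float] = field(default_factory=dict)


def _nearest_index(t: np.ndarray, target: float, tol_s: float) -> int | None:
    if t.size == 0:
        return None
    k = int(np.argmin(np.abs(t - target)))
    return k if abs(t[k] - target) <= tol_s else None


def delta_map_score(
    record: PatientRecord,
    t_s: float,
    window_min: float = 15.0,
    *,
    tol_s: float = 10.0,
) -> float | None:
    """MAP(t - window) - MAP(t): positive when pressure has fallen.

    Both endpoints must exist on the grid within ``tol_s``; returns None
    otherwise. The fall-positive orientation makes larger scores mean higher
    risk, so it feeds the same ROC machinery as the index.
    """
    now = _nearest_index(record.t, t_s, tol_s)
    then = _nearest_index(record.t, t_s - window_min * 60.0, tol_s)
    if now is None or then is None:
        return None
    return float(record.map[then] - record.map[now])


def lookback_score(
    record: PatientRecord,
    event: HypotensiveEvent,
    horizon_min: float,
    source: str = "index",
    cfg: AnalysisConfig = AnalysisConfig(),
    events: Sequence[HypotensiveEvent] = (),
) -> float | None:
    """Score at the single sample ``horizon_min`` before event onset.

    Returns None (the event drops out of this horizon's positives) when no
    sample lies within the tolerance, the score is absent there, or the
    look-back sample falls inside another hypotensive event (the sample would
    not represent a pre-hypotensive state).
    """
    target = event.start_t - horizon_min * 60.0
    k = _nearest_index(record.t, target, cfg.lookback_tol_s)
    if k is None:
        return None
    t_k = float(record.t[k])
    for other in events:
        if other is event:
            continue
        if other.start_t <= t_k < other.end_t:
            return None
    if source == "index":
        s = float(record.score[k])
        return None if np.isnan(s) else s
    if source == "delta_map":
        return delta_map_score(
            record, t_k, cfg.delta_map_window_min, tol_s=cfg.lookback_tol_s
        )
    raise ValueError(f"unknown score source {source!r}")


def _center_score(
    record: PatientRecord, point: NonEventPoint, source: str, cfg: AnalysisConfig
) -> float | None:
    if source == "index":
        k = _nearest_index(record.t, point.center_t, cfg.lookback_tol_s)
        if k is None:
            return None
        s = float(record.score[k])
        return None if np.isnan(s) else s
    if source == "delta_map":
        return delta_map_score(
            record, point.center_t, cfg.delta_map_window_min, tol_s=cfg.lookback_tol_s
        )
    raise ValueError(f"unknown score source {source!r}")


def labeled_points_by_patient(
    records: Sequence[PatientRecord],
    events: Mapping[str, Sequence[HypotensiveEvent]],
    nonevents: Mapping[str, Sequence[NonEventPoint]],
    horizon_min: float,
    source: str = "index",
    cfg: AnalysisConfig = AnalysisConfig(),
) -> dict[str, list[LabeledPoint]]:
    """Per-patient labeled points (the unit the bootstrap resamples).

    Every patient appears in the result, possibly with an empty list: a
    patient contributing no evaluable point still takes part in patient-level
    resampling.
    """
    out: dict[str, list[LabeledPoint]] = {}
    for rec in records:
        pts: list[LabeledPoint] = []
        evs = list(events.get(rec.patient_id, ()))
        for ev in evs:
            s = lookback_score(rec, ev, horizon_min, source, cfg, events=evs)
            if s is None:
                continue
            pts.append(
                LabeledPoint(
                    patient_id=rec.patient_id,
                    t=ev.start_t - horizon_min * 60.0,
                    label=1,
                    score=s,
                    horizon_min=horizon_min,
                    source=source,
                )
            )
        for ne in nonevents.get(rec.patient_id, ()):
            s = _center_score(rec, ne, source, cfg)
            if s is None:
                continue
            pts.append(
                LabeledPoint(
                    patient_id=rec.patient_id,
                    t=ne.center_t,
                    label=0,
                    score=s,
                    horizon_min=horizon_min,
                    source=source,
                )
            )
        out[rec.patient_id] = pts
    return out


def build_labeled_set(
    records: Sequence[PatientRecord],
    events: Mapping[str, Sequence[HypotensiveEvent]],
    nonevents: Mapping[str, Sequence[NonEventPoint]],
    horizon_min: float,
    source: str = "index",
    cfg: AnalysisConfig = AnalysisConfig(),
) -> list[LabeledPoint]:
    """Flatten per-patient points into one labeled set; both classes required."""
    by_patient = labeled_points_by_patient(
        records, events, nonevents, horizon_min, source, cfg
    )
    points = [p for pts in by_patient.values() for p in pts]
    n_pos = sum(p.label for p in points)
    n_neg = len(points) - n_pos
    if n_pos == 0:
        raise NoEvaluableDataError(
            f"no positive (pre-event) points at horizon {horizon_min:g} min "
            f"for source {source!r}"
        )
    if n_neg == 0:
        raise NoEvaluableDataError(
            f"no negative (non-event) points at horizon {horizon_min:g} min "
            f"for source {source!r}"
        )
    return points


def _split_scores(points: Sequence[LabeledPoint]) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([p.label for p in points], dtype=int)
    s = np.array([p.score for p in points], dtype=float)
    return y, s


def rank_auc(pos_scores: np.ndarray, neg_scores: np.ndarray) -> float:
    """Tie-adjusted concordance probability via the rank-sum identity.

    Equals the trapezoidal area under the empirical ROC curve; used where
    the full curve is not needed (e.g. inside bootstrap replicates).
    """
    pos = np.asarray(pos_scores, float)
    neg = np.asarray(neg_scores, float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("rank_auc needs both classes")
    ranks = rankdata(np.concatenate([pos, neg]))
    r_pos = ranks[: pos.size].sum()
    return float((r_pos - pos.size * (pos.size + 1) / 2.0) / (pos.size * neg.size))


def roc_curve(points: Sequence[LabeledPoint]) -> RocCurve:
    """Empirical ROC over thresholds = unique scores plus a sentinel.

    Sensitivity at threshold c is the fraction of positives with score >= c;
    specificity the fraction of negatives with score < c. The AUC is the
    trapezoidal area, identical to the tie-adjusted concordance probability.
    """
    y, s = _split_scores(points)
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_curve requires at least one point of each class")
    fpr, tpr, thr = _sk_roc_curve(y, s, drop_intermediate=False)
    return RocCurve(
        thresholds=np.asarray(thr, float),
        sens=np.asarray(tpr, float),
        spec=1.0 - np.asarray(fpr, float),
        auc=float(_trapezoid_auc(fpr, tpr)),
        n_pos=n_pos,
        n_neg=n_neg,
    )


def select_cutpoint(curve: RocCurve) -> CutpointResult:
    """Threshold minimizing |sens - spec|.

    Ties go first to the larger sens + spec, then to the smallest threshold,
    making the choice deterministic on discrete data.
    """
    d = np.abs(curve.sens - curve.spec)
    best = None
    for i in range(curve.thresholds.size):
        key = (d[i], -(curve.sens[i] + curve.spec[i]), curve.thresholds[i])
        if best is None or key < best[0]:
            best = (key, i)
    i = best[1]
    return CutpointResult(
        threshold=float(curve.thresholds[i]),
        sens=float(curve.sens[i]),
        spec=float(curve.spec[i]),
    )


def confusion_metrics(
    points: Sequence[LabeledPoint], threshold: float
) -> ConfusionMetrics:
    """Counts and rates at a fixed threshold (score >= threshold => alarm)."""
    y, s = _split_scores(points)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError("confusion_metrics requires both classes")
    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    return ConfusionMetrics(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sens=tp / (tp + fn),
        spec=tn / (tn + fp),
        ppv=tp / (tp + fp) if (tp + fp) > 0 else None,
        npv=tn / (tn + fn) if (tn + fn) > 0 else None,
    )


def ppv_npv_from_rates(
    sens: float, spec: float, n_pos: int, n_neg: int
) -> tuple[float | None, float | None]:
    """Predictive values implied by (sens, spec) at given class counts.

    ppv = sens*P / (sens*P + (1-spec)*N); npv = spec*N / (spec*N + (1-sens)*P).
    Either is None when its denominator vanishes.
    """
    if not (0.0 <= sens <= 1.0 and 0.0 <= spec <= 1.0):
        raise ValueError("sens and spec must lie in [0, 1]")
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("class counts must be positive")
    ppv_den = sens * n_pos + (1.0 - spec) * n_neg
    npv_den = spec * n_neg + (1.0 - sens) * n_pos
    ppv = sens * n_pos / ppv_den if ppv_den > 0 else None
    npv = spec * n_neg / npv_den if npv_den > 0 else None
    return ppv, npv
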