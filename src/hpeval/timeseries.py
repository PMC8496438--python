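"""Data model, validation and CSV I/O for 20-s averaged hemodynamic series.

Monitor exports are flat CSV tables, one row per 20-s interval-averaged
sample, with a fixed dialect (UTF-8, comma separated, dot decimal):

    patient_id,t_s,map,sbp,dbp,hr,score,quality_ok

``t_s`` is seconds from monitoring start; ``map``/``sbp``/``dbp`` are mmHg;
``hr`` is beats/min; ``score`` is a 0-100 prediction-index value and is left
empty (never ``0``) when the monitor produced none; ``quality_ok`` is 1/0.
Poor-quality samples stay in the file and are removed for analysis by
:func:`mask_poor_quality`; a removed sample breaks contiguity for every
run-based detector downstream (no interpolation across dropouts).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Sequence

import numpy as np
import pandas as pd

#: CSV column order of the fixed dialect.
COLUMNS = ["patient_id", "t_s", "map", "sbp", "dbp", "hr", "score", "quality_ok"]

#: Nominal grid spacing of monitor exports, seconds.
NOMINAL_INTERVAL_S = 20.0


class ParseError(ValueError):
    """A file does not conform to the CSV dialect."""


class ValidationError(ValueError):
    """A record violates a structural invariant (ordering, duplicates)."""


@dataclass(frozen=True)
class HemoSample:
    """One 20-s averaged monitor observation."""

    t: float            # seconds from monitoring start
    map: float          # mean arterial pressure, mmHg
    sbp: float          # systolic, mmHg
    dbp: float          # diastolic, mmHg
    hr: float           # heart rate, beats/min
    score: float        # prediction index in [0, 100]; NaN when absent
    quality_ok: bool


class PatientRecord:
    """Time-ordered sample series for one monitored case.

    Stores the series as parallel numpy arrays (``t`` seconds, pressures in
    mmHg, ``score`` with NaN for absent index values, ``quality_ok`` boolean).
    Timestamps must be strictly increasing. The record is the unit of
    patient-level bootstrap resampling.
    """

    def __init__(
        self,
        patient_id: str,
        t: Sequence[float],
        map: Sequence[float],
        sbp: Sequence[float],
        dbp: Sequence[float],
        hr: Sequence[float],
        score: Sequence[float] | None = None,
        quality_ok: Sequence[bool] | None = None,
    ) -> None:
        self.patient_id = str(patient_id)
        self.t = np.asarray(t, dtype=float)
        self.map = np.asarray(map, dtype=float)
        self.sbp = np.asarray(sbp, dtype=float)
        self.dbp = np.asarray(dbp, dtype=float)
        self.hr = np.asarray(hr, dtype=float)
        n = self.t.size
        self.score = (
            np.full(n, np.nan) if score is None else np.asarray(score, dtype=float)
        )
        self.quality_ok = (
            np.ones(n, dtype=bool)
            if quality_ok is None
            else np.asarray(quality_ok, dtype=bool)
        )
        for name in ("map", "sbp", "dbp", "hr", "score", "quality_ok"):
            if getattr(self, name).size != n:
                raise ValidationError(
                    f"{self.patient_id}: field {name!r} length != len(t)"
                )
        if n and self.t[0] < 0:
            raise ValidationError(f"{self.patient_id}: negative timestamp")
        if n > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                bad = int(np.argmax(dt <= 0)) + 1
                kind = "duplicate" if dt[bad - 1] == 0 else "non-increasing"
                raise ValidationError(
                    f"{self.patient_id}: {kind} timestamp at sample {bad} "
                    f"(t={self.t[bad]:g} s)"
                )

    @property
    def n_samples(self) -> int:
        return int(self.t.size)

    @property
    def monitoring_duration(self) -> float:
        """Usable monitoring time in minutes.

        Each quality-ok sample represents 20 s of exposure, so the duration is
        the usable sample count times the nominal interval; masked samples do
        not count.
        """
        return float(self.quality_ok.sum()) * NOMINAL_INTERVAL_S / 60.0

    @property
    def is_masked(self) -> bool:
        """True when no poor-quality samples remain."""
        return bool(self.quality_ok.all())

    def samples(self) -> Iterator[HemoSample]:
        for i in range(self.n_samples):
            yield HemoSample(
                t=float(self.t[i]),
                map=float(self.map[i]),
                sbp=float(self.sbp[i]),
                dbp=float(self.dbp[i]),
                hr=float(self.hr[i]),
                score=float(self.score[i]),
                quality_ok=bool(self.quality_ok[i]),
            )

    def __len__(self) -> int:
        return self.n_samples

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PatientRecord):
            return NotImplemented
        return self.patient_id == other.patient_id and all(
            np.array_equal(getattr(self, f), getattr(other, f), equal_nan=(f != "quality_ok"))
            for f in ("t", "map", "sbp", "dbp", "hr", "score", "quality_ok")
        )

    def __repr__(self) -> str:
        return (
            f"PatientRecord({self.patient_id!r}, n={self.n_samples}, "
            f"usable={self.monitoring_duration:.1f} min)"
        )


class Gap(NamedTuple):
    """An inter-sample interval off the nominal 20-s grid."""

    index: int      # index of the sample ending the interval
    dt_s: float     # observed interval, seconds


class RangeViolation(NamedTuple):
    index: int
    field: str
    value: float


@dataclass(frozen=True)
class ValidationReport:
    gaps: tuple[Gap, ...]
    range_violations: tuple[RangeViolation, ...]

    @property
    def ok(self) -> bool:
        return not self.gaps and not self.range_violations


def validate_record(
    record: PatientRecord,
    *,
    interval_s: float = NOMINAL_INTERVAL_S,
    tol_s: float = 2.0,
    map_range: tuple[float, float] = (20.0, 200.0),
    hr_range: tuple[float, float] = (20.0, 250.0),
) -> ValidationReport:
    """Report grid gaps and physiologic-range violations (report-only).

    A gap is any inter-sample interval deviating from the nominal spacing by
    more than ``tol_s``. Range checks flag MAP outside ``map_range`` and HR
    outside ``hr_range``.
    """
    gaps = []
    if record.n_samples > 1:
        dt = np.diff(record.t)
        for i in np.nonzero(np.abs(dt - interval_s) > tol_s)[0]:
            gaps.append(Gap(index=int(i) + 1, dt_s=float(dt[i])))
    violations = []
    for i in np.nonzero((record.map < map_range[0]) | (record.map > map_range[1]))[0]:
        violations.append(RangeViolation(int(i), "map", float(record.map[i])))
    for i in np.nonzero((record.hr < hr_range[0]) | (record.hr > hr_range[1]))[0]:
        violations.append(RangeViolation(int(i), "hr", float(record.hr[i])))
    return ValidationReport(gaps=tuple(gaps), range_violations=tuple(violations))


def mask_poor_quality(record: PatientRecord) -> PatientRecord:
    """Drop poor-quality samples; the masked time no longer counts.

    Removal (rather than imputation) is deliberate: a dropped sample breaks
    any consecutive-sample run seen by the event and bradycardia detectors.
    Emits a warning when nothing usable remains.
    """
    keep = record.quality_ok
    if keep.all():
        return record
    if not keep.any():
        warnings.warn(
            f"{record.patient_id}: all samples flagged poor-quality; "
            "record has no usable data",
            stacklevel=2,
        )
    return PatientRecord(
        patient_id=record.patient_id,
        t=record.t[keep],
        map=record.map[keep],
        sbp=record.sbp[keep],
        dbp=record.dbp[keep],
        hr=record.hr[keep],
        score=record.score[keep],
        quality_ok=record.quality_ok[keep],
    )


def _parse_quality(raw: pd.Series, path: Path) -> np.ndarray:
    mapping = {"1": True, "0": False, "true": True, "false": False}
    out = np.empty(len(raw), dtype=bool)
    for i, v in enumerate(raw.astype(str).str.strip().str.lower()):
        if v not in mapping:
            raise ParseError(f"{path}: line {i + 2}: bad quality_ok value {v!r}")
        out[i] = mapping[v]
    return out


def read_records(path: str | Path) -> list[PatientRecord]:
    """Read a cohort CSV in the fixed dialect into PatientRecords.

    One record per distinct ``patient_id`` (file order of first appearance);
    absent scores come back as NaN, never 0. Malformed numeric cells raise
    :class:`ParseError` naming the offending line; non-increasing timestamps
    within a patient raise :class:`ValidationError`.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if list(df.columns) != COLUMNS:
        raise ParseError(
            f"{path}: header {list(df.columns)} does not match dialect {COLUMNS}"
        )
    def to_float(col: str, absent_ok: bool = False) -> np.ndarray:
        # python float() is correctly rounded, unlike pandas' fast parser,
        # which keeps write->read round-trips bit-exact
        out = np.empty(len(df))
        for i, raw in enumerate(df[col]):
            if absent_ok and raw.strip() == "":
                out[i] = np.nan
                continue
            try:
                out[i] = float(raw)
            except ValueError:
                raise ParseError(
                    f"{path}: line {i + 2}: bad {col} value {raw!r}"
                ) from None
        return out

    numeric = {col: to_float(col) for col in ("t_s", "map", "sbp", "dbp", "hr")}
    score = to_float("score", absent_ok=True)
    quality = _parse_quality(df["quality_ok"], path) if len(df) else np.empty(0, bool)

    records = []
    for pid in df["patient_id"].drop_duplicates():
        idx = (df["patient_id"] == pid).to_numpy()
        records.append(
            PatientRecord(
                patient_id=pid,
                t=numeric["t_s"][idx],
                map=numeric["map"][idx],
                sbp=numeric["sbp"][idx],
                dbp=numeric["dbp"][idx],
                hr=numeric["hr"][idx],
                score=score[idx],
                quality_ok=quality[idx],
            )
        )
    return records


def write_records(cohort: Iterable[PatientRecord], path: str | Path) -> Path:
    """Write a cohort to CSV in the fixed dialect (round-trip exact).

    Floats are written with Python's shortest round-trip repr so that
    ``read_records(write_records(c)) == c`` field for field; absent scores
    become empty cells.
    """
    path = Path(path)
    frames = []
    for rec in cohort:
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": rec.patient_id,
                    "t_s": rec.t,
                    "map": rec.map,
                    "sbp": rec.sbp,
                    "dbp": rec.dbp,
                    "hr": rec.hr,
                    "score": rec.score,
                    "quality_ok": rec.quality_ok.astype(int),
                }
            )
        )
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=COLUMNS)
    # %.17g guarantees bit-exact float64 round-trips through text
    out.to_csv(path, index=False, na_rep="", float_format="%.17g")
    return path
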