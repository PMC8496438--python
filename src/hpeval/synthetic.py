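"""Synthetic intraoperative cohorts with surrogate and null prediction indices.

The generator emulates the statistical structure the evaluation consumes,
not full physiology. Per patient it draws a monitoring duration (lognormal,
median ~194 min), simulates mean arterial pressure as a mean-reverting
Ornstein-Uhlenbeck process around a normotensive baseline on the 20-s grid,
and superposes hypotensive episodes arriving as a Poisson process whose
per-patient rate carries gamma frailty (so a realistic fraction of patients,
roughly three quarters, has at least one event while the median event count
stays around four). Each episode is a smooth dip: a cosine descent from
baseline to the 65 mmHg threshold over a prodrome of several minutes, a
raised-cosine sub-threshold trough of configured depth and duration, and a
cosine recovery. Smooth entry/exit keeps event boundaries well defined on
the 20-s grid.

Two pluggable score sources stand in for a proprietary prediction index:

* ``surrogate`` - extrapolates the least-squares MAP trend over the
  preceding 3 min to ``lead`` minutes ahead and squashes the predicted MAP
  through a logistic centred on the threshold, plus Gaussian noise, clipped
  to [0, 100]. Monotone decreasing in predicted MAP at zero noise.
* ``null`` - i.i.d. uniform scores on [0, 100], an exchangeable negative
  control whose downstream AUC must sit at 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Any, Mapping

import numpy as np

from .timeseries import NOMINAL_INTERVAL_S, PatientRecord


@dataclass(frozen=True)
class SynthConfig:
    """Cohort-level generator settings (defaults define the study scenario)."""

    n_patients: int = 31
    monitoring_median_min: float = 194.0    # lognormal median
    monitoring_sigma: float = 0.5           # lognormal sd of log duration
    baseline_map: float = 80.0              # mmHg
    ou_theta: float = 0.3                   # 1/min mean reversion
    ou_sigma: float = 2.0                   # mmHg / sqrt(min) diffusion
    episode_rate_per_h: float = 1.8         # cohort-mean episode arrivals
    episode_rate_dispersion: float = 0.9    # gamma frailty shape (smaller = more zero-event patients)
    episode_depth_median: float = 6.0       # mmHg below threshold, lognormal median
    episode_depth_sigma: float = 0.6
    episode_duration_median_min: float = 2.67
    episode_duration_sigma: float = 0.8
    prodrome_min: float = 10.0              # descent baseline -> threshold
    recovery_min: float = 3.0               # ascent threshold -> baseline
    threshold: float = 65.0                 # mmHg
    dropout_prob: float = 0.01              # per-sample poor-quality probability
    hr_baseline_mean: float = 75.0          # beats/min, per-patient mean of baselines
    hr_baseline_sd: float = 6.0
    hr_ou_sd: float = 4.0                   # stationary sd of HR fluctuations
    pulse_pressure_mean: float = 45.0       # mmHg
    pulse_pressure_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in (
            "monitoring_median_min", "episode_rate_dispersion",
            "episode_depth_median", "episode_duration_median_min",
            "prodrome_min", "recovery_min", "threshold",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        for name in ("episode_rate_per_h", "ou_theta", "ou_sigma", "dropout_prob"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not self.dropout_prob < 1:
            raise ValueError("dropout_prob must be < 1")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "SynthConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown synth config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class IndexModel:
    """Pluggable prediction-index stand-in attached to generated records."""

    kind: str = "surrogate"         # "surrogate" | "null"
    lead_min: float = 5.0           # forecast horizon of the surrogate
    midpoint: float = 65.0          # logistic centre, mmHg
    slope: float = 0.5              # index units of log-odds per mmHg
    noise_sd: float = 3.0           # index units
    trend_window_min: float = 3.0   # least-squares window (9 samples)

    def __post_init__(self) -> None:
        if self.kind not in ("surrogate", "null"):
            raise ValueError(f"unknown index kind {self.kind!r}")
        if self.slope <= 0:
            raise ValueError("slope must be strictly positive")
        if self.noise_sd < 0 or self.trend_window_min <= 0 or self.lead_min <= 0:
            raise ValueError("noise_sd >= 0, trend_window_min > 0, lead_min > 0 required")

    @classmethod
    def from_dict(cls, data: Mapping[str, Any]) -> "IndexModel":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown index model keys: {sorted(unknown)}")
        return cls(**data)


def _ou_series(
    n: int, mean: float, theta_per_min: float, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Exact OU discretization on the 20-s grid, started at the mean."""
    dt = NOMINAL_INTERVAL_S / 60.0
    x = np.empty(n)
    if n == 0:
        return x
    x[0] = mean
    if theta_per_min == 0 or sigma == 0:
        phi = np.exp(-theta_per_min * dt)
        innov_sd = sigma * np.sqrt(dt) if theta_per_min == 0 else 0.0
        for i in range(1, n):
            x[i] = mean + phi * (x[i - 1] - mean) + (
                rng.normal(0.0, innov_sd) if innov_sd else 0.0
            )
        return x
    phi = np.exp(-theta_per_min * dt)
    innov_sd = sigma * np.sqrt((1.0 - phi**2) / (2.0 * theta_per_min))
    shocks = rng.normal(0.0, innov_sd, size=n - 1)
    for i in range(1, n):
        x[i] = mean + phi * (x[i - 1] - mean) + shocks[i - 1]
    return x


def _episode_profile(
    t: np.ndarray,
    onset_s: float,
    depth: float,
    duration_s: float,
    baseline: float,
    threshold: float,
    prodrome_s: float,
    recovery_s: float,
) -> np.ndarray:
    """Smooth dip profile: baseline outside, trough threshold-depth inside.

    ``onset_s`` is the moment MAP crosses the threshold going down; the
    sub-threshold trough is a raised cosine of the given duration, flanked by
    cosine ramps from/to baseline.
    """
    prof = np.full(t.size, baseline)
    drop = baseline - threshold
    # prodrome: baseline -> threshold
    u = (t - (onset_s - prodrome_s)) / prodrome_s
    m = (u >= 0) & (u <= 1)
    prof[m] = baseline - drop * 0.5 * (1.0 - np.cos(np.pi * u[m]))
    # sub-threshold trough: threshold -> threshold-depth -> threshold
    v = (t - onset_s) / duration_s
    m = (v > 0) & (v < 1)
    prof[m] = threshold - depth * np.sin(np.pi * v[m]) ** 2
    # recovery: threshold -> baseline
    w = (t - (onset_s + duration_s)) / recovery_s
    m = (w >= 0) & (w <= 1)
    prof[m] = threshold + drop * 0.5 * (1.0 - np.cos(np.pi * w[m]))
    return prof


def generate_map_trajectory(
    config: SynthConfig,
    duration_min: float,
    rng: np.random.Generator,
    *,
    episode_rate_per_h: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """MAP series on the 20-s grid: OU baseline with superposed episode dips.

    Returns ``(t_seconds, map_mmHg)``; empty arrays when duration <= 0.
    Episodes arrive Poisson at ``episode_rate_per_h`` (defaults to the
    config's cohort mean); dips combine with the baseline by elementwise
    minimum so overlapping episodes deepen rather than cancel.
    """
    if duration_min <= 0:
        return np.empty(0), np.empty(0)
    n = int(np.floor(duration_min * 60.0 / NOMINAL_INTERVAL_S))
    t = np.arange(n) * NOMINAL_INTERVAL_S
    base = _ou_series(n, config.baseline_map, config.ou_theta, config.ou_sigma, rng)
    rate = config.episode_rate_per_h if episode_rate_per_h is None else episode_rate_per_h
    m = base.copy()
    n_ep = rng.poisson(rate * duration_min / 60.0)
    for _ in range(n_ep):
        onset = rng.uniform(0.0, duration_min * 60.0)
        depth = float(
            np.clip(
                rng.lognormal(np.log(config.episode_depth_median), config.episode_depth_sigma),
                1.0,
                40.0,
            )
        )
        dur_s = 60.0 * float(
            np.clip(
                rng.lognormal(
                    np.log(config.episode_duration_median_min),
                    config.episode_duration_sigma,
                ),
                1.0 / 3.0,
                30.0,
            )
        )
        prof = _episode_profile(
            t,
            onset,
            depth,
            dur_s,
            config.baseline_map,
            config.threshold,
            config.prodrome_min * 60.0,
            config.recovery_min * 60.0,
        )
        m = np.minimum(m, prof)
    return t, m


def surrogate_index(
    record: PatientRecord,
    model: IndexModel,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Trend-extrapolation surrogate score series for a record.

    At each sample, the least-squares MAP trend over the preceding
    ``trend_window_min`` is extrapolated ``lead_min`` ahead and mapped to
    100 * logistic(slope * (midpoint - predicted MAP)), plus optional
    Gaussian noise, clipped to [0, 100]. Scores are NaN until the trend
    window is filled.
    """
    if record.n_samples < 2:
        raise ValueError("surrogate_index requires a record with >= 2 samples")
    t = record.t
    m = record.map
    n = t.size
    w_s = model.trend_window_min * 60.0
    k_needed = int(round(w_s / NOMINAL_INTERVAL_S))
    scores = np.full(n, np.nan)
    lead_s = model.lead_min * 60.0
    for i in range(n):
        lo = t[i] - w_s
        j0 = int(np.searchsorted(t, lo, side="right"))
        idx = slice(j0, i + 1)
        if i + 1 - j0 < k_needed:
            continue
        tt = t[idx]
        mm = m[idx]
        xm = tt.mean()
        ym = mm.mean()
        dx = tt - xm
        slope_fit = float(np.dot(dx, mm - ym) / np.dot(dx, dx))
        pred = ym + slope_fit * (t[i] + lead_s - xm)
        s = 100.0 / (1.0 + np.exp(-model.slope * (model.midpoint - pred)))
        if model.noise_sd > 0:
            if rng is None:
                raise ValueError("rng required when noise_sd > 0")
            s += rng.normal(0.0, model.noise_sd)
        scores[i] = np.clip(s, 0.0, 100.0)
    return scores


def null_index(record: PatientRecord, rng: np.random.Generator) -> np.ndarray:
    """I.i.d. uniform [0, 100] scores: the exchangeable negative control."""
    return rng.uniform(0.0, 100.0, size=record.n_samples)


def _patient_record(
    pid: str, config: SynthConfig, model: IndexModel, rng: np.random.Generator
) -> PatientRecord:
    duration_min = float(
        rng.lognormal(np.log(config.monitoring_median_min), config.monitoring_sigma)
    )
    duration_min = max(duration_min, 40.0)  # a case always outlasts induction
    frailty = rng.gamma(
        config.episode_rate_dispersion, 1.0 / config.episode_rate_dispersion
    )
    t, m = generate_map_trajectory(
        config,
        duration_min,
        rng,
        episode_rate_per_h=config.episode_rate_per_h * frailty,
    )
    n = t.size
    hr_mean = rng.normal(config.hr_baseline_mean, config.hr_baseline_sd)
    hr_theta = config.ou_theta
    hr_sigma = config.hr_ou_sd * np.sqrt(2.0 * hr_theta)
    hr = np.clip(_ou_series(n, hr_mean, hr_theta, hr_sigma, rng), 25.0, 240.0)
    pp = float(np.clip(rng.normal(config.pulse_pressure_mean, config.pulse_pressure_sd), 30.0, 60.0))
    sbp = m + 2.0 * pp / 3.0
    dbp = m - pp / 3.0
    quality = rng.random(n) >= config.dropout_prob
    rec = PatientRecord(
        patient_id=pid, t=t, map=m, sbp=sbp, dbp=dbp, hr=hr, quality_ok=quality
    )
    if model.kind == "null":
        score = null_index(rec, rng)
    else:
        score = surrogate_index(rec, model, rng)
    return PatientRecord(
        patient_id=pid,
        t=t,
        map=m,
        sbp=sbp,
        dbp=dbp,
        hr=hr,
        score=score,
        quality_ok=quality,
    )


def generate_cohort(
    config: SynthConfig, model: IndexModel = IndexModel()
) -> list[PatientRecord]:
    """Generate ``n_patients`` records, deterministic given ``config.seed``.

    One master seed expands into an independent substream per patient index,
    so the cohort is reproducible regardless of generation order.
    """
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_patients)
    width = len(str(config.n_patients))
    return [
        _patient_record(f"P{i + 1:0{width}d}", config, model, np.random.default_rng(children[i]))
        for i in range(config.n_patients)
    ]
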