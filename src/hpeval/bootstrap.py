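"""Patient-level bootstrap standard errors and asymptotic confidence intervals.

Within-patient repeated measures make pointwise CIs too narrow; the remedy
used here is to resample whole patients: N patients are drawn with
replacement from the N in the cohort, the metric is recomputed on each
resample (duplicated patients contributing duplicated data), and the
standard error is the standard deviation of the replicate metrics. The CI is
the normal approximation estimate +/- z * se, optionally clamped to the
metric's range (e.g. [0, 1] for proportions and AUC); a percentile interval
is available as an option.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence, TypeVar

import numpy as np
from scipy.stats import norm

T = TypeVar("T")

Bounds = tuple[float, float] | None


@dataclass(frozen=True)
class BootstrapResult:
    metric_name: str
    point_estimate: float
    se: float
    ci_low: float
    ci_high: float
    n_reps: int
    n_undefined: int    # replicates where the metric was undefined (dropped)
    seed: int | None


def asymptotic_ci(
    estimate: float,
    se: float,
    level: float = 0.95,
    bounds: Bounds = None,
) -> tuple[float, float]:
    """Normal-approximation interval estimate +/- z*se, clamped to bounds."""
    if not 0.0 < level < 1.0:
        raise ValueError(f"confidence level must lie in (0, 1), got {level}")
    if se < 0:
        raise ValueError("se must be nonnegative")
    z = float(norm.ppf((1.0 + level) / 2.0))
    lo, hi = estimate - z * se, estimate + z * se
    if bounds is not None:
        lo = max(lo, bounds[0])
        hi = min(hi, bounds[1])
    return lo, hi


def _as_value(v: object) -> float:
    if v is None:
        return math.nan
    return float(v)


def bootstrap_metrics(
    units: Sequence[T],
    metrics: Mapping[str, Callable[[list[T]], float | None]],
    n_reps: int = 2000,
    seed: int | np.random.SeedSequence | None = None,
    ci_level: float = 0.95,
    ci_method: str = "normal",
    bounds: Mapping[str, Bounds] | Bounds = None,
    *,
    strict: bool = False,
) -> dict[str, BootstrapResult]:
    """Bootstrap several metrics over shared patient resamples.

    ``units`` are the exchangeable units (patients, or any per-patient
    precomputation); each metric maps a list of units to a number, returning
    None/NaN or raising ValueError when undefined on a resample. Undefined
    replicates are dropped and counted. With ``strict=True`` a metric
    undefined on more than half of the replicates raises; otherwise its
    result carries NaN se/CI.
    """
    units = list(units)
    if not units:
        raise ValueError("bootstrap requires a nonempty cohort")
    if n_reps < 2:
        raise ValueError("n_reps must be at least 2")
    if ci_method not in ("normal", "percentile"):
        raise ValueError(f"unknown ci_method {ci_method!r}")

    points = {}
    for name, fn in metrics.items():
        v = _as_value(fn(units))
        if math.isnan(v):
            raise ValueError(f"metric {name!r} is undefined on the full cohort")
        points[name] = v

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(n_reps)
    n = len(units)
    reps: dict[str, list[float]] = {name: [] for name in metrics}
    undefined = {name: 0 for name in metrics}
    for child in children:
        rng = np.random.default_rng(child)
        idx = rng.integers(0, n, size=n)
        resample = [units[k] for k in idx]
        for name, fn in metrics.items():
            try:
                v = _as_value(fn(resample))
            except ValueError:
                v = math.nan
            if math.isnan(v):
                undefined[name] += 1
            else:
                reps[name].append(v)

    seed_int = seed if isinstance(seed, int) else None
    results = {}
    for name in metrics:
        point = points[name]
        b = bounds.get(name) if isinstance(bounds, Mapping) else bounds
        if undefined[name] > n_reps / 2:
            if strict:
                raise ValueError(
                    f"metric {name!r} undefined on {undefined[name]}/{n_reps} "
                    "replicates; not bootstrappable on this cohort"
                )
            se = math.nan
            lo = hi = math.nan
        else:
            vals = np.asarray(reps[name], float)
            se = float(np.std(vals, ddof=1))
            if ci_method == "normal":
                lo, hi = asymptotic_ci(point, se, ci_level, b)
            else:
                alpha = (1.0 - ci_level) / 2.0
                lo, hi = (
                    float(np.percentile(vals, 100 * alpha)),
                    float(np.percentile(vals, 100 * (1 - alpha))),
                )
                if b is not None:
                    lo, hi = max(lo, b[0]), min(hi, b[1])
        results[name] = BootstrapResult(
            metric_name=name,
            point_estimate=point,
            se=se,
            ci_low=lo,
            ci_high=hi,
            n_reps=n_reps,
            n_undefined=undefined[name],
            seed=seed_int,
        )
    return results


def bootstrap_metric(
    cohort: Sequence[T],
    metric: Callable[[list[T]], float | None],
    n_reps: int = 2000,
    seed: int | np.random.SeedSequence | None = None,
    ci_level: float = 0.95,
    ci_method: str = "normal",
    bounds: Bounds = None,
    metric_name: str = "metric",
) -> BootstrapResult:
    """Patient-level bootstrap of a single cohort-level metric.

    Raises when the metric is undefined on the full cohort or on more than
    half of the replicates.
    """
    return bootstrap_metrics(
        cohort,
        {metric_name: metric},
        n_reps=n_reps,
        seed=seed,
        ci_level=ci_level,
        ci_method=ci_method,
        bounds=bounds,
        strict=True,
    )[metric_name]
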