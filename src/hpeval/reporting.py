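"""End-to-end orchestration: cohort -> burden tables -> per-horizon ROC tables.

:func:`run_evaluation` drives the whole pipeline from a single config
mapping (or YAML path): load or synthesize a cohort, mask poor-quality
samples, detect hypotensive events and non-event sections, summarize the
hypotension burden per patient (median [IQR] across the cohort), then for
every requested score source and horizon build the labeled set, fit the ROC
curve, select the cutpoint, and attach patient-level bootstrap CIs to AUC,
sensitivity, specificity, PPV and NPV. Outputs are plain CSVs plus a JSON
manifest carrying the config snapshot, seeds, per-stage counts and sha256
digests of every written file, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .bootstrap import bootstrap_metrics
from .config import AnalysisConfig, load_yaml
from .events import (
    HypotensiveEvent,
    NonEventPoint,
    burden_summary,
    detect_hypotensive_events,
    extract_non_event_points,
)
from .roc import (
    LabeledPoint,
    NoEvaluableDataError,
    RocSummary,
    confusion_metrics,
    labeled_points_by_patient,
    rank_auc,
    roc_curve,
    select_cutpoint,
)
from .synthetic import IndexModel, SynthConfig, generate_cohort
from .timeseries import PatientRecord, mask_poor_quality, read_records, write_records

logger = logging.getLogger(__name__)

_CI_METRICS = ("auc", "sens", "spec", "ppv", "npv")


def _package_version() -> str:
    try:
        return _pkg_version("hpeval")
    except PackageNotFoundError:  # running from a source tree
        return "unknown"


def median_iqr(values: Sequence[float]) -> tuple[float, float, float]:
    """Median and 25th/75th percentiles, linear-interpolation convention."""
    arr = np.asarray(list(values), float)
    if arr.size == 0:
        return (np.nan, np.nan, np.nan)
    q25, q50, q75 = np.percentile(arr, [25.0, 50.0, 75.0])
    return float(q50), float(q25), float(q75)


@dataclass
class ReportBundle:
    """In-memory result of a full evaluation run."""

    burden: pd.DataFrame            # one row per patient
    burden_summary: pd.DataFrame    # median / q25 / q75 per burden column
    roc: pd.DataFrame               # one row per (source, horizon)
    roc_summaries: list[RocSummary]
    manifest: dict[str, Any]
    warnings: list[str]


def _alarm_rate(record: PatientRecord, threshold: float) -> float:
    """Fraction of scored samples at or above the alarm threshold."""
    scored = ~np.isnan(record.score)
    if not scored.any():
        return np.nan
    return float(np.mean(record.score[scored] >= threshold))


def _pooled(points_by_patient: Mapping[str, list[LabeledPoint]]) -> list[LabeledPoint]:
    return [p for pts in points_by_patient.values() for p in pts]


def _metric_fns(cutpoint: float) -> dict[str, Any]:
    """Cohort-level metric callables over lists of per-patient point lists."""

    def split(units: list[list[LabeledPoint]]):
        pts = [p for u in units for p in u]
        pos = np.array([p.score for p in pts if p.label == 1])
        neg = np.array([p.score for p in pts if p.label == 0])
        return pos, neg

    def auc(units):
        pos, neg = split(units)
        if pos.size == 0 or neg.size == 0:
            return None
        return rank_auc(pos, neg)

    def sens(units):
        pos, _ = split(units)
        return None if pos.size == 0 else float(np.mean(pos >= cutpoint))

    def spec(units):
        _, neg = split(units)
        return None if neg.size == 0 else float(np.mean(neg < cutpoint))

    def ppv(units):
        pos, neg = split(units)
        tp = int(np.sum(pos >= cutpoint))
        fp = int(np.sum(neg >= cutpoint))
        return tp / (tp + fp) if (tp + fp) > 0 else None

    def npv(units):
        pos, neg = split(units)
        tn = int(np.sum(neg < cutpoint))
        fn = int(np.sum(pos < cutpoint))
        return tn / (tn + fn) if (tn + fn) > 0 else None

    return {"auc": auc, "sens": sens, "spec": spec, "ppv": ppv, "npv": npv}


def evaluate_source_horizon(
    records: Sequence[PatientRecord],
    events: Mapping[str, Sequence[HypotensiveEvent]],
    nonevents: Mapping[str, Sequence[NonEventPoint]],
    source: str,
    horizon_min: float,
    cfg: AnalysisConfig,
    *,
    n_reps: int = 2000,
    seed: int | np.random.SeedSequence | None = None,
    ci_level: float = 0.95,
    ci_method: str = "normal",
) -> RocSummary:
    """One performance-table row: ROC, cutpoint, rates and bootstrap CIs.

    The cutpoint is selected once on the full cohort and held fixed across
    bootstrap replicates; replicates resample whole patients, duplicated
    patients contributing duplicated labeled points.
    """
    by_patient = labeled_points_by_patient(
        records, events, nonevents, horizon_min, source, cfg
    )
    points = _pooled(by_patient)
    n_pos = sum(p.label for p in points)
    n_neg = len(points) - n_pos
    if n_pos == 0 or n_neg == 0:
        missing = "positive" if n_pos == 0 else "negative"
        raise NoEvaluableDataError(
            f"no {missing} points for source {source!r} at {horizon_min:g} min"
        )
    curve = roc_curve(points)
    cut = select_cutpoint(curve)
    cm = confusion_metrics(points, cut.threshold)

    units = [by_patient[r.patient_id] for r in records]
    boots = bootstrap_metrics(
        units,
        _metric_fns(cut.threshold),
        n_reps=n_reps,
        seed=seed,
        ci_level=ci_level,
        ci_method=ci_method,
        bounds=(0.0, 1.0),
    )
    ci = {m: (boots[m].ci_low, boots[m].ci_high) for m in _CI_METRICS}
    se = {m: boots[m].se for m in _CI_METRICS}
    return RocSummary(
        source=source,
        horizon_min=horizon_min,
        n_pos=n_pos,
        n_neg=n_neg,
        auc=curve.auc,
        cutpoint=cut.threshold,
        sens=cm.sens,
        spec=cm.spec,
        ppv=cm.ppv,
        npv=cm.npv,
        ci=ci,
        se=se,
    )


def _roc_table(summaries: Sequence[RocSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row: dict[str, Any] = {
            "source": s.source,
            "horizon_min": s.horizon_min,
            "n_pos": s.n_pos,
            "n_neg": s.n_neg,
            "auc": s.auc,
            "cutpoint": s.cutpoint,
            "sens": s.sens,
            "spec": s.spec,
            "ppv": np.nan if s.ppv is None else s.ppv,
            "npv": np.nan if s.npv is None else s.npv,
        }
        for m in _CI_METRICS:
            lo, hi = s.ci.get(m, (np.nan, np.nan))
            row[f"{m}_ci_low"] = lo
            row[f"{m}_ci_high"] = hi
            row[f"{m}_se"] = s.se.get(m, np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_evaluation(
    config: Mapping[str, Any] | str | Path,
    out_dir: str | Path | None = None,
) -> ReportBundle:
    """Run the full pipeline from a config mapping or YAML path.

    Recognized keys (all optional): ``seed``, ``cohort_csv``, ``synth``,
    ``index``, ``analysis``, ``sources``, ``bootstrap`` (n_reps, ci_level,
    ci_method), ``out_dir``. Without ``cohort_csv`` a synthetic cohort is
    generated from ``synth``/``index`` with the run seed.
    """
    cfg_dict = dict(load_yaml(config)) if isinstance(config, (str, Path)) else dict(config)
    seed = int(cfg_dict.get("seed", 0))
    acfg = AnalysisConfig.from_dict(cfg_dict.get("analysis", {}))
    sources = list(cfg_dict.get("sources", ["index", "delta_map"]))
    bs_cfg = dict(cfg_dict.get("bootstrap", {}))
    n_reps = int(bs_cfg.get("n_reps", 2000))
    ci_level = float(bs_cfg.get("ci_level", 0.95))
    ci_method = str(bs_cfg.get("ci_method", "normal"))
    out_dir = out_dir if out_dir is not None else cfg_dict.get("out_dir")
    warnings_list: list[str] = []

    if cfg_dict.get("cohort_csv"):
        records = read_records(cfg_dict["cohort_csv"])
        logger.info("loaded %d patients from %s", len(records), cfg_dict["cohort_csv"])
    else:
        synth = SynthConfig.from_dict({**cfg_dict.get("synth", {}), "seed": seed})
        model = IndexModel.from_dict(cfg_dict.get("index", {}))
        records = generate_cohort(synth, model)
        logger.info("synthesized %d patients (seed %d)", len(records), seed)

    masked = [mask_poor_quality(r) for r in records]
    events = {r.patient_id: detect_hypotensive_events(r, acfg) for r in masked}
    nonevents = {
        r.patient_id: extract_non_event_points(r, events[r.patient_id], acfg)
        for r in masked
    }
    n_events = sum(len(v) for v in events.values())
    n_nonevents = sum(len(v) for v in nonevents.values())
    logger.info(
        "patients=%d events=%d nonevents=%d", len(masked), n_events, n_nonevents
    )

    burden_rows = []
    for rec in masked:
        b = burden_summary(rec, events[rec.patient_id], acfg)
        burden_rows.append(
            {
                "patient_id": b.patient_id,
                "monitoring_min": rec.monitoring_duration,
                "n_events": b.n_events,
                "cumulative_hypotension_min": b.cumulative_hypotension,
                "total_aut_mmhg_min": b.total_aut,
                "twa_mmhg": b.twa,
                "n_bradycardia_episodes": b.n_bradycardia_episodes,
                "alarm_rate": _alarm_rate(rec, acfg.alarm_threshold),
            }
        )
    burden = pd.DataFrame(burden_rows)

    summary_rows = []
    for col in (
        "monitoring_min",
        "n_events",
        "cumulative_hypotension_min",
        "total_aut_mmhg_min",
        "twa_mmhg",
        "n_bradycardia_episodes",
        "alarm_rate",
    ):
        med, q25, q75 = median_iqr(burden[col].dropna()) if len(burden) else (np.nan,) * 3
        summary_rows.append({"quantity": col, "median": med, "q25": q25, "q75": q75})
    frac_with_event = (
        float(np.mean(burden["n_events"] > 0)) if len(burden) else np.nan
    )
    summary_rows.append(
        {"quantity": "fraction_patients_with_event", "median": frac_with_event,
         "q25": np.nan, "q75": np.nan}
    )
    burden_sum = pd.DataFrame(summary_rows)

    ss = np.random.SeedSequence(seed)
    table_seeds = ss.spawn(len(sources) * len(acfg.horizons_min))
    summaries: list[RocSummary] = []
    counts: dict[str, list[int]] = {}
    k = 0
    for source in sources:
        for h in acfg.horizons_min:
            child = table_seeds[k]
            k += 1
            try:
                s = evaluate_source_horizon(
                    masked, events, nonevents, source, h, acfg,
                    n_reps=n_reps, seed=child, ci_level=ci_level, ci_method=ci_method,
                )
            except NoEvaluableDataError as exc:
                msg = f"skipping {source} at {h:g} min: {exc}"
                warnings_list.append(msg)
                logger.warning(msg)
                continue
            summaries.append(s)
            counts[f"{source}_h{h:g}"] = [s.n_pos, s.n_neg]
            logger.info(
                "%s @ %g min: AUC %.3f (n_pos=%d, n_neg=%d)",
                source, h, s.auc, s.n_pos, s.n_neg,
            )
    roc_df = _roc_table(summaries)

    manifest: dict[str, Any] = {
        "version": _package_version(),
        "seed": seed,
        "config": {
            "analysis": acfg.to_dict(),
            "sources": sources,
            "bootstrap": {"n_reps": n_reps, "ci_level": ci_level, "ci_method": ci_method},
            "synth": cfg_dict.get("synth", {}),
            "index": cfg_dict.get("index", {}),
            "cohort_csv": cfg_dict.get("cohort_csv"),
        },
        "counts": {
            "patients": len(records),
            "events": n_events,
            "nonevents": n_nonevents,
            "labeled_points": counts,
        },
        "warnings": warnings_list,
        "outputs": {},
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        files = {
            "burden.csv": burden,
            "burden_summary.csv": burden_sum,
            "roc.csv": roc_df,
        }
        if not cfg_dict.get("cohort_csv"):
            cohort_path = out / "cohort.csv"
            write_records(records, cohort_path)
            manifest["outputs"]["cohort.csv"] = _sha256(cohort_path)
        for name, df in files.items():
            path = out / name
            df.to_csv(path, index=False, float_format="%.10g")
            manifest["outputs"][name] = _sha256(path)
        with open(out / "manifest.json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")

    return ReportBundle(
        burden=burden,
        burden_summary=burden_sum,
        roc=roc_df,
        roc_summaries=summaries,
        manifest=manifest,
        warnings=warnings_list,
    )
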