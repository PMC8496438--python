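import numpy as np
import pytest

from hpeval import (
    AnalysisConfig,
    IndexModel,
    PatientRecord,
    SynthConfig,
    detect_hypotensive_events,
    extract_non_event_points,
    generate_cohort,
    mask_poor_quality,
)


def make_record(
    map_values,
    patient_id="P1",
    t=None,
    hr=None,
    score=None,
    quality=None,
    interval=20.0,
):
    """Build a record on the 20-s grid from a MAP sequence (test helper)."""
    m = np.asarray(map_values, dtype=float)
    n = m.size
    t = np.arange(n) * interval if t is None else np.asarray(t, float)
    hr = np.full(n, 75.0) if hr is None else np.asarray(hr, float)
    return PatientRecord(
        patient_id=patient_id,
        t=t,
        map=m,
        sbp=m + 30.0,
        dbp=m - 15.0,
        hr=hr,
        score=score,
        quality_ok=quality,
    )


@pytest.fixture
def cfg():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def default_cfg():
    return AnalysisConfig()


def _pipeline(records, cfg):
    masked = [mask_poor_quality(r) for r in records]
    events = {r.patient_id: detect_hypotensive_events(r, cfg) for r in masked}
    nonevents = {
        r.patient_id: extract_non_event_points(r, events[r.patient_id], cfg)
        for r in masked
    }
    return masked, events, nonevents


@pytest.fixture(scope="session")
def surrogate_cohort(default_cfg):
    """Default study scenario with the trend-surrogate index, seed 0."""
    records = generate_cohort(SynthConfig(seed=0), IndexModel(kind="surrogate"))
    return _pipeline(records, default_cfg)


@pytest.fixture(scope="session")
def null_cohort(default_cfg):
    """Same scenario scored by the uniform null index, seed 0."""
    records = generate_cohort(SynthConfig(seed=0), IndexModel(kind="null"))
    return _pipeline(records, default_cfg)
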