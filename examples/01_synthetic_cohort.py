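"""Generate a synthetic intraoperative cohort and summarize its burden.

Builds the default 31-patient scenario (OU-fluctuating MAP with smooth
hypotensive dips, trend-surrogate prediction index), detects sustained
sub-65-mmHg events, and prints the cohort-level burden summary. The printed
medians describe how much hypotension the cohort carries: events per
patient, minutes spent below threshold, and the time-weighted average depth
(TWA, mmHg) — the depth-duration burden normalized by monitoring time.
"""

import numpy as np

from hpeval import (
    AnalysisConfig,
    IndexModel,
    SynthConfig,
    burden_summary,
    detect_hypotensive_events,
    generate_cohort,
    mask_poor_quality,
)

cfg = AnalysisConfig()
cohort = generate_cohort(SynthConfig(seed=0), IndexModel(kind="surrogate"))
masked = [mask_poor_quality(r) for r in cohort]
events = {r.patient_id: detect_hypotensive_events(r, cfg) for r in masked}
summaries = [burden_summary(r, events[r.patient_id], cfg) for r in masked]

durations = [e.duration for evs in events.values() for e in evs]
print(f"patients:                 {len(masked)}")
print(f"with >=1 event:           {sum(b.n_events > 0 for b in summaries)} "
      f"({100 * np.mean([b.n_events > 0 for b in summaries]):.1f}%)")
print(f"total events:             {sum(b.n_events for b in summaries)}")
print(f"median events/patient:    {np.median([b.n_events for b in summaries]):.0f}")
print(f"median event duration:    {np.median(durations):.2f} min")
print(f"median monitoring time:   {np.median([r.monitoring_duration for r in masked]):.0f} min")
print(f"median TWA burden:        {np.median([b.twa for b in summaries]):.2f} mmHg")
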