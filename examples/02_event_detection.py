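"""Detect hypotensive events and burden metrics on a hand-checkable record.

A 60-min record sits at 80 mmHg except for two dips below the 65-mmHg
threshold: one sustained (8 samples, qualifies) and one of 40 s (too short
to count as an event). The printed numbers are directly verifiable by hand:
each 20-s sample below threshold contributes (65 - MAP)/3 mmHg*min of area
under the threshold (AUT), and TWA = AUT / monitoring minutes.
"""

import numpy as np

from hpeval import (
    AnalysisConfig,
    PatientRecord,
    area_under_threshold,
    detect_hypotensive_events,
    extract_non_event_points,
    twa_map,
)

m = np.full(180, 80.0)          # 60 min on the 20-s grid
m[30:38] = 60.0                 # 8 samples below threshold -> event
m[120:122] = 62.0               # 40 s below threshold -> not an event
rec = PatientRecord("demo", t=np.arange(180) * 20.0, map=m,
                    sbp=m + 30, dbp=m - 15, hr=np.full(180, 72.0))

cfg = AnalysisConfig()
events = detect_hypotensive_events(rec, cfg)
for ev in events:
    print(f"event: start {ev.start_t:.0f} s, {ev.n_samples} samples, "
          f"duration {ev.duration:.2f} min, AUT {ev.aut:.2f} mmHg*min, "
          f"nadir {ev.min_map:.0f} mmHg")
print(f"total AUT: {area_under_threshold(rec, events):.2f} mmHg*min "
      f"(the 40-s dip contributes nothing)")
print(f"TWA:       {twa_map(rec, events):.3f} mmHg over "
      f"{rec.monitoring_duration:.0f} min of monitoring")
nonevents = extract_non_event_points(rec, events, cfg)
print(f"non-event sections: {len(nonevents)} "
      f"(no 30-min normotensive span lies 20 min clear of the event "
      f"inside this 60-min record)")
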