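# Methods

This note documents the models, conventions and numerical choices behind
`hpeval`, in the order the pipeline applies them.

## Data model

Monitor exports are 20-s interval-averaged samples. Timestamps are seconds
from monitoring start on a nominal 20-s grid; ±2 s of jitter is tolerated
before an interval is reported as a gap. Poor-quality samples (the monitor's
own waveform-quality flag) are *removed*, not imputed: a removed sample
breaks every consecutive-sample run seen by the detectors, which is the
conservative reading of "excluded from analysis". Usable monitoring time is
counted as 20 s of exposure per retained sample, so masking 30 min of
samples shortens the TWA denominator by exactly 30 min even when the
removed samples are interior. Absent index scores are representable (empty
CSV cells, NaN in memory) and are never coerced to zero; operations that
need a score skip such samples.

CSV round-trips are bit-exact: floats are written with `%.17g` and parsed
with correctly-rounded conversion, so `read(write(cohort)) == cohort` field
for field.

## Event detection and burden

A hypotensive event is a maximal run of contiguous samples with MAP
strictly below 65 mmHg whose covered exposure (run length × 20 s) is at
least 60 s — i.e. at least three consecutive samples. Conventions worth
making explicit:

* A sample at exactly 65 mmHg belongs to neither events (strict `<`) nor
  normotensive sections (strict `>`), and it splits a sub-threshold run.
* No merging across recoveries: a single at-or-above-threshold sample
  separates two events.
* Sub-minute dips are not events and contribute nothing to the area under
  the threshold; burden is integrated over counted events only.
* Integration is rectangular — each sample is 20 s of exposure at its
  averaged value; the inputs are already interval averages, so trapezoidal
  smoothing would double-smooth. Per event, AUT = Σ (65 − MAP_i)/3 mmHg·min.
* TWA = total AUT / usable monitoring minutes; identically zero for
  event-free patients, undefined (an error) when no usable time remains.

Event `end_t` is the start plus covered exposure (exclusive), so distances
to either boundary are well defined for the gap rule below.

Bradycardia episodes are maximal runs with HR strictly below 60 beats/min.
No minimum duration is imposed (a single 20-s sample counts); the
`min_samples` argument makes this stricter when wanted.

## Non-event extraction

A non-event (ROC negative) is the centre sample of a 30-min continuous
section in which every sample has MAP > 65 mmHg, there are no missing
samples, and both section endpoints lie at least 20 min from every event
boundary (start or end). Sections are tiled greedily left-to-right without
overlap: the earliest feasible window is taken, then the search resumes at
its end. Greedy tiling is deterministic and allows several negatives per
patient; on the default synthetic cohort it yields ~50 negatives from 31
patients, the same order as the cohort sizes this design targets. A record
shorter than 30 min yields none.

## Horizon ROC

Each event contributes at most one positive per horizon h ∈ {5, 10, 15}
min: the score at the single sample nearest to onset − h, accepted only
within ±10 s. A windowed maximum would inflate sensitivity; a named time
point is the honest reading of "the value h minutes before the event". The
positive is dropped when the look-back sample does not exist (event too
early in the record), carries no score, or falls inside *another*
hypotensive event — such a sample does not represent a pre-hypotensive
state. This exclusion naturally thins positives at longer horizons.

Negatives are scored at their section centres. Classification is weak
inequality for alarms (score ≥ c) and strict for non-alarms (score < c).
Thresholds are the unique observed scores plus a sentinel above the
maximum; the curve and trapezoidal AUC come from scikit-learn
(`drop_intermediate=False`), and the AUC equals the tie-adjusted
concordance probability (verified against exhaustive pair counting in the
tests). The operating cutpoint minimizes |sens − spec|; ties prefer the
larger sens + spec, then the smaller threshold. (With both sens and spec
monotone in the threshold, two distinct zero-difference thresholds with
different sums cannot occur; the tie-breaks matter only for equal nonzero
differences.) PPV/NPV are reported at the cutpoint and are absent, not
zero, when their denominator is empty. `ppv_npv_from_rates` provides the
Bayes reconstruction ppv = sens·P/(sens·P + (1−spec)·N),
npv = spec·N/(spec·N + (1−sens)·P) from an operating point and class
counts.

The ΔMAP comparator is MAP(t − 15 min) − MAP(t), positive when pressure
has fallen, so larger values mean higher risk and positive cutpoints; both
endpoints must exist within ±10 s.

## Bootstrap inference

The patient is the exchangeable unit: each replicate draws N patients with
replacement from the N observed and regenerates the pooled labeled set
from the resampled patients (duplicates contribute duplicate points). Per
metric, SE is the standard deviation (ddof = 1) of replicate values;
replicates where a metric is undefined (e.g. a resample with no positives)
are dropped and counted, and a metric undefined in more than half the
replicates is declared not bootstrappable. The default interval is the
normal approximation estimate ± z·SE (z = 1.959964 at 95%), clamped to the
metric's range; a percentile interval is available but not default. The
cutpoint is selected once on the full cohort and held fixed across
replicates, so the CIs describe uncertainty at a fixed operating point;
re-selecting per replicate would mix cutpoint variability into every rate.
Replicate RNG comes from one master `SeedSequence` spawning a substream
per replicate, so results are reproducible and independent of evaluation
order. Default 2000 replicates.

## Synthetic cohort generator

The generator reproduces the summary structure the evaluation consumes —
not physiology. Defaults define the study scenario; all are configurable.

* **Monitoring duration**: lognormal, median 194 min, log-sd 0.5,
  floor 40 min.
* **Baseline MAP**: Ornstein–Uhlenbeck around 80 mmHg, mean reversion
  θ = 0.3 /min (half-life ≈ 2.3 min), diffusion σ = 2.0 mmHg/√min
  (stationary sd ≈ 2.6 mmHg), exact discretization at 20 s, started at the
  mean. At this amplitude the baseline essentially never crosses 65 mmHg
  on its own, so every event has a structured onset.
* **Episodes**: Poisson arrivals, cohort mean 1.8/h, with per-patient
  gamma frailty of shape 0.9 (mean 1). The frailty is what lets ~75–85% of
  patients have ≥ 1 event while the median count stays near 4: a pure
  Poisson process matching the median would leave almost no event-free
  patients. Each episode is a smooth dip taken as the pointwise minimum
  with the OU path: a cosine prodrome from baseline to 65 mmHg over
  10 min, a raised-cosine sub-threshold trough (depth lognormal, median
  6 mmHg, log-sd 0.6, clipped to [1, 40]; duration lognormal, median
  2.67 min, log-sd 0.8), and a 3-min cosine recovery. Smooth entry/exit
  avoids single-sample flicker across the threshold. The 10-min prodrome
  is the feature a trend-based predictor can exploit at a 5-min lead.
* **Other channels**: HR is an independent OU (per-patient mean
  N(75, 6²) bpm, stationary sd 4), occasionally dipping below 60 so the
  bradycardia counter has work; pulse pressure is constant per patient
  (N(45, 5²) mmHg) with SBP = MAP + 2PP/3, DBP = MAP − PP/3; samples are
  flagged poor-quality independently with probability 0.01.
* **Reproducibility**: one master seed spawns a `SeedSequence` substream
  per patient index, so cohorts are identical across runs and independent
  of generation order.

Calibration of these defaults against their targets (fraction of patients
with ≥ 1 event ≈ 77%, median ~4 events/patient, median event duration
≈ 2.67 min, median TWA ≈ 0.18 mmHg, ~50 negatives per cohort) is asserted
by the test suite over seeded replicates with Monte-Carlo tolerances.

**Surrogate index**: at each sample, a least-squares line through the
preceding 3 min of MAP (9 samples; scores are absent until the window
fills) is extrapolated 5 min ahead, and the predicted MAP is mapped to
100·logistic(0.5·(65 − predicted)) + N(0, 3²), clipped to [0, 100]. It is
monotone decreasing in predicted MAP at zero noise, scores 50 exactly when
the prediction sits on the threshold, and — because AUC is invariant to
monotone transforms — its discrimination is governed by the predicted-MAP
ranking plus the additive noise, not by the logistic slope. **Null index**:
i.i.d. uniform [0, 100], exactly exchangeable with labels, so its AUC must
be statistically indistinguishable from 0.5; a shuffled surrogate would
not give exact exchangeability.

What the generator does *not* emulate: treatment feedback (vasopressors
truncating events), HR–MAP coupling, drift in baseline over a case,
realistic waveform-quality clustering, or any mechanism of the proprietary
indices it stands in for. Passing tests therefore demonstrate that the
*evaluation machinery* is correct and well calibrated, not that any
particular commercial index performs at the reported level on real
patients.

## Problem sizes and runtime

Default analyses use 31-patient cohorts (~600 samples per patient), 2000
bootstrap replicates, and oracle-equivalence sweeps of 1000 random records
(≤ 500 samples) and 1000 random labeled sets (≤ 200 points); the full test
suite runs in well under a minute and the acceptance script in a few
seconds. Orchestrated runs in tests use smaller cohorts (5–8 patients,
20–50 replicates), which exercise every code path at negligible cost.

## Known limitations

* The non-event rule ("30-min section, 20 min from any event") is applied
  with multiple sections per patient; sources differ on whether one or many
  were intended, and the greedy tiling is this package's deterministic
  choice.
* Bradycardia has no minimum duration; a single 20-s sample counts.
* The normal-approximation CI can be anti-conservative for AUCs near 1
  with few patients; the percentile option is available.
* `delta_map` positives are not excluded when their *earlier* endpoint
  falls inside a previous event (only index look-backs are), matching the
  comparator's definition as a raw difference.
* The generator's episode depths/durations are independent; real events
  likely correlate depth with duration.
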