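"""Look-back scoring, ROC/AUC, cutpoint selection and predictive values."""

import numpy as np
import pytest

from hpeval import (
    HypotensiveEvent,
    LabeledPoint,
    NoEvaluableDataError,
    NonEventPoint,
    build_labeled_set,
    confusion_metrics,
    delta_map_score,
    lookback_score,
    ppv_npv_from_rates,
    roc_curve,
    select_cutpoint,
)

from conftest import make_record


def lp(label, score):
    return LabeledPoint("P", 0.0, label, float(score), 5.0, "index")


def points_from(pos, neg):
    return [lp(1, s) for s in pos] + [lp(0, s) for s in neg]


def pair_count_auc(pos, neg):
    """Independent concordance oracle: exhaustive pair counting, ties half."""
    pos = np.asarray(pos, float)[:, None]
    neg = np.asarray(neg, float)[None, :]
    return float(((pos > neg).sum() + 0.5 * (pos == neg).sum()) / (pos.size * neg.size))


def event_at(start, pid="P1"):
    return HypotensiveEvent(
        patient_id=pid, start_t=start, end_t=start + 60.0, n_samples=3,
        duration=1.0, aut=3.0, min_map=60.0,
    )


class TestLookback:
    def test_exact_grid_lookback(self, cfg):
        rec = make_record([80.0] * 100, score=np.arange(100, dtype=float))
        s = lookback_score(rec, event_at(1200.0), 5.0, "index", cfg)
        assert s == 45.0  # sample at t=900 s

    def test_lookback_before_monitoring_is_absent(self, cfg):
        rec = make_record([80.0] * 100, score=np.arange(100, dtype=float))
        assert lookback_score(rec, event_at(240.0), 10.0, "index", cfg) is None

    def test_jittered_grid_uses_nearest_within_tolerance(self, cfg):
        t = np.arange(100) * 20.0 + 5.0  # nearest to 900 is 905
        rec = make_record([80.0] * 100, t=t, score=np.arange(100, dtype=float))
        assert lookback_score(rec, event_at(1205.0), 5.0, "index", cfg) == 45.0

    def test_lookback_inside_other_event_is_excluded(self, cfg):
        rec = make_record([80.0] * 100, score=np.arange(100, dtype=float))
        ev = event_at(1200.0)
        other = event_at(880.0)  # covers [880, 940): contains t=900
        assert lookback_score(rec, ev, 5.0, "index", cfg, events=[other, ev]) is None

    def test_absent_score_sample_is_excluded(self, cfg):
        score = np.arange(100, dtype=float)
        score[45] = np.nan
        rec = make_record([80.0] * 100, score=score)
        assert lookback_score(rec, event_at(1200.0), 5.0, "index", cfg) is None


class TestDeltaMap:
    def test_constant_map_gives_zero(self):
        rec = make_record([80.0] * 100)
        assert delta_map_score(rec, 1800.0) == 0.0

    def test_linear_decline_one_mmhg_per_min(self):
        t = np.arange(100) * 20.0
        rec = make_record(80.0 - t / 60.0, t=t)
        assert delta_map_score(rec, 1800.0) == pytest.approx(15.0)

    def test_rising_map_is_negative(self):
        t = np.arange(100) * 20.0
        rec = make_record(80.0 + 0.5 * t / 60.0, t=t)
        assert delta_map_score(rec, 1800.0) == pytest.approx(-7.5)

    def test_missing_endpoint_is_absent(self):
        rec = make_record([80.0] * 30)  # 10 min of data
        assert delta_map_score(rec, 500.0) is None


class TestBuildLabeledSet:
    def _toy(self, cfg):
        m = np.full(400, 80.0)
        m[120:126] = 60.0   # event at t=2400
        m[350:356] = 60.0   # event at t=7000
        rec = make_record(m, score=np.full(400, 30.0))
        from hpeval import detect_hypotensive_events, extract_non_event_points

        events = detect_hypotensive_events(rec, cfg)
        nonevents = extract_non_event_points(rec, events, cfg)
        return rec, events, nonevents

    def test_toy_counts(self, cfg):
        rec, events, nonevents = self._toy(cfg)
        assert len(events) == 2 and len(nonevents) >= 1
        pts = build_labeled_set(
            [rec], {"P1": events}, {"P1": nonevents[:1]}, 5.0, "index", cfg
        )
        assert sum(p.label for p in pts) == 2
        assert sum(1 - p.label for p in pts) == 1

    def test_error_names_missing_class(self, cfg):
        rec, events, nonevents = self._toy(cfg)
        with pytest.raises(NoEvaluableDataError, match="positive"):
            build_labeled_set([rec], {"P1": []}, {"P1": nonevents}, 5.0, "index", cfg)
        with pytest.raises(NoEvaluableDataError, match="negative"):
            build_labeled_set([rec], {"P1": events}, {"P1": []}, 5.0, "index", cfg)

    def test_longer_horizons_cannot_gain_positives(self, default_cfg, surrogate_cohort):
        masked, events, nonevents = surrogate_cohort
        n_pos = {}
        for h in (5.0, 15.0):
            pts = build_labeled_set(masked, events, nonevents, h, "index", default_cfg)
            n_pos[h] = sum(p.label for p in pts)
        assert n_pos[15.0] <= n_pos[5.0]


class TestRocCurve:
    def test_perfect_separation(self):
        assert roc_curve(points_from([0.8, 0.9], [0.1, 0.2])).auc == 1.0

    def test_all_scores_identical(self):
        assert roc_curve(points_from([1.0, 1.0], [1.0, 1.0, 1.0])).auc == 0.5

    def test_hand_counted_auc(self):
        assert roc_curve(points_from([0.9, 0.4], [0.5, 0.1])).auc == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([lp(1, 0.5)])

    def test_matches_pair_counting_on_random_sets(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            n_pos = int(rng.integers(1, 100))
            n_neg = int(rng.integers(1, 100))
            pos = rng.integers(0, 10, n_pos) / 10.0  # discrete: forces ties
            neg = rng.integers(0, 10, n_neg) / 10.0
            got = roc_curve(points_from(pos, neg)).auc
            assert got == pytest.approx(pair_count_auc(pos, neg))

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(23)
        pos = rng.normal(1.0, 1.0, 40)
        neg = rng.normal(0.0, 1.0, 50)
        a1 = roc_curve(points_from(pos, neg)).auc
        a2 = roc_curve(points_from(np.exp(pos), np.exp(neg))).auc
        assert a1 == pytest.approx(a2)

    def test_label_swap_complements_auc(self):
        rng = np.random.default_rng(29)
        pos = rng.normal(1.0, 1.0, 30)
        neg = rng.normal(0.0, 1.0, 30)
        a = roc_curve(points_from(pos, neg)).auc
        b = roc_curve(points_from(neg, pos)).auc
        assert a + b == pytest.approx(1.0)


class TestCutpoint:
    def test_zero_diff_cutpoint(self):
        curve = roc_curve(points_from([0.9, 0.4], [0.5, 0.1]))
        cut = select_cutpoint(curve)
        assert cut.threshold == 0.5
        assert cut.sens == cut.spec == 0.5

    def test_perfect_separation_returns_smallest_qualifying(self):
        curve = roc_curve(points_from([0.8, 0.9], [0.1, 0.2]))
        cut = select_cutpoint(curve)
        assert cut.threshold == 0.8
        assert cut.sens == cut.spec == 1.0

    def test_tied_diff_prefers_larger_sens_plus_spec(self):
        # thresholds 3 and 2 both give |sens-spec| = 0.5; sums differ
        curve = roc_curve(points_from([2.0, 2.0], [1.0, 3.0]))
        cut = select_cutpoint(curve)
        assert cut.threshold == 2.0
        assert (cut.sens, cut.spec) == (1.0, 0.5)

    def test_tied_diff_and_sum_prefers_smallest_threshold(self):
        # thresholds 5 and 3 give (0.5, 1.0) and (1.0, 0.5): same diff, same sum
        curve = roc_curve(points_from([3.0, 5.0], [1.0, 3.0]))
        cut = select_cutpoint(curve)
        assert cut.threshold == 3.0

    def test_confusion_at_cutpoint_reproduces_rates(self):
        rng = np.random.default_rng(31)
        pts = points_from(rng.normal(1, 1, 60), rng.normal(0, 1, 60))
        cut = select_cutpoint(roc_curve(pts))
        cm = confusion_metrics(pts, cut.threshold)
        assert cm.sens == pytest.approx(cut.sens)
        assert cm.spec == pytest.approx(cut.spec)


class TestConfusionAndPredictiveValues:
    def test_hand_counts(self):
        pts = points_from([1.0] * 55 + [0.0] * 9, [1.0] * 7 + [0.0] * 42)
        cm = confusion_metrics(pts, 0.5)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (55, 7, 42, 9)
        assert cm.sens == pytest.approx(55 / 64)
        assert cm.spec == pytest.approx(42 / 49)
        assert cm.ppv == pytest.approx(55 / 62)
        assert cm.npv == pytest.approx(42 / 51)

    def test_threshold_below_all_scores(self):
        cm = confusion_metrics(points_from([0.5], [0.5]), 0.0)
        assert (cm.sens, cm.spec) == (1.0, 0.0)
        assert cm.npv is None

    def test_threshold_above_all_scores(self):
        cm = confusion_metrics(points_from([0.5], [0.5]), 2.0)
        assert (cm.sens, cm.spec) == (0.0, 1.0)
        assert cm.ppv is None

    def test_ppv_npv_closed_form_consistent_with_counts(self):
        ppv, npv = ppv_npv_from_rates(55 / 64, 42 / 49, 64, 49)
        assert ppv == pytest.approx(55 / 62)
        assert npv == pytest.approx(42 / 51)

    def test_perfect_rates(self):
        assert ppv_npv_from_rates(1.0, 1.0, 10, 10) == (1.0, 1.0)

    def test_degenerate_denominator_is_absent(self):
        ppv, npv = ppv_npv_from_rates(0.0, 1.0, 5, 5)
        assert ppv is None
        assert npv == pytest.approx(5 / 10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            ppv_npv_from_rates(1.2, 0.5, 5, 5)
        with pytest.raises(ValueError):
            ppv_npv_from_rates(0.5, 0.5, 0, 5)


class TestConcordanceProperty:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    scores = st.lists(st.integers(0, 8), min_size=1, max_size=30)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(pos=scores, neg=scores)
    def test_trapezoid_auc_equals_pair_counting(self, pos, neg):
        from hpeval import rank_auc

        curve_auc = roc_curve(points_from(pos, neg)).auc
        assert curve_auc == pytest.approx(pair_count_auc(pos, neg))
        assert rank_auc(pos, neg) == pytest.approx(pair_count_auc(pos, neg))
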