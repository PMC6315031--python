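"""Baseline estimation, threshold detection, CUSUM segmentation,
level assignment, classification and clustering."""

import numpy as np
import pytest

from poretrace.detect import (
    DetectionConfig,
    assign_levels,
    categorize_barcoded,
    classify_event,
    cluster_events,
    detect_events,
    estimate_baseline,
    fit_levels_cusum,
    segment_event,
)
from poretrace.pipeline import analyze_trace
from poretrace.simulate import TraceConfig, generate_trace
from poretrace.trace import CurrentTrace, Event, LevelSegment

FS = 100e3


def _event(level_means, n_per=100, baseline=6.0, labels=None, fs=FS):
    segs = []
    pos = 0
    for i, m in enumerate(level_means):
        seg = LevelSegment(pos, pos + n_per, m)
        if labels is not None:
            seg.level_label = labels[i]
        segs.append(seg)
        pos += n_per
    return Event(segments=segs, sampling_rate=fs, baseline_current=baseline)


class TestBaseline:
    def test_pure_baseline_recovered(self, sinx):
        cfg = TraceConfig(presets=sinx, duration=2.0, event_rate=0.0, seed=4)
        trace, _ = generate_trace(cfg)
        est = estimate_baseline(trace)
        se = trace.samples.std() / np.sqrt(len(trace))
        assert np.all(np.abs(est.means - sinx.baseline_nA) < max(3 * se, 3 * est.sds.mean()))

    def test_robust_to_deep_event(self, sinx):
        cfg = TraceConfig(presets=sinx, duration=2.0, event_rate=0.0, seed=4)
        trace, _ = generate_trace(cfg)
        clean = estimate_baseline(trace).means
        dirty = trace.samples.copy()
        dirty[5000:12000] -= 1.5  # one deep event, <20% of the window
        est = estimate_baseline(CurrentTrace(dirty, trace.sampling_rate)).means
        assert np.all(np.abs(est - clean) / clean < 0.01)

    def test_constant_trace_flagged(self):
        est = estimate_baseline(CurrentTrace(np.full(1000, 5.0), FS))
        assert est.constant
        assert np.all(est.sds == 0)


class TestDetectEvents:
    def test_recall_and_precision_on_preset_snr(self, sinx_run, sinx_events):
        trace, ann = sinx_run
        events = sinx_events
        matched_truth = 0
        for a in ann:
            if any(min(ev.end, a.end) - max(ev.start, a.start) > 0.5 * (a.end - a.start)
                   for ev in events):
                matched_truth += 1
        matched_det = 0
        for ev in events:
            if any(min(ev.end, a.end) - max(ev.start, a.start) > 0.5 * (a.end - a.start)
                   for a in ann):
                matched_det += 1
        assert matched_truth / len(ann) >= 0.95  # recall
        assert matched_det / len(events) >= 0.95  # precision

    def test_false_event_rate_on_white_noise(self):
        """At a 4-sigma threshold on white noise the count of detected
        excursions tracks the Gaussian tail expectation."""
        rng = np.random.default_rng(8)
        n = 2_000_000
        trace = CurrentTrace(5.0 + 0.01 * rng.standard_normal(n), FS)
        cfg = DetectionConfig(threshold_sd=4.0, hysteresis_sd=3.9, pad_sd=3.9,
                              min_duration_samples=3)
        # min duration 3 samples: expected runs of >=1 sample scaled by the
        # run-length distribution; count single-sample crossings instead
        cfg3 = DetectionConfig(threshold_sd=4.0, hysteresis_sd=3.9, pad_sd=3.9,
                               min_duration_samples=3)
        events = detect_events(trace, cfg3)
        from scipy.stats import norm

        p = norm.cdf(-4.0)
        expected_crossing_samples = n * p
        # events of >=3 consecutive sub-threshold samples are much rarer
        assert len(events) <= expected_crossing_samples
        total_below = int(np.sum(trace.samples < 5.0 - 4.0 * 0.01))
        assert 0.5 * expected_crossing_samples < total_below < 2.0 * expected_crossing_samples

    def test_truncated_event_flagged_and_excluded(self, sinx):
        cfg = TraceConfig(presets=sinx, duration=1.0, event_rate=0.0, seed=4)
        trace, _ = generate_trace(cfg)
        x = trace.samples.copy()
        x[-2000:] -= 1.5  # event still open at the trace end
        t2 = CurrentTrace(x, FS)
        assert detect_events(t2, DetectionConfig()) == []
        inc = detect_events(t2, DetectionConfig(include_truncated=True))
        assert len(inc) == 1 and inc[0].truncated


class TestCusum:
    def test_noiseless_piecewise_exact(self):
        x = np.concatenate([np.full(200, 4.5), np.full(150, 5.2), np.full(250, 4.5)])
        x = x + 1e-6 * np.sin(np.arange(x.size))  # avoid sd == 0 shortcut
        segs = fit_levels_cusum(x, DetectionConfig(), noise_sd=1e-6)
        assert len(segs) == 3
        assert segs[0][1] == 200 and segs[1][1] == 350
        assert segs[0][2] == pytest.approx(4.5, abs=1e-5)

    def test_constant_plus_white_noise_single_segment(self):
        rng = np.random.default_rng(1)
        x = 5.0 + 0.01 * rng.standard_normal(3000)
        segs = fit_levels_cusum(x, DetectionConfig())
        assert len(segs) == 1

    def test_segmentation_idempotent(self, sinx_run, sinx_events):
        trace, _ = sinx_run
        ev = next(e for e in sinx_events if e.event_class == "212")
        for seg in ev.segments:
            again = fit_levels_cusum(trace.samples[seg.start : seg.end], DetectionConfig())
            assert len(again) == 1

    def test_change_points_near_truth_on_212(self, sinx, sinx_run, sinx_events):
        trace, ann = sinx_run
        hits = 0
        checked = 0
        for a in ann:
            if a.event_class != "212":
                continue
            ev = next((e for e in sinx_events
                       if min(e.end, a.end) - max(e.start, a.start) > 0), None)
            if ev is None or len(ev.segments) != 3:
                continue
            checked += 1
            dwell = a.end - a.start
            tol = 5 + 0.01 * dwell
            fitted_cp = [s.start for s in ev.segments[1:]]
            true_cp = list(a.segment_starts[1:])
            if all(abs(f - t) <= tol for f, t in zip(fitted_cp, true_cp)):
                hits += 1
        assert checked > 0
        assert hits == checked


class TestAssignClassify:
    BANDS = {0: 0.0, 1: 0.8, 2: 1.5}

    def test_known_blockades_assigned(self):
        ev = _event([4.5, 5.2, 4.5])  # baseline 6.0: depths 1.5, 0.8, 1.5
        assign_levels(ev, self.BANDS)
        assert [s.level_label for s in ev.segments] == [2, 1, 2]
        assert classify_event(ev) == "212"

    def test_zero_blockade_is_level0(self):
        ev = _event([6.0])
        assign_levels(ev, self.BANDS)
        assert ev.segments[0].level_label == 0

    def test_midway_blockade_unassigned(self):
        ev = _event([6.0 - 1.15])  # exactly between the 0.8 and 1.5 bands
        assign_levels(ev, self.BANDS)
        assert ev.segments[0].level_label is None
        assert classify_event(ev) == "other"

    def test_class_string_collapses_runs(self):
        ev = _event([4.5, 4.5], labels=[2, 2])
        assert classify_event(ev) == "2"
        ev = _event([5.2, 5.2], labels=[1, 1])
        assert classify_event(ev) == "other"  # collapses to "1"
        ev = _event([4.5, 5.2], labels=[2, 1])
        assert classify_event(ev) == "21"

    def test_collapse_invariant_to_subdivision(self):
        whole = _event([4.5, 5.2, 4.5], labels=[2, 1, 2])
        split = _event([4.5, 4.5, 5.2, 5.2, 4.5], labels=[2, 2, 1, 1, 2])
        assert classify_event(whole) == classify_event(split) == "212"

    def test_noiseless_classification_exact(self, sinx):
        cfg = TraceConfig(presets=sinx, duration=20.0, event_rate=4.0, seed=55,
                          blockade_jitter=False)
        trace, ann = generate_trace(cfg)
        events = analyze_trace(trace, sinx)
        assert len(events) == len(ann)
        for ev, a in zip(events, ann):
            assert ev.event_class == a.event_class


class TestClusterEvents:
    def _population(self, sinx, seed=13):
        cfg = TraceConfig(
            presets=sinx, duration=60.0, event_rate=5.0, seed=seed, n_events=240,
            class_mixture={"2": 1 / 3, "21": 1 / 3, "212": 1 / 3},
        )
        trace, ann = generate_trace(cfg)
        events = analyze_trace(trace, sinx)
        truth = []
        for ev in events:
            best = min(ann, key=lambda a: abs(a.start - ev.start))
            truth.append(best.event_class)
        return events, truth

    def test_three_class_population_agreement(self, sinx):
        events, truth = self._population(sinx)
        res = cluster_events(events, k=3, seed=0)
        # majority-class mapping per cluster
        agree = 0
        for c in range(3):
            members = [t for t, l in zip(truth, res.labels) if l == c]
            if members:
                agree += max(members.count(cls) for cls in set(members))
        assert agree / len(truth) >= 0.90

    def test_deterministic_given_seed(self, sinx):
        events, _ = self._population(sinx)
        r1 = cluster_events(events, k=3, seed=5)
        r2 = cluster_events(events, k=3, seed=5)
        np.testing.assert_array_equal(r1.labels, r2.labels)

    def test_identical_features_flagged_degenerate(self):
        events = [_event([4.5], n_per=100) for _ in range(10)]
        res = cluster_events(events, k=3, seed=0)
        assert res.degenerate

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            cluster_events([_event([4.5])], k=3)


class TestCategorizeBarcoded:
    def test_threshold_rule(self):
        bias = 200.0
        deep = _event([6.0 - 3.2 * bias * 1e-3])  # 3.2 nS secondary level
        shallow = _event([6.0 - 1.8 * bias * 1e-3])
        assert categorize_barcoded(deep, bias) == "barcoded"
        assert categorize_barcoded(shallow, bias) == "plain"
        # boundary rule is a strict inequality: exactly-at-threshold is plain
        exactly_at = deep.blockage_conductance(bias)
        assert categorize_barcoded(deep, bias, threshold_nS=exactly_at) == "plain"
        with pytest.raises(ValueError):
            categorize_barcoded(deep, 0.0)
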