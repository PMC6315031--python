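"""Event/trace generation: structure, truth fidelity, determinism."""

import numpy as np
import pytest

from poretrace.simulate import (
    TraceConfig,
    default_presets,
    generate_event,
    generate_trace,
)


class TestGenerateEvent:
    def test_212_fractions_respected(self, sinx):
        _, truth = generate_event(
            "212", sinx, 10e-3, (0.43, 0.25, 0.32), 100e3, 0, blockade_jitter=False
        )
        counts = np.array(truth["segment_counts"])
        assert counts.sum() == 1000
        np.testing.assert_allclose(counts, [430, 250, 320], atol=1)
        assert truth["segment_levels"] == (2, 1, 2)

    def test_single_level_event(self, sinx):
        samples, truth = generate_event("2", sinx, 2e-3, (1.0,), 100e3, 0,
                                        blockade_jitter=False)
        assert truth["segment_levels"] == (2,)
        assert samples.mean() == pytest.approx(-1.5, abs=0.01)

    def test_barcoded_center_at_midpoint(self, mos2):
        w = mos2.barcode_width_fraction
        fractions = (0.5 - w / 2, w, 0.5 - w / 2)
        _, truth = generate_event("121", mos2, 4e-3, fractions, 100e3, 0)
        starts = truth["segment_starts"]
        counts = truth["segment_counts"]
        center = starts[1] + counts[1] / 2
        assert center == pytest.approx(truth["n_samples"] / 2, abs=1.0)
        assert truth["segment_levels"] == (1, 2, 1)

    def test_too_short_segment_rejected(self, sinx):
        with pytest.raises(ValueError, match="3 samples"):
            generate_event("212", sinx, 0.05e-3, (0.43, 0.25, 0.32), 100e3, 0)

    def test_bad_fractions_rejected(self, sinx):
        with pytest.raises(ValueError, match="fractions"):
            generate_event("212", sinx, 5e-3, (0.5, 0.5), 100e3, 0)


class TestGenerateTrace:
    def test_zero_rate_gives_pure_baseline(self, sinx):
        cfg = TraceConfig(presets=sinx, duration=0.5, event_rate=0.0, seed=0)
        trace, ann = generate_trace(cfg)
        assert len(ann) == 0
        assert trace.samples.mean() == pytest.approx(sinx.baseline_nA, abs=0.01)

    def test_identical_seed_bit_identical(self, sinx):
        cfg = TraceConfig(presets=sinx, duration=2.0, event_rate=5.0, seed=9)
        t1, a1 = generate_trace(cfg)
        t2, a2 = generate_trace(cfg)
        np.testing.assert_array_equal(t1.samples, t2.samples)
        assert [(e.start, e.end, e.event_class) for e in a1] == [
            (e.start, e.end, e.event_class) for e in a2
        ]

    def test_class_mixture_fraction(self, sinx):
        cfg = TraceConfig(presets=sinx, duration=90.0, event_rate=8.0, seed=3,
                          n_events=500)
        _, ann = generate_trace(cfg)
        frac = sum(a.event_class == "212" for a in ann) / len(ann)
        # 95% binomial interval around the mixture probability 0.10
        assert abs(frac - 0.10) < 1.96 * np.sqrt(0.1 * 0.9 / 500)

    def test_events_sorted_nonoverlapping_with_guard(self, sinx_run):
        _, ann = sinx_run
        guard = int(5e-3 * 100e3)
        for a, b in zip(ann, list(ann)[1:]):
            assert b.start - a.end >= guard

    def test_annotation_fidelity(self, sinx):
        """Re-measured segment means match preset levels within 3 SE."""
        cfg = TraceConfig(presets=sinx, duration=8.0, event_rate=5.0, seed=21,
                          blockade_jitter=False)
        trace, ann = generate_trace(cfg)
        assert len(ann) > 5
        base = sinx.baseline_nA
        for a in ann:
            ends = list(a.segment_starts[1:]) + [a.end]
            for s0, e0, lvl in zip(a.segment_starts, ends, a.segment_levels):
                chunk = trace.samples[s0:e0]
                depth = base - chunk.mean()
                se = chunk.std() / np.sqrt(chunk.size)
                expected = sinx.levels[lvl].blockade_nA
                assert abs(depth - expected) < 3 * se + 1e-9

    def test_dwell_fractions_sum_to_one(self, sinx_run):
        _, ann = sinx_run
        for a in ann:
            assert sum(a.segment_fractions) == pytest.approx(1.0, abs=1e-9)

    def test_infeasible_density_raises(self, sinx):
        with pytest.raises(ValueError, match="infeasible"):
            generate_trace(TraceConfig(presets=sinx, duration=1.0, event_rate=200.0, seed=0))

    def test_overfull_fixed_count_raises(self, sinx):
        with pytest.raises(ValueError, match="could only place"):
            generate_trace(TraceConfig(presets=sinx, duration=1.0, event_rate=10.0,
                                       seed=0, n_events=100))


class TestDefaultPresets:
    def test_sinx_levels(self, sinx):
        assert sinx.levels[1].blockade_nA == pytest.approx(0.8)
        assert sinx.levels[2].blockade_nA == pytest.approx(1.5)
        assert sinx.class_mixture["212"] == pytest.approx(0.10)

    def test_mos2_levels_in_conductance(self, mos2):
        to_nS = 1e3 / mos2.bias_mV
        assert mos2.levels[1].blockade_nA * to_nS == pytest.approx(1.8)
        assert mos2.levels[2].blockade_nA * to_nS == pytest.approx(3.2)
        assert mos2.orientation_p5 == pytest.approx(0.52)

    def test_unknown_system_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            default_presets("quartz")

    def test_level1_blockade_below_level2(self, sinx, mos2):
        for bundle in (sinx, mos2):
            assert bundle.levels[1].blockade_nA < bundle.levels[2].blockade_nA

    def test_dirichlet_concentration_matches_printed_sds(self, sinx):
        """The single concentration reproduces the printed per-segment sds
        as a least-squares compromise (all within a factor ~1.5)."""
        c = sinx.dirichlet_concentration
        m = np.array(sinx.dirichlet_mean)
        sds = np.sqrt(m * (1 - m) / (c + 1))
        target = np.array([0.12, 0.12, 0.08])
        assert np.all(sds / target < 1.5)
        assert np.all(sds / target > 0.67)
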