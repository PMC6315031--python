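"""Dwell fractions, barcode orientation/localization, pore geometry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from poretrace.simulate import TraceConfig, generate_trace
from poretrace.pipeline import analyze_trace, localize_barcodes
from poretrace.trace import Event, LevelSegment
from poretrace.translocation import (
    aggregate_dwell_fractions,
    barcode_position_histogram,
    detect_orientation,
    expected_relative_position,
    fractional_dwell_times,
    invert_pore_diameter,
    normalize_and_mirror,
    orientation_dwell_stats,
    pore_conductance,
    secondary_level_center,
)

TEMPLATE = "GACTAGGGTGACAATCTACCAC"  # written 3' -> 5'


def _event(counts, labels, means=None, baseline=6.0):
    segs = []
    pos = 0
    means = means or [baseline - (1.5 if l == 2 else 0.8) for l in labels]
    for c, l, m in zip(counts, labels, means):
        seg = LevelSegment(pos, pos + c, m)
        seg.level_label = l
        segs.append(seg)
        pos += c
    cls = "".join(str(l) for l in labels)
    cls = cls if cls in ("2", "21", "212") else "other"
    ev = Event(segments=segs, sampling_rate=100e3, baseline_current=baseline)
    ev.event_class = cls
    return ev


class TestDwellFractions:
    def test_printed_example(self):
        ev = _event([43, 25, 32], [2, 1, 2])
        assert fractional_dwell_times(ev) == pytest.approx((0.43, 0.25, 0.32))

    def test_equal_durations(self):
        ev = _event([50, 50, 50], [2, 1, 2])
        assert fractional_dwell_times(ev) == pytest.approx((1 / 3,) * 3)

    def test_wrong_class_rejected(self):
        ev = _event([50, 50], [2, 1])
        with pytest.raises(ValueError, match="212"):
            fractional_dwell_times(ev)

    def test_aggregate_of_identical_events_has_zero_sd(self):
        agg = aggregate_dwell_fractions([(0.4, 0.3, 0.3)] * 5)
        assert agg.sd == pytest.approx((0.0, 0.0, 0.0))
        assert sum(agg.mean) == pytest.approx(1.0)

    def test_constant_velocity_reference_deviation_zero(self):
        # segment dwell fractions proportional to designed contour lengths
        contour = (0.45, 0.2, 0.35)
        agg = aggregate_dwell_fractions([contour] * 4, reference_fractions=contour)
        assert agg.reference_deviation == pytest.approx((0.0, 0.0, 0.0))

    def test_dirichlet_population_recovers_printed_means(self, sinx):
        rng = np.random.default_rng(0)
        alpha = np.asarray(sinx.dirichlet_mean) * sinx.dirichlet_concentration
        draws = rng.dirichlet(alpha, size=31)
        agg = aggregate_dwell_fractions(draws)
        for m, target, sd in zip(agg.mean, (0.43, 0.25, 0.32), (0.12, 0.12, 0.08)):
            assert abs(m - target) < 2 * sd / np.sqrt(31)


class TestOrientation:
    SITE = 7.0 / 22.0  # ~0.318

    def test_center_near_site_is_3p(self):
        orientation, _ = detect_orientation(0.30, self.SITE)
        assert orientation == "3p_entry"

    def test_mirrored_center_is_5p(self):
        orientation, _ = detect_orientation(0.68, self.SITE)
        assert orientation == "5p_entry"

    def test_exact_tie_unassigned(self):
        orientation, _ = detect_orientation(0.5, self.SITE)
        assert orientation == "unassigned"

    def test_event_without_secondary_level_rejected(self):
        ev = _event([100], [1])
        with pytest.raises(ValueError, match="secondary"):
            secondary_level_center(ev)

    def test_secondary_center_from_labeled_event(self):
        ev = _event([40, 20, 140], [1, 2, 1], means=[5.6, 5.3, 5.6])
        assert secondary_level_center(ev) == pytest.approx(0.25)


class TestMirroring:
    def test_known_mirror(self):
        pos, excluded = normalize_and_mirror([0.7, 0.3], ["5p_entry", "3p_entry"])
        np.testing.assert_allclose(pos, [0.3, 0.3])
        assert excluded == 0

    def test_unassigned_excluded_and_counted(self):
        pos, excluded = normalize_and_mirror([0.5, 0.2], ["unassigned", "3p_entry"])
        assert pos.tolist() == [0.2]
        assert excluded == 1

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=50)
    def test_mirroring_is_involution(self, positions):
        orientations = ["5p_entry"] * len(positions)
        once, _ = normalize_and_mirror(positions, orientations)
        twice, _ = normalize_and_mirror(once, orientations)
        np.testing.assert_allclose(twice, positions, atol=1e-12)


class TestHistogram:
    def test_mode_bin_contains_site_for_simulated_population(self, mos2):
        cfg = TraceConfig(presets=mos2, duration=12.0, event_rate=20.0, seed=31,
                          n_events=104, class_mixture={"121": 1.0})
        trace, _ = generate_trace(cfg)
        events = analyze_trace(trace, mos2)
        site = expected_relative_position(TEMPLATE, "CCC")
        df = localize_barcodes(events, mos2.bias_mV, site)
        bc = df[(df.category == "barcoded") & (df.orientation != "unassigned")]
        hist = barcode_position_histogram(bc.position_3p_frame.values, 20,
                                          expected_position=site)
        width = hist.edges[1] - hist.edges[0]
        assert abs(hist.mode - site) <= width
        assert hist.n_events >= 90

    def test_identical_positions_single_bin(self):
        hist = barcode_position_histogram([0.33] * 12, 10)
        assert (hist.counts > 0).sum() == 1
        assert hist.mode == pytest.approx(0.35, abs=0.05)

    def test_uniform_positions_flat(self):
        rng = np.random.default_rng(7)
        pos = rng.uniform(0, 1, 2000)
        hist = barcode_position_histogram(pos, 10)
        from scipy.stats import chisquare

        stat, p = chisquare(hist.counts)
        assert p > 0.01

    def test_invariant_to_event_order(self):
        rng = np.random.default_rng(8)
        pos = rng.uniform(0, 1, 100)
        h1 = barcode_position_histogram(pos, 15)
        h2 = barcode_position_histogram(pos[::-1], 15)
        np.testing.assert_array_equal(h1.counts, h2.counts)

    def test_too_few_events_rejected(self):
        with pytest.raises(ValueError, match="10"):
            barcode_position_histogram([0.5] * 5)


class TestExpectedPosition:
    def test_printed_template_and_barcode(self):
        # CCC pairs with the single GGG run at positions 6-8 from the 3' end
        assert expected_relative_position(TEMPLATE, "CCC") == pytest.approx(7 / 22)

    def test_full_complement_centers_at_half(self):
        barcode = TEMPLATE.translate(str.maketrans("ACGT", "TGCA"))
        assert expected_relative_position(TEMPLATE, barcode) == pytest.approx(
            (1 + 22) / 2 / 22
        )

    def test_absent_site_rejected(self):
        with pytest.raises(ValueError, match="found 0"):
            expected_relative_position(TEMPLATE, "AAA")  # needs TTT on template

    def test_multiple_sites_rejected(self):
        with pytest.raises(ValueError, match="exactly one"):
            expected_relative_position(TEMPLATE, "C")  # G occurs repeatedly


class TestOrientationDwellStats:
    def test_fractions_and_dwells(self):
        orients = ["5p_entry"] * 6 + ["3p_entry"] * 4 + ["unassigned"]
        dwells = [3e-3] * 6 + [1e-3] * 4 + [9e-3]
        st_ = orientation_dwell_stats(orients, dwells)
        assert st_["5p_entry"]["fraction"] == pytest.approx(0.6)
        assert st_["5p_entry"]["mean_dwell_ms"] == pytest.approx(3.0)
        assert st_["3p_entry"]["mean_dwell_ms"] == pytest.approx(1.0)
        assert st_["n_unassigned"] == 1

    def test_single_orientation_input(self):
        st_ = orientation_dwell_stats(["5p_entry"] * 3, [2e-3] * 3)
        assert st_["3p_entry"]["n"] == 0
        assert st_["5p_entry"]["fraction"] == 1.0


class TestPoreConductance:
    def test_zero_length_limit_is_access_resistance(self):
        # G -> sigma * d as L -> 0
        sigma = 10.5
        assert pore_conductance(3.0, 0.0, sigma) == pytest.approx(sigma * 3.0 * 1e-9 * 1e9)

    def test_round_trip_inversion(self):
        g = pore_conductance(2.5, 6.7, 10.5)
        d = invert_pore_diameter(g, 6.7, 10.5)
        assert d == pytest.approx(2.5, rel=1e-6)

    def test_closed_form_hand_value(self):
        # d = 3 nm, L = 20/3 nm, sigma = 10 S/m
        d, L, sigma = 3e-9, 20e-9 / 3, 10.0
        expect = sigma / (4 * L / (np.pi * d**2) + 1 / d) * 1e9
        assert pore_conductance(3.0, 20 / 3, 10.0) == pytest.approx(expect, rel=1e-12)

    def test_unbracketed_conductance_rejected(self):
        with pytest.raises(ValueError, match="bracket"):
            invert_pore_diameter(1e9, 10.0, 10.0)

    @given(st.floats(0.5, 50.0), st.floats(0.0, 50.0), st.floats(1.0, 20.0))
    @settings(deadline=None, max_examples=50)
    def test_inversion_property(self, d, L, sigma):
        g = pore_conductance(d, L, sigma)
        assert invert_pore_diameter(g, L, sigma) == pytest.approx(d, rel=1e-6)
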