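#!/usr/bin/env python
"""Barcode localization on a 104-event barcoded-oligo population.

Categorizes events by the 2 nS blockage-conductance threshold, assigns
entry orientation from the secondary-level position against the site
derived from the template/barcode sequences, mirrors 5'-entry events and
histograms the normalized positions. The histogram mode should land at
the sequence-derived site (~0.318 from the 3' end).
"""

from pathlib import Path

import pandas as pd

from poretrace.experiments import BARCODE_5TO3, TEMPLATE_3TO5
from poretrace.pipeline import analyze_trace, localize_barcodes
from poretrace.simulate import TraceConfig, default_presets, generate_trace
from poretrace.translocation import (
    barcode_position_histogram,
    expected_relative_position,
    orientation_dwell_stats,
)

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

presets = default_presets("MoS2_barcode")
cfg = TraceConfig(presets=presets, duration=12.0, event_rate=20.0, seed=404,
                  n_events=104, class_mixture={"121": 1.0})
trace, _ = generate_trace(cfg)
events = analyze_trace(trace, presets)
site = expected_relative_position(TEMPLATE_3TO5, BARCODE_5TO3)
df = localize_barcodes(events, presets.bias_mV, site)
df.to_csv(OUT / "barcode_positions.tsv", sep="\t", index=False)

bc = df[(df.category == "barcoded") & (df.orientation != "unassigned")]
hist = barcode_position_histogram(bc.position_3p_frame.values, 20, expected_position=site)
pd.DataFrame(
    {"bin_left": hist.edges[:-1], "bin_right": hist.edges[1:], "count": hist.counts}
).to_csv(OUT / "barcode_position_histogram.tsv", sep="\t", index=False)

stats = orientation_dwell_stats(bc.orientation, bc.dwell_s)
print(f"template site (from 3' end): {site:.3f}")
print(f"{len(bc)} barcoded events; histogram mode {hist.mode:.3f} "
      f"(|mode - site| = {hist.mode_error:.3f})")
print(f"5' entry: {100*stats['5p_entry']['fraction']:.0f}% "
      f"(dwell {stats['5p_entry']['mean_dwell_ms']:.1f} ms); "
      f"3' entry: {100*stats['3p_entry']['fraction']:.0f}% "
      f"(dwell {stats['3p_entry']['mean_dwell_ms']:.1f} ms)")
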