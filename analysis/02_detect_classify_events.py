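#!/usr/bin/env python
"""Detect and classify events in the SiNx recording.

Reads results/sinx_400mv_trace.h5 (from 01), runs threshold detection,
CUSUM segmentation, level assignment, classification and clustering, and
writes the per-event table plus class fractions. The '212' fraction
should sit near the 10% mixture probability of the simulator.
"""

from pathlib import Path

import pandas as pd

from poretrace.detect import cluster_events
from poretrace.pipeline import analyze_trace, events_dataframe
from poretrace.simulate import default_presets
from poretrace.trace import read_annotations, read_trace

OUT = Path(__file__).resolve().parent.parent / "results"
presets = default_presets("SiNx_400mV")
trace = read_trace(OUT / "sinx_400mv_trace.h5")
truth = read_annotations(OUT / "sinx_400mv_annotations.tsv")

events = analyze_trace(trace, presets)
df = events_dataframe(events, presets.bias_mV)
if len(events) >= 3:
    df["cluster"] = cluster_events(events, k=3, seed=0).labels
df.to_csv(OUT / "sinx_events.tsv", sep="\t", index=False)

fractions = df["class"].value_counts(normalize=True)
summary = pd.DataFrame({"fraction_detected": fractions})
summary["fraction_true"] = pd.Series(
    pd.Series([a.event_class for a in truth]).value_counts(normalize=True)
)
summary.to_csv(OUT / "sinx_class_fractions.tsv", sep="\t")

print(f"detected {len(events)} events (truth: {len(truth)})")
print(summary.round(3).to_string())
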