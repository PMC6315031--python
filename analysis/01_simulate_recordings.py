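#!/usr/bin/env python
"""Generate the two demo recordings every later step analyzes.

Writes a SiNx ds-ss-ds recording and a MoS2 barcoded-oligo recording
(trace containers + ground-truth annotation TSVs) under results/.
"""

from pathlib import Path

from poretrace.simulate import TraceConfig, default_presets, generate_trace
from poretrace.trace import write_annotations, write_trace

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

for system, duration, rate, seed in (
    ("SiNx_400mV", 30.0, 5.0, 101),
    ("MoS2_barcode", 12.0, 20.0, 202),
):
    presets = default_presets(system)
    cfg = TraceConfig(presets=presets, duration=duration, event_rate=rate, seed=seed)
    trace, ann = generate_trace(cfg)
    stem = system.lower()
    write_trace(trace, OUT / f"{stem}_trace.h5", "container")
    write_annotations(ann, OUT / f"{stem}_annotations.tsv")
    print(
        f"{system}: {len(ann)} events over {trace.duration:.0f}s at "
        f"{presets.bias_mV:.0f} mV -> {OUT / (stem + '_trace.h5')}"
    )
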