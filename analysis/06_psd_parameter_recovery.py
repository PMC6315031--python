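#!/usr/bin/env python
"""Flicker-noise parameter recovery for all three occupancy levels.

For each level preset, synthesizes 20 independent noise traces of 2^19
samples at 100 kHz, averages their Welch PSDs, fits S = a1/f^beta + a2
below 5 kHz and checks the fitted flicker parameters against the
generating row's printed 95% confidence bounds.
"""

from pathlib import Path

import pandas as pd

from poretrace.experiments import psd_recovery
from poretrace.simulate import TABLE1_PSD

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

rows = []
for level in (0, 1, 2):
    rec = psd_recovery(level, seed=1 + level)
    row = TABLE1_PSD[level]
    rows.append(
        {
            "level": level,
            "a1_fitted": rec["a1"],
            "a1_preset": row["a1"],
            "a1_in_bounds": rec["a1_in_bounds"],
            "beta_fitted": rec["beta"],
            "beta_preset": row["beta"],
            "beta_in_bounds": rec["beta_in_bounds"],
        }
    )
table = pd.DataFrame(rows)
table.to_csv(OUT / "psd_parameter_recovery.tsv", sep="\t", index=False)
print(table.to_string(index=False))
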