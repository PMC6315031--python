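# poretrace

Multi-level signal analysis for solid-state nanopore DNA experiments:
detecting translocation events in ionic-current traces, resolving their
ssDNA/dsDNA sub-level structure, discriminating occupancy levels by
their noise, and localizing a hybridized barcode along a short template
strand — together with a synthetic-trace generator that reproduces the
statistical structure of such recordings with exact ground truth.

## Who this is for

Groups doing ds–ss–ds "topological barcoding" experiments on SiNx or
MoS2 pores, and anyone who needs a tested, seedable reference
implementation of the standard nanopore signal chain: robust baseline +
threshold detection, CUSUM sub-level segmentation, per-level noise
profiling (Gaussian-mixture marginals, flicker-noise spectra,
Hilbert–Huang energies) and conductance-based pore sizing.

## The models in brief

* **Event structure.** An event is a piecewise-constant excursion below
  the open-pore baseline; its class is the run-length-collapsed string
  of occupancy levels (1 = ssDNA, 2 = dsDNA): `"2"`, `"21"` (partial)
  or `"212"` (complete ds–ss–ds translocation). Segmentation is by
  two-sided Page CUSUM inside each detected window.
* **Noise.** Level-conditional noise is described in the time domain by
  a 4-component Gaussian mixture, tested with the tail-weighted CDF
  distance D = n ∫ (Fₙ−F)² [F(1−F)]⁻¹ dF (order-statistic form,
  parametric-bootstrap p-values), and in the frequency domain by
  S(f) = a₁/f^β + a₂ + a₃f + a₄f², fitted to Welch spectra below 5 kHz.
  Ambiguous segments are arbitrated by combining mixture likelihood and
  spectral discrepancy.
* **Barcodes.** Events deeper than 2 nS in blockage conductance carry a
  hybridized barcode; its entry orientation follows from the proximity
  of the secondary-level center to the site position derived by
  complement search of the barcode against the template, and mirrored
  (5′→3′ frame) positions histogram at the site.
* **Pore geometry.** G = σ·[4L/(πd²) + 1/d]⁻¹ (cylinder + access
  resistance), inverted for d by root finding.

See `docs/methods.md` for parameter defaults and their rationale.

## Worked example

Simulate a SiNx recording, detect and classify its events, and measure
dwell-fraction and blockade statistics:

```bash
python analysis/01_simulate_recordings.py
python analysis/02_detect_classify_events.py
python analysis/04_dwell_and_blockade.py
python analysis/05_barcode_localization.py
```

which prints (seeds fixed in the scripts):

```
detected 141 events (truth: 141)
       fraction_detected  fraction_true
2                  0.645          0.660
21                 0.234          0.241
212                0.092          0.099

dwell fractions over 26 complete translocations:
  segment  mean_fraction  sd_fraction  population_mean
 ds_first          0.433        0.135             0.43
ss_middle          0.256        0.107             0.25
  ds_last          0.311        0.131             0.32

blockade currents:
    level  mean_blockage_nA  se_nA  population_mean_nA  n_segments
ssDNA (1)             0.797  0.016                 0.8          84
dsDNA (2)             1.514  0.011                 1.5         211

template site (from 3' end): 0.318
102 barcoded events; histogram mode 0.275 (|mode - site| = 0.043)
5' entry: 52% (dwell 3.1 ms); 3' entry: 48% (dwell 1.0 ms)
```

Reading this: every simulated event was recovered; the complete
("212") translocations are ~10% of the population; their first dsDNA
segment occupies 0.43 of the dwell on average (large intramolecular
velocity variation — the first ds segment translocates slowest); the
two blockade levels read back at 0.8 and 1.5 nA; and on the barcoded
oligos the secondary-level positions cluster at the sequence-derived
site (~0.32 from the 3′ end), with 5′-first entries slower (3 ms) than
3′-first (1 ms).

The same stages are scriptable through one CLI:

```bash
poretrace --set simulate.duration=30 full --system SiNx_400mV --seed 7 --out-dir run/
poretrace localize --trace run/trace.h5 --out-dir run/   # MoS2 traces
```

Library entry points live in `poretrace.simulate` (generator),
`poretrace.detect` (detection/CUSUM/classification), `poretrace.noise`
(GMM/AD/PSD/HHT), `poretrace.translocation` (dwell fractions, barcode
localization, pore geometry) and `poretrace.pipeline` (end-to-end
wrappers).

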