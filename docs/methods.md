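# Methods

`poretrace` is a pipeline for multi-level analysis of solid-state
nanopore recordings — translocation event detection, CUSUM sub-level
segmentation, discriminative noise modeling, and barcode localization on
short oligos — driven by a synthetic trace generator with exact ground
truth. This note records the models, the defaults and why they were
chosen, and what the synthetic studies do and do not establish.

## Units and conventions

Current is nA, time s, bias mV, conductance nS (`G[nS] = 1e3·I[nA]/V[mV]`).
Noise PSD coefficients are in pA²/Hz — the conventional axis for
patch-clamp-amplifier nanopore spectra — and converted to nA at the point
where noise is composed into a trace. Were the same coefficients read in
nA²/Hz, the implied in-event noise rms would exceed 1 nA, larger than the
0.8/1.5 nA blockade steps themselves; pA²/Hz is the only reading
consistent with the recordings being analyzable. All sample-index
intervals are 0-based half-open.

## Synthetic recordings

The generator is phenomenological: it reproduces the *statistical*
structure of recordings (level means, noise marginals, noise spectra,
dwell and mixture statistics), not transport physics.

**Noise spectra.** Each occupancy level (0 = open pore, 1 = ssDNA,
2 = dsDNA/barcode) carries the four-term PSD model

    S(f) = a1/f^β + a2 + a3·f + a4·f²

with per-level `(a1, β)` set to the published per-level flicker fits
(Level 0: 4.14e-5, 0.202; Level 1: 3.70e-3, 0.380; Level 2: 3.15e-3,
0.473) and `a2 = a3 = a4 = 0` in the presets — only the flicker term was
reported per level, and inventing thermal/dielectric magnitudes would
change the very spectra the pipeline is meant to recover.

**Noise marginals.** Per-level noise marginals are 4-component Gaussian
mixtures. No published component values exist, so the preset shapes
encode the described qualitative features: Level-1 noise is right-skewed
(four nucleotides modulating the current), Level-2 noise concentrates
more mass at small values with heavier tails (base-pair steps), Level 0
is near-Gaussian. Each mixture is rescaled so its variance equals the
PSD integral over the synthesizable band at a 2^19-sample reference
record, keeping the time- and frequency-domain descriptions consistent.

**Combining both.** Colored Gaussian noise is synthesized by spectral
shaping (white complex-Gaussian spectrum scaled by √S, inverse FFT; the
expected one-sided periodogram then equals S exactly). The mixture
marginal is imposed by iterative amplitude-adjusted rank substitution
(IAAFT, 10 iterations, ending on the marginal): the output's empirical
distribution is exactly a mixture draw while the spectrum matches S to
within a few percent in band. A single substitution pass was found to
whiten the spectrum noticeably; iterating is what lets the generator
meet the 10% spectral-fidelity requirement that the recovery studies
rely on.

**Events.** Events are piecewise-constant level excursions plus
level-specific noise. Classes are level strings: "2" (dsDNA only),
"21", "212" (complete ds–ss–ds translocation) for the SiNx scenario;
plain ssDNA ("1") and barcoded ("121") for the MoS2 scenario. Per-event
level depths are drawn from the published population statistics
(ssDNA 0.8 ± 0.15 nA, dsDNA 1.5 ± 0.18 nA at 400 mV; 1.8 nS and 3.2 nS
for the MoS2 oligos, with spreads 0.08/0.15 nS chosen well inside the
2 nS categorization gap — the all-points histogram shows discrete,
separated levels). "212" dwell fractions follow a Dirichlet with mean
(0.43, 0.25, 0.32) and a single concentration least-squares matched to
the published sds (0.12, 0.12, 0.08). Dwell times are log-normal,
moment-matched to mean ± sd where published (barcoded oligos: 3 ± 1 ms
for 5′ entry, 1 ± 0.5 ms for 3′); the SiNx class dwells (4.0 / 1.7 /
0.6 ms for "212"/"2"/"21", cv 0.25–0.3) are set so that the mean "2"
dwell coincides with the first ds segment of "212" (an observed
regularity) and the three classes form distinguishable clusters in the
(log dwell, blockage) plane, as observed. Events arrive by a Poisson
process thinned to forbid overlap with a 5 ms guard gap. Everything is a
pure function of the config (seed included).

**Barcoded events.** The template 3′-GACTAGGGTGACAATCTACCAC-5′ carries a
(propynyl-C)₃ barcode; complement search places the site at template
positions 6–8 from the 3′ end, center 7/22 ≈ 0.318. The simulator places
the secondary (deeper) level's center at the site (3′ entry) or its
mirror (5′ entry, probability 0.52) plus N(0, 0.04) jitter, width 3/22
of the dwell. The jitter sd is a choice — it sets the localization
histogram's width, for which no number is published.

## Detection and segmentation

Baseline: per-window median and MAD (0.5 s windows), insensitive to
events under ~20% duty cycle. Events open below `baseline − 6σ`, close
above `baseline − 1σ`, and are padded outward to the `0.5σ` level so
shallow shoulders are not clipped; events shorter than 10 samples are
dropped, events open at a trace end are flagged truncated. The threshold
and minimum duration are conventions (no published values exist); both
are config keys.

Within each event a two-sided Page CUSUM runs against the running
segment mean, with drift = half the smallest expected level gap when
bands are known (else 4 local sds) and decision threshold 5 in
drift-normalized units; the change point is placed at the extremum of
the cumulative statistic. Adjacent segments closer than twice the pooled
standard error are merged, as are segments shorter than 5 samples.
Segments are labeled by nearest blockade band, with a tie margin (10% of
the band gap) that leaves genuinely ambiguous segments unassigned for
noise-based arbitration; the event class is the run-length-collapsed
string of non-baseline labels.

k-means clustering of events uses (log10 dwell, blockage in nA) in
natural units. Standardizing was considered and rejected: every class
reaches the dsDNA level, so blockage carries almost no class signal, and
rescaling that axis to unit variance makes the k-means optimum cut
across classes; in natural units the two axes have comparable magnitudes
(decades vs nA) and the clusters coincide with the classes.

## Noise models

**Weighted distribution distance.** Goodness of fit uses the
tail-weighted squared CDF distance (weight `[F(1−F)]⁻¹`), computed by
the exact order-statistic identity rather than quadrature (numerically
stable and identical — verified against quadrature to 1e-6). Because the
mixture parameters are estimated from the same data, classical critical
values do not apply; p-values come from a parametric bootstrap (default
199 resamples, size 0.05) in which each resample is refitted *with the
same estimation settings as the original fit* — using a weaker refit
makes the test conservative.

**EM.** Mixtures are fitted by a vectorized 1-D EM (k-means++-style
seeding, best of 10 restarts, variance floor 1e-6 of the data variance;
restarts that collapse a component are never preferred, since a
collapsed component inflates the likelihood spuriously). Bootstrap
resamples are fitted as one batched EM, which is what makes
bootstrap-heavy studies tractable. The implementation is cross-checked
against scikit-learn's `GaussianMixture` in the tests.

**PSD estimation and fitting.** Welch (Hann, 50% overlap); the model
`a1/f^β + a2` (optionally + a3·f) is fitted to log-PSD by least squares
with the spectrum normalized by its median for conditioning, three β
starts, and 95% bounds from the fit covariance. For white input the
flicker amplitude's bound includes zero and β is flagged unidentifiable.
The default band is 10 Hz–5 kHz, matching the band the published
per-level fits used.

**Profiles and arbitration.** Per-level profiles (4-GMM + PSD fit + HHT
band energy) are built from pooled mean-subtracted segments, with five
guard samples trimmed at each segment boundary (change-point placement
is only sample-accurate, and one sample of the neighbouring level is a
several-hundred-σ outlier on the residual scale). The Welch window
adapts per level to what the segments can hold; in-event windows are
short, which biases the in-event β estimates upward — per-level spectral
*recovery* claims therefore come from the long-record study, not from
profiles. Ambiguous segments are scored per level by total mixture
log-likelihood plus λ (default 1) times the negative summed squared
log-spectral discrepancy over the profile's band; the argmax wins unless
the margin is below the tie tolerance (2 score units).

**HHT.** Empirical mode decomposition by sifting (cubic-spline envelopes
with mirrored boundary extrema, Huang's SD stoppage at 0.2), then
analytic-signal instantaneous amplitude/frequency per IMF; band energy
is the mean squared amplitude where the instantaneous frequency falls in
the band (default 10 Hz–5 kHz — the discriminating band is not
published, so it is a config key). IMFs plus residual reconstruct the
input to machine precision by construction. On simulator data Level-1
segments show the highest median band energy, reproducing the reported
ordering.

## Translocation analysis

Dwell fractions of complete translocations pool contiguous same-label
runs (padded open-pore edges excluded) and are compared against a
constant-velocity reference map (fractions ∝ designed contour lengths)
when one is supplied. Barcode orientation is assigned purely from the
secondary-level center's proximity to the sequence-derived site vs its
mirror — the simulator's truth labels are never consulted; 5′-entry
events are mirrored (`p → 1 − p`, an involution) before histogramming.
The secondary-level "center" is the midpoint of the level run's first
and last sample, not amplitude-weighted. Pore size uses the classical
cylindrical-channel + access-resistance conductance model
`G = σ·[4L/(πd²) + 1/d]⁻¹`, inverted by monotone root finding.

## What the synthetic studies show — and don't

Passing recovery studies show the pipeline is *consistent*: analyzing
data generated under the package's own statistical model returns the
generating parameters (flicker parameters inside the published 95%
bounds; dwell fractions, blockades, class mixture, orientation
statistics within sampling error at the published population sizes).
They cannot show that real membranes obey these models: real recordings
have amplifier filtering and drift, event-rate nonstationarity,
level-depth correlations and non-mixture artifacts the generator omits.
Known limitations, found and kept visible during development:

* events whose drawn ssDNA and dsDNA depths come out nearly equal
  (a few σ coincidence) defy CUSUM splitting and band assignment — the
  very situation noise-based arbitration exists for; population studies
  lose a few percent of events this way;
* short events are slightly more likely to drop out of detection, which
  biases orientation fractions toward the slower 5′-entry population by
  roughly one percentage point;
* in-event spectral fits from short segments are upward-biased in β;
* the Level-0 baseline magnitude (6 nA per preset) is configurable with
  no fidelity claim — no published value exists.

## Problem sizes

Default study sizes follow the published populations: 31 complete
translocations for dwell fractions, 104 barcoded events for the position
histogram, 500-event populations for mixture/orientation statistics, and
20 × 2^19-sample records per level for spectral recovery. The test suite
re-runs the same studies at these sizes with fixed seeds.
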