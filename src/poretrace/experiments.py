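"""Reference simulation studies.

Each function runs one self-contained study on synthetic data generated
from the default presets and measures, through the analysis pipeline,
the statistic the presets were built to reproduce: per-level flicker
parameters, dwell fractions of complete translocations, level blockade
currents, the event-class mixture, and barcode orientation statistics.
They are used by the analysis drivers, the test suite and the
reproduction script.
"""

from __future__ import annotations

import numpy as np

from .detect import DetectionConfig
from .noise import fit_psd_model, welch_psd
from .pipeline import analyze_trace, localize_barcodes
from .simulate import (
    TABLE1_PSD,
    TraceConfig,
    default_presets,
    shaped_level_noise,
)
from .translocation import (
    aggregate_dwell_fractions,
    expected_relative_position,
    fractional_dwell_times,
    orientation_dwell_stats,
)

__all__ = [
    "TEMPLATE_3TO5",
    "BARCODE_5TO3",
    "psd_recovery",
    "dwell_fraction_recovery",
    "blockade_recovery",
    "classification_mixture",
    "orientation_recovery",
]

TEMPLATE_3TO5 = "GACTAGGGTGACAATCTACCAC"
BARCODE_5TO3 = "CCC"  # (propynyl-C)3; propynyl-C pairs as plain cytosine


def psd_recovery(
    level: int,
    seed: int = 1,
    n_traces: int = 20,
    n_samples: int = 2**19,
    fs: float = 100e3,
    welch_window: int = 2**16,
    band: tuple[float, float] = (10.0, 5000.0),
) -> dict:
    """Synthesize per-level noise from the preset and fit the PSD model back.

    Averages Welch PSDs over ``n_traces`` independent realizations, fits
    S = a1/f^beta + a2 over ``band`` and reports the fitted flicker
    parameters together with whether each lies inside the preset row's
    printed 95% confidence bounds.
    """
    presets = default_presets("SiNx_400mV")
    lv = presets.levels[level]
    rng = np.random.default_rng(seed)
    spectra = []
    for _ in range(n_traces):
        x = shaped_level_noise(lv.psd, lv.gmm, n_samples, fs, rng)
        f, P = welch_psd(x, fs, window_len=welch_window)
        spectra.append(P)
    P_mean = np.mean(spectra, axis=0)
    fit = fit_psd_model(f, P_mean, band=band)
    row = TABLE1_PSD[level]
    return {
        "level": level,
        "a1": fit.params.a1,
        "beta": fit.params.beta,
        "a2": fit.params.a2,
        "a1_in_bounds": bool(row["a1_ci"][0] <= fit.params.a1 <= row["a1_ci"][1]),
        "beta_in_bounds": bool(row["beta_ci"][0] <= fit.params.beta <= row["beta_ci"][1]),
        "n_traces": n_traces,
        "n_samples": n_samples,
    }


def _simulated_population(
    system: str,
    n_events: int,
    seed: int,
    event_rate: float,
    headroom: float = 1.7,
    **config_kwargs,
):
    presets = default_presets(system)
    cfg = TraceConfig(
        presets=presets,
        duration=n_events / event_rate * headroom + 2.0,
        event_rate=event_rate,
        seed=seed,
        n_events=n_events,
        **config_kwargs,
    )
    from .simulate import generate_trace

    trace, annotation = generate_trace(cfg)
    return presets, trace, annotation


def dwell_fraction_recovery(seed: int = 1, n_events: int = 31) -> dict:
    """Complete-translocation dwell fractions through detection + CUSUM.

    Simulates ``n_events`` '212' events with the default Dirichlet
    dwell-fraction model, segments them and measures the fraction of the
    total dwell spent in each sub-level.
    """
    presets, trace, _ = _simulated_population(
        "SiNx_400mV", n_events, seed, event_rate=5.0, class_mixture={"212": 1.0}
    )
    events = [ev for ev in analyze_trace(trace, presets) if ev.event_class == "212"]
    fractions = [fractional_dwell_times(ev) for ev in events]
    agg = aggregate_dwell_fractions(fractions)
    return {
        "mean_fractions": agg.mean,
        "sd_fractions": agg.sd,
        "n_events": agg.n_events,
        "generator_mean": presets.dirichlet_mean,
    }


def blockade_recovery(seed: int = 1, n_events: int = 200) -> dict:
    """Mean detected ssDNA / dsDNA blockade currents on the SiNx population."""
    presets, trace, _ = _simulated_population("SiNx_400mV", n_events, seed, event_rate=10.0)
    events = analyze_trace(trace, presets)
    per_level: dict[int, list[float]] = {1: [], 2: []}
    for ev in events:
        for seg in ev.segments:
            if seg.level_label in per_level:
                per_level[seg.level_label].append(ev.baseline_current - seg.mean_current)
    out = {"n_events": len(events)}
    for lvl, vals in per_level.items():
        arr = np.asarray(vals)
        out[f"level{lvl}_blockage_nA"] = float(arr.mean())
        out[f"level{lvl}_se_nA"] = float(arr.std(ddof=1) / np.sqrt(arr.size))
        out[f"level{lvl}_n_segments"] = int(arr.size)
    return out


def classification_mixture(seed: int = 1, n_events: int = 500) -> dict:
    """Fraction of detected events classified '212' under the default mixture."""
    presets, trace, annotation = _simulated_population(
        "SiNx_400mV", n_events, seed, event_rate=10.0
    )
    events = analyze_trace(trace, presets)
    n = len(events)
    n_212 = sum(ev.event_class == "212" for ev in events)
    return {
        "n_events": n,
        "fraction_212": n_212 / n,
        "percent_212": 100.0 * n_212 / n,
        "generator_probability": presets.class_mixture["212"],
        "true_fraction": sum(a.event_class == "212" for a in annotation) / len(annotation),
    }


def orientation_recovery(seed: int = 1, n_events: int = 500) -> dict:
    """Barcode orientation statistics on a simulated MoS2 oligo population.

    Orientation is assigned purely from the secondary-level position
    against the site position derived from the printed template/barcode
    sequences (the simulator's truth labels are never consulted).
    """
    presets, trace, _ = _simulated_population(
        "MoS2_barcode", n_events, seed, event_rate=20.0, class_mixture={"121": 1.0}
    )
    events = analyze_trace(trace, presets)
    site = expected_relative_position(TEMPLATE_3TO5, BARCODE_5TO3)
    df = localize_barcodes(events, presets.bias_mV, site)
    bc = df[df.category == "barcoded"]
    stats = orientation_dwell_stats(bc.orientation, bc.dwell_s)
    return {
        "n_events": len(df),
        "n_barcoded": int(len(bc)),
        "site": site,
        "fraction_5p": stats["5p_entry"]["fraction"],
        "percent_5p": 100.0 * stats["5p_entry"]["fraction"],
        "mean_dwell_5p_ms": stats["5p_entry"].get("mean_dwell_ms", float("nan")),
        "mean_dwell_3p_ms": stats["3p_entry"].get("mean_dwell_ms", float("nan")),
        "sd_dwell_5p_ms": stats["5p_entry"].get("sd_dwell_ms", float("nan")),
        "n_unassigned": stats["n_unassigned"],
    }
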