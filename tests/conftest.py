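"""Shared fixtures: presets and session-scoped simulated populations."""

import numpy as np
import pytest

from poretrace.detect import DetectionConfig
from poretrace.noise import baseline_segments, build_noise_profiles
from poretrace.pipeline import analyze_trace
from poretrace.simulate import TraceConfig, default_presets, generate_trace


@pytest.fixture(scope="session")
def sinx():
    return default_presets("SiNx_400mV")


@pytest.fixture(scope="session")
def mos2():
    return default_presets("MoS2_barcode")


@pytest.fixture(scope="session")
def sinx_run(sinx):
    """A medium SiNx recording with the default class mixture."""
    cfg = TraceConfig(presets=sinx, duration=16.0, event_rate=5.0, seed=101)
    trace, annotation = generate_trace(cfg)
    return trace, annotation


@pytest.fixture(scope="session")
def sinx_events(sinx, sinx_run):
    trace, _ = sinx_run
    return analyze_trace(trace, sinx)


@pytest.fixture(scope="session")
def profiling_run(sinx):
    """A '212'-rich long-dwell recording plus its fitted noise profiles.

    Long level residencies are what per-level spectral estimation needs;
    this mirrors profiling recordings taken from complete translocations.
    """
    cfg = TraceConfig(
        presets=sinx,
        duration=20.0,
        event_rate=3.0,
        seed=77,
        class_mixture={"212": 1.0},
        dwell_params={"212": (40e-3, 0.3)},
    )
    trace, annotation = generate_trace(cfg)
    events = analyze_trace(trace, sinx)
    segments = [s for ev in events for s in ev.segments]
    segments += baseline_segments(trace, events)
    profiles = build_noise_profiles(trace, segments, seed=0)
    return trace, events, profiles
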