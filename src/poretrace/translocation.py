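"""Intramolecular velocity statistics, barcode localization and pore geometry.

For complete ds-ss-ds translocations the three sub-level dwell fractions
measure intramolecular velocity variation against a constant-velocity
reference map. For barcoded short oligos the temporal center of the
deeper secondary level, normalized by event duration and mirrored onto a
common (3'-entry) orientation, localizes the barcode along the template;
the expected position comes from Watson-Crick complement search of the
barcode against the template sequence. Pore size follows the classical
conductance model of a cylindrical channel in series with the access
resistance of both mouths:

    G = sigma * [4 L / (pi d^2) + 1/d]^(-1)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .trace import Event

__all__ = [
    "DwellFractions",
    "BarcodeHistogram",
    "PoreGeometry",
    "fractional_dwell_times",
    "aggregate_dwell_fractions",
    "secondary_level_center",
    "detect_orientation",
    "normalize_and_mirror",
    "barcode_position_histogram",
    "expected_relative_position",
    "orientation_dwell_stats",
    "pore_conductance",
    "invert_pore_diameter",
]


# ---------------------------------------------------------------------------
# Dwell fractions of complete translocations
# ---------------------------------------------------------------------------


def fractional_dwell_times(event: Event) -> tuple[float, float, float]:
    """Per-sub-level fractions of total dwell for a complete ("212") event.

    Contiguous segments sharing a level label are pooled first, so a
    spuriously split level still yields the three ds-ss-ds runs.
    """
    if event.event_class != "212":
        raise ValueError(f"dwell fractions require a '212' event, got {event.event_class!r}")
    runs: list[list] = []  # [label, n_samples]
    for seg in event.segments:
        if seg.level_label == 0:
            continue  # padded open-pore edges are not part of the dwell
        if runs and runs[-1][0] == seg.level_label:
            runs[-1][1] += seg.n_samples
        else:
            runs.append([seg.level_label, seg.n_samples])
    durations = np.array([n for _, n in runs], float)
    if durations.size != 3:
        raise ValueError(f"'212' event must collapse to 3 level runs, got {durations.size}")
    f = durations / durations.sum()
    return float(f[0]), float(f[1]), float(f[2])


@dataclass(frozen=True)
class DwellFractions:
    """Population summary of per-segment dwell fractions."""

    mean: tuple[float, ...]
    sd: tuple[float, ...]
    n_events: int
    #: mean minus the constant-velocity reference map (fractions
    #: proportional to designed segment contour lengths), when given
    reference_deviation: tuple[float, ...] | None = None


def aggregate_dwell_fractions(
    events_or_fractions,
    reference_fractions=None,
) -> DwellFractions:
    """Mean and sd of segment dwell fractions over a population.

    Accepts '212' :class:`Event` objects or raw fraction triples. With
    ``reference_fractions`` (the constant-velocity expectation, e.g.
    segment contour-length fractions) the deviation of the means from the
    reference is reported.
    """
    rows = []
    for item in events_or_fractions:
        if isinstance(item, Event):
            rows.append(fractional_dwell_times(item))
        else:
            rows.append(tuple(float(v) for v in item))
    if len(rows) < 2:
        raise ValueError("need at least 2 events")
    arr = np.asarray(rows, float)
    if np.any(np.abs(arr.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("each event's fractions must sum to 1")
    dev = None
    if reference_fractions is not None:
        dev = tuple(arr.mean(axis=0) - np.asarray(reference_fractions, float))
    return DwellFractions(
        mean=tuple(arr.mean(axis=0)),
        sd=tuple(arr.std(axis=0, ddof=1)),
        n_events=arr.shape[0],
        reference_deviation=dev,
    )


# ---------------------------------------------------------------------------
# Barcode orientation and localization
# ---------------------------------------------------------------------------


def secondary_level_center(event: Event, secondary_label: int = 2) -> float:
    """Relative temporal center of the deeper (secondary) level in [0, 1].

    The center is the midpoint of the first and last sample of the
    contiguous secondary-level run, relative to the event span. Falls
    back to the deepest interior segment when labels are absent.
    """
    segs = [s for s in event.segments if s.level_label == secondary_label]
    if not segs:
        interior = event.segments[1:-1]
        if not interior:
            raise ValueError("event has no secondary level")
        deepest = min(interior, key=lambda s: s.mean_current)
        if deepest.mean_current >= min(s.mean_current for s in (event.segments[0], event.segments[-1])):
            raise ValueError("event has no secondary level")
        segs = [deepest]
    lo = min(s.start for s in segs)
    hi = max(s.end for s in segs)
    span = event.end - event.start
    return ((lo + hi) / 2.0 - event.start) / span


def detect_orientation(
    event_or_center,
    expected_site: float,
) -> tuple[str, float]:
    """Which end entered the pore first, from the secondary-level position.

    A 3'-entry event shows the barcode at the expected site position (as
    counted from the 3' end of the template); a 5'-entry event shows its
    mirror image. The orientation whose predicted position is nearer the
    observed center wins; exact ties stay unassigned. ``expected_site``
    must differ from 0.5 for the comparison to be informative.
    """
    if isinstance(event_or_center, Event):
        center = secondary_level_center(event_or_center)
    else:
        center = float(event_or_center)
    if not (0.0 <= center <= 1.0):
        raise ValueError("secondary-level center must lie in [0, 1]")
    d3 = abs(center - expected_site)
    d5 = abs(center - (1.0 - expected_site))
    if abs(d3 - d5) < 1e-12:
        return "unassigned", center
    return ("3p_entry" if d3 < d5 else "5p_entry"), center


def normalize_and_mirror(positions, orientations) -> tuple[np.ndarray, int]:
    """Mirror 5'-entry positions onto the 3'-entry frame (p -> 1 - p).

    Positions are already on the normalized [0, 1] event time axis.
    Mirroring is an involution; events with unassigned orientation are
    excluded and counted. Returns (positions, n_excluded).
    """
    out = []
    excluded = 0
    for p, o in zip(positions, orientations, strict=True):
        if o == "3p_entry":
            out.append(float(p))
        elif o == "5p_entry":
            out.append(1.0 - float(p))
        else:
            excluded += 1
    return np.asarray(out), excluded


@dataclass(frozen=True)
class BarcodeHistogram:
    """Histogram of normalized secondary-level positions."""

    counts: np.ndarray
    edges: np.ndarray
    mode: float  # center of the most occupied bin
    central68: tuple[float, float]  # 16th-84th percentile of positions
    n_events: int
    expected_position: float | None = None
    mode_error: float | None = None  # |mode - expected|


def barcode_position_histogram(
    positions,
    n_bins: int = 20,
    expected_position: float | None = None,
) -> BarcodeHistogram:
    """Histogram over [0, 1] with mode and central-68% dispersion."""
    pos = np.asarray(positions, float)
    if pos.size < 10:
        raise ValueError("need at least 10 events")
    counts, edges = np.histogram(pos, bins=n_bins, range=(0.0, 1.0))
    imode = int(np.argmax(counts))
    mode = float((edges[imode] + edges[imode + 1]) / 2.0)
    lo, hi = np.percentile(pos, [16.0, 84.0])
    return BarcodeHistogram(
        counts=counts,
        edges=edges,
        mode=mode,
        central68=(float(lo), float(hi)),
        n_events=int(pos.size),
        expected_position=expected_position,
        mode_error=None if expected_position is None else abs(mode - expected_position),
    )


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def expected_relative_position(template_3to5: str, barcode_5to3: str) -> float:
    """Relative longitudinal barcode position on the template, in [0, 1].

    The template is written 3'->5' and the barcode 5'->3', so antiparallel
    Watson-Crick pairing aligns the two strings in the same written
    direction: the barcode binds where its base-wise complement occurs in
    the template. Propynyl-modified cytosine pairs as plain C. Positions
    are counted 1-based from the 3' end of the template; the site center
    is the mean of the matched positions divided by the template length.

    Raises when the barcode has no site or more than one.
    """
    template = template_3to5.strip().upper().replace("U", "T")
    barcode = barcode_5to3.strip().upper().replace("U", "T")
    if not template or not barcode:
        raise ValueError("template and barcode must be non-empty")
    probe = barcode.translate(_COMPLEMENT)
    sites = []
    start = template.find(probe)
    while start != -1:
        sites.append(start)
        start = template.find(probe, start + 1)
    if len(sites) != 1:
        positions = [(s + 1, s + len(probe)) for s in sites]
        raise ValueError(
            f"barcode must have exactly one complementary site; found {len(sites)} "
            f"at (1-based, from 3' end): {positions}"
        )
    first = sites[0] + 1  # 1-based
    last = sites[0] + len(probe)
    center = (first + last) / 2.0
    return center / len(template)


def orientation_dwell_stats(orientations, dwell_times_s) -> dict:
    """Per-orientation entry fraction and dwell statistics (ms)."""
    orient = np.asarray(list(orientations))
    dwell = np.asarray(list(dwell_times_s), float)
    assigned = (orient == "3p_entry") | (orient == "5p_entry")
    n_assigned = int(assigned.sum())
    out = {"n_assigned": n_assigned, "n_unassigned": int((~assigned).sum())}
    for key in ("3p_entry", "5p_entry"):
        m = orient == key
        n = int(m.sum())
        entry = {"n": n, "fraction": n / n_assigned if n_assigned else float("nan")}
        if n:
            entry["mean_dwell_ms"] = float(np.mean(dwell[m]) * 1e3)
            entry["sd_dwell_ms"] = float(np.std(dwell[m], ddof=1) * 1e3) if n > 1 else 0.0
        out[key] = entry
    return out


# ---------------------------------------------------------------------------
# Pore geometry from conductance
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PoreGeometry:
    """Cylindrical pore: diameter and effective length in nm, electrolyte
    conductivity in S/m."""

    diameter_nm: float
    length_nm: float
    conductivity_S_per_m: float

    def __post_init__(self):
        if min(self.diameter_nm, self.conductivity_S_per_m) <= 0 or self.length_nm < 0:
            raise ValueError("diameter and conductivity must be positive, length non-negative")

    @property
    def conductance_nS(self) -> float:
        return pore_conductance(self.diameter_nm, self.length_nm, self.conductivity_S_per_m)


def pore_conductance(diameter_nm: float, length_nm: float, conductivity_S_per_m: float) -> float:
    """Open-pore conductance (nS): cylindrical channel + access resistance."""
    if diameter_nm <= 0 or conductivity_S_per_m <= 0 or length_nm < 0:
        raise ValueError("invalid geometry")
    d = diameter_nm * 1e-9
    L = length_nm * 1e-9
    G = conductivity_S_per_m / (4.0 * L / (np.pi * d**2) + 1.0 / d)
    return G * 1e9


def invert_pore_diameter(
    conductance_nS: float,
    length_nm: float,
    conductivity_S_per_m: float,
    d_max_nm: float = 1e4,
) -> float:
    """Pore diameter (nm) from conductance by monotone root finding.

    The forward model is strictly increasing in d, so the inverse is
    unique on (0, d_max). Raises when the conductance is outside the
    bracketing range.
    """
    if conductance_nS <= 0:
        raise ValueError("conductance must be positive")
    g_hi = pore_conductance(d_max_nm, length_nm, conductivity_S_per_m)
    if conductance_nS >= g_hi:
        raise ValueError(f"conductance {conductance_nS} nS not bracketed below d={d_max_nm} nm")
    return float(
        brentq(
            lambda d: pore_conductance(d, length_nm, conductivity_S_per_m) - conductance_nS,
            1e-6,
            d_max_nm,
            xtol=1e-12,
            rtol=1e-14,
        )
    )
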