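"""Event detection, CUSUM multi-level segmentation and classification.

The detector follows the conventional solid-state-nanopore recipe: a
robust (median/MAD) running baseline, a sigma-multiple threshold that
opens an event, a hysteresis level that closes it, outward boundary
padding so shallow leading sub-levels are not clipped, and a two-sided
CUSUM change-point pass inside each event to recover the piecewise-
constant level structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import median_abs_deviation
from sklearn.cluster import KMeans

from .trace import CurrentTrace, Event, LevelSegment, blockage_conductance

__all__ = [
    "DetectionConfig",
    "BaselineEstimate",
    "ClusterResult",
    "estimate_baseline",
    "detect_events",
    "fit_levels_cusum",
    "segment_event",
    "assign_levels",
    "classify_event",
    "cluster_events",
    "categorize_barcoded",
]


@dataclass
class DetectionConfig:
    """Tunables for detection and segmentation.

    The thresholds are expressed in multiples of the local baseline sd.
    ``cusum_drift_nA``/``cusum_threshold`` default to None, meaning
    "derive from the data": drift = half the smallest expected level gap
    when level bands are known (else 4 local sds), decision threshold
    5 units of drift-normalized log-likelihood.
    """

    baseline_window_s: float = 0.5
    threshold_sd: float = 6.0
    hysteresis_sd: float = 1.0
    pad_sd: float = 0.5
    min_duration_samples: int = 10
    min_segment_samples: int = 5
    cusum_drift_nA: float | None = None
    cusum_threshold: float = 5.0
    include_truncated: bool = False

    def __post_init__(self):
        if not (self.threshold_sd > self.hysteresis_sd >= 0):
            raise ValueError("need threshold_sd > hysteresis_sd >= 0")
        if self.min_duration_samples < 3 or self.min_segment_samples < 3:
            raise ValueError("minimum durations must be at least 3 samples")


@dataclass
class BaselineEstimate:
    """Windowed robust baseline: per-window median and MAD-based sd."""

    window_samples: int
    means: np.ndarray
    sds: np.ndarray
    constant: bool = False  # sd == 0 everywhere (flat trace)

    def mean_at(self, index) -> np.ndarray:
        w = np.minimum(np.asarray(index) // self.window_samples, self.means.size - 1)
        return self.means[w]

    def sd_at(self, index) -> np.ndarray:
        w = np.minimum(np.asarray(index) // self.window_samples, self.sds.size - 1)
        return self.sds[w]


def estimate_baseline(trace: CurrentTrace, cfg: DetectionConfig | None = None) -> BaselineEstimate:
    """Median/MAD baseline per window; robust to sparse deep events.

    The median is insensitive to events occupying well under half a
    window, so typical translocation duty cycles (<20%) leave the
    baseline essentially unchanged.
    """
    cfg = cfg or DetectionConfig()
    win = max(int(round(cfg.baseline_window_s * trace.sampling_rate)), 8)
    if len(trace) < win:
        win = len(trace)
    n_win = max(len(trace) // win, 1)
    means = np.empty(n_win)
    sds = np.empty(n_win)
    for i in range(n_win):
        chunk = trace.samples[i * win : (i + 1) * win if i < n_win - 1 else len(trace)]
        means[i] = np.median(chunk)
        sds[i] = median_abs_deviation(chunk, scale="normal")
    return BaselineEstimate(win, means, sds, constant=bool(np.all(sds == 0)))


def detect_events(
    trace: CurrentTrace,
    cfg: DetectionConfig | None = None,
    baseline: BaselineEstimate | None = None,
) -> list[Event]:
    """Threshold detection of downward current excursions.

    An event opens when the current drops below ``baseline - threshold_sd
    * sd``, closes on return above ``baseline - hysteresis_sd * sd`` and
    is then padded outward to the ``pad_sd`` level so shallow leading or
    trailing sub-levels are retained. Events shorter than
    ``min_duration_samples`` are discarded; events still open at either
    trace end are flagged truncated (and excluded unless
    ``include_truncated``).
    """
    cfg = cfg or DetectionConfig()
    baseline = baseline or estimate_baseline(trace, cfg)
    x = trace.samples
    idx = np.arange(x.size)
    mean = baseline.mean_at(idx)
    sd = baseline.sd_at(idx)
    if baseline.constant:
        return []

    deep = x < mean - cfg.threshold_sd * sd
    shallow = x < mean - cfg.pad_sd * sd
    close_level = mean - cfg.hysteresis_sd * sd

    events: list[Event] = []
    i = 0
    n = x.size
    while i < n:
        if not deep[i]:
            i += 1
            continue
        start = i
        # close on return above the hysteresis level
        j = i
        while j < n and not (x[j] > close_level[j]):
            j += 1
        end = j  # exclusive
        # outward padding to the pad level
        while start > 0 and shallow[start - 1]:
            start -= 1
        while end < n and shallow[end]:
            end += 1
        truncated = start == 0 and shallow[0] or end == n and shallow[n - 1]
        if end - start >= cfg.min_duration_samples and (cfg.include_truncated or not truncated):
            seg = LevelSegment(start, end, float(np.mean(x[start:end])))
            events.append(
                Event(
                    segments=[seg],
                    sampling_rate=trace.sampling_rate,
                    baseline_current=float(np.mean(mean[start:end])),
                    truncated=bool(truncated),
                )
            )
        i = end + 1
    return events


# ---------------------------------------------------------------------------
# CUSUM segmentation
# ---------------------------------------------------------------------------


def _robust_sd(x: np.ndarray) -> float:
    if x.size < 2:
        return 0.0
    return float(median_abs_deviation(np.diff(x), scale="normal") / np.sqrt(2.0))


def fit_levels_cusum(
    samples: np.ndarray,
    cfg: DetectionConfig | None = None,
    noise_sd: float | None = None,
) -> list[tuple[int, int, float]]:
    """Two-sided CUSUM change-point segmentation of a within-event signal.

    Runs Page's test for an upward and a downward mean shift of size
    ``drift`` against the running mean of the current segment; on an
    alarm, the change point is placed at the extremum of the cumulative
    statistic since the last restart. Adjacent segments whose means
    differ by less than twice the pooled standard error are merged, as
    are segments shorter than ``min_segment_samples``.

    Returns ``(start, end, mean)`` triples in local (window) indices.
    """
    cfg = cfg or DetectionConfig()
    x = np.asarray(samples, float)
    n = x.size
    if n == 0:
        return []
    sd = noise_sd if noise_sd is not None else _robust_sd(x)
    if sd == 0 or n < 2 * cfg.min_segment_samples:
        return [(0, n, float(np.mean(x)))]
    drift = cfg.cusum_drift_nA if cfg.cusum_drift_nA is not None else 4.0 * sd
    nu = drift / sd  # shift size in sd units
    h = cfg.cusum_threshold * nu  # decision threshold in normalized units

    change_points = [0]
    seg_start = 0
    gp = gm = 0.0
    sp_min_idx = sm_max_idx = 0
    sp = sm = 0.0  # cumulative (z - nu/2) and (z + nu/2) sums
    sp_min = sm_max = 0.0
    mean = x[0]
    count = 1
    k = 1
    while k < n:
        z = (x[k] - mean) / sd
        sp += z - nu / 2
        sm += z + nu / 2
        if sp < sp_min:
            sp_min, sp_min_idx = sp, k
        if sm > sm_max:
            sm_max, sm_max_idx = sm, k
        gp = max(0.0, gp + z - nu / 2)
        gm = min(0.0, gm + z + nu / 2)
        if gp > h or -gm > h:
            # change point = extremum of the cumulative statistic (last
            # instant the one-sided test was at zero)
            cp = (sp_min_idx if gp > h else sm_max_idx) + 1
            cp = max(cp, seg_start + 1)
            change_points.append(cp)
            seg_start = cp
            mean = float(np.mean(x[cp : k + 1]))
            count = k + 1 - cp
            gp = gm = sp = sm = sp_min = sm_max = 0.0
            sp_min_idx = sm_max_idx = k
        else:
            count += 1
            mean += (x[k] - mean) / count
        k += 1
    change_points.append(n)

    segs = [
        (a, b, float(np.mean(x[a:b])))
        for a, b in zip(change_points, change_points[1:])
        if b > a
    ]
    segs = _merge_short(segs, x, cfg.min_segment_samples)
    segs = _merge_similar(segs, x, sd)
    return segs


def _merge_short(segs, x, min_len):
    segs = list(segs)
    changed = True
    while changed and len(segs) > 1:
        changed = False
        for i, (a, b, m) in enumerate(segs):
            if b - a >= min_len:
                continue
            # merge into the neighbour with the closer mean
            left = segs[i - 1] if i > 0 else None
            right = segs[i + 1] if i < len(segs) - 1 else None
            if right is None or (left is not None and abs(left[2] - m) <= abs(right[2] - m)):
                j = i - 1
            else:
                j = i + 1
            lo = min(segs[i][0], segs[j][0])
            hi = max(segs[i][1], segs[j][1])
            merged = (lo, hi, float(np.mean(x[lo:hi])))
            segs[min(i, j)] = merged
            del segs[max(i, j)]
            changed = True
            break
    return segs


def _merge_similar(segs, x, sd):
    segs = list(segs)
    changed = True
    while changed and len(segs) > 1:
        changed = False
        for i in range(len(segs) - 1):
            a0, b0, m0 = segs[i]
            a1, b1, m1 = segs[i + 1]
            pooled_se = sd * np.sqrt(1.0 / (b0 - a0) + 1.0 / (b1 - a1))
            if abs(m1 - m0) < 2.0 * pooled_se:
                segs[i] = (a0, b1, float(np.mean(x[a0:b1])))
                del segs[i + 1]
                changed = True
                break
    return segs


def segment_event(
    trace: CurrentTrace,
    event: Event,
    cfg: DetectionConfig | None = None,
    level_gap_nA: float | None = None,
) -> Event:
    """Replace an event's single raw window with CUSUM-fitted segments.

    ``level_gap_nA`` (smallest expected gap between occupancy levels)
    sets the CUSUM drift to half that value, per standard practice.
    """
    cfg = cfg or DetectionConfig()
    if level_gap_nA is not None and cfg.cusum_drift_nA is None:
        from dataclasses import replace as _replace

        cfg = _replace(cfg, cusum_drift_nA=level_gap_nA / 2.0)
    window = trace.samples[event.start : event.end]
    segs = fit_levels_cusum(window, cfg)
    segments = [
        LevelSegment(event.start + a, event.start + b, m) for a, b, m in segs
    ]
    return Event(
        segments=segments,
        sampling_rate=event.sampling_rate,
        baseline_current=event.baseline_current,
        event_class=event.event_class,
        truncated=event.truncated,
    )


# ---------------------------------------------------------------------------
# Level assignment and classification
# ---------------------------------------------------------------------------


def assign_levels(
    event: Event,
    band_centers: dict[int, float],
    margin_fraction: float = 0.1,
) -> Event:
    """Label each segment by the nearest blockade band.

    ``band_centers`` maps level label -> blockade depth in nA below
    baseline (level 0 is depth 0). A segment whose two nearest bands are
    closer than ``margin_fraction`` of their separation apart in distance
    is left unassigned for noise-based arbitration.
    """
    labels = sorted(band_centers)
    centers = np.array([band_centers[l] for l in labels])
    for seg in event.segments:
        depth = event.baseline_current - seg.mean_current
        dist = np.abs(centers - depth)
        order = np.argsort(dist)
        best, second = order[0], order[1] if len(order) > 1 else order[0]
        gap = abs(centers[best] - centers[second]) or 1.0
        if len(order) > 1 and (dist[second] - dist[best]) < margin_fraction * gap:
            seg.level_label = None
        else:
            seg.level_label = labels[best]
    return event


def classify_event(event: Event) -> str:
    """Run-length-collapsed level string of the non-baseline segments.

    Collapsed strings other than "2", "21" and "212" (including any with
    unassigned segments) map to "other".
    """
    collapsed = []
    for seg in event.segments:
        lab = seg.level_label
        if lab == 0:
            continue
        tok = "u" if lab is None else str(lab)
        if not collapsed or collapsed[-1] != tok:
            collapsed.append(tok)
    string = "".join(collapsed)
    event.event_class = string if string in ("2", "21", "212") else "other"
    return event.event_class


@dataclass
class ClusterResult:
    """k-means clustering of events in (log dwell, blockage) space."""

    features: np.ndarray  # (n_events, 2): log10 dwell [s], blockage [nA]
    labels: np.ndarray
    centers: np.ndarray  # in standardized feature space
    k: int
    degenerate: bool = False


def cluster_events(
    events: list[Event], k: int = 3, seed: int = 0, standardize: bool = False
) -> ClusterResult:
    """Standard k-means (10 restarts, seeded) on (log10 dwell, blockage).

    By default the features keep their natural units (decades of dwell
    time, nA of blockage), matching the scatter on which the clusters are
    defined; these axes have comparable magnitudes. Standardizing is
    available but rescales a class-independent blockage spread to unit
    variance, which can drown the dwell-time structure.
    """
    if len(events) < k:
        raise ValueError(f"need at least k={k} events, got {len(events)}")
    feats = np.array(
        [[np.log10(ev.dwell_time), ev.blockage_current] for ev in events]
    )
    if not np.all(np.isfinite(feats)):
        raise ValueError("non-finite event features")
    sds = feats.std(axis=0)
    degenerate = bool(np.any(sds == 0))
    if standardize:
        std = np.where(sds == 0, 1.0, sds)
        z = (feats - feats.mean(axis=0)) / std
    else:
        z = feats - feats.mean(axis=0)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(z)
    return ClusterResult(
        features=feats,
        labels=km.labels_,
        centers=km.cluster_centers_,
        k=k,
        degenerate=degenerate,
    )


def categorize_barcoded(event: Event, bias_mV: float, threshold_nS: float = 2.0) -> str:
    """"barcoded" iff the deepest segment's blockage conductance exceeds
    the threshold (strict inequality; the printed rule is a 2 nS cut)."""
    g = max(
        blockage_conductance(event.baseline_current - seg.mean_current, bias_mV)
        for seg in event.segments
    )
    return "barcoded" if g > threshold_nS else "plain"
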