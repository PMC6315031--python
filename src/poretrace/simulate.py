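"""Synthetic nanopore recordings with known ground truth.

The generator emulates the statistical structure of solid-state nanopore
recordings: an open-pore baseline carrying flicker (1/f^beta) noise, and
translocation events built from piecewise-constant occupancy levels
(Level 1 = ssDNA, Level 2 = dsDNA / hybridized barcode), each carrying
level-specific noise with a prescribed marginal distribution (a Gaussian
mixture) and a prescribed power spectral density

    S(f) = a1 / f**beta + a2 + a3*f + a4*f**2.

PSD coefficients are expressed in pA^2/Hz and current traces in nA; the
conversion is applied when noise is composed into a trace.

Per-level noise is synthesized by spectral shaping (white Gaussian spectrum
scaled by sqrt(S)) followed by iterative amplitude-adjusted rank
substitution, so that the output carries the mixture marginal and the
target spectrum simultaneously (both are only exact in the limit, see
docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .trace import CurrentTrace, EventAnnotation, GroundTruthAnnotation

__all__ = [
    "PA_TO_NA",
    "TABLE1_PSD",
    "PSDModelParams",
    "GMMParams",
    "LevelPreset",
    "PresetBundle",
    "TraceConfig",
    "psd_model",
    "synthesize_colored_noise",
    "sample_level_noise",
    "shaped_level_noise",
    "generate_event",
    "generate_trace",
    "default_presets",
]

PA_TO_NA = 1e-3

# Printed per-level flicker-noise fits (a1 in pA^2/Hz at 1 Hz, beta
# dimensionless) with their 95% confidence bounds, SiNx pore at 400 mV.
TABLE1_PSD = {
    0: {"a1": 4.14e-5, "a1_ci": (1.30e-5, 6.98e-5), "beta": 0.202, "beta_ci": (0.110, 0.294)},
    1: {"a1": 3.70e-3, "a1_ci": (1.90e-3, 9.30e-3), "beta": 0.380, "beta_ci": (0.170, 0.591)},
    2: {"a1": 3.15e-3, "a1_ci": (9.33e-4, 7.24e-3), "beta": 0.473, "beta_ci": (0.289, 0.656)},
}


# ---------------------------------------------------------------------------
# Noise parameter containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PSDModelParams:
    """Coefficients of the four-term nanopore noise PSD model.

    ``a1/f**beta`` is flicker noise, ``a2`` white (thermal) noise, ``a3*f``
    dielectric and ``a4*f**2`` capacitive noise. Units are pA^2/Hz with f
    in Hz.
    """

    a1: float
    beta: float
    a2: float = 0.0
    a3: float = 0.0
    a4: float = 0.0

    def __post_init__(self):
        if min(self.a1, self.a2, self.a3, self.a4) < 0 or self.beta < 0:
            raise ValueError("PSD coefficients and beta must be non-negative")

    def __call__(self, f) -> np.ndarray:
        return psd_model(f, self.a1, self.beta, self.a2, self.a3, self.a4)

    def band_variance(self, f_lo: float, f_hi: float) -> float:
        """Integral of S(f) over [f_lo, f_hi] in pA^2 (closed form)."""
        if not (0 < f_lo < f_hi):
            raise ValueError("need 0 < f_lo < f_hi")
        if abs(self.beta - 1.0) < 1e-12:
            flick = self.a1 * np.log(f_hi / f_lo)
        else:
            p = 1.0 - self.beta
            flick = self.a1 * (f_hi**p - f_lo**p) / p
        return (
            flick
            + self.a2 * (f_hi - f_lo)
            + self.a3 * (f_hi**2 - f_lo**2) / 2
            + self.a4 * (f_hi**3 - f_lo**3) / 3
        )


def psd_model(f, a1, beta, a2=0.0, a3=0.0, a4=0.0):
    """Evaluate S(f) = a1/f^beta + a2 + a3 f + a4 f^2 elementwise."""
    f = np.asarray(f, dtype=float)
    return a1 * f ** (-beta) + a2 + a3 * f + a4 * f**2


@dataclass(frozen=True)
class GMMParams:
    """A univariate Gaussian mixture (weights, means, sds)."""

    weights: tuple[float, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]

    def __post_init__(self):
        w = np.asarray(self.weights, float)
        if len(self.weights) != len(self.means) or len(self.means) != len(self.sds):
            raise ValueError("weights, means and sds must have equal length")
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be non-negative and sum to 1")
        if np.any(np.asarray(self.sds) <= 0):
            raise ValueError("component sds must be positive")

    @property
    def n_components(self) -> int:
        return len(self.weights)

    @property
    def mean(self) -> float:
        return float(np.dot(self.weights, self.means))

    @property
    def variance(self) -> float:
        w = np.asarray(self.weights)
        m = np.asarray(self.means)
        s = np.asarray(self.sds)
        return float(np.dot(w, s**2 + m**2) - self.mean**2)

    def pdf(self, x) -> np.ndarray:
        x = np.asarray(x, float)[..., None]
        w = np.asarray(self.weights)
        m = np.asarray(self.means)
        s = np.asarray(self.sds)
        comp = np.exp(-0.5 * ((x - m) / s) ** 2) / (s * np.sqrt(2 * np.pi))
        return comp @ w

    def logpdf(self, x) -> np.ndarray:
        from scipy.special import logsumexp

        x = np.asarray(x, float)[..., None]
        w = np.log(np.asarray(self.weights))
        m = np.asarray(self.means)
        s = np.asarray(self.sds)
        lc = -0.5 * ((x - m) / s) ** 2 - np.log(s * np.sqrt(2 * np.pi))
        return logsumexp(lc + w, axis=-1)

    def cdf(self, x) -> np.ndarray:
        from scipy.stats import norm

        x = np.asarray(x, float)[..., None]
        comp = norm.cdf(x, loc=self.means, scale=self.sds)
        return comp @ np.asarray(self.weights)

    def shifted(self, delta: float) -> "GMMParams":
        return GMMParams(self.weights, tuple(m + delta for m in self.means), self.sds)

    def scaled(self, factor: float) -> "GMMParams":
        return GMMParams(
            self.weights,
            tuple(m * factor for m in self.means),
            tuple(s * factor for s in self.sds),
        )


def sample_level_noise(gmm: GMMParams, n: int, rng) -> np.ndarray:
    """i.i.d. draws from a Gaussian mixture (n may be 0)."""
    rng = np.random.default_rng(rng)
    n = int(n)
    if n == 0:
        return np.empty(0)
    comp = rng.choice(gmm.n_components, size=n, p=np.asarray(gmm.weights))
    return rng.normal(np.asarray(gmm.means)[comp], np.asarray(gmm.sds)[comp])


# ---------------------------------------------------------------------------
# Colored-noise synthesis
# ---------------------------------------------------------------------------


def synthesize_colored_noise(psd: PSDModelParams, n: int, fs: float, rng) -> np.ndarray:
    """Zero-mean Gaussian noise whose expected one-sided PSD is S(f).

    Synthesis is by spectral shaping: a white complex-Gaussian spectrum is
    scaled by sqrt(S(f_k) * fs * n / 2) per rFFT bin and inverse
    transformed. The DC bin is zeroed (zero-mean output).
    """
    n = int(n)
    if n < 2:
        raise ValueError("need n >= 2")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if psd.a1 == psd.a2 == psd.a3 == psd.a4 == 0:
        raise ValueError("degenerate spectrum: all PSD coefficients are zero")
    rng = np.random.default_rng(rng)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    target = np.zeros_like(freqs)
    target[1:] = psd(freqs[1:])
    # E[|X_k|^2] such that the one-sided periodogram estimates S(f_k).
    scale = np.sqrt(target * fs * n / 2.0)
    spec = scale * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)) / np.sqrt(2.0)
    spec[0] = 0.0
    if n % 2 == 0:  # real Nyquist bin; one-sided convention drops the factor 2
        spec[-1] = np.sqrt(target[-1] * fs * n) * rng.standard_normal()
    return np.fft.irfft(spec, n=n)


def shaped_level_noise(
    psd: PSDModelParams,
    gmm: GMMParams,
    n: int,
    fs: float,
    rng,
    n_iter: int = 10,
) -> np.ndarray:
    """Noise with (approximately) the PSD of ``psd`` and the marginal of ``gmm``.

    Iterative amplitude-adjusted rank substitution: starting from a colored
    Gaussian realization, alternately impose its amplitude spectrum and the
    sorted mixture sample, ending on the marginal so the output's empirical
    distribution is exactly the drawn mixture sample.
    """
    rng = np.random.default_rng(rng)
    n = int(n)
    if n < 8:
        # Too short for meaningful spectral shaping; marginal is what matters.
        return sample_level_noise(gmm, n, rng) - gmm.mean

    colored = synthesize_colored_noise(psd, n, fs, rng)
    marginal = np.sort(sample_level_noise(gmm, n, rng) - gmm.mean)
    amplitudes = np.abs(np.fft.rfft(colored))

    x = np.empty(n)
    x[np.argsort(colored)] = marginal
    for _ in range(max(0, int(n_iter))):
        spec = np.fft.rfft(x)
        phase = np.where(np.abs(spec) > 0, spec / np.maximum(np.abs(spec), 1e-300), 1.0)
        y = np.fft.irfft(amplitudes * phase, n=n)
        x = np.empty(n)
        x[np.argsort(y)] = marginal
    return x


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LevelPreset:
    """Noise and blockade description of one occupancy level.

    ``blockade_nA`` is the mean current drop below baseline (population
    mean); ``blockade_sd_nA`` the event-to-event spread. Either may be
    derived from a conductance blockade at a given bias.
    """

    level_label: int
    blockade_nA: float
    blockade_sd_nA: float
    psd: PSDModelParams
    gmm: GMMParams

    @property
    def noise_sd_pA(self) -> float:
        return float(np.sqrt(self.gmm.variance))


def _calibrated_gmm(level_label: int, target_sd: float) -> GMMParams:
    """Default 4-component mixture shape per level, scaled to ``target_sd``.

    The shapes encode the qualitative differences between the ssDNA and
    dsDNA noise marginals: Level-1 noise is right-skewed (four nucleotides
    modulating the current), Level-2 noise concentrates more mass at small
    values with heavier symmetric tails (base-pair steps), and Level-0 is
    close to Gaussian.
    """
    if level_label == 0:
        w, m, s = (0.35, 0.3, 0.2, 0.15), (-0.25, 0.1, 0.45, -0.6), (0.9, 0.9, 1.0, 1.05)
    elif level_label == 1:
        w, m, s = (0.45, 0.25, 0.2, 0.1), (-0.6, 0.2, 0.9, 1.8), (0.5, 0.5, 0.6, 0.7)
    elif level_label == 2:
        w, m, s = (0.5, 0.2, 0.2, 0.1), (0.0, -0.8, 0.8, 2.0), (0.25, 0.6, 0.6, 0.8)
    else:
        raise ValueError(f"no default mixture for level {level_label}")
    gmm = GMMParams(w, m, s)
    gmm = gmm.shifted(-gmm.mean)
    return gmm.scaled(target_sd / np.sqrt(gmm.variance))


#: Record length used to fix the mixture variance from the PSD integral.
_REFERENCE_N = 2**19


def _preset_for_level(
    level_label: int,
    blockade_nA: float,
    blockade_sd_nA: float,
    fs: float = 100e3,
) -> LevelPreset:
    row = TABLE1_PSD[level_label]
    psd = PSDModelParams(a1=row["a1"], beta=row["beta"])
    sd = np.sqrt(psd.band_variance(fs / _REFERENCE_N, fs / 2))
    return LevelPreset(
        level_label=level_label,
        blockade_nA=blockade_nA,
        blockade_sd_nA=blockade_sd_nA,
        psd=psd,
        gmm=_calibrated_gmm(level_label, sd),
    )


def _dirichlet_concentration(means: Sequence[float], sds: Sequence[float]) -> float:
    """Single Dirichlet concentration least-squares matched to marginal sds."""
    m = np.asarray(means)
    s = np.asarray(sds)

    def loss(c):
        return float(np.sum((np.sqrt(m * (1 - m) / (c + 1)) - s) ** 2))

    res = minimize_scalar(loss, bounds=(1.0, 500.0), method="bounded")
    return float(res.x)


# Population dwell-fraction model for complete ("212") translocations:
# printed means and sds of the three segment fractions.
DWELL_FRACTION_MEANS = (0.43, 0.25, 0.32)
DWELL_FRACTION_SDS = (0.12, 0.12, 0.08)


@dataclass(frozen=True)
class PresetBundle:
    """Bundled per-level presets plus scenario-wide statistics."""

    system: str
    bias_mV: float
    baseline_nA: float
    sampling_rate: float
    levels: dict[int, LevelPreset]
    class_mixture: dict[str, float]
    #: per-class lognormal dwell (mean_s, cv); barcoded classes keyed by orientation
    dwell_params: dict[str, tuple[float, float]]
    dirichlet_mean: tuple[float, ...] = DWELL_FRACTION_MEANS
    dirichlet_concentration: float = 0.0
    orientation_p5: float = float("nan")
    barcode_site: float = float("nan")
    barcode_width_fraction: float = float("nan")
    barcode_position_jitter: float = float("nan")

    def level0_psd(self) -> PSDModelParams:
        return self.levels[0].psd


def default_presets(system: str) -> PresetBundle:
    """Preset bundles for the two measurement scenarios.

    ``"SiNx_400mV"``: ds-ss-ds complex in a ~3 nm SiNx pore at 400 mV;
    ssDNA/dsDNA blockades 0.8/1.5 nA, per-level flicker-noise parameters
    from the printed per-level fits, event classes {"2", "21", "212"} with
    10% complete translocations.

    ``"MoS2_barcode"``: barcoded 22-mer ssDNA in a single-layer MoS2 pore;
    ssDNA blockade 1.8 nS, hybridized-barcode level 3.2 nS, 52% 5'-entry
    with 3 ms mean dwell (1 ms for 3'-entry), barcode site at 7/22 of the
    template from the 3' end.
    """
    if system == "SiNx_400mV":
        bias = 400.0
        return PresetBundle(
            system=system,
            bias_mV=bias,
            baseline_nA=6.0,
            sampling_rate=100e3,
            levels={
                0: _preset_for_level(0, 0.0, 0.0),
                1: _preset_for_level(1, 0.8, 0.15),
                2: _preset_for_level(2, 1.5, 0.18),
            },
            class_mixture={"2": 0.65, "21": 0.25, "212": 0.10},
            dwell_params={"212": (4.0e-3, 0.25), "2": (1.7e-3, 0.3), "21": (0.6e-3, 0.25)},
            dirichlet_mean=DWELL_FRACTION_MEANS,
            dirichlet_concentration=_dirichlet_concentration(
                DWELL_FRACTION_MEANS, DWELL_FRACTION_SDS
            ),
        )
    if system == "MoS2_barcode":
        bias = 200.0
        to_nA = bias * 1e-3  # nS -> nA at this bias (I[nA] = G[nS] * V[mV] / 1000)
        return PresetBundle(
            system=system,
            bias_mV=bias,
            baseline_nA=30.0 * to_nA,  # 30 nS open pore
            sampling_rate=100e3,
            levels={
                # population spreads kept well inside the 2 nS gap: the
                # all-points histogram shows discrete, separated levels
                0: _preset_for_level(0, 0.0, 0.0),
                1: _preset_for_level(1, 1.8 * to_nA, 0.08 * to_nA),
                2: _preset_for_level(2, 3.2 * to_nA, 0.15 * to_nA),
            },
            class_mixture={"1": 0.875, "121": 0.125},
            dwell_params={
                "1": (0.3e-3, 0.5),
                "121_5p": (3.0e-3, 1.0 / 3.0),
                "121_3p": (1.0e-3, 0.5),
            },
            orientation_p5=0.52,
            barcode_site=7.0 / 22.0,
            barcode_width_fraction=3.0 / 22.0,
            barcode_position_jitter=0.04,
        )
    raise ValueError(f"unknown preset system {system!r}")


# ---------------------------------------------------------------------------
# Event and trace generation
# ---------------------------------------------------------------------------


def _lognormal_ms(rng, mean_s: float, cv: float) -> float:
    """Draw from a lognormal moment-matched to the given mean and cv."""
    sigma2 = np.log1p(cv**2)
    mu = np.log(mean_s) - sigma2 / 2
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


_CLASS_LEVELS = {
    "2": (2,),
    "21": (2, 1),
    "212": (2, 1, 2),
    "1": (1,),
    "121": (1, 2, 1),
}


def generate_event(
    event_class: str,
    presets: PresetBundle,
    dwell_s: float,
    fractions: Sequence[float],
    fs: float,
    rng,
    blockade_jitter: bool = True,
) -> tuple[np.ndarray, dict]:
    """Synthesize one event's baseline-relative waveform and its truth.

    Returns ``(samples, truth)`` where ``samples`` is the current offset
    from baseline in nA (negative during blockage) and ``truth`` holds the
    realized segment boundaries, levels and dwell fractions.
    """
    rng = np.random.default_rng(rng)
    if event_class not in _CLASS_LEVELS:
        raise ValueError(f"unknown event class {event_class!r}")
    levels = _CLASS_LEVELS[event_class]
    fractions = np.asarray(fractions, float)
    if fractions.size != len(levels):
        raise ValueError(
            f"class {event_class!r} needs {len(levels)} fractions, got {fractions.size}"
        )
    if abs(fractions.sum() - 1.0) > 1e-9 or np.any(fractions <= 0):
        raise ValueError("fractions must be positive and sum to 1")

    n_total = int(round(dwell_s * fs))
    counts = np.maximum(np.rint(fractions * n_total).astype(int), 0)
    counts[-1] = n_total - counts[:-1].sum()
    if np.any(counts < 3):
        raise ValueError(
            f"segment shorter than 3 samples (dwell {dwell_s:.3g}s at {fs:.3g}Hz, "
            f"fractions {fractions.round(3).tolist()})"
        )

    # Per-event level depths: one draw per distinct level, shared by the
    # event's segments of that level (an event re-presents the same molecule).
    depth: dict[int, float] = {}
    for lvl in sorted(set(levels)):
        preset = presets.levels[lvl]
        d = preset.blockade_nA
        if blockade_jitter and preset.blockade_sd_nA > 0:
            d = -1.0
            while d <= 0:
                d = preset.blockade_nA + preset.blockade_sd_nA * rng.standard_normal()
        depth[lvl] = d
    if 1 in depth and 2 in depth and depth[2] <= depth[1]:
        depth[1], depth[2] = min(depth.values()), max(depth.values())

    samples = np.empty(n_total)
    seg_starts, pos = [], 0
    for lvl, cnt in zip(levels, counts):
        preset = presets.levels[lvl]
        noise = shaped_level_noise(preset.psd, preset.gmm, cnt, fs, rng)
        samples[pos : pos + cnt] = -depth[lvl] + PA_TO_NA * noise
        seg_starts.append(pos)
        pos += cnt

    truth = {
        "class": event_class,
        "n_samples": n_total,
        "segment_starts": tuple(seg_starts),
        "segment_counts": tuple(int(c) for c in counts),
        "segment_levels": levels,
        "segment_fractions": tuple(float(c) / n_total for c in counts),
        "depths_nA": depth,
    }
    return samples, truth


@dataclass
class TraceConfig:
    """Everything :func:`generate_trace` needs, seed included."""

    presets: PresetBundle
    duration: float = 10.0
    event_rate: float = 5.0
    seed: int | None = 0
    sampling_rate: float | None = None  # defaults to the bundle's rate
    baseline_nA: float | None = None
    class_mixture: dict[str, float] | None = None
    guard_gap_s: float = 5e-3
    blockade_jitter: bool = True
    dwell_fraction_jitter: bool = True
    orientation_p5: float | None = None
    barcode_site: float | None = None
    n_events: int | None = None  # overrides the Poisson count when set
    #: per-class (mean_s, cv) overrides, e.g. long dwells for noise profiling
    dwell_params: dict[str, tuple[float, float]] | None = None

    def __post_init__(self):
        mix = self.class_mixture or self.presets.class_mixture
        total = sum(mix.values())
        if any(p < 0 for p in mix.values()) or abs(total - 1.0) > 1e-9:
            raise ValueError("class mixture probabilities must be in [0,1] and sum to 1")
        for cls in mix:
            if cls not in _CLASS_LEVELS:
                raise ValueError(f"unknown event class {cls!r} in mixture")
        if self.duration <= 0 or self.event_rate < 0:
            raise ValueError("duration must be positive and event_rate non-negative")

    @property
    def fs(self) -> float:
        return self.sampling_rate or self.presets.sampling_rate

    @property
    def mixture(self) -> dict[str, float]:
        return self.class_mixture or self.presets.class_mixture

    @property
    def baseline(self) -> float:
        return self.baseline_nA if self.baseline_nA is not None else self.presets.baseline_nA


def _draw_event_plan(cfg: TraceConfig, rng) -> dict:
    """Draw class, orientation, dwell and fractions for one event."""
    presets = cfg.presets
    mix = cfg.mixture
    classes = sorted(mix)
    cls = classes[rng.choice(len(classes), p=[mix[c] for c in classes])]
    dwell_params = dict(presets.dwell_params)
    if cfg.dwell_params:
        dwell_params.update(cfg.dwell_params)
    orientation = "n/a"
    barcode_rel = float("nan")
    if cls == "121":
        p5 = cfg.orientation_p5 if cfg.orientation_p5 is not None else presets.orientation_p5
        orientation = "5p_entry" if rng.random() < p5 else "3p_entry"
        key = "121_5p" if orientation == "5p_entry" else "121_3p"
        mean_s, cv = dwell_params[key]
    else:
        mean_s, cv = dwell_params[cls]

    for _ in range(200):
        dwell = _lognormal_ms(rng, mean_s, cv)
        n_levels = len(_CLASS_LEVELS[cls])
        if cls == "212":
            if cfg.dwell_fraction_jitter:
                alpha = np.asarray(presets.dirichlet_mean) * presets.dirichlet_concentration
                fractions = rng.dirichlet(alpha)
            else:
                fractions = np.asarray(presets.dirichlet_mean)
        elif cls == "21":
            frac1 = rng.beta(0.6 * 15, 0.4 * 15) if cfg.dwell_fraction_jitter else 0.6
            fractions = np.array([frac1, 1 - frac1])
        elif cls == "121":
            site = cfg.barcode_site if cfg.barcode_site is not None else presets.barcode_site
            center = site if orientation == "3p_entry" else 1.0 - site
            center += presets.barcode_position_jitter * rng.standard_normal()
            w = presets.barcode_width_fraction
            center = float(np.clip(center, w / 2 + 0.02, 1 - w / 2 - 0.02))
            fractions = np.array([center - w / 2, w, 1 - center - w / 2])
            barcode_rel = center
        else:
            fractions = np.ones(n_levels) / n_levels
        n_total = int(round(dwell * cfg.fs))
        if n_total >= 3 * n_levels and np.all(
            np.rint(fractions * n_total) >= 3
        ):
            break
    else:
        raise RuntimeError(
            f"could not draw a feasible dwell/fraction combination for class {cls!r}"
        )
    return {
        "class": cls,
        "orientation": orientation,
        "dwell_s": dwell,
        "fractions": fractions,
        "barcode_rel_pos": barcode_rel,
    }


def generate_trace(config: TraceConfig) -> tuple[CurrentTrace, GroundTruthAnnotation]:
    """Generate an annotated trace: Level-0 baseline plus placed events.

    Events arrive by a homogeneous Poisson process thinned to forbid
    overlaps (a guard gap separates consecutive events). The returned
    annotation exactly describes the emitted events; identical config
    (including seed) yields identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.fs
    n = int(round(cfg.duration * fs))
    presets = cfg.presets

    dwell_params = dict(presets.dwell_params)
    if cfg.dwell_params:
        dwell_params.update(cfg.dwell_params)
    mean_dwell = max(p[0] for p in dwell_params.values())
    busy = cfg.event_rate * (mean_dwell + cfg.guard_gap_s)
    if busy > 0.5:
        raise ValueError(
            f"infeasible event density: event_rate*(max mean dwell + guard gap) = "
            f"{busy:.2f} > 0.5; reduce event_rate or dwell times"
        )

    lvl0 = presets.levels[0]
    baseline_noise = shaped_level_noise(lvl0.psd, lvl0.gmm, n, fs, rng)
    samples = cfg.baseline + PA_TO_NA * baseline_noise

    n_events = int(cfg.n_events) if cfg.n_events is not None else None
    if n_events is None and cfg.event_rate == 0:
        n_events = 0

    guard = int(round(cfg.guard_gap_s * fs))
    annotations: list[EventAnnotation] = []
    cursor = guard  # next admissible start sample
    event_id = 0
    while n_events is None or event_id < n_events:
        if n_events == 0:
            break
        # Poisson arrivals, thinned: gaps shorter than the guard are pushed out.
        if cfg.event_rate > 0:
            gap = int(round(rng.exponential(1.0 / cfg.event_rate) * fs))
        else:
            gap = guard
        start = cursor + max(gap, 0)
        plan = _draw_event_plan(cfg, rng)
        waveform, truth = generate_event(
            plan["class"], presets, plan["dwell_s"], plan["fractions"], fs, rng,
            blockade_jitter=cfg.blockade_jitter,
        )
        length = waveform.size
        if start + length + guard > n:
            break
        samples[start : start + length] += waveform
        annotations.append(
            EventAnnotation(
                event_id=event_id,
                start=start,
                end=start + length,
                event_class=plan["class"],
                orientation=plan["orientation"],
                barcode_rel_pos=plan["barcode_rel_pos"],
                segment_starts=tuple(start + s for s in truth["segment_starts"]),
                segment_levels=truth["segment_levels"],
                segment_fractions=truth["segment_fractions"],
            )
        )
        cursor = start + length + guard
        event_id += 1
    if n_events is not None and event_id < n_events:
        raise ValueError(
            f"could only place {event_id}/{n_events} events in {cfg.duration}s "
            f"at rate {cfg.event_rate}/s with a {cfg.guard_gap_s*1e3:.1f} ms guard gap"
        )

    trace = CurrentTrace(
        samples,
        fs,
        meta={
            "bias_mV": presets.bias_mV,
            "system": presets.system,
            "baseline_nA": cfg.baseline,
            "lowpass_hz": None,
        },
    )
    return trace, GroundTruthAnnotation(annotations)
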