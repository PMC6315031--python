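"""Discriminative noise analysis for nanopore current levels.

The level-conditional noise (after mean subtraction) is characterized
three ways and the descriptions are combined to arbitrate ambiguous
segments:

* time domain — a 4-component Gaussian mixture fitted by EM, with
  goodness of fit judged by the tail-weighted (Anderson-Darling)
  distance between empirical and model CDFs,

      D = n * integral (Fn(x) - F(x))^2 * w(x) dF(x),
      w(x) = [F(x) (1 - F(x))]^(-1),

  computed via the exact order-statistic identity and calibrated by
  parametric bootstrap (classical critical values do not apply once the
  mixture parameters are estimated from the same data);
* frequency domain — Welch PSD estimates fitted with the flicker-noise
  model S = a1/f^beta + a2 (+ optional dielectric/capacitive terms);
* Hilbert-Huang energies — empirical mode decomposition followed by
  analytic-signal instantaneous amplitudes, summarized as band energy.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import least_squares
from scipy.signal import hilbert as _hilbert
from scipy.signal import welch as _welch

from .simulate import GMMParams, PSDModelParams
from .trace import CurrentTrace, Event, LevelSegment

__all__ = [
    "ADStatistic",
    "PSDFit",
    "NoiseProfile",
    "fit_gmm",
    "ad_weighted_distance",
    "ad_gof_test",
    "welch_psd",
    "fit_psd_model",
    "build_noise_profiles",
    "baseline_segments",
    "classify_level_by_noise",
    "emd",
    "hht_energy",
]


# ---------------------------------------------------------------------------
# GMM fitting
# ---------------------------------------------------------------------------


_LOG_SQRT_2PI = 0.5 * np.log(2 * np.pi)


def _kmeanspp_centers(X: np.ndarray, K: int, rng) -> np.ndarray:
    """k-means++-style seeding per row of the (B, n) data matrix."""
    B, n = X.shape
    centers = np.empty((B, K))
    first = rng.integers(0, n, size=B)
    centers[:, 0] = X[np.arange(B), first]
    d2 = (X - centers[:, :1]) ** 2
    for k in range(1, K):
        prob = d2 / np.maximum(d2.sum(axis=1, keepdims=True), 1e-300)
        cum = np.cumsum(prob, axis=1)
        u = rng.random((B, 1))
        idx = np.minimum((cum < u).sum(axis=1), n - 1)
        centers[:, k] = X[np.arange(B), idx]
        d2 = np.minimum(d2, (X - centers[:, k : k + 1]) ** 2)
    return centers


def _em_batch(
    X: np.ndarray,
    K: int,
    rng,
    n_restarts: int = 10,
    max_iter: int = 200,
    tol: float = 1e-6,
    record_trajectory: bool = False,
):
    """Batched EM for 1-D Gaussian mixtures: rows of X are independent
    datasets fitted simultaneously; restarts are resolved per row by
    log-likelihood. Returns (weights, means, sds, loglik, degenerate,
    trajectory-of-best-restart-or-None)."""
    X = np.atleast_2d(np.asarray(X, float))
    B, n = X.shape
    var = X.var(axis=1, keepdims=True)
    floor = np.maximum(1e-6 * var, 1e-300)

    best = None
    best_traj = None
    best_degen = None
    for _ in range(max(1, int(n_restarts))):
        mu = _kmeanspp_centers(X, K, rng)
        sd = np.sqrt(np.maximum(var, floor)) * np.ones((B, K))
        w = np.full((B, K), 1.0 / K)
        ll_prev = np.full(B, -np.inf)
        traj = []
        for _it in range(max_iter):
            # E step (log domain)
            z = (X[:, :, None] - mu[:, None, :]) / sd[:, None, :]
            logp = -0.5 * z**2 - np.log(sd[:, None, :]) - _LOG_SQRT_2PI + np.log(w[:, None, :])
            m = logp.max(axis=2, keepdims=True)
            lse = m[:, :, 0] + np.log(np.exp(logp - m).sum(axis=2))
            ll = lse.mean(axis=1)
            resp = np.exp(logp - lse[:, :, None])
            # M step
            nk = resp.sum(axis=1) + 1e-300
            w = nk / n
            mu = (resp * X[:, :, None]).sum(axis=1) / nk
            var_k = (resp * (X[:, :, None] - mu[:, None, :]) ** 2).sum(axis=1) / nk
            sd = np.sqrt(np.maximum(var_k, floor))
            if record_trajectory:
                traj.append(ll.copy())
            if np.all(np.abs(ll - ll_prev) < tol * (np.abs(ll) + 1.0)):
                break
            ll_prev = ll
        degen = np.any(sd <= np.sqrt(floor) * 1.001, axis=1)
        if best is None:
            best = (w, mu, sd, ll)
            best_traj = traj
            best_degen = degen
        else:
            # a collapsed component inflates the likelihood spuriously, so
            # non-degenerate restarts win over degenerate ones regardless
            improve = ((ll > best[3]) & (degen == best_degen)) | (best_degen & ~degen)
            bw, bm, bs, bll = best
            bw[improve], bm[improve], bs[improve] = w[improve], mu[improve], sd[improve]
            bll[improve] = ll[improve]
            best = (bw, bm, bs, bll)
            best_degen = np.where(improve, degen, best_degen)
            if record_trajectory and improve[0]:
                best_traj = traj
    w, mu, sd, ll = best
    degenerate = best_degen
    order = np.argsort(mu, axis=1)
    take = np.arange(B)[:, None]
    trajectory = None
    if record_trajectory and best_traj:
        trajectory = np.array([t[0] for t in best_traj])
    return w[take, order], mu[take, order], sd[take, order], ll, degenerate, trajectory


def fit_gmm(
    samples,
    K: int = 4,
    seed: int = 0,
    n_restarts: int = 10,
    max_iter: int = 200,
    tol: float = 1e-6,
    return_trajectory: bool = False,
):
    """Maximum-likelihood Gaussian mixture via EM (best of ``n_restarts``,
    k-means++-style seeding, fixed seed).

    Requires ``n >= 50*K`` mean-subtracted samples. Components collapsing
    to zero variance are floored and flagged via a warning. With
    ``return_trajectory`` the winning restart's per-iteration mean
    log-likelihood is returned alongside (EM guarantees it is
    non-decreasing).
    """
    x = np.asarray(samples, float).ravel()
    n = x.size
    if n < 50 * K:
        raise ValueError(f"need at least 50*K={50*K} samples, got {n}")
    rng = np.random.default_rng(seed)
    w, mu, sd, ll, degen, traj = _em_batch(
        x[None, :], K, rng, n_restarts=n_restarts, max_iter=max_iter, tol=tol,
        record_trajectory=return_trajectory,
    )
    if degen[0]:
        warnings.warn("degenerate GMM component: sd floored")
    params = GMMParams(
        weights=tuple(w[0] / w[0].sum()), means=tuple(mu[0]), sds=tuple(sd[0])
    )
    if not return_trajectory:
        return params
    return params, traj


# ---------------------------------------------------------------------------
# Weighted distribution distance (Anderson-Darling)
# ---------------------------------------------------------------------------


def ad_weighted_distance(samples, model_cdf) -> float:
    """Tail-weighted squared CDF distance via the order-statistic identity.

        D = -n - (1/n) * sum_i (2i-1) [ln F(x_(i)) + ln(1 - F(x_(n+1-i)))]

    which equals the weighted integral definition exactly. CDF values at
    0 or 1 are clamped to a machine-epsilon margin (with a warning), as
    the weight diverges there.
    """
    x = np.sort(np.asarray(samples, float))
    n = x.size
    if n < 1:
        raise ValueError("need at least one sample")
    u = np.asarray(model_cdf(x), float)
    eps = np.finfo(float).tiny
    if np.any(u <= 0.0) or np.any(u >= 1.0):
        warnings.warn("model CDF hit 0 or 1 at a sample; clamping")
        u = np.clip(u, eps, 1.0 - np.finfo(float).epsneg)
    i = np.arange(1, n + 1)
    return float(-n - np.mean((2 * i - 1) * (np.log(u) + np.log1p(-u[::-1]))))


@dataclass(frozen=True)
class ADStatistic:
    """Weighted-distance GOF result with a parametric-bootstrap p-value."""

    D: float
    n: int
    p_value: float
    reject: bool
    size: float = 0.05
    n_boot: int = 199


def ad_gof_test(
    samples,
    fitted: GMMParams,
    n_boot: int = 199,
    seed: int = 0,
    size: float = 0.05,
    refit_K: int | None = None,
    refit_restarts: int = 1,
    refit_tol: float = 1e-5,
    refit_max_iter: int = 150,
) -> ADStatistic:
    """Parametric-bootstrap GOF test of a mixture fitted to the same data.

    Each bootstrap draw is simulated from the fitted mixture and the
    mixture is refitted before the distance is recomputed, which is what
    makes the p-value valid under estimated parameters (classical
    critical values are not).
    """
    if n_boot < 99:
        raise ValueError("n_boot must be at least 99")
    x = np.asarray(samples, float)
    n = x.size
    K = refit_K if refit_K is not None else fitted.n_components
    D_obs = ad_weighted_distance(x, fitted.cdf)
    rng = np.random.default_rng(seed)

    # simulate all bootstrap datasets at once and refit them batched
    comp = rng.choice(K, size=(n_boot, n), p=np.asarray(fitted.weights))
    Xb = rng.normal(np.asarray(fitted.means)[comp], np.asarray(fitted.sds)[comp])
    w, mu, sd, _, _, _ = _em_batch(
        Xb, K, rng, n_restarts=refit_restarts, max_iter=refit_max_iter, tol=refit_tol
    )

    exceed = 0
    for b in range(n_boot):
        gb = GMMParams(tuple(w[b] / w[b].sum()), tuple(mu[b]), tuple(sd[b]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if ad_weighted_distance(Xb[b], gb.cdf) >= D_obs:
                exceed += 1
    p = (1.0 + exceed) / (n_boot + 1.0)
    return ADStatistic(D=D_obs, n=n, p_value=p, reject=bool(p < size), size=size, n_boot=n_boot)


# ---------------------------------------------------------------------------
# Welch PSD and model fitting
# ---------------------------------------------------------------------------


def welch_psd(samples, fs: float, window_len: int = 4096, overlap: float = 0.5):
    """One-sided Welch PSD (Hann window, mean over overlapping segments)."""
    x = np.asarray(samples, float)
    if x.size < window_len:
        raise ValueError(f"need at least window_len={window_len} samples, got {x.size}")
    return _welch(x, fs=fs, window="hann", nperseg=window_len, noverlap=int(window_len * overlap))


@dataclass(frozen=True)
class PSDFit:
    """Flicker-noise model fit with 95% confidence bounds per parameter."""

    params: PSDModelParams
    ci: dict  # name -> (low, high)
    band: tuple[float, float]
    residual_norm: float
    a1_significant: bool = True
    beta_identifiable: bool = True

    def model(self, f):
        return self.params(f)


def fit_psd_model(
    freqs,
    psd,
    band: tuple[float, float] = (10.0, 5000.0),
    include_white: bool = True,
    full_model: bool = False,
) -> PSDFit:
    """Nonlinear least squares of log S(f) against the log Welch PSD.

    Default model is ``a1/f^beta + a2`` (the dielectric/capacitive terms
    a3, a4 are enabled by ``full_model``). Confidence bounds come from
    the fit covariance; for spectrally white input the flicker amplitude
    is reported non-significant (bound includes 0) and beta flagged
    unidentifiable.
    """
    f = np.asarray(freqs, float)
    P = np.asarray(psd, float)
    m = (f >= band[0]) & (f <= band[1]) & (P > 0) & (f > 0)
    if m.sum() < 10:
        raise ValueError("need at least 10 frequency bins in the fit band")
    f, P = f[m], P[m]
    # normalize for conditioning (PSD magnitudes span many decades)
    scale = float(np.median(P))
    Pn = P / scale
    logP = np.log(Pn)

    n_par = 4 if full_model else (3 if include_white else 2)

    def unpack(th):
        a1, beta = th[0], th[1]
        a2 = th[2] if n_par >= 3 else 0.0
        a3 = th[3] if n_par == 4 else 0.0
        return a1, beta, a2, a3

    def resid(th):
        a1, beta, a2, a3 = unpack(th)
        model = a1 * f ** (-beta) + a2 + a3 * f
        return np.log(np.maximum(model, 1e-300)) - logP

    p_lo = float(np.exp(logP[0]))
    p_hi = float(np.exp(np.median(logP[-10:])))
    res = None
    for beta0 in (0.2, 0.5, 1.0):
        x0 = [max(p_lo - p_hi, p_lo * 0.1) * f[0] ** beta0, beta0]
        lo = [0.0, 0.0]
        hi = [np.inf, 4.0]
        if n_par >= 3:
            x0.append(max(p_hi * 0.5, 1e-300))
            lo.append(0.0)
            hi.append(np.inf)
        if n_par == 4:
            x0.append(1e-300)
            lo.append(0.0)
            hi.append(np.inf)
        trial = least_squares(resid, x0, bounds=(lo, hi), x_scale="jac", max_nfev=5000)
        if res is None or trial.cost < res.cost:
            res = trial
    if not res.success and res.status <= 0:
        raise RuntimeError(f"PSD model fit did not converge: {res.message}; last iterate {res.x}")

    dof = max(f.size - n_par, 1)
    s2 = 2.0 * res.cost / dof
    JTJ = res.jac.T @ res.jac
    try:
        cov = s2 * np.linalg.inv(JTJ)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(n_par, np.inf)

    a1, beta, a2, a3 = unpack(res.x)
    a1, a2, a3 = a1 * scale, a2 * scale, a3 * scale
    names = ["a1", "beta", "a2", "a3"][:n_par]
    unit = {"a1": scale, "beta": 1.0, "a2": scale, "a3": scale}
    ci = {
        name: (float((v - 1.96 * s) * unit[name]), float((v + 1.96 * s) * unit[name]))
        for name, v, s in zip(names, res.x, se)
    }
    a1_sig = ci["a1"][0] > 0.0
    beta_ok = bool(np.isfinite(se[1]) and se[1] < 0.5 and a1_sig)
    params = PSDModelParams(a1=a1, beta=beta, a2=a2, a3=a3)
    return PSDFit(
        params=params,
        ci=ci,
        band=(float(f[0]), float(f[-1])),
        residual_norm=float(np.sqrt(2.0 * res.cost)),
        a1_significant=a1_sig,
        beta_identifiable=beta_ok,
    )


# ---------------------------------------------------------------------------
# Empirical mode decomposition / Hilbert-Huang energies
# ---------------------------------------------------------------------------


def _envelope_mean(x: np.ndarray):
    """Mean of upper/lower cubic-spline envelopes, or None when the signal
    has too few extrema to define them (mirror boundary extension)."""
    n = x.size
    d = np.diff(x)
    maxima = np.where((np.hstack([d, -1]) < 0) & (np.hstack([1, d]) > 0))[0]
    minima = np.where((np.hstack([d, -1]) > 0) & (np.hstack([1, d]) < 0))[0]
    if maxima.size < 2 or minima.size < 2:
        return None
    idx_max = np.concatenate([[-maxima[0]], maxima, [2 * (n - 1) - maxima[-1]]])
    idx_min = np.concatenate([[-minima[0]], minima, [2 * (n - 1) - minima[-1]]])
    # de-duplicate mirrored knots that coincide with the originals
    idx_max = np.unique(idx_max)
    idx_min = np.unique(idx_min)
    upper = CubicSpline(idx_max, x[np.clip(np.abs(idx_max), 0, n - 1)])(np.arange(n))
    lower = CubicSpline(idx_min, x[np.clip(np.abs(idx_min), 0, n - 1)])(np.arange(n))
    return 0.5 * (upper + lower)


def emd(
    samples,
    max_imfs: int = 12,
    stop_sd: float = 0.2,
    max_sifts: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical mode decomposition by sifting.

    Returns ``(imfs, residual)`` with ``imfs.sum(axis=0) + residual``
    reconstructing the input to machine precision. Sifting of one mode
    stops when the normalized squared change (Huang's SD criterion)
    falls below ``stop_sd``; exceeding ``max_sifts`` raises.
    """
    x = np.asarray(samples, float)
    residual = x.copy()
    imfs = []
    for _ in range(max_imfs):
        h = residual.copy()
        for it in range(max_sifts + 1):
            m = _envelope_mean(h)
            if m is None:
                break
            h_new = h - m
            denom = float(np.sum(h**2))
            sd = float(np.sum((h - h_new) ** 2)) / denom if denom > 0 else 0.0
            h = h_new
            if sd < stop_sd:
                break
        else:
            raise RuntimeError(f"sifting did not converge within {max_sifts} iterations")
        if m is None and not imfs:
            break  # monotone input: no oscillatory mode at all
        if m is None:
            break
        imfs.append(h)
        residual = residual - h
        d = np.diff(residual)
        n_extrema = int(np.sum((d[1:] * d[:-1]) < 0))
        if n_extrema < 3:
            break
    return np.asarray(imfs), residual


def hht_energy(samples, fs: float, band: tuple[float, float] = (10.0, 5000.0)) -> dict:
    """Per-IMF and total in-band Hilbert energy.

    Each IMF's analytic signal gives instantaneous amplitude a(t) and
    frequency f(t); the IMF's band energy is the mean squared amplitude
    over instants where f(t) lies in ``band``. Requires >= 512 samples.
    """
    x = np.asarray(samples, float)
    if x.size < 512:
        raise ValueError("need at least 512 samples for HHT energies")
    imfs, residual = emd(x)
    energies = []
    for imf in imfs:
        analytic = _hilbert(imf)
        amp = np.abs(analytic)
        phase = np.unwrap(np.angle(analytic))
        inst_f = np.abs(np.diff(phase)) * fs / (2 * np.pi)
        in_band = (inst_f >= band[0]) & (inst_f <= band[1])
        energies.append(float(np.mean(amp[:-1][in_band] ** 2)) if in_band.any() else 0.0)
    return {
        "imf_energies": energies,
        "total": float(np.sum(energies)),
        "n_imfs": len(energies),
        "band": band,
        "reconstruction_error": float(
            np.max(np.abs(imfs.sum(axis=0) + residual - x)) / max(np.max(np.abs(x)), 1e-300)
        )
        if len(imfs)
        else 0.0,
    }


# ---------------------------------------------------------------------------
# Per-level noise profiles and noise-based arbitration
# ---------------------------------------------------------------------------


@dataclass
class NoiseProfile:
    """Complete noise description of one occupancy level."""

    level_label: int
    gmm: GMMParams
    psd_fit: PSDFit
    hht: dict
    n_samples: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "level_label": self.level_label,
                "gmm": {
                    "weights": list(self.gmm.weights),
                    "means": list(self.gmm.means),
                    "sds": list(self.gmm.sds),
                },
                "psd": {
                    "a1": self.psd_fit.params.a1,
                    "beta": self.psd_fit.params.beta,
                    "a2": self.psd_fit.params.a2,
                    "a3": self.psd_fit.params.a3,
                    "a4": self.psd_fit.params.a4,
                    "ci": {k: list(v) for k, v in self.psd_fit.ci.items()},
                    "band": list(self.psd_fit.band),
                    "residual_norm": self.psd_fit.residual_norm,
                    "a1_significant": self.psd_fit.a1_significant,
                    "beta_identifiable": self.psd_fit.beta_identifiable,
                },
                "hht": self.hht,
                "n_samples": self.n_samples,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "NoiseProfile":
        d = json.loads(text)
        psd = d["psd"]
        fit = PSDFit(
            params=PSDModelParams(
                a1=psd["a1"], beta=psd["beta"], a2=psd["a2"], a3=psd["a3"], a4=psd["a4"]
            ),
            ci={k: tuple(v) for k, v in psd["ci"].items()},
            band=tuple(psd["band"]),
            residual_norm=psd["residual_norm"],
            a1_significant=psd["a1_significant"],
            beta_identifiable=psd["beta_identifiable"],
        )
        hht = dict(d["hht"])
        if "band" in hht:
            hht["band"] = tuple(hht["band"])
        return cls(
            level_label=d["level_label"],
            gmm=GMMParams(
                tuple(d["gmm"]["weights"]), tuple(d["gmm"]["means"]), tuple(d["gmm"]["sds"])
            ),
            psd_fit=fit,
            hht=hht,
            n_samples=d["n_samples"],
        )


def baseline_segments(trace: CurrentTrace, events: list[Event], margin: int = 50) -> list[LevelSegment]:
    """Level-0 segments: inter-event stretches, a safety margin away."""
    segs = []
    pos = margin
    bounds = sorted((ev.start, ev.end) for ev in events)
    for start, end in bounds:
        if start - margin > pos:
            chunk = trace.samples[pos : start - margin]
            segs.append(LevelSegment(pos, start - margin, float(np.mean(chunk)), level_label=0))
        pos = end + margin
    if len(trace) - margin > pos:
        chunk = trace.samples[pos : len(trace) - margin]
        segs.append(LevelSegment(pos, len(trace) - margin, float(np.mean(chunk)), level_label=0))
    return segs


def build_noise_profiles(
    trace: CurrentTrace,
    segments: list[LevelSegment],
    min_samples: int = 10_000,
    gmm_K: int = 4,
    seed: int = 0,
    max_window: int = 65_536,
    gmm_max_samples: int = 30_000,
    gmm_restarts: int = 5,
    hht_max_samples: int = 8_192,
    edge_trim: int = 5,
) -> dict[int, NoiseProfile]:
    """Per-level noise profiles from labeled segments.

    Each level's segments are mean-subtracted individually and pooled;
    levels with fewer than ``min_samples`` pooled samples are skipped.
    The Welch window adapts per level to the largest power of two the
    level's segments can hold (floor 256, cap ``max_window``), because
    in-event segments are short while baseline stretches are long; the
    flicker model is fitted over [2 fs/window, 5 kHz]. The mixture fit
    subsamples very large pools for tractability. ``edge_trim`` guard
    samples are dropped at both segment ends: change-point placement is
    only sample-accurate, and a single sample of the neighbouring level
    is an extreme outlier on the residual scale.
    """
    fs = trace.sampling_rate
    rng = np.random.default_rng(seed)
    by_level: dict[int, list[np.ndarray]] = {}
    for seg in segments:
        if seg.level_label is None:
            continue
        lo = seg.start + edge_trim
        hi = seg.end - edge_trim
        if hi - lo < 16:
            lo, hi = seg.start, seg.end
        chunk = trace.samples[lo:hi]
        by_level.setdefault(seg.level_label, []).append(chunk - np.mean(chunk))

    profiles: dict[int, NoiseProfile] = {}
    for level, chunks in sorted(by_level.items()):
        pooled = np.concatenate(chunks)
        if pooled.size < min_samples:
            continue
        sub = pooled
        if sub.size > gmm_max_samples:
            sub = rng.choice(pooled, size=gmm_max_samples, replace=False)
        gmm = fit_gmm(sub, K=gmm_K, seed=seed, n_restarts=gmm_restarts)

        lengths = sorted(c.size for c in chunks)
        median_len = lengths[len(lengths) // 2]
        window = 2 ** int(np.log2(max(min(median_len, max_window), 256)))
        while window > 256 and not any(c.size >= window for c in chunks):
            window //= 2
        if any(c.size >= window for c in chunks):
            spectra = [welch_psd(c, fs, window_len=window)[1] for c in chunks if c.size >= window]
            f = welch_psd(next(c for c in chunks if c.size >= window), fs, window_len=window)[0]
        else:
            # all segments shorter than the smallest window: fall back to the
            # pooled series (join discontinuities mildly bias the low band)
            f, P = welch_psd(pooled, fs, window_len=window)
            spectra = [P]
        P_mean = np.mean(spectra, axis=0)
        band = (2.0 * fs / window, 5000.0)
        fit = fit_psd_model(f, P_mean, band=band)
        hht = hht_energy(pooled[:hht_max_samples], fs) if pooled.size >= 512 else {}
        profiles[level] = NoiseProfile(
            level_label=level, gmm=gmm, psd_fit=fit, hht=hht, n_samples=int(pooled.size)
        )
    return profiles


def classify_level_by_noise(
    samples,
    profiles: dict[int, NoiseProfile],
    fs: float,
    lam: float = 1.0,
    tie_tol: float = 2.0,
    min_samples: int = 256,
) -> tuple[int | None, dict[int, float]]:
    """Arbitrate a segment's level from its noise alone.

    Per-level score = total mixture log-likelihood of the mean-subtracted
    samples plus ``lam`` times the negative spectral discrepancy (summed
    squared log-distance between the segment's Welch PSD and the level's
    fitted model over the profile's fit band). The argmax wins unless the
    margin over the runner-up is below ``tie_tol``, in which case the
    segment stays unassigned.
    """
    x = np.asarray(samples, float)
    if x.size < min_samples:
        return None, {}
    x = x - np.mean(x)
    window = min(256, x.size)
    f, P = welch_psd(x, fs, window_len=window)
    scores: dict[int, float] = {}
    for level, prof in profiles.items():
        ll = float(np.sum(prof.gmm.logpdf(x)))
        band = prof.psd_fit.band
        m = (f >= band[0]) & (f <= band[1]) & (P > 0)
        if m.any():
            model = np.maximum(prof.psd_fit.model(f[m]), 1e-300)
            disc = float(np.sum((np.log(P[m]) - np.log(model)) ** 2))
        else:
            disc = 0.0
        scores[level] = ll - lam * disc
    ranked = sorted(scores, key=scores.get, reverse=True)
    if len(ranked) > 1 and scores[ranked[0]] - scores[ranked[1]] < tie_tol:
        return None, scores
    return ranked[0], scores
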