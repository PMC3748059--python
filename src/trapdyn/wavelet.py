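"""Morlet continuous wavelet transform suite for weekly series.

Implements, in the convention of the classical geophysical CWT literature:

* the FFT-based Morlet (ω₀ = 6) continuous wavelet transform with dyadic
  scales s_j = s₀·2^{jδj} and Fourier periods λ_j = 4πs_j/(ω₀+√(2+ω₀²));
* pointwise power significance against a red-noise (AR(1)) background
  spectrum via the chi-squared distribution of normalized power;
* the cross-wavelet spectrum W_x·conj(W_y) with relative phase reported in
  the arrow convention used for spectral figures: 0° in-phase, +90° means
  the second series leads by a quarter period;
* smoothed wavelet coherence R² ∈ [0, 1] with Monte-Carlo significance from
  AR(1) surrogate pairs matched to the lag-1 autocorrelations of the inputs.

Series are log-transformed (with an optional offset for exact zeros, e.g.
rain-free weeks) and standardized before analysis; standardization makes
spectra invariant to units and scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

__all__ = [
    "OMEGA0",
    "fourier_factor",
    "preprocess",
    "CWTResult",
    "cwt_morlet",
    "SignificanceMask",
    "red_noise_significance",
    "CrossSpectrum",
    "cross_wavelet",
    "CoherenceResult",
    "coherence",
    "interaction_series",
    "spectrum_frame",
]

OMEGA0 = 6.0


def fourier_factor(w0: float = OMEGA0) -> float:
    """Scale-to-Fourier-period conversion: λ = factor · s."""
    return 4.0 * np.pi / (w0 + np.sqrt(2.0 + w0**2))


def preprocess(series, zero_offset: float = 0.0) -> np.ndarray:
    """Natural log then standardization to zero mean and unit variance.

    ``zero_offset`` is added before the log (use 1 for precipitation with
    exact zeros).  Non-positive values after the offset raise ValueError
    naming the first offending index.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 16:
        raise ValueError("series must have length >= 16")
    shifted = x + zero_offset
    bad = np.where(shifted <= 0)[0]
    if len(bad):
        raise ValueError(
            f"non-positive value at index {bad[0]} after zero_offset "
            f"{zero_offset}; log undefined"
        )
    lx = np.log(shifted)
    sd = lx.std()
    if sd == 0:
        raise ValueError("constant series cannot be standardized")
    return (lx - lx.mean()) / sd


def _ar1_coef(x: np.ndarray) -> float:
    """Ordinary lag-1 sample autocorrelation."""
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    denom = np.sum(x * x)
    if denom == 0:
        raise ValueError("lag-1 autocorrelation undefined for constant series")
    return float(np.sum(x[:-1] * x[1:]) / denom)


@dataclass(frozen=True)
class CWTResult:
    """Continuous wavelet transform of one series.

    ``coefficients`` has shape (n_scales, n_times); ``coi`` gives, per time
    point, the largest Fourier period unaffected by edge effects (the
    e-folding distance of the Morlet envelope is √2·s).
    """

    coefficients: np.ndarray
    scales: np.ndarray
    periods: np.ndarray
    coi: np.ndarray
    dt: float
    dj: float
    w0: float
    series_variance: float

    @property
    def power(self) -> np.ndarray:
        return np.abs(self.coefficients) ** 2

    @property
    def n_times(self) -> int:
        return self.coefficients.shape[1]

    def in_coi(self) -> np.ndarray:
        """Boolean matrix: True where the cell is inside the cone of influence."""
        return self.periods[:, None] < self.coi[None, :]

    def scale_index_for_period(self, period: float) -> int:
        return int(np.argmin(np.abs(self.periods - period)))


def cwt_morlet(series, dt: float = 1.0, dj: float = 1.0 / 12, s0: float | None = None,
               J: int | None = None, w0: float = OMEGA0, pad: bool = True,
               detrend_mean: bool = True) -> CWTResult:
    """Morlet CWT with FFT convolution and zero padding to a power of two.

    Defaults follow the classical routines: s₀ = 2δt, δj = 1/12 (twelve
    sub-octaves), J = log₂(nδt/s₀)/δj.  The wavelet is normalized so the
    expected power of unit-variance white noise is flat (≈1) across scales.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if s0 is None:
        s0 = 2.0 * dt
    if n * dt < 2.0 * s0:
        raise ValueError("series too short for the smallest scale")
    if J is None:
        J = int(np.floor(np.log2(n * dt / s0) / dj))
    if J < 1:
        raise ValueError("fewer than two scales; series too short")
    if detrend_mean:
        x = x - x.mean()
    # pad to at least double the series length so wrap-around from the
    # circular FFT convolution is pushed into the zero-padded region
    npad = int(2 ** (np.ceil(np.log2(n)) + 1)) if pad else n
    xh = np.fft.fft(x, npad)
    k = 2.0 * np.pi * np.fft.fftfreq(npad, d=dt)
    scales = s0 * 2.0 ** (dj * np.arange(J + 1))
    W = np.empty((J + 1, n), dtype=complex)
    norm_const = np.pi**-0.25
    for j, s in enumerate(scales):
        # analytic Morlet: support on positive frequencies only
        psi_hat = norm_const * np.sqrt(2.0 * np.pi * s / dt) \
            * np.exp(-0.5 * (s * k - w0) ** 2) * (k > 0)
        W[j] = np.fft.ifft(xh * psi_hat)[:n]
    ff = fourier_factor(w0)
    edge = np.minimum(np.arange(n), np.arange(n)[::-1]).astype(float)
    coi = ff / np.sqrt(2.0) * dt * edge  # 0 at both edges, maximal mid-series
    return CWTResult(
        coefficients=W, scales=scales, periods=ff * scales, coi=coi,
        dt=dt, dj=dj, w0=w0, series_variance=float(np.var(np.asarray(series, float))),
    )


# ---------------------------------------------------------------------------
# Red-noise significance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SignificanceMask:
    """Pointwise power significance against an AR(1) background."""

    mask: np.ndarray          # True where power exceeds the threshold
    threshold: np.ndarray     # per-scale chi-squared threshold
    background: np.ndarray    # per-scale red-noise spectrum (x series variance)
    r1: float
    level: float


def red_noise_background(r1: float, periods: np.ndarray, dt: float = 1.0) -> np.ndarray:
    """Normalized AR(1) (red-noise) spectrum at the scales' Fourier periods.

    P(f) = (1 − r₁²) / (1 + r₁² − 2r₁·cos(2πf·δt)) with f = 1/λ; flat (≡1)
    for white noise (r₁ = 0).
    """
    freq = dt / np.asarray(periods, dtype=float)
    return (1.0 - r1**2) / (1.0 + r1**2 - 2.0 * r1 * np.cos(2.0 * np.pi * freq))


def red_noise_significance(cwt: CWTResult, series, level: float = 0.95,
                           r1: float | None = None) -> SignificanceMask:
    """Chi-squared red-noise significance of the wavelet power spectrum.

    The background AR(1) coefficient is the series' lag-1 sample
    autocorrelation unless supplied.  Normalized power at each cell is
    distributed ½P_k·χ²₂ under the null, so the threshold at each scale is
    σ²·P_k·χ²₂(level)/2.
    """
    x = np.asarray(series, dtype=float)
    if r1 is None:
        r1 = _ar1_coef(x)
    if not (-1.0 < r1 < 1.0):
        raise ValueError(f"degenerate lag-1 autocorrelation r1={r1}")
    Pk = red_noise_background(r1, cwt.periods, cwt.dt) * float(np.var(x))
    threshold = Pk * stats.chi2.ppf(level, 2) / 2.0
    mask = cwt.power > threshold[:, None]
    return SignificanceMask(mask=mask, threshold=threshold, background=Pk,
                            r1=float(r1), level=level)


# ---------------------------------------------------------------------------
# Cross-wavelet spectrum and phase
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CrossSpectrum:
    """Cross-wavelet spectrum W_xy = W_x · conj(W_y) with relative phase.

    ``phase_deg`` follows the figure-arrow convention: 0° in-phase, +90°
    means the *second* series is a quarter period ahead of the first,
    ±180° anti-phase.  Values lie in (−180°, 180°].
    """

    w_xy: np.ndarray
    periods: np.ndarray
    coi: np.ndarray
    phase_deg: np.ndarray

    @property
    def cross_power(self) -> np.ndarray:
        return np.abs(self.w_xy)


def cross_wavelet(x: CWTResult, y: CWTResult) -> CrossSpectrum:
    """Cross-wavelet spectrum of two transforms on identical axes."""
    if x.coefficients.shape != y.coefficients.shape or \
            not np.allclose(x.scales, y.scales) or x.dt != y.dt:
        raise ValueError("transforms have mismatched time or scale axes")
    w_xy = x.coefficients * np.conj(y.coefficients)
    # angle(conj(Wx)·Wy) = phase(y) − phase(x): positive when y leads
    phase = np.degrees(np.angle(np.conj(w_xy)))
    phase = np.where(phase <= -180.0, phase + 360.0, phase)
    return CrossSpectrum(w_xy=w_xy, periods=x.periods, coi=x.coi, phase_deg=phase)


def mean_phase_deg(phases_deg: np.ndarray) -> float:
    """Circular mean of phase angles, in degrees in (−180, 180]."""
    rad = np.radians(np.asarray(phases_deg, dtype=float))
    m = np.degrees(np.angle(np.mean(np.exp(1j * rad))))
    return float(m if m > -180.0 else m + 360.0)


# ---------------------------------------------------------------------------
# Wavelet coherence
# ---------------------------------------------------------------------------

def _smooth(field: np.ndarray, scales: np.ndarray, dt: float, dj: float) -> np.ndarray:
    """Coherence smoothing: Gaussian in time (sd = s/δt samples per scale),
    boxcar across scales (width 0.6/δj scale steps)."""
    out = np.empty_like(field, dtype=float)
    for j, s in enumerate(scales):
        out[j] = gaussian_filter1d(field[j].real, sigma=s / dt, mode="nearest")
    width = max(1, int(round(0.6 / dj)))
    if width > 1:
        out = uniform_filter1d(out, size=width, axis=0, mode="nearest")
    return out


def _smooth_complex(field: np.ndarray, scales: np.ndarray, dt: float,
                    dj: float) -> np.ndarray:
    return _smooth(field.real, scales, dt, dj) + 1j * _smooth(field.imag, scales, dt, dj)


@dataclass(frozen=True)
class CoherenceResult:
    """Smoothed squared wavelet coherence with Monte-Carlo significance."""

    r2: np.ndarray
    periods: np.ndarray
    coi: np.ndarray
    phase_deg: np.ndarray
    significance: np.ndarray | None
    threshold: np.ndarray | None   # per-scale surrogate percentile
    r1x: float
    r1y: float
    n_surrogates: int
    level: float


def _coherence_matrix(Wx: CWTResult, Wy: CWTResult) -> np.ndarray:
    scales, dt, dj = Wx.scales, Wx.dt, Wx.dj
    inv_s = 1.0 / scales[:, None]
    sxx = _smooth(np.abs(Wx.coefficients) ** 2 * inv_s, scales, dt, dj)
    syy = _smooth(np.abs(Wy.coefficients) ** 2 * inv_s, scales, dt, dj)
    sxy = _smooth_complex(Wx.coefficients * np.conj(Wy.coefficients) * inv_s,
                          scales, dt, dj)
    r2 = np.abs(sxy) ** 2 / (sxx * syy)
    return np.clip(r2, 0.0, 1.0)


def _ar1_surrogate(rng: np.random.Generator, n: int, phi: float) -> np.ndarray:
    burn = 50
    eps = rng.normal(size=n + burn)
    z = np.empty(n + burn)
    z[0] = eps[0] / np.sqrt(max(1.0 - phi**2, 1e-12))
    for i in range(1, n + burn):
        z[i] = phi * z[i - 1] + eps[i]
    z = z[burn:]
    return (z - z.mean()) / z.std()


def coherence(x, y, n_surrogates: int = 300, level: float = 0.95,
              dt: float = 1.0, dj: float = 1.0 / 12, seed=None) -> CoherenceResult:
    """Squared wavelet coherence of two (preprocessed) series.

    R²(s, t) = |S(W_xy/s)|² / (S(|W_x|²/s) · S(|W_y|²/s)) with the smoothing
    operator ``S`` described in :func:`_smooth`.  Significance is assessed
    against ``n_surrogates`` AR(1) surrogate pairs matched to each input's
    lag-1 autocorrelation: the per-scale ``level`` quantile of surrogate R²
    values pooled over in-COI times.  Set ``n_surrogates=0`` to skip the
    Monte-Carlo step.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("series must share the same time axis")
    if min(1.0 / dj * 0.6, x.size) < 1:
        raise ValueError("degenerate smoothing window")
    Wx = cwt_morlet(x, dt=dt, dj=dj)
    Wy = cwt_morlet(y, dt=dt, dj=dj)
    r2 = _coherence_matrix(Wx, Wy)
    xs = cross_wavelet(Wx, Wy)

    sig = thr = None
    r1x, r1y = _ar1_coef(x), _ar1_coef(y)
    if n_surrogates > 0:
        rng = np.random.default_rng(seed)
        incoi = Wx.in_coi()
        pool: list[np.ndarray] = []
        for _ in range(n_surrogates):
            sx = _ar1_surrogate(rng, len(x), r1x)
            sy = _ar1_surrogate(rng, len(y), r1y)
            rs = _coherence_matrix(cwt_morlet(sx, dt=dt, dj=dj),
                                   cwt_morlet(sy, dt=dt, dj=dj))
            pool.append(rs)
        stack = np.stack(pool)  # (n_surr, n_scales, n_times)
        thr = np.empty(len(Wx.scales))
        for j in range(len(Wx.scales)):
            vals = stack[:, j, incoi[j]]
            thr[j] = np.quantile(vals, level) if vals.size else np.inf
        sig = r2 > thr[:, None]
    return CoherenceResult(
        r2=r2, periods=Wx.periods, coi=Wx.coi, phase_deg=xs.phase_deg,
        significance=sig, threshold=thr, r1x=r1x, r1y=r1y,
        n_surrogates=n_surrogates, level=level,
    )


# ---------------------------------------------------------------------------
# Derived interaction series and serialization
# ---------------------------------------------------------------------------

def interaction_series(a, b, zero_offset: float = 0.0) -> np.ndarray:
    """Elementwise product of two raw series, then :func:`preprocess`.

    Used to examine the joint (interaction) signal of two meteorological
    variables in the time-scale plane.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must share the same week axis")
    return preprocess(a * b, zero_offset=zero_offset)


def spectrum_frame(periods: np.ndarray, coi: np.ndarray, value: np.ndarray,
                   significant: np.ndarray | None = None,
                   phase_deg: np.ndarray | None = None) -> pd.DataFrame:
    """Long-format (time, period, value, in_coi, ...) table of a spectrum."""
    n_s, n_t = value.shape
    t_idx, s_idx = np.meshgrid(np.arange(n_t), np.arange(n_s))
    df = pd.DataFrame({
        "time": t_idx.ravel(),
        "period": np.repeat(periods, n_t),
        "value": value.ravel(),
        "in_coi": (periods[:, None] < coi[None, :]).ravel(),
    })
    if significant is not None:
        df["significant"] = significant.ravel()
    if phase_deg is not None:
        df["phase_deg"] = phase_deg.ravel()
    return df


def plot_power(cwt: CWTResult, mask: SignificanceMask | None = None, ax=None,
               title: str = "Wavelet power spectrum"):
    """Render a power spectrum panel (period on a log2 axis, COI shaded)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    t = np.arange(cwt.n_times)
    ax.contourf(t, cwt.periods, np.log2(cwt.power + 1e-12), levels=20, cmap="jet")
    if mask is not None:
        ax.contour(t, cwt.periods, mask.mask.astype(float), levels=[0.5],
                   colors="k", linewidths=1.5)
    ax.plot(t, cwt.coi, "k--", lw=1)
    ax.fill_between(t, cwt.coi, cwt.periods.max(), color="white", alpha=0.4)
    ax.set_yscale("log", base=2)
    ax.set_ylim(cwt.periods.max(), cwt.periods.min())
    ax.set_xlabel("week")
    ax.set_ylabel("period (weeks)")
    ax.set_title(title)
    return ax
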