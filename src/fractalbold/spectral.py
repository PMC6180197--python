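"""Power-spectrum operations: periodogram, 1/f^beta fit, fractality check.

A scale-free signal obeys S(f) = C_f |f|^(-beta) with beta the spectral
exponent, related to the Hurst exponent of the (noise-type) signal by
beta = 2H - 1; pink noise is beta = 1, white noise beta = 0 and Brownian
noise beta = 2.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import BetaNotFitted, NonPositivePower, SeriesTooShort
from .afa import _loglog_slope
from .series import TimeSeries

__all__ = [
    "SpectralFit",
    "periodogram",
    "fit_beta",
    "h_from_beta",
    "beta_from_h",
    "classify_fractal",
]


@dataclass(frozen=True)
class SpectralFit:
    """Positive-frequency power spectrum, optionally with a fitted power law.

    ``beta`` is the *negative* log-log OLS slope, so pink noise gives
    beta ~ +1; ``log_cf`` is the log10 intercept.
    """

    freqs: np.ndarray
    power: np.ndarray
    beta: float | None = None
    log_cf: float | None = None
    r_squared: float | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.freqs, dtype=float)
        p = np.asarray(self.power, dtype=float)
        if f.shape != p.shape:
            raise ValueError("freqs and power must align")
        if np.any(f <= 0) or np.any(np.diff(f) <= 0):
            raise ValueError("freqs must be positive and strictly increasing")
        if np.any(p < 0):
            raise ValueError("power must be >= 0")
        object.__setattr__(self, "freqs", f)
        object.__setattr__(self, "power", p)


def periodogram(ts: TimeSeries) -> SpectralFit:
    """Plain periodogram of the mean-removed series at positive frequencies.

    Frequencies are k/(N*dt) for k = 1..floor(N/2). Normalization:
    P(k) = |X_k|^2 / N with X the DFT of the centered samples, so that the
    sum of P over *all* N Fourier frequencies equals N * var(u) (Parseval).
    No tapering or averaging is applied.
    """
    if ts.n < 8:
        raise SeriesTooShort("periodogram needs N >= 8")
    u = ts.values - ts.values.mean()
    n = u.size
    x = np.fft.rfft(u)
    k = np.arange(1, n // 2 + 1)
    freqs = k / (n * ts.dt)
    power = np.abs(x[1: n // 2 + 1]) ** 2 / n
    return SpectralFit(freqs=freqs, power=power)


def fit_beta(spec: SpectralFit, min_bins: int = 8,
             band_fraction: float = 0.25) -> SpectralFit:
    """OLS power-law fit in log10-log10 axes; beta is the negative slope.

    Zero-power bins are dropped (:class:`NonPositivePower` if fewer than
    ``min_bins`` remain). The fit uses the low-frequency band
    f <= band_fraction * f_max by default: for scale-free signals the DFT
    periodogram flattens toward Nyquist (a sampled random walk has
    E[P(f)] ~ 1/(4 sin^2(pi f)), not f^-2), and because Fourier
    frequencies are linearly spaced an all-band log-log OLS is dominated
    by that region, biasing beta low by ~0.2 at beta = 2. If the band
    holds fewer than ``min_bins`` bins, the lowest ``min_bins``
    positive-power frequencies are used instead. ``band_fraction=1``
    recovers the all-band fit.
    """
    keep = spec.power > 0
    if int(keep.sum()) < min_bins:
        raise NonPositivePower(
            f"only {int(keep.sum())} positive-power bins (need >= {min_bins})")
    freqs, power = spec.freqs[keep], spec.power[keep]
    band = freqs <= band_fraction * freqs[-1]
    if int(band.sum()) < min_bins:
        band = np.zeros(freqs.size, dtype=bool)
        band[:min_bins] = True
    slope, intercept, r2 = _loglog_slope(
        np.log10(freqs[band]), np.log10(power[band]))
    return replace(spec, beta=-slope, log_cf=intercept, r_squared=r2)


def h_from_beta(beta: float) -> float:
    """Hurst exponent from the spectral exponent: H = (beta + 1) / 2."""
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    return (beta + 1.0) / 2.0


def beta_from_h(h: float) -> float:
    """Spectral exponent from the Hurst exponent: beta = 2H - 1."""
    if not np.isfinite(h):
        raise ValueError("h must be finite")
    return 2.0 * h - 1.0


def classify_fractal(spec: SpectralFit, min_beta: float = 0.5,
                     min_r2: float = 0.8) -> bool:
    """Is the spectrum compatible with a 1/f-type fractal signal?

    True iff the fitted beta >= min_beta and the log-log fit quality
    r^2 >= min_r2. Both thresholds are conventions exposed as arguments.
    """
    if spec.beta is None or spec.r_squared is None:
        raise BetaNotFitted("run fit_beta first")
    return bool(spec.beta >= min_beta and spec.r_squared >= min_r2)
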