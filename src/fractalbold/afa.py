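"""Adaptive fractal analysis (AFA).

The trend at scale ``w = 2n + 1`` is a *globally stitched* sequence of
overlapping local second-order polynomial fits: segments of length ``w``
overlap by ``n + 1`` points and are blended with linear weights
``w1 = 1 - (l-1)/n``, ``w2 = (l-1)/n`` across the overlap, giving a trend
with continuous value and derivative. The fluctuation function

    F(w) = sqrt( (1/N) * sum_i (u(i) - v(i))^2 )  ~  w^H

is evaluated on a dyadic-plus-one scale grid, and the Hurst exponent H is
the OLS slope of log2 F(w) against log2 w. By default the analysis runs on
the random-walk profile of the signal (cumulative sum of the mean-centered
samples), so beta = 1 noise yields H = 1 under beta = 2H - 1.

The same machinery provides the low/high-frequency decomposition (the LFC
is the adaptive trend at the smallest analysis scale; the HFC the residual)
and a q-order multifractal spectrum used for the monofractality check.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .errors import (
    DegenerateFluctuation,
    NonPositiveFluctuation,
    NoValidScales,
    TooFewScales,
    WindowNotOdd,
    WindowTooLarge,
    ZeroSegmentFluctuation,
)
from .series import TimeSeries, integrate_profile

__all__ = [
    "ScaleGrid",
    "TrendFit",
    "DecomposedSignal",
    "FluctuationCurve",
    "HurstEstimate",
    "MultifractalSpectrum",
    "make_scale_grid",
    "adaptive_trend",
    "fluctuation",
    "afa_curve",
    "estimate_hurst",
    "decompose_lfc_hfc",
    "multifractal_spectrum",
    "is_monofractal",
]


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScaleGrid:
    """Dyadic-plus-one analysis scales w = 2^n + 1, admissible for a series."""

    exponents: tuple[int, ...]
    windows: tuple[int, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.windows)
        if len(self.windows) != len(self.exponents):
            raise ValueError("exponents and windows must align")
        if np.any(np.diff(w) <= 0):
            raise ValueError("windows must be strictly increasing")
        if np.any(w % 2 == 0) or np.any(w < 5):
            raise ValueError("windows must be odd and >= 5")


@dataclass(frozen=True)
class TrendFit:
    """Stitched global order-2 trend v(i) at a single scale w."""

    trend: np.ndarray
    window: int


@dataclass(frozen=True)
class DecomposedSignal:
    """Low/high-frequency split: lfc + hfc reconstructs the input."""

    lfc: TimeSeries
    hfc: TimeSeries
    w_lfc: int


@dataclass(frozen=True)
class FluctuationCurve:
    """(w, F(w)) pairs over the scale grid."""

    windows: tuple[int, ...]
    fluctuations: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.windows) != len(self.fluctuations):
            raise ValueError("windows and fluctuations must align")
        f = np.asarray(self.fluctuations)
        if not np.all(np.isfinite(f)) or np.any(f < 0):
            raise ValueError("fluctuations must be finite and >= 0")


@dataclass(frozen=True)
class HurstEstimate:
    h: float
    intercept: float
    r_squared: float
    n_scales: int


@dataclass(frozen=True)
class MultifractalSpectrum:
    """q-order scaling exponents h(q); q = 2 is always present."""

    q_values: tuple[float, ...]
    h_of_q: tuple[float, ...]

    def h_at(self, q: float) -> float:
        for qi, hi in zip(self.q_values, self.h_of_q):
            if qi == q:
                return hi
        raise KeyError(f"q = {q} not in spectrum")


# --------------------------------------------------------------------------
# scale grid
# --------------------------------------------------------------------------

def make_scale_grid(n_min: int, n_max: int, series_length: int) -> ScaleGrid:
    """Windows {2^n + 1 : n_min <= n <= n_max} admissible for the series.

    A window is admissible when w <= floor(series_length / 2), i.e. at
    least two non-overlapping windows' worth of data exist. Raises
    :class:`NoValidScales` if fewer than three windows survive.
    """
    if not (2 <= n_min <= n_max):
        raise ValueError("need 2 <= n_min <= n_max")
    if series_length < 2:
        raise ValueError("series_length must be >= 2")
    limit = series_length // 2
    exps = [n for n in range(n_min, n_max + 1) if 2 ** n + 1 <= limit]
    if len(exps) < 3:
        raise NoValidScales(
            f"only {len(exps)} windows admissible for N = {series_length} "
            f"(need >= 3; rule w <= floor(N/2) = {limit})"
        )
    return ScaleGrid(tuple(exps), tuple(2 ** n + 1 for n in exps))


# --------------------------------------------------------------------------
# adaptive trend
# --------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _design(w: int) -> tuple[np.ndarray, np.ndarray]:
    """Order-2 Vandermonde on x in [-1, 1] (conditioning) and its pinv."""
    x = np.linspace(-1.0, 1.0, w)
    a = np.column_stack([np.ones(w), x, x * x])
    return a, np.linalg.pinv(a)


def _segment_starts(n_samples: int, w: int) -> list[int]:
    """Segment starts: stride n = (w-1)/2; a final segment is clamped to
    cover the last w samples when the stride does not land exactly."""
    n = (w - 1) // 2
    starts = list(range(0, n_samples - w + 1, n))
    if starts[-1] != n_samples - w:
        starts.append(n_samples - w)
    return starts


def adaptive_trend(series: np.ndarray, w: int) -> TrendFit:
    """Stitched global order-2 polynomial trend at scale w.

    Ordinary-least-squares quadratic per segment of length w; adjacent
    segments overlap by (w+1)/2 points and are blended with linear weights
    going 1 -> 0 for the earlier fit across the overlap. The clamped final
    segment (when N-1 is not a multiple of n) blends over its realized,
    deeper overlap. Any polynomial of order <= 2 is reproduced exactly.
    """
    u = np.asarray(series, dtype=float)
    n_samples = u.size
    if w % 2 == 0:
        raise WindowNotOdd(f"w = {w} is even")
    if w < 5:
        raise ValueError("w must be >= 5")
    if w > n_samples:
        raise WindowTooLarge(f"w = {w} > N = {n_samples}")

    a, pinv = _design(w)
    starts = _segment_starts(n_samples, w)
    # all-but-last segments share the stride; fit them in one batch
    seg_idx = np.asarray(starts)[:, None] + np.arange(w)[None, :]
    fits = a @ (pinv @ u[seg_idx].T)          # (w, n_segments)

    trend = np.empty(n_samples)
    covered = 0
    for j, s in enumerate(starts):
        fit = fits[:, j]
        if s >= covered:                       # first segment
            trend[s:s + w] = fit
        else:
            m = covered - s                    # realized overlap length
            if m >= 2:
                lam = np.linspace(0.0, 1.0, m)     # weight of the new fit
                trend[s:covered] = trend[s:covered] * (1.0 - lam) + fit[:m] * lam
            else:
                trend[s:covered] = 0.5 * (trend[s:covered] + fit[:m])
            trend[covered:s + w] = fit[m:]
        covered = s + w
    return TrendFit(trend=trend, window=w)


def fluctuation(series: np.ndarray, w: int) -> float:
    """Root-mean-square deviation of the series from its adaptive trend."""
    u = np.asarray(series, dtype=float)
    v = adaptive_trend(u, w).trend
    return float(np.sqrt(np.mean((u - v) ** 2)))


# --------------------------------------------------------------------------
# fluctuation curve and Hurst fit
# --------------------------------------------------------------------------

def afa_curve(ts: TimeSeries, grid: ScaleGrid, integrate: bool = True) -> FluctuationCurve:
    """F(w) over the grid, computed on the random-walk profile by default.

    Raises :class:`DegenerateFluctuation` when any F(w) is exactly zero
    (e.g. constant input), since the log-log fit is then undefined.
    """
    if grid.windows[-1] > ts.n:
        raise WindowTooLarge(
            f"grid window {grid.windows[-1]} exceeds series length {ts.n}")
    u = integrate_profile(ts).values if integrate else ts.values
    fs = [fluctuation(u, w) for w in grid.windows]
    if any(f == 0.0 for f in fs):
        raise DegenerateFluctuation("zero fluctuation at some scale")
    return FluctuationCurve(tuple(grid.windows), tuple(fs))


def _loglog_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS slope/intercept/r^2; r^2 defined as 1 for an exactly flat y."""
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else max(0.0, 1.0 - ss_res / ss_tot)
    return float(slope), float(intercept), min(r2, 1.0)


def estimate_hurst(curve: FluctuationCurve) -> HurstEstimate:
    """H = OLS slope of log2 F(w) on log2 w (the log-log diffusion plot)."""
    if len(curve.windows) < 3:
        raise TooFewScales("need >= 3 scales for the Hurst fit")
    f = np.asarray(curve.fluctuations)
    if np.any(f <= 0):
        raise NonPositiveFluctuation("all F(w) must be > 0")
    h, intercept, r2 = _loglog_slope(np.log2(curve.windows), np.log2(f))
    return HurstEstimate(h=h, intercept=intercept, r_squared=r2,
                         n_scales=len(curve.windows))


# --------------------------------------------------------------------------
# LFC / HFC decomposition
# --------------------------------------------------------------------------

def decompose_lfc_hfc(ts: TimeSeries, w_lfc: int = 33) -> DecomposedSignal:
    """Split a signal into low- and high-frequency components.

    The LFC is the adaptive order-2 trend at the smallest analysis scale
    (w = 33 by default), i.e. a smooth global piecewise-quadratic fit; the
    HFC is the residual. lfc + hfc reconstructs the input exactly.
    """
    fit = adaptive_trend(ts.values, w_lfc)
    lfc = ts.with_values(fit.trend, label=f"{ts.label}[lfc]" if ts.label else "lfc")
    hfc = ts.with_values(ts.values - fit.trend,
                         label=f"{ts.label}[hfc]" if ts.label else "hfc")
    return DecomposedSignal(lfc=lfc, hfc=hfc, w_lfc=w_lfc)


# --------------------------------------------------------------------------
# multifractal spectrum
# --------------------------------------------------------------------------

def multifractal_spectrum(
    ts: TimeSeries,
    grid: ScaleGrid,
    q_values: tuple[float, ...] = (-2.0, -1.0, 0.0, 1.0, 2.0),
    integrate: bool = True,
) -> MultifractalSpectrum:
    """q-order scaling exponents h(q) from segment-wise fluctuations.

    Per scale, residuals from the stitched adaptive trend are cut into
    floor(N/w) non-overlapping segments; segment RMS values F_seg are
    aggregated as F_q = (mean F_seg^q)^(1/q), with the log-average limit
    exp(mean log F_seg) at q = 0. h(q) is the slope of log2 F_q on log2 w.
    h(2) agrees with the pointwise monofractal estimate up to segment-vs-
    pointwise aggregation (tolerance ~0.05).
    """
    qs = tuple(float(q) for q in q_values)
    if 2.0 not in qs:
        raise ValueError("q_values must contain 2 (monofractal reference)")
    u = integrate_profile(ts).values if integrate else np.asarray(ts.values, float)
    n_samples = u.size

    log_fq = np.empty((len(qs), len(grid.windows)))
    for j, w in enumerate(grid.windows):
        resid = u - adaptive_trend(u, w).trend
        n_seg = n_samples // w
        segs = resid[: n_seg * w].reshape(n_seg, w)
        f_seg = np.sqrt(np.mean(segs ** 2, axis=1))
        if np.any(f_seg == 0.0) and any(q <= 0 for q in qs):
            raise ZeroSegmentFluctuation(
                f"zero segment fluctuation at w = {w} with non-positive q")
        for i, q in enumerate(qs):
            if q == 0.0:
                log_fq[i, j] = np.mean(np.log2(f_seg))
            else:
                log_fq[i, j] = np.log2(np.mean(f_seg ** q)) / q

    log_w = np.log2(grid.windows)
    h_of_q = tuple(_loglog_slope(log_w, log_fq[i])[0] for i in range(len(qs)))
    return MultifractalSpectrum(q_values=qs, h_of_q=h_of_q)


def is_monofractal(mf: MultifractalSpectrum, tol: float = 0.1) -> bool:
    """True when max_q |h(q) - h(2)| <= tol (single-H description adequate)."""
    h2 = mf.h_at(2.0)
    return all(abs(h - h2) <= tol for h in mf.h_of_q)
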