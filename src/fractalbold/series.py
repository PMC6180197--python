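"""Sampled-signal container and elementary signal operations.

A :class:`TimeSeries` is an ordered set of real samples ``u(i)`` with a
fixed sampling interval ``dt`` (seconds; BOLD data here are sampled at
TR = 2 s). All fractal operations in :mod:`fractalbold.afa` act on this
container or on raw sample arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import SeriesTooShort


@dataclass(frozen=True)
class TimeSeries:
    """A single sampled signal.

    Parameters
    ----------
    values : array-like of float
        The samples, length N >= 2, all finite.
    dt : float
        Sampling interval in seconds (> 0). Default 2.0 (fMRI TR).
    label : str
        Free-text label (e.g. region name).
    """

    values: np.ndarray
    dt: float = 2.0
    label: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 2:
            raise ValueError("TimeSeries needs a 1-d array of length >= 2")
        if not np.all(np.isfinite(vals)):
            raise ValueError("TimeSeries values must be finite")
        if not (self.dt > 0):
            raise ValueError("TimeSeries dt must be > 0")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return int(self.values.size)

    def with_values(self, values: np.ndarray, label: str | None = None) -> "TimeSeries":
        return replace(self, values=np.asarray(values, dtype=float),
                       label=self.label if label is None else label)


def integrate_profile(ts: TimeSeries) -> TimeSeries:
    """Random-walk profile: cumulative sum of the mean-centered samples.

    Converts a noise-like series into a walk-like one before fluctuation
    analysis, so that a 1/f (beta = 1) signal scales with H = 1. The last
    profile value is ~0 by construction.
    """
    vals = ts.values
    profile = np.cumsum(vals - vals.mean())
    return ts.with_values(profile)


def linear_detrend(ts: TimeSeries) -> TimeSeries:
    """Remove the ordinary-least-squares straight line in time.

    The output has zero mean and zero covariance with the sample index
    (standard OLS residual properties).
    """
    if ts.n < 3:
        raise SeriesTooShort("linear_detrend needs N >= 3")
    from scipy.signal import detrend as _detrend

    return ts.with_values(_detrend(ts.values, type="linear"))
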