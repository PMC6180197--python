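"""Typed exceptions raised by the fractalbold pipeline.

Degenerate inputs (constant series, empty masks, all-tied samples, ...)
raise one of these instead of propagating NaN through the analysis.
"""


class FractalError(Exception):
    """Base class for all fractalbold errors."""


# --- AFA / spectral ---------------------------------------------------------

class NoValidScales(FractalError):
    """Fewer than three windows survive the scale admissibility rule."""


class WindowNotOdd(FractalError):
    """AFA windows must be odd (w = 2n + 1)."""


class WindowTooLarge(FractalError):
    """Requested window exceeds the series length."""


class DegenerateFluctuation(FractalError):
    """A fluctuation F(w) is exactly zero; log-log fit undefined."""


class TooFewScales(FractalError):
    """Hurst fit needs at least three scales."""


class NonPositiveFluctuation(FractalError):
    """Hurst fit needs strictly positive fluctuations."""


class SeriesTooShort(FractalError):
    """Operation needs a longer series."""


class NonPositivePower(FractalError):
    """Too few positive-power bins remain for the spectral fit."""


class BetaNotFitted(FractalError):
    """Spectral exponent requested before fit_beta was run."""


class ZeroSegmentFluctuation(FractalError):
    """Segment fluctuation is zero with non-positive q order."""


# --- synthetic data ---------------------------------------------------------

class BadBeta(FractalError):
    """Spectral exponent outside the supported synthesis range."""


class EmbeddingFailure(FractalError):
    """Circulant embedding spectrum stayed negative after doubling."""


class RoiOutsideVolume(FractalError):
    """A phantom ROI does not intersect the volume."""


# --- ROI extraction ---------------------------------------------------------

class EmptyMask(FractalError):
    """No voxel center falls inside the sphere."""


class MaskVolumeMismatch(FractalError):
    """Mask geometry does not match the 4D volume."""


# --- statistics -------------------------------------------------------------

class AllTies(FractalError):
    """Every difference equals zero; signed-rank test undefined."""


class LengthMismatch(FractalError):
    """Paired samples of unequal length."""


class EmptyGroup(FractalError):
    """A group sample is empty."""


class ZeroVariance(FractalError):
    """Correlation undefined for a zero-variance input."""


class DegenerateGroups(FractalError):
    """ANOVA needs >= 2 groups with >= 2 values each and some variance."""


class BadPValue(FractalError):
    """A p-value outside [0, 1] was supplied."""


class SingleClass(FractalError):
    """Permutation test needs exactly two label classes, each >= 2."""


class TooFewValues(FractalError):
    """Not enough values for the requested resampling/test."""


class NegativeCount(FractalError):
    """Premature-response counts cannot be negative."""


class EmptyInput(FractalError):
    """Empty input where at least one value is required."""


class IncompleteCohort(FractalError):
    """Cohort table is missing (subject, region, condition) cells."""
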