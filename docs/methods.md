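# Methods

## The model

A scale-free (fractal) signal obeys a power-law spectrum

    S(f) = C_f |f|^(-beta),        beta = 2H - 1,

where `beta` is the spectral exponent and `H` the Hurst exponent of the
noise-type signal. Pink (1/f) noise has `beta = 1`, i.e. `H = 1`; white
noise `beta = 0` (`H = 0.5`); Brownian noise `beta = 2` (`H = 1.5`).
Regional BOLD fluctuations sampled at TR = 2 s sit in this family, and
departures of `H` from 1 quantify departures from pink-noise dynamics.

## Adaptive fractal analysis (AFA)

AFA measures the scaling of fluctuations around an *adaptively* estimated
trend. At scale `w = 2^n + 1` the signal is cut into segments of length
`w` overlapping by `n + 1` points; an ordinary-least-squares quadratic is
fitted per segment, and adjacent fits are blended across the overlap with
linear weights `w1 = 1 - (l-1)/n`, `w2 = (l-1)/n`, giving a globally
smooth trend `v(i)`. When `N - 1` is not a multiple of `n`, the final
segment is clamped to cover the last `w` samples and blended over its
realized (deeper) overlap, so every sample is fitted by a full-width
window. The fluctuation function

    F(w) = sqrt( (1/N) sum_i (u(i) - v(i))^2 )  ~  w^H

is evaluated on the dyadic-plus-one grid `n = 5..13` restricted by an
admissibility rule `w <= floor(N/2)` (at least two windows' worth of
data; at the study lengths N = 425/350 this leaves w = 33, 65, 129). `H`
is the OLS slope of `log2 F(w)` vs `log2 w`; at least three scales are
required. Because each segment trend is an exact quadratic fit, any
polynomial of order <= 2 is annihilated (F below 1e-8 of the signal
range), which the suite verifies property-based.

**Profile integration.** The fluctuation analysis operates by default on
the random-walk profile (cumulative sum of the mean-centered samples).
Only with this step does a `beta = 1` signal scale with `H = 1` as
`beta = 2H - 1` requires; the raw-signal variant is available via
`integrate=False`.

## LFC/HFC decomposition and the pipeline

The signal is split into a low-frequency component (LFC: the adaptive
quadratic trend at a small window) and a high-frequency component (HFC:
the residual); `lfc + hfc` reconstructs the input to 1e-9 relative. The
HFC of 1/f-like input fails the fractality check (its spectrum is not
inversely proportional to frequency), so only the LFC enters the Hurst
analysis.

The full per-series pipeline is

    linear detrend -> LFC (keep) -> profile -> AFA -> H.

**Choice of the pipeline LFC window.** The adaptive trend at window `w`
acts as a low-pass filter with cutoff near scale `w`. If the LFC window
equals the smallest analysis scale (33), the decomposition removes
exactly the content that `F(33)` of the profile measures; on simulated
`beta = 1` noise at N = 425 this inflates the mean estimate from 1.01 to
1.59. The pipeline therefore uses `w_lfc = 5` by default — the
decomposition should strip only sub-analysis-scale noise — while
`decompose_lfc_hfc` keeps a default of 33 for standalone smooth-LFC
inspection, where the goal is a visually faithful low-frequency fit
(e.g. recovering a period-100 sinusoid from SNR-1 noise with r > 0.95).
Measured pipeline bias at the study length: +0.01 at `beta = 1`
(`w_lfc = 5`), within +-0.03 across `beta = 0.5..1.5`.

## Spectral exponent

The periodogram is the plain (untapered, unaveraged) `|DFT|^2 / N` of
the mean-removed series at the positive Fourier frequencies
`k/(N dt)`, `k = 1..N/2`; summed over all N Fourier frequencies it
equals `N * var(u)` (Parseval). `beta` is the negative OLS slope of
`log10 S` vs `log10 f`.

**Fit band.** The fit uses the band `f <= f_max / 4` by default. The DFT
periodogram of scale-free noise flattens toward Nyquist (a sampled random
walk has `E[S(f)] ~ 1/(4 sin^2(pi f))`, not `f^-2`), and since Fourier
frequencies are linearly spaced, an all-band log-log OLS is dominated by
the top octave: its theoretical value for Brownian input is 1.80 rather
than 2. The quarter-band estimator recovers 1.99 (white noise: 0.00),
with `band_fraction=1` exposing the all-band variant. For short spectra
the band is widened to the lowest 8 positive-power bins.

A signal is classified fractal when `beta >= 0.5` and the log-log fit
`r^2 >= 0.8`; both thresholds are conventions exposed as arguments.

## Monofractality check

Per scale, residuals from the stitched trend are cut into `floor(N/w)`
non-overlapping segments; segment RMS values are aggregated as
`F_q(w) = (mean F_seg^q)^(1/q)` for `q != 0` and as the log-average
limit `exp(mean log F_seg)` at `q = 0` (standard q-order practice).
`h(q)` is the slope of `log2 F_q` vs `log2 w` over `q = -2..2`; the
signal is monofractal when `max_q |h(q) - h(2)| <= 0.1`. Segment-wise
`h(2)` agrees with the pointwise estimate within ~0.05 (aggregation
difference). Exact fGn passes the check; a binomial multiplicative
cascade (p = 0.7) fails it with `h(-2) - h(2) > 0.2`.

## Synthetic data

* **Colored noise** (spectral synthesis): Fourier amplitudes
  `f^(-beta/2)`, uniform phases, unit-variance rescale. `beta` in
  [-1, 3].
* **fGn** (Davies–Harte circulant embedding): exact stationary
  fractional Gaussian noise with autocovariance
  `gamma(k) = (|k+1|^2H - 2|k|^2H + |k-1|^2H)/2`, unit theoretical
  variance; the embedding doubles on a negative circulant spectrum.
* **Cohorts**: 103 subjects x 8 regions (rHC, lHC, lMFG, rMFG, ACC,
  rNAcc, lAMY, vmPFC) x 2 conditions (task 425 / rest 350 samples,
  dt = 2 s). Subject-level H ~ Normal(h_mean, 0.12) truncated to
  (0.2, 1.4); per-cell target means: rest 1.00, task 0.92, with a task
  deficit of 0.88 in ACC/rNAcc for the high-impulsivity phenotype —
  magnitudes anchored to the study design, all configurable. Premature
  response counts are drawn phenotype-conditionally on 0..6 with lowImp
  mass below 3 and highImp mass at >= 3, so the `count >= 3` rule
  reproduces the ~66:38 split by construction; accuracy, reward and
  reaction time are generated independent of H (the design's null
  behavioral findings). Time courses are colored noise at
  `beta = 2H - 1`.
* **Phantoms**: 4D volumes with white-noise background and spherical
  ROIs sharing a planted colored-noise signal plus voxel noise
  (SD 0.2), for end-to-end extraction tests.

What the generator does **not** emulate: hemodynamic convolution, head
motion, physiological noise, spatial autocorrelation beyond the planted
ROI signals, or within-subject H variability distinct from
between-subject spread. Passing tests therefore demonstrate estimator
and battery correctness under the stated noise model, not robustness to
real-scanner artifacts.

## ROI extraction

Spheres are defined in mm in the volume's reference frame; a voxel
belongs to the mask when its affine-mapped center lies in the closed
ball (MarsBar-style center-in-sphere convention; no partial-volume
weighting). Extraction is the arithmetic voxel mean per volume; a linear
(OLS) detrend precedes the fractal analysis. Upstream preprocessing
(realignment, normalization, smoothing) is out of scope — the module
analyzes whatever volume it is given. The packaged default ROI set is
the 8-peak waiting-impulsivity network with 10 mm radius.

## Statistical battery

* One-sample Wilcoxon signed-rank vs the hypothetical median 1 (rest),
  paired Wilcoxon (task vs rest; overall and per phenotype),
  Mann-Whitney U (phenotype contrast per condition), Pearson r (or
  Spearman) for behavior–H correlations, and one-way (1 x 2) ANOVA for
  the behavioral measures.
* Wilcoxon/U p-values are exact for tie-free samples with n <= 25
  (enumeration-backed; verified against brute-force oracles) and
  tie-corrected, continuity-corrected normal approximations otherwise;
  `Z` is reported alongside in the clinical-table convention. Exactness
  under midranks is ill-defined, so tied samples always use the
  approximation.
* Multiplicity: Benjamini–Hochberg step-up per family (families: 8
  regional tests per block; 4 behavioral ANOVAs; all computed
  correlation rows). The reported `q* = alpha/m` is the rank-1 BH
  critical value — the corrected per-comparison significance level
  printed alongside FDR control (m = 4 -> 0.0125, m = 8 -> 0.006 at 3
  decimals). Rejection always uses the full step-up rule.
* A label-permutation test (group mean difference, add-one p estimator)
  validates the premature-count grouping; percentile bootstrap supplies
  regional CIs. Both are seeded and vectorized.

Measured operating characteristics (fixed-seed simulations in the
suite): each test's type-I error within [0.03, 0.07] at nominal 0.05;
family-wise false-flag probability under fully null cohorts at or below
`alpha` + 2 Monte-Carlo SE; a strong planted task deficit in ACC/rNAcc
is detected in >= 90% of runs while the rest-condition family stays
clean. Note that with two true effects among 8 BH tests, the chance of
at least one additional false flag is ~10% by construction of the
step-up rule, so "exactly the planted regions and nothing else" cannot
exceed ~90% no matter how large the effect.

## Numerical choices and degenerate inputs

* Segment fits use an order-2 Vandermonde on x scaled to [-1, 1]
  (conditioning at large windows); a shared pseudoinverse per window
  vectorizes the per-segment fits.
* `r^2` of a perfectly flat log-log line is defined as 1 (zero residual
  around a zero-variance target).
* Constant series raise `DegenerateFluctuation` rather than returning
  NaN; the cohort runner logs such cells and continues. Zero-power
  spectral bins are dropped before the beta fit; zero segment
  fluctuations raise with non-positive q.
* All stochastic operations take explicit integer seeds and are pure
  functions of (parameters, seed).

## Problem sizes

Default simulation sizes used by the validation suite and the
acceptance checks: 200 series of N = 425 for the pink-noise
consistency check; 100 series of N = 8192 for the Brownian spectral
exponent; 2000 replicate cohorts (103 x 8) for empirical FDR; 100
truth-model cohorts for planted-effect recovery and 500 for null error
control; 50–100 seeds per point for fGn/colored-noise parameter
recovery. These sizes give Monte-Carlo standard errors comfortably
below the corresponding tolerances.

## Known limitations

* The Hurst estimate at N = 425 rests on three scales (33, 65, 129);
  its single-series SD is ~0.08. Longer series widen the grid and
  stabilize the slope.
* The spectral-exponent estimator fits the raw log-periodogram; for
  steep spectra (beta > ~2.5) scalloping loss and the finite fit band
  compress estimates slightly.
* The cohort model conflates within- and between-subject H variability
  in a single SD (0.12).
* The battery treats regions as separate tests within a family; no
  spatial or cross-region dependence model is attempted.
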