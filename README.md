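# fractalbold

Fractal analysis of BOLD fMRI time series: Hurst-exponent estimation by
**adaptive fractal analysis (AFA)**, spectral-exponent fitting, a
monofractality check, synthetic cohorts with known ground truth, spherical
ROI time-course extraction, and the nonparametric group/condition
statistical battery with false-discovery-rate control.

The package is aimed at researchers who quantify scale-free ("pink
noise") dynamics in regional brain signals — e.g. comparing fractality of
an impulsivity-related network between task and rest, or between high-
and low-impulsivity phenotypes — and at anyone who needs a tested,
seedable AFA/Hurst pipeline with a matching simulation harness.

## The method

A scale-free signal obeys S(f) = C_f |f|^(−β) with β = 2H − 1; pink noise
is β = 1 (H = 1), white noise β = 0 (H = 0.5), Brownian noise β = 2
(H = 1.5). AFA estimates H from the fluctuation function

    F(w) = [ (1/N) Σᵢ (u(i) − v(i))² ]^(1/2)  ~  w^H,

where v(i) is a *globally stitched* trend built from overlapping local
second-order polynomial fits at scale w = 2ⁿ + 1 (n = 5…13, restricted
to w ≤ ⌊N/2⌋), and u is the random-walk profile of the signal. H is the
slope of the log₂–log₂ diffusion plot. The per-series pipeline is:
linear detrend → low-frequency component (the adaptive trend at a small
window; the high-frequency residual is discarded as non-fractal) →
profile → AFA → H. See `docs/methods.md` for the full account.

## Worked example

```python
import fractalbold as fb

# pink noise at the task series length (425 volumes, TR = 2 s)
ts = fb.gen_colored_noise(n=425, beta=1.0, seed=1)
est = fb.hurst_for_series(ts, fb.RunConfig(detrend=False))
print(f"H = {est.h:.3f} (r2 = {est.r_squared:.3f}, {est.n_scales} scales)")
# H = 1.097 (r2 = 1.000, 3 scales)

# spectral exponent of the same series
spec = fb.fit_beta(fb.periodogram(ts))
print(f"beta = {spec.beta:.3f}  ->  H = {fb.h_from_beta(spec.beta):.3f}")
# beta = 1.000  ->  H = 1.000
```

H ≈ 1 and β ≈ 1 say the series is pink noise: the estimate sits on the
1/f reference that the cohort statistics test against (one-sample
Wilcoxon of regional H vs the hypothetical median 1). A single
three-scale estimate carries an SD of ~0.08; averaged over 200 seeds the
pipeline mean is 1.008 (the first acceptance quantity below).

The full study-shaped workflow lives in `analysis/` (thin drivers over
the library; intermediates go to `scratch/`, summary tables to
`results/`):

```bash
python analysis/01_simulate_cohort.py   # 103 subjects x 8 regions x 2 conditions
python analysis/02_estimate_hurst.py    # AFA H for all 1648 series
python analysis/03_group_statistics.py  # the nonparametric battery + FDR
python analysis/04_method_validation.py # estimator recovery on known processes
```

which prints, among other things:

```
phenotype split: {'lowImp': 64, 'highImp': 39} (premature-count threshold >= 3)
estimated H for 1648 series (mean |error| vs truth: 0.069)
pink-noise check at rest: 8/8 regions indistinguishable from H = 1 (q* = 0.0063)
task vs rest: 7/8 regions significantly lower at task
grouping permutation test: D = 2.84, p = 0.0001
```

i.e. the simulated rest condition is statistically pink in every region,
the planted task reduction of H is recovered, and the premature-response
grouping criterion survives a label-permutation check. The same
functionality is exposed as a CLI (`fractalbold simulate / extract /
afa / stats / report`) for file-based use, including mean time-course
extraction from 4D NIfTI volumes with 10 mm spherical ROIs at the
packaged 8-region network coordinates.

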