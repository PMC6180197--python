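"""Synthetic-data generators with known ground truth.

Every pipeline stage has a generator here: colored noise with a chosen
spectral exponent (spectral synthesis), exact fractional Gaussian noise
(Davies-Harte circulant embedding), full simulated cohorts mirroring the
study design (103 subjects x 8 regions x 2 conditions, task series of 425
samples and rest series of 350 at dt = 2 s, an impulsivity phenotype split
driven by integer premature-response counts), and small 4D phantoms with
planted-H spherical ROIs for testing extraction.

All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import BadBeta, EmbeddingFailure, RoiOutsideVolume
from .series import TimeSeries

__all__ = [
    "REGIONS",
    "CONDITIONS",
    "PHENOTYPES",
    "CohortSpec",
    "SyntheticCohort",
    "gen_colored_noise",
    "gen_fgn",
    "fgn_autocov",
    "gen_cohort_h",
    "gen_cohort",
    "gen_phantom",
]

REGIONS = ("rHC", "lHC", "lMFG", "rMFG", "ACC", "rNAcc", "lAMY", "vmPFC")
CONDITIONS = ("task", "rest")
PHENOTYPES = ("lowImp", "highImp")


# --------------------------------------------------------------------------
# colored noise by spectral synthesis
# --------------------------------------------------------------------------

def gen_colored_noise(n: int, beta: float, seed: int, dt: float = 2.0,
                      label: str = "") -> TimeSeries:
    """Colored noise with target spectrum S(f) ~ f^(-beta).

    Spectral synthesis: Fourier amplitudes proportional to f^(-beta/2),
    phases uniform on [0, 2pi), zero DC, inverse transform, rescaled to
    unit sample variance. Deterministic given the seed.
    """
    if n < 16:
        raise ValueError("n must be >= 16")
    if not (-1.0 <= beta <= 3.0):
        raise BadBeta(f"beta = {beta} outside [-1, 3]")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, d=1.0)[1:]          # unit-spacing grid; slope is dt-free
    amps = freqs ** (-beta / 2.0)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=freqs.size)
    spectrum = np.zeros(freqs.size + 1, dtype=complex)
    spectrum[1:] = amps * np.exp(1j * phases)
    if n % 2 == 0:                                  # Nyquist bin must be real
        spectrum[-1] = amps[-1] * np.cos(phases[-1])
    x = np.fft.irfft(spectrum, n)
    x = (x - x.mean()) / x.std()
    return TimeSeries(x, dt=dt, label=label)


# --------------------------------------------------------------------------
# exact fractional Gaussian noise (Davies-Harte)
# --------------------------------------------------------------------------

def fgn_autocov(k: np.ndarray | int, h: float) -> np.ndarray:
    """Closed-form fGn autocovariance gamma(k) for unit-variance fGn."""
    k = np.abs(np.asarray(k, dtype=float))
    return 0.5 * (np.abs(k + 1) ** (2 * h) - 2 * k ** (2 * h)
                  + np.abs(k - 1) ** (2 * h))


def gen_fgn(n: int, h: float, seed: int, dt: float = 2.0,
            label: str = "") -> TimeSeries:
    """Exact stationary fractional Gaussian noise via circulant embedding.

    Unit (theoretical) variance; autocovariance gamma(k) =
    0.5 * (|k+1|^2H - 2|k|^2H + |k-1|^2H). If the circulant spectrum has a
    negative eigenvalue the embedding is doubled; :class:`EmbeddingFailure`
    is raised only if it still fails at 64x the series length.
    """
    if not (0.0 < h < 1.0):
        raise ValueError("h must be in (0, 1)")
    if n < 16:
        raise ValueError("n must be >= 16")
    rng = np.random.default_rng(seed)
    m = n
    while True:
        row = np.concatenate([fgn_autocov(np.arange(m + 1), h),
                              fgn_autocov(np.arange(m - 1, 0, -1), h)])
        lam = np.fft.fft(row).real
        if lam.min() >= -1e-8 * lam.max():
            break
        m *= 2
        if m > 64 * n:
            raise EmbeddingFailure(f"circulant spectrum negative for h = {h}")
    lam = np.clip(lam, 0.0, None)
    g = 2 * m
    v1 = rng.standard_normal(m + 1)
    v2 = rng.standard_normal(m + 1)
    z = np.zeros(g, dtype=complex)
    z[0] = np.sqrt(lam[0]) * v1[0]
    z[m] = np.sqrt(lam[m]) * v1[m]
    j = np.arange(1, m)
    z[j] = np.sqrt(lam[j] / 2.0) * (v1[j] + 1j * v2[j])
    z[g - j] = np.conj(z[j])
    x = np.fft.fft(z).real / np.sqrt(g)
    return TimeSeries(x[:n], dt=dt, label=label)


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------

def _default_h_means() -> dict[tuple[str, str, str], float]:
    """Target H per (region, condition, phenotype).

    Anchored to the magnitudes of the study design: rest ~ 1.00 everywhere,
    task ~ 0.92, with a task deficit (~0.88) in ACC and right NAcc for the
    high-impulsivity phenotype.
    """
    means = {}
    for region in REGIONS:
        for phenotype in PHENOTYPES:
            means[(region, "rest", phenotype)] = 1.00
            task = 0.92
            if phenotype == "highImp" and region in ("ACC", "rNAcc"):
                task = 0.88
            means[(region, "task", phenotype)] = task
    return means


def _default_premature_model() -> dict[str, dict[int, float]]:
    # lowImp mass entirely below 3, highImp at >= 3, so the count >= 3
    # rule reproduces the phenotype split by construction.
    return {
        "lowImp": {0: 0.5, 1: 0.4, 2: 0.1},
        "highImp": {3: 0.7, 4: 0.2, 5: 0.07, 6: 0.03},
    }


@dataclass(frozen=True)
class CohortSpec:
    """Ground-truth model for a simulated study cohort.

    Defaults mirror the study design: 103 subjects, the 8-region waiting-
    impulsivity network, task/rest series of 425/350 samples at dt = 2 s,
    subject-level H ~ Normal(h_mean, h_sd) truncated to h_bounds, and a
    phenotype split of ~66:38 driven by integer premature-response counts.
    """

    n_subjects: int = 103
    regions: tuple[str, ...] = REGIONS
    n_task: int = 425
    n_rest: int = 350
    dt: float = 2.0
    h_means: Mapping[tuple[str, str, str], float] = field(
        default_factory=_default_h_means)
    h_sd: float = 0.12
    h_bounds: tuple[float, float] = (0.2, 1.4)
    premature_model: Mapping[str, Mapping[int, float]] = field(
        default_factory=_default_premature_model)
    phenotype_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"lowImp": 66 / 104, "highImp": 38 / 104})

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need >= 2 subjects")
        for key, mean in self.h_means.items():
            if not (0.0 < mean < 1.5):
                raise ValueError(f"h_mean {mean} for {key} outside (0, 1.5)")
        total = sum(self.phenotype_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("phenotype fractions must sum to 1")
        for phen, dist in self.premature_model.items():
            if any(c < 0 or c > 6 for c in dist):
                raise ValueError("premature counts must lie in 0..6")
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"premature model for {phen} must sum to 1")

    def n_samples(self, condition: str) -> int:
        return self.n_task if condition == "task" else self.n_rest


@dataclass(frozen=True)
class SyntheticCohort:
    """Simulated cohort: time courses, behavior table, and the truth table."""

    timecourses: Mapping[tuple[int, str, str], TimeSeries]
    behavior: pd.DataFrame      # subject, phenotype, premature, accuracy, reward, rt
    truth: pd.DataFrame         # subject, region, condition, h_true, phenotype
    spec: CohortSpec

    def write(self, outdir) -> None:
        """One CSV per (subject, condition) with regions as columns, plus
        behavior.csv and truth.csv."""
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for subject in range(self.spec.n_subjects):
            for condition in CONDITIONS:
                cols = {r: self.timecourses[(subject, r, condition)].values
                        for r in self.spec.regions}
                pd.DataFrame(cols).to_csv(
                    out / f"sub-{subject:03d}_{condition}.csv", index=False)
        self.behavior.to_csv(out / "behavior.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    """Rejection-sampled truncated normal (bounds are several sd wide)."""
    out = rng.normal(mean, sd, size)
    bad = (out <= lo) | (out >= hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out <= lo) | (out >= hi)
    return out


def gen_cohort_h(spec: CohortSpec, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the cohort truth model without synthesizing time series.

    Returns (truth, behavior): ``truth`` has one row per (subject, region,
    condition) with the generating h_true; ``behavior`` one row per subject
    with phenotype, premature count and the H-independent nuisance measures
    (accuracy, reward, reaction time). Used directly for large statistical
    simulations; :func:`gen_cohort` adds the series on top of it.
    """
    rng = np.random.default_rng(seed)
    phens = list(spec.phenotype_fractions)
    probs = [spec.phenotype_fractions[p] for p in phens]
    phenotype = rng.choice(phens, size=spec.n_subjects, p=probs)

    premature = np.empty(spec.n_subjects, dtype=int)
    for phen in phens:
        idx = np.flatnonzero(phenotype == phen)
        dist = spec.premature_model[phen]
        counts = np.array(list(dist), dtype=int)
        premature[idx] = rng.choice(counts, size=idx.size,
                                    p=[dist[c] for c in counts])

    behavior = pd.DataFrame({
        "subject": np.arange(spec.n_subjects),
        "phenotype": phenotype,
        "premature": premature,
        "accuracy": np.clip(rng.normal(0.9, 0.05, spec.n_subjects), 0.0, 1.0),
        "reward": rng.normal(20.0, 5.0, spec.n_subjects),
        "rt": rng.normal(450.0, 60.0, spec.n_subjects),
    })

    rows = []
    for subject in range(spec.n_subjects):
        phen = phenotype[subject]
        for region in spec.regions:
            for condition in CONDITIONS:
                mean = spec.h_means[(region, condition, phen)]
                h = _truncated_normal(rng, mean, spec.h_sd,
                                      *spec.h_bounds, size=1)[0]
                rows.append((subject, region, condition, h, phen))
    truth = pd.DataFrame(rows, columns=["subject", "region", "condition",
                                        "h_true", "phenotype"])
    return truth, behavior


def gen_cohort(spec: CohortSpec, seed: int) -> SyntheticCohort:
    """Full simulated cohort: per-cell colored-noise series at beta = 2H - 1.

    Subject-level H is drawn from the truth model; each time course is
    spectral-synthesis noise at the corresponding spectral exponent with
    the condition's series length. Bit-identical for a fixed seed.
    """
    truth, behavior = gen_cohort_h(spec, seed)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5E51E5]))
    timecourses: dict[tuple[int, str, str], TimeSeries] = {}
    for row in truth.itertuples(index=False):
        beta = 2.0 * row.h_true - 1.0
        child = int(rng.integers(0, 2 ** 31 - 1))
        timecourses[(row.subject, row.region, row.condition)] = gen_colored_noise(
            spec.n_samples(row.condition), beta, child, dt=spec.dt,
            label=f"sub-{row.subject:03d}/{row.region}/{row.condition}")
    return SyntheticCohort(timecourses=timecourses, behavior=behavior,
                           truth=truth, spec=spec)


# --------------------------------------------------------------------------
# 4D phantom
# --------------------------------------------------------------------------

def gen_phantom(shape: tuple[int, int, int], n_volumes: int,
                affine: np.ndarray, roi_specs: Sequence[tuple],
                seed: int, voxel_noise_sd: float = 0.2):
    """4D phantom volume with planted fractal ROI signals.

    Background voxels are white noise; voxels inside each spherical ROI
    share one colored-noise signal at the ROI's Hurst exponent (beta =
    2H - 1) plus independent voxel noise of SD ``voxel_noise_sd``.
    ``roi_specs`` is a sequence of (RoiDef, h) pairs. Returns a
    ``nibabel.Nifti1Image`` with the given affine.
    """
    import nibabel as nib

    from .roi import sphere_mask

    if min(shape) < 16:
        raise ValueError("phantom dims must be >= 16 in every axis")
    if n_volumes < 64:
        raise ValueError("phantom needs >= 64 volumes")
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((*shape, n_volumes))
    for roi, h in roi_specs:
        try:
            mask = sphere_mask(roi, affine, shape)
        except Exception as exc:
            raise RoiOutsideVolume(f"ROI {roi.label} outside phantom") from exc
        signal = gen_colored_noise(n_volumes, 2.0 * h - 1.0,
                                   int(rng.integers(0, 2 ** 31 - 1))).values
        i, j, k = mask.indices.T
        data[i, j, k, :] = (signal[None, :]
                            + voxel_noise_sd
                            * rng.standard_normal((mask.n_voxels, n_volumes)))
    return nib.Nifti1Image(data.astype(np.float32), affine)
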