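"""Nonparametric group/condition statistics over a cohort H table.

The battery mirrors a two-condition (task/rest), two-phenotype
(lowImp/highImp) regional Hurst-exponent study design:

* one-sample Wilcoxon signed-rank tests of H against the hypothetical
  median 1 (the pink-noise reference) per region at rest;
* paired Wilcoxon tests task vs rest, overall and per phenotype;
* Mann-Whitney U tests between phenotypes per region and condition;
* correlations between behavioral measures and H;
* one-way (1 x 2) ANOVA of the behavioral measures by phenotype;
* Benjamini-Hochberg FDR control per test family, reporting the
  rank-1 critical value q* = alpha / m alongside the step-up rule;
* a label-permutation test validating the phenotype grouping, and
  percentile bootstrap confidence intervals.

Wilcoxon and Mann-Whitney p-values are exact (enumeration) for small
tie-free samples and tie-corrected, continuity-corrected normal
approximations otherwise; Z statistics mirror the reporting convention
of clinical tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    AllTies,
    BadPValue,
    DegenerateGroups,
    EmptyGroup,
    EmptyInput,
    IncompleteCohort,
    LengthMismatch,
    NegativeCount,
    SingleClass,
    TooFewValues,
    ZeroVariance,
)
from .synth import CONDITIONS, PHENOTYPES

__all__ = [
    "TestResult",
    "FdrResult",
    "CohortTable",
    "StatsConfig",
    "classify_phenotype",
    "median_threshold",
    "wilcoxon_one_sample",
    "wilcoxon_paired",
    "mannwhitney_u",
    "pearson_corr",
    "oneway_anova",
    "bh_fdr",
    "permutation_group_test",
    "bootstrap_ci",
    "run_full_analysis",
]

EXACT_N_MAX = 25     # exact signed-rank/U enumeration up to here (tie-free)


@dataclass(frozen=True)
class TestResult:
    """A single test: statistic name (Z, U, W, F, r, D), value, two-sided p."""

    statistic_name: str
    statistic: float
    p: float
    n: tuple[int, ...]
    extra: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p = {self.p} outside [0, 1]")


@dataclass(frozen=True)
class FdrResult:
    """Benjamini-Hochberg outcome for one family of m tests."""

    m: int
    alpha: float
    q_star: float            # rank-1 critical value alpha / m
    rejected: tuple[bool, ...]


# --------------------------------------------------------------------------
# phenotype classification
# --------------------------------------------------------------------------

def classify_phenotype(premature_count: int, threshold: int = 3) -> str:
    """highImp iff the premature-response count >= threshold (default 3)."""
    if premature_count < 0:
        raise NegativeCount(f"count = {premature_count}")
    return "highImp" if premature_count >= threshold else "lowImp"


def median_threshold(counts: Sequence[int]) -> int:
    """Sample median of the counts, rounded up to the next integer."""
    if len(counts) == 0:
        raise EmptyInput("median_threshold needs at least one count")
    return int(math.ceil(float(np.median(counts))))


# --------------------------------------------------------------------------
# rank tests
# --------------------------------------------------------------------------

def _signed_rank_z(d: np.ndarray) -> tuple[float, float]:
    """Continuity-corrected, tie-corrected normal Z for the signed-rank sum.

    Returns (W_plus, z)."""
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    tie_sum = sum(t ** 3 - t for t in np.unique(np.abs(d), return_counts=True)[1])
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie_sum / 48.0
    diff = w_plus - mu
    cc = 0.5 * np.sign(diff)
    z = (diff - cc) / math.sqrt(sigma2) if sigma2 > 0 else 0.0
    return w_plus, float(z)


def wilcoxon_one_sample(values: Sequence[float],
                        hypothetical_median: float = 1.0) -> TestResult:
    """One-sample Wilcoxon signed-rank test against a hypothetical median.

    Zero differences are dropped (signed-rank convention). Exact
    enumeration p for tie-free samples with n <= 25, otherwise the
    continuity-corrected normal approximation with tie correction.
    """
    d = np.asarray(values, dtype=float) - hypothetical_median
    d = d[d != 0.0]
    if d.size == 0:
        raise AllTies("every value equals the hypothetical median")
    if d.size < 6:
        raise TooFewValues("need >= 6 nonzero differences")
    w_plus, z = _signed_rank_z(d)
    tie_free = np.unique(np.abs(d)).size == d.size
    if d.size <= EXACT_N_MAX and tie_free:
        p = float(sps.wilcoxon(d, alternative="two-sided", method="exact").pvalue)
    else:
        p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return TestResult("Z", z, p, (int(d.size),), {"W_plus": w_plus})


def wilcoxon_paired(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Related-samples Wilcoxon signed-rank test on a - b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise LengthMismatch(f"{a.size} vs {b.size}")
    return wilcoxon_one_sample(a - b, hypothetical_median=0.0)


def mannwhitney_u(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Mann-Whitney U test for two independent samples.

    U is the statistic of sample ``a`` (number of (a, b) pairs with
    a > b, ties half-counted); Z is reported alongside from the
    tie-corrected, continuity-corrected normal approximation. Exact p for
    small tie-free samples.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise EmptyGroup("both groups must be nonempty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (tie_free and max(n1, n2) <= EXACT_N_MAX) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    u1 = float(res.statistic)
    mu = n1 * n2 / 2.0
    n = n1 + n2
    tie_sum = sum(t ** 3 - t for t in np.unique(pooled, return_counts=True)[1])
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_sum / (n * (n - 1)))
    diff = u1 - mu
    z = (diff - 0.5 * np.sign(diff)) / math.sqrt(sigma2) if sigma2 > 0 else 0.0
    return TestResult("Z", float(z), float(res.pvalue), (n1, n2), {"U": u1})


# --------------------------------------------------------------------------
# correlation / ANOVA
# --------------------------------------------------------------------------

def pearson_corr(x: Sequence[float], y: Sequence[float],
                 method: str = "pearson") -> TestResult:
    """Pearson r (default) or Spearman rho with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise LengthMismatch(f"{x.size} vs {y.size}")
    if x.size < 4:
        raise TooFewValues("need >= 4 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ZeroVariance("correlation undefined for constant input")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return TestResult("r", float(r), float(p), (int(x.size),))


def oneway_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way ANOVA; with two groups this equals the squared pooled t."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(g.size < 2 for g in arrays):
        raise DegenerateGroups("need >= 2 groups with >= 2 values each")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        raise DegenerateGroups("all values identical")
    f, p = sps.f_oneway(*arrays)
    k = len(arrays)
    n = pooled.size
    return TestResult("F", float(f), float(p),
                      tuple(int(g.size) for g in arrays),
                      {"df1": float(k - 1), "df2": float(n - k)})


# --------------------------------------------------------------------------
# multiplicity / resampling
# --------------------------------------------------------------------------

def bh_fdr(pvals: Sequence[float], alpha: float = 0.05) -> FdrResult:
    """Benjamini-Hochberg step-up rule at family level alpha.

    The reported q* is the rank-1 critical value alpha / m (the corrected
    per-comparison significance level quoted alongside FDR control);
    rejection uses the full step-up rule.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size < 1:
        raise EmptyInput("need at least one p-value")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise BadPValue("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    rejected = multipletests(p, alpha=alpha, method="fdr_bh")[0]
    return FdrResult(m=int(p.size), alpha=alpha, q_star=alpha / p.size,
                     rejected=tuple(bool(r) for r in rejected))


def permutation_group_test(values: Sequence[float], labels: Sequence,
                           n_perm: int = 10000, seed: int = 0) -> TestResult:
    """Label-permutation test of the difference in group means.

    p = (1 + #{|stat_perm| >= |stat_obs|}) / (n_perm + 1) with labels
    shuffled uniformly. Validates a grouping criterion (e.g. the
    premature-response threshold) without distributional assumptions.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size != 2 or counts.min() < 2:
        raise SingleClass("need exactly two label classes with >= 2 members")
    in_a = labels == classes[0]
    n1 = int(in_a.sum())
    observed = values[in_a].mean() - values[~in_a].mean()
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.broadcast_to(values, (n_perm, values.size)).copy(),
                         axis=1)
    stat = perms[:, :n1].mean(axis=1) - perms[:, n1:].mean(axis=1)
    p = (1.0 + np.count_nonzero(np.abs(stat) >= abs(observed))) / (n_perm + 1.0)
    return TestResult("D", float(observed), float(p),
                      (n1, int(values.size - n1)))


_STAT_FUNCS: dict[str, Callable] = {"mean": np.mean, "median": np.median}


def bootstrap_ci(values: Sequence[float], stat: str | Callable = "mean",
                 b: int = 1000, level: float = 0.95,
                 seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap confidence interval of a summary statistic."""
    values = np.asarray(values, dtype=float)
    if values.size < 3:
        raise TooFewValues("bootstrap needs >= 3 values")
    func = _STAT_FUNCS[stat] if isinstance(stat, str) else stat
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, values.size, size=(b, values.size))
    boots = func(values[idx], axis=1)
    lo, hi = np.percentile(boots, [50 * (1 - level), 100 - 50 * (1 - level)])
    return float(lo), float(hi)


# --------------------------------------------------------------------------
# cohort table and the full battery
# --------------------------------------------------------------------------

BEHAVIOR_MEASURES = ("premature", "accuracy", "reward", "rt")


@dataclass(frozen=True)
class CohortTable:
    """Subjects x regions x conditions H values joined to behavior.

    ``h``: long table with columns subject, region, condition, h.
    ``behavior``: one row per subject with phenotype, premature, accuracy,
    reward, rt.
    """

    h: pd.DataFrame
    behavior: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("subject", "region", "condition", "h"):
            if col not in self.h.columns:
                raise ValueError(f"h table missing column {col!r}")
        for col in ("subject", "phenotype", *BEHAVIOR_MEASURES):
            if col not in self.behavior.columns:
                raise ValueError(f"behavior table missing column {col!r}")
        bad_cond = set(self.h["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise ValueError(f"unknown conditions {bad_cond}")
        bad_phen = set(self.behavior["phenotype"]) - set(PHENOTYPES)
        if bad_phen:
            raise ValueError(f"unknown phenotypes {bad_phen}")
        if self.h.duplicated(["subject", "region", "condition"]).any():
            raise ValueError("duplicate (subject, region, condition) rows")

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(pd.unique(self.h["region"]))

    def merged(self) -> pd.DataFrame:
        return self.h.merge(self.behavior, on="subject", validate="many_to_one")

    def check_complete(self) -> None:
        counts = self.h.groupby("subject").size()
        expected = len(self.regions) * len(CONDITIONS)
        subjects = set(self.behavior["subject"])
        if set(self.h["subject"]) != subjects or (counts != expected).any():
            raise IncompleteCohort("missing (subject, region, condition) cells")


def _msd(x: pd.Series) -> str:
    return f"{x.mean():.2f} ({x.std(ddof=1):.2f})"


@dataclass(frozen=True)
class StatsConfig:
    """Knobs of the statistical battery."""

    alpha: float = 0.05
    correlation_method: str = "pearson"     # or "spearman"
    correlation_condition: str = "task"
    hypothetical_median: float = 1.0
    pink_noise_condition: str = "rest"


def run_full_analysis(cohort: CohortTable,
                      config: StatsConfig | None = None) -> dict[str, pd.DataFrame]:
    """The full statistical battery; returns the five report tables.

    1. ``pink_noise``: per-region one-sample Wilcoxon of rest H vs the
       hypothetical median 1, BH-FDR over the 8 regions.
    2. ``task_vs_rest``: paired Wilcoxon task vs rest, overall and per
       phenotype (one BH family of 8 per column block).
    3. ``phenotype``: Mann-Whitney lowImp vs highImp per region, task and
       rest blocks (one BH family of 8 each).
    4. ``correlations``: behavioral measures x regions against H in the
       configured condition, one BH family over all computed rows.
    5. ``behavior_anova``: one-way ANOVA of each behavioral measure by
       phenotype, BH family of 4.
    """
    cfg = config or StatsConfig()
    cohort.check_complete()
    df = cohort.merged()
    regions = list(cohort.regions)
    alpha = cfg.alpha

    def attach_fdr(table: pd.DataFrame, pcol: str = "p") -> pd.DataFrame:
        fdr = bh_fdr(table[pcol].to_numpy(), alpha)
        table = table.copy()
        table["significant"] = fdr.rejected
        table["q_star"] = round(fdr.q_star, 4)
        return table

    # 1 -- pink noise at rest
    rows = []
    rest = df[df["condition"] == cfg.pink_noise_condition]
    for region in regions:
        h = rest.loc[rest["region"] == region, "h"]
        res = wilcoxon_one_sample(h, cfg.hypothetical_median)
        rows.append({"region": region, "M(SD)": _msd(h),
                     "Z": res.statistic, "p": res.p})
    pink = attach_fdr(pd.DataFrame(rows))

    # 2 -- task vs rest (overall / lowImp / highImp), paired per subject
    wide = df.pivot_table(index=["subject", "region", "phenotype"],
                          columns="condition", values="h").reset_index()
    blocks: dict[str, pd.DataFrame] = {
        "overall": wide,
        "lowImp": wide[wide["phenotype"] == "lowImp"],
        "highImp": wide[wide["phenotype"] == "highImp"],
    }
    rows = []
    for region in regions:
        row: dict = {"region": region}
        for name, block in blocks.items():
            sub = block[block["region"] == region]
            res = wilcoxon_paired(sub["task"], sub["rest"])
            row[f"{name}_task"] = _msd(sub["task"])
            row[f"{name}_rest"] = _msd(sub["rest"])
            row[f"{name}_Z"] = res.statistic
            row[f"{name}_p"] = res.p
        rows.append(row)
    task_rest = pd.DataFrame(rows)
    for name in blocks:
        fdr = bh_fdr(task_rest[f"{name}_p"].to_numpy(), alpha)
        task_rest[f"{name}_significant"] = fdr.rejected
    task_rest["q_star"] = round(alpha / len(regions), 4)

    # 3 -- phenotype contrast per condition
    rows = []
    for condition in CONDITIONS:
        sub = df[df["condition"] == condition]
        for region in regions:
            cell = sub[sub["region"] == region]
            low = cell.loc[cell["phenotype"] == "lowImp", "h"]
            high = cell.loc[cell["phenotype"] == "highImp", "h"]
            res = mannwhitney_u(low, high)
            rows.append({"condition": condition, "region": region,
                         "lowImp_M(SD)": _msd(low), "highImp_M(SD)": _msd(high),
                         "Z": res.statistic, "p": res.p})
    phenotype = pd.DataFrame(rows)
    parts = []
    for condition in CONDITIONS:
        parts.append(attach_fdr(
            phenotype[phenotype["condition"] == condition]))
    phenotype = pd.concat(parts, ignore_index=True)

    # 4 -- behavior x H correlations in the configured condition
    cond_df = df[df["condition"] == cfg.correlation_condition]
    rows = []
    for measure in BEHAVIOR_MEASURES:
        for region in regions:
            cell = cond_df[cond_df["region"] == region]
            res = pearson_corr(cell[measure], cell["h"],
                               method=cfg.correlation_method)
            rows.append({"measure": measure, "region": region,
                         "r": res.statistic, "p": res.p})
    correlations = attach_fdr(pd.DataFrame(rows))

    # 5 -- behavioral ANOVA by phenotype
    rows = []
    for measure in BEHAVIOR_MEASURES:
        groups = [cohort.behavior.loc[cohort.behavior["phenotype"] == ph,
                                      measure] for ph in PHENOTYPES]
        res = oneway_anova(groups)
        rows.append({"measure": measure, "F": res.statistic,
                     "df1": res.extra["df1"], "df2": res.extra["df2"],
                     "p": res.p})
    anova = attach_fdr(pd.DataFrame(rows))

    return {"pink_noise": pink, "task_vs_rest": task_rest,
            "phenotype": phenotype, "correlations": correlations,
            "behavior_anova": anova}
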