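"""End-to-end Hurst pipeline, run configuration, and report emission.

The per-series pipeline is: linear detrend -> LFC/HFC decomposition (keep
the LFC) -> random-walk profile -> adaptive fractal analysis over the
admissible scale grid -> Hurst estimate from the log-log diffusion plot.

The pipeline's LFC window defaults to 5 samples: the decomposition must
remove only sub-analysis-scale noise, and a trend window approaching the
smallest analysis scale (w = 33) suppresses F(33) itself and inflates H
(see docs/methods.md). ``decompose_lfc_hfc`` keeps its own default of 33
for standalone smooth-LFC use.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .afa import (
    FluctuationCurve,
    HurstEstimate,
    afa_curve,
    decompose_lfc_hfc,
    estimate_hurst,
    make_scale_grid,
)
from .errors import FractalError
from .series import TimeSeries, linear_detrend
from .stats import CohortTable, StatsConfig
from .synth import SyntheticCohort

__all__ = [
    "RunConfig",
    "hurst_for_series",
    "curve_for_series",
    "cohort_hurst_table",
    "read_timecourses",
    "write_hurst_table",
    "write_report_tables",
    "write_manifest",
]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full analysis run (JSON-serializable).

    Scale-grid bounds follow w = 2^n + 1, n = n_min..n_max with the
    admissibility rule w <= floor(N/2).
    """

    n_min: int = 5
    n_max: int = 13
    w_lfc: int = 5            # pipeline LFC window; see module docstring
    integrate: bool = True
    detrend: bool = True
    decompose: bool = True
    alpha: float = 0.05
    dt: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (2 <= self.n_min <= self.n_max):
            raise ValueError("need 2 <= n_min <= n_max")
        if self.w_lfc < 5 or self.w_lfc % 2 == 0:
            raise ValueError("w_lfc must be odd and >= 5")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def stats_config(self) -> StatsConfig:
        return StatsConfig(alpha=self.alpha)


def curve_for_series(ts: TimeSeries, config: RunConfig) -> FluctuationCurve:
    """Detrend -> decompose (keep LFC) -> profile -> fluctuation curve."""
    from .errors import DegenerateFluctuation

    if np.ptp(ts.values) == 0:
        # detrending would reduce a constant column to float dust, whose
        # "fluctuations" are numerical noise, not signal
        raise DegenerateFluctuation("constant series")
    if config.detrend:
        ts = linear_detrend(ts)
    if config.decompose:
        ts = decompose_lfc_hfc(ts, config.w_lfc).lfc
    grid = make_scale_grid(config.n_min, config.n_max, ts.n)
    return afa_curve(ts, grid, integrate=config.integrate)


def hurst_for_series(ts: TimeSeries, config: RunConfig | None = None) -> HurstEstimate:
    """Full per-series pipeline ending in the Hurst estimate."""
    return estimate_hurst(curve_for_series(ts, config or RunConfig()))


def cohort_hurst_table(
    cohort: SyntheticCohort, config: RunConfig | None = None
) -> tuple[CohortTable, list[dict]]:
    """AFA over every (subject, region, condition) cell of a cohort.

    Degenerate cells (zero fluctuation, too few scales) are skipped and
    returned in the failure list; the run continues.
    """
    config = config or RunConfig()
    rows, failures = [], []
    for (subject, region, condition), ts in cohort.timecourses.items():
        try:
            est = hurst_for_series(ts, config)
        except FractalError as exc:
            failures.append({"subject": subject, "region": region,
                             "condition": condition,
                             "error": type(exc).__name__, "detail": str(exc)})
            continue
        rows.append({"subject": subject, "region": region,
                     "condition": condition, "h": est.h,
                     "intercept": est.intercept, "r2": est.r_squared,
                     "n_scales": est.n_scales})
    table = pd.DataFrame(rows)
    return CohortTable(h=table, behavior=cohort.behavior), failures


# --------------------------------------------------------------------------
# I/O
# --------------------------------------------------------------------------

def read_timecourses(path, dt: float = 2.0) -> dict[str, TimeSeries]:
    """Read a multi-column time-course table (header row = region labels,
    one row per volume) into labelled TimeSeries."""
    df = pd.read_csv(path, sep=None, engine="python")
    return {col: TimeSeries(df[col].to_numpy(dtype=float), dt=dt, label=col)
            for col in df.columns}


def write_curve_table(curves: dict[tuple[str, str], FluctuationCurve], path) -> None:
    """FluctuationCurve table: region, condition, w, F_w."""
    rows = [
        {"region": region, "condition": condition, "w": w, "F_w": f}
        for (region, condition), curve in curves.items()
        for w, f in zip(curve.windows, curve.fluctuations)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def write_hurst_table(table: CohortTable, path) -> None:
    table.h.to_csv(path, index=False)


def write_report_tables(tables: dict[str, pd.DataFrame], outdir) -> list[Path]:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, table in tables.items():
        p = out / f"{name}.csv"
        table.to_csv(p, index=False)
        paths.append(p)
    return paths


def write_manifest(outdir, config: RunConfig, extra: dict | None = None) -> Path:
    """Reproducibility manifest: config echo, seed and versions."""
    import scipy

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_dict(),
        "versions": {"fractalbold": __version__, "numpy": np.__version__,
                     "scipy": scipy.__version__, "pandas": pd.__version__},
    }
    if extra:
        manifest.update(extra)
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def diffusion_plot(curve: FluctuationCurve, est: HurstEstimate, path,
                   title: str = "") -> None:
    """Log-log diffusion plot of F(w) with the fitted slope H."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    w = np.asarray(curve.windows, dtype=float)
    f = np.asarray(curve.fluctuations, dtype=float)
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.plot(np.log2(w), np.log2(f), "o", color="k")
    ax.plot(np.log2(w), est.h * np.log2(w) + est.intercept, "-",
            label=f"H = {est.h:.2f} (r$^2$ = {est.r_squared:.2f})")
    ax.set_xlabel("log$_2$ w")
    ax.set_ylabel("log$_2$ F(w)")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
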