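import numpy as np
import pytest

import fractalbold as fb
from fractalbold.stats import CohortTable
from fractalbold.synth import PHENOTYPES, REGIONS


def table_from_truth(spec: fb.CohortSpec, seed: int) -> CohortTable:
    """Cohort H table taken directly from the generating truth model
    (no time-series synthesis); used for large statistical simulations."""
    truth, behavior = fb.gen_cohort_h(spec, seed)
    h = truth.rename(columns={"h_true": "h"})[
        ["subject", "region", "condition", "h"]]
    return CohortTable(h=h, behavior=behavior)


def flat_h_means(task: float = 1.0, rest: float = 1.0,
                 overrides: dict | None = None) -> dict:
    means = {}
    for region in REGIONS:
        for phen in PHENOTYPES:
            means[(region, "rest", phen)] = rest
            means[(region, "task", phen)] = task
    if overrides:
        means.update(overrides)
    return means


@pytest.fixture(scope="session")
def task_grid() -> fb.ScaleGrid:
    """Admissible scale grid for the task series length (N = 425)."""
    return fb.make_scale_grid(5, 13, 425)


@pytest.fixture(scope="session")
def long_grid() -> fb.ScaleGrid:
    return fb.make_scale_grid(5, 13, 4096)


@pytest.fixture(scope="session")
def small_cohort() -> fb.SyntheticCohort:
    """A reduced synthetic cohort for end-to-end tests (seed chosen so both
    phenotypes have enough members for the paired tests)."""
    return fb.gen_cohort(fb.CohortSpec(n_subjects=30), seed=42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
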