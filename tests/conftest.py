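import numpy as np
import pytest

from fatiguerisk.hrv import NormTable, default_norm_table
from fatiguerisk.synthetic import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def norms() -> NormTable:
    return default_norm_table()


@pytest.fixture(scope="session")
def small_cohort():
    """A small cohort with RRI recordings and warning events (shared)."""
    spec = CohortSpec(n_drivers=3, n_days=3, seed=11, mean_wt_hours=4.0)
    return spec, generate_cohort(spec)


@pytest.fixture(scope="session")
def score_cohort():
    """A score-only cohort (no beat/trace synthesis) for association tests."""
    spec = CohortSpec(n_drivers=10, n_days=8, seed=21)
    return spec, generate_cohort(spec, include_rri=False, include_events=False)
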